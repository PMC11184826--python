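"""Matrix profile, annotation vector and corrected-matrix-profile selection."""

import numpy as np
import pytest

from gaitseg import select_reference_stride
from gaitseg.errors import (ArgumentError, DegenerateSignalError,
                            SignalTooShortError)
from gaitseg.io_preproc import DerivedSignals
from gaitseg.motif import (annotation_vector, corrected_matrix_profile,
                           matrix_profile)


def brute_force_mp(x, m):
    """All-pairs z-normalized distance scan (independent oracle)."""
    x = np.asarray(x, dtype=float)
    w = len(x) - m + 1
    Z = np.empty((w, m))
    for i in range(w):
        win = x[i:i + m]
        sd = win.std()
        Z[i] = (win - win.mean()) / sd if sd > 1e-12 else 0.0
    excl = max(1, int(round(m / 2)))
    mp = np.full(w, np.inf)
    for i in range(w):
        for j in range(w):
            if abs(i - j) < excl:
                continue
            d = np.sqrt(((Z[i] - Z[j]) ** 2).sum())
            mp[i] = min(mp[i], d)
    return mp


def brute_force_av(omega, jerk, m, use_jerk=True):
    """Direct evaluation of the central-third annotation sum."""
    omax = np.abs(omega).max()
    jmax = jerk.max()
    w = len(omega) - m + 1
    av = np.zeros(w)
    for i in range(w):
        for k in range(i + m // 3, i + (2 * m) // 3 + 1):
            av[i] += omega[k] / omax
            if use_jerk and jmax > 0:
                av[i] += jerk[k] / jmax
    return av


class TestMatrixProfile:
    def test_periodic_series_near_zero(self):
        P = 50
        x = np.sin(2 * np.pi * np.arange(10 * P) / P)
        mp, _ = matrix_profile(x, P)
        assert mp.max() < 1e-6

    def test_monotone_ramp_degenerate(self):
        mp, _ = matrix_profile(np.arange(200, dtype=float), 20)
        assert mp.max() < 1e-6

    def test_embedded_pattern_pair(self, rng):
        n, m = 300, 25
        x = rng.normal(scale=0.5, size=n)
        pattern = 5 * np.sin(np.linspace(0, 2 * np.pi, m))
        x[40:40 + m] += pattern
        x[200:200 + m] += pattern
        mp, nn = matrix_profile(x, m)
        best = int(np.argmin(mp))
        assert min(abs(best - 40), abs(best - 200)) <= 2
        assert min(abs(nn[best] - 40), abs(nn[best] - 200)) <= 2

    @pytest.mark.parametrize("seed,n,m", [(0, 200, 16), (1, 400, 25), (2, 500, 50)])
    def test_equals_brute_force(self, seed, n, m):
        x = np.random.default_rng(seed).normal(size=n)
        mp, _ = matrix_profile(x, m)
        assert np.abs(mp - brute_force_mp(x, m)).max() < 1e-6

    def test_too_short(self):
        with pytest.raises(SignalTooShortError):
            matrix_profile(np.zeros(30), 20)

    def test_m_too_small(self):
        with pytest.raises(ArgumentError):
            matrix_profile(np.zeros(30), 3)


class TestAnnotationVector:
    def test_saturated_signal_worked_example(self):
        # omega == omega_max and jerk == j_max everywhere, m=6:
        # 3 inclusive central-third terms x 2 channels = 6
        n, m = 30, 6
        av = annotation_vector(np.ones(n), np.ones(n), m, rescale=False)
        assert np.allclose(av, 6.0)
        # flat raw vector rescales to all ones (no CMP correction)
        assert np.allclose(annotation_vector(np.ones(n), np.ones(n), m), 1.0)

    def test_matches_direct_summation(self, rng):
        omega = rng.normal(size=150)
        jerk = np.abs(rng.normal(size=150))
        for m in (9, 12, 30):
            got = annotation_vector(omega, jerk, m, rescale=False)
            assert np.allclose(got, brute_force_av(omega, jerk, m))

    def test_central_bump_maximizes_centered_window(self):
        n, m = 200, 60
        omega = np.zeros(n)
        c = 100
        omega += 10 * np.exp(-0.5 * ((np.arange(n) - c) / 3.0) ** 2)
        jerk = np.full(n, 0.1)
        av = annotation_vector(omega, jerk, m, rescale=False)
        assert abs(int(np.argmax(av)) - (c - m // 2)) <= 2

    def test_all_negative_omega_is_finite(self):
        av = annotation_vector(-np.abs(np.sin(np.arange(50.0))) - 0.1,
                               np.zeros(50), 9, rescale=False)
        assert np.isfinite(av).all()

    def test_zero_omega_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            annotation_vector(np.zeros(50), np.zeros(50), 9)

    def test_gyration_only_drops_jerk_term(self, rng):
        omega = rng.normal(size=100)
        jerk = np.abs(rng.normal(size=100))
        got = annotation_vector(omega, jerk, 12, rescale=False, use_jerk=False)
        assert np.allclose(got, brute_force_av(omega, jerk, 12, use_jerk=False))


class TestCorrectedMatrixProfile:
    def test_av_one_identity(self, rng):
        mp = np.abs(rng.normal(size=50))
        assert np.array_equal(corrected_matrix_profile(mp, np.ones(50)), mp)

    def test_av_zero_uniform_shift(self, rng):
        mp = np.abs(rng.normal(size=50))
        out = corrected_matrix_profile(mp, np.zeros(50))
        assert np.allclose(out, mp + mp.max())
        assert np.argmin(out) == np.argmin(mp)

    def test_correction_moves_argmin(self):
        mp = np.array([1.0, 0.5, 0.6, 2.0])
        av = np.array([0.5, 0.0, 1.0, 0.5])
        out = corrected_matrix_profile(mp, av)
        assert np.allclose(out, mp + (1 - av) * 2.0)
        assert np.argmin(out) == 2  # moved from index 1 to the favored index

    def test_cmp_dominates_mp(self, rng):
        mp = np.abs(rng.normal(size=80))
        av = rng.uniform(size=80)
        assert np.all(corrected_matrix_profile(mp, av) >= mp - 1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ArgumentError):
            corrected_matrix_profile(np.zeros(5), np.zeros(6))


class TestSelectReferenceStride:
    def test_healthy_walk_overlaps_true_stride(self, healthy_walk):
        sig = healthy_walk.left
        m = 130
        res = select_reference_stride(sig, m)
        starts = np.array([w.start for w in healthy_walk.stride_windows["left"]])
        assert np.abs(starts - res.start).min() <= 0.15 * m
        # swing peak inside the central third of the chosen window
        peak = int(np.argmax(sig.omega[res.start:res.start + m]))
        assert m // 3 <= peak <= (2 * m) // 3

    def test_two_stride_minimal_signal(self):
        P = 60
        x = np.sin(2 * np.pi * np.arange(2 * P) / P)
        jerk = 1 + np.cos(2 * np.pi * np.arange(2 * P) / P)
        # the motif itself: the only exact repeat pair is the two strides
        mp, nn = matrix_profile(x, P)
        assert int(np.argmin(mp)) in (0, P)
        assert np.abs(mp - brute_force_mp(x, P)).max() < 1e-6
        # the composed selection additionally centers the gyration hump
        res = select_reference_stride(DerivedSignals(x, jerk, 100.0), P)
        peak = int(np.argmax(x[res.start:res.start + P]))
        assert P // 3 <= peak <= (2 * P) // 3

    def test_too_short_propagates(self, healthy_walk):
        short = DerivedSignals(healthy_walk.left.omega[:200],
                               healthy_walk.left.jerk[:200], 100.0)
        with pytest.raises(SignalTooShortError):
            select_reference_stride(short, 130)

    def test_affine_rescaling_invariance(self, healthy_walk):
        sig = healthy_walk.left
        res0 = select_reference_stride(sig, 130)
        scaled = DerivedSignals(sig.omega * 3.5, sig.jerk * 3.5, sig.fs)
        assert select_reference_stride(scaled, 130).start == res0.start
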