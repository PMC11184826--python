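"""Model stride handling, constrained multivariate DTW and event transfer."""

import json
from functools import lru_cache

import numpy as np
import pytest

from gaitseg import SynthParams, mdtwd, select_reference_stride, synth_walk
from gaitseg.core import Interval, znorm
from gaitseg._dtw import itakura_mask
from gaitseg.errors import ArgumentError, ConstraintError, FormatError
from gaitseg.motif import MotifResult
from gaitseg.template_annotate import (ModelStride, WarpingPath,
                                       annotate_reference, center_align,
                                       load_model_stride, resample_model,
                                       save_model_stride, transfer_events)


def brute_force_dtw(A, B, mask=None):
    """Exhaustive min-cost alignment (independent DP oracle, tiny inputs)."""
    A = np.atleast_2d(np.asarray(A, float).T).T
    B = np.atleast_2d(np.asarray(B, float).T).T
    n, m = len(A), len(B)

    def cost(i, j):
        return float(np.sqrt(((A[i] - B[j]) ** 2).sum()))

    @lru_cache(maxsize=None)
    def rec(i, j):
        if mask is not None and not mask[i, j]:
            return np.inf
        c = cost(i, j)
        if i == 0 and j == 0:
            return c
        prev = []
        if i > 0 and j > 0:
            prev.append(rec(i - 1, j - 1))
        if i > 0:
            prev.append(rec(i - 1, j))
        if j > 0:
            prev.append(rec(i, j - 1))
        return c + min(prev)

    return rec(n - 1, m - 1)


class TestModelStrideFixture:
    def test_default_fixture_valid(self, model):
        e = model.events
        assert e["FF"] < e["HO"] < e["TO"] < e["HS"]
        assert model.n > 0 and model.fs == 100.0

    def test_out_of_order_events_rejected(self, tmp_path, model):
        bad = ModelStride(omega=model.omega, jerk=model.jerk, fs=model.fs,
                          events={"TO": 91, "HS": 39})
        save_model_stride(bad, tmp_path / "m.csv", tmp_path / "m.json")
        with pytest.raises(FormatError, match="order"):
            load_model_stride(str(tmp_path / "m"))

    def test_malformed_sidecar(self, tmp_path, model):
        save_model_stride(model, tmp_path / "m.csv", tmp_path / "m.json")
        (tmp_path / "m.json").write_text(json.dumps({"fs": 100.0}))
        with pytest.raises(FormatError):
            load_model_stride(str(tmp_path / "m"))

    def test_roundtrip(self, tmp_path, model):
        save_model_stride(model, tmp_path / "m.csv", tmp_path / "m.json")
        back = load_model_stride(str(tmp_path / "m"))
        assert back.events == model.events
        assert np.allclose(back.omega, model.omega)
        assert np.allclose(back.jerk, model.jerk)


class TestCenterAlign:
    def test_aligned_peaks_identity(self, model):
        out = center_align(model, model.omega)
        assert np.array_equal(out.omega, model.omega)
        assert out.events == model.events

    def test_shift_arithmetic(self, model):
        ref = np.roll(model.omega, 20)
        out = center_align(model, ref)
        assert int(np.argmax(out.omega)) == int(np.argmax(ref))
        assert out.events["TO"] == (model.events["TO"] + 20) % model.n

    def test_shift_is_invertible(self, model):
        ref = np.roll(model.omega, 35)
        back = center_align(center_align(model, ref), model.omega)
        assert np.allclose(back.omega, model.omega)
        assert back.events == model.events


class TestMdtwd:
    def test_identical_series_zero_diagonal(self, model):
        d, path = mdtwd(model.omega, model.jerk, model.omega, model.jerk)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(path.pairs,
                              np.column_stack([np.arange(model.n)] * 2))

    def test_repeated_sample_matches_brute_force(self):
        a = np.array([0.0, 1.0, 3.0, 2.0, 0.5, -1.0])
        aj = np.array([1.0, 0.0, 2.0, 1.0, 0.0, 0.5])
        b = np.insert(a, 3, a[2])  # one repeated sample
        bj = np.insert(aj, 3, aj[2])
        d, path = mdtwd(a, aj, b, bj, normalize=False)
        A = np.column_stack([a, aj])
        B = np.column_stack([b, bj])
        assert d == pytest.approx(
            brute_force_dtw(A, B, itakura_mask(len(a), len(b), 2.0)), abs=1e-9)
        assert len(path) == len(b)  # repeat absorbed by one (0,1) step
        assert d == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_constrained_cost_at_least_unconstrained(self, seed):
        r = np.random.default_rng(seed)
        n, m = 8, 10
        a, aj = r.normal(size=n), r.normal(size=n)
        b, bj = r.normal(size=m), r.normal(size=m)
        d, path = mdtwd(a, aj, b, bj, normalize=False)
        A, B = np.column_stack([a, aj]), np.column_stack([b, bj])
        unconstrained = brute_force_dtw(A, B)
        constrained = brute_force_dtw(A, B, itakura_mask(n, m, 2.0))
        assert d == pytest.approx(constrained, abs=1e-9)
        assert d >= unconstrained - 1e-9
        path.validate(n, m, slope=2.0)

    def test_channel_swap_symmetry(self, rng):
        a, aj = rng.normal(size=20), rng.normal(size=20)
        b, bj = rng.normal(size=20), rng.normal(size=20)
        d1, _ = mdtwd(a, aj, b, bj)
        d2, _ = mdtwd(aj, a, bj, b)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_series_symmetry(self, rng):
        a, aj = rng.normal(size=15), rng.normal(size=15)
        b, bj = rng.normal(size=15), rng.normal(size=15)
        assert mdtwd(a, aj, b, bj)[0] == pytest.approx(
            mdtwd(b, bj, a, aj)[0], abs=1e-9)

    def test_univariate_mode(self, rng):
        a = rng.normal(size=12)
        d, _ = mdtwd(a, None, a, None)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_channels(self, rng):
        with pytest.raises(ArgumentError):
            mdtwd(rng.normal(size=5), rng.normal(size=5),
                  rng.normal(size=5), None)

    def test_infeasible_length_ratio(self, rng):
        # lengths 2 vs 10 cannot be joined under slope 2
        with pytest.raises(ConstraintError):
            mdtwd(rng.normal(size=2), None, rng.normal(size=10), None)


class TestTransferEvents:
    def _path(self, pairs):
        return WarpingPath(np.asarray(pairs))

    def test_identity_path_maps_offsets(self):
        path = self._path([(i, i) for i in range(100)])
        ann = transfer_events(path, {"TO": 30, "HS": 70}, Interval(500, 600))
        assert ann.to_idx == 530 and ann.hs_idx == 570

    def test_to_takes_last_matched_point(self):
        pairs = ([(i, i) for i in range(30)]
                 + [(30, 30), (30, 31), (30, 32)]
                 + [(30 + k, 32 + k) for k in range(1, 60)])
        ann = transfer_events(self._path(pairs), {"TO": 30, "HS": 70},
                              Interval(0, 92))
        assert ann.to_idx == 32  # last subject sample matched to model TO

    def test_hs_takes_first_matched_point(self):
        pairs = ([(i, i) for i in range(70)]
                 + [(70, 70), (70, 71)]
                 + [(70 + k, 71 + k) for k in range(1, 20)])
        ann = transfer_events(self._path(pairs), {"TO": 30, "HS": 70},
                              Interval(0, 91))
        assert ann.hs_idx == 70  # first subject sample matched to model HS

    def test_model_self_annotation_fixed_point(self, model):
        d, path = mdtwd(model.omega, model.jerk, model.omega, model.jerk)
        ann = transfer_events(path, model.events, Interval(0, model.n),
                              distance=d)
        assert ann.to_idx == model.events["TO"]
        assert ann.hs_idx == model.events["HS"]


class TestResampleModel:
    def test_identity_when_lengths_match(self, model):
        assert resample_model(model, model.n) is model

    def test_events_scale_proportionally(self, model):
        out = resample_model(model, 2 * model.n - 1)
        assert out.n == 2 * model.n - 1
        assert out.events["TO"] == pytest.approx(2 * model.events["TO"], abs=1)
        e = out.events
        assert e["FF"] < e["HO"] < e["TO"] < e["HS"]


class TestAnnotateReference:
    @pytest.mark.parametrize("foot", ["left", "right"])
    def test_recovers_true_events_on_healthy_walk(self, healthy_walk, model, foot):
        """Reference-stride TO/HS land within 40 ms of ground truth."""
        sig = getattr(healthy_walk, foot)
        m = 130
        res = select_reference_stride(sig, m)
        ann = annotate_reference(sig, res, model=model)
        fs = sig.fs
        d_to = np.abs(healthy_walk.truth.times("FC", foot) - ann.to_idx / fs)
        d_hs = np.abs(healthy_walk.truth.times("IC", foot) - ann.hs_idx / fs)
        assert d_to.min() < 0.040
        assert d_hs.min() < 0.040
        assert ann.window.start <= ann.to_idx < ann.hs_idx < ann.window.stop
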