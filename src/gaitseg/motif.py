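"""Part 2 — reference-stride isolation with an annotation-corrected matrix profile.

The matrix profile (MP) of the gyration signal gives, for every length-m
subsequence, the z-normalized Euclidean distance to its nearest non-trivial
neighbor; minima mark recurring motifs. An annotation vector (AV) biases
the search toward windows whose *central third* carries large gyration and
jerk, i.e. windows centered on the swing phase:

    AV_i = sum_{k=i+m/3}^{i+2m/3} ( omega_k / omega_max + j_k / j_max )

with omega_max and j_max the global maxima of |omega| and jerk over the
walk, omega kept signed. After min-max rescaling of AV to [0, 1], the
corrected matrix profile is

    CMP_i = MP_i + (1 - AV_i) * max(MP)

and the reference stride is the window starting at argmin(CMP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Interval
from .errors import ArgumentError, DegenerateSignalError, SignalTooShortError
from .io_preproc import DerivedSignals

_EPS = 1e-12


@dataclass
class MotifResult:
    """Matrix-profile diagnostics and the selected reference-stride window."""

    m: int
    mp: np.ndarray
    nn_idx: np.ndarray  # nearest-neighbor index per window (diagnostics)
    av: np.ndarray      # annotation vector rescaled to [0, 1]
    cmp: np.ndarray
    start: int
    window: Interval


def _znorm_windows(x: np.ndarray, m: int) -> np.ndarray:
    W = sliding_window_view(np.asarray(x, dtype=float), m)
    mu = W.mean(axis=1, keepdims=True)
    sd = W.std(axis=1, keepdims=True)
    return np.where(sd > _EPS, (W - mu) / np.where(sd > _EPS, sd, 1.0), 0.0)


def matrix_profile(omega: np.ndarray, m: int,
                   block: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Self-join matrix profile of *omega* with window length *m*.

    Returns ``(mp, nn_idx)``. Distances are z-normalized Euclidean; trivial
    matches are suppressed with an exclusion zone of m/2 around each window.
    Constant (zero-variance) windows z-normalize to zero vectors.
    """
    omega = np.asarray(omega, dtype=float)
    n = len(omega)
    if m < 4:
        raise ArgumentError(f"window length m={m} must be >= 4")
    if n < 2 * m:
        raise SignalTooShortError(
            f"signal of length {n} shorter than two windows of m={m}"
        )
    Z = _znorm_windows(omega, m)  # (w, m), rows have norm sqrt(m) or 0
    w = Z.shape[0]
    excl = max(1, int(round(m / 2)))
    mp = np.empty(w)
    nn = np.empty(w, dtype=int)
    for b0 in range(0, w, block):
        b1 = min(b0 + block, w)
        # squared z-normalized distance: 2*(m - <z_i, z_j>)
        dot = Z[b0:b1] @ Z.T
        d2 = np.clip(2.0 * (m - dot), 0.0, None)
        for i in range(b0, b1):
            j0, j1 = max(0, i - excl + 1), min(w, i + excl)
            d2[i - b0, j0:j1] = np.inf
        nn[b0:b1] = np.argmin(d2, axis=1)
        mp[b0:b1] = np.sqrt(d2[np.arange(b1 - b0), nn[b0:b1]])
    return mp, nn


def annotation_vector(omega: np.ndarray, jerk: np.ndarray, m: int,
                      rescale: bool = True, use_jerk: bool = True) -> np.ndarray:
    """Annotation vector favoring windows with strong central-third activity.

    With ``rescale=False`` the raw central-third sums are returned; the
    rescaled form is min-max mapped to [0, 1] for the CMP correction (a flat
    vector rescales to all ones, i.e. no correction). ``use_jerk=False``
    drops the jerk term (gyration-only ablation).
    """
    omega = np.asarray(omega, dtype=float)
    jerk = np.asarray(jerk, dtype=float)
    n = len(omega)
    if len(jerk) != n:
        raise ArgumentError("omega and jerk must have equal length")
    w = n - m + 1
    if w < 1:
        raise ArgumentError(f"window m={m} longer than signal {n}")
    omax = float(np.abs(omega).max())
    if omax < _EPS:
        raise DegenerateSignalError("omega is identically zero (omega_max = 0)")
    contrib = omega / omax
    if use_jerk:
        jmax = float(jerk.max())
        if jmax > _EPS:
            contrib = contrib + jerk / jmax
    lo, hi = m // 3, (2 * m) // 3  # inclusive bounds
    cs = np.concatenate(([0.0], np.cumsum(contrib)))
    i = np.arange(w)
    av = cs[np.minimum(i + hi + 1, n)] - cs[i + lo]
    if not rescale:
        return av
    rng = av.max() - av.min()
    if rng < _EPS:
        return np.ones(w)
    return (av - av.min()) / rng


def corrected_matrix_profile(mp: np.ndarray, av: np.ndarray) -> np.ndarray:
    """Combine MP and rescaled AV: ``cmp = mp + (1 - av) * max(mp)``."""
    mp = np.asarray(mp, dtype=float)
    av = np.asarray(av, dtype=float)
    if mp.shape != av.shape:
        raise ArgumentError(f"length mismatch: mp {mp.shape} vs av {av.shape}")
    return mp + (1.0 - av) * mp.max()


def select_reference_stride(sig: DerivedSignals, m: int,
                            use_jerk: bool = True) -> MotifResult:
    """Pick the reference-stride window: argmin of the corrected matrix profile."""
    mp, nn = matrix_profile(sig.omega, m)
    av = annotation_vector(sig.omega, sig.jerk, m, rescale=True, use_jerk=use_jerk)
    cmp_ = corrected_matrix_profile(mp, av)
    start = int(np.argmin(cmp_))
    return MotifResult(m=m, mp=mp, nn_idx=nn, av=av, cmp=cmp_, start=start,
                       window=Interval(start, start + m))
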