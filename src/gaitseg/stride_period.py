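"""Part 1 — average stride duration by multiparametric autocorrelation.

Foot-worn IMU signals of straight walking are quasi-periodic with period
equal to the stride time. The per-foot autocorrelations of the gyration and
jerk channels are averaged into a single "multiparametric" autocorrelation,
the stride lag is read off its first qualifying peak inside a physiological
band, and the shorter of the two per-foot estimates is kept to avoid
overestimating the stride duration.

Peak rule: among local maxima in the band whose prominence is at least
``prominence_frac`` of the band maximum, the first one whose *height* is at
least ``height_frac`` of the band maximum is selected. The height gate is
needed because signals with sharp jerk bursts at both toe-off and
heel-strike exhibit a genuine secondary autocorrelation bump at a lag equal
to the swing duration (toe-off bursts aligning with heel-strike bursts);
that bump is prominent but much lower than the stride peak. If no peak
qualifies the band's global maximum is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ArgumentError
from .io_preproc import DerivedSignals

DEFAULT_BAND_S = (0.4, 4.0)
DEFAULT_PROMINENCE_FRAC = 0.1
DEFAULT_HEIGHT_FRAC = 0.5

_EPS = 1e-12


@dataclass
class StridePeriodEstimate:
    """Per-foot stride lags and the retained stride duration L (seconds)."""

    lag_left: int
    lag_right: int
    L: float
    fs: float
    acf_left: np.ndarray
    acf_right: np.ndarray


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized (biased) autocorrelation for lags ``0..max_lag``.

    The mean is removed internally; the result is normalized by the lag-0
    value so ``acf[0] == 1``. A zero-variance input contributes 1 at lag 0
    and 0 elsewhere rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ArgumentError(f"max_lag {max_lag} must be < signal length {n}")
    xm = x - x.mean()
    r0 = float(xm @ xm)
    out = np.zeros(max_lag + 1)
    out[0] = 1.0
    if r0 < _EPS:
        return out
    full = sps.correlate(xm, xm, mode="full", method="auto")
    out[:] = full[n - 1 : n + max_lag] / r0
    return out


def multiparametric_acf(sig: DerivedSignals, max_lag: int) -> np.ndarray:
    """Element-wise mean of the omega and jerk autocorrelations."""
    return 0.5 * (autocorrelation(sig.omega, max_lag)
                  + autocorrelation(sig.jerk, max_lag))


def first_peak_lag(acf: np.ndarray, fs: float,
                   band: tuple[float, float] = DEFAULT_BAND_S,
                   prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                   height_frac: float = DEFAULT_HEIGHT_FRAC) -> int:
    """Lag (samples) of the first qualifying autocorrelation peak in *band*."""
    acf = np.asarray(acf, dtype=float)
    lo = max(1, int(np.ceil(band[0] * fs)))
    hi = min(len(acf) - 1, int(np.floor(band[1] * fs)))
    if hi < lo:
        raise ArgumentError(f"band {band} empty at fs={fs} for acf of length {len(acf)}")
    seg = acf[lo : hi + 1]
    band_max = float(seg.max())
    prom_thr = max(prominence_frac * band_max, _EPS)
    peaks, _ = sps.find_peaks(seg, prominence=prom_thr)
    for p in peaks:
        if seg[p] >= height_frac * band_max:
            return lo + int(p)
    return lo + int(np.argmax(seg))


def estimate_stride_duration(left: DerivedSignals, right: DerivedSignals,
                             band: tuple[float, float] = DEFAULT_BAND_S,
                             prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                             height_frac: float = DEFAULT_HEIGHT_FRAC) -> StridePeriodEstimate:
    """Estimate the average stride duration L from both feet.

    Per-foot lags come from the multiparametric autocorrelation; the shorter
    of the two is kept (``L = min(lag_left, lag_right) / fs``) to avoid
    overestimation. This does not erase left/right asymmetry — it only fixes
    the window length used downstream.
    """
    if left.fs != right.fs:
        raise ArgumentError("left and right feet must share the sampling rate")
    fs = left.fs
    out = {}
    for name, sig in (("left", left), ("right", right)):
        max_lag = min(sig.n - 1, int(np.ceil(band[1] * fs)) + 1)
        acf = multiparametric_acf(sig, max_lag)
        lag = first_peak_lag(acf, fs, band, prominence_frac, height_frac)
        out[name] = (lag, acf)
    lag_left, acf_left = out["left"]
    lag_right, acf_right = out["right"]
    return StridePeriodEstimate(
        lag_left=lag_left, lag_right=lag_right,
        L=min(lag_left, lag_right) / fs, fs=fs,
        acf_left=acf_left, acf_right=acf_right,
    )
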