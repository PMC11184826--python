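"""Reading, gap repair, filtering and derivation of the two signals of interest.

The detector consumes two per-foot time series derived from a foot-mounted
IMU sampled at 100 Hz:

* ``omega`` — the sagittal-plane gyration, i.e. the angular velocity about
  the medio-lateral (y) axis, in deg/s. Dominated by a large positive lobe
  during the swing phase, with negative lobes around toe-off and heel-strike.
* ``jerk`` — the Euclidean norm of the time-derivative of the gravity-free
  3-axis acceleration, in m/s^3. Sharp bursts mark toe-off and heel-strike;
  the foot-flat phase is quiet.

Raw channels are low-pass filtered (Butterworth, order 8, 14 Hz cut-off,
applied forward-backward so no phase lag is introduced between channels or
against gold-standard timestamps) before differentiation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import interp1d

from .errors import ArgumentError, FilterError, FormatError, RecordingInvalidError

#: channel columns expected in a raw per-foot CSV export
REQUIRED_CHANNELS = ["freeAccX", "freeAccY", "freeAccZ", "gyrX", "gyrY", "gyrZ"]
#: accepted names for the sample-counter / time column
COUNTER_ALIASES = ("PacketCounter", "t", "time", "time_s")

DEFAULT_FS = 100.0
DEFAULT_CUTOFF_HZ = 14.0
DEFAULT_ORDER = 8
DEFAULT_MAX_GAP_S = 0.5


@dataclass
class ImuRecording:
    """One foot's multichannel IMU signal on a uniform time grid.

    Samples missing from the raw export are represented by NaN rows and
    flagged in ``missing`` until :func:`interpolate_gaps` repairs them.
    """

    foot: str
    fs: float
    t: np.ndarray
    free_acc: np.ndarray  # (n, 3) m/s^2, gravity-free
    gyro: np.ndarray      # (n, 3) deg/s
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.free_acc = np.asarray(self.free_acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.t)
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if n < 2:
            raise FormatError("recording must contain at least 2 samples")
        if self.free_acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise FormatError("free_acc and gyro must both have shape (n, 3)")
        if self.foot not in ("left", "right"):
            raise ArgumentError(f"foot must be 'left' or 'right', got {self.foot!r}")

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass
class DerivedSignals:
    """The (omega, jerk) pair the whole detection algorithm consumes."""

    omega: np.ndarray  # deg/s
    jerk: np.ndarray   # m/s^3, >= 0
    fs: float

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.jerk = np.asarray(self.jerk, dtype=float)
        if self.omega.shape != self.jerk.shape or self.omega.ndim != 1:
            raise ArgumentError("omega and jerk must be 1-D of equal length")

    @property
    def n(self) -> int:
        return len(self.omega)


def read_imu_csv(path, foot: str, fs: float = DEFAULT_FS) -> ImuRecording:
    """Read a raw per-foot IMU CSV onto a uniform grid.

    The file must contain a sample-counter (``PacketCounter``) or time
    column plus the six channel columns ``freeAccX/Y/Z`` and ``gyrX/Y/Z``.
    Rows missing from the counter sequence become NaN samples flagged in
    ``missing``. Magnetometer or other extra columns are ignored.
    """
    df = pd.read_csv(path)
    counter_col = next((c for c in COUNTER_ALIASES if c in df.columns), None)
    if counter_col is None:
        raise FormatError(
            f"no sample counter/time column found (expected one of {COUNTER_ALIASES})"
        )
    for col in REQUIRED_CHANNELS:
        if col not in df.columns:
            raise FormatError(f"missing required channel column {col!r}")

    raw = df[counter_col].to_numpy(dtype=float)
    if counter_col == "PacketCounter":
        idx = np.round(raw - raw[0]).astype(int)
    else:  # seconds
        idx = np.round((raw - raw[0]) * fs).astype(int)
    if np.any(np.diff(idx) <= 0):
        raise FormatError(f"non-monotone sample counter in column {counter_col!r}")

    n = int(idx[-1]) + 1
    free_acc = np.full((n, 3), np.nan)
    gyro = np.full((n, 3), np.nan)
    free_acc[idx] = df[["freeAccX", "freeAccY", "freeAccZ"]].to_numpy(dtype=float)
    gyro[idx] = df[["gyrX", "gyrY", "gyrZ"]].to_numpy(dtype=float)
    missing = np.ones(n, dtype=bool)
    missing[idx] = False
    t = np.arange(n) / fs
    return ImuRecording(foot=foot, fs=fs, t=t, free_acc=free_acc, gyro=gyro,
                        missing=missing)


def _gap_runs(missing: np.ndarray):
    """Yield (start, length) of each run of missing samples."""
    n = len(missing)
    i = 0
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            yield i, j - i
            i = j
        else:
            i += 1


def interpolate_gaps(rec: ImuRecording, max_gap_s: float = DEFAULT_MAX_GAP_S) -> ImuRecording:
    """Fill gaps by quadratic interpolation; reject long sensor dropouts.

    A gap longer than ``max_gap_s`` (default 0.5 s, the logistical exclusion
    rule for a sensor "not recording") invalidates the recording. A gap-free
    recording is returned unchanged.
    """
    if not rec.missing.any():
        return rec
    for start, length in _gap_runs(rec.missing):
        if length / rec.fs > max_gap_s:
            raise RecordingInvalidError(
                f"{rec.foot} foot: sensor gap of {length / rec.fs:.2f} s at "
                f"t={start / rec.fs:.2f} s exceeds {max_gap_s} s"
            )
    valid = ~rec.missing
    if valid.sum() < 3:
        raise RecordingInvalidError(f"{rec.foot} foot: too few valid samples")
    free_acc = rec.free_acc.copy()
    gyro = rec.gyro.copy()
    tv = rec.t[valid]
    for arr in (free_acc, gyro):
        for c in range(3):
            f = interp1d(tv, arr[valid, c], kind="quadratic", assume_sorted=True)
            arr[~valid, c] = f(rec.t[~valid])
    return dataclasses.replace(rec, free_acc=free_acc, gyro=gyro,
                               missing=np.zeros(rec.n, dtype=bool))


def lowpass_filter(x: np.ndarray, fs: float,
                   cutoff: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (order 8, 14 Hz by default).

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the squared single-pass response and the group delay is zero.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ArgumentError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= max(3 * order, padlen):
        raise FilterError(
            f"sequence of length {len(x)} too short for order-{order} zero-phase filter"
        )
    return sps.sosfiltfilt(sos, x)


def derive_signals(rec: ImuRecording) -> DerivedSignals:
    """Compute the (omega, jerk) pair from a gap-free, filtered recording.

    Jerk uses central differences in the interior and one-sided differences
    at the boundaries (second-order accurate, no lag); omega is the gyro
    y-channel copied verbatim.
    """
    if np.isnan(rec.free_acc).any() or np.isnan(rec.gyro).any():
        raise RecordingInvalidError(
            f"{rec.foot} foot: recording still contains gaps; repair them first"
        )
    dt = 1.0 / rec.fs
    dacc = np.gradient(rec.free_acc, dt, axis=0)
    jerk = np.sqrt((dacc ** 2).sum(axis=1))
    omega = rec.gyro[:, 1].copy()
    return DerivedSignals(omega=omega, jerk=jerk, fs=rec.fs)


def preprocess(rec: ImuRecording,
               cutoff: float = DEFAULT_CUTOFF_HZ,
               order: int = DEFAULT_ORDER,
               max_gap_s: float = DEFAULT_MAX_GAP_S) -> DerivedSignals:
    """Gap repair + per-channel zero-phase filtering + signal derivation."""
    rec = interpolate_gaps(rec, max_gap_s=max_gap_s)
    free_acc = np.column_stack(
        [lowpass_filter(rec.free_acc[:, c], rec.fs, cutoff, order) for c in range(3)]
    )
    gyro = np.column_stack(
        [lowpass_filter(rec.gyro[:, c], rec.fs, cutoff, order) for c in range(3)]
    )
    rec = dataclasses.replace(rec, free_acc=free_acc, gyro=gyro)
    return derive_signals(rec)


def write_derived_csv(sig: DerivedSignals, path) -> None:
    t = np.arange(sig.n) / sig.fs
    pd.DataFrame({"t": t, "omega": sig.omega, "jerk": sig.jerk}).to_csv(path, index=False)


def read_derived_csv(path, fs: float | None = None) -> DerivedSignals:
    df = pd.read_csv(path)
    for col in ("t", "omega", "jerk"):
        if col not in df.columns:
            raise FormatError(f"derived CSV missing column {col!r}")
    if fs is None:
        dt = np.diff(df["t"].to_numpy(dtype=float))
        if len(dt) == 0 or dt.min() <= 0:
            raise FormatError("derived CSV time column not strictly increasing")
        fs = 1.0 / float(np.median(dt))
    return DerivedSignals(omega=df["omega"].to_numpy(dtype=float),
                          jerk=df["jerk"].to_numpy(dtype=float), fs=fs)
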