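"""Part 3 — annotate the reference stride by multivariate DTW against a model stride.

A canonical "model stride" with known event offsets (foot-flat FF, heel-off
HO, toe-off TO, heel-strike HS; FF < HO < TO < HS, with TO and HS mandatory)
is aligned to the subject's reference stride and its TO/HS labels are
transferred through the warping path:

* the model is linearly resampled to the reference-window length and
  circularly shifted so both swing peaks (gyration maxima) coincide;
* dependent multivariate DTW (channels stacked into 2-D points, each channel
  z-normalized per series) under an Itakura slope-2 constraint yields the
  optimal warping path;
* the *last* subject sample matched to the model's TO becomes the subject's
  TO, the *first* subject sample matched to the model's HS becomes the HS.

The packaged default model stride is synthetic (generated by
:mod:`gaitseg.synthgait` at default parameters) with exact event offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._dtw import dtw_constrained, itakura_mask
from .core import Interval, znorm
from .errors import ArgumentError, FormatError, GaitSegError
from .io_preproc import DerivedSignals
from .motif import MotifResult

logger = logging.getLogger(__name__)

DEFAULT_SLOPE = 2.0
EVENT_ORDER = ("FF", "HO", "TO", "HS")
_EPS = 1e-12


@dataclass
class ModelStride:
    """One canonical annotated stride (omega, jerk, event offsets in samples)."""

    omega: np.ndarray
    jerk: np.ndarray
    fs: float
    events: dict  # name -> sample offset; TO and HS mandatory

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.jerk = np.asarray(self.jerk, dtype=float)
        if self.omega.shape != self.jerk.shape or self.omega.ndim != 1:
            raise FormatError("model stride omega/jerk must be 1-D of equal length")

    @property
    def n(self) -> int:
        return len(self.omega)

    def validate(self) -> "ModelStride":
        for ev in ("TO", "HS"):
            if ev not in self.events:
                raise FormatError(f"model stride missing mandatory event {ev}")
        present = [e for e in EVENT_ORDER if e in self.events]
        offs = [int(self.events[e]) for e in present]
        if any(o < 0 or o >= self.n for o in offs):
            raise FormatError("model stride event offsets must lie inside the stride")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise FormatError(
                f"model stride events out of order: {dict(zip(present, offs))}"
            )
        return self


@dataclass
class WarpingPath:
    """Monotone alignment between a model series and a subject series."""

    pairs: np.ndarray  # (L, 2) int, (model index, subject index)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, n_model: int, n_subject: int, slope: float | None = None) -> None:
        p = self.pairs
        if tuple(p[0]) != (0, 0) or tuple(p[-1]) != (n_model - 1, n_subject - 1):
            raise ArgumentError("warping path must join the series endpoints")
        steps = np.diff(p, axis=0)
        ok = {(1, 0), (0, 1), (1, 1)}
        if any(tuple(s) not in ok for s in steps):
            raise ArgumentError("warping path steps must be in {(1,0),(0,1),(1,1)}")
        if slope is not None:
            mask = itakura_mask(n_model, n_subject, slope)
            if not mask[p[:, 0], p[:, 1]].all():
                raise ArgumentError("warping path leaves the Itakura parallelogram")


@dataclass
class AnnotatedStride:
    """Reference stride with transferred TO/HS indices (walk coordinates)."""

    window: Interval
    to_idx: int
    hs_idx: int
    distance: float
    omega: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    jerk: np.ndarray = field(default=None, repr=False)   # type: ignore[assignment]

    @property
    def to_offset(self) -> int:
        return self.to_idx - self.window.start

    @property
    def hs_offset(self) -> int:
        return self.hs_idx - self.window.start


def load_model_stride(source=None) -> ModelStride:
    """Load a model stride from CSV (t, omega, jerk) + JSON sidecar (fs, events).

    With no *source*, the packaged synthetic default is used. *source* may be
    a ``(csv_path, json_path)`` pair or a base path to which ``.csv`` /
    ``.json`` are appended.
    """
    if source is None:
        base = resources.files("gaitseg.data")
        csv_src = base / "model_stride_synthetic.csv"
        json_src = base / "model_stride_synthetic.json"
        with resources.as_file(csv_src) as c, resources.as_file(json_src) as j:
            return _read_model(c, j)
    if isinstance(source, (tuple, list)) and len(source) == 2:
        return _read_model(source[0], source[1])
    return _read_model(f"{source}.csv", f"{source}.json")


def _read_model(csv_path, json_path) -> ModelStride:
    df = pd.read_csv(csv_path)
    for col in ("omega", "jerk"):
        if col not in df.columns:
            raise FormatError(f"model stride CSV missing column {col!r}")
    try:
        with open(json_path) as fh:
            meta = json.load(fh)
        fs = float(meta["fs"])
        events = {str(k): int(v) for k, v in meta["events"].items()}
    except (OSError, KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed model stride sidecar {json_path}: {exc}") from exc
    return ModelStride(omega=df["omega"].to_numpy(dtype=float),
                       jerk=df["jerk"].to_numpy(dtype=float),
                       fs=fs, events=events).validate()


def save_model_stride(model: ModelStride, csv_path, json_path) -> None:
    t = np.arange(model.n) / model.fs
    pd.DataFrame({"t": t, "omega": model.omega, "jerk": model.jerk}).to_csv(
        csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump({"fs": model.fs,
                   "events": {k: int(v) for k, v in model.events.items()}},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")


def resample_model(model: ModelStride, m: int) -> ModelStride:
    """Linearly resample a model stride to length *m*, rescaling event offsets."""
    if m == model.n:
        return model
    if m < 2:
        raise ArgumentError("resampled length must be >= 2")
    xs = np.linspace(0.0, model.n - 1, m)
    scale = (m - 1) / (model.n - 1)
    events = {}
    last = -1
    for name in EVENT_ORDER:
        if name in model.events:
            off = int(round(model.events[name] * scale))
            off = max(off, last + 1)  # keep strict ordering after rounding
            events[name] = min(off, m - 1)
            last = events[name]
    return ModelStride(omega=np.interp(xs, np.arange(model.n), model.omega),
                       jerk=np.interp(xs, np.arange(model.n), model.jerk),
                       fs=model.fs * scale, events=events)


def center_align(model: ModelStride, ref_omega: np.ndarray) -> ModelStride:
    """Circularly shift the model so both gyration (swing) peaks coincide.

    Event offsets move with the shift, modulo the stride length; if the
    shift wraps events across the window boundary the TO-before-HS ordering
    can break — this is logged, not silently reordered.
    """
    ref_omega = np.asarray(ref_omega, dtype=float)
    if np.ptp(model.omega) < _EPS or np.ptp(ref_omega) < _EPS:
        raise ArgumentError("cannot center-align constant series")
    shift = int(np.argmax(ref_omega)) - int(np.argmax(model.omega))
    n = model.n
    events = {k: (int(v) + shift) % n for k, v in model.events.items()}
    out = ModelStride(omega=np.roll(model.omega, shift),
                      jerk=np.roll(model.jerk, shift),
                      fs=model.fs, events=events)
    if "TO" in events and "HS" in events and events["TO"] >= events["HS"]:
        logger.warning("center_align wrapped events: TO offset %d >= HS offset %d",
                       events["TO"], events["HS"])
    return out


def mdtwd(a_omega, a_jerk, b_omega, b_jerk, slope: float = DEFAULT_SLOPE,
          normalize: bool = True) -> tuple[float, WarpingPath]:
    """Dependent multivariate DTW under an Itakura slope constraint.

    Channels are z-normalized per series and stacked into vector-valued
    points; the cost of matching two points is their Euclidean distance.
    Pass ``a_jerk=b_jerk=None`` for the gyration-only (1-D) variant. Returns
    the optimal summed cost and one optimal warping path.
    """
    if (a_jerk is None) != (b_jerk is None):
        raise ArgumentError("both series must carry the same channels")

    def stack(om, jk):
        chans = [np.asarray(om, dtype=float)]
        if jk is not None:
            chans.append(np.asarray(jk, dtype=float))
        if normalize:
            out = []
            for c in chans:
                if c.std() < _EPS:
                    logger.warning("constant channel in mdtwd; set to zeros")
                out.append(znorm(c))
            chans = out
        return np.column_stack(chans)

    A, B = stack(a_omega, a_jerk), stack(b_omega, b_jerk)
    if len(A) < 2 or len(B) < 2:
        raise ArgumentError("series must have length >= 2")
    C = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2))
    mask = itakura_mask(len(A), len(B), slope)
    dist, pairs = dtw_constrained(C, mask)
    return dist, WarpingPath(pairs)


def transfer_events(path: WarpingPath, events, window: Interval,
                    distance: float = float("nan"),
                    omega: np.ndarray | None = None,
                    jerk: np.ndarray | None = None) -> AnnotatedStride:
    """Transfer model TO/HS through a warping path into walk coordinates.

    TO maps to the *last* subject sample matched to the model's TO point;
    HS maps to the *first* subject sample matched to the model's HS point.
    """
    if isinstance(events, ModelStride):
        events = events.events
    pairs = path.pairs
    out = {}
    for name, reduce_ in (("TO", np.max), ("HS", np.min)):
        js = pairs[pairs[:, 0] == int(events[name]), 1]
        if len(js) == 0:
            raise GaitSegError(
                f"model {name} offset {events[name]} absent from warping path"
            )
        out[name] = window.start + int(reduce_(js))
    if out["TO"] >= out["HS"]:
        logger.warning("transferred events out of order within window %s: "
                       "TO=%d, HS=%d", window, out["TO"], out["HS"])
    return AnnotatedStride(window=window, to_idx=out["TO"], hs_idx=out["HS"],
                           distance=distance, omega=omega, jerk=jerk)


def annotate_reference(sig: DerivedSignals, motif: MotifResult,
                       model: ModelStride | None = None,
                       slope: float = DEFAULT_SLOPE,
                       use_jerk: bool = True) -> AnnotatedStride:
    """Annotate the selected reference stride with TO and HS.

    Resamples the model to the reference-window length, centers the swing
    peaks, runs mDTWd and transfers the model's TO/HS through the path.
    """
    if model is None:
        model = load_model_stride()
    win = motif.window
    ref_o = sig.omega[win.start:win.stop]
    ref_j = sig.jerk[win.start:win.stop]
    model_r = resample_model(model, motif.m)
    model_c = center_align(model_r, ref_o)
    dist, path = mdtwd(model_c.omega, model_c.jerk if use_jerk else None,
                       ref_o, ref_j if use_jerk else None, slope=slope)
    return transfer_events(path, model_c.events, win, distance=dist,
                           omega=ref_o, jerk=ref_j)
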