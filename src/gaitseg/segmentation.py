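"""Part 4 — detect every stride by template matching with the annotated reference.

Candidate stride starts are the local maxima of the sliding z-normalized
correlation between the annotated reference stride and the walk. Each
candidate window is re-scored with slope-constrained dependent multivariate
DTW; candidates whose path-length-normalized dissimilarity exceeds
``lambda_thr`` (default 0.4) are rejected, and the survivors are selected
greedily by ascending dissimilarity subject to a pairwise window-overlap cap
of ``mu * m`` samples (default ``mu = 0.1``). The template's TO/HS offsets
are transferred into every accepted window through its warping path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import Interval, znorm
from .config import RunConfig
from .errors import ArgumentError, GaitSegError
from .io_preproc import DerivedSignals, ImuRecording, preprocess
from .motif import MotifResult, select_reference_stride
from .stride_period import StridePeriodEstimate, estimate_stride_duration
from .template_annotate import (AnnotatedStride, ModelStride, load_model_stride,
                                annotate_reference, mdtwd, transfer_events)

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class SegmentationParams:
    """Template-matching parameters (defaults adapted to degraded strides)."""

    lambda_thr: float = 0.4   # max path-normalized mDTWd dissimilarity
    mu: float = 0.1           # tolerated fractional overlap between windows
    len_band: tuple = (0.7, 1.3)  # reserved for multi-length search (off)
    slope: float = 2.0        # Itakura slope constraint
    gyration_only: bool = False

    def __post_init__(self) -> None:
        if not self.lambda_thr > 0:
            raise ArgumentError("lambda_thr must be > 0")
        if not 0 <= self.mu < 1:
            raise ArgumentError("mu must be in [0, 1)")


@dataclass(frozen=True)
class GaitEvent:
    type: str   # "TO" | "HS"
    foot: str   # "left" | "right"
    time: float  # seconds from recording start


@dataclass
class GaitEventList:
    """Typed, timed, per-foot gait events plus the stride windows behind them."""

    events: list = field(default_factory=list)
    windows: list = field(default_factory=list)    # Interval per accepted stride
    distances: list = field(default_factory=list)  # normalized mDTWd per stride

    def sort(self) -> "GaitEventList":
        self.events.sort(key=lambda e: (e.time, e.type))
        return self

    def times(self, type_: str | None = None, foot: str | None = None) -> np.ndarray:
        return np.asarray([e.time for e in self.events
                           if (type_ is None or e.type == type_)
                           and (foot is None or e.foot == foot)])

    def __len__(self) -> int:
        return len(self.events)

    def extend(self, other: "GaitEventList") -> "GaitEventList":
        self.events.extend(other.events)
        self.windows.extend(other.windows)
        self.distances.extend(other.distances)
        return self.sort()


def correlation_profile(sig: DerivedSignals, template_omega: np.ndarray,
                        template_jerk: np.ndarray | None = None) -> np.ndarray:
    """Sliding z-normalized correlation of the stacked template against the walk.

    The per-channel Pearson correlations between the template and every
    length-m window are averaged over channels; values lie in [-1, 1].
    Zero-variance windows contribute correlation 0.
    """
    m = len(template_omega)
    n = sig.n
    if m > n:
        raise ArgumentError(f"template length {m} exceeds signal length {n}")
    chans = [(sig.omega, template_omega)]
    if template_jerk is not None:
        chans.append((sig.jerk, template_jerk))
    prof = np.zeros(n - m + 1)
    for x, t in chans:
        tz = znorm(t)
        num = np.correlate(np.asarray(x, dtype=float), tz, mode="valid")
        c1 = np.convolve(x, np.ones(m), mode="valid")
        c2 = np.convolve(np.asarray(x, dtype=float) ** 2, np.ones(m), mode="valid")
        var = np.clip(c2 / m - (c1 / m) ** 2, 0.0, None)
        sd = np.sqrt(var)
        prof += np.where(sd > _EPS, num / (m * np.where(sd > _EPS, sd, 1.0)), 0.0)
    return np.clip(prof / len(chans), -1.0, 1.0)


def _greedy_select(candidates: list, m: int, mu: float) -> list:
    """Greedy acceptance by ascending dissimilarity with overlap cap mu*m.

    *candidates* is a list of ``(d_norm, start, path)`` tuples.
    """
    accepted: list = []
    for d, s, path in sorted(candidates, key=lambda c: (c[0], c[1])):
        win = Interval(s, s + m)
        if all(win.overlap(w) <= mu * m for _, w, _ in accepted):
            accepted.append((d, win, path))
    accepted.sort(key=lambda c: c[1].start)
    return accepted


def detect_strides(sig: DerivedSignals, template: AnnotatedStride,
                   params: SegmentationParams | None = None,
                   foot: str = "left",
                   analysis_interval: tuple | None = None) -> GaitEventList:
    """Detect all strides of one foot and emit their TO/HS events.

    Returns an empty list (with a warning) when no candidate window passes
    the acceptance threshold.
    """
    params = params or SegmentationParams()
    m = len(template.omega)
    use_jerk = not params.gyration_only
    profile = correlation_profile(sig, template.omega,
                                  template.jerk if use_jerk else None)
    starts, _ = sps.find_peaks(profile)
    if analysis_interval is not None:
        t0, t1 = analysis_interval
        starts = [s for s in starts
                  if s / sig.fs >= t0 and (s + m) / sig.fs <= t1]
    candidates = []
    for s in starts:
        w_o = sig.omega[s:s + m]
        w_j = sig.jerk[s:s + m]
        dist, path = mdtwd(template.omega, template.jerk if use_jerk else None,
                           w_o, w_j if use_jerk else None, slope=params.slope)
        d_norm = dist / len(path)
        if d_norm <= params.lambda_thr:
            candidates.append((d_norm, int(s), path))
    accepted = _greedy_select(candidates, m, params.mu)
    out = GaitEventList()
    if not accepted:
        logger.warning("no stride accepted for %s foot "
                       "(%d candidates, lambda=%.2f)", foot, len(starts),
                       params.lambda_thr)
        return out
    events = {"TO": template.to_offset, "HS": template.hs_offset}
    for d, win, path in accepted:
        ann = transfer_events(path, events, win, distance=d)
        out.events.append(GaitEvent("TO", foot, ann.to_idx / sig.fs))
        out.events.append(GaitEvent("HS", foot, ann.hs_idx / sig.fs))
        out.windows.append(win)
        out.distances.append(d)
    return out.sort()


@dataclass
class PipelineResult:
    """Per-foot event lists plus the diagnostics of every algorithm part."""

    events_left: GaitEventList
    events_right: GaitEventList
    period: StridePeriodEstimate
    motif_left: MotifResult
    motif_right: MotifResult
    annotated_left: AnnotatedStride
    annotated_right: AnnotatedStride

    @property
    def L(self) -> float:
        return self.period.L

    def all_events(self) -> GaitEventList:
        out = GaitEventList()
        out.extend(self.events_left)
        out.extend(self.events_right)
        return out


class _Stage:
    """Re-raise package errors with the failing algorithm stage in front."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("part %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, GaitSegError):
            raise type(exc)(f"[{self.name}] {exc}") from exc
        return False


def run_pipeline_derived(left: DerivedSignals, right: DerivedSignals,
                         config: RunConfig | None = None,
                         model: ModelStride | None = None) -> PipelineResult:
    """Parts 1-4 on already-derived (omega, jerk) signals."""
    config = config or RunConfig()
    if model is None:
        model = (load_model_stride(config.model_stride)
                 if config.model_stride else load_model_stride())
    params = SegmentationParams(lambda_thr=config.lambda_thr, mu=config.mu,
                                slope=config.itakura_slope,
                                gyration_only=config.gyration_only)
    use_jerk = not config.gyration_only
    with _Stage("1/4 stride-period"):
        period = estimate_stride_duration(left, right, band=config.acf_band_s,
                                          prominence_frac=config.acf_prominence_frac,
                                          height_frac=config.acf_height_frac)
    m = int(round(period.L * left.fs))
    motifs, annotated, events = {}, {}, {}
    for foot, sig in (("left", left), ("right", right)):
        with _Stage(f"2/4 motif ({foot})"):
            motifs[foot] = select_reference_stride(sig, m, use_jerk=use_jerk)
        with _Stage(f"3/4 annotate ({foot})"):
            annotated[foot] = annotate_reference(sig, motifs[foot], model=model,
                                                 slope=config.itakura_slope,
                                                 use_jerk=use_jerk)
        with _Stage(f"4/4 segmentation ({foot})"):
            events[foot] = detect_strides(sig, annotated[foot], params, foot=foot,
                                          analysis_interval=config.analysis_interval)
    return PipelineResult(events_left=events["left"], events_right=events["right"],
                          period=period,
                          motif_left=motifs["left"], motif_right=motifs["right"],
                          annotated_left=annotated["left"],
                          annotated_right=annotated["right"])


def run_pipeline(left_rec: ImuRecording, right_rec: ImuRecording,
                 config: RunConfig | None = None,
                 model: ModelStride | None = None) -> PipelineResult:
    """Full pipeline from raw recordings: preprocess then parts 1-4."""
    config = config or RunConfig()
    with _Stage("0/4 preprocess"):
        left = preprocess(left_rec, cutoff=config.filter_cutoff_hz,
                          order=config.filter_order, max_gap_s=config.max_gap_s)
        right = preprocess(right_rec, cutoff=config.filter_cutoff_hz,
                           order=config.filter_order, max_gap_s=config.max_gap_s)
    return run_pipeline_derived(left, right, config=config, model=model)
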