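"""Evaluation against a gold-standard event list.

Detected toe-offs are compared to gold final contacts (TO <-> FC) and
detected heel-strikes to gold initial contacts (HS <-> IC). Matching is
one-to-one: admissible pairs (same foot, corresponding type, absolute time
difference within ``tol_frac`` of a stride duration — 20% by default) are
accepted greedily by ascending |dt|, each event used at most once. Reported
metrics are recall, precision, the F1 score (harmonic mean), and the
absolute timing errors of matched TO and HS events in milliseconds (median,
IQR and mean).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError
from .segmentation import GaitEvent, GaitEventList

#: detected event type -> gold-standard annotation type
TYPE_MAP = {"TO": "FC", "HS": "IC"}
#: accepted spellings of gold types, normalized to FC/IC
GOLD_ALIASES = {"FC": "FC", "IC": "IC", "TO": "FC", "HS": "IC"}

DEFAULT_TOL_FRAC = 0.2


@dataclass
class GoldEventList:
    """Gold-standard (instrumented-walkway style) IC/FC annotations."""

    events: list = field(default_factory=list)  # (type, foot, time_s)

    def __post_init__(self) -> None:
        norm = []
        for typ, foot, time in self.events:
            if typ not in GOLD_ALIASES:
                raise ArgumentError(f"unknown gold event type {typ!r}")
            norm.append((GOLD_ALIASES[typ], foot, float(time)))
        norm.sort(key=lambda e: (e[1], e[2], e[0]))
        self.events = norm

    def times(self, type_: str | None = None, foot: str | None = None) -> np.ndarray:
        return np.asarray([t for (ty, f, t) in self.events
                           if (type_ is None or ty == type_)
                           and (foot is None or f == foot)])

    def __len__(self) -> int:
        return len(self.events)

    def mean_stride_s(self) -> float | None:
        """Mean interval between consecutive same-type, same-foot events."""
        diffs = []
        for foot in {f for _, f, _ in self.events}:
            for typ in ("FC", "IC"):
                ts = self.times(typ, foot)
                if len(ts) >= 2:
                    diffs.extend(np.diff(ts))
        return float(np.mean(diffs)) if diffs else None


def read_gold_csv(path) -> GoldEventList:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append((row["type"], row["foot"], float(row["time_s"])))
    return GoldEventList(events)


def write_gold_csv(gold: GoldEventList, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["type", "foot", "time_s"])
        for typ, foot, t in gold.events:
            w.writerow([typ, foot, repr(float(t))])


@dataclass(frozen=True)
class Match:
    detected: GaitEvent
    gold: tuple  # (type, foot, time)
    dt_s: float  # detected - gold, signed

    @property
    def abs_ms(self) -> float:
        return abs(self.dt_s) * 1000.0


def match_events(detected: GaitEventList, gold: GoldEventList,
                 stride_duration: float,
                 tol_frac: float = DEFAULT_TOL_FRAC) -> list[Match]:
    """One-to-one greedy matching by ascending absolute time difference.

    A pair is admissible when foot and (mapped) type agree and |dt| does not
    exceed ``tol_frac * stride_duration``. Ties are broken by earliest gold
    then earliest detected event.
    """
    if stride_duration is None or stride_duration <= 0:
        raise ArgumentError("stride_duration must be positive")
    tol = tol_frac * stride_duration
    pairs = []
    det = list(detected.events)
    for di, d in enumerate(det):
        gtype = TYPE_MAP.get(d.type)
        if gtype is None:
            continue
        for gi, (typ, foot, t) in enumerate(gold.events):
            if typ == gtype and foot == d.foot and abs(d.time - t) <= tol:
                pairs.append((abs(d.time - t), t, d.time, di, gi))
    pairs.sort()
    used_d: set = set()
    used_g: set = set()
    matches = []
    for _, _, _, di, gi in pairs:
        if di in used_d or gi in used_g:
            continue
        used_d.add(di)
        used_g.add(gi)
        d = det[di]
        g = gold.events[gi]
        matches.append(Match(detected=d, gold=g, dt_s=d.time - g[2]))
    return matches


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    for name, v in (("recall", recall), ("precision", precision)):
        if not 0 <= v <= 1:
            raise ArgumentError(f"{name} must be in [0, 1], got {v}")
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def _stats(vals_ms: np.ndarray) -> dict:
    if len(vals_ms) == 0:
        return {"n": 0, "median": None, "iqr": None, "mean": None}
    return {"n": int(len(vals_ms)),
            "median": float(np.median(vals_ms)),
            "iqr": (float(np.percentile(vals_ms, 25)),
                    float(np.percentile(vals_ms, 75))),
            "mean": float(np.mean(vals_ms))}


@dataclass
class EvalReport:
    recall: float | None
    precision: float | None
    f1: float | None
    delta_to_ms: np.ndarray
    delta_hs_ms: np.ndarray
    n_gold: int
    n_detected: int
    n_matched: int
    gold_empty: bool = False

    @property
    def delta_all_ms(self) -> np.ndarray:
        return np.concatenate([self.delta_to_ms, self.delta_hs_ms])

    def to_dict(self) -> dict:
        return {"recall": self.recall, "precision": self.precision, "f1": self.f1,
                "n_gold": self.n_gold, "n_detected": self.n_detected,
                "n_matched": self.n_matched, "gold_empty": self.gold_empty,
                "delta_to_ms": _stats(self.delta_to_ms),
                "delta_hs_ms": _stats(self.delta_hs_ms),
                "delta_all_ms": _stats(self.delta_all_ms)}


def evaluate(detected: GaitEventList, gold: GoldEventList,
             stride_duration: float | None = None,
             tol_frac: float = DEFAULT_TOL_FRAC) -> EvalReport:
    """Full evaluation: matching, recall/precision/F1 and timing errors."""
    if len(gold) == 0:
        return EvalReport(recall=None, precision=None, f1=None,
                          delta_to_ms=np.asarray([]), delta_hs_ms=np.asarray([]),
                          n_gold=0, n_detected=len(detected), n_matched=0,
                          gold_empty=True)
    if stride_duration is None:
        stride_duration = gold.mean_stride_s()
        if stride_duration is None:
            raise ArgumentError("cannot infer stride duration from gold list; "
                                "pass stride_duration explicitly")
    if len(detected) == 0:
        return EvalReport(recall=0.0, precision=0.0, f1=0.0,
                          delta_to_ms=np.asarray([]), delta_hs_ms=np.asarray([]),
                          n_gold=len(gold), n_detected=0, n_matched=0)
    matches = match_events(detected, gold, stride_duration, tol_frac)
    recall = len(matches) / len(gold)
    precision = len(matches) / len(detected)
    d_to = np.asarray([m.abs_ms for m in matches if m.detected.type == "TO"])
    d_hs = np.asarray([m.abs_ms for m in matches if m.detected.type == "HS"])
    return EvalReport(recall=recall, precision=precision,
                      f1=f1_score(recall, precision),
                      delta_to_ms=d_to, delta_hs_ms=d_hs,
                      n_gold=len(gold), n_detected=len(detected),
                      n_matched=len(matches))
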