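"""Synthetic two-foot gait generator with exact ground-truth events.

Each stride is built from an idealized sagittal-gyration / jerk-norm
morphology: the stride starts at mid-stance, toe-off (TO) sits at 30% of
the stride, the swing phase spans ``swing_frac`` of the stride (so
heel-strike HS falls at ``0.3 + swing_frac``), and the swing-phase gyration
peak lies exactly between TO and HS. Gyration shows the dominant positive
swing lobe with negative lobes adjacent to TO and HS and a small heel-off
dip; jerk shows sharp positive bursts at TO and HS (the HS burst scaled by
``hs_jerk_atten`` to emulate degraded heel-strikes) over a quiet foot-flat
baseline.

Walks concatenate strides with truncated-normal durations, phase-shift the
right foot by half a stride, add white noise and band-limit everything with
the same 14 Hz zero-phase filter as the real preprocessing chain, so
synthetic signals share the pipeline's bandwidth. Ground-truth TO/HS times
are emitted as FC/IC in a :class:`~gaitseg.metrics.GoldEventList`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import truncnorm

from .core import Interval
from .errors import ArgumentError
from .io_preproc import DerivedSignals, lowpass_filter
from .metrics import GoldEventList, write_gold_csv
from .template_annotate import ModelStride

# stride morphology (fractions of the stride, amplitudes in signal units)
FF_FRAC = 0.05
HO_FRAC = 0.20
TO_FRAC = 0.30
OMEGA_SWING_AMP = 320.0  # deg/s, dominant swing lobe
OMEGA_LOBE_AMP = 90.0    # deg/s, negative lobes at TO and HS
OMEGA_HO_DIP = 25.0      # deg/s, small heel-off dip
JERK_BASE = 2.0          # m/s^3, quiet foot-flat baseline
JERK_BURST_AMP = 60.0    # m/s^3, TO and HS bursts
SWING_W = 0.06           # Gaussian widths, fractions of the stride
LOBE_W = 0.03
BURST_W = 0.015
HO_W = 0.04


@dataclass
class SynthParams:
    """Study conditions for one synthetic walk."""

    n_strides: int = 10
    stride_s: float = 1.3      # mean stride time, s
    stride_cv: float = 0.05    # fractional SD of stride time
    fs: float = 100.0
    swing_frac: float = 0.4    # swing fraction of the stride
    asym: float = 1.0          # right/left stride-time ratio
    hs_jerk_atten: float = 1.0  # HS burst attenuation in [0, 1]
    noise_sd: float = 0.1      # white-noise SD, fraction of signal amplitude
    lead_s: float = 2.0        # quiet lead-in / lead-out, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_s <= 0 or self.fs <= 0:
            raise ArgumentError("stride_s and fs must be positive")
        if not 0 < self.swing_frac < 1:
            raise ArgumentError("swing_frac must be in (0, 1)")
        if self.n_strides < 2:
            raise ArgumentError("n_strides must be >= 2")
        if TO_FRAC + self.swing_frac >= 1.0:
            raise ArgumentError("swing_frac too large: heel-strike past stride end")


@dataclass
class SyntheticWalk:
    left: DerivedSignals
    right: DerivedSignals
    truth: GoldEventList
    params: SynthParams
    stride_windows: dict = field(default_factory=dict)  # foot -> [Interval]


def _gauss(u: np.ndarray, c: float, w: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - c) / w) ** 2)


def synth_stride(params: SynthParams, duration_s: float | None = None
                 ) -> tuple[np.ndarray, np.ndarray, int, int]:
    """One noiseless stride: ``(omega, jerk, to_offset, hs_offset)``."""
    dur = params.stride_s if duration_s is None else duration_s
    n = int(round(dur * params.fs))
    if n < 10:
        raise ArgumentError(f"stride of {dur} s too short at fs={params.fs}")
    to_off = int(round(TO_FRAC * n))
    hs_off = to_off + int(round(params.swing_frac * n))
    mid = 0.5 * (to_off + hs_off) / n
    u = np.arange(n) / n
    omega = (OMEGA_SWING_AMP * _gauss(u, mid, SWING_W)
             - OMEGA_LOBE_AMP * _gauss(u, to_off / n, LOBE_W)
             - OMEGA_LOBE_AMP * _gauss(u, hs_off / n, LOBE_W)
             - OMEGA_HO_DIP * _gauss(u, HO_FRAC, HO_W))
    jerk = (JERK_BASE
            + JERK_BURST_AMP * _gauss(u, to_off / n, BURST_W)
            + JERK_BURST_AMP * params.hs_jerk_atten * _gauss(u, hs_off / n, BURST_W))
    return omega, jerk, to_off, hs_off


def model_stride(params: SynthParams | None = None) -> ModelStride:
    """The canonical annotated stride (used for the packaged fixture)."""
    params = params or SynthParams()
    omega, jerk, to_off, hs_off = synth_stride(params)
    n = len(omega)
    events = {"FF": int(round(FF_FRAC * n)), "HO": int(round(HO_FRAC * n)),
              "TO": to_off, "HS": hs_off}
    return ModelStride(omega=omega, jerk=jerk, fs=params.fs,
                       events=events).validate()


def _durations(rng: np.random.Generator, mean: float, cv: float,
               count: int) -> np.ndarray:
    if cv == 0:
        return np.full(count, mean)
    return truncnorm.rvs(-3.0, 3.0, loc=mean, scale=cv * mean, size=count,
                         random_state=rng)


def synth_walk(params: SynthParams) -> SyntheticWalk:
    """A two-foot walk with exact ground truth, reproducible from ``seed``."""
    rng = np.random.default_rng(params.seed)
    lead = int(round(params.lead_s * params.fs))
    dur_l = _durations(rng, params.stride_s, params.stride_cv, params.n_strides)
    dur_r = _durations(rng, params.stride_s * params.asym, params.stride_cv,
                       params.n_strides)

    def build(durs: np.ndarray, lead_n: int):
        omega = [np.zeros(lead_n)]
        jerk = [np.full(lead_n, JERK_BASE)]
        truth, windows = [], []
        pos = lead_n
        for d in durs:
            o, j, to_off, hs_off = synth_stride(params, duration_s=float(d))
            omega.append(o)
            jerk.append(j)
            truth.append(("FC", (pos + to_off) / params.fs))
            truth.append(("IC", (pos + hs_off) / params.fs))
            windows.append(Interval(pos, pos + len(o)))
            pos += len(o)
        omega.append(np.zeros(lead))
        jerk.append(np.full(lead, JERK_BASE))
        return np.concatenate(omega), np.concatenate(jerk), truth, windows

    o_l, j_l, truth_l, win_l = build(dur_l, lead)
    o_r, j_r, truth_r, win_r = build(
        dur_r, lead + int(round(0.5 * params.stride_s * params.fs)))

    n = max(len(o_l), len(o_r))
    feet = {}
    truth_events = ([(t, "left", s) for t, s in truth_l]
                    + [(t, "right", s) for t, s in truth_r])
    for foot, (o, j) in (("left", (o_l, j_l)), ("right", (o_r, j_r))):
        o = np.concatenate([o, np.zeros(n - len(o))])
        j = np.concatenate([j, np.full(n - len(j), JERK_BASE)])
        if params.noise_sd > 0:
            o = o + rng.normal(0.0, params.noise_sd * OMEGA_SWING_AMP, n)
            j = j + rng.normal(0.0, params.noise_sd * JERK_BURST_AMP, n)
            o = lowpass_filter(o, params.fs)
            j = np.clip(lowpass_filter(j, params.fs), 0.0, None)
        feet[foot] = DerivedSignals(omega=o, jerk=j, fs=params.fs)

    return SyntheticWalk(left=feet["left"], right=feet["right"],
                         truth=GoldEventList(truth_events), params=params,
                         stride_windows={"left": win_l, "right": win_r})


def render_raw_csv(walk: SyntheticWalk, outdir) -> dict:
    """Write per-foot raw CSVs (io_preproc dialect) plus the gold list.

    The free-acceleration x-channel is the cumulative integral of the jerk
    track, so differentiating it in the preprocessing chain reproduces the
    jerk norm; the gyro y-channel carries omega verbatim.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for foot in ("left", "right"):
        sig: DerivedSignals = getattr(walk, foot)
        acc_x = cumulative_trapezoid(sig.jerk, dx=1.0 / sig.fs, initial=0.0)
        zeros = np.zeros(sig.n)
        df = pd.DataFrame({
            "PacketCounter": np.arange(1, sig.n + 1),
            "freeAccX": acc_x, "freeAccY": zeros, "freeAccZ": zeros,
            "gyrX": zeros, "gyrY": sig.omega, "gyrZ": zeros,
        })
        path = os.path.join(outdir, f"{foot}.csv")
        df.to_csv(path, index=False)
        paths[foot] = path
    gold_path = os.path.join(outdir, "gold.csv")
    write_gold_csv(walk.truth, gold_path)
    paths["gold"] = gold_path
    return paths
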