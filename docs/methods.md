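# Methods

`gaitseg` detects the two gait events that bound the swing phase — toe-off
(TO, the foot leaves the ground) and heel-strike (HS, the foot contacts the
ground) — from a single foot-mounted inertial sensor per foot, with no
per-subject training and no external equipment. It targets not only regular
healthy gait but strongly degraded gait (very slow speeds, high stride-time
variability, attenuated heel-strike impacts), where fixed-rule detectors
tend to fail.

## Signals of interest

From the 100 Hz gravity-free 3-axis acceleration `a(t)` and 3-axis angular
velocity, two scalar series are derived after zero-phase low-pass filtering
(Butterworth, order 8, cut-off 14 Hz) of every raw channel:

* the **sagittal gyration** Ω(t) = ω_y(t) (deg/s), angular velocity about
  the medio-lateral axis: a large positive lobe during swing, negative
  lobes near TO and HS;
* the **jerk norm** J(t) = ‖da/dt‖ (m/s³): sharp non-negative bursts at TO
  and HS, quiet during foot-flat.

Missing samples (identified from the packet counter) are repaired by
quadratic interpolation; a gap longer than 0.5 s invalidates the recording.
Differentiation uses central differences in the interior and one-sided
differences at the boundaries: second-order accurate and lag-free, which
matters because timing errors are scored in milliseconds. The filter is
applied forward-backward; this doubles the effective magnitude order and
removes group delay. Whether the original processing chain was zero-phase
is not documented anywhere we could rely on; we chose zero-phase so that Ω,
J and gold timestamps share a common time base (a single-pass order-8
filter at 14 Hz would delay events by roughly 20–30 ms).

## The four-part detector

**Part 1 — stride period.** The per-foot autocorrelations of Ω and J
(biased estimator, unit lag-0) are averaged into one multiparametric
autocorrelation. The stride lag is the first qualifying peak inside a
physiological band (0.4–4.0 s, covering ~1 s healthy strides down to
0.2–0.3 m/s pathological gait); the shorter of the two per-foot estimates
is kept, L = min(lag_L, lag_R)/fs, to avoid overestimation. A peak
qualifies when its prominence is ≥ 10% **and its height is ≥ 50%** of the
band maximum. The height gate is a deliberate design choice: any gait
signal with sharp jerk bursts at both TO and HS has a genuine secondary
autocorrelation bump at a lag equal to the swing duration (TO bursts
aligning with HS bursts of the same stride), whose normalized height is of
order A·B/(A²+B²) ≈ 0.4 relative to the stride peak for comparable burst
amplitudes A, B. That bump passes a bare prominence test and would halve
the estimated period; it never approaches the height gate, while the true
stride peak is essentially the band maximum. With fs = 100 Hz the lag is
quantized to 10 ms; both fractions are configurable.

**Part 2 — reference stride.** With window length m = L·fs, the matrix
profile of Ω gives each window's z-normalized Euclidean distance to its
nearest neighbor (exclusion zone m/2 for trivial matches); recurring stride
shapes appear as minima. Windows are biased toward swing-centered
placement by the annotation vector

    AV_i = Σ_{k=i+⌊m/3⌋}^{i+⌊2m/3⌋} ( ω_k/ω_max + j_k/j_max ),

with ω_max = max|Ω| and j_max = max J over the whole walk and ω_k kept
signed (a window whose central third holds the negative lobes rather than
the swing lobe is thereby penalized). AV is min-max rescaled to [0, 1]
(a flat AV is treated as all ones, i.e. no correction) and combined as

    CMP_i = MP_i + (1 − AV_i) · max(MP),

so a low-annotation location must beat the best motif by the full MP range
to win. The reference stride is the window at argmin(CMP). The matrix
profile is computed exactly (blocked z-normalized dot products), not
approximated; a brute-force all-pairs scan serves as the test oracle.
Constant windows z-normalize to zero vectors, so quiet lead-in/lead-out
segments never form spurious zero-distance motifs.

**Part 3 — annotation.** A packaged model stride with known event offsets
(FF < HO < TO < HS; TO and HS mandatory, FF and HO indicative) is linearly
resampled to length m (event offsets rescaled proportionally, kept strictly
ordered) and circularly shifted so its gyration maximum coincides with the
reference window's (swing-peak centering; if the shift wraps events across
the window edge the ordering violation is logged, never silently
reordered). Dependent multivariate DTW (mDTWd) then aligns model and
reference: each channel is z-normalized per series, samples are stacked
into 2-D points, the cost of a match is the Euclidean point distance, and
the path — steps (1,0), (0,1), (1,1) from (0,0) to (m−1, m−1) — is
restricted to an Itakura parallelogram with maximum slope 2 (local tempo
distortion at most a factor of two, appropriate because the swing phase is
already centered in both series). Ties in the dynamic program prefer the
diagonal, then the model-advancing step, for reproducible paths. Events
transfer through the path: TO maps to the **last** subject sample matched
to the model's TO, HS to the **first** subject sample matched to the
model's HS — the conservative ends of the matched runs, which bound the
swing phase from inside. The packaged model stride is synthetic (generated
by `gaitseg.synthgait` at default parameters, 1.3 s at 100 Hz), standing in
for an unpublished healthy-subject stride; any user-supplied stride in the
same CSV + JSON format can replace it.

**Part 4 — segmentation.** The annotated reference stride becomes the
matching template for the whole walk. Candidate starts are the local
maxima of the sliding z-normalized correlation between the stacked
(Ω, J) template and the walk. Each candidate window of length m is
re-scored by mDTWd; its dissimilarity is the path cost divided by the path
length. Candidates with dissimilarity above λ = 0.4 are rejected; the rest
are accepted greedily by ascending dissimilarity, subject to a pairwise
window-overlap cap of μ·m samples with μ = 0.1. TO and HS transfer into
every accepted window through its warping path. λ and μ are the published
degraded-gait operating point; their precise semantics are not restated in
the source material, so both are plain configuration here. An empty
detection is a warned, empty result — not an exception.

## Evaluation

Detected TO pair with gold final contacts (FC), detected HS with gold
initial contacts (IC), per foot. Matching is one-to-one and greedy by
ascending absolute time difference (ties: earliest gold, then earliest
detection); a pair is admissible within 20% of a stride duration, taken
from the gold list's mean same-type inter-event interval when available
(the algorithm's L otherwise). Recall = matched gold / total gold,
precision = matched detections / total detections,
F1 = 2·recall·precision/(recall+precision) (zero when both are zero).
Timing errors |Δ_TO|, |Δ_HS| are reported in ms as median, IQR and mean —
both location statistics, since published tables mix the two conventions.
Greedy matching equals optimal assignment except in contrived instances;
it is deterministic, which we weight higher.

## Synthetic gait generator

`synthgait` emulates what the detector consumes, with exact ground truth:
strides start at mid-stance, TO at 30% of the stride, HS at 30% +
swing_frac (default 0.4, so the swing peak sits exactly mid-swing);
Ω is a sum of Gaussians (swing lobe +320 deg/s, TO/HS lobes −90 deg/s,
heel-off dip −25 deg/s), J is a 2 m/s³ baseline plus 60 m/s³ Gaussian
bursts at TO and HS, the HS burst scaled by `hs_jerk_atten`. Stride times
are truncated-normal (±3 SD, keeping durations positive); the right foot
is phase-shifted half a stride and may have a different mean (`asym`).
White noise (SD a fraction of each channel's dominant amplitude, default
0.1) is added and the walk is re-filtered with the same 14 Hz zero-phase
filter as the real chain, so synthetic and real signals share a bandwidth.
Quiet 2 s lead-in/lead-out segments emulate initiation off the walkway.
Defaults (10 strides at 1.3 s, CV 5%) approximate a healthy 10 m walk; the
degraded condition used in the recovery suites (CV 25%, `hs_jerk_atten`
0.3) spans the reported speed gap between healthy and impaired cohorts.
`render_raw_csv` additionally writes raw-format CSVs whose free-acc channel
is the cumulative integral of J (so the preprocessing chain reproduces J by
differentiation) and whose gyro-y channel is Ω verbatim.

What the generator does **not** model: real 3-D limb kinematics, gravity
leakage, sensor drift, turning, double-support irregularities,
stride-to-stride morphology changes beyond amplitude scaling, or
non-HS initial contacts (toe-strike). Passing recovery suites therefore
demonstrates internal correctness of the pipeline under controlled
conditions, not clinical validity on patient data.

## Numerical and design notes

* Problem sizes in tests and the acceptance script: walks of 10 strides
  (~17 s at 100 Hz), 20 seeds per condition, 50-run parameter sweeps —
  enough for stable means at interactive runtimes.
* The DTW dynamic program is a numba kernel; the matrix profile is blocked
  numpy. Both are exact, oracle-checked against brute force.
* Degenerate inputs: constant channels z-normalize to zeros (warned);
  all-zero Ω is a hard error for the annotation vector; signals shorter
  than 2m cannot yield a motif and raise.
* Determinism: detection contains no randomness; the generator is fully
  determined by its seed; JSON outputs are key-sorted with round-trip
  float formatting, so identical configurations reproduce byte-identical
  files.

## Known limitations

* Under very high stride-time variability (CV ≈ 25%) the fixed-length
  template plus endpoint-pinned DTW rejects strides whose duration is far
  from L (normalized dissimilarity above λ), and mean F1 settles just
  around 0.9 rather than near 1: the single-scalar stride period is the
  binding approximation. A multi-length candidate search (`len_band`) is
  scaffolded but off by default.
* L is a single scalar per walk; cadence drift within a walk is not
  tracked.
* Spatial parameters (stride length, speed), u-turns and real-time
  streaming are out of scope.
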