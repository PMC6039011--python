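# Methods

## Model

`mocapfill` treats a capture session as an `N × M × 3` array of marker
positions (millimetres) with an explicit boolean observation mask.
Missing runs ("gaps") per marker are bounded by the last observed frame
`n1` and the first observed frame `n2`; the frames `n1+1 … n2−1` are
reconstructed. The method rests on two assumptions about optical MoCap
of articulated bodies:

* markers attached to the same or an adjacent segment keep a nearly
  constant mutual distance, so the standard deviation `σ_j` of the
  distance between a target and another marker identifies useful
  *reference* markers without any skeleton model;
* the relation between a target and a few good references is smooth and
  low-dimensional, so it can be learned from the observed frames of the
  very sequence being repaired (the method is transductive — there is
  no separate training corpus).

Before any modelling the sequence is centred by subtracting, per frame,
the mean position of the observed markers; this strips the global path
from every trajectory and is undone at the end. Inter-marker distances
are unchanged by centring, so rankings and densities are unaffected.

Four candidate reconstructions per gap (global linear regression; local
interpolation, quadratic regression and Gaussian-kernel regression in a
reference-triad frame), a per-candidate linear continuity ramp, a
per-frame likelihood-weighted average (PMA), and a distance
confidence-interval projection are described in the README; the notes
below record the engineering choices behind them.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `theta` | 50 | mm | σ threshold for global-regression inputs; raise it for sparse marker sets |
| `grnn_s` | 0.3 | – | kernel smoothness on standardized features; larger for slow motion |
| `ci_bounds` | (0.05, 0.95) | – | CDF levels of the spacing-constraint annulus |
| `min_overlap` | 10 | frames | co-observation needed before a marker may act as reference |
| `fallback_k` | 3 | – | lowest-σ gap-complete markers used when nothing passes `theta` |
| `pma_references` | 3 | – | references in the weight product (the observed subset is used when fewer are visible) |
| `stride` | 1 | – | training subsampling; ranking, fitting and density estimation use every `stride`-th frame, prediction stays at full rate |
| `max_spacing_iter` | 10 | sweeps | cap for the recursive spacing projection |

σ uses the sample (ddof = 1) convention, configurable. Benchmarks in
the test-suite and acceptance script run with `stride = 4` at 120 fps;
on smooth motion this changes errors by well under 10%.

## Numerical choices

* **Least squares** via `numpy.linalg.lstsq`; a rank-deficient design
  silently yields the minimum-norm solution (logged at INFO).
* **Triad frames**: a triad is invalid when `‖p2−p1‖ < 1e−6 mm` or the
  sine of the angle at `p1` is below 1e−6 (near-collinear); invalid
  frames fall through to the next reference triplet rather than raising.
  The inverse change of basis is the transpose — never a numeric
  inversion.
* **Triplet succession**: the σ-ordered reference list seeds the triad
  `(r1, r2, r3)`; on failure the highest-σ member implicated in the
  failure is replaced by the next-ranked reference, capped at 120
  triads per gap. This generalises the one worked example of the rule
  (replace `p3` by `p4`) to arbitrary failure patterns.
* **GRNN**: features standardized by training mean/std (zero-variance
  features get std 1 — they carry no information); weights are computed
  in log space with per-query max subtraction; a total underflow falls
  back to the nearest training neighbour.
* **KDE**: Gaussian kernels with Silverman bandwidth
  `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`, floored at 1e−3 mm. The CDF is
  a trapezoid accumulation on a 512-point grid spanning the samples
  ± 3h, renormalised for the ~0.27% tail mass outside; `r`, `R` come
  from monotone inverse interpolation. Density *evaluation* (for PMA
  weights) is the analytic log-sum-exp mixture, so far-out candidates
  receive a small positive likelihood instead of 0. A constant distance
  sample degenerates to the band `median ± h`.
* **PMA weights** are normalised per frame after max-subtraction in log
  space; frames where no density-bearing reference is observed (or the
  product underflows) fall back to uniform weights and are flagged in
  the gap report.
* **Spacing constraint** runs in centred coordinates (distances are
  invariant since target and references share the per-frame offset) and
  only on gap frames. The recursive variant is cyclic projection onto
  up to three annuli — a nonconvex scheme that converges to the
  intersection only up to a small limit cycle: on feasible test
  configurations the residual violation is ≲ 1e−3 mm on ~100 mm radii.
  It is *not* the default (the single-reference projection is), and
  iteration is capped with a warning because three annuli may have an
  empty intersection.
* **One-sided gaps** (sequence boundaries): interpolation holds the
  single border's local coordinates constant; regression models predict
  as usual; the continuity ramp becomes a constant offset from the one
  available border.
* Gap borders are required of GLR design markers as well as the gap
  interior, because the continuity ramp needs model predictions at both
  borders.

## The synthetic benchmark

The generator builds a 15-segment humanoid tree (pelvis root, spine,
head, three-segment arms, three-segment legs) carrying 41 markers at
fixed offsets in their segment frames — the marker-count/frame-rate
regime (41 markers, 120 fps) of the public full-body databases this
method targets. Joint Euler angles are sums of two sinusoids with
random amplitude (up to a per-joint scale, 8–45°), frequency
(0.2–1.2 Hz, ordinary movement tempo) and phase; the root follows a
slow sinusoidal path with yaw. Isotropic Gaussian noise of 0.5 mm
(typical optical-capture accuracy) is added last. Sequences are
deterministic given a seed; gap injection draws markers and start
frames uniformly, keeps observed borders, and never places two gaps on
one marker in a draw.

What the generator does *not* emulate — and what passing tests
therefore do not show about real data:

* **Non-stationarity.** Real motion drifts (turns, posture changes,
  aperiodic actions); the generator is stationary and quasi-periodic.
  Consequently the individual models fit unusually well (errors of a
  few mm rather than tens of mm) and their residuals oscillate at the
  joint frequencies instead of drifting. Two observed consequences,
  documented here because they shape the evaluation results:
  the continuity ramp — which cancels slowly drifting model bias on
  real data — adds variance here for gaps ≥ 1 s, because the border
  errors it anchors to are uncorrelated with the interior errors; and
  the error growth with the number of concomitant gaps is weak, because
  1-s gaps on a 60-s timeline rarely overlap in time and the models
  remain well-trained. The spacing constraint, by contrast, never
  increased the error in any probe. On recordings with genuine drift
  both constraints are expected to pay off far more (that regime is not
  reproducible from synthetic stationary motion).
* **Soft-tissue artefact and marker swap/ghosting** are absent; noise
  is i.i.d. isotropic.
* Arm and leg segments carry only two or three markers, so their
  reference triads necessarily span joints; those markers are the hard
  cases (single-gap errors up to ~30 mm vs ~1 mm for pelvis markers),
  which is a realistic property of sparse marker sets.

## Evaluation protocol

Gaps of equal length are injected at uniformly random markers/frames;
the recovery error is the mean over gaps of the mean per-frame
Euclidean deviation over each gap's missing frames (mm). Experiments
repeat this over independent iterations; a master seed spawns one child
stream per iteration so the gap placements are identical across method
rosters and across swept conditions (conditions with more gaps extend
the smaller condition's placements). The paired constraint test
recovers the same injected gaps with and without the continuity ramp +
spacing constraint and applies a two-sided paired t-test to the
per-iteration errors; zero-variance differences are reported as the
degenerate p = 1 (all-zero) or p = 0 (constant non-zero) case and
flagged.

## Scope and limitations

* File I/O covers CSV/TSV trajectory tables; the reader/writer API is
  format-keyed so a binary C3D backend can be added behind the same
  interface.
* External reconstruction methods can be plugged in by implementing the
  small `RecoveryModel` interface (fit-and-predict per gap); none are
  bundled.
* A marker with no sufficiently co-observed companion is *isolated* and
  reported unrecoverable; frames with zero observed markers (blackouts)
  abort centring — the method fundamentally needs at least three
  visible markers.
* Real-time operation, Kalman smoothing and optimisation-based
  constraint fitting are out of scope.
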