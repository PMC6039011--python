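# mocapfill

Automatic recovery of missing samples in optical motion-capture (MoCap)
marker trajectories.

Optical MoCap tracks retroreflective markers at high frame rates, but
occlusions leave *gaps*: runs of frames in which a marker's 3D position
is unrecorded. `mocapfill` fills those gaps automatically — no skeleton
model, no pre-recorded training set — by ensembling several data-driven
recovery models that are trained on the incomplete sequence itself, and
enforcing soft physical constraints on the result. It is aimed at
biomechanists, movement scientists and animation pipelines that need
complete trajectories before any downstream analysis.

## Method

A sequence is an `N × (3M)` matrix (N frames, M markers, millimetres).
For a missing marker trajectory `m`, every other marker `p_j` is ranked
by the standard deviation of the inter-marker distance,
`σ_j = std‖m − p_j‖`: near-rigid attachment means low `σ_j`, so the
lowest-σ markers act as *references* for reconstruction. Four candidate
reconstructions are produced per gap:

1. **GLR** — global linear regression of each axis of `m` on all markers
   with `σ_j < θ` (default θ = 50 mm) that are observed throughout the gap;
2. **LI** — linear interpolation of `m` expressed in the orthonormal
   coordinate frame built from the reference triad `(p_1, p_2, p_3)`;
3. **LPR** — per-axis least squares of the local coordinates of `m` on
   the quadratic expansion of the triad's three informative coordinates
   `X^l = (x_{p2}, x_{p3}, z_{p3})`;
4. **LGRNN** — a generalized regression neural network (Gaussian-kernel
   Nadaraya–Watson regressor, smoothness `s = 0.3`) on the standardized
   `X^l`.

When a reference is itself missing during part of a gap, the local
models swap in the next-ranked reference and iterate on the residual
frames. Regression candidates get a linear *continuity ramp* so they
match the observed border samples exactly. The candidates are then
combined by **Probabilistic Model Averaging (PMA)**: at each frame,
candidate `k` is weighted by

    ω_k(n) = f_1(d̆_1k(n)) · f_2(d̆_2k(n)) · f_3(d̆_3k(n)),

the product of kernel-density estimates `f_j` of the distances between
`m` and its top three references, evaluated at the candidate's actual
distances `d̆_jk`. Finally a *spacing constraint* projects any recovered
point whose distance to its first reference falls outside the
[5th, 95th]-percentile confidence interval radially onto the nearer
bounding sphere (a recursive variant cycles this over three references).

The package also ships a forward-kinematics synthetic generator
(15-segment humanoid, 41 markers, 120 fps) and the random-gap
evaluation protocol, so everything can be benchmarked without any
recordings.

## Worked example

```python
import numpy as np
from mocapfill import (SyntheticSkeletonConfig, generate_synthetic_sequence,
                       introduce_random_gaps, recover_pma, recovery_error)

cfg = SyntheticSkeletonConfig(duration_s=20.0)          # 41 markers, 120 fps
truth = generate_synthetic_sequence(cfg, seed=1)
masked, gaps = introduce_random_gaps(truth, g=3, gap_seconds=1.0, seed=2)

result = recover_pma(masked, gaps=gaps, stride=4)
for rep in result.reports:
    g = rep.gap
    w = {k: round(v, 2) for k, v in rep.mean_weights.items()}
    print(f"marker {truth.labels[g.marker]:12s} frames {g.n1+2}-{g.n2}: "
          f"weights {w}, spacing moved {rep.constrained_frames} frames")
print(f"mean recovery error: {recovery_error(truth, result.sequence, gaps):.2f} mm")
```

prints

```
marker r_thigh_2    frames 598-717: weights {'glr': 0.05, 'li': 0.63, 'lpr': 0.19, 'lgrnn': 0.13}, spacing moved 2 frames
marker pelvis_5     frames 682-801: weights {'glr': 0.28, 'li': 0.21, 'lpr': 0.29, 'lgrnn': 0.22}, spacing moved 1 frames
marker l_forearm_2  frames 1857-1976: weights {'glr': 0.04, 'li': 0.54, 'lpr': 0.2, 'lgrnn': 0.22}, spacing moved 0 frames
mean recovery error: 3.51 mm
```

Three one-second gaps on random markers are filled with a mean error of
3.51 mm against the known ground truth (marker noise is 0.5 mm). The
per-gap weights show PMA favouring different models for different
markers — local interpolation for the thigh marker, a near-even blend
for the pelvis marker. The same pipeline is available as a
scikit-learn transformer
(`PMAGapFiller().fit_transform(X)` on an `(N, 3M)` array with NaN gaps)
and from the shell:

```bash
mocapfill synth   --out session.csv --duration 20 --seed 1
mocapfill recover --in gapped.csv --out filled.csv --models glr,lpr,lgrnn
mocapfill evaluate --gaps 3 --gap-seconds 1 --iterations 20 --seed 7 --out report.csv
```

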