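"""Trajectory-continuity and soft-skeleton (spacing) constraints.

Two physically motivated corrections applicable to any candidate
reconstruction:

* **Continuity ramp** — body inertia forbids jumps, so the recovered
  trajectory is corrected by a per-axis linear ramp interpolating the
  prediction errors at the two gap borders; after correction the
  candidate matches the observed border samples exactly.

* **Spacing constraint** — the distance between a marker and a closely
  related reference varies little (near-rigid attachment).  The
  distribution of each target-reference distance is estimated by a
  Gaussian kernel density from the observed frames; the 5th and 95th
  percentiles of its CDF define two spheres around the reference, and a
  recovered point falling outside the annulus between them is projected
  radially onto the nearer sphere.  A stricter recursive variant cycles
  the projection over the first few references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import Gap, MotionSequence
from .references import ReferenceRanking

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceDensity",
    "apply_continuity_ramp",
    "estimate_distance_density",
    "project_to_ci",
    "apply_spacing_constraint",
]


def apply_continuity_ramp(
    candidate: np.ndarray,
    frames: np.ndarray,
    seq: MotionSequence,
    gap: Gap,
) -> np.ndarray:
    """Subtract the linear ramp of border prediction errors from a candidate.

    ``candidate`` holds predictions (possibly NaN) at ``frames``, which must
    include any existing gap border.  The per-axis error delta is measured
    at each observed border; over the gap the correction interpolates
    linearly between the two deltas, forcing the corrected candidate
    through the observed border samples.  One-sided gaps get a constant
    offset from the single available border.  Frames outside the gap span
    are untouched by construction (the ramp is only evaluated on
    ``frames``).
    """
    target = gap.marker
    n1, n2 = gap.n1, gap.n2
    out = candidate.copy()

    def border_delta(nb: int) -> np.ndarray | None:
        if not (0 <= nb < seq.n_frames) or not seq.mask[nb, target]:
            return None
        (idx,) = np.nonzero(frames == nb)
        if idx.size == 0 or not np.isfinite(candidate[idx[0]]).all():
            return None
        return candidate[idx[0]] - seq.positions[nb, target, :]

    d1 = border_delta(n1)
    d2 = border_delta(n2)
    if d1 is None and d2 is None:
        logger.info("continuity ramp skipped: no usable border for gap at marker %d",
                    target + 1)
        return out
    if d1 is not None and d2 is not None:
        t = (frames - n1) / (n2 - n1)
        delta = d1[None, :] + t[:, None] * (d2 - d1)[None, :]
    else:
        delta = np.tile(d1 if d1 is not None else d2, (frames.size, 1))
    return out - delta


@dataclass
class DistanceDensity:
    """KDE of one target-reference distance, with CDF and confidence radii.

    The density is a Gaussian mixture centred on the observed distance
    samples with Silverman's rule-of-thumb bandwidth
    ``h = 0.9 min(sd, IQR/1.34) n^(-1/5)`` (floored at 1e-3 mm so a
    constant distance still yields a proper, narrow density).  The CDF is
    accumulated by trapezoidal integration on a regular grid spanning the
    samples ± 3 bandwidths; the confidence radii ``r`` and ``R`` are the
    inverse-interpolated quantiles at ``ci_low`` / ``ci_high``.  Density
    evaluation is analytic (log-sum-exp over kernels), so points beyond
    the grid still receive a small positive likelihood.
    """

    target: int
    reference: int
    samples: np.ndarray
    bandwidth: float
    grid: np.ndarray
    pdf_grid: np.ndarray
    cdf_grid: np.ndarray
    r: float
    R: float
    ci: tuple[float, float]

    def logpdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        h = self.bandwidth
        z = (x[:, None] - self.samples[None, :]) / h
        lognorm = np.log(self.samples.size) + np.log(h) + 0.5 * np.log(2 * np.pi)
        return logsumexp(-0.5 * z ** 2, axis=1) - lognorm

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        return np.interp(np.atleast_1d(x), self.grid, self.cdf_grid, left=0.0, right=1.0)


def _silverman_bandwidth(d: np.ndarray) -> float:
    n = d.size
    sd = np.std(d, ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(d, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34)
    if spread == 0:
        spread = max(sd, iqr / 1.34)
    h = 0.9 * spread * n ** (-0.2)
    return max(h, 1e-3)


def estimate_distance_density(
    seq: MotionSequence,
    target: int,
    reference: int,
    ci_bounds: tuple[float, float] = (0.05, 0.95),
    min_overlap: int = 10,
    grid_points: int = 512,
    stride: int = 1,
) -> DistanceDensity:
    """Estimate the density of the target-reference distance from observed frames."""
    lo, hi = ci_bounds
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("ci_bounds must satisfy 0 <= low < high <= 1")
    both = seq.mask[:, target] & seq.mask[:, reference]
    rows = np.flatnonzero(both)
    if stride > 1:
        rows = rows[::stride]
    if rows.size < min_overlap:
        raise ValueError(
            f"markers {target + 1} and {reference + 1} co-observed in only "
            f"{rows.size} frames (< {min_overlap})"
        )
    d = np.linalg.norm(
        seq.positions[rows, target, :] - seq.positions[rows, reference, :], axis=1
    )
    h = _silverman_bandwidth(d)
    degenerate = d.max() == d.min()
    grid = np.linspace(d.min() - 3 * h, d.max() + 3 * h, grid_points)
    z = (grid[:, None] - d[None, :]) / h
    pdf = np.exp(-0.5 * z ** 2).sum(axis=1) / (d.size * h * np.sqrt(2 * np.pi))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    total = cdf[-1]
    cdf = cdf / total  # renormalise the small tail mass beyond ±3h
    r = float(np.interp(lo, cdf, grid))
    R = float(np.interp(hi, cdf, grid))
    if degenerate or not r < R:  # constant sample: one-bandwidth band around it
        mid = float(np.median(d))
        r, R = mid - h, mid + h
    return DistanceDensity(
        target=target, reference=reference, samples=d, bandwidth=h,
        grid=grid, pdf_grid=pdf, cdf_grid=cdf, r=r, R=R, ci=(lo, hi),
    )


def project_to_ci(
    point: np.ndarray,
    reference: np.ndarray,
    density: DistanceDensity,
    fallback_dir: np.ndarray | None = None,
) -> np.ndarray:
    """Project a point into the annulus r <= ||point - reference|| <= R.

    Points already inside the annulus are returned unchanged; others move
    radially to the nearer sphere.  A point coinciding with the reference
    has no radial direction; it is displaced along ``fallback_dir`` (global
    x by default) to radius r.
    """
    point = np.asarray(point, dtype=float)
    rel = point - reference
    d = float(np.linalg.norm(rel))
    if d == 0.0:
        direction = np.array([1.0, 0.0, 0.0]) if fallback_dir is None else (
            np.asarray(fallback_dir, float) / np.linalg.norm(fallback_dir))
        logger.info("project_to_ci: point coincides with reference; displaced along fallback")
        return reference + density.r * direction
    if density.r <= d <= density.R:
        return point.copy()
    radius = density.r if d < density.r else density.R
    return reference + rel * (radius / d)


def apply_spacing_constraint(
    positions: np.ndarray,
    frames: np.ndarray,
    seq: MotionSequence,
    ranking: ReferenceRanking,
    densities: dict[int, DistanceDensity],
    mode: str = "single",
    max_iter: int = 10,
    n_refs: int = 3,
) -> np.ndarray:
    """Constrain recovered positions to plausible reference distances.

    ``positions`` are recovered coordinates at ``frames`` (gap frames only).
    In ``single`` mode each point is projected onto the confidence annulus
    of the best-ranked reference observed at that frame.  In ``recursive``
    mode the projection cycles over the first ``n_refs`` observed
    references until every constraint is satisfied or ``max_iter`` sweeps
    are exhausted (the confidence annuli may have an empty intersection,
    in which case the last projection wins and a warning is logged).
    """
    if mode not in ("single", "recursive"):
        raise ValueError(f"unknown spacing mode {mode!r}")
    out = positions.copy()
    use = 1 if mode == "single" else n_refs
    for i, n in enumerate(frames):
        if not np.isfinite(out[i]).all():
            continue
        refs = [j for j in ranking.markers
                if seq.mask[n, j] and j in densities][:use]
        if not refs:
            continue
        if mode == "single":
            j = refs[0]
            out[i] = project_to_ci(out[i], seq.positions[n, j, :], densities[j])
            continue
        for sweep in range(max_iter):
            moved = False
            for j in refs:
                proj = project_to_ci(out[i], seq.positions[n, j, :], densities[j])
                if not np.allclose(proj, out[i]):
                    out[i] = proj
                    moved = True
            if not moved:
                break
        else:
            logger.warning(
                "spacing constraint did not converge at frame %d (marker %d); "
                "confidence annuli may not intersect", n + 1, ranking.target + 1,
            )
    return out
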