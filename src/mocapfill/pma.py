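"""Probabilistic Model Averaging (PMA) and the full recovery pipeline.

Each candidate reconstruction is weighted, frame by frame, by how
plausible its distances to the target's best reference markers are under
the kernel-density estimates of those distances:

    w_k(n) = f_1(d_1k(n)) * f_2(d_2k(n)) * f_3(d_3k(n)),

where f_j is the estimated density of the distance between the target
and its j-th reference, and d_jk the candidate's distance to that
reference.  The final trajectory is the per-frame weighted average of
the candidates.  Products are evaluated in log space to avoid underflow
of small likelihoods.

The end-to-end pipeline is: center the sequence, rank references and
estimate distance densities, run each recovery model on each gap, apply
the continuity ramp (except to interpolation, which honours the borders
by construction), average with PMA, apply the spacing constraint, and
translate back to the original coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constraints import (
    DistanceDensity,
    apply_continuity_ramp,
    apply_spacing_constraint,
    estimate_distance_density,
)
from .core import Gap, MotionSequence, center_sequence, decenter_sequence, find_gaps
from .models import Candidate, RecoveryModel, make_models, recover_candidates
from .references import IsolatedMarkerError, ReferenceRanking, rank_references

logger = logging.getLogger(__name__)

__all__ = [
    "PmaWeights",
    "GapReport",
    "RecoveryResult",
    "compute_weights",
    "weighted_average",
    "recover_pma",
]


@dataclass
class PmaWeights:
    """Per-frame, per-candidate normalised weights over a gap's interior."""

    frames: np.ndarray            # (F,) gap interior frame indices
    weights: np.ndarray           # (F, K) normalised; 0 where candidate absent
    fallback: np.ndarray          # (F,) True where uniform fallback was used
    references: tuple[int, ...]   # density-bearing references considered


def compute_weights(
    candidates: Sequence[Candidate],
    seq: MotionSequence,
    densities: dict[int, DistanceDensity],
    ranking: ReferenceRanking,
    n_refs: int = 3,
) -> PmaWeights:
    """Likelihood weights of each candidate at each missing frame.

    At each frame the product runs over the first ``n_refs`` ranked
    references that are observed there and have a density estimate; if
    none qualifies (or all weights underflow) the frame falls back to
    uniform weights over the available candidates and is flagged.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    gap = candidates[0].gap
    frames = gap.interior
    frames = frames[(frames >= 0) & (frames < seq.n_frames)]
    K = len(candidates)
    ranked = [j for j in ranking.markers if j in densities]

    # candidate positions at each frame: (F, K, 3)
    pos = np.full((frames.size, K, 3), np.nan)
    for k, cand in enumerate(candidates):
        idx = np.searchsorted(cand.frames, frames)
        inside = (idx < cand.frames.size)
        idx = np.clip(idx, 0, cand.frames.size - 1)
        hit = inside & (cand.frames[idx] == frames)
        pos[hit, k] = cand.values[idx[hit]]
    have = np.isfinite(pos).all(axis=2)  # (F, K)

    logw = np.zeros((frames.size, K))
    counted = np.zeros(frames.size, dtype=int)
    for j in ranked:
        obs = seq.mask[frames, j] & (counted < n_refs)
        if not obs.any():
            continue
        ref_pos = seq.positions[frames[obs], j, :]
        for k in range(K):
            sel = obs & have[:, k]
            if not sel.any():
                continue
            d = np.linalg.norm(pos[sel, k] - seq.positions[frames[sel], j, :], axis=1)
            logw[sel, k] += densities[j].logpdf(d)
        counted[obs] += 1

    weights = np.zeros((frames.size, K))
    fallback = np.zeros(frames.size, dtype=bool)
    for i in range(frames.size):
        avail = have[i]
        if not avail.any():
            continue
        if counted[i] == 0:
            weights[i, avail] = 1.0 / avail.sum()
            fallback[i] = True
            continue
        lw = logw[i, avail]
        w = np.exp(lw - lw.max())
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            weights[i, avail] = 1.0 / avail.sum()
            fallback[i] = True
        else:
            weights[i, avail] = w / s
    return PmaWeights(frames=frames, weights=weights, fallback=fallback,
                      references=tuple(ranked[:n_refs]))


def weighted_average(candidates: Sequence[Candidate], weights: PmaWeights) -> np.ndarray:
    """Per-frame, per-axis convex combination of the candidates.

    Returns (F, 3) positions over ``weights.frames``; NaN where no
    candidate covered the frame.
    """
    F = weights.frames.size
    out = np.full((F, 3), np.nan)
    for i, n in enumerate(weights.frames):
        acc = np.zeros(3)
        tot = 0.0
        for k, cand in enumerate(candidates):
            w = weights.weights[i, k]
            if w <= 0:
                continue
            v = cand.value_at(n)
            if np.isfinite(v).all():
                acc += w * v
                tot += w
        if tot > 0:
            out[i] = acc / tot
    return out


@dataclass
class GapReport:
    """Diagnostics for one gap: which models ran and how they were weighted."""

    gap: Gap
    models_applied: list[str]
    mean_weights: dict[str, float]
    fallback_frames: int
    constrained_frames: int
    recovered: bool
    reason: str = ""


@dataclass
class RecoveryResult:
    """Outcome of the full pipeline: filled sequence plus per-gap diagnostics."""

    sequence: MotionSequence
    reports: list[GapReport] = field(default_factory=list)

    @property
    def unrecovered(self) -> list[Gap]:
        return [r.gap for r in self.reports if not r.recovered]


def recover_pma(
    seq: MotionSequence,
    gaps: Sequence[Gap] | None = None,
    models: Sequence[RecoveryModel] | Sequence[str] | None = None,
    theta: float = 50.0,
    grnn_s: float = 0.3,
    min_overlap: int = 10,
    fallback_k: int = 3,
    pma_references: int = 3,
    extra_density_refs: int = 3,
    ci_bounds: tuple[float, float] = (0.05, 0.95),
    spacing_mode: str | None = "single",
    max_spacing_iter: int = 10,
    continuity: bool = True,
    stride: int = 1,
    kde_grid: int = 512,
) -> RecoveryResult:
    """Run the complete gap-recovery pipeline on a sequence.

    Parameters mirror the method's tunables: ``theta`` is the distance-
    variability threshold (mm) for global-regression inputs, ``grnn_s``
    the kernel smoothness for standardized features, ``ci_bounds`` the
    spacing-constraint confidence interval, ``spacing_mode`` one of
    ``"single"``, ``"recursive"`` or None (off), and ``stride`` the
    training subsampling factor (reference ranking, model fitting and
    density estimation use every ``stride``-th frame; prediction is always
    at full rate).  Unrecoverable gaps are reported, not raised.
    """
    if gaps is None:
        gaps = find_gaps(seq)
    if not gaps:
        return RecoveryResult(sequence=seq.copy(), reports=[])
    if models is None:
        model_objs = make_models(theta=theta, grnn_s=grnn_s, fallback_k=fallback_k)
    elif all(isinstance(m, str) for m in models):
        model_objs = make_models(tuple(models), theta=theta, grnn_s=grnn_s,
                                 fallback_k=fallback_k)
    else:
        model_objs = list(models)  # type: ignore[arg-type]

    work = center_sequence(seq)
    targets = sorted({g.marker for g in gaps})

    rankings: dict[int, ReferenceRanking] = {}
    densities: dict[int, dict[int, DistanceDensity]] = {}
    reports: list[GapReport] = []
    bad_targets: set[int] = set()
    for t in targets:
        try:
            rankings[t] = _strided_ranking(work, t, min_overlap, stride)
        except IsolatedMarkerError as exc:
            logger.warning("%s", exc)
            bad_targets.add(t)
            continue
        densities[t] = {}
        for j in rankings[t].markers[: pma_references + extra_density_refs]:
            try:
                densities[t][j] = estimate_distance_density(
                    work, t, j, ci_bounds=ci_bounds, min_overlap=min_overlap,
                    grid_points=kde_grid, stride=stride,
                )
            except ValueError:
                continue

    for t in bad_targets:
        for gap in [g for g in gaps if g.marker == t]:
            reports.append(GapReport(gap=gap, models_applied=[], mean_weights={},
                                     fallback_frames=0, constrained_frames=0,
                                     recovered=False, reason="isolated marker"))
    gaps = [g for g in gaps if g.marker not in bad_targets]

    candidates = recover_candidates(model_objs, work, gaps, rankings, stride=stride)

    out_pos = work.positions.copy()
    out_mask = work.mask.copy()
    for gap in gaps:
        cands = candidates[gap]
        ranking = rankings[gap.marker]
        dens = densities[gap.marker]
        if not cands:
            reports.append(GapReport(gap=gap, models_applied=[], mean_weights={},
                                     fallback_frames=0, constrained_frames=0,
                                     recovered=False, reason="no applicable model"))
            continue
        if continuity:
            for cand in cands:
                if not cand.skip_ramp:
                    cand.values = apply_continuity_ramp(cand.values, cand.frames, work, gap)
        weights = compute_weights(cands, work, dens, ranking, n_refs=pma_references)
        avg = weighted_average(cands, weights)
        n_constrained = 0
        if spacing_mode is not None and dens:
            constrained = apply_spacing_constraint(
                avg, weights.frames, work, ranking, dens,
                mode=spacing_mode, max_iter=max_spacing_iter, n_refs=pma_references,
            )
            n_constrained = int((~np.isclose(constrained, avg) & np.isfinite(avg)).any(axis=1).sum())
            avg = constrained
        filled = np.isfinite(avg).all(axis=1)
        out_pos[weights.frames[filled], gap.marker, :] = avg[filled]
        out_mask[weights.frames[filled], gap.marker] = True
        mean_w = {
            cand.model: float(np.nanmean(weights.weights[:, k]))
            for k, cand in enumerate(cands)
        }
        reports.append(GapReport(
            gap=gap,
            models_applied=[c.model for c in cands],
            mean_weights=mean_w,
            fallback_frames=int(weights.fallback.sum()),
            constrained_frames=n_constrained,
            recovered=bool(filled.all()),
            reason="" if filled.all() else "partial recovery",
        ))

    recovered_seq = MotionSequence(
        positions=out_pos, mask=out_mask, fps=work.fps,
        labels=list(work.labels), centered_offset=work.centered_offset,
    )
    return RecoveryResult(sequence=decenter_sequence(recovered_seq), reports=reports)


def _strided_ranking(
    seq: MotionSequence, target: int, min_overlap: int, stride: int
) -> ReferenceRanking:
    if stride <= 1:
        return rank_references(seq, target, min_overlap=min_overlap)
    view = MotionSequence(
        positions=seq.positions[::stride],
        mask=seq.mask[::stride],
        fps=seq.fps / stride,
        labels=list(seq.labels),
    )
    return rank_references(view, target, min_overlap=min_overlap)
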