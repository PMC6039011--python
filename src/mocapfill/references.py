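"""Reference-marker ranking by inter-marker distance variability.

Markers attached to the same (or an adjacent) body segment keep a nearly
constant mutual distance, so the standard deviation of the Euclidean
distance between a target marker and each other marker,

    sigma_j = std( || m(n) - p_j(n) || ),

is a skeleton-free proxy for skeletal relatedness: the lower sigma_j,
the better p_j serves as a *reference* for reconstructing m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Gap, MotionSequence

__all__ = [
    "ReferenceRanking",
    "IsolatedMarkerError",
    "distance_sigma",
    "rank_references",
    "select_design_markers",
]


class IsolatedMarkerError(ValueError):
    """No other marker shares enough observed frames with the target."""


@dataclass(frozen=True)
class ReferenceRanking:
    """Other markers ordered by ascending distance variability sigma_j."""

    target: int
    markers: tuple[int, ...]      # ascending sigma, ties broken by index
    sigmas: tuple[float, ...]     # mm
    overlaps: tuple[int, ...]     # co-observed frame counts

    def __len__(self) -> int:
        return len(self.markers)

    def top(self, k: int) -> tuple[int, ...]:
        return self.markers[:k]


def distance_sigma(
    seq: MotionSequence,
    target: int,
    other: int,
    min_overlap: int = 10,
    ddof: int = 1,
) -> tuple[float, int]:
    """Standard deviation (mm) of the target-other distance over co-observed frames.

    Returns ``(sigma, overlap)``; ``sigma`` is NaN when fewer than
    ``min_overlap`` frames have both markers observed.  ``ddof=1`` (sample
    standard deviation) by default.
    """
    both = seq.mask[:, target] & seq.mask[:, other]
    overlap = int(both.sum())
    if overlap < max(min_overlap, 2):
        return float("nan"), overlap
    diff = seq.positions[both, target, :] - seq.positions[both, other, :]
    dist = np.linalg.norm(diff, axis=1)
    return float(np.std(dist, ddof=ddof)), overlap


def rank_references(
    seq: MotionSequence,
    target: int,
    min_overlap: int = 10,
    ddof: int = 1,
) -> ReferenceRanking:
    """Rank every other marker by ascending sigma_j.

    Markers with insufficient co-observation are dropped.  Ties are broken
    by marker index so the ordering is deterministic.
    """
    tmask = seq.mask[:, target]
    tpos = seq.positions[:, target, :]
    entries: list[tuple[float, int, int]] = []
    for j in range(seq.n_markers):
        if j == target:
            continue
        both = tmask & seq.mask[:, j]
        overlap = int(both.sum())
        if overlap < max(min_overlap, 2):
            continue
        dist = np.linalg.norm(tpos[both] - seq.positions[both, j, :], axis=1)
        entries.append((float(np.std(dist, ddof=ddof)), j, overlap))
    if not entries:
        raise IsolatedMarkerError(
            f"marker {target + 1} ({seq.labels[target]}) shares fewer than "
            f"{min_overlap} observed frames with every other marker"
        )
    entries.sort(key=lambda t: (t[0], t[1]))
    return ReferenceRanking(
        target=target,
        markers=tuple(j for _, j, _ in entries),
        sigmas=tuple(s for s, _, _ in entries),
        overlaps=tuple(o for _, _, o in entries),
    )


def select_design_markers(
    ranking: ReferenceRanking,
    gap: Gap,
    seq: MotionSequence,
    theta: float = 50.0,
    fallback_k: int = 3,
) -> list[int]:
    """Markers usable as regression inputs for one gap.

    A marker qualifies when its distance variability is below ``theta``
    (default 50 mm) *and* it is observed at every missing frame of the gap
    (border frames included where they exist).  When no marker passes the
    variability threshold, the ``fallback_k`` lowest-sigma gap-complete
    markers are used instead so that global regression stays applicable.

    Returns an empty list when no marker at all is observed throughout the
    gap (the model is then inapplicable for this gap).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    frames = gap.interior
    borders = [n for n in (gap.n1, gap.n2) if 0 <= n < seq.n_frames]
    span = np.r_[frames, borders]
    complete = [
        (j, s) for j, s in zip(ranking.markers, ranking.sigmas)
        if seq.mask[span, j].all()
    ]
    if not complete:
        return []
    selected = [j for j, s in complete if s < theta]
    if not selected:
        selected = [j for j, _ in complete[:fallback_k]]
    return selected
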