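"""Individual gap-recovery models.

Four data-driven models produce candidate reconstructions of a missing
marker trajectory, all trained on the incomplete sequence itself:

* **GLR** — global linear regression: per-axis least squares of the
  target on all low-variability markers observed throughout the gap.
* **LI** — local interpolation: linear interpolation of the target's
  coordinates expressed in the frame of a reference triad.
* **LPR** — local polynomial regression: per-axis least squares of the
  local target coordinates on the quadratic expansion of the triad's
  three informative coordinates.
* **LGRNN** — local generalized regression neural network: a Gaussian
  kernel (Nadaraya–Watson) regressor on the standardized triad features;
  its output is bounded by the training extrema, so it cannot predict
  wildly implausible positions.

The three local models share a *triplet iteration*: they start from the
three best references (lowest distance variability) and, whenever a
reference is itself missing or the triad degenerates during part of the
gap, swap in the next-ranked reference and fill the residual frames,
until the gap is recovered or the reference list is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import Gap, MotionSequence
from .local_frames import (
    LocalFrame,
    build_local_frame,
    from_local,
    quadratic_expansion,
    to_local,
    triad_features,
)
from .references import ReferenceRanking, select_design_markers

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "RecoveryModel",
    "GlobalLinearRegression",
    "LocalInterpolation",
    "LocalPolynomialRegression",
    "LocalGRNN",
    "default_models",
    "make_models",
    "recover_candidates",
]

MAX_TRIPLETS = 120  # C(10, 3): cap on reference triads tried per gap


@dataclass
class Candidate:
    """One model's reconstruction of a gap.

    ``frames`` spans the gap borders (clipped to the sequence); ``values``
    is NaN wherever the model could not produce a prediction.  Border
    predictions, where present, are used only by the continuity ramp —
    observed frames are never overwritten in the output sequence.
    """

    model: str
    gap: Gap
    frames: np.ndarray
    values: np.ndarray
    skip_ramp: bool = False
    triplets_used: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def interior_values(self) -> np.ndarray:
        sel = (self.frames > self.gap.n1) & (self.frames < self.gap.n2)
        return self.values[sel]

    @property
    def complete(self) -> bool:
        """True when every missing frame of the gap received a prediction."""
        return bool(np.isfinite(self.interior_values).all())

    def value_at(self, n: int) -> np.ndarray:
        (idx,) = np.nonzero(self.frames == n)
        if idx.size == 0:
            return np.full(3, np.nan)
        return self.values[idx[0]]


def _gap_span(gap: Gap, n_frames: int) -> np.ndarray:
    lo = max(gap.n1, 0)
    hi = min(gap.n2, n_frames - 1)
    return np.arange(lo, hi + 1)


def _training_rows(mask_ok: np.ndarray, gap: Gap, stride: int) -> np.ndarray:
    """Frame indices usable for fitting: observed everywhere needed and
    outside the gap interval, optionally subsampled for speed."""
    ok = mask_ok.copy()
    ok[max(gap.n1 + 1, 0):gap.n2] = False
    rows = np.flatnonzero(ok)
    if stride > 1:
        rows = rows[::stride]
    return rows


class RecoveryModel:
    """Common interface of the individual recovery models.

    Subclasses implement :meth:`recover_gap`, writing predictions only to
    frames inside (or at the borders of) the requested gap.  External
    reconstruction methods can be plugged in by implementing the same
    interface.
    """

    name: str = "base"

    def recover_gap(
        self,
        seq: MotionSequence,
        gap: Gap,
        ranking: ReferenceRanking,
        stride: int = 1,
    ) -> Candidate | None:
        raise NotImplementedError

    def get_params(self) -> dict:
        return dict(self.__dict__)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"


class GlobalLinearRegression(RecoveryModel):
    """Per-axis least squares on all gap-complete, low-variability markers."""

    name = "glr"

    def __init__(self, theta: float = 50.0, fallback_k: int = 3, min_train_frames: int = 0):
        self.theta = theta
        self.fallback_k = fallback_k
        self.min_train_frames = min_train_frames

    def recover_gap(self, seq, gap, ranking, stride=1):
        design = select_design_markers(ranking, gap, seq, theta=self.theta,
                                       fallback_k=self.fallback_k)
        if not design:
            return None
        target = ranking.target
        ok = seq.mask[:, target] & seq.mask[:, design].all(axis=1)
        rows = _training_rows(ok, gap, stride)
        n_cols = 3 * len(design) + 1
        min_rows = max(n_cols + 1, self.min_train_frames)
        if rows.size < min_rows:
            logger.debug("glr: %d training frames < %d required", rows.size, min_rows)
            return None
        X_full = seq.positions[:, design, :].reshape(seq.n_frames, -1)
        X = np.column_stack([X_full[rows], np.ones(rows.size)])
        y = seq.positions[rows, target, :]
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < n_cols:
            logger.info("glr: rank-deficient design (%d < %d); minimum-norm fit", rank, n_cols)
        span = _gap_span(gap, seq.n_frames)
        Xq = np.column_stack([X_full[span], np.ones(span.size)])
        values = Xq @ beta
        return Candidate(model=self.name, gap=gap, frames=span, values=values)


def _advance_triplet(
    triad: list[int],
    refs: Sequence[int],
    cursor: int,
    drop_candidates: Iterable[int],
) -> tuple[list[int], int] | None:
    """Replace one triad member with the next-ranked reference.

    ``triad`` holds rank indices into ``refs``.  Among the members that
    caused the failure (``drop_candidates``, rank indices), the
    highest-variability one is dropped; if none was identified the
    highest-variability member goes.  Returns None when the reference
    list is exhausted.
    """
    if cursor >= len(refs):
        return None
    drop_set = [i for i in drop_candidates if i in triad]
    drop = max(drop_set) if drop_set else max(triad)
    new = [i for i in triad if i != drop] + [cursor]
    return new, cursor + 1


class _LocalModel(RecoveryModel):
    """Shared triplet-iteration machinery for the local models."""

    def _fit_predict(
        self,
        seq: MotionSequence,
        gap: Gap,
        target: int,
        triad_markers: tuple[int, int, int],
        frame: LocalFrame,
        predict_at: np.ndarray,
        stride: int,
    ) -> np.ndarray | None:
        """Return (len(predict_at), 3) local-coordinate predictions or None
        if this triad cannot fit a model.  NaN rows where the triad is
        unusable at an individual frame."""
        raise NotImplementedError

    def recover_gap(self, seq, gap, ranking, stride=1):
        target = ranking.target
        refs = ranking.markers
        if len(refs) < 3:
            return None
        span = _gap_span(gap, seq.n_frames)
        values = np.full((span.size, 3), np.nan)
        interior_sel = (span > gap.n1) & (span < gap.n2)
        triad = [0, 1, 2]
        cursor = 3
        used: list[tuple[int, int, int]] = []
        for _ in range(MAX_TRIPLETS):
            markers = tuple(refs[i] for i in triad)
            frame = build_local_frame(
                seq.positions[:, markers[0], :],
                seq.positions[:, markers[1], :],
                seq.positions[:, markers[2], :],
            )
            todo = span[~np.isfinite(values).all(axis=1)]
            pred = self._fit_predict(seq, gap, target, markers, frame, todo, stride)
            if pred is not None:
                got = np.isfinite(pred).all(axis=1)
                if got.any():
                    used.append(markers)
                idx = np.searchsorted(span, todo[got])
                values[idx] = pred[got]
            if np.isfinite(values[interior_sel]).all():
                break
            # advance: drop the worst triad member that is missing/invalid
            # on the remaining frames (or the worst member outright)
            todo = span[~np.isfinite(values).all(axis=1) & interior_sel]
            missing = [
                i for i in triad
                if not seq.mask[todo, refs[i]].all() or not frame.valid[todo].all()
            ]
            step = _advance_triplet(triad, refs, cursor, missing)
            if step is None:
                break
            triad, cursor = step
        if not np.isfinite(values[interior_sel]).any():
            return None
        return Candidate(
            model=self.name, gap=gap, frames=span, values=values,
            skip_ramp=getattr(self, "_interpolating", False), triplets_used=used,
        )


class LocalInterpolation(_LocalModel):
    """Linear interpolation of the target in a reference-triad frame.

    The target is projected into the triad frame at the gap borders and
    interpolated linearly in local coordinates across the gap, then mapped
    back to global coordinates frame by frame.  This matches the observed
    borders exactly, so no continuity ramp is needed afterwards.  For a
    one-sided gap the single available border's local coordinates are held
    constant.
    """

    name = "li"
    _interpolating = True

    def _fit_predict(self, seq, gap, target, triad_markers, frame, predict_at, stride):
        n1, n2 = gap.n1, gap.n2
        borders = []
        for nb in (n1, n2):
            if 0 <= nb < seq.n_frames and seq.mask[nb, target] \
                    and frame.valid[nb] \
                    and all(seq.mask[nb, j] for j in triad_markers):
                borders.append(nb)
        if not borders:
            return None
        m_local = to_local(seq.positions[:, target, :], frame)
        if len(borders) == 2:
            l1, l2 = m_local[n1], m_local[n2]
            t = (predict_at - n1) / (n2 - n1)
            local_pred = l1[None, :] + t[:, None] * (l2 - l1)[None, :]
        else:
            local_pred = np.tile(m_local[borders[0]], (predict_at.size, 1))
        out = from_local(local_pred, _frame_subset(frame, predict_at))
        # triad members must be observed at the predicted frame
        obs = seq.mask[np.ix_(predict_at, list(triad_markers))].all(axis=1)
        out[~obs] = np.nan
        return out


def _frame_subset(frame: LocalFrame, idx: np.ndarray) -> LocalFrame:
    return LocalFrame(origin=frame.origin[idx], basis=frame.basis[idx], valid=frame.valid[idx])


class LocalPolynomialRegression(_LocalModel):
    """Quadratic regression of local target coordinates on triad features.

    For each local axis, least squares on the 9-term quadratic expansion
    of X^l = (x_p2, x_p3, z_p3) plus an intercept, trained on frames where
    the target and the whole triad are observed (gap frames excluded).
    """

    name = "lpr"

    def __init__(self, min_train_frames: int = 11):
        self.min_train_frames = min_train_frames

    def _fit_predict(self, seq, gap, target, triad_markers, frame, predict_at, stride):
        j1, j2, j3 = triad_markers
        ok = (seq.mask[:, target] & seq.mask[:, j1] & seq.mask[:, j2]
              & seq.mask[:, j3] & frame.valid)
        rows = _training_rows(ok, gap, stride)
        if rows.size < max(11, self.min_train_frames):
            return None
        feats = triad_features(seq.positions[:, j2, :], seq.positions[:, j3, :], frame)
        Xq = quadratic_expansion(feats)
        X = np.column_stack([Xq[rows], np.ones(rows.size)])
        y = to_local(seq.positions[:, target, :], frame)[rows]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        Xp = np.column_stack([Xq[predict_at], np.ones(predict_at.size)])
        local_pred = Xp @ beta
        return from_local(local_pred, _frame_subset(frame, predict_at))


class LocalGRNN(_LocalModel):
    """Gaussian-kernel (Nadaraya–Watson) regression on standardized triad features.

    The prediction at a query is the kernel-weighted mean of the training
    local target coordinates,

        m_l(q) = sum_k m_l(k) exp(-||x(q)-x(k)||^2 / (2 s^2)) / sum_k exp(...),

    with features standardized to zero mean and unit variance on the
    training rows.  The smoothness ``s`` defaults to 0.3 (for standardized
    inputs); larger values suit slow motion, smaller ones sharp motion.
    """

    name = "lgrnn"

    def __init__(self, s: float = 0.3, min_train_frames: int = 1):
        if s <= 0:
            raise ValueError("smoothness s must be positive")
        self.s = s
        self.min_train_frames = min_train_frames

    def _fit_predict(self, seq, gap, target, triad_markers, frame, predict_at, stride):
        j1, j2, j3 = triad_markers
        ok = (seq.mask[:, target] & seq.mask[:, j1] & seq.mask[:, j2]
              & seq.mask[:, j3] & frame.valid)
        rows = _training_rows(ok, gap, stride)
        if rows.size < max(1, self.min_train_frames):
            return None
        feats = triad_features(seq.positions[:, j2, :], seq.positions[:, j3, :], frame)
        y = to_local(seq.positions[:, target, :], frame)[rows]
        mu = feats[rows].mean(axis=0)
        sd = feats[rows].std(axis=0)
        sd[sd == 0] = 1.0  # constant feature carries no information
        Xt = (feats[rows] - mu) / sd
        Xp = (feats[predict_at] - mu) / sd
        # log-space kernel weights, normalised per query
        d2 = ((Xp[:, None, :] - Xt[None, :, :]) ** 2).sum(axis=2)
        logw = -d2 / (2.0 * self.s ** 2)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        wsum = w.sum(axis=1, keepdims=True)
        local_pred = (w @ y) / wsum
        dead = ~np.isfinite(local_pred).all(axis=1)
        if dead.any():  # total underflow: nearest-neighbour fallback
            logger.info("lgrnn: kernel underflow at %d queries; nearest neighbour used",
                        int(dead.sum()))
            nn = d2[dead].argmin(axis=1)
            local_pred[dead] = y[nn]
        return from_local(local_pred, _frame_subset(frame, predict_at))


_MODEL_REGISTRY: dict[str, type] = {
    "glr": GlobalLinearRegression,
    "li": LocalInterpolation,
    "lpr": LocalPolynomialRegression,
    "lgrnn": LocalGRNN,
}


def make_models(
    names: Sequence[str] = ("glr", "li", "lpr", "lgrnn"),
    theta: float = 50.0,
    grnn_s: float = 0.3,
    fallback_k: int = 3,
    min_train_frames: int = 0,
) -> list[RecoveryModel]:
    """Instantiate recovery models by name with shared configuration."""
    models: list[RecoveryModel] = []
    for name in names:
        if name not in _MODEL_REGISTRY:
            raise ValueError(f"unknown model {name!r}; known: {sorted(_MODEL_REGISTRY)}")
        if name == "glr":
            models.append(GlobalLinearRegression(theta=theta, fallback_k=fallback_k,
                                                 min_train_frames=min_train_frames))
        elif name == "li":
            models.append(LocalInterpolation())
        elif name == "lpr":
            models.append(LocalPolynomialRegression(
                min_train_frames=max(11, min_train_frames)))
        else:
            models.append(LocalGRNN(s=grnn_s, min_train_frames=max(1, min_train_frames)))
    return models


def default_models() -> list[RecoveryModel]:
    return make_models()


def recover_candidates(
    models: Sequence[RecoveryModel],
    seq: MotionSequence,
    gaps: Sequence[Gap],
    rankings: dict[int, ReferenceRanking],
    stride: int = 1,
) -> dict[Gap, list[Candidate]]:
    """Apply every model to every gap; inapplicable models are simply absent."""
    out: dict[Gap, list[Candidate]] = {}
    for gap in gaps:
        cands: list[Candidate] = []
        ranking = rankings[gap.marker]
        for model in models:
            cand = model.recover_gap(seq, gap, ranking, stride=stride)
            if cand is not None:
                cands.append(cand)
        out[gap] = cands
    return out
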