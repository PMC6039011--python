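"""Scikit-learn estimator interface to the recovery pipeline.

:class:`PMAGapFiller` is a transformer in the mould of sklearn's
imputers: it consumes an ``(N, 3M)`` array of marker coordinates with
NaN marking missing samples (column order ``x1,y1,z1,x2,...``), learns
the reference rankings and inter-marker distance densities from the
observed entries, and fills the missing runs with the probabilistic
model average.  It composes with sklearn pipelines and clones cleanly
through ``get_params``/``set_params``.

Gap filling is transductive — the statistics come from the very sequence
being repaired — so the idiomatic call is ``fit_transform(X)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import MotionSequence, find_gaps
from .pma import RecoveryResult, recover_pma

__all__ = ["PMAGapFiller"]


class PMAGapFiller(TransformerMixin, BaseEstimator):
    """Fill occlusion gaps in marker trajectories by probabilistic model averaging.

    Parameters
    ----------
    models : tuple of str
        Recovery models to ensemble, a subset of ``("glr", "li", "lpr",
        "lgrnn")``.  A single name yields that model's (constrained)
        output directly.
    theta : float
        Distance-variability threshold (mm) for selecting global linear
        regression inputs.
    grnn_s : float
        Kernel smoothness of the local GRNN on standardized features.
    ci_bounds : tuple of float
        Lower/upper CDF levels of the spacing-constraint confidence
        interval.
    spacing_mode : {"single", "recursive", None}
        Spacing constraint applied to the averaged trajectory; None
        disables it.
    continuity : bool
        Apply the border-matching continuity ramp to regression
        candidates.
    stride : int
        Training subsampling factor (ranking, fitting, density
        estimation); prediction stays at full frame rate.
    fps : float
        Frame rate of the sequences passed as bare arrays.

    Attributes
    ----------
    n_features_in_ : int
        Number of coordinate columns (3M) seen in ``fit``.
    n_markers_ : int
        Number of markers M.
    result_ : RecoveryResult
        Full diagnostics of the last ``transform`` (weights per model,
        constraint activations, unrecovered gaps).

    Examples
    --------
    >>> filler = PMAGapFiller(models=("glr", "lpr", "lgrnn"))
    >>> X_filled = filler.fit_transform(X)   # X: (N, 3M) with NaN gaps
    """

    def __init__(
        self,
        models: tuple[str, ...] = ("glr", "li", "lpr", "lgrnn"),
        theta: float = 50.0,
        grnn_s: float = 0.3,
        min_overlap: int = 10,
        fallback_k: int = 3,
        pma_references: int = 3,
        ci_bounds: tuple[float, float] = (0.05, 0.95),
        spacing_mode: str | None = "single",
        max_spacing_iter: int = 10,
        continuity: bool = True,
        stride: int = 1,
        fps: float = 120.0,
    ):
        self.models = models
        self.theta = theta
        self.grnn_s = grnn_s
        self.min_overlap = min_overlap
        self.fallback_k = fallback_k
        self.pma_references = pma_references
        self.ci_bounds = ci_bounds
        self.spacing_mode = spacing_mode
        self.max_spacing_iter = max_spacing_iter
        self.continuity = continuity
        self.stride = stride
        self.fps = fps

    def _as_sequence(self, X) -> MotionSequence:
        if isinstance(X, MotionSequence):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 3:
            raise ValueError("X must be (N, 3M): x,y,z triplets per marker")
        return MotionSequence.from_array(X, fps=self.fps)

    def fit(self, X, y=None):
        """Validate the input layout and record its dimensions."""
        seq = self._as_sequence(X)
        self.n_features_in_ = 3 * seq.n_markers
        self.n_markers_ = seq.n_markers
        return self

    def transform(self, X) -> np.ndarray:
        """Fill the missing samples of X; observed entries pass through bitwise."""
        check_is_fitted(self, "n_features_in_")
        seq = self._as_sequence(X)
        if 3 * seq.n_markers != self.n_features_in_:
            raise ValueError(
                f"X has {3 * seq.n_markers} columns, expected {self.n_features_in_}")
        result = self._recover(seq)
        self.result_ = result
        out = result.sequence.to_array()
        if isinstance(X, MotionSequence):
            return out
        obs = np.isfinite(np.asarray(X, dtype=float))
        out[obs] = np.asarray(X, dtype=float)[obs]
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)

    def transform_sequence(self, seq: MotionSequence) -> RecoveryResult:
        """Sequence-in, diagnostics-out variant for library users."""
        self.fit(seq)
        result = self._recover(seq)
        self.result_ = result
        return result

    def _recover(self, seq: MotionSequence) -> RecoveryResult:
        return recover_pma(
            seq,
            gaps=find_gaps(seq),
            models=tuple(self.models),
            theta=self.theta,
            grnn_s=self.grnn_s,
            min_overlap=self.min_overlap,
            fallback_k=self.fallback_k,
            pma_references=self.pma_references,
            ci_bounds=self.ci_bounds,
            spacing_mode=self.spacing_mode,
            max_spacing_iter=self.max_spacing_iter,
            continuity=self.continuity,
            stride=self.stride,
        )
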