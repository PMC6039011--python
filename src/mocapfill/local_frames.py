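"""Per-frame local coordinate systems built from marker triads.

Three reference markers (p1, p2, p3) define, at each frame, an
orthonormal right-handed basis:

    u1 = (p2 - p1) / ||p2 - p1||
    u2 = (p2 - p1) x (p3 - p1), normalised      (normal to the triad plane)
    u3 = u1 x u2

Expressing a target trajectory in this frame strips the rigid motion of
the segment carrying the triad, leaving a low-variance residual that is
far easier to interpolate or regress.  In the local frame the triad
itself has a canonical structure: p1 at the origin, p2 on the local
x-axis, p3 in the local x-z plane — so the triad contributes exactly
three informative scalar coordinates per frame,

    X^l = (x_p2, x_p3, z_p3),

which serve as regression inputs for the local models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocalFrame",
    "build_local_frame",
    "to_local",
    "from_local",
    "triad_features",
    "quadratic_expansion",
]

# Triads are degenerate when p1==p2 or the three points are (near) collinear.
_LENGTH_TOL = 1e-6       # mm, minimum ||p2 - p1||
_COLLINEAR_TOL = 1e-6    # minimum sin of the angle at p1


@dataclass
class LocalFrame:
    """Per-frame origin and orthonormal basis, with validity flags."""

    origin: np.ndarray   # (N, 3) = p1
    basis: np.ndarray    # (N, 3, 3), rows u1, u2, u3
    valid: np.ndarray    # (N,) bool

    @property
    def n_frames(self) -> int:
        return self.origin.shape[0]


def build_local_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> LocalFrame:
    """Construct the triad frame at every sample of (N, 3) position arrays.

    Frames where any marker is missing (NaN) or the triad is degenerate
    (coincident p1, p2 or collinear points) are flagged invalid rather
    than raising.
    """
    p1, p2, p3 = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (p1, p2, p3))
    n = p1.shape[0]
    v1 = p2 - p1
    w = p3 - p1
    with np.errstate(invalid="ignore"):
        v2 = np.cross(v1, w)
        l1 = np.linalg.norm(v1, axis=1)
        l2 = np.linalg.norm(v2, axis=1)
        lw = np.linalg.norm(w, axis=1)
        finite = np.isfinite(p1).all(1) & np.isfinite(p2).all(1) & np.isfinite(p3).all(1)
        nondeg = finite & (l1 > _LENGTH_TOL) & (lw > _LENGTH_TOL)
        # sin of the angle between v1 and p3-p1
        nondeg &= np.divide(l2, l1 * lw, out=np.zeros(n), where=nondeg) > _COLLINEAR_TOL

        basis = np.zeros((n, 3, 3))
        u1 = np.divide(v1, l1[:, None], out=np.zeros_like(v1), where=nondeg[:, None])
        u2 = np.divide(v2, l2[:, None], out=np.zeros_like(v2), where=nondeg[:, None])
    u3 = np.cross(u1, u2)
    basis[:, 0], basis[:, 1], basis[:, 2] = u1, u2, u3
    return LocalFrame(origin=p1.copy(), basis=basis, valid=nondeg)


def to_local(m: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Project a global (N, 3) trajectory into the triad frame.

    ``m_l(n) = P(n) @ (m(n) - p1(n))`` with P rows (u1, u2, u3).  Samples at
    invalid frames (or NaN inputs) come back NaN.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    rel = m - frame.origin
    local = np.einsum("nij,nj->ni", frame.basis, rel)
    local[~frame.valid] = np.nan
    return local


def from_local(m_l: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Map local coordinates back to global ones.

    The basis is orthonormal, so the inverse change of basis is the
    transpose: ``m(n) = P(n)^T @ m_l(n) + p1(n)``.
    """
    m_l = np.atleast_2d(np.asarray(m_l, dtype=float))
    out = np.einsum("nji,nj->ni", frame.basis, m_l) + frame.origin
    out[~frame.valid] = np.nan
    return out


def triad_features(p2: np.ndarray, p3: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """The three informative triad coordinates X^l = (x_p2, x_p3, z_p3) per frame."""
    l2 = to_local(p2, frame)
    l3 = to_local(p3, frame)
    return np.column_stack([l2[:, 0], l3[:, 0], l3[:, 2]])


def quadratic_expansion(x: np.ndarray) -> np.ndarray:
    """Expand (…, 3) features to the 9-term quadratic basis.

    Order: X1, X2, X3, X1^2, X2^2, X3^2, X1*X2, X1*X3, X2*X3.
    """
    x = np.asarray(x, dtype=float)
    x1, x2, x3 = x[..., 0], x[..., 1], x[..., 2]
    return np.stack(
        [x1, x2, x3, x1 ** 2, x2 ** 2, x3 ** 2, x1 * x2, x1 * x3, x2 * x3],
        axis=-1,
    )
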