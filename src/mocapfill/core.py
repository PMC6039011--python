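"""Core data model for optical motion-capture trajectories.

A recording is a sequence of ``N`` frames, each holding the 3D positions
(in millimetres) of ``M`` retroreflective markers.  Occlusions leave
*gaps*: maximal runs of frames in which one marker was not observed.
Missing samples are tracked with an explicit boolean mask; the position
array additionally carries NaN at unobserved samples so that accidental
use of missing data fails loudly.

Frames are 0-based internally.  User-facing reports (CLI, diagnostics)
are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionSequence",
    "Gap",
    "BlackoutError",
    "read_sequence",
    "write_sequence",
    "center_sequence",
    "decenter_sequence",
    "find_gaps",
]


class BlackoutError(ValueError):
    """Raised when a frame has no observed marker at all.

    The recovery method needs at least three simultaneously observed
    markers to build reference frames and distance likelihoods; a frame
    with zero observed markers cannot even be centered.
    """


@dataclass(frozen=True)
class Gap:
    """A maximal run of missing frames for one marker.

    ``n1`` is the last observed frame before the gap and ``n2`` the first
    observed frame after it, so the missing interval is ``n1+1 .. n2-1``
    (inclusive).  One-sided gaps touching the sequence boundary have
    ``left_open`` / ``right_open`` set; for those, ``n1`` (resp. ``n2``)
    is -1 (resp. N) and carries no observation.
    """

    marker: int
    n1: int
    n2: int
    left_open: bool = False
    right_open: bool = False

    def __post_init__(self) -> None:
        if self.n1 >= self.n2:
            raise ValueError(f"gap borders must satisfy n1 < n2, got {self.n1} >= {self.n2}")
        if self.n2 - self.n1 < 2:
            raise ValueError("gap interval is empty")

    @property
    def interior(self) -> np.ndarray:
        """Indices of the missing frames, ``n1+1 .. n2-1``."""
        return np.arange(self.n1 + 1, self.n2)

    @property
    def n_missing(self) -> int:
        return self.n2 - self.n1 - 1

    @property
    def two_sided(self) -> bool:
        return not (self.left_open or self.right_open)


@dataclass
class MotionSequence:
    """Marker trajectories with an explicit missing-sample mask.

    Parameters
    ----------
    positions : ndarray, shape (N, M, 3)
        Marker coordinates in millimetres; NaN where unobserved.
    mask : ndarray of bool, shape (N, M)
        True where the marker was observed.
    fps : float
        Frame rate in frames per second.
    labels : list of str
        Unique marker names, length M.
    centered_offset : ndarray, shape (N, 3), optional
        Per-frame mean that was subtracted by :func:`center_sequence`.
    """

    positions: np.ndarray
    mask: np.ndarray
    fps: float
    labels: list[str] = field(default_factory=list)
    centered_offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (N, M, 3)")
        n, m, _ = self.positions.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 frames and 1 marker")
        if self.mask.shape != (n, m):
            raise ValueError("mask shape must be (N, M)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.labels:
            self.labels = [f"m{j + 1}" for j in range(m)]
        if len(self.labels) != m or len(set(self.labels)) != m:
            raise ValueError("labels must be unique and match marker count")
        if not np.all(np.isfinite(self.positions[self.mask])):
            raise ValueError("observed positions must be finite")
        # enforce NaN sentinel at unobserved samples
        self.positions = self.positions.copy()
        self.positions[~self.mask] = np.nan

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "MotionSequence":
        return MotionSequence(
            positions=self.positions.copy(),
            mask=self.mask.copy(),
            fps=self.fps,
            labels=list(self.labels),
            centered_offset=None if self.centered_offset is None else self.centered_offset.copy(),
        )

    def to_frame_table(self) -> pd.DataFrame:
        """Wide table: one row per frame, columns ``<label>_x/_y/_z``."""
        data: dict[str, np.ndarray] = {"frame": np.arange(1, self.n_frames + 1)}
        for j, lab in enumerate(self.labels):
            for a, ax in enumerate("xyz"):
                data[f"{lab}_{ax}"] = self.positions[:, j, a]
        return pd.DataFrame(data)

    @classmethod
    def from_array(
        cls,
        flat: np.ndarray,
        fps: float,
        labels: Sequence[str] | None = None,
    ) -> "MotionSequence":
        """Build from an ``(N, 3M)`` array with NaN marking missing samples."""
        flat = np.asarray(flat, dtype=float)
        if flat.ndim != 2 or flat.shape[1] % 3:
            raise ValueError("flat array must have shape (N, 3M)")
        pos = flat.reshape(flat.shape[0], -1, 3)
        mask = np.all(np.isfinite(pos), axis=2)
        return cls(positions=pos, mask=mask, fps=fps,
                   labels=list(labels) if labels else [])

    def to_array(self) -> np.ndarray:
        """Flatten to ``(N, 3M)`` with NaN at missing samples."""
        return self.positions.reshape(self.n_frames, -1)


def _parse_table(df: pd.DataFrame, path: str, fps: float) -> MotionSequence:
    cols = [c for c in df.columns if c != "frame"]
    if len(cols) % 3:
        raise ValueError(
            f"{path}: expected marker columns in (x,y,z) triplets, got {len(cols)} coordinate columns"
        )
    labels = []
    for k in range(0, len(cols), 3):
        trio = cols[k:k + 3]
        stems = {c.rsplit("_", 1)[0] for c in trio}
        suffixes = [c.rsplit("_", 1)[-1] for c in trio]
        if len(stems) != 1 or suffixes != ["x", "y", "z"]:
            raise ValueError(f"{path}: malformed column triplet {trio!r}; expected <label>_x,_y,_z")
        labels.append(stems.pop())
    values = df[cols].to_numpy(dtype=float)
    return MotionSequence.from_array(values, fps=fps, labels=labels)


def read_sequence(path: str | Path, format: str | None = None, fps: float = 120.0) -> MotionSequence:
    """Read marker trajectories from a TSV/CSV trajectory table.

    The table must have a header row ``frame,<label>_x,<label>_y,<label>_z,...``;
    empty or NaN cells mark missing samples.  Coordinates are assumed to be
    in millimetres.  ``fps`` is taken from the ``# fps=<value>`` comment on
    the first line when present, else from the argument.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {format!r}; supported: tsv, csv")
    sep = "\t" if format == "tsv" else ","
    text = path.read_text()
    file_fps = fps
    if text.startswith("#"):
        header, _, text = text.partition("\n")
        for tok in header.lstrip("#").replace(",", " ").split():
            if tok.startswith("fps="):
                file_fps = float(tok[4:])
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ValueError(f"{path}: could not parse trajectory table: {exc}") from exc
    return _parse_table(df, str(path), file_fps)


def write_sequence(seq: MotionSequence, path: str | Path, format: str | None = None) -> None:
    """Write a sequence as a TSV/CSV trajectory table (NaN cells left empty)."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {format!r}; supported: tsv, csv")
    sep = "\t" if format == "tsv" else ","
    df = seq.to_frame_table()
    with open(path, "w") as fh:
        fh.write(f"# fps={seq.fps:g}\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.6f")


def center_sequence(seq: MotionSequence) -> MotionSequence:
    """Subtract the per-frame mean of the observed markers from every marker.

    Removes the global-motion component so that recovery models see less
    trajectory variance; the offset is stored on the result so
    :func:`decenter_sequence` can restore the original coordinates.
    """
    if not seq.mask.any(axis=1).all():
        bad = int(np.flatnonzero(~seq.mask.any(axis=1))[0])
        raise BlackoutError(f"frame {bad + 1} has no observed marker (blackout)")
    with np.errstate(invalid="ignore"):
        offset = np.nanmean(seq.positions, axis=1)  # (N, 3) over observed markers
    centered = seq.positions - offset[:, None, :]
    prior = seq.centered_offset
    total = offset if prior is None else offset + prior
    return MotionSequence(
        positions=centered, mask=seq.mask, fps=seq.fps,
        labels=list(seq.labels), centered_offset=total,
    )


def decenter_sequence(seq: MotionSequence) -> MotionSequence:
    """Add the stored per-frame mean back (inverse of :func:`center_sequence`)."""
    if seq.centered_offset is None:
        return seq.copy()
    restored = seq.positions + seq.centered_offset[:, None, :]
    return MotionSequence(
        positions=restored, mask=seq.mask, fps=seq.fps,
        labels=list(seq.labels), centered_offset=None,
    )


def find_gaps(seq: MotionSequence, markers: Sequence[int] | None = None) -> list[Gap]:
    """Locate all maximal missing runs per marker.

    Runs touching the first or last frame are flagged one-sided
    (``left_open`` / ``right_open``) and use sentinel borders -1 / N.
    """
    gaps: list[Gap] = []
    n = seq.n_frames
    cols = range(seq.n_markers) if markers is None else markers
    for j in cols:
        missing = ~seq.mask[:, j]
        if not missing.any():
            continue
        # run-length boundaries of the missing indicator
        d = np.diff(missing.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if missing[0]:
            starts = np.r_[0, starts]
        if missing[-1]:
            ends = np.r_[ends, n]
        for s, e in zip(starts, ends):
            gaps.append(Gap(
                marker=j, n1=s - 1, n2=e,
                left_open=(s == 0), right_open=(e == n),
            ))
    return gaps
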