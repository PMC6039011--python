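"""Forward-kinematics generator of synthetic marker data.

Builds articulated-skeleton sequences so that the whole pipeline can be
exercised and benchmarked without real recordings: a tree of rigid
segments, joint angles animated by sums of sinusoids, markers rigidly
attached to segments (fixed offsets in the segment frame), a slow global
path for the root, and isotropic Gaussian measurement noise added last.

Same-segment markers therefore keep exactly constant mutual distances up
to the noise level, which is the property the recovery method exploits.
The default skeleton is a 15-segment humanoid carrying 41 markers at
120 fps — the marker-set regime of common optical-capture databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Gap, MotionSequence

__all__ = [
    "SegmentSpec",
    "SyntheticSkeletonConfig",
    "default_humanoid",
    "generate_synthetic_sequence",
    "introduce_random_gaps",
]


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment: attachment to its parent and its marker cloud."""

    name: str
    parent: str | None          # None for the root
    offset: tuple[float, float, float]   # attachment point in the parent frame, mm
    amplitude_deg: float        # joint-angle sinusoid amplitude scale
    markers: tuple[tuple[float, float, float], ...]  # offsets in the segment frame, mm


def _m(*offsets: tuple[float, float, float]) -> tuple[tuple[float, float, float], ...]:
    return tuple(offsets)


def default_humanoid() -> list[SegmentSpec]:
    """A 15-segment humanoid tree carrying 41 markers."""
    return [
        SegmentSpec("pelvis", None, (0, 0, 0), 10.0,
                    _m((80, 0, 0), (-80, 0, 0), (0, 90, 20), (0, -90, 20), (0, 0, -60))),
        SegmentSpec("spine", "pelvis", (0, 0, 120), 8.0,
                    _m((0, 60, 150), (0, -60, 150), (70, 0, 260), (-70, 0, 260))),
        SegmentSpec("head", "spine", (0, 0, 320), 12.0,
                    _m((0, 70, 120), (0, -70, 120), (60, 0, 160), (-60, 0, 160))),
        SegmentSpec("l_upper_arm", "spine", (0, 190, 280), 45.0,
                    _m((0, 0, -100), (40, 0, -180))),
        SegmentSpec("l_forearm", "l_upper_arm", (0, 20, -260), 35.0,
                    _m((0, 0, -80), (30, 0, -160))),
        SegmentSpec("l_hand", "l_forearm", (0, 0, -240), 15.0,
                    _m((0, 0, -40), (0, 30, -80))),
        SegmentSpec("r_upper_arm", "spine", (0, -190, 280), 45.0,
                    _m((0, 0, -100), (40, 0, -180))),
        SegmentSpec("r_forearm", "r_upper_arm", (0, -20, -260), 35.0,
                    _m((0, 0, -80), (30, 0, -160))),
        SegmentSpec("r_hand", "r_forearm", (0, 0, -240), 15.0,
                    _m((0, 0, -40), (0, -30, -80))),
        SegmentSpec("l_thigh", "pelvis", (0, 100, -40), 35.0,
                    _m((60, 0, -150), (0, 50, -250), (40, 0, -350))),
        SegmentSpec("l_shank", "l_thigh", (0, 0, -420), 30.0,
                    _m((50, 0, -120), (0, 40, -280))),
        SegmentSpec("l_foot", "l_shank", (0, 0, -400), 15.0,
                    _m((120, 0, -40), (40, 40, -50), (-40, 0, -40))),
        SegmentSpec("r_thigh", "pelvis", (0, -100, -40), 35.0,
                    _m((60, 0, -150), (0, -50, -250), (40, 0, -350))),
        SegmentSpec("r_shank", "r_thigh", (0, 0, -420), 30.0,
                    _m((50, 0, -120), (0, -40, -280))),
        SegmentSpec("r_foot", "r_shank", (0, 0, -400), 15.0,
                    _m((120, 0, -40), (40, -40, -50), (-40, 0, -40))),
    ]


@dataclass
class SyntheticSkeletonConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the regime of the recordings the method targets:
    41 markers on a 15-segment humanoid, 120 fps, 60 s, with 0.5 mm
    isotropic marker noise (typical optical-capture accuracy).  Joint
    sinusoid frequencies span 0.2-1.2 Hz (ordinary human movement tempo)
    and the root follows a slow, smooth path.
    """

    segments: list[SegmentSpec] = field(default_factory=default_humanoid)
    fps: float = 120.0
    duration_s: float = 60.0
    noise_std_mm: float = 0.5
    n_harmonics: int = 2
    freq_range_hz: tuple[float, float] = (0.2, 1.2)
    path_amplitude_mm: float = 400.0
    path_freq_hz: float = 0.08

    @property
    def n_markers(self) -> int:
        return sum(len(s.markers) for s in self.segments)

    @property
    def marker_labels(self) -> list[str]:
        return [f"{s.name}_{i + 1}" for s in self.segments for i in range(len(s.markers))]


def generate_synthetic_sequence(
    cfg: SyntheticSkeletonConfig | None = None,
    seed: int = 0,
) -> MotionSequence:
    """Generate a fully observed, deterministic synthetic sequence.

    Forward kinematics over the segment tree: each segment's orientation
    is its parent's composed with an intrinsic x-y-z Euler rotation whose
    angles are sums of sinusoids (random amplitude up to the segment's
    scale, random frequency and phase, all drawn from ``seed``).  Markers
    are placed at fixed offsets in the segment frame; noise is added last.
    """
    cfg = cfg or SyntheticSkeletonConfig()
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.fps))
    if n < 2:
        raise ValueError("duration too short")
    t = np.arange(n) / cfg.fps

    by_name = {s.name: s for s in cfg.segments}
    order = [s.name for s in cfg.segments]
    for s in cfg.segments:
        if s.parent is not None and s.parent not in by_name:
            raise ValueError(f"segment {s.name!r} has unknown parent {s.parent!r}")

    def angle_signal(amp_deg: float) -> np.ndarray:
        out = np.zeros(n)
        for _ in range(cfg.n_harmonics):
            a = rng.uniform(0.3, 1.0) * amp_deg
            f = rng.uniform(*cfg.freq_range_hz)
            phi = rng.uniform(0, 2 * np.pi)
            out += a * np.sin(2 * np.pi * f * t + phi)
        return np.deg2rad(out / cfg.n_harmonics)

    rotations: dict[str, Rotation] = {}
    origins: dict[str, np.ndarray] = {}
    markers: list[np.ndarray] = []
    for name in order:
        s = by_name[name]
        angles = np.column_stack([angle_signal(s.amplitude_deg) for _ in range(3)])
        local_rot = Rotation.from_euler("xyz", angles)
        if s.parent is None:
            # global path: smooth translation plus slow yaw of the root
            pf = cfg.path_freq_hz
            path = np.column_stack([
                cfg.path_amplitude_mm * np.sin(2 * np.pi * pf * t),
                cfg.path_amplitude_mm * np.sin(2 * np.pi * pf * 0.7 * t + 1.0),
                1000.0 + 30.0 * np.sin(2 * np.pi * 2 * pf * t),
            ])
            yaw = np.deg2rad(20.0) * np.sin(2 * np.pi * pf * t)
            base = Rotation.from_euler("z", yaw[:, None])
            rotations[name] = base * local_rot
            origins[name] = path
        else:
            pr = rotations[s.parent]
            rotations[name] = pr * local_rot
            origins[name] = origins[s.parent] + pr.apply(np.asarray(s.offset, float))
        rot = rotations[name]
        for off in s.markers:
            markers.append(origins[name] + rot.apply(np.asarray(off, float)))

    positions = np.stack(markers, axis=1)  # (N, M, 3)
    if cfg.noise_std_mm > 0:
        positions = positions + rng.normal(0.0, cfg.noise_std_mm, positions.shape)
    mask = np.ones(positions.shape[:2], dtype=bool)
    return MotionSequence(positions=positions, mask=mask, fps=cfg.fps,
                          labels=cfg.marker_labels)


def introduce_random_gaps(
    seq: MotionSequence,
    g: int,
    gap_seconds: float,
    seed: int | np.random.Generator = 0,
) -> tuple[MotionSequence, list[Gap]]:
    """Mask ``g`` random gaps of equal length (uniform marker and start frame).

    Each gap keeps observed border frames on both sides; at most one gap
    per marker per draw (collisions are resampled).  Gaps across markers
    may overlap in time — simultaneous ("concomitant") gaps are exactly
    the hard case the evaluation probes.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = int(round(gap_seconds * seq.fps))
    if length < 2:
        raise ValueError("gap must span at least 2 frames")
    n = seq.n_frames
    if length > n - 2:
        raise ValueError(f"gap of {length} frames does not fit in {n}-frame sequence")
    if g > seq.n_markers:
        raise ValueError(f"cannot place {g} single-marker gaps among {seq.n_markers} markers")
    masked = seq.copy()
    gaps: list[Gap] = []
    used: set[int] = set()
    attempts = 0
    while len(gaps) < g:
        attempts += 1
        if attempts > 1000 * g:
            raise ValueError("could not place gaps with observed borders; sequence too sparse")
        j = int(rng.integers(seq.n_markers))
        if j in used:
            continue
        start = int(rng.integers(1, n - length))  # first missing frame
        n1, n2 = start - 1, start + length
        span_ok = seq.mask[n1, j] and seq.mask[n2, j] and seq.mask[start:n2, j].all()
        if not span_ok:
            continue
        used.add(j)
        masked.mask[start:n2, j] = False
        masked.positions[start:n2, j, :] = np.nan
        gaps.append(Gap(marker=j, n1=n1, n2=n2))
    return masked, gaps
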