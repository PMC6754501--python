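"""Core data types shared across the stack."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

PHASE_STEP = 2.0 * np.pi / 3.0
N_ANGLES = 3
N_PHASES = 3
FRAMES_PER_SET = N_ANGLES * N_PHASES

__all__ = [
    "FRAMES_PER_SET",
    "FrameRecord",
    "IlluminationParams",
    "N_ANGLES",
    "N_PHASES",
    "PHASE_STEP",
    "RawSimSet",
]


@dataclass
class IlluminationParams:
    """Per-angle illumination pattern parameters.

    Attributes
    ----------
    wave_vectors : (3, 2) array of pattern wave vectors (ky, kx) in cycles/µm
    start_phases : (3,) pattern phase of the FIRST frame of each angle (rad)
    modulation : pattern contrast m in (0, 1] (values slightly above 1 are
        tolerated with a warning at estimation time)
    phase_step : phase increment between consecutive frames of an angle;
        fixed 2π/3 in this stack
    scores : optional per-angle estimation quality scores
    """

    wave_vectors: np.ndarray
    start_phases: np.ndarray
    modulation: float
    phase_step: float = PHASE_STEP
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wave_vectors = np.asarray(self.wave_vectors, dtype=float)
        self.start_phases = np.asarray(self.start_phases, dtype=float)
        if self.wave_vectors.shape != (N_ANGLES, 2):
            raise ValueError(
                f"expected {N_ANGLES} wave vectors of shape (3, 2), got {self.wave_vectors.shape}"
            )
        if self.start_phases.shape != (N_ANGLES,):
            raise ValueError(f"expected {N_ANGLES} start phases, got {self.start_phases.shape}")
        if self.modulation < 0:
            raise ValueError(f"modulation must be non-negative, got {self.modulation}")

    def phases_for_angle(self, angle: int) -> np.ndarray:
        """The three pattern phases of frames (angle, 0..2)."""
        return self.start_phases[angle] + self.phase_step * np.arange(N_PHASES)

    def pattern_magnitudes(self) -> np.ndarray:
        return np.hypot(self.wave_vectors[:, 0], self.wave_vectors[:, 1])

    def angle_spacings_deg(self) -> np.ndarray:
        """Pairwise angular spacings between consecutive pattern orientations (deg, mod 180)."""
        ang = np.degrees(np.arctan2(self.wave_vectors[:, 0], self.wave_vectors[:, 1])) % 180.0
        d = np.diff(np.concatenate([ang, ang[:1] + 180.0]))
        return np.abs(((d + 90.0) % 180.0) - 90.0)


@dataclass
class RawSimSet:
    """One channel's nine raw frames (3 angles × 3 phases), angle-major order.

    ``frames[3a + p]`` is the frame for angle ``a``, phase index ``p``.
    """

    frames: np.ndarray
    channel_id: int = 0
    exposure_ms: float = 1.0
    timestamps_ns: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] != FRAMES_PER_SET:
            raise ValueError(
                f"expected {FRAMES_PER_SET} frames of identical shape, got array "
                f"of shape {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("raw frames must be non-negative")
        if np.issubdtype(self.frames.dtype, np.integer) and self.frames.max(initial=0) > 0xFFFF:
            raise ValueError("integer raw frames must be 16-bit representable")
        if self.timestamps_ns is None:
            self.timestamps_ns = np.arange(FRAMES_PER_SET, dtype=np.int64)
        self.timestamps_ns = np.asarray(self.timestamps_ns, dtype=np.int64)
        if self.timestamps_ns.shape != (FRAMES_PER_SET,):
            raise ValueError("need one timestamp per frame")
        if np.any(np.diff(self.timestamps_ns) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frames_for_angle(self, angle: int) -> np.ndarray:
        if not 0 <= angle < N_ANGLES:
            raise IndexError(f"angle index out of range: {angle}")
        return self.frames[N_PHASES * angle: N_PHASES * (angle + 1)]


@dataclass
class FrameRecord:
    """A single raw frame with full acquisition bookkeeping (stream atom)."""

    image: np.ndarray
    channel_id: int
    sequence_index: int
    angle_index: int
    phase_index: int
    timestamp_ns: int

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("frame image must be 2D")
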