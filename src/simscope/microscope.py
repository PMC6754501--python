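"""The virtual microscope: sinusoidal two-beam illumination, OTF blur,
camera noise, multi-channel mis-registration and timestamped frame streams.

Forward model per raw frame (fluorescence is incoherent, so the pattern
multiplies the sample *before* the detection blur)::

    counts = quantize( Poisson( scale · blur(phantom × illumination) )
                       + Gaussian(0, read_noise) + offset )
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import scipy.ndimage as ndi

from simscope.model import (FRAMES_PER_SET, N_ANGLES, N_PHASES, FrameRecord,
                            IlluminationParams, RawSimSet)
from simscope.optics import OtfModel
from simscope.phantoms import Phantom
from simscope.timing import TimingConfig, plan_acquisition, timestamp_series

__all__ = [
    "CameraModel",
    "default_illumination",
    "simulate_multichannel_sequence",
    "simulate_raw_set",
    "sinusoidal_illumination",
]

CAMERA_OFFSET_DEFAULT = 100.0  # sCMOS-like baseline, counts


@dataclass(frozen=True)
class CameraModel:
    """Noise/quantization model of the virtual sCMOS camera."""

    read_noise_e: float = 1.2
    offset: float = CAMERA_OFFSET_DEFAULT
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.read_noise_e < 0 or self.offset < 0:
            raise ValueError("noise parameters must be non-negative")


def sinusoidal_illumination(shape: tuple[int, int], pixel_size: float,
                            p: Sequence[float], phase: float, m: float) -> np.ndarray:
    """Two-beam interference pattern ``I(r) = 1 + m·cos(2π p·r + φ)``.

    ``p`` is the pattern wave vector (ky, kx) in cycles/µm; positions are
    pixel centers in µm.  The spatial mean over a whole number of periods is 1.
    """
    if not 0 <= m <= 1:
        raise ValueError(f"modulation must be in [0, 1], got {m}")
    ky, kx = float(p[0]), float(p[1])
    y = np.arange(shape[0]) * pixel_size
    x = np.arange(shape[1]) * pixel_size
    arg = 2.0 * np.pi * (ky * y[:, None] + kx * x[None, :]) + phase
    return 1.0 + m * np.cos(arg)


def _blur(image: np.ndarray, otf_grid: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(image) * otf_grid).real


def default_illumination(otf: OtfModel, *, k_fraction: float = 0.8, modulation: float = 0.9,
                         start_phases: Sequence[float] = (0.0, 0.0, 0.0),
                         angle_offset_deg: float = 10.0) -> IlluminationParams:
    """Three pattern orientations 60° apart at ``k_fraction·k_c``."""
    k_mag = k_fraction * otf.cutoff
    angles = np.radians(angle_offset_deg + 60.0 * np.arange(N_ANGLES))
    wave_vectors = k_mag * np.stack([np.sin(angles), np.cos(angles)], axis=1)
    return IlluminationParams(wave_vectors=wave_vectors,
                              start_phases=np.asarray(start_phases, dtype=float),
                              modulation=modulation)


def simulate_raw_set(phantom: Phantom, illum: IlluminationParams, otf: OtfModel,
                     photons_scale: float = 1.0, seed: int = 0, *,
                     camera: CameraModel | None = None, noiseless: bool = False,
                     channel_id: int = 0, exposure_ms: float = 1.0,
                     timestamps_ns: np.ndarray | None = None) -> RawSimSet:
    """Image a phantom through the full 9-frame SIM sequence, angle-major.

    With ``noiseless=True`` frames stay float and skip noise, offset and
    quantization (the scale is still applied).
    """
    camera = camera or CameraModel()
    if phantom.image.shape != otf.grid_shape:
        raise ValueError(
            f"phantom grid {phantom.image.shape} does not match OTF grid {otf.grid_shape}")
    if abs(phantom.pixel_size - otf.pixel_size) > 1e-12:
        raise ValueError("phantom and OTF pixel sizes disagree")
    if photons_scale < 0:
        raise ValueError("photons_scale must be non-negative")
    cutoff = otf.cutoff
    if np.any(illum.pattern_magnitudes() >= cutoff):
        raise ValueError("pattern frequency must lie inside the detection cutoff")

    otf_grid = otf.otf_grid()
    rng = np.random.default_rng(seed)
    frames = np.empty((FRAMES_PER_SET,) + phantom.image.shape,
                      dtype=float if noiseless else np.uint16)
    for a in range(N_ANGLES):
        phases = illum.phases_for_angle(a)
        for j in range(N_PHASES):
            pattern = sinusoidal_illumination(phantom.image.shape, phantom.pixel_size,
                                              illum.wave_vectors[a], phases[j],
                                              illum.modulation)
            signal = photons_scale * _blur(phantom.image * pattern, otf_grid)
            signal = np.clip(signal, 0.0, None)
            if noiseless:
                frames[N_PHASES * a + j] = signal
            else:
                counts = rng.poisson(signal).astype(float)
                counts += rng.normal(0.0, camera.read_noise_e, size=signal.shape)
                counts += camera.offset
                counts = np.clip(counts, 0.0, 0xFFFF)
                frames[N_PHASES * a + j] = (np.round(counts).astype(np.uint16)
                                            if camera.quantize else counts)
    if timestamps_ns is None:
        plan = plan_acquisition(TimingConfig(exposure_ms=exposure_ms,
                                             roi_lines=min(phantom.image.shape[0], 2048)))
        timestamps_ns, _ = timestamp_series(plan, 1)
    return RawSimSet(frames=frames, channel_id=channel_id, exposure_ms=exposure_ms,
                     timestamps_ns=timestamps_ns,
                     meta={"phantom_kind": phantom.kind, "seed": seed,
                           "noiseless": noiseless, "photons_scale": photons_scale})


def _warp_affine(image: np.ndarray, matrix: np.ndarray, shift: Sequence[float]) -> np.ndarray:
    """Warp ground truth: output(r) = image(M·r + shift), bilinear."""
    return ndi.affine_transform(image, np.asarray(matrix, dtype=float),
                                offset=np.asarray(shift, dtype=float), order=1,
                                mode="constant", cval=0.0)


def simulate_multichannel_sequence(
        phantoms: Sequence[Phantom], illums: Sequence[IlluminationParams],
        otfs: Sequence[OtfModel], n_timepoints: int, *,
        misregistration: Sequence[tuple[np.ndarray, Sequence[float]]] | None = None,
        drift_per_timepoint: Sequence[float] = (0.0, 0.0),
        photons_scale: float = 1.0, camera: CameraModel | None = None,
        noiseless: bool = False, seed: int = 0,
        timing: TimingConfig | None = None) -> Iterator[FrameRecord]:
    """Emit timestamped frames in the interleaved acquisition order.

    Channels are exposed round-robin within each raw-frame slot (the order
    the timing planner produces).  Channel ``c``'s ground truth is warped by
    its mis-registration affine before imaging; a global drift accumulates
    per timepoint.  Sequence indices count per channel.
    """
    n_channels = len(phantoms)
    if not 1 <= n_channels <= 3:
        raise ValueError(f"channel count must be 1..3, got {n_channels}")
    if len(illums) != n_channels or len(otfs) != n_channels:
        raise ValueError("phantoms, illums and otfs must have equal lengths")
    if misregistration is None:
        misregistration = [(np.eye(2), (0.0, 0.0))] * n_channels
    timing = timing or TimingConfig(n_channels=n_channels)
    if timing.n_channels != n_channels:
        raise ValueError("timing config channel count mismatch")
    plan = plan_acquisition(timing)

    drift = np.asarray(drift_per_timepoint, dtype=float)
    for t_idx in range(n_timepoints):
        sets = []
        for c in range(n_channels):
            matrix, shift = misregistration[c]
            total_shift = np.asarray(shift, dtype=float) + t_idx * drift
            ph = phantoms[c]
            warped = Phantom(image=_warp_affine(ph.image, matrix, total_shift),
                             kind=ph.kind, seed=ph.seed, pixel_size=ph.pixel_size,
                             centers=ph.centers, params=ph.params)
            sets.append(simulate_raw_set(
                warped, illums[c], otfs[c], photons_scale,
                seed=seed + 1000 * t_idx + c, camera=camera, noiseless=noiseless,
                channel_id=c, exposure_ms=timing.exposure_ms))
        raw_ts, _ = timestamp_series(plan, 1, t0_ns=int(round(t_idx * plan.cycle_ms * 1e6)))
        slot = 0
        for raw_idx in range(FRAMES_PER_SET):
            for c in range(n_channels):
                yield FrameRecord(
                    image=sets[c].frames[raw_idx], channel_id=c,
                    sequence_index=t_idx * FRAMES_PER_SET + raw_idx,
                    angle_index=raw_idx // N_PHASES, phase_index=raw_idx % N_PHASES,
                    timestamp_ns=int(raw_ts[slot]))
                slot += 1
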