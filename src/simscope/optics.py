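"""Frequency grids, diffraction cutoff and the ideal incoherent 2D OTF/PSF.

All spatial frequencies are in cycles/µm, all lengths in µm.  Frequency
arrays follow the standard DFT layout with DC in the corner (``numpy.fft``
convention); centered views are produced only for display/export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OtfModel",
    "diffraction_cutoff",
    "frequency_axes",
    "ideal_otf_2d",
    "make_frequency_grid",
    "psf_from_otf",
]


def diffraction_cutoff(na: float, em_wavelength: float) -> float:
    """Incoherent detection cutoff ``k_c = 2·NA/λ`` in cycles/µm.

    Parameters
    ----------
    na : numerical aperture (0 < na < 2)
    em_wavelength : emission wavelength in µm (> 0)
    """
    if not 0 < na < 2:
        raise ValueError(f"numerical aperture must be in (0, 2), got {na}")
    if em_wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {em_wavelength}")
    return 2.0 * na / em_wavelength


def _check_grid_shape(shape: tuple[int, int]) -> tuple[int, int]:
    if len(shape) != 2:
        raise ValueError(f"shape must be 2D, got {shape}")
    rows, cols = int(shape[0]), int(shape[1])
    for n in (rows, cols):
        if n < 8:
            raise ValueError(f"grid dimensions must be >= 8, got {shape}")
        if n % 2:
            raise ValueError(f"grid dimensions must be even, got {shape}")
    return rows, cols


def frequency_axes(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis spatial-frequency samples (cycles/µm), DC first (fftfreq layout)."""
    rows, cols = _check_grid_shape(shape)
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    fy = np.fft.fftfreq(rows, d=pixel_size)
    fx = np.fft.fftfreq(cols, d=pixel_size)
    return fy, fx


def make_frequency_grid(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Per-pixel spatial-frequency magnitude map |k| in cycles/µm.

    DC sits in the ``[0, 0]`` corner; the Nyquist magnitude along each axis is
    ``1/(2·pixel_size)``.
    """
    fy, fx = frequency_axes(shape, pixel_size)
    return np.hypot(fy[:, None], fx[None, :])


@dataclass(frozen=True)
class OtfModel:
    """Ideal incoherent 2D transfer model on a fixed frequency grid.

    Attributes
    ----------
    na : numerical aperture
    em_wavelength : emission wavelength (µm)
    pixel_size : projected pixel pitch in sample space (µm)
    grid_shape : (rows, cols) of the frequency grid the model evaluates on
    """

    na: float
    em_wavelength: float
    pixel_size: float
    grid_shape: tuple[int, int] = (512, 512)
    cutoff: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cutoff", diffraction_cutoff(self.na, self.em_wavelength))
        _check_grid_shape(self.grid_shape)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    def frequency_grid(self, shape: tuple[int, int] | None = None,
                       pixel_size: float | None = None) -> np.ndarray:
        return make_frequency_grid(shape or self.grid_shape, pixel_size or self.pixel_size)

    def otf_grid(self, shape: tuple[int, int] | None = None,
                 pixel_size: float | None = None) -> np.ndarray:
        """OTF values on the (DC-at-corner) frequency grid."""
        return ideal_otf_2d(self, self.frequency_grid(shape, pixel_size))


def ideal_otf_2d(model: OtfModel, k: np.ndarray | float) -> np.ndarray | float:
    """Ideal incoherent 2D OTF value(s) at frequency magnitude ``k`` (cycles/µm).

    ``otf(k) = (2/π)·(arccos ρ − ρ·√(1−ρ²))`` with ``ρ = k/k_c``, zero beyond
    the cutoff.  Real, in [0, 1], radially symmetric and monotonically
    non-increasing.
    """
    karr = np.asarray(k, dtype=float)
    if np.any(karr < 0):
        raise ValueError("frequency magnitudes must be non-negative")
    rho = np.clip(karr / model.cutoff, 0.0, 1.0)
    val = (2.0 / np.pi) * (np.arccos(rho) - rho * np.sqrt(1.0 - rho * rho))
    val = np.where(karr >= model.cutoff, 0.0, val)
    if np.isscalar(k):
        return float(val)
    return val


def psf_from_otf(model: OtfModel) -> np.ndarray:
    """Real-space PSF: centered, real, non-negative, normalized to unit sum."""
    otf = model.otf_grid()
    psf = np.fft.ifft2(otf)
    psf = np.fft.fftshift(psf.real)
    # tiny negative ringing from the discrete transform is clipped
    psf = np.clip(psf, 0.0, None)
    return psf / psf.sum()
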