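"""Illumination-parameter recovery from a raw SIM set.

Band separation inverts, per spatial frequency, the 3×3 phase-mixing system

    D_j(k) = S_0(k) + (m/2)·e^{+iφ_j}·S_{+1}(k) + (m/2)·e^{−iφ_j}·S_{−1}(k)

where ``S_{+1}(k) = OTF(k)·S̃(k − p)`` holds the object spectrum shifted by
the pattern wave vector ``p``.  The wave vector is found by maximizing the
cross-correlation between the zero-order and the shifted first-order band
over their OTF overlap; the complex correlation factor at the optimum yields
the start phase (argument) and the modulation depth (magnitude).

Separation for estimation uses a provisional ``m = 1``; the final estimate
enters only the reconstruction weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from simscope.model import N_ANGLES, N_PHASES, IlluminationParams, RawSimSet
from simscope.optics import OtfModel, ideal_otf_2d, make_frequency_grid

__all__ = [
    "BandSet",
    "DegeneratePhasesError",
    "EstimationError",
    "estimate_k_coarse",
    "fit_channel_params",
    "refine_k_subpixel",
    "remix_bands",
    "separate_bands",
]

MIN_COARSE_SCORE = 0.2  # below this the data is considered pattern-free
OTF_SUPPORT_EPS = 1e-3


class EstimationError(RuntimeError):
    pass


class DegeneratePhasesError(EstimationError):
    """Raised when the three phases do not span the mixing system."""


@dataclass
class BandSet:
    """Separated Fourier bands for one angle (DC-at-corner layout).

    ``band0`` is the unshifted component; ``band_plus``/``band_minus`` hold
    the ±1 components still centered at their acquisition position.
    """

    band0: np.ndarray
    band_plus: np.ndarray
    band_minus: np.ndarray
    phases: np.ndarray
    modulation_assumed: float


def _mixing_matrix(phases: np.ndarray, m: float) -> np.ndarray:
    # column order: b = 0, +1, -1
    c = np.array([1.0, m / 2.0, m / 2.0])
    b = np.array([0.0, 1.0, -1.0])
    return c[None, :] * np.exp(1j * b[None, :] * np.asarray(phases)[:, None])


def separate_bands(frames: np.ndarray, phases: np.ndarray, m: float = 1.0) -> BandSet:
    """Unmix three phase frames of one angle into S_0, S_+1, S_-1.

    Exact per-frequency 3×3 inversion; raises :class:`DegeneratePhasesError`
    when the phases are not distinct mod 2π.
    """
    frames = np.asarray(frames, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if frames.shape[0] != N_PHASES or frames.ndim != 3:
        raise ValueError(f"expected 3 frames, got shape {frames.shape}")
    if phases.shape != (N_PHASES,):
        raise ValueError("expected 3 phases")
    M = _mixing_matrix(phases, m)
    if np.linalg.cond(M) > 1e8:
        raise DegeneratePhasesError(
            f"phase set {phases} is degenerate (singular mixing matrix)")
    Minv = np.linalg.inv(M)
    spectra = np.fft.fft2(frames, axes=(-2, -1))
    bands = np.tensordot(Minv, spectra, axes=(1, 0))
    return BandSet(band0=bands[0], band_plus=bands[1], band_minus=bands[2],
                   phases=phases, modulation_assumed=m)


def remix_bands(bands: BandSet) -> np.ndarray:
    """Rebuild the three raw frames' Fourier data from separated bands."""
    M = _mixing_matrix(bands.phases, bands.modulation_assumed)
    stack = np.stack([bands.band0, bands.band_plus, bands.band_minus])
    return np.tensordot(M, stack, axes=(1, 0))


def _support_mask(otf_grid: np.ndarray) -> np.ndarray:
    return otf_grid > OTF_SUPPORT_EPS


def estimate_k_coarse(band0: np.ndarray, band1: np.ndarray, otf: OtfModel,
                      search_annulus: tuple[float, float] = (0.2, 1.0),
                      min_score: float = MIN_COARSE_SCORE
                      ) -> tuple[np.ndarray, float, bool]:
    """Integer-bin wave-vector candidate by normalized cross-correlation.

    Returns ``(p_bins, score, above_threshold)`` where ``p_bins`` is the
    signed (row, col) frequency-bin shift maximizing
    ``|Σ_k conj(B0(k))·B1(k+p)|`` over an annulus ``search_annulus × k_c``,
    normalized by the band energies (Cauchy–Schwarz bound 1).
    """
    shape = band0.shape
    otf_grid = otf.otf_grid(shape)
    mask = _support_mask(otf_grid)
    # whiten by the OTF (regularized) so the correlation is governed by the
    # object spectrum, not by the OTF-weight mismatch across the overlap
    whitener = mask / (otf_grid + 0.1)
    b0 = band0 * whitener
    b1 = band1 * whitener
    e0 = float(np.sum(np.abs(b0) ** 2))
    e1 = float(np.sum(np.abs(b1) ** 2))
    if e0 == 0.0:
        raise EstimationError("all-zero band; cannot estimate pattern frequency")
    if e1 <= 1e-20 * e0:
        # pattern-free data: the first-order band is numerically empty
        return np.zeros(2), 0.0, False

    oversample = 2  # half-bin sampling keeps off-grid peaks from decorrelating
    fine_shape = (oversample * shape[0], oversample * shape[1])

    def _shift_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """C(p) = Σ_k conj(a(k))·b(k+p), sampled at 1/oversample-bin shifts."""
        prod = np.conj(np.fft.ifft2(a)) * np.fft.ifft2(b) * a.size
        padded = np.zeros(fine_shape, dtype=complex)
        padded[: shape[0], : shape[1]] = prod
        return np.fft.fft2(padded)

    # normalized cross-correlation over the per-shift OTF overlap region:
    # |Σ conj(B0)B1(·+p)| / sqrt(Σ|B0|²·M(·+p) · Σ M·|B1(·+p)|²)
    corr = _shift_corr(b0, b1)
    mask_f = mask.astype(float)

    def _int_shift_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.fft.fft2(np.conj(np.fft.ifft2(a)) * np.fft.ifft2(b)) * a.size

    # overlap energies vary slowly with the shift: evaluate at integer shifts
    # and look up the nearest one for the oversampled correlation samples
    energy0_int = np.abs(_int_shift_corr(np.abs(b0) ** 2, mask_f))
    energy1_int = np.abs(_int_shift_corr(mask_f, np.abs(b1) ** 2))
    src_r = np.round(np.arange(fine_shape[0]) / oversample).astype(int) % shape[0]
    src_c = np.round(np.arange(fine_shape[1]) / oversample).astype(int) % shape[1]
    energy0 = energy0_int[np.ix_(src_r, src_c)]
    energy1 = energy1_int[np.ix_(src_r, src_c)]
    with np.errstate(invalid="ignore", divide="ignore"):
        score_map = np.abs(corr) / np.sqrt(energy0 * energy1)
    score_map = np.nan_to_num(score_map, nan=0.0, posinf=0.0)

    kmag = make_frequency_grid(fine_shape, otf.pixel_size)
    lo, hi = search_annulus
    annulus = (kmag >= lo * otf.cutoff) & (kmag <= hi * otf.cutoff)
    if not annulus.any():
        raise EstimationError(f"empty search annulus {search_annulus}")
    score_map = np.where(annulus, score_map, -np.inf)
    idx = np.unravel_index(int(np.argmax(score_map)), fine_shape)
    score = float(score_map[idx])
    # wrap to signed fine bins, then back to (fractional) frequency bins
    p_bins = np.array(
        [idx[0] if idx[0] <= fine_shape[0] // 2 else idx[0] - fine_shape[0],
         idx[1] if idx[1] <= fine_shape[1] // 2 else idx[1] - fine_shape[1]],
        dtype=float) / oversample
    return p_bins, score, score >= min_score


class _OverlapCorrelator:
    """Cached evaluator of the complex overlap factor between two bands.

    Cross-weighting each band with the *other* band's displaced OTF makes the
    pointwise ratio equal to ``m·e^{iφ}`` for noiseless data.
    """

    def __init__(self, band0: np.ndarray, band1: np.ndarray, otf: OtfModel):
        self.shape = band0.shape
        rows, cols = self.shape
        self.otf = otf
        self.band0 = band0
        self.c1 = np.fft.ifft2(band1)  # real-space image of band1
        self.yy = np.arange(rows)[:, None] / rows
        self.xx = np.arange(cols)[None, :] / cols
        self.fy = np.fft.fftfreq(rows, d=otf.pixel_size)[:, None]
        self.fx = np.fft.fftfreq(cols, d=otf.pixel_size)[None, :]
        k_here = np.hypot(self.fy, self.fx)
        self.otf_here = ideal_otf_2d(otf, k_here)
        # exclude the lowest frequencies: the camera baseline (DC) and any
        # slow background live there and would swamp the correlation sums
        self.mask_here = _support_mask(self.otf_here) & (k_here > 0.05 * otf.cutoff)
        # per-bin noise power, measured where the OTF passes no signal;
        # used to debias the energy terms (noise inflates |band|²)
        outside = k_here >= otf.cutoff
        if outside.any():
            self.noise0 = float(np.mean(np.abs(band0[outside]) ** 2))
            self.noise1 = float(np.mean(np.abs(band1[outside]) ** 2))
        else:
            self.noise0 = self.noise1 = 0.0

    def __call__(self, p_bins: np.ndarray) -> tuple[complex, float]:
        rows, cols = self.shape
        ramp = np.exp(-2j * np.pi * (p_bins[0] * self.yy + p_bins[1] * self.xx))
        band1_shifted = np.fft.fft2(self.c1 * ramp)  # B1(k + p)
        dky = p_bins[0] / (rows * self.otf.pixel_size)
        dkx = p_bins[1] / (cols * self.otf.pixel_size)
        k_shifted = np.hypot(self.fy + dky, self.fx + dkx)
        otf_shifted = ideal_otf_2d(self.otf, k_shifted)
        overlap = self.mask_here & _support_mask(otf_shifted)
        if not overlap.any():
            raise EstimationError("no OTF overlap at candidate shift")
        a = np.where(overlap, self.band0 * otf_shifted, 0.0)
        b = np.where(overlap, band1_shifted * self.otf_here, 0.0)
        ea = float(np.sum(np.abs(a) ** 2))
        if ea == 0.0:
            raise EstimationError("zero-energy overlap region")
        num = complex(np.sum(np.conj(a) * b))
        eb = float(np.sum(np.abs(b) ** 2))
        # debias: E|a|² = |signal|² + σ²·otf², so subtract the noise share
        # (clamped: at very low SNR the bias estimate may overshoot)
        bias_a = self.noise0 * float(np.sum(np.where(overlap, otf_shifted ** 2, 0.0)))
        bias_b = self.noise1 * float(np.sum(np.where(overlap, self.otf_here ** 2, 0.0)))
        denom = max(ea - bias_a, 0.05 * ea)
        eb_sig = max(eb - bias_b, 0.05 * eb)
        score = abs(num) / np.sqrt(denom * eb_sig) if eb > 0 else 0.0
        return num / denom, score


def refine_k_subpixel(band0: np.ndarray, band1: np.ndarray, otf: OtfModel,
                      coarse_p_bins: np.ndarray, *, max_iter: int = 30,
                      tol_bins: float = 1e-3
                      ) -> tuple[np.ndarray, float, float, float]:
    """Sub-bin refinement of the pattern wave vector.

    Shrinking-bracket search on the normalized overlap-correlation magnitude
    under continuous shifts.  Returns ``(p_cycles_per_um, phi, m, score)``.
    ``m`` is clipped to (0, 1.5]; values above 1 trigger a warning.
    """
    shape = band0.shape
    best = np.asarray(coarse_p_bins, dtype=float).copy()
    step = 0.5
    correlator = _OverlapCorrelator(band0, band1, otf)

    def objective(p):
        _, s = correlator(p)
        return s

    best_score = objective(best)
    it = 0
    while step > tol_bins:
        improved = False
        for dy in (-step, 0.0, step):
            for dx in (-step, 0.0, step):
                if dy == 0.0 and dx == 0.0:
                    continue
                cand = best + np.array([dy, dx])
                s = objective(cand)
                if s > best_score:
                    best_score, best = s, cand
                    improved = True
        if not improved:
            step /= 2.0
        it += 1
        if it > max_iter and step > tol_bins:
            raise EstimationError(
                f"sub-pixel refinement did not converge after {it} iterations "
                f"(step={step:.2e} bins, score={best_score:.3f})")

    factor, score = correlator(best)
    m = abs(factor)
    phi = float(np.angle(factor))
    if m > 1.0:
        warnings.warn(f"estimated modulation depth {m:.3f} > 1; clipping to 1.5 max",
                      stacklevel=2)
    m = float(np.clip(m, 1e-6, 1.5))
    p_cycles = np.array([best[0] / (shape[0] * otf.pixel_size),
                         best[1] / (shape[1] * otf.pixel_size)])
    return p_cycles, phi, m, float(score)


def fit_channel_params(raw: RawSimSet, otf: OtfModel, *,
                       search_annulus: tuple[float, float] = (0.2, 1.0),
                       min_score: float = MIN_COARSE_SCORE) -> IlluminationParams:
    """Full per-channel estimation: separation (provisional m=1), coarse and
    sub-pixel wave-vector search for each of the three angles.

    The returned parameters carry per-angle quality scores; angles scoring
    below ``min_score`` trigger a warning.
    """
    if raw.frame_shape != otf.grid_shape:
        raise ValueError("raw set geometry does not match the OTF grid")
    nominal = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    wave_vectors = np.zeros((N_ANGLES, 2))
    start_phases = np.zeros(N_ANGLES)
    mods = np.zeros(N_ANGLES)
    scores = np.zeros(N_ANGLES)
    for a in range(N_ANGLES):
        bands = separate_bands(raw.frames_for_angle(a), nominal, m=1.0)
        p_bins, cscore, ok = estimate_k_coarse(bands.band0, bands.band_plus, otf,
                                               search_annulus, min_score)
        if not ok:
            warnings.warn(
                f"angle {a}: coarse correlation score {cscore:.3f} below "
                f"threshold {min_score}; data may lack a pattern", stacklevel=2)
        p, phi, m, score = refine_k_subpixel(bands.band0, bands.band_plus, otf, p_bins)
        wave_vectors[a] = p
        start_phases[a] = phi
        mods[a] = m
        scores[a] = score
    return IlluminationParams(wave_vectors=wave_vectors, start_phases=start_phases,
                              modulation=float(np.mean(mods)), scores=scores)
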