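"""Binary phase-grating patterns for a pixelated SLM and the multicolor
pattern search.

Gratings are parameterized by an integer normal vector ``(u, v)`` (coprime,
encoding a rational-slope orientation) and a period in SLM pixels measured
along the normal.  A pixel's state depends only on ``τ = u·x + v·y``, so a
phase step of ``period/3`` is realizable as an exact cyclic translation iff
``period·√(u²+v²)/3`` is (near-)integer.

Diffraction-order intensities are computed from the *realized* (rounded)
bitmap profile, treating on/off pixels as a 0/π phase pattern (field
amplitude ``1 − 2·bit``), so rounding-induced spurious orders are captured.
Spot positions are kept in normalized Fourier-plane units of
``wavelength / period`` along the grating normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DiffractionSpot",
    "FourierMask",
    "PatternSearchInfeasible",
    "SlmGrating",
    "SlmPatternSet",
    "binary_grating_pattern",
    "export_pattern_set",
    "multicolor_pattern_search",
    "predicted_spot_positions",
    "read_pattern_bitmap",
    "score_mask_transmission",
]

DEFAULT_SLM_SHAPE = (1024, 1280)
N_ANGLES = 3
N_PHASES = 3
PHASE_SHIFT_TOL = 0.05  # max deviation of period/3 from a lattice shift, in τ units


class PatternSearchInfeasible(RuntimeError):
    """No pattern set satisfies the constraints; carries a structured report."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class SlmGrating:
    """Orientation (integer normal) + period along the normal, in SLM px."""

    normal: tuple[int, int]  # (u, v) acting on (x, y); coprime
    period_px: float

    def __post_init__(self) -> None:
        u, v = self.normal
        if (u, v) == (0, 0) or math.gcd(abs(u), abs(v)) != 1:
            raise ValueError(f"normal must be a coprime integer vector, got {self.normal}")
        if self.period_px < 2:
            raise ValueError(f"grating period must be >= 2 px, got {self.period_px}")

    @property
    def norm(self) -> float:
        return math.hypot(*self.normal)

    @property
    def repeat_units(self) -> float:
        """Pattern repeat length in τ = u·x+v·y units."""
        return self.period_px * self.norm

    @property
    def orientation_deg(self) -> float:
        u, v = self.normal
        return math.degrees(math.atan2(v, u)) % 180.0

    def phase_shift_error(self, n_phases: int = N_PHASES) -> float:
        """Distance of ``repeat/n_phases`` from the nearest integer (τ units)."""
        s = self.repeat_units / n_phases
        return abs(s - round(s))


def binary_grating_pattern(slm_shape: tuple[int, int], grating: SlmGrating,
                           phase_step_index: int, n_phases: int = N_PHASES,
                           tol: float = PHASE_SHIFT_TOL) -> np.ndarray:
    """Binary bitmap of the grating at the given phase step.

    Phase step ``j`` translates the pattern by ``j·period/3`` along the
    grating normal, realized as an exact cyclic translation on the pixel
    lattice (rounded to the nearest lattice shift; unrealizable steps raise).
    """
    err = grating.phase_shift_error(n_phases)
    if err > tol:
        raise ValueError(
            f"phase step period/{n_phases} deviates from a representable lattice "
            f"shift by {err:.3f} τ-units (> {tol}); grating {grating} unrealizable")
    rows, cols = slm_shape
    u, v = grating.normal
    L = grating.repeat_units
    shift = round(phase_step_index * L / n_phases)
    yy, xx = np.mgrid[0:rows, 0:cols]
    tau = u * xx + v * yy - shift
    return (np.mod(tau / L, 1.0) < 0.5)


@dataclass(frozen=True)
class DiffractionSpot:
    order: int
    position: tuple[float, float]  # normalized Fourier-plane (x, y)
    intensity: float


def _profile_orders(grating: SlmGrating, orders: np.ndarray,
                    n_periods: int = 64) -> np.ndarray:
    """Relative intensities |c_n|² of the phase-grating field along τ.

    Direct (non-uniform) Fourier sum of the realized profile
    ``f(τ) = 1 − 2·bit(τ)`` over an integer number of repeats.
    """
    L = grating.repeat_units
    # sample an integer number of (approximate) repeats to limit leakage
    T = int(round(n_periods * L))
    tau = np.arange(T)
    bits = (np.mod(tau / L, 1.0) < 0.5).astype(float)
    f = 1.0 - 2.0 * bits
    phases = np.exp(-2j * np.pi * np.outer(orders, tau) / L)
    coeffs = phases @ f / T
    return np.abs(coeffs) ** 2


def predicted_spot_positions(grating: SlmGrating, wavelength_nm: float,
                             max_order: int = 7) -> list[DiffractionSpot]:
    """Diffraction orders n = 0, ±1, … ±max_order of the realized grating.

    Order ``n`` sits at ``n·λ/period`` along the unit normal (normalized
    units, λ in nm, period in px); intensities come from the direct transform
    of the realized bitmap profile.  A 50 % duty-cycle phase grating has a
    vanishing zeroth order and suppressed even orders.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    u, v = grating.normal
    s = grating.norm
    nx, ny = u / s, v / s
    orders = np.arange(-max_order, max_order + 1)
    intensities = _profile_orders(grating, orders)
    radius_unit = wavelength_nm / grating.period_px
    spots = []
    for n, inten in zip(orders, intensities):
        r = n * radius_unit
        spots.append(DiffractionSpot(order=int(n), position=(r * nx, r * ny),
                                     intensity=float(inten)))
    return spots


@dataclass
class FourierMask:
    """Stationary order-selection mask: open holes, blocked elsewhere.

    Holes come in ±1-symmetric pairs; no hole at DC.
    """

    hole_positions: list[tuple[float, float]]
    hole_radius: float

    def __post_init__(self) -> None:
        if not self.hole_positions:
            raise ValueError("mask must define at least one hole")
        if self.hole_radius <= 0:
            raise ValueError("hole radius must be positive")
        for (hx, hy) in self.hole_positions:
            if math.hypot(hx, hy) <= self.hole_radius:
                raise ValueError("mask holes must exclude the zeroth order (DC)")

    def contains(self, position: tuple[float, float]) -> bool:
        return any(math.hypot(position[0] - hx, position[1] - hy) <= self.hole_radius
                   for hx, hy in self.hole_positions)

    def clearance(self, position: tuple[float, float]) -> float:
        """Distance from a position to the nearest hole edge (negative inside)."""
        return min(math.hypot(position[0] - hx, position[1] - hy) - self.hole_radius
                   for hx, hy in self.hole_positions)


def score_mask_transmission(spots: list[DiffractionSpot], mask: FourierMask
                            ) -> tuple[float, float]:
    """(wanted_fraction, leakage_fraction) of a spot list through a mask.

    wanted = ±1-order intensity inside holes / total ±1 intensity;
    leakage = other orders' intensity inside holes / their total intensity.
    """
    wanted_tot = wanted_in = other_tot = other_in = 0.0
    for spot in spots:
        inside = mask.contains(spot.position)
        if abs(spot.order) == 1:
            wanted_tot += spot.intensity
            if inside:
                wanted_in += spot.intensity
        else:
            other_tot += spot.intensity
            if inside:
                other_in += spot.intensity
    wanted = wanted_in / wanted_tot if wanted_tot > 0 else 0.0
    leakage = other_in / other_tot if other_tot > 0 else 0.0
    return wanted, leakage


@dataclass
class SlmPatternSet:
    """Binary grating bitmaps per (wavelength, angle, phase)."""

    slm_shape: tuple[int, int]
    wavelengths_nm: list[float]
    gratings: dict[tuple[float, int], SlmGrating]  # (wavelength, angle) -> grating
    patterns: dict[tuple[float, int, int], np.ndarray] = field(default_factory=dict)
    phase_offsets: dict[tuple[float, int, int], float] = field(default_factory=dict)

    def realize(self) -> None:
        """Render all bitmaps (3 phases per angle per wavelength)."""
        for (wl, a), grating in self.gratings.items():
            L = grating.repeat_units
            for j in range(N_PHASES):
                self.patterns[(wl, a, j)] = binary_grating_pattern(
                    self.slm_shape, grating, j)
                self.phase_offsets[(wl, a, j)] = (
                    2.0 * np.pi * round(j * L / N_PHASES) / L)

    @property
    def periods(self) -> dict[tuple[float, int], float]:
        return {k: g.period_px for k, g in self.gratings.items()}

    @property
    def orientations(self) -> dict[tuple[float, int], float]:
        return {k: g.orientation_deg for k, g in self.gratings.items()}


def _candidate_normals(target_deg: float, window_deg: float, max_component: int
                       ) -> list[tuple[int, int]]:
    out = []
    for u in range(-max_component, max_component + 1):
        for v in range(0, max_component + 1):
            if (u, v) == (0, 0) or math.gcd(abs(u), abs(v)) != 1:
                continue
            if v == 0 and u < 0:
                continue
            ang = math.degrees(math.atan2(v, u)) % 180.0
            d = abs(((ang - target_deg) + 90.0) % 180.0 - 90.0)
            if d <= window_deg:
                out.append((u, v))
    return out


def _realizable_periods(normal: tuple[int, int], period_range: tuple[float, float]
                        ) -> list[float]:
    """Periods whose phase steps are exact lattice shifts: repeat = 3k τ-units."""
    s = math.hypot(*normal)
    lo, hi = period_range
    k_lo = math.ceil(max(lo, 2.0) * s / 3.0)
    k_hi = math.floor(hi * s / 3.0)
    return [3.0 * k / s for k in range(max(k_lo, 1), k_hi + 1) if 3.0 * k / s >= 2.0]


def multicolor_pattern_search(
        wavelengths_nm: list[float], target_spot_radius: float,
        radius_tolerance: float, period_search_range: tuple[float, float] = (4.0, 60.0),
        *, n_angles: int = N_ANGLES, slm_shape: tuple[int, int] = DEFAULT_SLM_SHAPE,
        angle_targets_deg: tuple[float, ...] = (0.0, 60.0, 120.0),
        angle_window_deg: float = 8.0, max_normal_component: int = 12,
        clearance_margin: float = 0.0, intensity_floor: float = 1e-4,
        realize: bool = True) -> tuple[SlmPatternSet, FourierMask, dict]:
    """Exhaustive search for a multicolor-compatible SLM pattern set.

    Accepts sets where (i) every wavelength's ±1 spots for every angle fall
    within ``radius_tolerance`` of the shared hole positions, (ii) spurious
    orders of all wavelengths stay outside every hole by
    ``clearance_margin``, (iii) phase steps are exactly realizable.  The best
    set maximizes the minimal spurious-order clearance.  Spot radii are in
    normalized ``λ[nm]/period[px]`` units.
    """
    if not 1 <= len(wavelengths_nm) <= 3:
        raise ValueError("1–3 wavelengths supported")
    if n_angles != N_ANGLES:
        raise ValueError("exactly 3 pattern orientations are supported")
    report: dict = {"tightest_constraint": None, "angles": []}

    chosen: dict[tuple[float, int], SlmGrating] = {}
    hole_positions: list[tuple[float, float]] = []
    all_spots: list[tuple[float, int, list[DiffractionSpot]]] = []
    for a, target_deg in enumerate(angle_targets_deg):
        best_for_angle = None
        tightest = "no realizable orientation/period in range"
        for normal in _candidate_normals(target_deg, angle_window_deg,
                                         max_normal_component):
            periods = _realizable_periods(normal, period_search_range)
            if not periods:
                tightest = "no phase-realizable period in search range"
                continue
            per_wl = {}
            worst_dev = 0.0
            ok = True
            for wl in wavelengths_nm:
                devs = [(abs(wl / per - target_spot_radius), per) for per in periods]
                dev, per = min(devs)
                if dev > radius_tolerance:
                    ok = False
                    tightest = (f"angle {a}: wavelength {wl} nm cannot reach target "
                                f"radius {target_spot_radius} within ±{radius_tolerance} "
                                f"(best deviation {dev:.4f})")
                    break
                per_wl[wl] = SlmGrating(normal=normal, period_px=per)
                worst_dev = max(worst_dev, dev)
            if ok and (best_for_angle is None or worst_dev < best_for_angle[0]):
                best_for_angle = (worst_dev, normal, per_wl)
        if best_for_angle is None:
            raise PatternSearchInfeasible(
                f"no feasible pattern for angle {a} ({target_deg}°): {tightest}",
                {"tightest_constraint": tightest, "angle": a})
        _, normal, per_wl = best_for_angle
        u, v = normal
        s = math.hypot(u, v)
        mean_radius = float(np.mean([wl / per_wl[wl].period_px for wl in wavelengths_nm]))
        hole = (mean_radius * u / s, mean_radius * v / s)
        hole_positions.extend([hole, (-hole[0], -hole[1])])
        for wl in wavelengths_nm:
            chosen[(wl, a)] = per_wl[wl]
            all_spots.append((wl, a, predicted_spot_positions(per_wl[wl], wl)))
        report["angles"].append({"angle_index": a, "normal": normal,
                                 "orientation_deg": math.degrees(math.atan2(v, u)) % 180.0,
                                 "hole_radius_norm": mean_radius})

    mask = FourierMask(hole_positions=hole_positions, hole_radius=radius_tolerance)
    # spurious-order clearance across all wavelengths and angles
    min_clearance = math.inf
    for wl, a, spots in all_spots:
        for spot in spots:
            if abs(spot.order) == 1:
                if not mask.contains(spot.position):
                    raise PatternSearchInfeasible(
                        f"±1 spot of {wl} nm, angle {a} misses its hole",
                        {"tightest_constraint": "first-order spot outside hole",
                         "wavelength": wl, "angle": a})
            elif spot.intensity > intensity_floor:
                min_clearance = min(min_clearance, mask.clearance(spot.position))
    if min_clearance < clearance_margin:
        raise PatternSearchInfeasible(
            f"spurious order clears holes by only {min_clearance:.4f} "
            f"(margin {clearance_margin})",
            {"tightest_constraint": "spurious-order clearance", "clearance": min_clearance})

    pattern_set = SlmPatternSet(slm_shape=slm_shape, wavelengths_nm=list(wavelengths_nm),
                                gratings=chosen)
    if realize:
        pattern_set.realize()
    gains = {wl: float(np.mean([wl / chosen[(wl, a)].period_px
                                for a in range(N_ANGLES)]) / target_spot_radius)
             for wl in wavelengths_nm}
    report.update({"min_spurious_clearance": min_clearance,
                   "relative_gain_per_wavelength": gains})
    return pattern_set, mask, report


def export_pattern_set(pattern_set: SlmPatternSet, mask: FourierMask,
                       out_dir: str | Path) -> list[Path]:
    """Write one 1-bit PNG per (wavelength, angle, phase) in acquisition order
    plus a text table of mask hole centers/radii.  Returns the written paths.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not pattern_set.patterns:
        pattern_set.realize()
    paths = []
    for wl in pattern_set.wavelengths_nm:
        for a in range(N_ANGLES):
            for j in range(N_PHASES):
                bitmap = pattern_set.patterns[(wl, a, j)]
                path = out / f"pattern_wl{int(round(wl))}_a{a}_p{j}.png"
                Image.fromarray(bitmap.astype(np.uint8) * 255).convert("1").save(path)
                paths.append(path)
    mask_path = out / "mask_holes.tsv"
    with open(mask_path, "w") as fh:
        fh.write("# x_norm\ty_norm\tradius_norm\n")
        for hx, hy in mask.hole_positions:
            fh.write(f"{hx:.6f}\t{hy:.6f}\t{mask.hole_radius:.6f}\n")
    paths.append(mask_path)
    return paths


def read_pattern_bitmap(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("1"), dtype=bool)
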