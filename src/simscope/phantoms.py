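"""Synthetic ground-truth scenes for the virtual microscope.

Phantoms are non-negative intensity maps (photons/pixel at unit exposure)
with the generating truth (emitter centers, bead radii) recorded so tests
can score estimators against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Phantom", "make_phantom"]

KINDS = ("points", "bead_clusters", "lines", "siemens_star")


@dataclass
class Phantom:
    """Ground-truth scene.

    Attributes
    ----------
    image : non-negative intensity map
    kind : phantom family name
    seed : RNG seed used
    pixel_size : µm per pixel
    centers : (n, 2) sub-pixel emitter/bead centers as (row, col), or empty
    params : the keyword parameters the phantom was built with
    """

    image: np.ndarray
    kind: str
    seed: int
    pixel_size: float
    centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if not np.all(np.isfinite(self.image)) or np.any(self.image < 0):
            raise ValueError("phantom image must be finite and non-negative")


def _splat_point(img: np.ndarray, center: tuple[float, float], intensity: float) -> None:
    """Deposit a sub-pixel point by bilinear weighting into 4 neighbours."""
    r, c = center
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
                img[rr, cc] += intensity * wr * wc


def _draw_disk(img: np.ndarray, center: tuple[float, float], radius_px: float,
               intensity: float) -> None:
    """Anti-aliased disk: edge pixels weighted by coverage approximation."""
    r, c = center
    lo_r = max(0, int(np.floor(r - radius_px - 1)))
    hi_r = min(img.shape[0], int(np.ceil(r + radius_px + 2)))
    lo_c = max(0, int(np.floor(c - radius_px - 1)))
    hi_c = min(img.shape[1], int(np.ceil(c + radius_px + 2)))
    if lo_r >= hi_r or lo_c >= hi_c:
        return
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dist = np.hypot(yy - r, xx - c)
    img[lo_r:hi_r, lo_c:hi_c] += intensity * np.clip(radius_px + 0.5 - dist, 0.0, 1.0)


def make_phantom(kind: str, shape: tuple[int, int], seed: int = 0, *,
                 pixel_size: float = 0.08, **params: Any) -> Phantom:
    """Build a deterministic phantom of the given kind.

    Supported kinds and their keyword parameters:

    - ``points``: ``n`` emitters (default 1), ``intensity``, ``centers``
      (explicit (row, col) list overrides random placement), ``margin``.
    - ``bead_clusters``: ``n_clusters`` (default 6), ``beads_per_cluster``
      (default 4), ``bead_diameter_um`` (default 0.2), ``cluster_sigma_px``,
      ``intensity`` — emulates a slide of closely packed fluorescent beads.
    - ``lines``: ``n_lines`` (default 8), ``intensity``.
    - ``siemens_star``: ``n_spokes`` (default 18), ``intensity``.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; supported: {KINDS}")
    rows, cols = shape
    if rows < 64 or cols < 64:
        raise ValueError(f"phantom shape must be at least 64x64, got {shape}")
    rng = np.random.default_rng(seed)
    img = np.zeros((rows, cols), dtype=float)
    centers: list[tuple[float, float]] = []
    intensity = float(params.get("intensity", 1000.0))

    if kind == "points":
        n = int(params.get("n", 1))
        margin = float(params.get("margin", 0.15))
        explicit = params.get("centers")
        if explicit is not None:
            pts = [tuple(map(float, c)) for c in explicit]
        else:
            pts = [
                (rng.uniform(margin * rows, (1 - margin) * rows),
                 rng.uniform(margin * cols, (1 - margin) * cols))
                for _ in range(n)
            ]
        for p in pts:
            _splat_point(img, p, intensity)
            centers.append(p)

    elif kind == "bead_clusters":
        n_clusters = int(params.get("n_clusters", 6))
        beads = int(params.get("beads_per_cluster", 4))
        diam_um = float(params.get("bead_diameter_um", 0.2))
        sigma = float(params.get("cluster_sigma_px", 4.0))
        radius_px = 0.5 * diam_um / pixel_size
        for _ in range(n_clusters):
            cr = rng.uniform(0.1 * rows, 0.9 * rows)
            cc = rng.uniform(0.1 * cols, 0.9 * cols)
            for _ in range(beads):
                p = (cr + rng.normal(0, sigma), cc + rng.normal(0, sigma))
                _draw_disk(img, p, radius_px, intensity)
                centers.append(p)

    elif kind == "lines":
        n_lines = int(params.get("n_lines", 8))
        yy, xx = np.mgrid[0:rows, 0:cols]
        for _ in range(n_lines):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(0, max(rows, cols))
            d = np.abs(np.cos(theta) * xx + np.sin(theta) * yy - offset)
            img += intensity * np.clip(1.0 - d, 0.0, 1.0)

    elif kind == "siemens_star":
        n_spokes = int(params.get("n_spokes", 18))
        yy, xx = np.mgrid[0:rows, 0:cols]
        cy, cx = (rows - 1) / 2, (cols - 1) / 2
        theta = np.arctan2(yy - cy, xx - cx)
        rr = np.hypot(yy - cy, xx - cx)
        img = intensity * (0.5 * (1 + np.sign(np.sin(n_spokes * theta))))
        img[rr > 0.45 * min(rows, cols)] = 0.0
        img[rr < 2] = intensity
        centers.append((cy, cx))

    return Phantom(image=img, kind=kind, seed=seed, pixel_size=pixel_size,
                   centers=np.asarray(centers, dtype=float).reshape(-1, 2),
                   params=dict(params))
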