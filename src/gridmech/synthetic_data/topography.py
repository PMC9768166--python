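"""Synthetic AFM height maps of a micropatterned, bio-passivated surface.

The simulated field of view mimics the two-step photopatterning layout
used to measure layer thicknesses: a protein (ECM) square and an ablated
(bare) square sit side by side in a passivation plateau.  Heights are

    passivation plateau : ``passivation_height``  (~2 nm PLL-g-PEG)
    pattern (ECM) square: ``ecm_height``          (~0.5 nm gelatin)
    ablated square      : 0                        (bare reference)

The pattern/passivation boundary is not the ideal square: the boundary
is displaced by a correlated, periodic Gaussian process ("edge wander")
parametrized along the square's perimeter, emulating the
nanometre-scale irregularity of photopatterned edges.  The displacement
acts along the square's max-norm radial direction, which keeps the
boundary simple (star-shaped about the square center) and makes the
normal distance from the ideal edge equal the wander value exactly.
i.i.d. Gaussian roughness is added to every pixel.  The true
(pre-raster) boundary polyline and the true region masks are returned
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..types import BoundaryTrace, TopographyMap

__all__ = ["TopographyConfig", "gen_topography"]


@dataclass
class TopographyConfig:
    """Parameters of the synthetic topography generator.

    Attributes
    ----------
    seed : int
        RNG seed.
    map_size : int
        Map side in pixels (square map).
    pixel_size : float
        Lateral pixel size in nm.
    passivation_height : float
        Passivation plateau height in nm (default 2.0).
    ecm_height : float
        ECM pattern height in nm (default 0.5).
    roughness_sd : float
        i.i.d. Gaussian roughness added everywhere, nm.
    edge_wander_sd : float
        Pointwise standard deviation of the boundary displacement, nm.
    edge_correlation_length : float
        Correlation length of the wander along the perimeter, nm.
    square_side : float
        Side of the pattern and ablated squares, in µm.
    boundary_samples : int
        Number of vertices sampling the wandered boundary polyline.
    """

    seed: int = 0
    map_size: int = 512
    pixel_size: float = 25.0
    passivation_height: float = 2.0
    ecm_height: float = 0.5
    roughness_sd: float = 0.0
    edge_wander_sd: float = 0.0
    edge_correlation_length: float = 250.0
    square_side: float = 5.0
    boundary_samples: int = 2048

    def validate(self) -> None:
        if self.map_size < 8:
            raise ValueError("map_size too small")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("passivation_height", "ecm_height"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.roughness_sd < 0 or self.edge_wander_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.edge_correlation_length <= 0:
            raise ValueError("edge_correlation_length must be positive")
        if self.square_side <= 0:
            raise ValueError("square_side must be positive")
        if self.edge_wander_sd > 0.2 * self.square_side * 1e3:
            raise ValueError("edge_wander_sd too large relative to the square side")
        extent = self.map_size * self.pixel_size  # nm
        if 2.2 * self.square_side * 1e3 > extent:
            raise ValueError(
                f"two {self.square_side} µm squares do not fit a "
                f"{extent / 1e3:.2f} µm map; enlarge map_size or shrink square_side"
            )


def _correlated_wander(rng: np.random.Generator, n: int, sd: float,
                       corr_len_samples: float) -> np.ndarray:
    """Zero-mean periodic Gaussian process with pointwise sd ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.normal(size=n)
    smooth = gaussian_filter1d(white, sigma=corr_len_samples, mode="wrap")
    s = smooth.std()
    if s == 0:
        return np.zeros(n)
    return sd * (smooth - smooth.mean()) / s


def _perimeter_param(u: np.ndarray, v: np.ndarray, half: float) -> np.ndarray:
    """Perimeter parameter t in [0, 4) of the max-norm projection of (u, v).

    Edges in order: bottom (v = −h), right (u = h), top (v = h),
    left (u = −h); within each edge t advances linearly.
    """
    r = np.maximum(np.abs(u), np.abs(v))
    r = np.where(r == 0, 1.0, r)  # center maps to an arbitrary parameter
    pu, pv = half * u / r, half * v / r
    t = np.empty(np.shape(u), dtype=float)
    bottom = (pv <= -half * (1 - 1e-12)) & (np.abs(pu) <= half)
    right = (pu >= half * (1 - 1e-12)) & ~bottom
    top = (pv >= half * (1 - 1e-12)) & ~bottom & ~right
    left = ~(bottom | right | top)
    t[bottom] = (pu[bottom] + half) / (2 * half)
    t[right] = 1.0 + (pv[right] + half) / (2 * half)
    t[top] = 2.0 + (half - pu[top]) / (2 * half)
    t[left] = 3.0 + (half - pv[left]) / (2 * half)
    return np.clip(t, 0.0, 4.0 - 1e-12)


def gen_topography(cfg: TopographyConfig) -> tuple[TopographyMap, BoundaryTrace]:
    """Generate a height map plus ground-truth masks and pattern boundary.

    Returns
    -------
    topo : TopographyMap
        Heights in nm with masks ``pattern``, ``ablated``, ``passivation``
        partitioning the map.
    boundary : BoundaryTrace
        The true (pre-raster) wandered pattern boundary, with the ideal
        square recorded as ``reference_square``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    extent = cfg.map_size * cfg.pixel_size  # nm
    side_nm = cfg.square_side * 1e3
    half = side_nm / 2.0

    # pattern square left of center, ablated square right of center
    gap = (extent - 2 * side_nm) / 3.0
    pattern_center = np.array([gap + half, extent / 2.0])
    ablated_center = np.array([2 * gap + 3 * half, extent / 2.0])

    # wander process sampled on a uniform perimeter grid t_k in [0, 4)
    n_b = cfg.boundary_samples
    t_grid = 4.0 * np.arange(n_b) / n_b
    step_nm = 4.0 * side_nm / n_b  # arclength per boundary sample
    wander = _correlated_wander(
        rng, n_b, cfg.edge_wander_sd, cfg.edge_correlation_length / step_nm
    )

    def w_of_t(t: np.ndarray) -> np.ndarray:
        return np.interp(t, t_grid, wander, period=4.0)

    # true boundary polyline: ideal boundary point at parameter t, scaled
    # radially (max-norm) so its normal distance from the ideal edge is w(t)
    edge = np.floor(t_grid).astype(int)
    frac = t_grid - edge
    pu = np.where(edge == 0, -half + 2 * half * frac,
         np.where(edge == 1, half,
         np.where(edge == 2, half - 2 * half * frac, -half)))
    pv = np.where(edge == 0, -half,
         np.where(edge == 1, -half + 2 * half * frac,
         np.where(edge == 2, half, half - 2 * half * frac)))
    scale = (half + wander) / half
    boundary_pts = np.column_stack([pu * scale, pv * scale]) + pattern_center

    # raster masks; pixel (row i, col j) has its center at ((j+.5), (i+.5))*px
    idx = (np.arange(cfg.map_size) + 0.5) * cfg.pixel_size
    X, Y = np.meshgrid(idx, idx)
    u = X - pattern_center[0]
    v = Y - pattern_center[1]
    r = np.maximum(np.abs(u), np.abs(v))
    t_px = _perimeter_param(u, v, half)
    pattern_mask = r <= half + w_of_t(t_px)

    ua = np.abs(X - ablated_center[0])
    va = np.abs(Y - ablated_center[1])
    ablated_mask = (np.maximum(ua, va) <= half) & ~pattern_mask

    heights = np.full((cfg.map_size, cfg.map_size), cfg.passivation_height)
    heights[pattern_mask] = cfg.ecm_height
    heights[ablated_mask] = 0.0
    if cfg.roughness_sd > 0:
        heights = heights + rng.normal(0.0, cfg.roughness_sd, size=heights.shape)

    passivation_mask = ~(pattern_mask | ablated_mask)
    topo = TopographyMap(
        heights=heights,
        pixel_size=cfg.pixel_size,
        masks={
            "pattern": pattern_mask,
            "ablated": ablated_mask,
            "passivation": passivation_mask,
        },
        meta={"config": cfg, "synthetic": True},
    )
    boundary = BoundaryTrace(
        polyline=boundary_pts,
        closed=True,
        reference_square={
            "center": tuple(pattern_center),
            "side": side_nm,
            "angle": 0.0,
        },
    )
    return topo, boundary
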