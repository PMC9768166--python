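"""Synthetic adherens-junction punctum geometry.

Two roughly parallel membrane patches (3D point sets) separated by the
inter-membrane gap, bridged by rod-like densities.  Single rods carry
the cadherin-scale ~4.5 nm diameter; a configurable fraction form
clustered assemblies with widths up to ~20 nm.  Membrane roughness is a
laterally correlated Gaussian undulation field per surface (membranes
are smooth at the point-spacing scale), normalized so each point's z
displacement has the configured standard deviation; the two surfaces
undulate independently, so paired points across the gap differ by
gap + N(0, 2*roughness^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..types import JunctionSegmentation

__all__ = ["JunctionConfig", "gen_junction_geometry"]


@dataclass
class JunctionConfig:
    """Parameters of the junction-geometry generator.

    Attributes
    ----------
    seed : int
        RNG seed.
    membrane_gap : float
        Mean inter-membrane distance in nm (default 15.4).
    membrane_roughness : float
        Per-surface Gaussian z-roughness sd in nm.
    n_rods : int
        Number of bridging rods (default 23, splitting 13 clustered /
        10 individual at the default clustered fraction).
    rod_diameter : float
        Single-rod width in nm (default 4.5).
    clustered_fraction : float
        Fraction of rods belonging to clustered assemblies; their widths
        are drawn above 1.5x the single-rod diameter.
    cluster_width_max : float
        Maximum clustered-assembly width in nm (default 20.4).
    patch_size : float
        Lateral extent of the membrane patches in nm.
    lateral_spacing : float
        Lateral point spacing of the membrane point sets in nm.
    roughness_correlation_length : float
        Lateral correlation length of the membrane undulation, nm.
    """

    seed: int = 0
    membrane_gap: float = 15.4
    membrane_roughness: float = 0.0
    n_rods: int = 23
    rod_diameter: float = 4.5
    clustered_fraction: float = 13.0 / 23.0
    cluster_width_max: float = 20.4
    patch_size: float = 300.0
    lateral_spacing: float = 10.0
    roughness_correlation_length: float = 40.0

    def validate(self) -> None:
        if self.membrane_gap <= 0:
            raise ValueError("membrane_gap must be positive")
        if self.membrane_roughness < 0:
            raise ValueError("membrane_roughness must be non-negative")
        if self.n_rods < 0:
            raise ValueError("n_rods must be non-negative")
        if self.rod_diameter <= 0:
            raise ValueError("rod_diameter must be positive")
        if not 0.0 <= self.clustered_fraction <= 1.0:
            raise ValueError("clustered_fraction must lie in [0, 1]")
        if self.cluster_width_max < self.rod_diameter:
            raise ValueError("cluster_width_max must be >= rod_diameter")
        if self.patch_size <= 0 or self.lateral_spacing <= 0:
            raise ValueError("patch_size and lateral_spacing must be positive")
        if self.roughness_correlation_length <= 0:
            raise ValueError("roughness_correlation_length must be positive")


def gen_junction_geometry(cfg: JunctionConfig) -> JunctionSegmentation:
    """Generate two membrane point-set surfaces and width-annotated rods.

    The two surfaces share the same lateral grid, so with zero roughness
    every nearest-surface distance equals ``membrane_gap`` exactly.  The
    clustered rod count is ``round(clustered_fraction * n_rods)``;
    clustered widths are drawn uniformly in
    ``[1.5 * rod_diameter, cluster_width_max]`` and individual rods keep
    ``rod_diameter``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    xy = np.arange(0.0, cfg.patch_size + cfg.lateral_spacing / 2, cfg.lateral_spacing)
    gx, gy = np.meshgrid(xy, xy)
    shape = gx.shape
    half = cfg.membrane_gap / 2.0

    def undulation() -> np.ndarray:
        if cfg.membrane_roughness == 0:
            return np.zeros(shape)
        field = gaussian_filter(
            rng.normal(size=shape),
            sigma=cfg.roughness_correlation_length / cfg.lateral_spacing,
            mode="wrap",
        )
        s = field.std()
        if s == 0:
            return np.zeros(shape)
        return cfg.membrane_roughness * (field - field.mean()) / s

    za = half + undulation()
    zb = -half + undulation()
    membrane_a = np.column_stack([gx.ravel(), gy.ravel(), za.ravel()])
    membrane_b = np.column_stack([gx.ravel(), gy.ravel(), zb.ravel()])

    n_clustered = int(round(cfg.clustered_fraction * cfg.n_rods))
    widths = np.full(cfg.n_rods, cfg.rod_diameter)
    if n_clustered:
        widths[:n_clustered] = rng.uniform(
            1.5 * cfg.rod_diameter, cfg.cluster_width_max, n_clustered
        )
    order = rng.permutation(cfg.n_rods)
    widths = widths[order]
    clustered_truth = (np.arange(cfg.n_rods) < n_clustered)[order]

    rx = rng.uniform(0.0, cfg.patch_size, cfg.n_rods)
    ry = rng.uniform(0.0, cfg.patch_size, cfg.n_rods)
    rod_start = np.column_stack([rx, ry, np.full(cfg.n_rods, -half)])
    rod_end = np.column_stack([rx, ry, np.full(cfg.n_rods, half)])

    return JunctionSegmentation(
        membrane_a=membrane_a,
        membrane_b=membrane_b,
        rod_start=rod_start,
        rod_end=rod_end,
        rod_width=widths,
        meta={
            "config": cfg,
            "n_clustered_true": int(n_clustered),
            "clustered_truth": clustered_truth,
            "synthetic": True,
        },
    )
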