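"""Step heights and boundary irregularity from AFM height maps.

Quantifies what the pattern-characterization imaging shows: the
passivation and ECM layers as plateau step heights over the ablated
reference, and the nanometre-scale irregularity of the pattern edge as
the RMS normal deviation of the traced boundary from its best-fit ideal
square.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from skimage import measure

from .types import BoundaryTrace, TopographyMap

__all__ = [
    "level_plane",
    "step_height",
    "trace_boundary",
    "boundary_irregularity",
]


def level_plane(topo: TopographyMap, reference_mask: np.ndarray | str = "ablated") -> TopographyMap:
    """Subtract the least-squares plane fitted on the reference region.

    Standard first-order AFM leveling: a plane a·x + b·y + c is fitted to
    the heights inside ``reference_mask`` (a boolean array or the name of
    one of the map's masks) and subtracted everywhere, so the reference
    region's mean is ~0 afterwards.
    """
    if isinstance(reference_mask, str):
        reference_mask = topo.masks[reference_mask]
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != topo.heights.shape:
        raise ValueError("reference mask shape does not match the map")
    if mask.sum() < 3:
        raise ValueError("reference region must contain at least 3 pixels")
    rows, cols = np.nonzero(mask)
    if np.ptp(rows) == 0 and np.ptp(cols) == 0:
        raise ValueError("degenerate reference region: pixels are collinear")
    A = np.column_stack([cols, rows, np.ones(len(rows))])
    coef, *_ = np.linalg.lstsq(A, topo.heights[mask], rcond=None)
    jj, ii = np.meshgrid(np.arange(topo.heights.shape[1]), np.arange(topo.heights.shape[0]))
    plane = coef[0] * jj + coef[1] * ii + coef[2]
    return TopographyMap(
        heights=topo.heights - plane,
        pixel_size=topo.pixel_size,
        masks={k: v.copy() for k, v in topo.masks.items()},
        meta={**topo.meta, "leveled": True},
    )


def step_height(
    topo: TopographyMap, region_a: str, region_b: str
) -> tuple[float, float]:
    """Robust plateau step between two regions: median(a) − median(b), nm.

    The spread is the quadrature sum of each region's robust sd
    (1.4826 × MAD), making the estimate insensitive to edge pixels
    straddling the step.  Returns ``(step, sd)``.
    """
    ma, mb = topo.masks[region_a], topo.masks[region_b]
    if not ma.any() or not mb.any():
        raise ValueError("both region masks must be nonempty")
    if (ma & mb).any():
        raise ValueError(f"regions {region_a!r} and {region_b!r} overlap")
    ha, hb = topo.heights[ma], topo.heights[mb]
    step = float(np.median(ha) - np.median(hb))
    mad = lambda v: 1.4826 * np.median(np.abs(v - np.median(v)))  # noqa: E731
    sd = float(np.hypot(mad(ha), mad(hb)))
    return step, sd


def trace_boundary(
    source: TopographyMap | np.ndarray,
    region: str = "pattern",
) -> BoundaryTrace:
    """Sub-pixel contour of the pattern region, in nm.

    Runs marching squares (crossing interpolation at the 0.5 level) on
    the region's boolean mask.  With a :class:`TopographyMap` the mask
    named ``region`` is used; a bare boolean array is accepted directly
    (pixel size 1 nm).  The pattern must be simply connected: zero or
    multiple closed contours raise, listing the component count.
    """
    if isinstance(source, TopographyMap):
        mask = source.masks[region]
        px = source.pixel_size
    else:
        mask = np.asarray(source, dtype=bool)
        px = 1.0
    if not mask.any():
        raise ValueError("empty pattern region: nothing to trace")
    contours = measure.find_contours(mask.astype(float), 0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if len(closed) != 1:
        raise ValueError(
            f"pattern region is not simply connected: found {len(closed)} "
            f"closed contour(s) ({len(contours)} total)"
        )
    c = closed[0][:-1]  # drop duplicated end point
    # find_contours yields (row, col) pixel indices; pixel centers sit at
    # (index + 0.5) * pixel_size, matching the generator's convention
    polyline = np.column_stack([(c[:, 1] + 0.5), (c[:, 0] + 0.5)]) * px
    return BoundaryTrace(polyline=polyline, closed=True)


def _square_residuals(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
    cx, cy, theta, half = params
    ct, st = np.cos(theta), np.sin(theta)
    u = (pts[:, 0] - cx) * ct + (pts[:, 1] - cy) * st
    v = -(pts[:, 0] - cx) * st + (pts[:, 1] - cy) * ct
    return np.maximum(np.abs(u), np.abs(v)) - half


def fit_square(pts: np.ndarray) -> dict:
    """Best-fit ideal square (center, side, angle) minimizing RMS normal deviation."""
    pts = np.asarray(pts, dtype=float)
    centroid = pts.mean(axis=0)
    perim = np.sum(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1))
    half0 = perim / 8.0
    best = None
    for theta0 in np.deg2rad([0.0, 15.0, 30.0]):  # square symmetry: period 90°
        x0 = np.array([centroid[0], centroid[1], theta0, half0])
        try:
            res = least_squares(_square_residuals, x0, args=(pts,), method="lm")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or best.x[3] <= 0:
        raise ValueError("ideal-square fit failed on this boundary")
    cx, cy, theta, half = best.x
    return {"center": (float(cx), float(cy)), "side": float(2 * half), "angle": float(theta % (np.pi / 2))}


def boundary_irregularity(
    trace: BoundaryTrace, reference: dict | None = None
) -> dict:
    """Deviation of a traced boundary from an ideal square.

    Returns ``rms_deviation`` (nm): RMS normal distance of the polyline
    from the best-fit (or supplied) ideal square, and
    ``excess_perimeter``: measured/ideal perimeter − 1.  Both are
    invariant under rigid motions of the trace.
    """
    ref = reference or trace.reference_square or fit_square(trace.polyline)
    params = np.array([ref["center"][0], ref["center"][1], ref.get("angle", 0.0), ref["side"] / 2.0])
    resid = _square_residuals(params, trace.polyline)
    rms = float(np.sqrt(np.mean(resid**2)))
    ideal_perimeter = 4.0 * ref["side"]
    if ideal_perimeter <= 0:
        raise ValueError("reference square has non-positive perimeter")
    return {
        "rms_deviation": rms,
        "excess_perimeter": float(trace.length / ideal_perimeter - 1.0),
        "reference_square": ref,
    }
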