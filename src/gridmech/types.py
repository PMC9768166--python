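"""Shared data containers.

Unit conventions used throughout the package: vertical and lateral
distances in nanometres, time in seconds, photodiode signal in volts,
forces in nanonewtons and stiffnesses in N/m (1 nN/nm == 1 N/m).
Grid-planning geometry works in micrometres and is documented locally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ForceCurve",
    "TopographyMap",
    "BoundaryTrace",
    "JunctionSegmentation",
]


@dataclass
class ForceCurve:
    """One AFM approach record.

    Exactly one of ``signal`` (photodiode volts, pre-calibration) or
    ``deflection`` (cantilever deflection in nm, post-calibration) is
    present.  ``piezo`` is the vertical piezo extension in nm, increasing
    toward the surface.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, monotone non-decreasing.
    piezo : ndarray
        Piezo extension in nm.
    signal : ndarray, optional
        Raw photodiode signal in volts.
    deflection : ndarray, optional
        Calibrated cantilever deflection in nm.
    loading_rate : float, optional
        Commanded approach speed in nm/s.
    square_id : str, optional
        Label of the grid square the curve was acquired on.
    meta : dict
        Free-form acquisition metadata (sensitivity, ground truth for
        synthetic curves, ...).
    """

    time: np.ndarray
    piezo: np.ndarray
    signal: np.ndarray | None = None
    deflection: np.ndarray | None = None
    loading_rate: float | None = None
    square_id: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.piezo = np.asarray(self.piezo, dtype=float)
        if (self.signal is None) == (self.deflection is None):
            raise ValueError(
                "exactly one of 'signal' (V) or 'deflection' (nm) must be set"
            )
        if self.signal is not None:
            self.signal = np.asarray(self.signal, dtype=float)
        if self.deflection is not None:
            self.deflection = np.asarray(self.deflection, dtype=float)
        n = len(self.time)
        if len(self.piezo) != n or len(self.channel) != n:
            raise ValueError("time, piezo and signal/deflection lengths differ")
        if n and np.any(np.diff(self.time) < 0):
            raise ValueError("time axis must be monotone non-decreasing")

    @property
    def channel(self) -> np.ndarray:
        """The measured channel, whichever of signal/deflection is present."""
        return self.signal if self.signal is not None else self.deflection  # type: ignore[return-value]

    @property
    def in_volts(self) -> bool:
        return self.signal is not None

    @property
    def sampling_rate(self) -> float:
        """Mean sampling rate in Hz."""
        dt = np.diff(self.time)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("cannot infer sampling rate from degenerate time axis")
        return 1.0 / float(np.mean(dt))

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TopographyMap:
    """A 2D height map in nm with labelled region masks.

    ``masks`` maps region names (``pattern``, ``passivation``, ``ablated``,
    optionally ``background``) to boolean arrays of the map's shape.  Masks
    must be pairwise disjoint.
    """

    heights: np.ndarray
    pixel_size: float  # nm / pixel
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        total = np.zeros(self.heights.shape, dtype=int)
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.heights.shape:
                raise ValueError(f"mask {name!r} shape does not match heights")
            self.masks[name] = m
            total += m
        if np.any(total > 1):
            raise ValueError("region masks must be disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]


@dataclass
class BoundaryTrace:
    """An ordered boundary polyline in nm, optionally closed.

    ``reference_square`` (if set) holds the ideal square the trace is
    compared against: dict with keys ``center`` (x, y), ``side`` and
    ``angle`` (radians).
    """

    polyline: np.ndarray  # (N, 2) in nm, columns (x, y)
    closed: bool = True
    reference_square: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (N, 2) array")
        if len(self.polyline) < 3:
            raise ValueError("polyline needs at least 3 points")

    @property
    def length(self) -> float:
        """Polyline length in nm (closing segment included when closed)."""
        pts = self.polyline
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class JunctionSegmentation:
    """Segmented junction geometry: two membrane surfaces and bridging rods.

    Membranes are 3D point sets in nm.  Rods are straight segments with a
    width annotation (nm); endpoints should lie between the membranes.
    """

    membrane_a: np.ndarray  # (Na, 3) nm
    membrane_b: np.ndarray  # (Nb, 3) nm
    rod_start: np.ndarray  # (R, 3) nm
    rod_end: np.ndarray  # (R, 3) nm
    rod_width: np.ndarray  # (R,) nm
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membrane_a = np.atleast_2d(np.asarray(self.membrane_a, dtype=float))
        self.membrane_b = np.atleast_2d(np.asarray(self.membrane_b, dtype=float))
        for name in ("membrane_a", "membrane_b"):
            pts = getattr(self, name)
            if pts.shape[0] == 0 or pts.shape[1] != 3:
                raise ValueError(f"{name} must be a nonempty (N, 3) point set")
        self.rod_start = np.asarray(self.rod_start, dtype=float).reshape(-1, 3)
        self.rod_end = np.asarray(self.rod_end, dtype=float).reshape(-1, 3)
        self.rod_width = np.asarray(self.rod_width, dtype=float).ravel()
        if not (len(self.rod_start) == len(self.rod_end) == len(self.rod_width)):
            raise ValueError("rod arrays must have matching lengths")
        if np.any(self.rod_width <= 0):
            raise ValueError("rod widths must be positive")

    @property
    def n_rods(self) -> int:
        return len(self.rod_width)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "JunctionSegmentation":
        """Return a copy with a rigid motion applied to all coordinates."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return JunctionSegmentation(
            membrane_a=self.membrane_a @ R.T + t,
            membrane_b=self.membrane_b @ R.T + t,
            rod_start=self.rod_start @ R.T + t,
            rod_end=self.rod_end @ R.T + t,
            rod_width=self.rod_width.copy(),
            meta=dict(self.meta),
        )
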