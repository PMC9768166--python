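"""Readers and writers for the package's on-disk formats.

Force curves: delimited text (CSV with header) or HDF5 groups; columns
are ``time_s``, ``piezo_nm`` and exactly one of ``signal_V`` /
``deflection_nm``.  Height maps: 32-bit TIFF in nm with the pixel size
stored in the image description; masks as label TIFF.  Occupancy tables:
CSV.  Junction geometry: two delimited point/segment tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .types import ForceCurve, JunctionSegmentation, TopographyMap

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_curve_hdf5",
    "read_curve_hdf5",
    "write_topography_tiff",
    "read_topography_tiff",
    "write_junction_tables",
    "read_junction_tables",
]

_CHANNELS = ("signal_V", "deflection_nm")


def _curve_frame(curve: ForceCurve) -> pd.DataFrame:
    data = {"time_s": curve.time, "piezo_nm": curve.piezo}
    if curve.in_volts:
        data["signal_V"] = curve.signal
    else:
        data["deflection_nm"] = curve.deflection
    return pd.DataFrame(data)


def write_curve_csv(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    header_meta = {
        "loading_rate_nm_s": curve.loading_rate,
        "square_id": curve.square_id,
    }
    with open(path, "w") as fh:
        fh.write(f"# gridmech force curve {json.dumps(header_meta)}\n")
        _curve_frame(curve).to_csv(fh, index=False)


def read_curve_csv(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.split("curve", 1)[1])
            except (IndexError, json.JSONDecodeError):
                meta = {}
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    present = [c for c in _CHANNELS if c in df.columns]
    if len(present) != 1:
        raise ValueError(
            f"curve file must contain exactly one of {_CHANNELS}, found {present}"
        )
    kwargs = {"signal": df[present[0]].to_numpy()} if present[0] == "signal_V" else {
        "deflection": df[present[0]].to_numpy()
    }
    return ForceCurve(
        time=df["time_s"].to_numpy(),
        piezo=df["piezo_nm"].to_numpy(),
        loading_rate=meta.get("loading_rate_nm_s"),
        square_id=meta.get("square_id"),
        **kwargs,
    )


def write_curve_hdf5(curve: ForceCurve, path: str | Path, group: str = "curve") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("time_s", data=curve.time)
        g.create_dataset("piezo_nm", data=curve.piezo)
        if curve.in_volts:
            g.create_dataset("signal_V", data=curve.signal)
        else:
            g.create_dataset("deflection_nm", data=curve.deflection)
        if curve.loading_rate is not None:
            g.attrs["loading_rate_nm_s"] = curve.loading_rate
        if curve.square_id is not None:
            g.attrs["square_id"] = curve.square_id


def read_curve_hdf5(path: str | Path, group: str = "curve") -> ForceCurve:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        present = [c for c in _CHANNELS if c in g]
        if len(present) != 1:
            raise ValueError(
                f"HDF5 group must contain exactly one of {_CHANNELS}, found {present}"
            )
        kwargs = (
            {"signal": g["signal_V"][:]}
            if present[0] == "signal_V"
            else {"deflection": g["deflection_nm"][:]}
        )
        return ForceCurve(
            time=g["time_s"][:],
            piezo=g["piezo_nm"][:],
            loading_rate=g.attrs.get("loading_rate_nm_s"),
            square_id=g.attrs.get("square_id"),
            **kwargs,
        )


_MASK_ORDER = ("pattern", "passivation", "ablated", "background")


def write_topography_tiff(topo: TopographyMap, path: str | Path) -> None:
    """Heights as float32 TIFF (nm); masks as a uint8 label page alongside."""
    path = Path(path)
    desc = json.dumps({"units": "nm", "pixel_size_nm": topo.pixel_size})
    tifffile.imwrite(path, topo.heights.astype(np.float32), description=desc)
    if topo.masks:
        labels = np.zeros(topo.heights.shape, dtype=np.uint8)
        for code, name in enumerate(_MASK_ORDER, start=1):
            if name in topo.masks:
                labels[topo.masks[name]] = code
        tifffile.imwrite(path.with_suffix(".masks.tif"), labels)


def read_topography_tiff(path: str | Path) -> TopographyMap:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        heights = tf.pages[0].asarray().astype(float)
        desc = tf.pages[0].tags.get("ImageDescription")
        pixel_size = 1.0
        if desc is not None:
            try:
                pixel_size = float(json.loads(desc.value)["pixel_size_nm"])
            except (json.JSONDecodeError, KeyError, TypeError):
                pass
    masks: dict[str, np.ndarray] = {}
    mask_path = path.with_suffix(".masks.tif")
    if mask_path.exists():
        labels = tifffile.imread(mask_path)
        for code, name in enumerate(_MASK_ORDER, start=1):
            m = labels == code
            if m.any():
                masks[name] = m
    return TopographyMap(heights=heights, pixel_size=pixel_size, masks=masks)


def write_junction_tables(seg: JunctionSegmentation, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.points.csv`` (x,y,z,surface) and ``<prefix>.rods.csv``."""
    prefix = Path(prefix)
    points_path = prefix.with_suffix(".points.csv")
    rods_path = prefix.with_suffix(".rods.csv")
    pts = pd.concat(
        [
            pd.DataFrame(seg.membrane_a, columns=["x_nm", "y_nm", "z_nm"]).assign(surface="A"),
            pd.DataFrame(seg.membrane_b, columns=["x_nm", "y_nm", "z_nm"]).assign(surface="B"),
        ],
        ignore_index=True,
    )
    pts.to_csv(points_path, index=False)
    rods = pd.DataFrame(
        np.column_stack([seg.rod_start, seg.rod_end, seg.rod_width]),
        columns=["x0_nm", "y0_nm", "z0_nm", "x1_nm", "y1_nm", "z1_nm", "width_nm"],
    )
    rods.to_csv(rods_path, index=False)
    return points_path, rods_path


def read_junction_tables(prefix: str | Path) -> JunctionSegmentation:
    prefix = Path(prefix)
    pts = pd.read_csv(prefix.with_suffix(".points.csv"))
    rods = pd.read_csv(prefix.with_suffix(".rods.csv"))
    coords = ["x_nm", "y_nm", "z_nm"]
    return JunctionSegmentation(
        membrane_a=pts.loc[pts["surface"] == "A", coords].to_numpy(),
        membrane_b=pts.loc[pts["surface"] == "B", coords].to_numpy(),
        rod_start=rods[["x0_nm", "y0_nm", "z0_nm"]].to_numpy(),
        rod_end=rods[["x1_nm", "y1_nm", "z1_nm"]].to_numpy(),
        rod_width=rods["width_nm"].to_numpy(),
    )
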