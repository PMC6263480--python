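"""Readers and writers for the pipeline's on-disk formats.

Point clouds travel as ASCII PLY (double-precision x, y, z) or as CSV with
an ``x,y,z`` header; polar records as CSV (``omega_deg,azimuth_deg,range_m``);
plot delineations as GeoJSON polygons carrying a ``plot_id`` property;
rasters as ESRI ASCII grids (see :mod:`canopy3d.raster`); tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .cloud import PointCloud
from .geometry import RECORD_COLUMNS


def write_ply(cloud: PointCloud, path) -> None:
    """Write an ASCII PLY with double-precision vertex coordinates."""
    pts = cloud.points
    header = (
        "ply\n"
        "format ascii 1.0\n"
        f"comment frame_state {cloud.frame_state}\n"
        f"element vertex {len(pts)}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "end_header\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, pts, fmt="%.12g")


def read_ply(path) -> PointCloud:
    """Read an ASCII PLY containing x, y, z vertex properties."""
    frame_state = "raw"
    n_vertices = None
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unterminated PLY header")
            tok = line.split()
            if tok[:2] == ["comment", "frame_state"] and len(tok) == 3:
                frame_state = tok[2]
            elif tok[:2] == ["element", "vertex"]:
                n_vertices = int(tok[2])
            elif tok and tok[0] == "format" and tok[1] != "ascii":
                raise ValueError(f"{path}: only ASCII PLY is supported")
            elif tok == ["end_header"]:
                break
        if n_vertices == 0:
            data = np.empty((0, 3))
        else:
            data = np.loadtxt(fh, ndmin=2)
    if data.size == 0:
        data = np.empty((0, 3))
    if n_vertices is not None and data.shape[0] != n_vertices:
        raise ValueError(
            f"{path}: header promises {n_vertices} vertices, body has {data.shape[0]}"
        )
    return PointCloud(data[:, :3], frame_state=frame_state)


def write_cloud_csv(cloud: PointCloud, path) -> None:
    pd.DataFrame(cloud.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_cloud_csv(path, frame_state: str = "raw") -> PointCloud:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cloud CSV missing columns {missing}")
    return PointCloud(df[["x", "y", "z"]].to_numpy(float), frame_state=frame_state)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: records CSV missing columns {missing}")
    return df


def read_plot_polygons(path) -> dict[object, shapely.Geometry]:
    """Read plot delineations from GeoJSON keyed by the plot_id property."""
    with open(path) as fh:
        collection = json.load(fh)
    return plot_polygons_from_geojson(collection)


def plot_polygons_from_geojson(collection: dict) -> dict[object, shapely.Geometry]:
    if collection.get("type") != "FeatureCollection":
        raise ValueError("plot delineation GeoJSON must be a FeatureCollection")
    plots: dict[object, shapely.Geometry] = {}
    for feature in collection.get("features", []):
        props = feature.get("properties") or {}
        if "plot_id" not in props:
            raise ValueError("every plot feature needs a plot_id property")
        plots[props["plot_id"]] = shapely.geometry.shape(feature["geometry"])
    if not plots:
        raise ValueError("no plot features found")
    return plots


def write_geojson(collection: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1)


def write_json(data: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
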