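"""Readers and writers for the formats the pipeline touches.

Rasters are single-band GeoTIFFs with 8-bit class codes, a palette colour
table, and the georeferencing carried in the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL nodata tag,
written and parsed directly through :mod:`tifffile`.  Vector transport layers
and point sets use GeoJSON; validation points also round-trip through CSV
(columns ``x, y, map_class, ref_class``; comma-separated, header row, UTF-8,
'.' decimal).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .classes import ClassRegistry, CodeMapping, default_transport_mapping
from .errors import FormatError
from .grid import NODATA, CategoricalRaster, GridSpec

log = logging.getLogger(__name__)

# GeoTIFF / GDAL tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113
# GeoKey ids
_GT_MODEL_TYPE = 1024
_GT_RASTER_TYPE = 1025
_PROJECTED_CRS = 3072


@dataclass
class TransportLayer:
    """Class-attributed transport geometries (polylines or polygons)."""

    geometries: list[BaseGeometry]
    class_codes: list[int]
    crs_id: int

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.class_codes):
            raise FormatError("one class code per geometry required")
        for g in self.geometries:
            if g.is_empty:
                raise FormatError("empty geometry in transport layer")
            if not math.isfinite(g.bounds[0]):
                raise FormatError("non-finite geometry in transport layer")

    def __len__(self) -> int:
        return len(self.geometries)

    def codes_present(self) -> list[int]:
        return sorted(set(self.class_codes))


@dataclass
class ValidationPoints:
    """Point records of (x, y, map class, optional reference class)."""

    table: pd.DataFrame
    crs_id: int | None = None

    def __post_init__(self) -> None:
        required = {"x", "y", "map_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"points table missing columns: {sorted(missing)}")
        if "ref_class" not in self.table.columns:
            self.table = self.table.assign(ref_class=pd.array([pd.NA] * len(self.table),
                                                              dtype="Int64"))

    def __len__(self) -> int:
        return len(self.table)

    def check_inside(self, grid: GridSpec) -> None:
        for i, row in self.table.iterrows():
            if not (math.isnan(row.x) or grid.contains_point(row.x, row.y)):
                raise FormatError(f"point {i} at ({row.x}, {row.y}) outside the map grid")


# ---------------------------------------------------------------------------
# rasters


def write_raster(raster: CategoricalRaster, path, registry: ClassRegistry | None = None) -> None:
    """Write a categorical raster as a palette GeoTIFF with full georeferencing."""
    vals = raster.values
    if vals.min() < 0 or vals.max() > 255:
        raise FormatError("8-bit GeoTIFF writer requires codes in 0..255")
    vals = vals.astype(np.uint8)
    g = raster.grid
    colormap = np.zeros((3, 256), dtype=np.uint16)
    if registry is not None:
        for cid, (r, gg, b) in registry.colormap().items():
            colormap[:, cid] = (r * 257, gg * 257, b * 257)
    geokeys = (1, 1, 0, 3,
               _GT_MODEL_TYPE, 0, 1, 1,      # projected CRS
               _GT_RASTER_TYPE, 0, 1, 1,     # PixelIsArea
               _PROJECTED_CRS, 0, 1, g.crs_id)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, str(raster.nodata_code)),
    ]
    tifffile.imwrite(path, vals, photometric="palette", colormap=colormap,
                     extratags=extratags)


def _tag_value(page, code):
    tag = page.tags.get(code)
    return None if tag is None else tag.value


def read_raster(path) -> CategoricalRaster:
    """Read a single-band integer GeoTIFF written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel and page.samplesperpixel > 1:
            raise FormatError(f"{path}: expected a single band, got {page.samplesperpixel}")
        arr = page.asarray()
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected a single 2-D band")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"{path}: expected integer codes, got {arr.dtype}")
        scale = _tag_value(page, _MODEL_PIXEL_SCALE)
        tiepoint = _tag_value(page, _MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise FormatError(f"{path}: missing georeferencing tags")
        geokeys = _tag_value(page, _GEO_KEY_DIRECTORY)
        crs_id = 0
        if geokeys is not None:
            keys = list(geokeys)
            for i in range(4, len(keys) - 3, 4):
                if keys[i] == _PROJECTED_CRS:
                    crs_id = int(keys[i + 3])
        nodata_tag = _tag_value(page, _GDAL_NODATA)
        nodata = int(float(nodata_tag)) if nodata_tag is not None else NODATA
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-9:
        raise FormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    # tiepoint maps raster (i, j) to map (x, y); the writer anchors (0, 0)
    ox = float(tiepoint[3]) - float(tiepoint[0]) * sx
    oy = float(tiepoint[4]) + float(tiepoint[1]) * sy
    grid = GridSpec(crs_id=crs_id, origin_x=ox, origin_y=oy, cell_size=sx,
                    n_rows=arr.shape[0], n_cols=arr.shape[1])
    return CategoricalRaster(grid, arr, nodata_code=nodata)


def read_colormap(path) -> dict[int, tuple[int, int, int]]:
    """Colour table of a palette GeoTIFF as {code: 8-bit RGB}, zero entries dropped."""
    with tifffile.TiffFile(path) as tf:
        cmap = tf.pages[0].colormap
    if cmap is None:
        return {}
    out = {}
    for code in range(cmap.shape[1]):
        rgb = tuple(int(v // 257) for v in cmap[:, code])
        if any(rgb):
            out[code] = rgb
    return out


def write_heights(raster, path) -> None:
    """Write a metric building-height layer as a float32 GeoTIFF (NaN nodata)."""
    g = raster.grid
    geokeys = (1, 1, 0, 3,
               _GT_MODEL_TYPE, 0, 1, 1,
               _GT_RASTER_TYPE, 0, 1, 1,
               _PROJECTED_CRS, 0, 1, g.crs_id)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, raster.values.astype(np.float32), extratags=extratags)


def read_heights(path):
    """Read a building-height layer: float band -> metric

    :class:`~urbanfuse.grid.ContinuousRaster`, integer band -> pre-binned
    :class:`~urbanfuse.grid.CategoricalRaster` of classes 0..10.
    """
    from .grid import ContinuousRaster

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if np.issubdtype(arr.dtype, np.integer):
            pass
        elif not np.issubdtype(arr.dtype, np.floating):
            raise FormatError(f"{path}: unsupported height dtype {arr.dtype}")
        scale = _tag_value(page, _MODEL_PIXEL_SCALE)
        tiepoint = _tag_value(page, _MODEL_TIEPOINT)
        geokeys = _tag_value(page, _GEO_KEY_DIRECTORY)
    if scale is None or tiepoint is None:
        raise FormatError(f"{path}: missing georeferencing tags")
    crs_id = 0
    if geokeys is not None:
        keys = list(geokeys)
        for i in range(4, len(keys) - 3, 4):
            if keys[i] == _PROJECTED_CRS:
                crs_id = int(keys[i + 3])
    grid = GridSpec(crs_id=crs_id, origin_x=float(tiepoint[3]),
                    origin_y=float(tiepoint[4]), cell_size=float(scale[0]),
                    n_rows=arr.shape[0], n_cols=arr.shape[1])
    if np.issubdtype(arr.dtype, np.integer):
        return CategoricalRaster(grid, arr, nodata_code=0)
    return ContinuousRaster(grid, arr.astype(np.float64))


# ---------------------------------------------------------------------------
# vectors


def write_transport(layer: TransportLayer, path, code_field: str = "code") -> None:
    features = [
        {"type": "Feature",
         "properties": {code_field: int(code)},
         "geometry": geom_mapping(geom)}
        for geom, code in zip(layer.geometries, layer.class_codes)
    ]
    doc = {"type": "FeatureCollection",
           "crs_id": layer.crs_id,
           "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_transport(path, code_field: str = "code",
                   mapping: CodeMapping | None = None) -> TransportLayer:
    """Read a GeoJSON transport layer, keeping only declared class codes.

    Retained and dropped feature counts are logged; a missing attribute field
    fails with the fields that are available.
    """
    mapping = mapping or default_transport_mapping()
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    geoms, codes, dropped = [], [], 0
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if code_field not in props:
            raise FormatError(
                f"{path}: missing field {code_field!r}; available: {sorted(props)}")
        code = int(props[code_field])
        if code in mapping.mapping:
            geoms.append(geom_shape(feat["geometry"]))
            codes.append(code)
        else:
            dropped += 1
    if dropped:
        log.info("%s: dropped %d features with undeclared transport codes", path, dropped)
    if not geoms:
        log.warning("%s: empty transport layer", path)
    return TransportLayer(geoms, codes, crs_id=int(doc.get("crs_id", 0)))


# ---------------------------------------------------------------------------
# points


def write_points(points: ValidationPoints, path) -> None:
    path = str(path)
    if path.endswith(".csv"):
        points.table.to_csv(path, index=False)
    elif path.endswith((".geojson", ".json")):
        feats = []
        for _, row in points.table.iterrows():
            props = {"map_class": int(row.map_class)}
            if pd.notna(row.ref_class):
                props["ref_class"] = int(row.ref_class)
            feats.append({"type": "Feature", "properties": props,
                          "geometry": {"type": "Point", "coordinates": [row.x, row.y]}})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "crs_id": points.crs_id,
                       "features": feats}, fh)
    else:
        raise FormatError(f"unsupported points format: {path}")


def read_points(path) -> ValidationPoints:
    path = str(path)
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        for col in ("x", "y"):
            if col in df.columns:
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise FormatError(
                        f"{path}: non-numeric {col!r} value {df[col].iloc[row]!r} "
                        f"at data row {row}")
                df[col] = pd.to_numeric(df[col])
        if "map_class" not in df.columns:
            raise FormatError(f"{path}: missing map_class column")
        # labels may be integer class ids or class names
        for col, dtype in (("map_class", "int64"), ("ref_class", "Int64")):
            if col in df.columns:
                try:
                    df[col] = df[col].astype(dtype)
                except (ValueError, TypeError):
                    pass
        return ValidationPoints(df)
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            doc = json.load(fh)
        rows = []
        for feat in doc.get("features", []):
            x, y = feat["geometry"]["coordinates"]
            props = feat.get("properties") or {}
            rows.append({"x": float(x), "y": float(y),
                         "map_class": int(props["map_class"]),
                         "ref_class": props.get("ref_class", pd.NA)})
        df = pd.DataFrame(rows, columns=["x", "y", "map_class", "ref_class"])
        df["ref_class"] = df["ref_class"].astype("Int64")
        return ValidationPoints(df, crs_id=doc.get("crs_id"))
    raise FormatError(f"unsupported points format: {path}")
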