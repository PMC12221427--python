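"""Layer stacking and reclassification: the per-pixel fusion decision.

Four co-registered layers are combined into the final land-cover map:

1. a categorical base layer distinguishing vegetation types, sealed surface
   and water (CLC+ Backbone style raw codes),
2. a water-and-wetness status layer whose permanent-wet codes convert
   vegetation and water pixels to Wetland,
3. a building-height layer (metric heights or pre-binned classes) that
   replaces sealed pixels carrying a height by one of ten building classes,
4. a transport raster (from :mod:`urbanfuse.transport`) that replaces the
   remaining sealed pixels it covers by a road or rail class.

Sealed pixels touched by neither heights nor transport stay Sealed; pixels
that are not sealed and not flagged wet pass through unchanged.  The decision
is pure and per-pixel; :func:`fuse` is the vectorised implementation and
:func:`fuse_pixel` the scalar reference it must agree with.
"""

from __future__ import annotations

import hashlib
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from math import isfinite

import numpy as np
import pandas as pd
import yaml

from .classes import FusionConfig
from .errors import AlignmentError, GridError
from .grid import (NODATA, CategoricalRaster, ContinuousRaster, GridSpec,
                   check_alignment)
from .io import TransportLayer

log = logging.getLogger(__name__)


def height_to_class(height: float | None, bin_edges) -> int | None:
    """Building class 1..10 for a metric height, or None.

    Class k covers [edge_k, edge_{k+1}); the top interval is closed at the
    last edge.  Heights below the first edge (no building, or below the
    minimum buildable height), above the last edge, or non-finite give None.
    """
    if height is None or not isfinite(height):
        return None
    edges = list(bin_edges)
    if height < edges[0]:
        return None
    if height == edges[-1]:
        return len(edges) - 1
    k = bisect_right(edges, height)
    return k if k <= len(edges) - 1 else None


@dataclass(frozen=True)
class PixelState:
    """The four co-located inputs to the fusion decision for one cell.

    ``base_class`` is an internal class id (or the nodata sentinel);
    ``height_class`` a building class 1..10 or None; ``transport_class`` an
    internal transport class id or None.
    """

    base_class: int
    wet_flag: bool = False
    height_class: int | None = None
    transport_class: int | None = None


def fuse_pixel(state: PixelState, cfg: FusionConfig, nodata: int = NODATA) -> int:
    """Pure per-pixel fusion rule; the reference the raster path must match.

    In order: nodata propagates; permanent wetness converts wetland-eligible
    base classes (vegetation and water) to Wetland; sealed pixels with a
    building height become that building class; remaining sealed pixels under
    transport become that transport class; all other sealed pixels stay
    Sealed; everything else passes through.
    """
    reg = cfg.registry
    if state.base_class == nodata:
        return nodata
    if state.base_class in cfg.wetland_eligible and state.wet_flag:
        return reg.wetland_id
    if state.base_class == reg.sealed_id:
        if state.height_class is not None:
            return reg.ids("building")[state.height_class - 1]
        if state.transport_class is not None:
            return state.transport_class
        return reg.sealed_id
    return state.base_class


@dataclass
class FusedMap:
    """Final land-cover raster plus per-class tallies and provenance."""

    raster: CategoricalRaster
    tallies: dict[int, int]
    provenance: dict = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return self.raster.grid


def _height_classes(heights, cfg: FusionConfig, shape) -> np.ndarray:
    """Array of building classes 0 (= none) or 1..10 from either height form."""
    if heights is None:
        return np.zeros(shape, dtype=np.int64)
    if isinstance(heights, ContinuousRaster):
        h = heights.values
        edges = np.asarray(cfg.height_bin_edges)
        bad = ~np.isfinite(h)
        n_bad = int(bad.sum() - np.isnan(h).sum())
        if n_bad:
            log.info("height layer: %d non-finite heights treated as none", n_bad)
        hc = np.digitize(np.where(bad, -np.inf, h), edges)  # 0 below, 11 above top
        hc[np.isclose(np.where(bad, np.nan, h), edges[-1], rtol=0, atol=0)] = 10
        hc[hc > 10] = 0
        return hc
    if isinstance(heights, CategoricalRaster):
        hc = heights.values.astype(np.int64)
        hc[hc == heights.nodata_code] = 0
        if hc.max(initial=0) > 10:
            raise GridError("pre-binned height raster must hold classes 0..10")
        return hc
    raise GridError(f"unsupported height layer type {type(heights).__name__}")


def _require_aligned(name_a: str, a: GridSpec, name_b: str, b: GridSpec,
                     strict: bool) -> None:
    verdict = check_alignment(a, b)
    if not verdict:
        if strict:
            raise AlignmentError(f"{name_a} vs {name_b}: {verdict.reason}")
        log.warning("lenient mode: %s vs %s misaligned (%s); snapping to %s grid",
                    name_a, name_b, verdict.reason, name_a)
    if a.shape != b.shape:
        raise AlignmentError(
            f"{name_a} vs {name_b}: shapes differ {a.shape} != {b.shape}")


def fuse(base: CategoricalRaster,
         wetness: CategoricalRaster | None,
         heights: ContinuousRaster | CategoricalRaster | None,
         transport: CategoricalRaster | TransportLayer | None,
         cfg: FusionConfig | None = None) -> FusedMap:
    """Fuse the four layers into the final land-cover map.

    ``wetness``, ``heights`` and ``transport`` may each be None (empty
    overlay).  ``transport`` may be a raster of raw transport codes or a
    vector layer, in which case it is buffered and rasterized here with the
    configured distance and priority.  In strict mode (default) all layers
    must be grid-aligned with the base; lenient mode snaps them onto the base
    lattice by nearest neighbour (a pure origin shift) and logs the offset.
    """
    cfg = cfg or FusionConfig()
    grid = base.grid
    if isinstance(transport, TransportLayer):
        from .transport import buffer_transport, max_area_assign

        raw_priority = _internal_to_raw_priority(cfg)
        buffered = buffer_transport(transport, cfg.buffer_distance)
        transport = max_area_assign(buffered, grid, raw_priority)
    for name, layer in (("wetness", wetness), ("heights", heights),
                        ("transport", transport)):
        if layer is not None:
            _require_aligned("base", grid, name, layer.grid, cfg.strict_alignment)

    from .classes import reclassify

    mapped = reclassify(base, cfg.base_mapping)
    out = mapped.values.astype(np.uint8).copy()
    nodata_mask = mapped.values == cfg.base_mapping.nodata_out

    # wetness overlay on vegetation/water
    if wetness is not None:
        wet = np.isin(wetness.values, list(cfg.wet_trigger_codes))
        wet &= wetness.values != wetness.nodata_code
    else:
        wet = np.zeros(grid.shape, dtype=bool)
    eligible = np.isin(mapped.values, list(cfg.wetland_eligible))
    out[eligible & wet] = cfg.registry.wetland_id

    # height overlay on sealed
    sealed = mapped.values == cfg.registry.sealed_id
    hc = _height_classes(heights, cfg, grid.shape)
    building_ids = np.asarray([0] + cfg.registry.ids("building"), dtype=np.uint8)
    has_height = sealed & (hc > 0)
    out[has_height] = building_ids[hc[has_height]]

    # transport overlay on the remaining sealed pixels
    if transport is not None:
        tmap = reclassify(transport, cfg.transport_mapping)
        has_transport = tmap.values != cfg.transport_mapping.nodata_out
        pick = sealed & ~has_height & has_transport
        out[pick] = tmap.values[pick].astype(np.uint8)

    out[nodata_mask] = NODATA
    raster = CategoricalRaster(grid, out, nodata_code=NODATA)
    tallies = {k: v for k, v in raster.tally().items() if k != NODATA}
    result = FusedMap(raster, tallies, provenance=_provenance(cfg, base, wetness,
                                                              heights, transport))
    log.info("fused map: %d classes over %d cells (%d nodata)",
             len(tallies), grid.n_rows * grid.n_cols, int(nodata_mask.sum()))
    return result


def _internal_to_raw_priority(cfg: FusionConfig) -> list[int]:
    """Transport priority expressed in raw product codes."""
    inverse = {v: k for k, v in cfg.transport_mapping.mapping.items()}
    return [inverse[cfg.registry.id_of(name)] for name in cfg.transport_priority]


def _provenance(cfg, *layers) -> dict:
    digests = []
    for layer in layers:
        if layer is None:
            digests.append(None)
        else:
            arr = layer.values if hasattr(layer, "values") else None
            digests.append(hashlib.sha256(arr.tobytes()).hexdigest()[:16]
                           if arr is not None else "vector")
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    from . import __version__

    return {"config_hash": cfg_hash, "layer_checksums": digests,
            "package_version": __version__}


def class_tally(fused: FusedMap) -> pd.DataFrame:
    """Cell count and area (ha) per final class present in the map."""
    cell_ha = fused.grid.cell_size ** 2 / 10_000.0
    rows = []
    for cid, count in sorted(fused.tallies.items()):
        rows.append({"class_id": cid, "count": count, "area_ha": count * cell_ha})
    return pd.DataFrame(rows, columns=["class_id", "count", "area_ha"])
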