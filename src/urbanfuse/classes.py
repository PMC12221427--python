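"""Class scheme, product-code translation, and the fusion configuration.

The final land-cover legend combines a vegetation-focused base scheme with
anthropogenic classes: seven vegetation types, non-/sparsely vegetated, water,
wetland, sealed surface, ten building-height classes and three transport
classes (fast transit roads, other roads, railways) — 24 classes in total.

Raw product codes (the integers a distributed raster actually stores) are
translated to this internal legend through :class:`CodeMapping` tables.  The
default tables are editable implementation choices informed by the Copernicus
product documentation; they are not facts about the method itself and every
entry can be overridden from YAML config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import CodeError
from .grid import NODATA, CategoricalRaster

log = logging.getLogger(__name__)

Role = str
ROLES = (
    "base_vegetation",
    "base_natural",
    "water",
    "wetland",
    "sealed",
    "building",
    "transport",
)


@dataclass(frozen=True)
class ClassEntry:
    class_id: int
    name: str
    role: Role
    colour: tuple[int, int, int] = (128, 128, 128)


class ClassRegistry:
    """Ordered land-cover legend with role-based structural invariants.

    The registry enforces the shape of the final legend: exactly ten building
    classes, exactly three transport classes, and a single water, wetland and
    sealed entry each.
    """

    def __init__(self, entries: list[ClassEntry]):
        ids = [e.class_id for e in entries]
        if len(ids) != len(set(ids)):
            raise CodeError("duplicate class ids in registry")
        for e in entries:
            if e.role not in ROLES:
                raise CodeError(f"unknown role {e.role!r} for class {e.class_id}")
        by_role = {}
        for e in entries:
            by_role.setdefault(e.role, []).append(e)
        for role, want in (("building", 10), ("transport", 3),
                           ("water", 1), ("wetland", 1), ("sealed", 1)):
            got = len(by_role.get(role, []))
            if got != want:
                raise CodeError(f"registry must have exactly {want} {role} entries, got {got}")
        self.entries = list(entries)
        self._by_id = {e.class_id: e for e in entries}

    def __contains__(self, class_id: int) -> bool:
        return class_id in self._by_id

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, class_id: int) -> ClassEntry:
        return self._by_id[class_id]

    def ids(self, role: Role | None = None) -> list[int]:
        return [e.class_id for e in self.entries if role is None or e.role == role]

    def name_of(self, class_id: int) -> str:
        return self._by_id[class_id].name

    def id_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.class_id
        raise CodeError(f"no class named {name!r}")

    @property
    def sealed_id(self) -> int:
        return self.ids("sealed")[0]

    @property
    def water_id(self) -> int:
        return self.ids("water")[0]

    @property
    def wetland_id(self) -> int:
        return self.ids("wetland")[0]

    def colormap(self) -> dict[int, tuple[int, int, int]]:
        return {e.class_id: e.colour for e in self.entries}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> list[dict]:
        return [
            {"class_id": e.class_id, "name": e.name, "role": e.role,
             "colour": list(e.colour)}
            for e in self.entries
        ]

    @classmethod
    def from_dict(cls, data: list[dict]) -> "ClassRegistry":
        return cls([
            ClassEntry(int(d["class_id"]), str(d["name"]), str(d["role"]),
                       tuple(int(c) for c in d.get("colour", (128, 128, 128))))
            for d in data
        ])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"classes": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClassRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["classes"])


def default_registry() -> ClassRegistry:
    """The default 24-class legend.

    Note: the enumerable final classes total 24 (7 vegetation + non-/sparsely
    vegetated + water + wetland + sealed + 10 buildings + 3 transport), even
    though the legend is sometimes summarised as 23 classes; see the methods
    note for the discrepancy.
    """
    veg = [
        (2, "needle_leaved_trees", (20, 90, 50)),
        (3, "broadleaved_deciduous_trees", (60, 150, 60)),
        (4, "broadleaved_evergreen_trees", (0, 120, 70)),
        (5, "bushes_and_shrubs", (160, 190, 90)),
        (6, "grassland", (150, 210, 110)),
        (7, "crops", (230, 210, 130)),
        (8, "lichens_and_mosses", (190, 200, 160)),
    ]
    entries = [ClassEntry(1, "sealed", "sealed", (120, 120, 120))]
    entries += [ClassEntry(i, n, "base_vegetation", c) for i, n, c in veg]
    entries.append(ClassEntry(9, "non_sparsely_vegetated", "base_natural", (200, 180, 150)))
    entries.append(ClassEntry(10, "water", "water", (60, 100, 200)))
    entries.append(ClassEntry(11, "wetland", "wetland", (110, 170, 200)))
    for k in range(1, 11):
        shade = 110 - 9 * k
        entries.append(ClassEntry(11 + k, f"building_height_{k}", "building",
                                  (shade, shade, shade + 30)))
    entries.append(ClassEntry(22, "fast_transit_roads", "transport", (200, 60, 60)))
    entries.append(ClassEntry(23, "other_roads", "transport", (230, 140, 80)))
    entries.append(ClassEntry(24, "railways", "transport", (90, 60, 110)))
    return ClassRegistry(entries)


@dataclass
class CodeMapping:
    """Translation from raw product codes to internal class ids (or flags).

    ``policy`` controls undeclared input codes: ``"strict"`` raises,
    ``"nodata"`` maps them to the nodata sentinel and logs a count.
    """

    layer_name: str
    mapping: dict[int, int]
    policy: str = "strict"
    nodata_in: int = NODATA
    nodata_out: int = NODATA

    def __post_init__(self) -> None:
        if self.policy not in ("strict", "nodata"):
            raise CodeError(f"unknown undeclared-code policy {self.policy!r}")

    def lookup(self, code: int) -> int:
        if code == self.nodata_in:
            return self.nodata_out
        if code in self.mapping:
            return self.mapping[code]
        if self.policy == "strict":
            raise CodeError(f"{self.layer_name}: undeclared raw code {code}")
        return self.nodata_out

    def lut(self, max_code: int = 255) -> np.ndarray:
        """Dense lookup table for vectorised translation of uint8 rasters."""
        table = np.full(max_code + 1, self.nodata_out, dtype=np.int64)
        for raw, internal in self.mapping.items():
            table[raw] = internal
        table[self.nodata_in] = self.nodata_out
        return table

    def declared(self, codes: np.ndarray) -> np.ndarray:
        known = np.isin(codes, list(self.mapping)) | (codes == self.nodata_in)
        return known

    def compose(self, other: "CodeMapping") -> "CodeMapping":
        """Mapping equivalent to applying ``self`` then ``other``."""
        comp = {raw: other.lookup(mid) for raw, mid in self.mapping.items()}
        return CodeMapping(f"{self.layer_name}->{other.layer_name}", comp,
                           policy=self.policy, nodata_in=self.nodata_in,
                           nodata_out=other.nodata_out)


def reclassify(raster: CategoricalRaster, mapping: CodeMapping) -> CategoricalRaster:
    """Per-cell translation of a categorical raster through a code mapping.

    Nodata passes through; the input raster is left untouched.  Under the
    strict policy an undeclared code aborts, naming the code and the first
    offending cell.
    """
    vals = raster.values
    if mapping.policy == "strict":
        known = mapping.declared(vals) | (vals == raster.nodata_code)
        if not known.all():
            r, c = np.argwhere(~known)[0]
            raise CodeError(
                f"{mapping.layer_name}: undeclared raw code {int(vals[r, c])} "
                f"at cell ({int(r)}, {int(c)})"
            )
    table = mapping.lut(int(max(255, vals.max())))
    out = table[vals]
    out[vals == raster.nodata_code] = mapping.nodata_out
    n_dropped = int(((out == mapping.nodata_out) & (vals != raster.nodata_code)).sum())
    if n_dropped:
        log.info("%s: %d cells mapped to nodata by lenient policy",
                 mapping.layer_name, n_dropped)
    dtype = np.uint8 if out.max() <= 255 and out.min() >= 0 else np.int64
    return CategoricalRaster(raster.grid, out.astype(dtype), mapping.nodata_out)


# -- default raw-code tables ---------------------------------------------

#: Raw codes of the base land-cover product (CLC+ Backbone style).
BASE_RAW_CODES = {
    1: "sealed", 2: "needle_leaved_trees", 3: "broadleaved_deciduous_trees",
    4: "broadleaved_evergreen_trees", 5: "bushes_and_shrubs", 6: "grassland",
    7: "crops", 8: "lichens_and_mosses", 9: "non_sparsely_vegetated", 10: "water",
}

#: Raw codes of the water-and-wetness status product.
WETNESS_RAW_CODES = {
    0: "dry", 1: "permanent_water", 2: "temporary_water",
    3: "permanent_wetness", 4: "temporary_wetness",
}

#: Raw codes of the transport product (roads and rail network style).
TRANSPORT_RAW_CODES = {1: "fast_transit_roads", 2: "other_roads", 3: "railways"}


def default_base_mapping(registry: ClassRegistry | None = None) -> CodeMapping:
    reg = registry or default_registry()
    return CodeMapping("base", {raw: reg.id_of(name) for raw, name in BASE_RAW_CODES.items()})


def default_transport_mapping(registry: ClassRegistry | None = None) -> CodeMapping:
    reg = registry or default_registry()
    return CodeMapping("transport",
                       {raw: reg.id_of(name) for raw, name in TRANSPORT_RAW_CODES.items()},
                       nodata_in=0, nodata_out=NODATA)


@dataclass
class FusionConfig:
    """Everything the fusion decision function needs beyond the rasters.

    Parameters
    ----------
    registry : final class legend.
    base_mapping, transport_mapping : raw-code translation tables.
    wet_trigger_codes : wetness raw codes treated as "permanent wet".
    height_bin_edges : 11 ascending metres delimiting the 10 building classes;
        the lowest edge is the minimum buildable height (default 2 m), the top
        edge the tallest mapped building (368 m).  The interior edges are an
        implementation default — the products define only the 2–368 m span.
    buffer_distance : transport buffer radius in metres (default 7).
    transport_priority : tie-break order for maximum-area rasterization.
    wetland_eligible : base class ids that the wetness overlay may convert to
        wetland (the seven vegetation classes plus water).
    strict_alignment : refuse misaligned inputs instead of snapping.
    """

    registry: ClassRegistry = field(default_factory=default_registry)
    base_mapping: CodeMapping | None = None
    transport_mapping: CodeMapping | None = None
    wet_trigger_codes: frozenset[int] = frozenset({1, 3})
    height_bin_edges: tuple[float, ...] = (2, 5, 8, 11, 14, 17, 20, 25, 30, 50, 368)
    buffer_distance: float = 7.0
    transport_priority: tuple[str, ...] = ("railways", "fast_transit_roads", "other_roads")
    wetland_eligible: frozenset[int] | None = None
    strict_alignment: bool = True

    def __post_init__(self) -> None:
        if self.base_mapping is None:
            self.base_mapping = default_base_mapping(self.registry)
        if self.transport_mapping is None:
            self.transport_mapping = default_transport_mapping(self.registry)
        edges = tuple(float(e) for e in self.height_bin_edges)
        if len(edges) != 11 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise CodeError("height_bin_edges must be 11 strictly increasing values")
        self.height_bin_edges = edges
        if self.buffer_distance < 0:
            raise CodeError("buffer_distance must be >= 0")
        transport_names = {self.registry.name_of(i) for i in self.registry.ids("transport")}
        if set(self.transport_priority) != transport_names:
            raise CodeError(
                f"transport_priority must be a permutation of {sorted(transport_names)}"
            )
        if self.wetland_eligible is None:
            self.wetland_eligible = frozenset(
                self.registry.ids("base_vegetation") + [self.registry.water_id]
            )
        else:
            self.wetland_eligible = frozenset(self.wetland_eligible)

    @property
    def priority_ids(self) -> tuple[int, ...]:
        return tuple(self.registry.id_of(n) for n in self.transport_priority)

    def to_dict(self) -> dict:
        return {
            "registry": self.registry.to_dict(),
            "base_mapping": {int(k): int(v) for k, v in self.base_mapping.mapping.items()},
            "transport_mapping": {int(k): int(v) for k, v in self.transport_mapping.mapping.items()},
            "wet_trigger_codes": sorted(self.wet_trigger_codes),
            "height_bin_edges": list(self.height_bin_edges),
            "buffer_distance": self.buffer_distance,
            "transport_priority": list(self.transport_priority),
            "wetland_eligible": sorted(self.wetland_eligible),
            "strict_alignment": self.strict_alignment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        reg = ClassRegistry.from_dict(d["registry"]) if "registry" in d else default_registry()
        kwargs = {}
        if "base_mapping" in d:
            kwargs["base_mapping"] = CodeMapping(
                "base", {int(k): int(v) for k, v in d["base_mapping"].items()})
        if "transport_mapping" in d:
            kwargs["transport_mapping"] = CodeMapping(
                "transport", {int(k): int(v) for k, v in d["transport_mapping"].items()},
                nodata_in=0)
        for key in ("height_bin_edges", "buffer_distance", "transport_priority",
                    "strict_alignment"):
            if key in d:
                kwargs[key] = d[key]
        if "transport_priority" in kwargs:
            kwargs["transport_priority"] = tuple(kwargs["transport_priority"])
        if "wet_trigger_codes" in d:
            kwargs["wet_trigger_codes"] = frozenset(d["wet_trigger_codes"])
        if "wetland_eligible" in d:
            kwargs["wetland_eligible"] = frozenset(d["wetland_eligible"])
        return cls(registry=reg, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FusionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
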