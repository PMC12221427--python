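"""Buffer a small road/rail network and rasterize it by maximum area.

Two crossing roads and a railway are buffered by 7 m (round caps, so a 100 m
segment becomes a stadium of area 2*r*L + pi*r^2) and each 10 m cell receives
the class covering the largest share of it; an exact tie falls to the
priority order (railways > fast transit > other roads).
"""

import math

from shapely.geometry import LineString

import urbanfuse as uf

grid = uf.GridSpec(origin_x=0.0, origin_y=0.0, cell_size=10.0,
                   n_rows=12, n_cols=12)
network = uf.TransportLayer(
    [LineString([(5, -60), (115, -60)]),    # other road, west-east
     LineString([(60, -5), (60, -115)]),    # other road, north-south
     LineString([(5, -5), (115, -115)])],   # railway, diagonal
    [2, 2, 3], crs_id=3035)

buffered = uf.buffer_transport(network, 7.0)
stadium = 2 * 7 * 110 + math.pi * 7 ** 2
print(f"buffered area per class: "
      f"{ {c: round(g.area) for c, g in zip(buffered.class_codes, buffered.geometries)} } m²")
print(f"(closed-form stadium area of one 110 m segment: {stadium:.0f} m²)")

raster = uf.max_area_assign(buffered, grid, priority=(3, 1, 2))
print("rasterized classes (0 = no transport, 2 = other roads, 3 = railway):")
for row in raster.values:
    print(" ".join(str(v) for v in row))
covered = (raster.values != 0).sum()
print(f"{covered} of {grid.n_rows * grid.n_cols} cells carry transport")
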