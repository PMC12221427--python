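# Methods

## The fusion model

`urbanfuse` treats urban land-cover mapping as categorical raster fusion on a
shared lattice. All inputs are brought onto one grid of square cells
(default 10 m, the resolution of the pan-European thematic products the
pipeline emulates), addressed 0-based and row-major from the top-left
corner; cell (r, c) covers the half-open square
[x₀ + c·s, x₀ + (c+1)·s) × (y₀ − (r+1)·s, y₀ − r·s]. The half-open
convention fixes every point/cell containment question (a point on a shared
edge belongs to exactly one cell). The default CRS for synthetic data is
EPSG:3035 (metre-based, equal-area, the system the emulated products ship
in); the package never reprojects — inputs must already share a lattice, and
`check_alignment` decides that by CRS id, cell size and integer-multiple
origin offsets (tolerance 1e-9 of a cell).

The fusion itself is a pure per-pixel decision over four co-located values
(base class, permanent-wet flag, building-height class, transport class),
applied in a fixed order: nodata propagation, wetland overlay, height
overlay, transport overlay, residual sealed, identity. Two branches deserve
justification:

* **Wetland eligibility.** The wetness overlay refines only water and
  vegetation; its eligible set is the seven vegetation classes plus water.
  Sealed pixels are deliberately excluded (they are routed to the
  height/transport branches), and so is non-/sparsely vegetated ground —
  whether bare ground counts as "vegetation" for the wetland rule is
  genuinely open, and we exclude it; the set is a config field
  (`wetland_eligible`) for users who disagree.
* **Precedence on sealed pixels.** A sealed pixel carrying both a building
  height and transport coverage becomes the building class: the height
  product identifies built structures directly, while transport coverage is
  a buffered, rasterized vector and therefore bleeds one cell beyond the
  carriageway. Wetness on a sealed pixel changes nothing. Heights on
  non-sealed pixels (e.g. a tree canopy cell) are ignored rather than
  treated as buildings. Evaluation order wetland-before-heights is fixed for
  determinism even though, with the default eligibility set, the branches
  are disjoint.

Because the decision is per-pixel and total, the implementation carries its
own oracle: `fuse` is vectorised numpy, `fuse_pixel` is the scalar reference,
and the generator's expected maps are produced by a naive double loop over
`fuse_pixel`. The equivalence of the two paths on arbitrary scenes is the
package's central invariant.

## Class legend and code tables

The final legend holds 24 classes: 7 vegetation, non-/sparsely vegetated,
water, wetland, sealed, 10 building-height classes, 3 transport classes.
Summaries of this scheme sometimes quote 23 final classes (or "14 classes
added to the initial 10"), which does not match the enumerable legend; the
registry carries all 24 and we surface the discrepancy here rather than
silently dropping a class. Raw product codes (base 1–10, wetness status
0–4, transport 1–3) are implementation defaults informed by the product
documentation, not facts about the method; every table is editable YAML, and
undeclared codes either abort (strict, default) or map to nodata with a
logged count.

Wetness codes 1 (permanent water) and 3 (permanent wetness) trigger the
wetland rule by default — the "permanent wet" semantics; temporary codes do
not.

## Building-height binning

The height product distinguishes ten building classes spanning 2–368 m, but
the interior bin boundaries are not published. The default edges
2, 5, 8, 11, 14, 17, 20, 25, 30, 50, 368 m are an implementation default
(roughly storey-sized steps at the low end, where urban variation matters,
coarse at the top) and are clearly a placeholder, not a product fact; any 11
strictly increasing edges can be configured. Binning is half-open on the
left edge, with the top interval closed at 368 m; heights below 2 m, above
368 m or non-finite mean "no building" (the below-floor case is the
product's own convention; the others are logged). Pre-binned class rasters
(values 0–10) bypass the edges entirely, and both paths are required by test
to produce identical maps on generated scenes.

## Transport rasterization

Centrelines are buffered by 7 m — enough to make a carriageway survive on a
10 m grid without drowning neighbouring cells — with round caps and joins at
16 segments per quarter circle (configurable; at that resolution a stadium
around a 100 m segment is within 0.02 % of the closed form 2rL + πr²).
Same-class geometries are dissolved before any area is measured; without the
dissolve, "the class with the maximum area" is ill-defined when a class
covers a cell with two overlapping features. Each cell then takes the class
of largest intersection area; any strictly positive coverage is eligible (no
minimum-fraction cutoff, since the maximum-area rule alone decides), and
exact ties fall to a priority order, default railways > fast transit roads >
other roads, chosen so the rarer and narrower feature survives a 50/50
split. Cap style, tie-breaking and the dissolve step are all choices the
underlying method leaves open; they are fixed here and configurable.

The implementation computes per-cell intersection areas vectorised over the
cells inside each class geometry's bounding box; tests compare it against an
exhaustive cell-by-cell intersection oracle, which uses the same geometry
engine and therefore agrees exactly, tie cells included.

## Accuracy assessment

Rows of the confusion matrix are map classes, columns reference classes
(verified against the bundled sample: 54/67 = 0.81 reproduces the published
Sealed user accuracy, 54/77 = 0.70 the producer accuracy). Statistics are
the standard UA/PA/OA and Cohen's κ; κ is reported as undefined when
p_e = 1 (single-cell matrices), and per-class accuracies with an empty
marginal as NaN. Reports keep full precision and add half-up rounding at 2
decimals, the usual printed precision.

Stratified sampling draws exactly the requested number of distinct cells per
mapped class, uniformly without replacement, via numpy's PCG64 generator —
a named, seedable algorithm, so a seed reproduces the point set across
platforms. Per-class sizes are a user input (published assessments use
uneven strata); a proportional allocator with a per-class floor is provided
as convenience. Reference labelling is external by design: the package
ingests labelled points, it does not label.

The package ships one real validation dataset: the 530-point, 12-class
confusion matrix from an accuracy assessment of a Copernicus land-cover map
of Munich (overall accuracy 0.82, κ 0.79 at printed precision), used as a
fixed reference for the statistics and as the worked example for
matrix-to-points expansion.

## Synthetic cities

The generator emulates the statistical structure of the four products on a
200×200 default grid (2 km at 10 m): a grassland matrix with crop patches
toward the fringe, broadleaved/needle-leaved park stands, scattered shrubs
and bare ground; a meandering river and a lake with a permanent-wet fringe
(80 % of bank cells by default); gridded street blocks (spacing 25 cells)
built up with probability 0.5, 60 % of built cells carrying log-normal
heights (median 8 m, σ = 0.6, clipped to 2–368 m, ~3 % deliberately below
the 2 m floor to exercise the "no building" branch); other-road centrelines
on the street grid plus one fast-transit road and one railway; a small
nodata margin on the base layer. Every draw comes from one seeded PCG64
generator, so scenes are byte-reproducible.

What the generator does *not* emulate: realistic urban morphology, mixed
pixels (each synthetic cell has exactly one true class), registration error
between products, and classification noise. Passing tests therefore
demonstrate that the fusion, rasterization and assessment machinery is
exact, not that real products are accurate — the map accuracy question is
what the bundled Munich sample addresses. Rebuilding an actual city's map
requires the real Copernicus downloads and is explicitly out of scope.

## Numerical and I/O choices

* Class codes are 8-bit with nodata 255; 24 classes fit comfortably and the
  format stays colormap-capable. GeoTIFF georeferencing is written and
  parsed directly via the standard tags (ModelPixelScale, ModelTiepoint,
  GeoKeyDirectory, GDAL nodata) on top of `tifffile`; vectors and points use
  GeoJSON; points and matrices CSV (comma, header, UTF-8, '.' decimal).
* Area comparisons in the rasterizer are exact within the geometry engine;
  no epsilon is applied to ties, because both the implementation and the
  oracle derive areas from identical geometry operations.
* Strict alignment is the default; lenient mode snaps a layer onto the base
  lattice (pure origin shift, logged) and still requires equal shape.
* Every pipeline stage logs input/output class tallies, so information loss
  (e.g. vegetation cells overwritten when streets are stamped into the base)
  is auditable.

## Problem sizes

The test suite and the acceptance script regenerate everything at run time:
50–100 synthetic cities at 200×200 for fusion/oracle equivalence, 50 random
polygon scenes on grids up to 20×20 (up to 10 polygons) for the rasterizer
oracle, 100 random matrices for the pairs round-trip. These sizes give
per-pixel-exhaustive coverage of every branch while keeping a full run in
minutes on one CPU.

## Known limitations

* No reprojection, no multi-band rasters, no float rasters beyond the height
  layer; cloud-optimised/tiled access is out of scope.
* The interior height-bin edges are placeholders (see above).
* Confidence intervals on κ and area-weighted accuracy estimation are not
  implemented; the assessment mirrors the plain counts-based protocol.
* GeoPackage/Shapefile are not read; vector interchange is GeoJSON.
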