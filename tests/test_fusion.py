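"""Height binning and the per-pixel fusion decision, scalar and raster paths."""

import numpy as np
import pytest

import urbanfuse as uf
from urbanfuse.errors import AlignmentError
from urbanfuse.fusion import PixelState

EDGES = (2, 5, 8, 11, 14, 17, 20, 25, 30, 50, 368)


class TestHeightToClass:
    @pytest.mark.parametrize("height,expected", [
        (1.9, None),          # below the 2 m floor of the height product
        (2.0, 1),             # lower edges closed
        (4.999, 1),
        (5.0, 2),
        (367.9, 10),
        (368.0, 10),          # top interval closed at the last edge
        (400.0, None),
        (float("nan"), None),
        (float("inf"), None),
        (None, None),
    ])
    def test_examples(self, height, expected):
        assert uf.height_to_class(height, EDGES) == expected

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(2)
        heights = rng.uniform(0, 400, size=1000)

        def linear_scan(h):
            for k in range(10):
                if EDGES[k] <= h < EDGES[k + 1]:
                    return k + 1
            return 10 if h == EDGES[-1] else None

        for h in heights:
            assert uf.height_to_class(float(h), EDGES) == linear_scan(float(h))


class TestFusePixel:
    def ids(self, cfg):
        reg = cfg.registry
        return reg, reg.sealed_id, reg.water_id, reg.wetland_id

    def test_wet_water_becomes_wetland(self, cfg):
        reg, sealed, water, wetland = self.ids(cfg)
        assert uf.fuse_pixel(PixelState(water, wet_flag=True), cfg) == wetland

    def test_height_takes_precedence_over_transport_on_sealed(self, cfg):
        reg, sealed, *_ = self.ids(cfg)
        other_roads = reg.id_of("other_roads")
        out = uf.fuse_pixel(PixelState(sealed, False, 4, other_roads), cfg)
        assert out == reg.ids("building")[3]

    def test_heights_never_overwrite_vegetation(self, cfg):
        reg = cfg.registry
        grass = reg.id_of("grassland")
        assert uf.fuse_pixel(PixelState(grass, False, 4, None), cfg) == grass

    def test_bare_sealed_stays_sealed(self, cfg):
        reg, sealed, *_ = self.ids(cfg)
        assert uf.fuse_pixel(PixelState(sealed, False, None, None), cfg) == sealed

    def test_nodata_propagates(self, cfg):
        assert uf.fuse_pixel(PixelState(uf.NODATA, True, 3,
                                        cfg.registry.id_of("railways")), cfg) == uf.NODATA

    def test_wetness_on_sealed_changes_nothing(self, cfg):
        reg, sealed, *_ = self.ids(cfg)
        assert uf.fuse_pixel(PixelState(sealed, wet_flag=True), cfg) == sealed


def six_pixel_scene(cfg):
    """Worked 1x6 scene covering every fusion branch."""
    reg = cfg.registry
    grid = uf.GridSpec(n_rows=1, n_cols=6)
    base = uf.CategoricalRaster(grid, np.array(
        [[1, 1, 1, 10, 6, 7]], dtype=np.uint8))      # sealed x3, water, grass, crops
    wetness = uf.CategoricalRaster(grid, np.array(
        [[0, 0, 0, 3, 3, 0]], dtype=np.uint8))       # permanent wetness on 2 cells
    heights = uf.ContinuousRaster(grid, np.array(
        [[6.0, np.nan, np.nan, np.nan, np.nan, np.nan]]))  # class 2 on the first
    transport = uf.CategoricalRaster(grid, np.array(
        [[0, 3, 0, 0, 0, 0]], dtype=np.uint8), nodata_code=0)  # railway under cell 1
    expected = [reg.ids("building")[1], reg.id_of("railways"), reg.sealed_id,
                reg.wetland_id, reg.wetland_id, reg.id_of("crops")]
    return base, wetness, heights, transport, expected


class TestFuse:
    def test_identity_path_with_empty_overlays(self, cfg):
        grid = uf.GridSpec(n_rows=3, n_cols=3)
        base = uf.CategoricalRaster(grid, np.full((3, 3), 6, dtype=np.uint8))
        fused = uf.fuse(base, None, None, None, cfg)
        assert (fused.raster.values == cfg.base_mapping.lookup(6)).all()

    def test_six_pixel_worked_scene(self, cfg):
        base, wetness, heights, transport, expected = six_pixel_scene(cfg)
        fused = uf.fuse(base, wetness, heights, transport, cfg)
        assert fused.raster.values[0].tolist() == expected

    def test_tally_of_worked_scene(self, cfg):
        base, wetness, heights, transport, expected = six_pixel_scene(cfg)
        fused = uf.fuse(base, wetness, heights, transport, cfg)
        df = uf.class_tally(fused)
        assert df["count"].sum() == 6
        counts = dict(zip(df.class_id, df["count"]))
        assert counts[cfg.registry.wetland_id] == 2
        assert counts[cfg.registry.id_of("crops")] == 1
        assert df.area_ha.sum() == pytest.approx(6 * 0.01)

    def test_tally_invariant_under_transposition(self, cfg, small_scene):
        fused = uf.fuse(small_scene.base, small_scene.wetness,
                        small_scene.heights_m, small_scene.transport_raster, cfg)
        transposed = uf.FusedMap(
            uf.CategoricalRaster(
                uf.GridSpec(n_rows=fused.grid.n_cols, n_cols=fused.grid.n_rows,
                            cell_size=fused.grid.cell_size),
                fused.raster.values.T.copy()),
            {}, {})
        transposed.tallies = {k: v for k, v in transposed.raster.tally().items()
                              if k != uf.NODATA}
        assert transposed.tallies == fused.tallies

    def test_misaligned_strict_names_pair(self, cfg):
        base = uf.CategoricalRaster(uf.GridSpec(n_rows=2, n_cols=2),
                                    np.full((2, 2), 6, dtype=np.uint8))
        shifted = uf.CategoricalRaster(
            uf.GridSpec(origin_x=3.0, n_rows=2, n_cols=2),
            np.zeros((2, 2), dtype=np.uint8))
        with pytest.raises(AlignmentError, match="wetness"):
            uf.fuse(base, shifted, None, None, cfg)

    def test_matches_per_pixel_oracle(self, cfg, small_scene):
        fused = uf.fuse(small_scene.base, small_scene.wetness,
                        small_scene.heights_m, small_scene.transport_raster, cfg)
        assert (fused.raster.values == small_scene.expected.values).all()

    def test_prebinned_heights_equivalent_to_metric(self, cfg, small_scene):
        via_metric = uf.fuse(small_scene.base, small_scene.wetness,
                             small_scene.heights_m, small_scene.transport_raster, cfg)
        via_binned = uf.fuse(small_scene.base, small_scene.wetness,
                             small_scene.heights_class, small_scene.transport_raster,
                             cfg)
        assert (via_metric.raster.values == via_binned.raster.values).all()

    def test_nodata_conservation(self, cfg, small_scene):
        fused = uf.fuse(small_scene.base, small_scene.wetness,
                        small_scene.heights_m, small_scene.transport_raster, cfg)
        n_in = int((small_scene.base.values == small_scene.base.nodata_code).sum())
        n_out = int((fused.raster.values == uf.NODATA).sum())
        assert n_in == n_out
        assert sum(fused.tallies.values()) + n_out == small_scene.grid.n_rows * \
            small_scene.grid.n_cols

    def test_non_sealed_dry_pixels_are_fixed_points(self, cfg, small_scene):
        mapped = uf.reclassify(small_scene.base, cfg.base_mapping)
        fused = uf.fuse(small_scene.base, small_scene.wetness,
                        small_scene.heights_m, small_scene.transport_raster, cfg)
        wet = np.isin(small_scene.wetness.values, list(cfg.wet_trigger_codes))
        untouched = (mapped.values != cfg.registry.sealed_id) & ~wet \
            & (mapped.values != uf.NODATA)
        assert (fused.raster.values[untouched] == mapped.values[untouched]).all()

    def test_idempotent_on_own_output(self, cfg, small_scene):
        fused = uf.fuse(small_scene.base, small_scene.wetness,
                        small_scene.heights_m, small_scene.transport_raster, cfg)
        identity = uf.CodeMapping("identity",
                                  {e.class_id: e.class_id
                                   for e in cfg.registry.entries})
        cfg2 = uf.FusionConfig(registry=cfg.registry, base_mapping=identity)
        again = uf.fuse(fused.raster, None, None, None, cfg2)
        assert (again.raster.values == fused.raster.values).all()
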