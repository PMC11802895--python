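import numpy as np
import pandas as pd
import pytest

import dendromito as dm
from dendromito.model import IntegrityError, SchemaError, ValidationError


class TestCalibration:
    @pytest.mark.parametrize(
        "px,expected", [(500, 1.0), (0, 0.0), (1000, 2.0)]
    )
    def test_length_conversion_at_2nm(self, px, expected):
        assert dm.px_to_um(px) == pytest.approx(expected)

    def test_area_conversion_at_2nm(self):
        # 250,000 px^2 * (2 nm / 1000)^2 = 1.0 um^2
        assert dm.px2_to_um2(250_000) == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm.px_to_um(-1)
        with pytest.raises(ValueError):
            dm.px2_to_um2(-5)

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            dm.PixelCalibration(pixel_size_nm=0)


class TestObjectTableIO:
    def test_round_trip_preserves_every_field(self, small_ds, tmp_path):
        f = tmp_path / "objects.csv"
        dm.write_objects(small_ds, f)
        loaded = dm.load_objects(f)
        assert len(loaded.objects) == len(small_ds.objects)
        ref = small_ds.sorted_copy()
        for col in ("area_um2", "feret_um", "aspect_ratio", "nn_dist_um"):
            np.testing.assert_array_equal(
                loaded.objects[col].to_numpy(), ref.objects[col].to_numpy()
            )
        for a, b in zip(loaded.objects["vertices"], ref.objects["vertices"]):
            np.testing.assert_allclose(np.asarray(a), np.asarray(b), rtol=0, atol=0)

    def test_write_load_write_is_byte_stable(self, small_ds, tmp_path):
        f1 = tmp_path / "a.csv"
        f2 = tmp_path / "b.csv"
        dm.write_objects(small_ds, f1)
        dm.write_objects(dm.load_objects(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_three_object_csv_identity(self, tmp_path):
        ds = dm.generate_morphology(
            dm.mito_config(seed=0, n_animals=1, n_sections_per_animal=1, n_tiles_per_section=1)
        )
        f = tmp_path / "objects.csv"
        dm.write_objects(ds, f)
        loaded = dm.load_objects(f)
        assert len(loaded.objects) == len(ds.objects)
        assert loaded.tiles["tile_id"].nunique() == len(ds.tiles)

    def test_missing_column_names_the_column(self, small_ds, tmp_path):
        f = tmp_path / "objects.csv"
        dm.write_objects(small_ds, f)
        df = pd.read_csv(f).drop(columns=["object_class"])
        g = tmp_path / "broken.csv"
        df.to_csv(g, index=False)
        with pytest.raises(SchemaError, match="object_class"):
            dm.load_objects(g)

    def test_unknown_layer_value_rejected(self, small_ds, tmp_path):
        f = tmp_path / "objects.csv"
        dm.write_objects(small_ds, f)
        df = pd.read_csv(f)
        df.loc[0, "layer"] = "CA1"
        g = tmp_path / "broken.csv"
        df.to_csv(g, index=False)
        with pytest.raises(IntegrityError, match="CA1"):
            dm.load_objects(g)

    def test_degenerate_polygon_lists_object_id(self, small_ds, tmp_path):
        f = tmp_path / "objects.csv"
        dm.write_objects(small_ds, f)
        df = pd.read_csv(f)
        df.loc[0, "vertices_json"] = "[[0.0,0.0],[1.0,1.0]]"
        bad_id = df.loc[0, "object_id"]
        g = tmp_path / "broken.csv"
        df.to_csv(g, index=False)
        with pytest.raises(ValidationError, match=bad_id):
            dm.load_objects(g)

    def test_unknown_schema_rejected(self, tmp_path):
        with pytest.raises(SchemaError):
            dm.load_objects(tmp_path / "x.csv", schema="mask_stack")


class TestDatasetInvariants:
    def test_tile_area_consistency_enforced(self, small_ds):
        tiles = small_ds.tiles.copy()
        tiles.loc[0, "area_um2"] = 99.0
        with pytest.raises(IntegrityError, match="area_um2"):
            dm.HierarchicalDataset(small_ds.animals, small_ds.sections, tiles, small_ds.objects)

    def test_dangling_tile_reference_rejected(self, small_ds):
        obj = small_ds.objects.copy()
        obj.loc[0, "tile_id"] = "nonexistent"
        with pytest.raises(IntegrityError):
            dm.HierarchicalDataset(small_ds.animals, small_ds.sections, small_ds.tiles, obj)

    def test_row_permutation_changes_no_statistic(self, small_ds):
        shuffled = dm.HierarchicalDataset(
            animals=small_ds.animals.sample(frac=1, random_state=9, ignore_index=True),
            sections=small_ds.sections.sample(frac=1, random_state=9, ignore_index=True),
            tiles=small_ds.tiles.sample(frac=1, random_state=9, ignore_index=True),
            objects=small_ds.objects.sample(frac=1, random_state=9, ignore_index=True),
        )
        t1 = dm.summary_table(small_ds)
        t2 = dm.summary_table(shuffled)
        pd.testing.assert_frame_equal(t1, t2)
        cfg = dm.BootstrapConfig(n_iterations=50, level_sizes=(2, 2, 4, 10), seed=3)
        r1 = dm.bootstrap_distribution(small_ds, ("CTL", "SLM"), "area", cfg)
        r2 = dm.bootstrap_distribution(shuffled, ("CTL", "SLM"), "area", cfg)
        np.testing.assert_array_equal(r1.medians, r2.medians)


class TestSummaryTable:
    def test_median_and_counts_small_group(self):
        from conftest import make_flat_dataset

        ds = make_flat_dataset({(0, 0, 0): [1.0, 2.0, 3.0]})
        ds.objects["feret_um"] = 1.0
        ds.objects["aspect_ratio"] = 1.0
        tab = dm.summary_table(ds)
        row = tab[(tab.genotype == "CTL") & (tab.layer == "SLM")].iloc[0]
        assert row["area_um2_median"] == 2.0
        assert row["n_objects"] == 3
        assert row["n_tiles"] == 1
        assert row["n_mice"] == 1

    def test_single_object_group_std_zero(self):
        from conftest import make_flat_dataset

        ds = make_flat_dataset({(0, 0, 0): [1.7]})
        ds.objects["feret_um"] = 1.0
        ds.objects["aspect_ratio"] = 1.0
        tab = dm.summary_table(ds)
        row = tab[(tab.genotype == "CTL") & (tab.layer == "SLM")].iloc[0]
        assert row["area_um2_median"] == 1.7
        assert row["area_um2_std"] == 0.0

    def test_empty_groups_emitted_with_zero_n(self):
        from conftest import make_flat_dataset

        ds = make_flat_dataset({(0, 0, 0): [1.0]})
        ds.objects["feret_um"] = 1.0
        ds.objects["aspect_ratio"] = 1.0
        tab = dm.summary_table(ds)
        assert len(tab) == 6  # all genotype x layer rows present
        empty = tab[(tab.genotype == "cKO") & (tab.layer == "SO")].iloc[0]
        assert empty["n_objects"] == 0
        assert np.isnan(empty["area_um2_median"])

    def test_generated_medians_near_configured_targets(self, paper_scale_ds):
        # sample medians track the generator's configured targets
        # (e.g. CTL SLM area 0.153 um^2) up to animal random effects
        tab = dm.summary_table(paper_scale_ds)
        cfg = dm.mito_config()
        for _, row in tab.iterrows():
            target = cfg.groups[(row.genotype, row.layer)].median_area_um2
            assert row["area_um2_median"] == pytest.approx(target, rel=0.25)
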