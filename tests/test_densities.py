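import numpy as np
import pandas as pd
import pytest

from voxatlas import ontology as ont
from voxatlas.densities import (
    DensityAtlas,
    NisslVolume,
    ScalingConfig,
    aggregate_types,
    estimate_densities,
    global_scale,
    nissl_granularity,
    nissl_scale,
    project_to_volume,
    qc_filter,
    transplant,
)
from voxatlas.errors import ScalingError
from voxatlas.ontology import AnnotationVolume

from .conftest import build_hierarchy


class TestQcFilter:
    def test_zero_coordinate_cell_dropped(self):
        cells = pd.DataFrame(
            {"x_um": [0.0, 5.0], "y_um": [0.0, 5.0], "z_um": [3.0, 5.0], "qc_pass": [True, True]}
        )
        assert len(qc_filter(cells)) == 1

    def test_all_pass_table_unchanged(self):
        cells = pd.DataFrame(
            {"x_um": [1.0, 2.0], "y_um": [1.0, 2.0], "z_um": [1.0, 2.0], "qc_pass": [True, True]}
        )
        assert len(qc_filter(cells)) == 2

    def test_mixed_failures_counted(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(
            {
                "x_um": rng.uniform(1, 9, 10),
                "y_um": rng.uniform(1, 9, 10),
                "z_um": rng.uniform(1, 9, 10),
                "qc_pass": [True] * 10,
            }
        )
        cells.loc[0, "qc_pass"] = False
        cells.loc[1, "x_um"] = 0.0
        cells.loc[2, "x_um"] = 99.0  # outside bounds
        out = qc_filter(cells, bounds_um=(10, 10, 10))
        assert len(out) == 7


class TestEstimateDensities:
    def test_forced_arithmetic(self):
        """40 + 60 cells over 0.02 + 0.03 mm^3 -> 2000 cells/mm^3."""
        cells = pd.DataFrame(
            {"region_id": [1] * 100, "t_type": ["T"] * 100, "slice_id": [0] * 40 + [1] * 60}
        )
        vols = pd.DataFrame(
            {"region_id": [1, 1], "slice_id": [0, 1], "voxel_count": [2, 3],
             "volume_mm3": [0.02, 0.03]}
        )
        atlas = estimate_densities(cells, vols)
        assert atlas.densities.loc[1, "T"] == pytest.approx(2000.0)

    def test_sampled_region_without_cells_is_zero_not_na(self):
        cells = pd.DataFrame({"region_id": [1], "t_type": ["T"], "slice_id": [0]})
        vols = pd.DataFrame(
            {"region_id": [1, 2], "slice_id": [0, 0], "voxel_count": [1, 1],
             "volume_mm3": [0.01, 0.01]}
        )
        atlas = estimate_densities(cells, vols, all_regions=[1, 2])
        assert atlas.densities.loc[2, "T"] == 0.0

    def test_unsampled_region_is_na(self):
        cells = pd.DataFrame({"region_id": [1], "t_type": ["T"], "slice_id": [0]})
        vols = pd.DataFrame(
            {"region_id": [1], "slice_id": [0], "voxel_count": [1], "volume_mm3": [0.01]}
        )
        atlas = estimate_densities(cells, vols, all_regions=[1, 3])
        assert np.isnan(atlas.densities.loc[3, "T"])

    def test_recovers_generating_rates_on_synthetic_brain(self, truth_brain, cells_and_slices):
        cells, geoms = cells_and_slices
        cells = qc_filter(cells)
        vols = ont.region_volumes_per_slice(truth_brain.annotation, geoms)
        atlas = estimate_densities(
            cells,
            vols,
            all_regions=truth_brain.hierarchy.leaves,
            all_types=list(truth_brain.taxonomy.index),
        )
        sampled = vols.groupby("region_id")["volume_mm3"].sum()
        truth = truth_brain.densities
        inside = 0
        total = 0
        for rid in truth.index:
            v = sampled.get(rid, 0.0)
            if v <= 0:
                continue
            for tt in truth.columns:
                lam = truth.loc[rid, tt]
                if lam == 0:
                    continue
                se = np.sqrt(lam / v)  # Poisson standard error of the rate
                total += 1
                if abs(atlas.densities.loc[rid, tt] - lam) <= 3 * se:
                    inside += 1
        assert total > 50
        assert inside / total >= 0.95


@pytest.fixture
def truth_atlas(truth_brain):
    return truth_brain.truth_atlas()


def group_neuron_totals(atlas, truth_brain, cfg):
    counts = atlas.cell_counts()
    tax = truth_brain.taxonomy
    neuron = tax[tax["class"].isin(cfg.neuron_classes)].index
    groups = pd.Series(
        {r: truth_brain.hierarchy.group_of(r, cfg.group_acronyms) for r in counts.index}
    )
    return {
        g: counts.loc[groups[groups == g].index, neuron].sum().sum()
        for g in ["cerebral_cortex", "cerebellum", "rest"]
    }


class TestGlobalScale:
    def test_group_totals_hit_published_targets(self, truth_atlas, truth_brain):
        cfg = ScalingConfig()
        scaled = global_scale(truth_atlas, cfg, truth_brain.hierarchy, truth_brain.taxonomy)
        totals = group_neuron_totals(scaled, truth_brain, cfg)
        assert totals["cerebral_cortex"] == pytest.approx(12_618_420, rel=1e-9)
        assert totals["cerebellum"] == pytest.approx(41_825_100, rel=1e-9)
        assert totals["rest"] == pytest.approx(16_446_480, rel=1e-9)
        assert sum(totals.values()) == pytest.approx(70_890_000, rel=1e-9)
        assert scaled.cell_counts().sum().sum() == pytest.approx(108_690_000, rel=1e-9)

    def test_group_already_at_target_unchanged(self, truth_atlas, truth_brain):
        cfg = ScalingConfig()
        once = global_scale(truth_atlas, cfg, truth_brain.hierarchy, truth_brain.taxonomy)
        twice = global_scale(once, cfg, truth_brain.hierarchy, truth_brain.taxonomy)
        pd.testing.assert_frame_equal(once.densities, twice.densities)

    def test_within_group_ratios_preserved(self, truth_atlas, truth_brain):
        cfg = ScalingConfig()
        scaled = global_scale(truth_atlas, cfg, truth_brain.hierarchy, truth_brain.taxonomy)
        ctx = [r for r in truth_atlas.densities.index
               if truth_brain.hierarchy.group_of(r, cfg.group_acronyms) == "cerebral_cortex"]
        before = truth_atlas.densities.loc[ctx, "CTX_Exc_1"]
        after = scaled.densities.loc[ctx, "CTX_Exc_1"]
        ratio = (after / before).dropna()
        assert ratio.nunique() <= 1 or np.allclose(ratio, ratio.iloc[0])

    def test_cerebellar_inhibitory_held_constant(self, truth_atlas, truth_brain):
        cfg = ScalingConfig()
        scaled = global_scale(truth_atlas, cfg, truth_brain.hierarchy, truth_brain.taxonomy)
        cb = [r for r in truth_atlas.densities.index
              if truth_brain.hierarchy.group_of(r, cfg.group_acronyms) == "cerebellum"]
        inhib = truth_brain.taxonomy[truth_brain.taxonomy["class"].isin(["GABA", "Mod"])].index
        pd.testing.assert_frame_equal(
            scaled.densities.loc[cb, inhib], truth_atlas.densities.loc[cb, inhib]
        )

    def test_target_below_fixed_mass_errors(self, truth_atlas, truth_brain):
        cfg = ScalingConfig(group_targets={"cerebral_cortex": 1.0,
                                           "cerebellum": 41_825_100,
                                           "rest": 16_446_480})
        huge = transplant(
            truth_atlas,
            [{"region": truth_atlas.densities.index[0], "type": "CTX_Exc_1", "density": 1e9}],
        )
        with pytest.raises(ScalingError):
            global_scale(huge, cfg, truth_brain.hierarchy, truth_brain.taxonomy)


class TestTransplant:
    def test_transplanted_entries_survive_scaling_bitwise(self, truth_atlas, truth_brain):
        rid = truth_atlas.densities.index[0]
        planted = transplant(truth_atlas, [{"region": rid, "type": "CTX_Exc_1", "density": 1234.5}])
        scaled = global_scale(planted, ScalingConfig(), truth_brain.hierarchy, truth_brain.taxonomy)
        assert scaled.densities.loc[rid, "CTX_Exc_1"] == 1234.5
        assert scaled.fixed.loc[rid, "CTX_Exc_1"]

    def test_empty_entry_list_is_identity(self, truth_atlas):
        out = transplant(truth_atlas, [])
        pd.testing.assert_frame_equal(out.densities, truth_atlas.densities)

    def test_unknown_region_listed_in_error(self, truth_atlas):
        with pytest.raises(ScalingError, match="99999"):
            transplant(truth_atlas, [{"region": 99999, "type": "CTX_Exc_1", "density": 1.0}])


class TestNisslScale:
    def test_max_intensity_region_anchored_at_four_million(self, truth_brain, truth_atlas):
        scaled = nissl_scale(
            truth_atlas, truth_brain.nissl, truth_brain.annotation,
            anchor="max", anchor_density=4_000_000.0,
        )
        means = truth_brain.nissl.region_means(truth_brain.annotation)
        top = means.idxmax()
        assert scaled.densities.loc[top].sum() == pytest.approx(4_000_000.0)

    def test_totals_proportional_to_intensity(self, truth_brain, truth_atlas):
        scaled = nissl_scale(
            truth_atlas, truth_brain.nissl, truth_brain.annotation, anchor="max",
            anchor_density=4e6,
        )
        means = truth_brain.nissl.region_means(truth_brain.annotation)
        totals = scaled.densities.sum(axis=1)
        expected = 4e6 * means / means.max()
        for rid in totals.index:
            assert totals[rid] == pytest.approx(expected[rid], rel=1e-9)

    def test_within_region_type_ratios_preserved(self, truth_brain, truth_atlas):
        scaled = nissl_scale(truth_atlas, truth_brain.nissl, truth_brain.annotation)
        rid = truth_atlas.densities.index[0]
        before = truth_atlas.densities.loc[rid]
        after = scaled.densities.loc[rid]
        nz = before > 0
        ratios = (after[nz] / before[nz]).to_numpy()
        assert np.allclose(ratios, ratios[0])

    def test_min_anchor_pins_lowest_intensity_region(self, truth_brain, truth_atlas):
        means = truth_brain.nissl.region_means(truth_brain.annotation)
        low = means.idxmin()
        before_total = truth_atlas.densities.loc[low].sum()
        scaled = nissl_scale(
            truth_atlas, truth_brain.nissl, truth_brain.annotation,
            anchor="min", anchor_density=None,
        )
        assert scaled.densities.loc[low].sum() == pytest.approx(before_total)


class TestNisslGranularity:
    def test_two_voxel_hand_computation(self):
        grid = np.array([[[1, 1]]], dtype=np.int32)
        ann = AnnotationVolume(grid=grid, voxel_size_um=25.0)
        nissl = NisslVolume(grid=np.array([[[1.0, 3.0]]]), voxel_size_um=25.0)
        dens = np.array([[[10.0, 10.0]]])
        out = nissl_granularity(dens, nissl, ann)
        np.testing.assert_allclose(out, [[[5.0, 15.0]]])

    def test_uniform_intensity_leaves_volume_unchanged(self):
        grid = np.full((2, 2, 2), 7, dtype=np.int32)
        ann = AnnotationVolume(grid=grid, voxel_size_um=25.0)
        nissl = NisslVolume(grid=np.full((2, 2, 2), 2.5), voxel_size_um=25.0)
        dens = np.full((2, 2, 2), 42.0)
        np.testing.assert_allclose(nissl_granularity(dens, nissl, ann), dens)

    def test_region_means_conserved_on_synthetic_brain(self, truth_brain, truth_atlas):
        vol = project_to_volume(truth_atlas, truth_brain.annotation, "CTX_Exc_1")
        out = nissl_granularity(vol, truth_brain.nissl, truth_brain.annotation)
        ids = truth_brain.annotation.grid
        for rid in truth_atlas.densities.index[:5]:
            mask = ids == rid
            assert np.nanmean(out[mask]) == pytest.approx(np.nanmean(vol[mask]), rel=1e-9)


class TestProjectToVolume:
    def test_single_region_phantom_painted_uniformly(self):
        grid = np.zeros((3, 3, 3), dtype=np.int32)
        grid[1] = 5
        ann = AnnotationVolume(grid=grid, voxel_size_um=25.0)
        atlas = DensityAtlas(
            densities=pd.DataFrame({"T": [100.0]}, index=[5]),
            counts=pd.DataFrame({"T": [np.nan]}, index=[5]),
        )
        out = project_to_volume(atlas, ann, "T")
        assert (out[1] == 100.0).all()
        assert np.isnan(out[0]).all()  # outside brain

    def test_na_region_distinct_from_zero(self, toy_atlas):
        grid = np.array([[[10, 11, 12]]], dtype=np.int32)
        ann = AnnotationVolume(grid=grid, voxel_size_um=25.0)
        out = project_to_volume(toy_atlas, ann, "A")
        assert out[0, 0, 0] == 100.0
        assert out[0, 0, 1] == 0.0
        assert np.isnan(out[0, 0, 2])

    def test_voxel_sum_matches_count_bookkeeping(self, truth_brain):
        atlas = truth_brain.truth_atlas()
        vol = project_to_volume(atlas, truth_brain.annotation, "Microglia_Glia")
        total_from_voxels = np.nansum(vol) * truth_brain.annotation.voxel_volume_mm3
        total_from_counts = atlas.cell_counts()["Microglia_Glia"].sum()
        assert total_from_voxels == pytest.approx(total_from_counts, rel=1e-9)

    def test_missing_annotation_id_warns_nan(self, toy_atlas):
        grid = np.array([[[10, 77]]], dtype=np.int32)
        ann = AnnotationVolume(grid=grid, voxel_size_um=25.0)
        with pytest.warns(UserWarning, match="missing"):
            out = project_to_volume(toy_atlas, ann, "A")
        assert np.isnan(out[0, 0, 1])


class TestAggregateTypes:
    def test_two_clusters_sum_within_subclass(self):
        atlas = DensityAtlas(
            densities=pd.DataFrame({"c1": [10.0], "c2": [20.0]}, index=[1]),
            counts=pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=[1]),
        )
        tax = pd.DataFrame({"subclass": ["S", "S"]}, index=["c1", "c2"])
        out = aggregate_types(atlas, tax, "subclass")
        assert out.densities.loc[1, "S"] == 30.0

    def test_totals_invariant_across_levels(self, truth_brain):
        atlas = truth_brain.truth_atlas()
        tax = truth_brain.taxonomy
        by_class = aggregate_types(atlas, tax, "class")
        by_subclass = aggregate_types(atlas, tax, "subclass")
        np.testing.assert_allclose(
            by_class.densities.sum(axis=1), by_subclass.densities.sum(axis=1)
        )
        np.testing.assert_allclose(
            by_class.densities.sum(axis=1), atlas.densities.sum(axis=1)
        )

    def test_na_only_when_all_members_na(self):
        atlas = DensityAtlas(
            densities=pd.DataFrame(
                {"c1": [np.nan, np.nan], "c2": [5.0, np.nan]}, index=[1, 2]
            ),
            counts=pd.DataFrame({"c1": [np.nan, np.nan], "c2": [1.0, np.nan]}, index=[1, 2]),
        )
        tax = pd.DataFrame({"class": ["K", "K"]}, index=["c1", "c2"])
        out = aggregate_types(atlas, tax, "class")
        assert out.densities.loc[1, "K"] == 5.0
        assert np.isnan(out.densities.loc[2, "K"])
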