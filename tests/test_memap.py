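import numpy as np
import pandas as pd
import pytest

from voxatlas.densities import DensityAtlas
from voxatlas.errors import MappingError
from voxatlas.memap import (
    GeneSelectionParams,
    align_t_types,
    extrapolate_knn,
    me_densities,
    mrna_validate,
    p_m_given_t,
    p_me_given_t,
    select_genes_zero_inflation,
    select_me_predictive_genes,
)


class TestZeroInflationGeneSelection:
    def test_defaults_match_published_curve_parameters(self):
        p = GeneSelectionParams()
        assert (p.yoffset, p.xoffset, p.decay) == (0.04, 6.2, 1.2)
        assert (p.n_genes, p.k_neighbors) == (100, 10)

    def test_ubiquitous_gene_not_selected(self):
        counts = pd.DataFrame({"g": np.full(50, 500.0)})
        assert select_genes_zero_inflation(counts) == []

    def test_toy_matrix_matches_direct_inequality(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {
                "hi_dropout_hi_expr": [0, 0, 0, 800, 900, 0, 1000, 0, 0, 0],
                "always_on": rng.integers(50, 200, 10).astype(float),
                "low_expr_some_zero": [0, 1, 2, 1, 0, 2, 1, 1, 0, 1],
                "silent": np.zeros(10),
                "half_zero_mid": [0, 0, 0, 0, 0, 60, 70, 80, 90, 50],
            }
        )
        p = GeneSelectionParams()
        got = select_genes_zero_inflation(counts, p)
        for g in counts.columns:
            col = counts[g].to_numpy(float)
            nz = col > 0
            if not nz.any():
                assert g not in got
                continue
            zf = 1 - nz.mean()
            mu = np.log2(col[nz] + 1).mean()
            expect = zf > np.exp(-p.decay * (mu - p.xoffset)) + p.yoffset
            assert (g in got) == expect

    def test_silent_gene_warns(self):
        with pytest.warns(UserWarning, match="zero cells"):
            select_genes_zero_inflation(pd.DataFrame({"g": [0.0, 0.0]}))


class TestAlignTTypes:
    def test_query_equal_to_reference_profile_assigned_exactly(self):
        ref = pd.DataFrame(
            [[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]],
            index=["T1", "T2", "T3"], columns=["g1", "g2", "g3"],
        )
        cells = ref.loc[["T2"]].rename(index={"T2": "cell0"})
        assigned, _ = align_t_types(ref, cells)
        assert assigned["cell0"] == "T2"

    def test_low_support_native_labels_excluded_from_contingency(self):
        ref = pd.DataFrame(
            [[10.0, 0], [0, 10.0]], index=["T1", "T2"], columns=["g1", "g2"]
        )
        cells = pd.DataFrame(
            [[9.0, 0], [11.0, 0], [10.0, 1], [0, 10.0], [0, 9.0]],
            index=[f"c{i}" for i in range(5)], columns=["g1", "g2"],
        )
        native = pd.Series(["A", "A", "A", "B", "B"], index=cells.index)
        _, cont = align_t_types(ref, cells, native_labels=native, min_support=3)
        assert "A" in cont.index
        assert "B" not in cont.index  # only 2 supporting cells

    def test_simulation_assignment_accuracy(self, patchseq_small):
        ps = patchseq_small
        assigned, _ = align_t_types(ps.ref_expression, ps.expression)
        assert (assigned == ps.cells["t_type"]).mean() >= 0.95

    def test_empty_gene_intersection_errors(self):
        ref = pd.DataFrame([[1.0]], index=["T"], columns=["g1"])
        cells = pd.DataFrame([[1.0]], index=["c"], columns=["g2"])
        with pytest.raises(MappingError):
            align_t_types(ref, cells)


class TestProbabilityMaps:
    def test_p_m_given_t_counting(self):
        cells = pd.DataFrame(
            {"t_type": ["T"] * 4, "m_type": ["m1", "m1", "m1", "m2"]}
        )
        pm = p_m_given_t(cells)
        assert pm.loc["T", "m1"] == pytest.approx(0.75)
        assert pm.loc["T", "m2"] == pytest.approx(0.25)

    def test_pure_ttype_gives_indicator_row(self):
        pm = p_m_given_t(pd.DataFrame({"t_type": ["T"] * 3, "m_type": ["m"] * 3}))
        assert pm.loc["T", "m"] == 1.0

    def test_outer_product_example(self):
        pm = pd.DataFrame([[1.0, 0.0]], index=["T"], columns=["m1", "m2"])
        pe = pd.DataFrame([[0.5, 0.5]], index=["T"], columns=["e1", "e2"])
        pme = p_me_given_t(pm, pe)
        np.testing.assert_allclose(pme.loc["T"], [0.5, 0.5, 0.0, 0.0])
        assert list(pme.columns) == ["m1|e1", "m1|e2", "m2|e1", "m2|e2"]

    def test_two_by_two_products_by_hand(self):
        pm = pd.DataFrame([[0.3, 0.7]], index=["T"], columns=["m1", "m2"])
        pe = pd.DataFrame([[0.2, 0.8]], index=["T"], columns=["e1", "e2"])
        pme = p_me_given_t(pm, pe)
        np.testing.assert_allclose(pme.loc["T"], [0.06, 0.24, 0.14, 0.56])
        assert pme.loc["T"].sum() == pytest.approx(1.0)

    def test_unshared_ttype_excluded_with_warning(self):
        pm = pd.DataFrame([[1.0]], index=["T1"], columns=["m"])
        pe = pd.DataFrame([[1.0], [1.0]], index=["T1", "T2"], columns=["e"])
        with pytest.warns(UserWarning, match="T2"):
            pme = p_me_given_t(pm, pe)
        assert list(pme.index) == ["T1"]


class TestGeneSubspaceSelection:
    def test_planted_informative_genes_recovered(self):
        """10 me-informative genes planted among 185 noise genes and 5
        region-marker genes; the subspace keeps the informative ones and
        rejects the markers."""
        rng = np.random.default_rng(3)
        n, n_noise = 240, 185
        me = rng.integers(0, 3, n)
        region = rng.integers(0, 3, n)
        informative = np.stack([me * 2.0 + rng.normal(0, 0.2, n) for _ in range(10)], axis=1)
        markers = np.stack([region * 2.0 + rng.normal(0, 0.2, n) for _ in range(5)], axis=1)
        noise = rng.normal(size=(n, n_noise))
        X = pd.DataFrame(
            np.hstack([informative, markers, noise]),
            columns=[f"info_{i}" for i in range(10)]
            + [f"rg_{i}" for i in range(5)]
            + [f"noise_{i}" for i in range(n_noise)],
        )
        got = select_me_predictive_genes(
            X, pd.Series(me, index=X.index), pd.Series(region, index=X.index),
            GeneSelectionParams(n_genes=20, n_region_low=150), seed=0,
        )
        assert sum(g.startswith("info_") for g in got) >= 8
        assert not any(g.startswith("rg_") for g in got)

    def test_region_marker_gene_excluded(self):
        rng = np.random.default_rng(4)
        n = 200
        me = rng.integers(0, 2, n)
        region = rng.integers(0, 2, n)
        X = pd.DataFrame(
            {
                "me_gene": me * 3.0 + rng.normal(0, 0.1, n),
                "region_gene": region * 3.0 + rng.normal(0, 0.1, n),
                "noise": rng.normal(size=n),
            }
        )
        got = select_me_predictive_genes(
            X, pd.Series(me, index=X.index), pd.Series(region, index=X.index),
            GeneSelectionParams(n_genes=1, n_region_low=2), seed=0,
        )
        assert got == ["me_gene"]


class TestExtrapolateKnn:
    def test_equidistant_neighbors_average(self):
        covered = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["T1", "T2"], columns=["a", "b"]
        )
        expr = pd.DataFrame(
            {"g": [0.0, 2.0, 1.0]}, index=["T1", "T2", "U"]
        )
        full, flags = extrapolate_knn(covered, expr, k=2)
        np.testing.assert_allclose(full.loc["U"], [0.5, 0.5])
        assert flags["U"] == "extrapolated"
        assert flags["T1"] == "direct"

    def test_coincident_type_copies_neighbor_row(self):
        covered = pd.DataFrame(
            [[0.9, 0.1], [0.2, 0.8]], index=["T1", "T2"], columns=["a", "b"]
        )
        expr = pd.DataFrame({"g1": [0.0, 5.0, 0.0], "g2": [1.0, 2.0, 1.0]},
                            index=["T1", "T2", "U"])
        full, _ = extrapolate_knn(covered, expr, k=2)
        np.testing.assert_allclose(full.loc["U"], covered.loc["T1"])

    def test_extrapolated_rows_sum_to_one(self, patchseq_small):
        ps = patchseq_small
        pm = p_m_given_t(ps.cells.rename(columns={"m_archetype": "m_type"}))
        covered = pm.iloc[:-2]
        full, flags = extrapolate_knn(covered, ps.ref_expression, k=3)
        np.testing.assert_allclose(full.sum(axis=1), 1.0, rtol=1e-9)
        assert (flags == "extrapolated").sum() == 2

    def test_fewer_covered_than_k_warns(self):
        covered = pd.DataFrame([[1.0]], index=["T1"], columns=["a"])
        expr = pd.DataFrame({"g": [0.0, 1.0]}, index=["T1", "U"])
        with pytest.warns(UserWarning, match="using all"):
            full, _ = extrapolate_knn(covered, expr, k=10)
        np.testing.assert_allclose(full.loc["U"], [1.0])


class TestCrossValidation:
    def test_cv_scores_tiny_for_smooth_probability_field(self):
        """When probability rows vary smoothly with expression, held-out
        rows are predicted by their neighbors with small error."""
        rng = np.random.default_rng(0)
        n = 30
        x = np.sort(rng.uniform(0, 1, n))
        p = np.column_stack([x, 1 - x])  # rows vary smoothly along x
        covered = pd.DataFrame(p, index=[f"T{i}" for i in range(n)], columns=["a", "b"])
        expr = pd.DataFrame({"g": x * 10}, index=covered.index)
        from voxatlas.memap import cross_validate_extrapolation

        scores = cross_validate_extrapolation(covered, expr, k_values=(2, 5), seed=0)
        assert set(scores.columns) == {"mse", "mae"}
        assert (scores["mse"] < 0.02).all()
        assert scores.loc[2, "mse"] <= scores.loc[5, "mse"]  # tighter neighborhood wins here


class TestMeDensities:
    def test_single_ttype_linearity(self):
        atlas = DensityAtlas(
            densities=pd.DataFrame({"T": [100.0]}, index=[1]),
            counts=pd.DataFrame({"T": [10.0]}, index=[1]),
        )
        pmap = pd.DataFrame([[0.3, 0.7]], index=["T"], columns=["me1", "me2"])
        out = me_densities(pmap, atlas)
        np.testing.assert_allclose(out.densities.loc[1], [30.0, 70.0])

    def test_regional_totals_conserved(self, truth_brain, patchseq_small):
        ps = patchseq_small
        atlas = truth_brain.truth_atlas()
        neuronal = list(ps.p_m_given_t.index)
        sub = DensityAtlas(
            densities=atlas.densities[neuronal],
            counts=atlas.counts[neuronal],
            region_volumes=atlas.region_volumes,
        )
        pme = p_me_given_t(ps.p_m_given_t, ps.p_e_given_t)
        out = me_densities(pme, sub)
        np.testing.assert_allclose(
            out.densities.sum(axis=1), sub.densities.sum(axis=1), rtol=1e-9
        )

    def test_three_region_matrix_product_by_hand(self):
        D = pd.DataFrame(
            [[10.0, 0.0, 5.0, 1.0], [0.0, 2.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]],
            index=[1, 2, 3], columns=["T1", "T2", "T3", "T4"],
        )
        P = pd.DataFrame(
            [[1.0, 0.0], [0.5, 0.5], [0.0, 1.0], [0.25, 0.75]],
            index=["T1", "T2", "T3", "T4"], columns=["x", "y"],
        )
        atlas = DensityAtlas(densities=D, counts=D.copy())
        out = me_densities(P, atlas)
        np.testing.assert_allclose(out.densities.to_numpy(), D.to_numpy() @ P.to_numpy())

    def test_na_region_propagates(self):
        D = pd.DataFrame([[np.nan], [3.0]], index=[1, 2], columns=["T"])
        atlas = DensityAtlas(densities=D, counts=D.copy())
        P = pd.DataFrame([[1.0]], index=["T"], columns=["me"])
        out = me_densities(P, atlas)
        assert np.isnan(out.densities.loc[1, "me"])

    def test_missing_probability_row_errors(self):
        atlas = DensityAtlas(
            densities=pd.DataFrame({"T": [1.0]}, index=[1]),
            counts=pd.DataFrame({"T": [1.0]}, index=[1]),
        )
        with pytest.raises(MappingError, match="T"):
            me_densities(pd.DataFrame([[1.0]], index=["other"], columns=["me"]), atlas)


class TestMrnaValidation:
    def test_published_correction_factor(self):
        D = pd.DataFrame([[1.0]], index=[1], columns=["T"])
        E = pd.DataFrame([[1.0]], index=["T"], columns=["g"])
        P = pd.DataFrame([[1.0]], index=["T"], columns=["me"])
        out = mrna_validate(D, P, E, n_me=458, n_t=4804)
        assert out.correction == pytest.approx((458 / 4804) ** 2)
        assert out.correction == pytest.approx(0.009, abs=5e-4)

    def test_identity_map_is_exact_fixed_point(self):
        rng = np.random.default_rng(0)
        D = pd.DataFrame(rng.uniform(0, 10, (3, 4)), index=[1, 2, 3],
                         columns=["T1", "T2", "T3", "T4"])
        E = pd.DataFrame(rng.uniform(0, 5, (4, 6)), index=["T1", "T2", "T3", "T4"])
        P = pd.DataFrame(np.eye(4), index=["T1", "T2", "T3", "T4"],
                         columns=["T1", "T2", "T3", "T4"])
        out = mrna_validate(D, P, E)
        assert out.correction == 1.0
        np.testing.assert_allclose(out.mrna_me.to_numpy(), out.mrna_t.to_numpy())
        assert np.nanmax(out.relative_error.to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_two_region_toy_matrices_by_hand(self):
        D = pd.DataFrame([[2.0, 1.0, 0.0], [0.0, 3.0, 1.0]], index=["r1", "r2"],
                         columns=["T1", "T2", "T3"])
        E = pd.DataFrame([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]],
                         index=["T1", "T2", "T3"], columns=["gA", "gB"])
        P = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]],
                         index=["T1", "T2", "T3"], columns=["me1", "me2"])
        out = mrna_validate(D, P, E)
        corr = (2 / 3) ** 2
        expect_me = (D.to_numpy() @ P.to_numpy()) @ (P.to_numpy().T @ E.to_numpy()) * corr
        np.testing.assert_allclose(out.mrna_me.to_numpy(), expect_me)
        np.testing.assert_allclose(out.mrna_t.to_numpy(), D.to_numpy() @ E.to_numpy())
        assert np.isnan(out.relative_error.to_numpy()[out.mrna_t.to_numpy() == 0]).all()
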