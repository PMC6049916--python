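import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from blendr.cohort_stats import (
    CovariateTable,
    bh_adjust,
    build_design,
    cohens_d,
    fit_linear,
    index_covariate_scan,
    meta_fixed,
    meta_scan,
    pc_association,
    welch_t,
)
from blendr.core import ExpressionMatrix, compute_indices
from blendr.errors import InputError, SchemaError, ValidationError
from blendr.simulate import make_synthetic_db, simulate_cohort
from oracles import ols_normal_equations, stepup_bh


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"Intercept": np.ones(10), "x": x})
        res = fit_linear(2 * x, X)
        assert res.params.loc["x", "beta"] == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_on_balanced_design(self):
        rng = np.random.default_rng(0)
        a = np.repeat([0.0, 1.0], 4)
        b = np.tile([0.0, 1.0], 4)
        X = pd.DataFrame({"Intercept": np.ones(8), "a": a, "b": b})
        y = 1.5 + 2.0 * a - 0.7 * b + rng.normal(0, 0.1, 8)
        res = fit_linear(y, X)
        expected = ols_normal_equations(X.to_numpy(), y)
        np.testing.assert_allclose(res.params["beta"].to_numpy(), expected, atol=1e-10)
        assert res.df_resid == 8 - 3

    def test_duplicated_column_is_rank_error(self):
        X = pd.DataFrame({"Intercept": np.ones(6), "x": np.arange(6.0), "x2": np.arange(6.0)})
        with pytest.raises(ValidationError, match="collinear"):
            fit_linear(np.arange(6.0), X)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"Intercept": np.ones(2), "x": [0.0, 1.0]})
        with pytest.raises(InputError):
            fit_linear([1.0, 2.0], X)


class TestBuildDesign:
    def test_treatment_coding_against_reference(self):
        covars = CovariateTable(
            pd.DataFrame({"diagnosis": ["CTRL", "MDD", "BP"], "age": [40.0, 50.0, 60.0]})
        )
        X = build_design(covars, ["diagnosis", "age"])
        assert "diagnosis[CTRL]" not in X.columns
        assert set(X.columns) == {"Intercept", "diagnosis[MDD]", "diagnosis[BP]", "age"}

    def test_missing_column_listed(self):
        covars = CovariateTable(pd.DataFrame({"age": [1.0, 2.0]}))
        with pytest.raises(SchemaError, match="brain_pH"):
            build_design(covars, ["brain_pH", "age"])

    def test_listwise_deletion(self):
        covars = CovariateTable(pd.DataFrame({"age": [1.0, np.nan, 3.0]}))
        assert len(build_design(covars, ["age"])) == 2


class TestMetaFixed:
    def test_equal_variances_give_plain_mean(self):
        res = meta_fixed([1.0, 3.0], [1.0, 1.0])
        assert res["b"] == pytest.approx(2.0)
        assert res["se"] == pytest.approx(1 / np.sqrt(2), abs=1e-5)

    def test_single_study(self):
        res = meta_fixed([0.4], [0.04])
        assert res["b"] == pytest.approx(0.4)
        assert res["se"] == pytest.approx(0.2)

    def test_weight_dominance(self):
        res = meta_fixed([0.0, 2.0], [0.01, 100.0])
        w = np.array([1 / 0.01, 1 / 100.0])
        expected = (w * np.array([0.0, 2.0])).sum() / w.sum()
        assert res["b"] == pytest.approx(expected)
        assert res["b"] == pytest.approx(0.0002, rel=1e-3)

    def test_pooled_se_below_each_study(self):
        res = meta_fixed([0.1, 0.2, 0.3], [0.04, 0.09, 0.01])
        assert res["se"] < np.sqrt(0.01)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            meta_fixed([1.0], [0.0])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_definition_and_statsmodels(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, stepup_bh(list(p)), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_monotone_order_preserving_and_inflationary(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=20))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()  # order preserved
        assert (q >= p - 1e-15).all()
        # re-adjusting never shrinks a q-value
        assert (bh_adjust(q) >= q - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_equal_variance_case(self):
        res = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res["t"] == pytest.approx(-np.sqrt(3 / 2), abs=1e-5)  # -1.22474
        assert res["df"] == pytest.approx(4.0)

    def test_reduces_to_pooled_t_for_equal_n_and_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 1.0
        res = welch_t(x, y)
        # equal n, equal variance: df = n1 + n2 - 2
        assert res["df"] == pytest.approx(len(x) + len(y) - 2)

    def test_welch_satterthwaite_df_hand_computed(self):
        x = [0.0, 4.0, 8.0]  # var 16, n 3
        y = [1.0, 1.5, 2.0, 2.5, 3.0]  # var 0.625, n 5
        res = welch_t(x, y)
        sx, sy = 16.0 / 3, 0.625 / 5
        df = (sx + sy) ** 2 / (sx**2 / 2 + sy**2 / 4)
        assert res["df"] == pytest.approx(df)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(InputError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(InputError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestCohensD:
    def test_unit_difference_at_unit_sd(self):
        # both groups have sd exactly 1 and means 1 and 0 -> d = 1
        h = 1.0 / np.sqrt(2)
        x = [1.0 - h, 1.0 + h]
        y = [-h, h]
        assert cohens_d(x, y) == pytest.approx(1.0)

    def test_hand_computed_pooled_sd(self):
        # s1^2 = s2^2 = 2 -> pooled sd = sqrt(2); d = (1-5)/sqrt(2)
        assert cohens_d([0.0, 2.0], [4.0, 6.0]) == pytest.approx(-4 / np.sqrt(2))

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(InputError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestScanAndMeta:
    def test_scan_recovers_planted_effect(self, profiles10):
        coh = simulate_cohort(
            profiles10, 150, effects={"diagnosis:MDD": {"Astrocyte": -0.8}}, seed=21
        )
        table = compute_indices(coh.expr, make_synthetic_db(profiles10), min_genes=1)
        scan = index_covariate_scan(table, CovariateTable(coh.metadata), formula="eq1")
        row = scan[(scan.cell_type == "Astrocyte") & (scan.covariate == "diagnosis[MDD]")]
        assert row["beta"].iloc[0] < 0
        assert row["p"].iloc[0] < 0.01
        assert (scan["q"] >= scan["p"] - 1e-15).all()

    def test_missing_preset_column_is_error(self, profiles10):
        coh = simulate_cohort(profiles10, 30, seed=22)
        table = compute_indices(coh.expr, make_synthetic_db(profiles10), min_genes=1)
        covars = CovariateTable(coh.metadata.drop(columns=["brain_pH"]))
        with pytest.raises(SchemaError, match="brain_pH"):
            index_covariate_scan(table, covars, formula="eq1")

    def test_meta_scan_pools_across_datasets(self):
        scans = {}
        for name, beta in (("d1", 0.4), ("d2", 0.6)):
            scans[name] = pd.DataFrame(
                {
                    "cell_type": ["Astrocyte"],
                    "covariate": ["age"],
                    "beta": [beta],
                    "se": [0.1],
                }
            )
        pooled = meta_scan(scans)
        assert pooled["b"].iloc[0] == pytest.approx(0.5)
        assert pooled["se"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))
        assert pooled["n_studies"].iloc[0] == 2


class TestPcAssociation:
    def test_rank_one_matrix_loads_on_single_factor(self):
        rng = np.random.default_rng(4)
        factor = rng.normal(0, 1, 12)
        loadings = rng.normal(0, 1, 40)
        values = pd.DataFrame(
            np.outer(loadings, factor),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(12)],
        )
        matrix = ExpressionMatrix(values, pd.Series(values.index, index=values.index))
        indices = pd.DataFrame({"Astrocyte": factor - factor.mean()}, index=values.columns)
        out = pc_association(matrix, indices, n_pcs=2)
        assert out["variance_explained"].iloc[0] == pytest.approx(100.0)
        assert out["r2"].loc["PC1", "Astrocyte"] == pytest.approx(1.0)

    def test_excluding_all_db_genes_is_error(self, profiles10, db10):
        coh = simulate_cohort(profiles10, 20, seed=23)
        marker_rows = coh.expr.gene_symbols.isin(db10.genes)
        sub = ExpressionMatrix(
            coh.expr.values.loc[marker_rows.to_numpy()],
            coh.expr.gene_symbols[marker_rows],
        )
        indices = compute_indices(coh.expr, db10, min_genes=1)
        with pytest.raises(InputError):
            pc_association(sub, indices, exclude_db_genes=True, db=db10)

    def test_composition_dominates_pc1_even_without_marker_genes(self, profiles10, db10):
        coh = simulate_cohort(profiles10, 80, noise_sd=0.2, seed=24)
        indices = compute_indices(coh.expr, db10, min_genes=1)
        out = pc_association(
            coh.expr,
            indices,
            n_pcs=2,
            exclude_db_genes=True,
            db=db10,
            combinations={"astro_endo": ["Astrocyte", "Endothelial"]},
        )
        assert out["r2"].shape == (2, 11)

    def test_n_pcs_bounded(self, profiles10, db10):
        coh = simulate_cohort(profiles10, 10, seed=25)
        indices = compute_indices(coh.expr, db10, min_genes=1)
        with pytest.raises(InputError):
            pc_association(coh.expr, indices, n_pcs=50)
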