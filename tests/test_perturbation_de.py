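import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cohortscreen.datatypes import ExpressionDataset, ProbeMap
from cohortscreen.errors import DegenerateDataError, DesignError, DomainError
from cohortscreen.perturbation_de import (
    DESelectionCriteria,
    ModeratedTParams,
    bh_adjust,
    estimate_variance_prior,
    fit_two_group,
    moderated_t_test,
    run_de,
    select_de_candidates,
)


def dataset(data, n_treated):
    data = np.asarray(data, dtype=float)
    cols = [f"T{i}" for i in range(n_treated)] + \
           [f"C{i}" for i in range(data.shape[1] - n_treated)]
    ds = ExpressionDataset(
        "de", pd.DataFrame(data, index=[f"P{i}" for i in range(data.shape[0])],
                           columns=cols), "log2")
    labels = {c: ("treated" if c.startswith("T") else "control") for c in cols}
    return ds, labels


class TestFitTwoGroup:
    def test_hand_computed_pooled_variance(self):
        ds, labels = dataset([[3, 5, 1, 3]], n_treated=2)
        fit = fit_two_group(ds, labels)
        assert fit["log2_fc"].iloc[0] == 2.0
        assert fit["s_sq"].iloc[0] == 2.0
        assert fit["residual_df"].iloc[0] == 2

    def test_identical_groups_zero_fc(self):
        ds, labels = dataset([[4, 5, 4, 5]], n_treated=2)
        assert fit_two_group(ds, labels)["log2_fc"].iloc[0] == 0.0

    def test_single_control_sample_rejected(self):
        ds, labels = dataset([[1, 2, 3]], n_treated=2)
        with pytest.raises(DesignError):
            fit_two_group(ds, labels)


class TestVariancePrior:
    def test_equal_variances_give_infinite_d0(self):
        params = estimate_variance_prior(np.full(100, 0.3), residual_df=4)
        assert math.isinf(params.d0)
        # with var(log s^2) = 0, s0_sq = exp(mean(e)) = s^2 * (d/2)/exp(digamma(d/2))
        from scipy.special import digamma

        assert params.s0_sq == pytest.approx(
            0.3 * 2 / math.exp(digamma(2)), rel=1e-9)

    def test_parameter_recovery_from_scaled_inv_chisq(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, df = 4.0, 0.05, 4
        sigma_sq = d0_true * s0_true / rng.chisquare(d0_true, size=2000)
        s_sq = sigma_sq * rng.chisquare(df, size=2000) / df
        params = estimate_variance_prior(s_sq, df)
        assert 2.5 <= params.d0 <= 6.5
        assert abs(params.s0_sq - s0_true) / s0_true <= 0.30

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DegenerateDataError):
            estimate_variance_prior(np.zeros(10), 4)

    def test_small_sample_warns_but_returns(self):
        with pytest.warns(UserWarning):
            params = estimate_variance_prior([0.1, 0.2, 0.3], 4)
        assert params.s0_sq > 0

    def test_matches_limma_on_frozen_fixture(self):
        """Cross-check against Bioconductor limma's eBayes on a seeded
        fixture (oracle values computed once with lmFit/eBayes)."""
        rng = np.random.default_rng(np.random.SeedSequence([20240901]))
        sigma_sq = 4 * 0.05 / rng.chisquare(4, size=40)
        mu = rng.uniform(6, 10, size=40)
        data = mu[:, None] + np.sqrt(sigma_sq)[:, None] * \
            rng.standard_normal((40, 6))
        data[:5, :3] += 1.0
        ds, labels = dataset(data, n_treated=3)
        fit = fit_two_group(ds, labels)
        with pytest.warns(UserWarning):  # < 50 probes
            params = estimate_variance_prior(fit["s_sq"].to_numpy(), 4)
        assert params.d0 == pytest.approx(3.754924955, rel=1e-6)
        assert params.s0_sq == pytest.approx(0.04777669416, rel=1e-6)
        mod = moderated_t_test(fit, params)
        limma = {  # probe -> (t, p)
            "P0": (7.629734054, 7.23571657451e-05),
            "P1": (5.17923751, 0.000930568537006),
            "P5": (-1.043379456, 0.32820327383),
            "P19": (0.305385685, 0.768108183374),
            "P39": (-0.2350605803, 0.820249350613),
        }
        for probe, (t_ref, p_ref) in limma.items():
            assert mod.loc[probe, "t_mod"] == pytest.approx(t_ref, rel=1e-6)
            assert mod.loc[probe, "p_value"] == pytest.approx(p_ref, rel=1e-6)


class TestModeratedT:
    def test_zero_prior_equals_classical_pooled_t(self):
        rng = np.random.default_rng(1)
        data = rng.normal(8, 1, size=(50, 6))
        data[:10, :3] += 1.5
        ds, labels = dataset(data, n_treated=3)
        fit = fit_two_group(ds, labels)
        mod = moderated_t_test(fit, ModeratedTParams(d0=0.0, s0_sq=1.0))
        t_ref, p_ref = sps.ttest_ind(data[:, :3], data[:, 3:], axis=1,
                                     equal_var=True)
        assert np.allclose(mod["t_mod"].to_numpy(), t_ref, atol=1e-12)
        assert np.allclose(mod["p_value"].to_numpy(), p_ref, atol=1e-12)

    def test_hand_computed_shrunken_t(self):
        fit = pd.DataFrame({"log2_fc": [1.0], "s_sq": [0.25],
                            "residual_df": [4], "n_treated": [3],
                            "n_control": [3]}, index=["P"])
        mod = moderated_t_test(fit, ModeratedTParams(d0=4.0, s0_sq=0.25))
        # s_tilde^2 = 0.25 -> t = 1/sqrt(0.25*(2/3)) = sqrt(6)
        assert mod["t_mod"].iloc[0] == pytest.approx(math.sqrt(6), abs=1e-9)
        assert mod["df_total"].iloc[0] == 8
        assert mod["p_value"].iloc[0] == pytest.approx(
            2 * sps.t.sf(math.sqrt(6), 8), abs=1e-12)

    def test_zero_fold_change_gives_p_one(self):
        fit = pd.DataFrame({"log2_fc": [0.0], "s_sq": [0.1],
                            "residual_df": [4], "n_treated": [3],
                            "n_control": [3]}, index=["P"])
        mod = moderated_t_test(fit, ModeratedTParams(d0=2.0, s0_sq=0.1))
        assert mod["t_mod"].iloc[0] == 0.0
        assert mod["p_value"].iloc[0] == 1.0

    def test_infinite_d0_uses_normal_limit(self):
        fit = pd.DataFrame({"log2_fc": [1.0], "s_sq": [99.0],
                            "residual_df": [4], "n_treated": [3],
                            "n_control": [3]}, index=["P"])
        mod = moderated_t_test(fit, ModeratedTParams(d0=math.inf, s0_sq=0.25))
        z = 1.0 / math.sqrt(0.25 * (2 / 3))
        assert mod["p_value"].iloc[0] == pytest.approx(2 * sps.norm.sf(z), rel=1e-9)


class TestBHAdjust:
    def test_step_up_hand_example(self):
        out = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_all_ones_and_single_value(self):
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_bounds_and_monotonicity_property(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(1.0, 200 * p) + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


class TestSelection:
    @staticmethod
    def results():
        return pd.DataFrame({
            "gene_symbol": ["GA", "GA", "GB", None, "GC"],
            "log2_fc": [1.0, 0.9, -1.0, 2.0, 0.3],
            "linear_fc": [2.0, 1.87, -2.0, 4.0, 1.23],
            "s_sq": [0.1] * 5,
            "t_mod": [5.0, 4.0, -5.0, 8.0, 1.0],
            "p_value": [0.001, 0.002, 0.001, 0.0001, 0.3],
            "adj_p": [0.01, 0.01, 0.01, 0.001, 0.4],
        }, index=[f"P{i}" for i in range(5)])

    def test_two_stage_selection_and_gene_collapse(self):
        sel = select_de_candidates(self.results(), DESelectionCriteria())
        assert sel.significant == ["P0", "P1", "P2", "P3"]
        assert sel.fc_filtered == ["P0", "P1", "P2", "P3"]
        # P3 is unannotated: stays in probe list, absent from gene list;
        # P0/P1 share gene GA -> one candidate gene entry
        assert sel.candidate_genes == ["GA", "GB"]
        assert sel.n_up == 3 and sel.n_down == 1

    def test_significant_but_below_fc_cut(self):
        res = self.results()
        res.loc["P0", "linear_fc"] = 1.3
        sel = select_de_candidates(res, DESelectionCriteria())
        assert "P0" in sel.significant and "P0" not in sel.fc_filtered

    def test_linear_fc_sign_convention(self):
        ds, labels = dataset([[3, 3, 4, 4], [5, 5, 4, 4], [4, 4, 4, 4]],
                             n_treated=2)
        res = run_de(ds, labels, params=ModeratedTParams(d0=0.0, s0_sq=1.0))
        assert res["linear_fc"].tolist() == [-2.0, 2.0, 1.0]
        assert (res["linear_fc"].abs() >= 1).all()
        assert (res["adj_p"] >= res["p_value"] - 1e-15).all()


class TestPipelineProperties:
    def test_null_p_values_uniform(self):
        """Moderated-t p-values are calibrated under the null: with both
        groups from one Gaussian, about 5% fall below 0.05."""
        rng = np.random.default_rng(77)
        data = rng.normal(8.0, 0.5, size=(5000, 8))
        ds, labels = dataset(data, n_treated=4)
        res = run_de(ds, labels)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_d0_zero_pipeline_equals_plain_t_plus_bh(self):
        rng = np.random.default_rng(5)
        data = rng.normal(8, 1, size=(1000, 6))
        data[:50, :3] += 1.0
        ds, labels = dataset(data, n_treated=3)
        res = run_de(ds, labels, params=ModeratedTParams(d0=0.0, s0_sq=1.0))
        t_ref, p_ref = sps.ttest_ind(data[:, :3], data[:, 3:], axis=1,
                                     equal_var=True)
        assert np.allclose(res["t_mod"], t_ref, atol=1e-10)
        assert np.allclose(res["adj_p"], bh_adjust(p_ref), atol=1e-10)
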