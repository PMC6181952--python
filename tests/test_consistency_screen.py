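import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cohortscreen.consistency_screen import (
    ScreenCriteria,
    aggregate_screen,
    correlate_with_anchor,
    mann_whitney_u,
    spearman,
    tumor_vs_normal,
)
from cohortscreen.datatypes import ClinicalTable, ExpressionDataset, ProbeMap
from cohortscreen.errors import (
    ConfigurationError,
    DegenerateDataError,
    SampleSizeError,
)


class TestSpearman:
    def test_identity_gives_rho_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(1.0)

    def test_classical_formula_example(self):
        # sum of squared rank differences = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_exact_p_n3_enumeration(self):
        # |rho| >= 1 attained only by identity and reversal: 2 of 3! = 6
        _, p = spearman([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman(x, y)
        # independent brute-force oracle over all 720 permutations
        import itertools

        rx = sps.rankdata(x)
        count = total = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_n_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base)
        assert spearman(x, y ** 3) == pytest.approx(base)

    def test_constant_vector_and_small_n_errors(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(SampleSizeError):
            spearman([1, 2], [1, 2])

    def test_pairwise_complete_removal(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, 4.0, np.nan, 6.0]
        rho, _ = spearman(x, y)
        rho_ref, _ = spearman([1, 2, 4, 6], [2, 1, 4, 6])
        assert rho == pytest.approx(rho_ref)


class TestMannWhitney:
    def test_exact_example(self):
        u, p, shift = mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert u == 9.0
        assert p == pytest.approx(2 / 20, abs=1e-12)
        assert shift == 3.0

    def test_identical_groups_p_one(self):
        _, p, shift = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)
        assert shift == 0.0

    def test_all_tied_values_p_one(self):
        _, p, _ = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(SampleSizeError):
            mann_whitney_u([1, 2], [1, 2, 3])

    def test_exact_and_approximate_agree_at_n8(self):
        # sanity property: seeded Gaussian draws, both p-value routes close
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = rng.normal(0.5, 1, size=8)
            b = rng.normal(0.0, 1, size=8)
            p_exact = sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue
            p_approx = sps.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_approx) < 0.02
            # the package routes n=8 tie-free data to the exact branch
            _, p_pkg, _ = mann_whitney_u(a, b)
            assert p_pkg == pytest.approx(p_exact, abs=1e-12)


def _screen_world(rho=0.9, shift=-2.0, n_tumor=30, n_normal=10, n_cohorts=3,
                  seed=0):
    """Tiny hand-built world: ANCH + CAND (correlated, shifted) + NULL."""
    rng = np.random.default_rng(seed)
    cohorts = []
    for ci in range(n_cohorts):
        n = n_normal + n_tumor
        anchor = rng.normal(size=n)
        cand = rho * anchor + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        null = rng.normal(size=n)
        tumor_mask = np.r_[np.zeros(n_normal), np.ones(n_tumor)].astype(bool)
        cand = cand + shift * tumor_mask
        ids = [f"c{ci}_{i}" for i in range(n)]
        matrix = pd.DataFrame([8 + anchor, 8 + cand, 8 + null],
                              index=["ANCH", "CAND", "NULL"], columns=ids)
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": ids,
            "tissue_class": ["normal"] * n_normal + ["primary_tumor"] * n_tumor,
        }))
        cohorts.append(ExpressionDataset(f"d{ci}", matrix, "log2", samples=clin))
    return cohorts, ProbeMap.identity(["ANCH", "CAND", "NULL"])


class TestCorrelateWithAnchor:
    def test_passes_and_boundary_inclusive(self):
        crit = ScreenCriteria()
        rec = pd.DataFrame()  # appease linters
        cohorts, pmap = _screen_world()
        rec = correlate_with_anchor(cohorts, pmap, "ANCH", ["CAND", "NULL"], crit)
        cand = rec[rec["gene"] == "CAND"]
        assert len(cand) == 3 and cand["passes"].all()
        # boundary: rho exactly rho_min and p exactly p_max still passes
        row = {"rho": 0.2, "p_value": 0.05}
        assert (row["rho"] >= crit.rho_min) and (row["p_value"] <= crit.p_max)

    def test_negative_rho_fails_when_positive_required(self):
        cohorts, pmap = _screen_world(rho=-0.9)
        rec = correlate_with_anchor(cohorts, pmap, "ANCH", ["CAND"],
                                    ScreenCriteria())
        assert not rec["passes"].any()
        rec2 = correlate_with_anchor(cohorts, pmap, "ANCH", ["CAND"],
                                     ScreenCriteria(require_positive_rho=False))
        assert rec2["passes"].all()

    def test_tumor_only_restriction(self):
        cohorts, pmap = _screen_world()
        rec = correlate_with_anchor(cohorts, pmap, "ANCH", ["CAND"],
                                    ScreenCriteria())
        assert (rec["n_samples"] == 30).all()

    def test_anchor_absent_everywhere_errors(self):
        cohorts, pmap = _screen_world()
        with pytest.raises(ConfigurationError):
            correlate_with_anchor(cohorts, pmap, "NOPE", ["CAND"],
                                  ScreenCriteria())

    def test_missing_gene_shrinks_denominator(self):
        cohorts, pmap = _screen_world()
        # drop CAND from the first cohort's matrix
        cohorts[0] = cohorts[0].with_matrix(cohorts[0].matrix.drop(index="CAND"))
        rec = correlate_with_anchor(cohorts, pmap, "ANCH", ["CAND"],
                                    ScreenCriteria())
        assert len(rec) == 2


class TestTumorVsNormal:
    def test_down_shift_passes_down_criterion(self):
        cohorts, pmap = _screen_world()
        rec = tumor_vs_normal(cohorts, pmap, ["CAND", "NULL"], ScreenCriteria())
        cand = rec[rec["gene"] == "CAND"]
        assert cand["passes"].all()
        assert (cand["direction"] == "down").all()
        assert (cand["median_shift"] < 0).all()

    def test_direction_mismatch_fails(self):
        cohorts, pmap = _screen_world(shift=2.0)
        rec = tumor_vs_normal(cohorts, pmap, ["CAND"],
                              ScreenCriteria(alteration_direction="down"))
        assert not rec["passes"].any()
        rec_up = tumor_vs_normal(cohorts, pmap, ["CAND"],
                                 ScreenCriteria(alteration_direction="up"))
        assert rec_up["passes"].all()

    def test_cohort_without_normals_not_evaluable(self):
        cohorts, pmap = _screen_world(n_normal=2, n_cohorts=1, n_tumor=10)
        rec = tumor_vs_normal(cohorts, pmap, ["CAND"], ScreenCriteria())
        assert rec.empty


class TestAggregateScreen:
    @staticmethod
    def records(gene, outcomes, kind="corr"):
        rows = []
        for i, ok in enumerate(outcomes):
            row = {"dataset_id": f"d{i}", "gene": gene, "p_value": 0.01,
                   "passes": ok}
            if kind == "corr":
                row.update(rho=0.5, n_samples=30)
            else:
                row.update(median_shift=-1.0, direction="down" if ok else "none")
            rows.append(row)
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("corr_pass,alt_pass,expected", [
        ((True,) * 4 + (False,) * 3, (True,) * 4 + (False,) * 3, True),   # 4/7, 4/7
        ((True,) * 3 + (False,) * 4, (True,) * 7, False),                 # 3/7 fails
        ((True,) * 4 + (False,) * 2, (True, True, False), True),          # 4/6, 2/3
    ])
    def test_strict_majority_rule(self, corr_pass, alt_pass, expected):
        corr = self.records("G", corr_pass, "corr")
        alt = self.records("G", alt_pass, "alt")
        v = aggregate_screen(corr, alt, ScreenCriteria())
        assert bool(v.loc[v["gene"] == "G", "selected"].iloc[0]) is expected

    def test_invariant_to_cohort_order(self):
        corr = self.records("G", (True, False, True, True), "corr")
        alt = self.records("G", (True, True, False, True), "alt")
        v1 = aggregate_screen(corr, alt, ScreenCriteria())
        v2 = aggregate_screen(corr.iloc[::-1], alt.iloc[::-1], ScreenCriteria())
        pd.testing.assert_frame_equal(v1, v2)

    def test_mixed_directions_use_majority_under_any(self):
        alt = pd.DataFrame({
            "dataset_id": [f"d{i}" for i in range(5)],
            "gene": "G",
            "median_shift": [-1, -1, 1, 1, 1],
            "p_value": [0.01] * 5,
            "direction": ["down", "down", "up", "up", "up"],
            "passes": [True] * 5,
        })
        corr = self.records("G", (True,) * 5, "corr")
        v = aggregate_screen(corr, alt,
                             ScreenCriteria(alteration_direction="any"))
        # majority direction (up) gives 3/5 > 50% -> selected, but the
        # two 'down' cohorts must not have been pooled with the 'up' ones
        assert v["n_pass_alt"].iloc[0] == 3
        assert bool(v["selected"].iloc[0])
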