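import numpy as np
import pytest
from scipy import stats as sps

from pvs_sas.stats import (
    CohortRecord,
    chi2_yates,
    cohort_frame,
    gated_correlation,
    group_tests,
    partial_correlation,
    shapiro_wilk,
    t_from_summary,
)


class TestShapiroWilk:
    def test_w_bounded_at_minimum_n(self):
        w, p = shapiro_wilk([1.0, 2.0, 2.5])
        assert 0 < w <= 1

    def test_calibration_under_null(self):
        """Normal samples: p > 0.05 in at least 90% of 100 seeded draws."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=50)
            _, p = shapiro_wilk(x)
            hits += p > 0.05
        assert hits >= 90

    def test_power_against_exponential(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=50)
            _, p = shapiro_wilk(x)
            hits += p < 0.05
        assert hits >= 90

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            shapiro_wilk([2.0] * 10)

    @pytest.mark.parametrize("n", [2, 5001])
    def test_n_out_of_range(self, n):
        with pytest.raises(ValueError, match="3 <= n"):
            shapiro_wilk(np.arange(n, dtype=float))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            shapiro_wilk([1.0, np.nan, 2.0])


class TestGatedCorrelation:
    def test_perfect_linear(self):
        x = np.random.default_rng(0).normal(size=40)
        res = gated_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_gate_selects_pearson_for_normal_pairs(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        res = gated_correlation(x, y)
        assert res.method == "pearson"
        assert res.normality_p_x > 0.05 and res.normality_p_y > 0.05

    def test_gate_selects_spearman_for_heavy_tail(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = np.exp(rng.normal(size=100) * 2)
        res = gated_correlation(x, y)
        assert res.method == "spearman"

    def test_independent_variables_small_r(self):
        rng = np.random.default_rng(3)
        res = gated_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(res.r) < 0.1
        assert res.p > 0.01

    def test_ties_flagged(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(size=60))
        y = rng.normal(size=60)
        res = gated_correlation(x, y)
        assert res.ties_present


class TestPartialCorrelation:
    def test_reduces_to_plain_without_covariates(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        plain_r, plain_p = sps.pearsonr(x, y)
        res = partial_correlation(x, y, method="pearson")
        assert res.r == pytest.approx(plain_r, abs=1e-12)
        assert res.p == pytest.approx(plain_p, abs=1e-10)

    def test_spearman_reduces_to_rank_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = x**3 + rng.normal(size=50) * 0.1
        res = partial_correlation(x, y, method="spearman")
        want = sps.spearmanr(x, y)
        assert res.r == pytest.approx(want.statistic, abs=1e-12)

    def test_confounded_triple_partial_vanishes(self):
        """x and y both driven by a confounder c: the marginal correlation
        is large but the partial correlation given c is ~0."""
        rng = np.random.default_rng(7)
        c = rng.normal(size=500)
        x = c + 0.3 * rng.normal(size=500)
        y = 2 * c + 0.3 * rng.normal(size=500)
        marginal = partial_correlation(x, y, method="pearson")
        partial = partial_correlation(x, y, c[:, None], method="pearson")
        assert marginal.r > 0.8
        assert abs(partial.r) < 0.1

    def test_residual_oracle_normal_equations(self):
        """Residualization agrees with explicit normal-equation solves."""
        rng = np.random.default_rng(8)
        n, k = 80, 3
        cov = rng.normal(size=(n, k))
        x = cov @ [1.0, -2.0, 0.5] + rng.normal(size=n)
        y = cov @ [0.3, 1.0, -1.0] + rng.normal(size=n)
        res = partial_correlation(x, y, cov, method="pearson")
        design = np.column_stack([np.ones(n), cov])
        beta_x = np.linalg.solve(design.T @ design, design.T @ x)
        beta_y = np.linalg.solve(design.T @ design, design.T @ y)
        rx, ry = x - design @ beta_x, y - design @ beta_y
        want = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
        assert res.r == pytest.approx(want, abs=1e-12)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(9)
        n, k = 48, 2
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, k))
        res = partial_correlation(x, y, cov, method="pearson")
        r = res.r
        t = r * np.sqrt((n - 2 - k) / (1 - r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 44), abs=1e-12)

    def test_matches_pingouin(self):
        """Cross-check against an independent partial-correlation implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(10)
        n = 60
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.8 * df["c1"]
        for method in ("pearson", "spearman"):
            want = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method=method)
            res = partial_correlation(
                df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]], method=method
            )
            assert res.r == pytest.approx(float(want["r"].iloc[0]), abs=1e-9)
            assert res.p == pytest.approx(float(want["p_val"].iloc[0]), abs=1e-9)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(11)
        n = 30
        c1 = rng.normal(size=n)
        cov = np.column_stack([c1, 2 * c1])
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(
                rng.normal(size=n), rng.normal(size=n), cov, method="pearson",
                covariate_names=["a", "b"],
            )

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation([1.0, 2, 3, 4], [1.0, 2, 3, 4], np.ones((4, 2)), method="pearson")


class TestGroupTests:
    def test_gender_chi_square_yates(self):
        """12/21 vs 18/27 males: continuity-corrected p = .707."""
        chi2, p = chi2_yates([[12, 9], [18, 9]])
        assert p == pytest.approx(0.707, abs=5e-4)

    def test_gender_uncorrected_differs(self):
        chi2, p = sps.chi2_contingency([[12, 9], [18, 9]], correction=False)[:2]
        assert p == pytest.approx(0.499, abs=5e-4)

    def test_age_pooled_t(self):
        """Group age summaries: pooled two-sided t gives p = .127 at df 46."""
        t, p = t_from_summary(34.95, 10.15, 21, 39.70, 10.77, 27)
        assert p == pytest.approx(0.127, abs=5e-4)

    def test_welch_flag_changes_result(self):
        t_p, p_p = t_from_summary(1.0, 1.0, 10, 2.0, 3.0, 40)
        t_w, p_w = t_from_summary(1.0, 1.0, 10, 2.0, 3.0, 40, equal_var=False)
        assert p_p != p_w

    def test_identical_groups_t_zero(self):
        records = []
        for g in ("MDD", "HC"):
            for i in range(5):
                records.append(
                    CohortRecord(
                        subject_id=f"{g}{i}", group=g, age=30.0 + i, gender="male",
                        tleq_ce=2, tleq_oc=5, madrs=10,
                    )
                )
        table = group_tests(records)
        age_row = table[table["variable"] == "age"].iloc[0]
        assert age_row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert age_row["p"] == pytest.approx(1.0)

    def test_cohort_table_end_to_end(self):
        from pvs_sas.synthetic_phantom import CohortSimParams, generate_cohort

        records = generate_cohort(CohortSimParams(n_subjects=48, seed=0))
        table = group_tests(records)
        assert set(table["variable"]) >= {"age", "tleq_ce", "total_volume_mm3", "gender_male"}
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()

    def test_gender_encoding(self):
        records = [
            CohortRecord(subject_id="a", group="MDD", age=30, gender="male"),
            CohortRecord(subject_id="b", group="HC", age=31, gender="female"),
        ]
        df = cohort_frame(records)
        assert df["gender_male"].tolist() == [1.0, 0.0]


class TestCohortRecoveryWithGenerator:
    def test_partial_r_recovers_target(self):
        """Generated cohort with Spearman target 0.5: the gated partial
        correlation (age + gender controlled) lands near the target, and
        the zero-inflated trauma margin forces the Spearman branch."""
        from pvs_sas.synthetic_phantom import CohortSimParams, generate_cohort

        records = generate_cohort(CohortSimParams(n_subjects=500, target_rho=0.5, seed=1))
        df = cohort_frame(records)
        res = partial_correlation(
            df["tleq_ce"].to_numpy(float),
            df["total_volume_mm3"].to_numpy(float),
            df[["age", "gender_male"]],
        )
        assert res.method == "spearman"
        assert 0.4 <= res.r <= 0.6
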