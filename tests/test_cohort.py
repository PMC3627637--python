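"""Cohort statistics: correlations, standardized joint models, staging,
stratification, and duplicate-scan reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lungqct as L
from lungqct.errors import (
    CollinearityError,
    InsufficientDuplicatesError,
    ValidationError,
    ZeroVarianceError,
)


class TestCorrelations:
    def test_pearson_exact_cases(self):
        x = np.arange(10.0)
        r, _ = L.pearson_correlation(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = L.pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = L.pearson_correlation(x, y)
        oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_spearman_monotone_and_reversed(self):
        x = np.linspace(-2, 2, 20)
        rho, _ = L.spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = L.spearman_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_spearman_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 3.0, 4.0, 4.0, 6.0, 7.0, 7.0, 9.0])
        rho, _ = L.spearman_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # mid-ranks for ties
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ZeroVarianceError):
            L.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ZeroVarianceError):
            L.spearman_correlation([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


class TestStandardize:
    def test_unit_example(self):
        assert L.standardize([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_output_moments_and_idempotence(self):
        rng = np.random.default_rng(8)
        x = rng.gamma(2.0, 3.0, 200)
        z = L.standardize(x)
        assert abs(z.mean()) < 1e-10
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert L.standardize(z) == pytest.approx(z, abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ZeroVarianceError):
            L.standardize(np.full(10, 3.0))


def _toy_cohort(n=400, seed=0):
    rng = np.random.default_rng(seed)
    emph = rng.gamma(2.0, 3.0, n)
    gas = 0.6 * L.standardize(emph) + 0.8 * rng.normal(size=n)
    return pd.DataFrame(
        {
            "insp_950": emph,
            "ei_mla": 0.87 + 0.07 * gas,
            "noise": rng.normal(size=n),
        }
    )


class TestJointOutcomeModel:
    def test_noiseless_combo_recovered_exactly(self):
        df = _toy_cohort()
        df["outcome"] = -0.3 * L.standardize(df.insp_950) - 0.3 * L.standardize(df.ei_mla)
        res = L.joint_outcome_model(df, "outcome", "ei_mla")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.beta_emphysema == pytest.approx(-0.3, abs=1e-10)
        assert res.beta_gastrap == pytest.approx(-0.3, abs=1e-10)

    def test_rescaling_raw_predictors_leaves_fit_unchanged(self):
        df = _toy_cohort()
        df["outcome"] = (
            2.0 - 0.4 * L.standardize(df.insp_950) + 0.2 * L.standardize(df.ei_mla)
            + 0.1 * df.noise
        )
        base = L.joint_outcome_model(df, "outcome", "ei_mla")
        scaled = df.assign(insp_950=df.insp_950 * 17.3, ei_mla=df.ei_mla * 0.004)
        res = L.joint_outcome_model(scaled, "outcome", "ei_mla")
        assert res.beta_emphysema == pytest.approx(base.beta_emphysema, rel=1e-9)
        assert res.beta_gastrap == pytest.approx(base.beta_gastrap, rel=1e-9)
        assert res.p_emphysema == pytest.approx(base.p_emphysema, rel=1e-6)
        assert res.r_squared == pytest.approx(base.r_squared, rel=1e-12)

    def test_r_squared_equals_squared_corr_of_fitted_and_observed(self):
        df = _toy_cohort(seed=3)
        df["outcome"] = -0.5 * L.standardize(df.insp_950) + 0.5 * df.noise
        res = L.joint_outcome_model(df, "outcome", "ei_mla")
        r = np.corrcoef(res.fitted, res.observed)[0, 1]
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_permuted_outcome_has_near_null_r_squared(self):
        rng = np.random.default_rng(21)
        df = _toy_cohort(n=2000, seed=4)
        df["outcome"] = -0.4 * L.standardize(df.insp_950) + 0.3 * df.noise
        permuted = df.assign(outcome=rng.permutation(df.outcome.to_numpy()))
        res = L.joint_outcome_model(permuted, "outcome", "ei_mla")
        # permutation null for R^2 with 2 predictors ~ Beta(1, (n-3)/2);
        # 99th percentile at n=2000 is ~0.0046
        null_99 = stats.beta(1, (len(df) - 3) / 2).ppf(0.99)
        assert res.r_squared < null_99

    def test_collinear_design_names_culprits(self):
        df = _toy_cohort()
        df["outcome"] = df.noise
        df["dup"] = df.insp_950 * 2.0  # perfectly collinear after standardization
        with pytest.raises(CollinearityError, match="collinear"):
            L.joint_outcome_model(df, "outcome", "ei_mla", covariates=["dup"])

    def test_covariates_enter_model(self):
        df = _toy_cohort(n=500, seed=9)
        df["age"] = np.random.default_rng(1).normal(60, 9, len(df))
        df["outcome"] = (
            -0.3 * L.standardize(df.insp_950) + 0.05 * L.standardize(df.age) + 0.2 * df.noise
        )
        res = L.joint_outcome_model(df, "outcome", "ei_mla", covariates=["age"])
        assert "age" in res.params.index
        assert res.n == 500


class TestStratification:
    def test_uniform_cohorts_land_in_expected_stratum(self):
        former = pd.DataFrame(
            {"insp_950": [20.0] * 5, "smoking_status": ["former"] * 5}
        )
        strata = L.stratify_cohort(former)
        assert len(strata["severe_emphysema"]) == 5
        current = pd.DataFrame(
            {"insp_950": [3.0] * 7, "smoking_status": ["current"] * 7}
        )
        strata = L.stratify_cohort(current)
        assert len(strata["no_emphysema"]) == 7

    def test_partition_conserves_counts(self):
        df, _, _ = L.generate_cohort(L.CohortSpec(n=300, seed=77))
        strata = L.stratify_cohort(df)
        assert (
            len(strata["severe_emphysema"])
            + len(strata["intermediate"])
            + len(strata["no_emphysema"])
            == len(df)
        )
        assert len(strata["all"]) == len(df)


class TestGoldStage:
    @pytest.mark.parametrize(
        "ratio, fev1pp, expected",
        [
            (0.65, 85, "GOLD1"),
            (0.65, 55, "GOLD2"),
            (0.65, 40, "GOLD3"),
            (0.65, 20, "GOLD4"),
            (0.75, 90, "GOLD0"),
            (0.75, 70, "unclassified"),  # reduced FEV1, normal ratio
            (0.69, 80, "GOLD1"),
        ],
    )
    def test_staging_rules(self, ratio, fev1pp, expected):
        assert L.gold_stage(ratio, fev1pp).value == expected

    def test_never_obstructed_stage_without_low_ratio(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            ratio = rng.uniform(0.7, 1.0)
            stage = L.gold_stage(ratio, rng.uniform(10, 150))
            assert stage in (L.GoldStage.GOLD0, L.GoldStage.UNCLASSIFIED)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            L.gold_stage(1.5, 80)
        with pytest.raises(ValidationError):
            L.gold_stage(0.6, -5)


class TestDuplicateReproducibility:
    def _frames(self, n=10, seed=0, transform=None):
        rng = np.random.default_rng(seed)
        t1 = pd.DataFrame(
            {
                "exp_856": rng.uniform(0, 60, n),
                "ei_mla": rng.uniform(0.6, 1.0, n),
                "rvc_856_950": rng.uniform(-0.8, 0.0, n),
            }
        )
        t2 = t1.copy() if transform is None else t1.apply(transform)
        return t1, t2

    def test_identical_timepoints_give_rho_one(self):
        t1, t2 = self._frames()
        table = L.duplicate_reproducibility((t1, t2))
        assert table["spearman_rho"].to_numpy() == pytest.approx(np.ones(3))

    def test_monotone_transform_gives_rho_one(self):
        t1, t2 = self._frames(transform=lambda c: np.exp(c / 10))
        table = L.duplicate_reproducibility((t1, t2))
        assert table["spearman_rho"].to_numpy() == pytest.approx(np.ones(3))

    def test_synthetic_duplicates_match_midrank_oracle(self):
        _, dups, _ = L.generate_cohort(L.CohortSpec(n=100, seed=6, n_duplicates=18))
        t1 = dups[dups.visit == 1].reset_index(drop=True)
        t2 = dups[dups.visit == 2].reset_index(drop=True)
        table = L.duplicate_reproducibility((t1, t2))
        for m in ("exp_856", "ei_mla", "rvc_856_950"):
            oracle = np.corrcoef(stats.rankdata(t1[m]), stats.rankdata(t2[m]))[0, 1]
            assert table.loc[m, "spearman_rho"] == pytest.approx(oracle, abs=1e-12)
        assert (table["n"] == 18).all()

    def test_too_few_pairs_rejected(self):
        t1, t2 = self._frames(n=2)
        with pytest.raises(InsufficientDuplicatesError):
            L.duplicate_reproducibility((t1, t2))

    def test_accepts_metrics_record_tuples(self):
        rng = np.random.default_rng(31)
        pairs = []
        for _ in range(5):
            t1 = {"exp_856": rng.uniform(0, 60), "ei_mla": rng.uniform(0.6, 1.0),
                  "rvc_856_950": rng.uniform(-0.8, 0.0)}
            t2 = {k: v + rng.normal(0, 0.01) for k, v in t1.items()}
            pairs.append((t1, t2))
        table = L.duplicate_reproducibility(pairs)
        assert set(table.index) == {"exp_856", "ei_mla", "rvc_856_950"}
        assert (table["n"] == 5).all()


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        df = _toy_cohort(n=100, seed=2)
        table = L.correlation_matrix(df, ["insp_950"], ["insp_950"])
        assert table.r.loc["insp_950", "insp_950"] == pytest.approx(1.0)

    def test_symmetric_when_measures_equal_outcomes(self):
        df = _toy_cohort(n=150, seed=3)
        cols = ["insp_950", "ei_mla", "noise"]
        table = L.correlation_matrix(df, cols, cols)
        assert np.allclose(table.r.to_numpy(), table.r.to_numpy().T)

    def test_independent_columns_have_small_r(self):
        rng = np.random.default_rng(44)
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        table = L.correlation_matrix(df, ["a"], ["b"])
        assert abs(table.r.loc["a", "b"]) < 0.05

    def test_residual_vs_emphysema_cell_is_zero(self):
        df, _, _ = L.generate_cohort(L.CohortSpec(n=2000, seed=15))
        fit = L.fit_gas_trapping_residuals(df["exp_856"], df["insp_950"])
        df = df.assign(residual=fit.residuals)
        table = L.correlation_matrix(df, ["residual"], ["insp_950"])
        assert abs(table.r.loc["residual", "insp_950"]) < 1e-8

    def test_constant_cell_reported_not_fatal(self):
        df = _toy_cohort(n=50, seed=5)
        df["flat"] = 1.0
        table = L.correlation_matrix(df, ["insp_950"], ["flat"])
        assert np.isnan(table.r.loc["insp_950", "flat"])
        assert ("insp_950", "flat") in table.reasons

    def test_pairwise_complete_handling(self):
        df = _toy_cohort(n=60, seed=6)
        df.loc[:9, "ei_mla"] = np.nan
        table = L.correlation_matrix(df, ["insp_950"], ["ei_mla"])
        assert table.n.loc["insp_950", "ei_mla"] == 50
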