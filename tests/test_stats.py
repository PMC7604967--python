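"""Statistical validation battery: oracles, calibration, model surface."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from sphenoscore.cohorts import CohortModel, CohortTable, reconstruct_printed_cohort, simulate_cohort
from sphenoscore.config import PipelineConfig
from sphenoscore.stats import (
    CohortScoreModel,
    adjusted_odds_ratios,
    descriptive_summary,
    discriminant_accuracy,
    score_outcome_correlation,
    spearman_rho,
    univariate_tests,
)


def _midrank_pearson(x, y):
    """Brute-force oracle: mid-ranks by counting, then the Pearson formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, xi in enumerate(v):
            less = np.sum(v < xi)
            equal = np.sum(v == xi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_strictly_increasing(self):
        rs, _ = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rs == pytest.approx(1.0)

    def test_strictly_reversed(self):
        rs, _ = spearman_rho([1, 2, 3, 4], [9, 7, 5, 3][::-1][::-1])
        assert rs == pytest.approx(-1.0)

    def test_tied_vector_matches_rank_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rs, _ = spearman_rho(x, y)
        assert rs == pytest.approx(_midrank_pearson(x, y), abs=1e-12)

    def test_thousand_random_tied_vectors_match_oracle(self):
        """Implementation agrees with the brute-force mid-rank oracle to 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(4, 12)
            x = rng.integers(0, 4, size=n)
            y = rng.integers(0, 4, size=n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rs, _ = spearman_rho(x, y)
            assert rs == pytest.approx(_midrank_pearson(x, y), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            spearman_rho([1, 2, 3], [1, 2])

    def test_constant_vector(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestDescriptives:
    def test_printed_cohort_mean_and_sd(self):
        d = descriptive_summary(reconstruct_printed_cohort())
        assert round(d["score_mean"], 1) == 5.3
        assert round(d["score_sd"], 1) == 2.8

    def test_single_repeated_value_sd_zero(self):
        df = pd.DataFrame(
            {
                "volume_grade": [1] * 5,
                "arterial_score": [2] * 5,
                "cs_involved": [False] * 5,
                "bone_invaded": [False] * 5,
                "total_score": [3] * 5,
            }
        )
        d = descriptive_summary(CohortTable(data=df))
        assert d["score_sd"] == 0.0

    def test_percentages_sum_to_100(self):
        d = descriptive_summary(reconstruct_printed_cohort())
        for var, table in d["counts"].items():
            assert sum(p for _, p in table.values()) == pytest.approx(100.0, abs=0.3)


@pytest.fixture(scope="module")
def sim_cohort():
    return simulate_cohort(CohortModel(n_patients=400, beta_score=1.0, seed=9))


class TestUnivariate:
    def test_chi_square_matches_hand_oracle(self):
        # 2x2 table (20,10 / 10,20): sum (O-E)^2/E with E=15 everywhere = 4*25/15
        from scipy.stats import chi2_contingency

        chi2, _, _, _ = chi2_contingency(np.array([[20, 10], [10, 20]]), correction=False)
        assert chi2 == pytest.approx(4 * 25 / 15, abs=1e-4)

    def test_constant_variable_gives_p_one(self, sim_cohort):
        df = sim_cohort.data.copy()
        df["volume_grade"] = 2
        df["total_score"] = (
            df["volume_grade"]
            + df["arterial_score"]
            + 2 * df["cs_involved"].astype(int)
            + df["bone_invaded"].astype(int)
        )
        p = univariate_tests(CohortTable(df, "simulated"))
        assert p["volume_grade"] == 1.0

    def test_strong_effect_detected(self):
        hits = 0
        for seed in range(20):
            sim = simulate_cohort(CohortModel(n_patients=200, beta_score=2.0, seed=seed))
            if univariate_tests(sim)["total_score"] < 0.05:
                hits += 1
        assert hits >= 19

    def test_kw_invariant_under_monotone_relabel(self, sim_cohort):
        base = univariate_tests(sim_cohort)["arterial_score"]
        df = sim_cohort.data.copy()
        df["arterial_score"] = df["arterial_score"].map({0: 0, 1: 10, 2: 20, 3: 35, 4: 99})
        df["total_score"] = (
            df["volume_grade"]
            + df["arterial_score"]
            + 2 * df["cs_involved"].astype(int)
            + df["bone_invaded"].astype(int)
        )
        relabeled = univariate_tests(CohortTable(df, "simulated"))["arterial_score"]
        assert relabeled == pytest.approx(base, abs=1e-12)

    def test_requires_simpson(self):
        with pytest.raises(ValueError, match="simpson"):
            univariate_tests(reconstruct_printed_cohort())


class TestOddsRatios:
    def test_null_simulation_ors_near_one(self):
        """With zero generating effect, adjusted ORs stay in [0.8, 1.25]."""
        ok = 0
        for seed in range(10):
            sim = simulate_cohort(
                CohortModel(n_patients=2000, beta_score=0.0, outcome_beta=0.0, seed=seed)
            )
            ors = adjusted_odds_ratios(sim)
            ok += all(0.8 <= v["or"] <= 1.25 for v in ors.values())
        assert ok >= 8

    def test_binary_family_runs(self, sim_cohort):
        ors = adjusted_odds_ratios(sim_cohort, family="binary")
        assert set(ors) == {"volume_grade", "arterial_score", "cs_involved", "bone_invaded"}
        assert all(v["ci_low"] <= v["or"] <= v["ci_high"] for v in ors.values())

    def test_single_level_outcome_rejected(self):
        df = reconstruct_printed_cohort().data.copy()
        df["simpson_grade"] = 2
        with pytest.raises(ValueError, match="single level"):
            adjusted_odds_ratios(CohortTable(df, "user"))


class TestDiscriminant:
    def test_perfectly_separable_is_100(self):
        grades = np.repeat([1, 2, 3, 4], 10)
        df = pd.DataFrame(
            {
                "volume_grade": 1,
                "arterial_score": grades - 1,  # distinct score per class
                "cs_involved": False,
                "bone_invaded": False,
                "total_score": grades,
                "simpson_grade": grades,
            }
        )
        assert discriminant_accuracy(CohortTable(df, "user")) == 100.0

    def test_chance_level_for_independent_balanced_classes(self):
        th = tuple(float(logit(q)) for q in (0.25, 0.5, 0.75))
        sim = simulate_cohort(
            CohortModel(n_patients=4000, beta_score=0.0, thresholds=th, seed=2)
        )
        acc = discriminant_accuracy(sim)
        assert acc == pytest.approx(25.0, abs=5.0)

    def test_strong_effect_approaches_band_ceiling(self):
        sim = simulate_cohort(CohortModel(n_patients=1000, beta_score=50.0, seed=3))
        assert discriminant_accuracy(sim) > 90.0

    def test_fewer_records_than_classes(self):
        df = simulate_cohort(CohortModel(n_patients=200, seed=0)).data
        few = df.drop_duplicates("simpson_grade")  # one record per grade level
        with pytest.raises(ValueError, match="fewer records"):
            discriminant_accuracy(CohortTable(few, "user"))

    def test_leave_one_out_mode(self, sim_cohort):
        acc = discriminant_accuracy(sim_cohort, mode="loo")
        assert 0.0 <= acc <= 100.0


class TestOutcomeCorrelation:
    def test_negative_effect_gives_negative_rs(self, sim_cohort):
        rs, _ = score_outcome_correlation(sim_cohort)
        assert rs < 0

    def test_reverse_ranked_outcome(self):
        df = reconstruct_printed_cohort().data.copy()
        # outcome strictly decreasing in score: perfect negative rank agreement
        df["outcome_grade"] = -df["total_score"]
        rs, _ = score_outcome_correlation(CohortTable(df, "user"))
        assert rs == pytest.approx(-1.0)

    def test_constant_outcome_rejected(self):
        df = reconstruct_printed_cohort().data.copy()
        df["outcome_grade"] = 1
        with pytest.raises(ValueError, match="constant"):
            score_outcome_correlation(CohortTable(df, "user"))


class TestModelSurface:
    def test_fit_produces_full_report(self, sim_cohort):
        res = CohortScoreModel(sim_cohort).fit()
        r = res.report
        assert r.n == 400
        assert set(r.univariate_p) == {
            "volume_grade",
            "arterial_score",
            "total_score",
            "cs_involved",
            "bone_invaded",
        }
        assert -1 <= r.score_grade_rs[0] <= 1
        assert 0 <= r.discriminant_accuracy_pct <= 100
        assert r.score_outcome_rs[0] < 0
        text = res.summary()
        assert "score vs resection grade" in text
        assert "discriminant accuracy" in text

    def test_from_dataframe_and_config(self, sim_cohort):
        cfg = PipelineConfig(regression_family="binary", discriminant_mode="loo")
        res = CohortScoreModel.from_dataframe(sim_cohort.data, cfg).fit()
        assert res.report.adjusted_or

    def test_printed_cohort_skips_grade_battery(self):
        res = CohortScoreModel(reconstruct_printed_cohort()).fit()
        assert res.report.univariate_p == {}
        assert res.report.score_grade_rs is None
        assert round(res.report.score_mean, 1) == 5.3


class TestParameterRecovery:
    def test_proportional_odds_recovers_beta(self):
        """Refitting the generating model on its own simulations recovers the
        slope with small mean bias (10 seeds at n=2000 here)."""
        import warnings

        from statsmodels.miscmodels.ordinal_model import OrderedModel

        est = []
        for seed in range(10):
            sim = simulate_cohort(CohortModel(n_patients=2000, beta_score=1.0, seed=seed))
            endog = pd.Categorical(sim.data["simpson_grade"].astype(int), ordered=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = OrderedModel(
                    endog, sim.data[["total_score"]].astype(float), distr="logit"
                ).fit(method="bfgs", disp=False)
            est.append(float(fit.params.iloc[0]))
        assert abs(np.mean(est) - 1.0) < 0.15
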