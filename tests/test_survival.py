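import numpy as np
import pandas as pd
import pytest

import oracles
from petstab import (
    bonferroni_alpha,
    bootstrap_cindex_difference,
    cohort_to_frame,
    effective_tests,
    feature_correlation,
    generate_survival_cohort,
    harrell_cindex,
    multivariable_cox,
    univariable_cox,
)


class TestHarrellCindex:
    def test_perfect_ranking(self):
        assert harrell_cindex([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1]) == 1.0

    def test_hand_example_five_of_six(self):
        assert harrell_cindex([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 1, 2]) == pytest.approx(
            5.0 / 6.0
        )

    def test_censoring_restricts_comparable_pairs(self):
        assert harrell_cindex([2, 3, 4], [1, 0, 1], [3, 1, 2]) == 1.0

    def test_negative_time_risk_is_exactly_one(self, rng):
        t = rng.exponential(10, 50)
        assert harrell_cindex(t, np.ones(50, dtype=int), -t) == 1.0

    def test_constant_risk_is_half(self, rng):
        t = rng.exponential(10, 50)
        assert harrell_cindex(t, np.ones(50, dtype=int), np.zeros(50)) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.6).astype(int)
        r = rng.normal(size=80)
        base = harrell_cindex(t, e, r)
        assert harrell_cindex(t, e, np.exp(r)) == pytest.approx(base)
        assert harrell_cindex(t, e, 3 * r + 7) == pytest.approx(base)

    def test_matches_pair_enumeration(self, rng):
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.5).astype(int)
        e[0] = 1
        r = rng.normal(size=30)
        assert harrell_cindex(t, e, r) == pytest.approx(
            oracles.brute_cindex(t, e, r)
        )

    def test_no_comparable_pairs_flagged(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_cindex([1.0, 2.0], [0, 0], [1.0, 2.0])


class TestUnivariableCox:
    def test_null_feature_hr_near_one(self):
        df = cohort_to_frame(generate_survival_cohort(500, {"f": 0.0}, seed=7))
        fit = univariable_cox(
            df.f.to_numpy(), df.time_months.to_numpy(), df.event.to_numpy()
        )
        assert 0.85 <= fit.hr <= 1.18
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_known_hazard_recovered(self):
        df = cohort_to_frame(
            generate_survival_cohort(500, {"f": np.log(2)}, censor_rate=0.0, seed=42)
        )
        fit = univariable_cox(
            df.f.to_numpy(), df.time_months.to_numpy(), df.event.to_numpy()
        )
        assert 1.8 <= fit.hr <= 2.2

    def test_matches_partial_likelihood_maximizer(self, rng):
        for _ in range(5):
            n = rng.integers(5, 9)
            x = rng.normal(size=n)
            t = rng.exponential(size=n)
            e = np.ones(n, dtype=int)
            fit = univariable_cox(x, t, e)
            assert fit.coef == pytest.approx(oracles.brute_cox_coef(t, e, x), abs=1e-6)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariable_cox(np.ones(20), np.arange(1, 21.0), np.ones(20))

    def test_perfect_separation_flagged(self):
        t = np.arange(1.0, 13.0)
        fit = univariable_cox(-t, t, np.ones(12))
        assert not fit.converged


class TestMultivariableCox:
    def test_recovers_prognostic_among_null(self):
        df = cohort_to_frame(
            generate_survival_cohort(
                500, {"f1": np.log(2), "f2": 0.0}, censor_rate=0.0, seed=21
            )
        )
        fits = {
            r.feature: r
            for r in multivariable_cox(
                df[["f1", "f2"]], df.time_months.to_numpy(), df.event.to_numpy()
            )
        }
        assert 1.7 <= fits["f1"].hr <= 2.3
        assert fits["f2"].ci_low <= 1.0 <= fits["f2"].ci_high

    def test_duplicate_column_named_in_error(self):
        df = cohort_to_frame(generate_survival_cohort(50, {"f": 0.5}, seed=3))
        dup = pd.DataFrame({"f": df.f, "f_copy": df.f})
        with pytest.raises(ValueError, match="f_copy"):
            multivariable_cox(dup, df.time_months.to_numpy(), df.event.to_numpy())

    def test_single_feature_matches_univariable(self):
        df = cohort_to_frame(generate_survival_cohort(100, {"f": 0.4}, seed=9))
        multi = multivariable_cox(
            df[["f"]], df.time_months.to_numpy(), df.event.to_numpy()
        )[0]
        uni = univariable_cox(
            df.f.to_numpy(), df.time_months.to_numpy(), df.event.to_numpy(), name="f"
        )
        assert multi.coef == pytest.approx(uni.coef, abs=1e-8)


class TestBootstrapCindexDifference:
    def test_identical_scores_null_result(self, rng):
        t = rng.exponential(10, 40)
        e = (rng.random(40) < 0.6).astype(int)
        r = rng.normal(size=40)
        cmp = bootstrap_cindex_difference(t, e, r, r, n_boot=100, seed=5)
        assert cmp.difference == 0.0
        assert (cmp.boot_ci_low, cmp.boot_ci_high) == (0.0, 0.0)
        assert cmp.p_value == 1.0

    def test_prognostic_vs_noise_excludes_zero(self):
        df = cohort_to_frame(
            generate_survival_cohort(200, {"f": 1.0, "noise": 0.0},
                                     censor_rate=0.0, seed=31)
        )
        cmp = bootstrap_cindex_difference(
            df.time_months.to_numpy(),
            df.event.to_numpy(),
            df.f.to_numpy(),
            df.noise.to_numpy(),
            n_boot=300,
            seed=11,
        )
        assert cmp.boot_ci_low > 0.0

    def test_deterministic_given_seed(self, rng):
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.6).astype(int)
        ra, rb = rng.normal(size=30), rng.normal(size=30)
        a = bootstrap_cindex_difference(t, e, ra, rb, n_boot=50, seed=4)
        b = bootstrap_cindex_difference(t, e, ra, rb, n_boot=50, seed=4)
        assert a == b

    def test_null_scores_ci_covers_zero_in_most_runs(self):
        rng = np.random.default_rng(17)
        covered = 0
        for _ in range(20):
            t = rng.exponential(10, 100)
            e = (rng.random(100) < 0.6).astype(int)
            ra, rb = rng.normal(size=100), rng.normal(size=100)
            cmp = bootstrap_cindex_difference(t, e, ra, rb, n_boot=200, seed=int(rng.integers(1e6)))
            if cmp.boot_ci_low <= 0.0 <= cmp.boot_ci_high:
                covered += 1
        assert covered >= 18


class TestMultipleTesting:
    def build_structured_correlation(self):
        # 12 features: 4 mutually collinear entropies, an IDN/IDMN pair,
        # 6 independent others
        names = [
            "suv_max", "nhoc_max", "nhoc_peak", "nhop_max", "nhop_peak",
            "sphericity", "entropy", "joint_entropy", "sum_entropy",
            "run_entropy", "idn", "idmn",
        ]
        r = np.eye(12)
        entropy_idx = [names.index(n) for n in
                       ("entropy", "joint_entropy", "sum_entropy", "run_entropy")]
        for i in entropy_idx:
            for j in entropy_idx:
                if i != j:
                    r[i, j] = 0.92
        i, j = names.index("idn"), names.index("idmn")
        r[i, j] = r[j, i] = 0.95
        return pd.DataFrame(r, index=names, columns=names)

    def test_described_cluster_structure_gives_eight(self):
        assert effective_tests(self.build_structured_correlation()) == 8

    def test_identity_matrix_counts_features(self):
        assert effective_tests(pd.DataFrame(np.eye(7))) == 7

    def test_all_collinear_counts_one(self):
        assert effective_tests(pd.DataFrame(np.ones((5, 5)))) == 1

    @pytest.mark.parametrize("m,expected", [(8, 0.00625), (1, 0.05), (10, 0.005)])
    def test_bonferroni_division(self, m, expected):
        assert bonferroni_alpha(0.05, m) == pytest.approx(expected)


class TestFeatureCorrelation:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": -x})
        corr = feature_correlation(df)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_features_near_zero(self, rng):
        df = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        corr = feature_correlation(df)
        off = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.15)

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 2.0, 2.0, 2.0]})
        corr = feature_correlation(df)
        assert np.isnan(corr.loc["a", "b"])
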