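"""Odds ratios, logistic regression, rank statistics, calibration test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dsbrepair import cohort
from dsbrepair.association import (
    CollinearityError,
    TwoByTwo,
    dummy_code,
    fit_logistic,
    genotype_or_table,
    hodges_lehmann,
    hosmer_lemeshow,
    mann_whitney,
    odds_ratio_woolf,
    repeff_crude_ors,
    round_half_up,
)
from dsbrepair.scoring import published_group_counts

counts_strategy = st.integers(min_value=1, max_value=60)


class TestWoolfOddsRatio:
    def test_inefficient_repair_or(self):
        res = odds_ratio_woolf(TwoByTwo(38, 1, 11, 12))
        assert res.or_value == pytest.approx(456 / 11)
        assert round_half_up(res.ci_low, 2) == pytest.approx(4.84)
        assert res.ci_high == pytest.approx(355.0, abs=0.5)

    def test_symmetric_table(self):
        assert odds_ratio_woolf(TwoByTwo(5, 5, 5, 5)).or_value == 1.0

    def test_rare_genotype_or(self):
        res = odds_ratio_woolf(TwoByTwo(8, 19, 2, 32))
        assert round_half_up(res.or_value, 2) == pytest.approx(6.74)

    def test_zero_cell_flagged_na(self):
        res = odds_ratio_woolf(TwoByTwo(0, 43, 3, 41))
        assert not res.defined
        assert res.or_value == 0.0 and np.isnan(res.ci_high)

    def test_zero_cell_haldane(self):
        res = odds_ratio_woolf(TwoByTwo(0, 43, 3, 41), zero_cell="haldane")
        assert res.defined
        assert res.or_value == pytest.approx((0.5 * 41.5) / (43.5 * 3.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)

    @given(a=counts_strategy, b=counts_strategy,
           c=counts_strategy, d=counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_reciprocity_and_log_symmetry(self, a, b, c, d):
        """Swapping exposure columns inverts the OR; the Woolf interval
        is symmetric about the OR on the log scale."""
        t = TwoByTwo(a, b, c, d)
        res = odds_ratio_woolf(t)
        swapped = odds_ratio_woolf(t.swap_exposure())
        assert swapped.or_value == pytest.approx(1 / res.or_value, rel=1e-12)
        assert (np.log(res.ci_low) + np.log(res.ci_high)
                == pytest.approx(2 * np.log(res.or_value), rel=1e-9, abs=1e-9))


# Printed per-genotype odds ratios and intervals of the reference study.
# Comparison is to one unit in the last printed digit: the source table
# mixes rounding and truncation in its final digit (e.g. it prints 2.75
# where the cross-product of its own counts gives 2.756).
PUBLISHED_GENOTYPE_ORS = {
    "rs3218536": [("C/T", 3.15, 0.31, 31.49), ("T/T", 3.00, 0.08, 107.45)],
    "rs1801320": [("G/C", 6.74, 1.29, 35.08), ("C/C", 2.75, 1.07, 7.06)],
    "rs7180135": [("A/G", 1.76, 0.42, 7.31), ("A/A", 0.69, 0.15, 3.19)],
    "rs1801321": [("G/T", 2.97, 0.85, 10.31), ("T/T", 3.45, 1.20, 9.94)],
    "rs2619681": [("C/T", 1.00, 0.40, 2.51), ("T/T", 1.00, 0.13, 7.57)],
    "rs963917": [("A/G", 0.34, 0.13, 0.86), ("A/A", 0.09, 0.02, 0.49)],
    "rs963918": [("C/T", 2.14, 0.58, 7.86), ("T/T", 0.93, 0.25, 3.54)],
    "rs3784099": [("A/G", 3.14, 1.26, 7.83), ("A/A", 0.75, 0.13, 4.49)],
    "rs10483813": [("A/T", 1.42, 0.51, 3.96), ("A/A", 0.34, 0.03, 3.47)],
    "rs1042522": [("C/G", 1.03, 0.39, 2.73), ("G/G", 0.31, 0.10, 1.01)],
    "rs1051669": [("C/T", 1.68, 0.71, 4.01)],
    "rs2155209": [("C/T", 1.37, 0.54, 3.46), ("C/C", 0.36, 0.09, 1.40)],
    "rs132774": [("C/G", 1.73, 0.66, 4.57), ("C/C", 1.15, 0.40, 3.27)],
    "rs207906": [("A/G", 1.71, 0.61, 4.75), ("A/A", 1.14, 0.26, 4.96)],
    "rs7003908": [("A/C", 1.30, 0.49, 3.44), ("C/C", 3.50, 0.85, 14.41)],
    "rs861539": [("A/G", 0.21, 0.02, 1.99), ("A/A", 0.53, 0.16, 1.77)],
    "rs45549040": [("C/C", 1.91, 0.17, 21.84)],
}


class TestGenotypeOrTable:
    @pytest.mark.parametrize("snp_id", sorted(PUBLISHED_GENOTYPE_ORS))
    def test_reproduces_published_rows(self, snp_id):
        table = cohort.genotype_count_frame(snp_id)
        results = {r.label: r for r in genotype_or_table(table)}
        for genotype, or_p, lo_p, hi_p in PUBLISHED_GENOTYPE_ORS[snp_id]:
            res = results[genotype]
            assert res.defined
            assert abs(round_half_up(res.or_value, 2) - or_p) <= 0.0101
            assert abs(round_half_up(res.ci_low, 2) - lo_p) <= 0.0101
            assert abs(round_half_up(res.ci_high, 2) - hi_p) <= 0.0101

    def test_undefined_rows_flagged(self):
        """Unobserved genotype cells yield NA-flagged results, mirroring
        the published table's NA rows."""
        res = {r.label: r for r in
               genotype_or_table(cohort.genotype_count_frame("rs45549040"))}
        assert not res["A/C"].defined and res["A/C"].or_value == 0.0
        res = {r.label: r for r in
               genotype_or_table(cohort.genotype_count_frame("rs1051669"))}
        assert not res["T/T"].defined and np.isinf(res["T/T"].or_value)

    def test_identical_arms_give_unit_ors(self):
        import pandas as pd
        table = pd.DataFrame({"control": [10, 20, 15], "case": [10, 20, 15]},
                             index=["A/A", "A/B", "B/B"])
        for res in genotype_or_table(table):
            assert res.or_value == pytest.approx(1.0)


class TestRepeffCrudeOrs:
    def test_published_values(self):
        results = repeff_crude_ors(published_group_counts())
        values = [round_half_up(r.or_value, 2) for r in results]
        assert values == pytest.approx([1.09, 5.45, 41.45])
        lo = [round_half_up(r.ci_low, 2) for r in results]
        hi = [round_half_up(r.ci_high, 1) for r in results]
        assert lo == pytest.approx([0.06, 0.55, 4.84])
        assert hi[0] == pytest.approx(19.6)
        assert hi[1] == pytest.approx(54.3, abs=0.05)
        assert results[2].ci_high == pytest.approx(355.0, abs=0.5)

    def test_uniform_counts(self):
        import pandas as pd
        counts = pd.DataFrame({g: [10, 10] for g in (1, 2, 3, 4)},
                              index=["control", "case"])
        assert [r.or_value for r in repeff_crude_ors(counts)] == [1, 1, 1]

    def test_group_permutation_swaps_ors(self):
        import pandas as pd
        counts = published_group_counts()
        permuted = counts[[1, 3, 2, 4]]
        permuted.columns = [1, 2, 3, 4]
        base = [r.or_value for r in repeff_crude_ors(counts)]
        swapped = [r.or_value for r in repeff_crude_ors(permuted)]
        assert swapped[0] == pytest.approx(base[1])
        assert swapped[1] == pytest.approx(base[0])
        assert swapped[2] == pytest.approx(base[2])


class TestLogisticRegression:
    @staticmethod
    def expand(table: TwoByTwo):
        y = np.array([1] * int(table.a + table.b) + [0] * int(table.c + table.d))
        x = np.array([1] * int(table.a) + [0] * int(table.b)
                     + [1] * int(table.c) + [0] * int(table.d))
        return y, x

    def test_single_predictor_equals_log_cross_ratio(self):
        y, x = self.expand(TwoByTwo(8, 19, 2, 32))
        fit = fit_logistic(y, x)
        assert fit.converged
        assert fit.coef[1] == pytest.approx(np.log(6.7368421), abs=1e-7)
        woolf = odds_ratio_woolf(TwoByTwo(8, 19, 2, 32))
        assert fit.ci_low[1] == pytest.approx(woolf.ci_low, rel=1e-6)
        assert fit.ci_high[1] == pytest.approx(woolf.ci_high, rel=1e-6)

    def test_independent_predictor_zero_coefficient(self):
        y, x = self.expand(TwoByTwo(10, 10, 10, 10))
        fit = fit_logistic(y, x)
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(300, 3)).astype(float)
        eta = -0.5 + X @ np.array([0.8, -0.4, 0.2])
        y = rng.random(300) < 1 / (1 + np.exp(-eta))
        fit = fit_logistic(y.astype(int), X)
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.array([0] * 20 + [1] * 20)
        x = y.astype(float)
        fit = fit_logistic(y, x)
        assert not fit.converged
        assert "separation" in fit.diagnostic

    def test_collinear_dummies_named(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 50).astype(float)
        X = np.column_stack([a, 1 - a])
        y = rng.integers(0, 2, 50)
        with pytest.raises(CollinearityError) as err:
            fit_logistic(y, X, feature_names=["dup_a", "dup_b"])
        assert "dup" in str(err.value)

    def test_constant_column_rejected(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(CollinearityError):
            fit_logistic(y, np.ones(20))

    def test_adjusted_model_recovers_planted_effects(self):
        """Multivariable fit (repair group-4 indicator + two SNP dummy
        sets) recovers planted odds ratios within 15% at n = 2000/2000.

        Covariates are sampled independently within each arm, so the
        data-generating process is exactly logistic with coefficients
        equal to the marginal log odds ratios.  Estimates are averaged
        over three seeds on the log scale to suppress Monte-Carlo noise
        (one seed's standard error on a log-OR here is ~0.085)."""
        from dsbrepair.scoring import score_cohort
        log_ors: dict[str, list[float]] = {}
        for seed in (21, 22, 23):
            cfg = cohort.default_config(n_cases=2000, n_controls=2000,
                                        seed=seed)
            cfg = cohort.plant_association(cfg, "rs1801321", 3.45,
                                           genotype="T/T")
            cfg = cohort.plant_association(cfg, "rs1801320", 6.74,
                                           genotype="G/C")
            frame = cohort.generate_cohort_frame(cfg)
            scored = score_cohort(frame, mode="fixed")
            merged = frame.merge(scored[["subject_id", "group"]],
                                 on="subject_id")
            y = (merged["arm"] == "case").to_numpy(int)
            cols, names = [], []
            g4 = (merged["group"] == 4).to_numpy(float)
            cols.append(g4[:, None]); names.append("repeff_g4")
            for snp in ("rs1801321", "rs1801320"):
                order = cfg.snp(snp).genotypes
                coded, nm, _ = dummy_code(merged[snp], reference=order[0],
                                          name=snp)
                cols.append(coded); names.extend(nm)
            X = np.column_stack(cols)
            fit = fit_logistic(y, X, feature_names=names)
            assert fit.converged
            for name, coef in zip(fit.names, fit.coef):
                log_ors.setdefault(name, []).append(coef)
        mean_or = {n: float(np.exp(np.mean(v))) for n, v in log_ors.items()}
        assert mean_or["rs1801321[T/T]"] == pytest.approx(3.45, rel=0.15)
        assert mean_or["rs1801320[G/C]"] == pytest.approx(6.74, rel=0.15)
        # group-4 membership is strongly case-associated by construction
        true_g4_or = (38 / 7) / (11 / 34)
        assert mean_or["repeff_g4"] == pytest.approx(true_g4_or, rel=0.15)


def mann_whitney_enumeration(x, y):
    """Exact-null oracle: U by pair counting and the exact two-sided p
    over every assignment of the pooled values to the two samples."""
    x, y = list(x), list(y)
    u_obs = sum(0.5 if xi == yj else float(xi > yj) for xi in x for yj in y)
    pooled = x + y
    n1 = len(x)
    mean = n1 * len(y) / 2.0
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(0.5 if a == b else float(a > b) for a in xs for b in ys)
        total += 1
        if abs(u - mean) >= abs(u_obs - mean) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u == pytest.approx(8.0)  # n^2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_small(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        _, p_exact = mann_whitney_enumeration([1, 2, 3], [4, 5, 6])
        assert p_exact == pytest.approx(2 / 20)  # one-tail 1/20, two-sided

    @pytest.mark.parametrize("seed", range(8))
    def test_u_matches_pair_counting_oracle(self, seed):
        """Midrank-sum U equals the brute-force pair-counting U, and the
        approximate p tracks the exact enumeration p at n <= 7."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(3, 8)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(3, 8)).astype(float)
        res = mann_whitney(x, y)
        u_exact, p_exact = mann_whitney_enumeration(x, y)
        assert res.u == pytest.approx(u_exact, abs=1e-9)
        # the corrected normal approximation deviates from the exact
        # permutation p by up to ~0.15 at these sample sizes
        assert res.p_value == pytest.approx(p_exact, abs=0.15)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        res = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert res.u == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_study_scale_power(self):
        """Generated RepEff samples with the study's group structure
        separate at p < 1e-4 in at least 95% of 200 seeds (n = 45/45)."""
        from dsbrepair.scoring import compute_repeff
        hits = 0
        for seed in range(200):
            cfg = cohort.default_config(seed=seed)
            frame = cohort.generate_cohort_frame(cfg)
            repeff = compute_repeff(frame["damage_t0"].to_numpy(),
                                    frame["damage_t120"].to_numpy())
            arm = frame["arm"].to_numpy()
            res = mann_whitney(repeff[arm == "case"],
                               repeff[arm == "control"])
            hits += res.p_value < 1e-4
        assert hits >= 190


class TestHodgesLehmann:
    def test_identical_samples(self):
        assert hodges_lehmann([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_example(self):
        assert hodges_lehmann([3, 5], [1, 2]) == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(3, 2, size=9)
        y = rng.normal(0, 2, size=7)
        diffs = sorted(xi - yj for xi in x for yj in y)
        mid = len(diffs) // 2
        expected = (diffs[mid] if len(diffs) % 2
                    else (diffs[mid - 1] + diffs[mid]) / 2)
        assert hodges_lehmann(x, y) == pytest.approx(expected)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_shift_equivariance(self, x, y, k):
        assert hodges_lehmann(np.array(x) + k, y) == pytest.approx(
            hodges_lehmann(x, y) + k, abs=1e-9)


class TestHosmerLemeshow:
    def test_constant_model_statistic_zero(self):
        y = np.array([0, 1] * 20)
        p = np.full(40, y.mean())
        res = hosmer_lemeshow(p, y, g=2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_model_rejects_at_nominal_rate(self):
        """Data simulated from the fitted model family yields ~5%
        rejections at alpha = 0.05 over 500 replicates."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(500):
            x = rng.normal(size=300)
            p_true = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
            y = (rng.random(300) < p_true).astype(int)
            fit = fit_logistic(y, x)
            res = hosmer_lemeshow(fit.fitted, y)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / 500 <= 0.09

    def test_misspecified_model_detected(self):
        """Quadratic truth fitted linearly is rejected most of the time."""
        rng = np.random.default_rng(23)
        rejections = 0
        for _ in range(40):
            x = rng.normal(size=2000)
            p_true = 1 / (1 + np.exp(-(-1.0 + 1.5 * x ** 2)))
            y = (rng.random(2000) < p_true).astype(int)
            fit = fit_logistic(y, x)
            res = hosmer_lemeshow(fit.fitted, y)
            rejections += res.p_value < 0.05
        assert rejections / 40 > 0.5
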