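"""Reliability and comparison statistics against brute-force oracles."""

import numpy as np
import pytest
from itertools import combinations

import pandas as pd

import wmnquant as w
from wmnquant.stats import mann_whitney


def icc_a1_oracle(test, retest):
    """ICC(A,1) assembled directly from two-way ANOVA mean squares."""
    x = np.column_stack([test, retest]).astype(float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestTestRetest:
    def test_identical_retest(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (5.0, 5.0), (9.0, 9.0)]
        rep = w.test_retest(pairs)
        assert rep.r == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.bland_altman.mean_diff == 0.0
        assert rep.bland_altman.loa_lower == rep.bland_altman.loa_upper == 0.0

    def test_constant_offset_penalised_by_icc_not_r(self):
        test = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = w.test_retest(np.column_stack([test, test + 2.0]))
        assert rep.r == pytest.approx(1.0)
        assert rep.icc < 1.0
        assert rep.bland_altman.mean_diff == pytest.approx(2.0)

    def test_zero_variance_flags_r_but_computes_icc(self):
        pairs = [(3.0, 2.0), (3.0, 4.0), (3.0, 3.0)]
        rep = w.test_retest(pairs)
        assert np.isnan(rep.r)
        assert np.isfinite(rep.icc)

    def test_icc_matches_anova_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            test = rng.normal(1000, 300, 10)
            retest = test + rng.normal(0, 100, 10)
            rep = w.test_retest(np.column_stack([test, retest]))
            assert rep.icc == pytest.approx(icc_a1_oracle(test, retest), abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            w.test_retest([(1.0, 2.0)])

    def test_loa_cover_95pct_of_normal_differences(self, rng):
        cover = []
        for _ in range(200):
            test = rng.normal(0, 1, 500)
            retest = test + rng.normal(0.3, 1.0, 500)
            ba = w.bland_altman(test, retest)
            d = retest - test
            cover.append(np.mean((d >= ba.loa_lower) & (d <= ba.loa_upper)))
        assert np.mean(cover) * 100 == pytest.approx(95.0, abs=2.0)


def mw_exact_oracle(x, y):
    """Two-sided Mann–Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs_u = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    m = len(x) * len(y)
    stat = min(obs_u, m - obs_u)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        total += 1
        if min(u, m - u) <= stat + 1e-12:
            count += 1
    return count / total


class TestGroupComparisons:
    def test_mann_whitney_exact_small_groups(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(mw_exact_oracle(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])))

    def test_mann_whitney_matches_enumeration_on_random_groups(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 4)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(mw_exact_oracle(x, y), abs=1e-9)

    def test_identical_columns_give_p_one(self):
        df = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 1, 1, 1], "c": [1.0, 1, 1, 1]})
        comps = w.compare_methods(df)
        assert comps[0].test == "kruskal-wallis"
        assert comps[0].p_value == pytest.approx(1.0)

    def test_method_comparison_structure(self, rng):
        df = pd.DataFrame(
            {
                "wsa_auto": rng.normal(2000, 300, 12),
                "wsa_manual": rng.normal(1500, 300, 12),
                "sa": rng.normal(1500, 400, 12),
            }
        )
        comps = w.compare_methods(df)
        assert len(comps) == 1 + 3  # omnibus + 3 pairwise
        for c in comps[1:]:
            assert c.test == "mann-whitney"
            assert 0 <= c.p_value <= 1

    def test_separated_groups_detected(self, rng):
        hits = 0
        for rep in range(200):
            ctrl = rng.uniform(500, 1500, 12)
            epi = rng.uniform(800, 4500, 30)
            comp = w.compare_groups(
                np.r_[ctrl, epi],
                np.r_[["control"] * 12, ["epilepsy"] * 30],
                "epilepsy",
                "control",
            )
            hits += comp.p_value < 0.05
        assert hits / 200 >= 0.95


class TestClinicalCorrelations:
    def test_density_correlates_with_itself(self, rng):
        dens = rng.normal(1500, 400, 30)
        out = w.clinical_correlations(dens, pd.DataFrame({"self": dens}), alpha=0.002)
        assert out[0].statistic == pytest.approx(1.0)
        assert out[0].significant

    def test_hand_ranked_fixture(self):
        dens = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        cov = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        # Spearman via the rank formula 1 - 6 Σd² / (n(n²-1))
        d = np.array([-2, 1, -1, 2, 0], dtype=float)  # rank differences
        expected = 1 - 6 * np.sum(d**2) / (5 * 24)
        out = w.clinical_correlations(dens, pd.DataFrame({"cov": cov}), alpha=0.002)
        assert out[0].statistic == pytest.approx(expected)

    def test_constant_covariate_flagged_undefined(self):
        out = w.clinical_correlations(
            np.array([1.0, 2, 3, 4]), pd.DataFrame({"c": [5.0, 5, 5, 5]})
        )
        assert np.isnan(out[0].statistic)
        assert out[0].significant is False

    def test_bonferroni_alpha_controls_family_wise_error(self, rng):
        """25 independent null covariates at α = 0.002 → FWER ≤ 5%."""
        fw = 0
        reps = 500
        for _ in range(reps):
            dens = rng.normal(0, 1, 30)
            covs = pd.DataFrame(rng.normal(0, 1, (30, 25)))
            covs.columns = [f"c{i}" for i in range(25)]
            out = w.clinical_correlations(dens, covs, alpha=0.002)
            fw += any(o.significant for o in out)
        assert fw / reps <= 0.05 + 0.02


def test_lowest_noise_method_attains_highest_icc(rng):
    """The reliability ranking criterion: with method-specific retest noise,
    the least noisy method gets the best ICC."""
    truth = rng.normal(2000, 600, 10)
    noise = {"wsa_manual": 50.0, "sa": 250.0, "stereology": 500.0}
    iccs = {}
    for method, sd in noise.items():
        rep = w.test_retest(
            np.column_stack([truth + rng.normal(0, sd, 10), truth + rng.normal(0, sd, 10)])
        )
        iccs[method] = rep.icc
    assert max(iccs, key=iccs.get) == "wsa_manual"
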