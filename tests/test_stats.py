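"""Statistical toolbox: hand values, enumeration oracles, calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from connstage.stats import (
    ancova_group_effect,
    bh_fdr,
    chi_square_contingency,
    cohens_d_residuals,
    jonckheere_terpstra,
    logistic_domain_impairment,
    oneway_anova,
    pearson_correlation,
    residualize,
)


# ---- independent oracles --------------------------------------------

def jt_stat_oracle(groups):
    stat = 0.0
    for gi, gj in itertools.combinations(range(len(groups)), 2):
        for x in groups[gi]:
            for y in groups[gj]:
                if x < y:
                    stat += 1.0
                elif x == y:
                    stat += 0.5
    return stat


def jt_exact_p_oracle(groups):
    """One-sided exact p by exhaustive enumeration of label permutations."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    observed = jt_stat_oracle(groups)
    ge = total = 0
    seen = set()
    for perm in itertools.permutations(pooled):
        if perm in seen:
            continue
        seen.add(perm)
        split = []
        k = 0
        for s in sizes:
            split.append(perm[k:k + s])
            k += s
        total += 1
        if jt_stat_oracle(split) >= observed - 1e-9:
            ge += 1
    return ge / total


def bh_stepup_oracle(p, q):
    """Literal step-up definition: largest k with p_(k) <= k q / m."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    sig = np.zeros(m, dtype=bool)
    sig[order[:k_star]] = True
    return sig


# ---- residualization and effect sizes -------------------------------

class TestResidualize:
    def test_orthogonal_covariate_gives_centered_y(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        x = np.tile([1.0, -1.0], 20)  # orthogonal to intercept
        y = y - (x @ y) / (x @ x) * x  # force exact orthogonality
        res = residualize(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(18, 40, 60)
        y = 2 * age + rng.normal(size=60)
        res = residualize(y, pd.DataFrame({"age": age}))
        assert abs(np.corrcoef(res, age)[0, 1]) < 1e-10

    def test_collinear_design_names_columns(self):
        x = np.arange(10.0)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            residualize(np.ones(10), cov)


class TestCohensD:
    def test_hand_value(self):
        assert cohens_d_residuals([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_equal_samples_zero(self):
        assert cohens_d_residuals([1, 2, 5], [1, 2, 5]) == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(1, 1, size=25)
        d0 = cohens_d_residuals(a, b)
        d1 = cohens_d_residuals(3 * a - 7, 3 * b - 7)
        assert d0 == pytest.approx(d1)

    def test_zero_pooled_sd_flagged(self):
        assert math.isnan(cohens_d_residuals([1, 1], [2, 2]))


class TestAncova:
    def _cov(self, n, rng):
        return pd.DataFrame({"age": rng.uniform(18, 40, n)})

    def test_null_groups_large_p_small_d(self):
        rng = np.random.default_rng(3)
        n = 80
        cov = self._cov(n, rng)
        y = 0.5 * cov["age"].to_numpy() + rng.normal(size=n)
        group = pd.Series(["a"] * 40 + ["b"] * 40)
        eff = ancova_group_effect(y, group, cov)
        assert eff.p_value > 0.05
        assert abs(eff.cohens_d) < 0.5

    def test_planted_shift_recovered(self):
        """Median recovered d within 0.25 of the planted 1-SD shift."""
        rng = np.random.default_rng(4)
        ds = []
        for _ in range(100):
            cov = self._cov(100, rng)
            y = rng.normal(size=100)
            y[:50] += 1.0  # group a shifted up by one pooled SD
            group = pd.Series(["a"] * 50 + ["b"] * 50)
            ds.append(ancova_group_effect(y, group, cov).cohens_d)
        assert abs(np.median(ds) - 1.0) < 0.25

    def test_sign_convention_first_minus_second(self):
        rng = np.random.default_rng(5)
        cov = self._cov(60, rng)
        y = np.concatenate([np.full(30, 5.0), np.full(30, 3.0)]) + rng.normal(
            scale=0.5, size=60
        )
        eff = ancova_group_effect(y, pd.Series(["HC"] * 30 + ["EPP"] * 30), cov,
                                  order=["HC", "EPP"])
        assert eff.cohens_d > 0  # HC minus patient positive for reductions

    def test_confounded_group_rejected(self):
        cov = pd.DataFrame({"flag": [0.0] * 5 + [1.0] * 5})
        group = pd.Series(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="confounded"):
            ancova_group_effect(np.arange(10.0), group, cov)


# ---- Jonckheere-Terpstra --------------------------------------------

class TestJonckheereTerpstra:
    def test_maximal_ordering_example(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5]], "increasing")
        assert res.statistic == 8.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 30)

    def test_two_groups_equals_mannwhitney_exceedance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        res = jonckheere_terpstra([a, b], "increasing", enumeration_cap=1)
        u = sps.mannwhitneyu(b, a, alternative="greater").statistic
        assert res.statistic == pytest.approx(u)

    @pytest.mark.parametrize(
        "sizes", [(2, 2, 2), (3, 2, 3), (2, 2, 2, 2), (4, 4), (3, 5)]
    )
    def test_exact_p_matches_enumeration_oracle(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for rep in range(3):
            # integer draws force ties into the enumeration
            pooled = rng.integers(0, 4, size=sum(sizes))
            groups, k = [], 0
            for s in sizes:
                groups.append(pooled[k:k + s].tolist())
                k += s
            res = jonckheere_terpstra(groups, "increasing")
            assert res.method in ("exact", "degenerate")
            if res.method == "exact":
                assert res.p_value == pytest.approx(jt_exact_p_oracle(groups))

    def test_decreasing_is_reversal(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc=-m, size=4) for m in range(3)]
        dec = jonckheere_terpstra(groups, "decreasing")
        inc = jonckheere_terpstra(groups[::-1], "increasing")
        assert dec.statistic == inc.statistic
        assert dec.p_value == inc.p_value

    def test_constant_data_half(self):
        res = jonckheere_terpstra([[2, 2], [2, 2], [2]], "increasing")
        assert res.p_value == 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            jonckheere_terpstra([[1, 2], []], "increasing")

    def test_asymptotic_close_to_permutation_oracle(self):
        """Normal approximation within ~0.015 of a seeded permutation p."""
        rng = np.random.default_rng(8)
        n_perm = 4000
        for _ in range(15):
            data = rng.normal(size=30) + np.repeat([0.0, 0.3, 0.6], 10)
            groups = [data[:10], data[10:20], data[20:]]
            res = jonckheere_terpstra(groups, "increasing", enumeration_cap=1)
            assert res.method == "asymptotic"
            less = (data[:, None] < data[None, :]).astype(float)
            less += 0.5 * (data[:, None] == data[None, :])
            np.fill_diagonal(less, 0.0)
            labels = np.repeat([0, 1, 2], 10)
            count = 0
            for _ in range(n_perm):
                lp = rng.permutation(labels)
                mask = lp[:, None] < lp[None, :]
                if (less * mask).sum() >= res.statistic - 1e-9:
                    count += 1
            mc_p = count / n_perm
            assert abs(res.p_value - mc_p) < 0.015 + 3 * math.sqrt(
                mc_p * (1 - mc_p) / n_perm
            )

    def test_null_calibration(self):
        """Type-I proportion at alpha=0.05 in [0.03, 0.07] under the null."""
        rng = np.random.default_rng(9)
        hits = 0
        n_tests = 2000
        for _ in range(n_tests):
            data = rng.normal(size=24)
            res = jonckheere_terpstra(
                [data[:8], data[8:16], data[16:]], "increasing", enumeration_cap=1
            )
            hits += res.p_value < 0.05
        assert 0.03 <= hits / n_tests <= 0.07


# ---- FDR, correlation, contingency, ANOVA ---------------------------

class TestBhFdr:
    def test_single_small_p_significant(self):
        sig, _ = bh_fdr([0.01], 0.05)
        assert sig[0]

    def test_stepup_hand_example(self):
        sig, _ = bh_fdr([0.01, 0.02, 0.04, 0.2], 0.05)
        np.testing.assert_array_equal(sig, [True, True, False, False])

    def test_empty_input(self):
        sig, adj = bh_fdr([], 0.05)
        assert sig.size == 0 and adj.size == 0

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
    def test_matches_stepup_oracle(self, m):
        rng = np.random.default_rng(m)
        for _ in range(50):
            p = np.round(rng.uniform(size=m), 3)
            sig, _ = bh_fdr(p, 0.05)
            np.testing.assert_array_equal(sig, bh_stepup_oracle(p, 0.05))

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(size=20)
        _, adj = bh_fdr(p, 0.05)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x + 3)[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        r, p = pearson_correlation(np.ones(5), np.arange(5.0))
        assert math.isnan(r) and math.isnan(p)

    def test_monte_carlo_recovery(self):
        """Mean estimate within 0.05 of rho=0.4 at n=76 over 200 replicates."""
        rng = np.random.default_rng(10)
        rho, n = 0.4, 76
        rs = []
        for _ in range(200):
            x = rng.normal(size=n)
            y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
            rs.append(pearson_correlation(x, y)[0])
        assert abs(np.mean(rs) - rho) < 0.05


class TestChiSquare:
    def test_gender_table(self):
        _, p = chi_square_contingency([[48, 28], [49, 22]])
        assert p == pytest.approx(0.45, abs=0.005)

    def test_handedness_table(self):
        chi2, p = chi_square_contingency([[25, 0], [39, 7]])
        assert chi2 == pytest.approx(4.2, abs=0.05)
        assert p == pytest.approx(0.040, abs=0.0005)

    def test_proportional_table_independent(self):
        chi2, p = chi_square_contingency([[10, 10], [20, 20]])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_contingency([[0, 0], [3, 4]])


class TestOnewayAnova:
    def test_equal_means_zero_f(self):
        F, p = oneway_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_summary_examples(self):
        _, p1 = oneway_anova([(76, 26.8, 6.1), (71, 26.0, 6.2)])
        assert p1 == pytest.approx(0.43, abs=0.005)
        _, p2 = oneway_anova([(25, 23.5, 4.6), (46, 27.3, 6.5)])
        assert p2 == pytest.approx(0.012, abs=0.0005)

    def test_summary_equals_raw(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(m, 1, size=n) for m, n in ((0, 8), (0.5, 12), (1, 6))]
        summaries = [(len(g), g.mean(), g.std(ddof=1)) for g in groups]
        F_raw, p_raw = oneway_anova(groups)
        F_sum, p_sum = oneway_anova(summaries)
        assert F_sum == pytest.approx(F_raw)
        assert p_sum == pytest.approx(p_raw)

    def test_degenerate_flagged(self):
        F, p = oneway_anova([[1.0, 1.0], [1.0, 1.0]])
        assert math.isnan(F) and math.isnan(p)


class TestLogisticImpairment:
    def _frame(self, rng, shift, n=70):
        hc = rng.normal(size=n)
        epp = rng.normal(loc=-shift, size=n)
        scores = pd.DataFrame({"speed": np.concatenate([hc, epp])})
        status = ["HC"] * n + ["EPP"] * n
        return scores, status

    def test_identical_distributions_or_near_one(self):
        rng = np.random.default_rng(12)
        ors = []
        for _ in range(20):
            scores, status = self._frame(rng, 0.0)
            ors.append(logistic_domain_impairment(scores, status)["odds_ratio"][0])
        assert abs(np.median(np.log(ors))) < 0.3

    def test_planted_shift_direction(self):
        """Lower scores in patients -> OR per SD below 1 almost surely."""
        rng = np.random.default_rng(13)
        correct = 0
        for _ in range(200):
            scores, status = self._frame(rng, 1.0, n=73)
            out = logistic_domain_impairment(scores, status)
            correct += out["odds_ratio"][0] < 1.0
        assert correct >= 0.95 * 200

    def test_domains_ranked_by_effect(self):
        rng = np.random.default_rng(14)
        n = 80
        strong = np.concatenate([rng.normal(size=n), rng.normal(-1.5, 1, size=n)])
        weak = np.concatenate([rng.normal(size=n), rng.normal(-0.2, 1, size=n)])
        scores = pd.DataFrame({"weak": weak, "strong": strong})
        out = logistic_domain_impairment(scores, ["HC"] * n + ["EPP"] * n)
        assert out.iloc[0]["domain"] == "strong"

    def test_separation_fallback(self):
        scores = pd.DataFrame({"x": np.concatenate([np.ones(10), -np.ones(10)])})
        status = ["HC"] * 10 + ["EPP"] * 10
        out = logistic_domain_impairment(scores, status)
        assert np.isfinite(out["p_value"][0])
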