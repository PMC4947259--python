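"""Variance components, heritability, conditional means and simple tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fsibqtl.phenostats import (
    VarianceComponents,
    conditional_means,
    line_mean_h2,
    oneway_f_test,
    pearson_with_ci,
    regress,
    variance_components,
)


def balanced_pheno(rng, n_geno=100, sigma_g=1.0, sigma_e=1.0, year_effect=3.0):
    g = np.repeat(np.arange(n_geno), 4)
    u = rng.normal(0, sigma_g, n_geno)
    yr = np.tile([2014, 2014, 2015, 2015], n_geno)
    y = 50 + u[g] + (yr == 2015) * year_effect + rng.normal(0, sigma_e, 4 * n_geno)
    return pd.DataFrame(
        {
            "genotype_id": [f"g{i:04d}" for i in g],
            "family_id": "F",
            "replicate": np.tile([1, 2], 2 * n_geno),
            "year": yr,
            "heading_days": y,
        }
    ), u


class TestVarianceComponents:
    def test_recovery_balanced(self):
        rng = np.random.default_rng(31)
        ests = []
        for _ in range(15):
            ph, _ = balanced_pheno(rng, n_geno=360)
            vc = variance_components(ph)
            ests.append((vc.sigma2_g, vc.sigma2_e))
        med = np.median(np.array(ests), axis=0)
        assert abs(med[0] - 1.0) < 0.15
        assert abs(med[1] - 1.0) < 0.15

    def test_matches_lme4_style_fit(self):
        # independent cross-check: statsmodels MixedLM REML on the same data
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(32)
        ph, _ = balanced_pheno(rng, n_geno=80)
        vc = variance_components(ph)
        m = smf.mixedlm(
            "heading_days ~ C(year)", ph, groups=ph["genotype_id"]
        ).fit(reml=True)
        assert vc.sigma2_g == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3)
        assert vc.sigma2_e == pytest.approx(float(m.scale), rel=1e-3)
        assert vc.fixed_effects["year_2015"] == pytest.approx(
            float(m.params["C(year)[T.2015]"]), rel=1e-3
        )

    def test_zero_residual_h2_one(self):
        rng = np.random.default_rng(33)
        ph, _ = balanced_pheno(rng, n_geno=50, sigma_e=1e-8)
        vc = variance_components(ph)
        assert line_mean_h2(vc) > 0.999

    def test_zero_genetic_variance_boundary(self):
        rng = np.random.default_rng(34)
        ph, _ = balanced_pheno(rng, n_geno=100, sigma_g=0.0)
        vc = variance_components(ph)
        assert vc.sigma2_g < 0.1 * vc.sigma2_e

    def test_singleton_genotypes_rejected(self):
        ph = pd.DataFrame(
            {
                "genotype_id": ["a", "b", "c"],
                "family_id": "F",
                "replicate": 1,
                "year": 2015,
                "heading_days": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            variance_components(ph)

    def test_consistency_with_sample_size(self):
        rng = np.random.default_rng(35)
        errs = {}
        for n in (90, 360):
            e = []
            for _ in range(10):
                ph, _ = balanced_pheno(rng, n_geno=n)
                vc = variance_components(ph)
                e.append(abs(vc.sigma2_g - 1.0))
            errs[n] = np.median(e)
        assert errs[360] < errs[90]


class TestHeritability:
    def test_closed_form(self):
        vc = VarianceComponents(1.0, 1.0, {}, 4.0)
        assert line_mean_h2(vc) == pytest.approx(0.8)
        assert line_mean_h2(VarianceComponents(1.0, 0.0, {}, 2.0)) == 1.0

    def test_monotonicity(self):
        base = line_mean_h2(VarianceComponents(1.0, 1.0, {}, 4.0))
        assert line_mean_h2(VarianceComponents(2.0, 1.0, {}, 4.0)) > base
        assert line_mean_h2(VarianceComponents(1.0, 2.0, {}, 4.0)) < base

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            line_mean_h2(VarianceComponents(0.0, 0.0, {}, 4.0))


class TestConditionalMeans:
    def test_no_shrinkage_limit(self):
        rng = np.random.default_rng(36)
        ph, _ = balanced_pheno(rng, n_geno=40, sigma_g=2.0, sigma_e=1e-6)
        cm = conditional_means(ph)
        raw = (
            ph.assign(adj=ph["heading_days"] - (ph["year"] == 2015) * 0)
            .groupby("genotype_id")["heading_days"]
            .mean()
        )
        # with no residual noise the year effect is estimated exactly, so
        # conditional means equal year-adjusted genotype means
        vc = variance_components(ph)
        adj = ph["heading_days"] - (ph["year"] == 2015) * vc.fixed_effects["year_2015"]
        raw_adj = adj.groupby(ph["genotype_id"]).mean()
        np.testing.assert_allclose(cm.sort_index(), raw_adj.sort_index(), atol=1e-3)

    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(37)
        ph, _ = balanced_pheno(rng, n_geno=60, sigma_g=0.0, sigma_e=1.0)
        cm = conditional_means(ph)
        assert cm.std() < 0.2  # collapses toward the grand mean

    def test_rank_preserved_vs_raw_means(self):
        rng = np.random.default_rng(38)
        ph, _ = balanced_pheno(rng, n_geno=50)
        cm = conditional_means(ph)
        vc = variance_components(ph)
        adj = ph["heading_days"] - (ph["year"] == 2015) * vc.fixed_effects["year_2015"]
        raw = adj.groupby(ph["genotype_id"]).mean()
        r = stats.spearmanr(cm.sort_index(), raw.sort_index()).statistic
        assert r > 0.9999  # balanced design: uniform shrinkage keeps the order


class TestPearson:
    def test_exact_correlations(self):
        x = np.arange(10.0)
        r, lo, hi = pearson_with_ci(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson_with_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_ci_coverage(self):
        rng = np.random.default_rng(39)
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        covered = 0
        n_sim = 1000
        for _ in range(n_sim):
            xy = rng.multivariate_normal([0, 0], cov, size=300)
            _, lo, hi = pearson_with_ci(xy[:, 0], xy[:, 1])
            covered += lo <= rho <= hi
        assert abs(covered / n_sim - 0.95) < 0.02

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestOnewayF:
    def test_published_tail_value(self):
        # the F(1,685) = 3.385 replicate comparison: upper tail = 0.07 (2 dp)
        p = float(stats.f.sf(3.385, 1, 685))
        assert round(p, 2) == 0.07

    def test_identical_groups(self):
        f, d1, d2, mse, p = oneway_f_test([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert f == 0.0 and p == 1.0

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(40)
        for _ in range(10):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 1, 15)
            f, d1, d2, mse, p = oneway_f_test(
                np.concatenate([a, b]), [0] * 12 + [1] * 15
            )
            t = stats.ttest_ind(a, b)
            assert f == pytest.approx(t.statistic**2, rel=1e-10)
            assert p == pytest.approx(t.pvalue, rel=1e-10)

    def test_permutation_oracle(self):
        rng = np.random.default_rng(41)
        y = rng.normal(0, 1, 20)
        g = np.array([0] * 10 + [1] * 10)
        f_obs, _, _, _, p = oneway_f_test(y, g)
        perm = np.empty(10_000)
        for i in range(10_000):
            perm[i] = oneway_f_test(y, rng.permutation(g))[0]
        p_perm = float(np.mean(perm >= f_obs - 1e-12))
        se = max(np.sqrt(p_perm * (1 - p_perm) / 10_000), 1e-4)
        assert abs(p - p_perm) <= 3 * se + 0.01  # normal-theory vs permutation

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_f_test([1.0, 2.0], [0, 0])


class TestRegress:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, se, p = regress(2 * x + 1, x)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_negative_coupling_detected(self):
        # aftermath-on-heading regression recovers the built-in negative slope
        rng = np.random.default_rng(42)
        n_neg = 0
        for _ in range(40):
            heading = rng.normal(50, 3, 60)
            aftermath = 5 - 0.4 * (heading - 50) + rng.normal(0, 1, 60)
            slope, *_ = regress(aftermath, heading)
            n_neg += slope < 0
        assert n_neg / 40 >= 0.95

    def test_shift_invariance_and_constant_x(self):
        rng = np.random.default_rng(43)
        x = rng.normal(0, 1, 30)
        y = 2 * x + rng.normal(0, 1, 30)
        s1, *_ = regress(y, x)
        s2, *_ = regress(y + 100.0, x)
        assert s1 == pytest.approx(s2)
        with pytest.raises(ValueError):
            regress(y, np.zeros(30))
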