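"""Kruskal-Wallis machinery, BH q-values and the per-family scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fsibqtl import simdata as sd
from fsibqtl.assoc import SkippedTest, bh_qvalues, chisq_sf, kruskal_wallis, run_family_scan
from fsibqtl.filtering import select_testcross_markers

from conftest import toy_matrix


class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1..6, rank sums 6 and 15: H = (12/42)(12+75) - 21 = 3.857
        h, df, p = kruskal_wallis([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert h == pytest.approx(27 / 7, abs=1e-9)
        assert df == 1

    def test_identical_values_guarded(self):
        h, df, p = kruskal_wallis([3.0] * 8, list("AAAABBBB"))
        assert h == 0.0 and p == 1.0

    def test_single_group_skipped(self):
        with pytest.raises(SkippedTest):
            kruskal_wallis([1.0, 2.0, np.nan], ["A", "A", "B"])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            y = rng.integers(0, 6, size=40).astype(float)  # heavy ties
            g = rng.integers(0, 3, size=40)
            if len(np.unique(g)) < 2 or len(np.unique(y)) < 2:
                continue
            h, df, p = kruskal_wallis(y, g)
            ref = stats.kruskal(*(y[g == k] for k in np.unique(g)))
            assert h == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_permutation_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 30)
        g = np.array([0] * 15 + [1] * 15)
        h, _, p = kruskal_wallis(y, g)
        perm = np.empty(10_000)
        for i in range(10_000):
            hp, _, _ = kruskal_wallis(y, rng.permutation(g))
            perm[i] = hp
        p_perm = float(np.mean(perm >= h - 1e-12))
        se = np.sqrt(p_perm * (1 - p_perm) / 10_000)
        assert abs(p - p_perm) <= 3 * se

    def test_two_group_equals_squared_wilcoxon(self):
        # with two groups H equals the squared standardized rank-sum statistic
        rng = np.random.default_rng(11)
        for _ in range(10):
            n1, n2 = rng.integers(5, 20, 2)
            y = rng.normal(0, 1, n1 + n2)
            g = np.array([0] * n1 + [1] * n2)
            h, _, _ = kruskal_wallis(y, g)
            ranks = stats.rankdata(y)
            w = ranks[g == 0].sum()
            n = n1 + n2
            z = (w - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12)
            assert h == pytest.approx(z**2, rel=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=8, max_size=30),
        st.floats(0.1, 5.0),
        st.floats(-10, 10),
    )
    def test_monotone_transform_invariance(self, vals, scale, shift):
        g = np.arange(len(vals)) % 2
        if len(np.unique(vals)) < 2:
            return
        h1, _, _ = kruskal_wallis(vals, g)
        transformed = scale * np.asarray(vals) + shift  # strictly monotone
        if len(np.unique(transformed)) != len(np.unique(vals)):
            return  # float rounding collapsed distinct values: not monotone
        h2, _, _ = kruskal_wallis(transformed, g)
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestChisqSf:
    @pytest.mark.parametrize(
        "x,df,expected,rel",
        [
            (16.05, 1, 6.15e-5, 0.025),  # printed two-decimal statistic
            (12.69, 1, 0.00036, 0.025),
            (10.83, 1, 0.00099, 0.025),
            (0.0, 1, 1.0, 1e-12),
            (3.8415, 1, 0.05, 1e-4),
        ],
    )
    def test_tail_values(self, x, df, expected, rel):
        assert chisq_sf(x, df) == pytest.approx(expected, rel=rel)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chisq_sf(-1.0, 1)


class TestBhQvalues:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_qvalues([0.01, 0.04, 0.9]), [0.03, 0.06, 0.9])

    def test_single_and_empty(self):
        assert bh_qvalues([0.2]) == pytest.approx([0.2])
        assert bh_qvalues([]).size == 0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_qvalues(p), q_ref, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_q_geq_p_and_sorted_monotone(self, pvals):
        q = bh_qvalues(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_fdr_control_mixed_simulation(self):
        # 10% shifted alternatives among nulls: BH at 0.05 controls FDR
        rng = np.random.default_rng(9)
        fdrs = []
        for _ in range(200):
            p_null = rng.uniform(0, 1, 180)
            z = rng.normal(3.5, 1, 20)
            p_alt = stats.norm.sf(z)
            p = np.concatenate([p_null, p_alt])
            is_null = np.arange(200) < 180
            q = bh_qvalues(p)
            rejected = q <= 0.05
            if rejected.any():
                fdrs.append(np.mean(is_null[rejected]))
        assert np.mean(fdrs) <= 0.05 + 2.576 * np.std(fdrs) / np.sqrt(len(fdrs))


class TestFamilyScan:
    def _family_with_qtl(self, seed, effect=2.0, var_explained=0.3):
        gmap = sd.make_genetic_map(1, 100.0, 101, seed=seed)
        loci = sd.make_loci(gmap, scaffolds_per_lg=20)
        parents = sd.make_parent_pair(
            loci, "F", seed=seed + 1, p_testcross=1.0, p_hethet=0.0, cross_mode="F1_fullsib"
        )
        fam = sd.simulate_family(parents, loci, 60, seed=seed + 2)
        resid = np.sqrt(effect**2 * 0.25 * (1 - var_explained) / var_explained)
        spec = sd.QTLSpec(
            qtls=[sd.QTL(1, 50.0, effect)], family_mean=50.0, residual_sd=resid
        )
        ph, _ = sd.simulate_phenotypes(fam, spec, years=(2015,), reps=(1,), seed=seed + 3)
        return fam, ph.set_index("genotype_id")["heading_days"]

    def test_id_mismatch_raises(self):
        gm = toy_matrix(np.ones((2, 4)) * np.array([0, 1, 0, 1]))
        with pytest.raises(KeyError, match="missing"):
            run_family_scan(gm, {"F_000": 1.0}, family_id="F")

    def test_qtl_recovery_rate(self):
        hits = 0
        reps = 40
        for r in range(reps):
            fam, y = self._family_with_qtl(5000 + 10 * r)
            sel, _ = select_testcross_markers(fam)
            scan = run_family_scan(sel, y, family_id="F")
            best = scan.loc[scan["p_value"].idxmin()]
            sites = sel.sites
            cm = sites.loc[
                (sites["scaffold"] == best["scaffold"]) & (sites["pos_bp"] == best["pos_bp"]),
                "pos_cm",
            ].iloc[0]
            hits += abs(cm - 50.0) <= 10.0
        assert hits / reps >= 0.80

    def test_permuted_phenotype_type_one_error(self):
        rng = np.random.default_rng(21)
        fam, y = self._family_with_qtl(8000)
        sel, _ = select_testcross_markers(fam)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        scan = run_family_scan(sel, y_perm, family_id="F")
        frac = (scan["p_value"] < 0.05).mean()
        m = len(scan)
        # markers are linked, so allow inflation of the binomial CI
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / m) + 0.05

    def test_scan_output_contract(self):
        fam, y = self._family_with_qtl(9000)
        sel, _ = select_testcross_markers(fam)
        scan = run_family_scan(sel, y, trait="heading", family_id="F")
        assert {"scaffold", "pos_bp", "H", "df", "p_value", "q_value"} <= set(scan.columns)
        assert (scan["df"] == 1).all()
        assert np.all(scan["q_value"] >= scan["p_value"] - 1e-12)
        assert scan.attrs["m_tests"] == len(scan)
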