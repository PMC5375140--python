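"""Core statistics: summaries, F_ST, Fisher, LD, Tajima's D, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mitoscan.popgen import (
    bh_fdr,
    fisher_exact_allele,
    ld_pairs,
    ld_scan,
    locus_summaries,
    tajimas_d,
    wc_theta,
    weir_cockerham_fst,
)

from .conftest import make_gm
from .oracles import (
    bh_stepup_reference,
    fisher_two_sided_exact,
    tajimas_d_reference,
    wc_theta_scalar,
)


class TestLocusSummaries:
    def test_hand_computed_counts(self):
        # counts AA=1, Aa=2, aa=1 -> p=0.5, Ho=0.5, He=2*0.25*(8/7)
        gm = make_gm(np.array([[0], [1], [1], [2]]))
        s = locus_summaries(gm)
        assert s["miaf"][0] == pytest.approx(0.5)
        assert s["ho"][0] == pytest.approx(0.5)
        assert s["he"][0] == pytest.approx(2 * 0.25 * 8 / 7)

    def test_all_heterozygous_and_monomorphic(self):
        gm = make_gm(np.array([[1, 0], [1, 0], [1, 0]]))
        s = locus_summaries(gm)
        assert s["ho"][0] == 1.0
        assert s["miaf"][1] == 0.0 and s["ho"][1] == 0.0 and s["he"][1] == 0.0

    def test_call_rate_ignores_missing_in_frequencies(self):
        gm = make_gm(np.array([[2], [np.nan], [0], [2]]))
        s = locus_summaries(gm)
        assert s["call_rate"][0] == pytest.approx(0.75)
        assert s["miaf"][0] == pytest.approx(min(4 / 6, 2 / 6))


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        d = np.vstack([np.full((10, 1), 2.0), np.full((10, 1), 0.0)])
        theta, *_ = wc_theta(d, np.array(["a"] * 10 + ["b"] * 10))
        assert theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups_nonpositive(self):
        # same sample allele frequencies and heterozygote counts in both
        block = np.array([[0.0], [1.0], [1.0], [2.0]])
        d = np.vstack([block, block])
        theta, *_ = wc_theta(d, np.array(["a"] * 4 + ["b"] * 4))
        assert theta[0] <= 0.0

    def test_matches_scalar_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            d = rng.integers(0, 3, size=(8, 1)).astype(float)
            d[rng.random((8, 1)) < 0.1] = np.nan
            labels = np.array(["a"] * 4 + ["b"] * 4)
            expected = wc_theta_scalar([d[:4, 0], d[4:, 0]])
            theta, *_ = wc_theta(d, labels)
            if np.isnan(expected):
                assert np.isnan(theta[0])
            else:
                assert theta[0] == pytest.approx(expected, abs=1e-12)

    def test_three_group_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(12, 5)).astype(float)
        labels = np.repeat(["a", "b", "c"], 4)
        theta, *_ = wc_theta(d, labels)
        for j in range(5):
            exp = wc_theta_scalar([d[:4, j], d[4:8, j], d[8:, j]])
            if np.isnan(exp):
                assert np.isnan(theta[j])
            else:
                assert theta[j] == pytest.approx(exp, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_allele_and_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(10, 3)).astype(float)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        theta, *_ = wc_theta(d, labels)
        theta_flip, *_ = wc_theta(2.0 - d, labels)
        swapped = np.where(labels == "a", "b", "a")
        theta_swap, *_ = wc_theta(d, swapped)
        np.testing.assert_allclose(theta, theta_flip, atol=1e-12)
        np.testing.assert_allclose(theta, theta_swap, atol=1e-12)

    def test_monomorphic_undefined_and_multilocus(self, toy_gm):
        d = np.zeros((6, 1))
        theta, *_ = wc_theta(d, np.array(["a"] * 3 + ["b"] * 3))
        assert np.isnan(theta[0])
        table, multi = weir_cockerham_fst(toy_gm, toy_gm.mt_labels())
        ok = table.dropna(subset=["a"])
        assert multi == pytest.approx(
            ok["a"].sum() / (ok["a"] + ok["b"] + ok["c"]).sum()
        )


class TestFisherExact:
    def test_disjoint_fixed_table(self):
        # alleles completely separated by group: p = 2 / C(20, 10)
        d = np.vstack([np.full((5, 1), 2.0), np.zeros((5, 1))])
        gm = make_gm(d, mt=["north"] * 5 + ["south"] * 5)
        p = fisher_exact_allele(gm, gm.mt_labels())["fisher_p"][0]
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_balanced_table_is_one(self):
        d = np.vstack([np.full((5, 1), 1.0), np.full((5, 1), 1.0)])
        gm = make_gm(d, mt=["north"] * 5 + ["south"] * 5)
        assert fisher_exact_allele(gm, gm.mt_labels())["fisher_p"][0] == 1.0

    def test_transpose_invariance_via_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            p1 = fisher_two_sided_exact(a, b, c, d)
            p2 = fisher_two_sided_exact(a, c, b, d)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_scipy_matches_exact_enumeration_sample(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 10, size=4)
            expected = fisher_two_sided_exact(int(a), int(b), int(c), int(d))
            got = sps.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(expected, abs=1e-12)


class TestLD:
    def test_duplicated_locus_perfect_ld(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, size=(40, 1)).astype(float)
        gm = make_gm(np.hstack([col, col]))
        out = ld_pairs(gm, np.array([0]), np.array([1]))
        assert out["r2"][0] == pytest.approx(1.0, abs=1e-12)
        assert out["d_prime"][0] == pytest.approx(1.0, abs=1e-6)

    def test_mean_r2_under_linkage_equilibrium(self):
        # independent loci: E[sample r^2] = 1/(n-1) for n diploid dosages
        rng = np.random.default_rng(6)
        n, L = 100, 400
        d = rng.binomial(2, 0.4, size=(n, L)).astype(float)
        gm = make_gm(d, scaffolds=[f"s{j}" for j in range(L)], positions=[100] * L)
        out = ld_pairs(gm, np.arange(0, L - 1, 2), np.arange(1, L, 2))
        assert out["r2"].mean() == pytest.approx(1.0 / (n - 1), rel=0.25)

    def test_em_recovers_hand_built_haplotypes(self):
        # 6 individuals from phased haplotypes with no double
        # heterozygote, so phase (hence the haplotype counts) is
        # unambiguous: AB/AB, AB/Ab, ab/ab, aB/ab, Ab/ab, AB/aB
        pairs = [
            ((1, 1), (1, 1)),
            ((1, 1), (1, 0)),
            ((0, 0), (0, 0)),
            ((0, 1), (0, 0)),
            ((1, 0), (0, 0)),
            ((1, 1), (0, 1)),
        ]
        d = np.array([[h1[0] + h2[0], h1[1] + h2[1]] for h1, h2 in pairs], dtype=float)
        gm = make_gm(d)
        out = ld_pairs(gm, np.array([0]), np.array([1]))
        # counts: AB=4, Ab=2, aB=2, ab=4 of 12 -> D = 1/3 - 1/4, Dmax = 1/4
        assert out["d_prime"][0] == pytest.approx((1 / 3 - 1 / 4) / (1 / 4), abs=1e-6)

    def test_em_matches_numerical_mle_with_double_heterozygotes(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(11)
        d = rng.binomial(2, [0.5, 0.4], size=(30, 2)).astype(float)
        gm = make_gm(d)
        out = ld_pairs(gm, np.array([0]), np.array([1]))

        counts = np.zeros((3, 3))
        for g1, g2 in d.astype(int):
            counts[g1, g2] += 1

        def neg_loglik(x):
            f11, f10, f01 = x
            f00 = 1.0 - f11 - f10 - f01
            if min(f11, f10, f01, f00) <= 0:
                return 1e9
            ll = 0.0
            for g1 in range(3):
                for g2 in range(3):
                    if counts[g1, g2] == 0:
                        continue
                    pr = 0.0
                    hap1 = [(1, 1, f11), (1, 0, f10), (0, 1, f01), (0, 0, f00)]
                    for a1, b1, fa in hap1:
                        for a2, b2, fb in hap1:
                            if a1 + a2 == g1 and b1 + b2 == g2:
                                pr += fa * fb
                    ll += counts[g1, g2] * np.log(pr)
            return -ll

        best = min(
            (
                minimize(
                    neg_loglik,
                    x0,
                    method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12},
                )
                for x0 in ([0.25, 0.25, 0.25], [0.4, 0.1, 0.1], [0.1, 0.4, 0.1])
            ),
            key=lambda r: r.fun,
        )
        f11, f10, f01 = best.x
        p, q = f11 + f10, f11 + f01
        dcoef = f11 - p * q
        dmax = min(p * (1 - q), (1 - p) * q) if dcoef >= 0 else min(p * q, (1 - p) * (1 - q))
        assert out["d_prime"][0] == pytest.approx(dcoef / dmax, abs=1e-4)

    def test_monomorphic_member_dropped_and_window(self):
        d = np.hstack(
            [np.zeros((10, 1)), np.random.default_rng(1).integers(0, 3, (10, 3)).astype(float)]
        )
        gm = make_gm(d)
        out = ld_scan(gm, window_snps=2)
        assert not (out["locus_i"] == "l0").any()
        # window of 2 -> only adjacent pairs
        assert all(
            int(i[1:]) + 1 == int(j[1:]) for i, j in zip(out["locus_i"], out["locus_j"])
        )


class TestTajimasD:
    def test_empty_window_undefined(self):
        gm = make_gm(np.zeros((6, 2)), positions=[5, 20])
        out = tajimas_d(gm, window_bp=50)
        assert len(out) == 1 and out["S"][0] == 0 and np.isnan(out["D"][0])

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, [0.3, 0.45, 0.2], size=(10, 3)).astype(float)
        gm = make_gm(d, positions=[3, 17, 41])
        out = tajimas_d(gm, window_bp=50)
        freqs = [d[:, j].sum() / 20 for j in range(3)]
        expected = tajimas_d_reference(freqs, n_seq=20)
        assert out["D"][0] == pytest.approx(expected, abs=1e-10)

    def test_window_width_merges_consistently(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.3, size=(12, 4)).astype(float)
        gm = make_gm(d, positions=[10, 60, 110, 160])
        narrow = tajimas_d(gm, window_bp=50)
        wide = tajimas_d(gm, window_bp=100)
        assert narrow["S"].sum() == wide["S"].sum()
        assert len(wide) == 2 and (wide["S"] == 2).all()
        for _, row in wide.iterrows():
            in_win = [
                j
                for j in range(4)
                if row.window_start <= gm.loci["pos"][j] - 1 < row.window_start + 100
            ]
            freqs = [d[:, j].sum() / 24 for j in in_win]
            assert row.D == pytest.approx(tajimas_d_reference(freqs, 24), abs=1e-10)


class TestBHFDR:
    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_passthrough(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_reference_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 60))
            q = bh_fdr(p)
            np.testing.assert_array_equal(q, bh_stepup_reference(p))
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-15
            )

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_dominates_p_and_bounded(self, plist):
        p = np.array(plist)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and q.max() <= 1.0
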