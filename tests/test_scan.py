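"""The wF_ST scan, permutation null, outlier calling and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoscan.scan import (
    call_outliers,
    empirical_p,
    fst_density_compare,
    permutation_null,
    scan_concordance,
    wfst_scan,
    PermutationNull,
)
from mitoscan.simulate import SimScenario, simulate_genotypes

from .conftest import make_gm
from .oracles import hypergeom_sf_exact


class TestWfstScan:
    def test_relabel_symmetry(self, null_cohort):
        gm, _ = null_cohort
        labels = gm.mt_labels()
        flipped = np.where(labels == "north", "south", "north")
        a = wfst_scan(gm, labels)["fst"]
        b = wfst_scan(gm, flipped)["fst"]
        np.testing.assert_allclose(a, b, atol=1e-12, equal_nan=True)

    def test_null_distribution_straddles_zero(self, null_cohort):
        gm, _ = null_cohort
        fst = wfst_scan(gm)["fst"].dropna()
        assert (fst > 0).any() and (fst < 0).any()
        assert abs(fst.mean()) < 0.02

    def test_planted_exceed_null(self):
        sc = SimScenario(n_individuals=155, n_loci=1500, n_planted=100, seed=21)
        gm, truth = simulate_genotypes(sc)
        fst = wfst_scan(gm).set_index(gm.loci["locus_id"])["fst"]
        planted = fst.index.isin(truth.planted_locus_ids)
        assert fst[planted].mean() > fst[~planted].mean()

    def test_unknown_mt_excluded(self, null_cohort):
        gm, _ = null_cohort
        labels = gm.mt_labels().copy()
        labels[:5] = "unknown"
        out = wfst_scan(gm, labels)
        assert len(out) == gm.n_loci  # loci preserved, individuals dropped


class TestPermutationNull:
    def test_determinism(self, null_cohort):
        gm, _ = null_cohort
        n1 = permutation_null(gm, n_perm=120, seed=7)
        n2 = permutation_null(gm, n_perm=120, seed=7)
        for a, b in zip(n1.null_values, n2.null_values):
            np.testing.assert_array_equal(a, b)

    def test_shuffling_individuals_changes_nothing(self, null_cohort):
        gm, _ = null_cohort
        order = np.random.default_rng(0).permutation(gm.n_individuals)
        gm2 = gm.take_samples(order)
        a = wfst_scan(gm)["fst"]
        b = wfst_scan(gm2)["fst"]
        np.testing.assert_allclose(a, b, atol=1e-12, equal_nan=True)

    def test_calibration_under_null(self, null_cohort):
        gm, _ = null_cohort
        null = permutation_null(gm, n_perm=200, seed=13)
        p = empirical_p(wfst_scan(gm)["fst"].to_numpy(), null)
        p = p[~np.isnan(p)]
        # p approximately uniform: both tails populated
        assert sps.kstest(p, "uniform").pvalue > 1e-4
        assert np.quantile(np.concatenate(null.null_values), 0.99) < 0.1

    def test_he_stratification_changes_p(self):
        # He gradient: low-MiAF loci have different null theta dispersion,
        # so a binned p differs from the pooled-null p for some loci
        rng = np.random.default_rng(3)
        n, L = 100, 400
        freqs = np.concatenate([np.full(L // 2, 0.03), np.full(L // 2, 0.5)])
        d = rng.binomial(2, freqs, size=(n, L)).astype(float)
        gm = make_gm(d, mt=["north"] * 40 + ["south"] * 60)
        binned = permutation_null(gm, n_perm=150, he_bins=8, seed=5)
        pooled = permutation_null(gm, n_perm=150, he_bins=1, seed=5)
        theta = wfst_scan(gm)["fst"].to_numpy()
        p_b = empirical_p(theta, binned)
        p_p = empirical_p(theta, pooled)
        assert binned.n_bins > 1
        assert np.nanmax(np.abs(p_b - p_p)) > 0.01

    def test_min_perm_guard(self, null_cohort):
        gm, _ = null_cohort
        with pytest.raises(ValueError):
            permutation_null(gm, n_perm=50)

    def test_sparse_bins_merged(self, null_cohort):
        gm, _ = null_cohort
        null = permutation_null(gm, n_perm=120, he_bins=10, seed=1, min_bin_count=10**9)
        assert null.n_bins == 1  # everything merged into one bin


class TestEmpiricalP:
    @staticmethod
    def _null_of(values):
        v = np.sort(np.asarray(values, dtype=np.float32))
        return PermutationNull(
            n_permutations=1, group_sizes=(1, 1), bin_edges=np.array([0.0, 1.0]),
            bin_of_locus=np.zeros(1, dtype=int), null_values=[v], seed=0,
        )

    def test_add_one_rule_extremes(self):
        null = self._null_of(np.linspace(-0.1, 0.1, 99_999))
        p = empirical_p(np.array([0.5]), null)
        assert p[0] == pytest.approx(1e-5)

    def test_median_gives_half(self):
        null = self._null_of(np.linspace(-1, 1, 10001))
        p = empirical_p(np.array([0.0]), null)
        assert p[0] == pytest.approx(0.5, abs=0.001)

    def test_within_one_over_m_of_naive(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=5000)
        null = self._null_of(vals)
        for theta in rng.normal(size=50):
            p = empirical_p(np.array([theta]), null)[0]
            naive = (np.sort(vals) >= theta).sum() / len(vals)
            assert abs(p - naive) <= 1.0 / (len(vals) + 1) + 1e-12

    def test_undefined_theta_propagates(self):
        null = self._null_of([0.0, 0.1])
        assert np.isnan(empirical_p(np.array([np.nan]), null)[0])


class TestCallOutliers:
    def test_hand_bh_example(self):
        p = np.array([0.001] * 5 + [0.5] * 95)
        stats = pd.DataFrame({"locus_id": [f"l{i}" for i in range(100)], "p_perm": p})
        out = call_outliers(stats)
        assert out["outlier_fdr10"].sum() == 5
        assert set(out.loc[out["outlier_fdr10"], "locus_id"]) == {f"l{i}" for i in range(5)}

    def test_uniform_p_expectations(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=10000)
        out = call_outliers(pd.DataFrame({"locus_id": np.arange(10000), "p_perm": p}))
        assert 60 <= out["outlier"].sum() <= 140
        assert out["outlier_fdr1"].sum() <= 2

    def test_threshold_sets_nested(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(size=500), rng.uniform(0, 1e-4, size=20)])
        out = call_outliers(pd.DataFrame({"locus_id": np.arange(520), "p_perm": p}))
        assert (out["outlier_bonferroni"] <= out["outlier_fdr1"]).all()
        assert (out["outlier_fdr1"] <= out["outlier_fdr10"]).all()
        assert (out["outlier_fdr10"] <= out["outlier"]).all()


class TestConcordance:
    def test_identical_sets(self):
        u = set(range(100))
        a = set(range(10))
        r = scan_concordance(a, a, u)
        assert r["jaccard"] == 1.0 and r["enrichment_p"] < 1e-12

    def test_study_scale_overlap_matches_exact_oracle(self):
        # overlap structure at the study's scale: 349- and 229-locus
        # sets sharing 219 loci of 11,705
        u = set(range(11705))
        a = set(range(349))
        b = set(range(219)) | set(range(11000, 11010))
        r = scan_concordance(a, b, u)
        assert r["n_overlap"] == 219
        expected = hypergeom_sf_exact(219, 11705, 349, 229)
        assert r["enrichment_p"] == pytest.approx(expected, rel=1e-6)

    def test_random_sets_expected_overlap(self):
        rng = np.random.default_rng(7)
        u = np.arange(2000)
        overlaps = []
        for _ in range(50):
            a = set(rng.choice(u, 200, replace=False))
            b = set(rng.choice(u, 100, replace=False))
            overlaps.append(scan_concordance(a, b, set(u))["n_overlap"])
        assert np.mean(overlaps) == pytest.approx(200 * 100 / 2000, abs=1.5)

    def test_disjoint_universe_rejected(self):
        with pytest.raises(ValueError):
            scan_concordance({1}, {999}, {1, 2, 3})


class TestFstDensityCompare:
    def test_self_comparison_near_zero(self):
        sc = SimScenario(n_individuals=100, n_loci=400, n_planted=0, missing_rate=0.0, seed=31)
        gm, _ = simulate_genotypes(sc)
        south = gm.take_samples(gm.mt_labels() == "south")
        out = fst_density_compare(gm, south, outlier_ids=set())
        sv = out.loc[out["comparison"] == "south_vs_external", "fst"].dropna()
        assert abs(sv.mean()) < 0.01

    def test_directional_shift_toward_closer_population(self):
        # external population built from the south group's frequencies:
        # north-vs-external densities sit right of south-vs-external
        sc = SimScenario(n_individuals=155, n_loci=600, n_planted=200,
                         planted_delta=0.25, seed=32, missing_rate=0.0)
        gm, truth = simulate_genotypes(sc)
        south = gm.take_samples(gm.mt_labels() == "south")
        out = fst_density_compare(gm, south, outlier_ids=truth.planted_locus_ids)
        nv = out.loc[out["comparison"] == "north_vs_external", "fst"].dropna()
        sv = out.loc[out["comparison"] == "south_vs_external", "fst"].dropna()
        assert nv.mean() > sv.mean()
        # all four comparisons exported over the same locus universe
        assert set(out["comparison"]) == {
            "within_outlier", "within_nonoutlier", "north_vs_external", "south_vs_external",
        }
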