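"""Windowed F_ST / PBS / H12 statistics, peak calling and permutation nulls."""

import numpy as np
import pytest

from resistscan.selection import (
    delta_h12, detect_outlier_windows, estimate_mode, h12_from_haplotypes,
    hudson_fst_components, permutation_filter, window_slices, windowed_fst,
    windowed_h12, windowed_pbs,
)
from resistscan.simulate import SimConfig, SweepSpec, simulate_cohort

from conftest import make_genotype_data


def hudson_site_oracle(g1, g2):
    """Per-site Hudson components by explicit allele counting."""
    nums, dens = [], []
    for j in range(g1.shape[1]):
        a1 = g1[:, j][g1[:, j] >= 0]
        a2 = g2[:, j][g2[:, j] >= 0]
        n1, n2 = 2 * len(a1), 2 * len(a2)
        if n1 < 2 or n2 < 2:
            nums.append(0.0)
            dens.append(0.0)
            continue
        p1, p2 = a1.sum() / n1, a2.sum() / n2
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        nums.append(num)
        dens.append(den)
    return np.array(nums), np.array(dens)


class TestHudsonFst:
    def test_identical_groups_fst_at_finite_sample_floor(self, rng):
        # the unbiased numerator subtracts sampling variance, so literally
        # identical groups sit slightly below 0, vanishing as n grows
        geno = rng.integers(0, 3, size=(200, 40)).astype(np.int8)
        g = make_genotype_data(np.vstack([geno, geno]))
        ids = g.sample_ids
        scan = windowed_fst(g, ids[:200], ids[200:], window_snps=40)
        assert scan.values[0] <= 0.0
        assert abs(scan.values[0]) < 0.01

    def test_fixed_difference_fst_one(self):
        geno = np.vstack([np.zeros((8, 30)), np.full((8, 30), 2)])
        g = make_genotype_data(geno.astype(np.int8))
        ids = g.sample_ids
        scan = windowed_fst(g, ids[:8], ids[8:], window_snps=30)
        assert scan.values[0] == pytest.approx(1.0)

    def test_matches_per_site_loop_oracle(self, rng):
        geno = rng.integers(0, 3, size=(20, 1000)).astype(np.int8)
        g = make_genotype_data(geno)
        ids = g.sample_ids
        scan = windowed_fst(g, ids[:10], ids[10:], window_snps=1000)
        num, den = hudson_site_oracle(geno[:10], geno[10:])
        assert scan.values[0] == pytest.approx(num.sum() / den.sum(),
                                               abs=1e-12)
        assert scan.values[0] <= 1.0

    def test_sib_average_equals_single_subset_without_sibs(self, rng):
        geno = rng.integers(0, 3, size=(12, 50)).astype(np.int8)
        g = make_genotype_data(geno)
        ids = g.sample_ids
        plain = windowed_fst(g, ids[:6], ids[6:], window_snps=50)
        averaged = windowed_fst(g, ids[:6], ids[6:],
                                sib_subsets=[ids], window_snps=50)
        np.testing.assert_allclose(plain.values, averaged.values)

    def test_sib_averaging_is_mean_over_subsets(self, rng):
        geno = rng.integers(0, 3, size=(12, 50)).astype(np.int8)
        g = make_genotype_data(geno)
        ids = g.sample_ids
        subsets = [ids[:10], ids[2:]]
        avg = windowed_fst(g, ids[:6], ids[6:], sib_subsets=subsets,
                           window_snps=50)
        v1 = windowed_fst(g, ids[:6], ids[6:10], window_snps=50).values
        v2 = windowed_fst(g, ids[2:6], ids[6:], window_snps=50).values
        np.testing.assert_allclose(avg.values, (v1 + v2) / 2)

    def test_zero_denominator_window_is_nan(self):
        geno = np.zeros((10, 30), dtype=np.int8)       # monomorphic
        g = make_genotype_data(geno)
        ids = g.sample_ids
        scan = windowed_fst(g, ids[:5], ids[5:], window_snps=30)
        assert np.isnan(scan.values[0])


class TestPbs:
    def test_all_fst_zero_gives_zero(self, rng):
        geno = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        g = make_genotype_data(np.vstack([geno, geno, geno]))
        ids = g.sample_ids
        scan = windowed_pbs(g, ids[:6], ids[6:12], ids[12:], window_snps=30)
        assert scan.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_branch_lengths(self):
        # PBS from known F values: F_RS=F_RO=0.2, F_SO=0 -> -log(0.8)
        t_rs = t_ro = -np.log(1 - 0.2)
        t_so = 0.0
        assert (t_rs + t_ro - t_so) / 2 == pytest.approx(0.22314, abs=1e-4)

    def test_branch_sum_identity(self, rng):
        geno = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        g = make_genotype_data(geno)
        ids = g.sample_ids
        r, s, o = ids[:10], ids[10:20], ids[20:]
        pbs_r = windowed_pbs(g, r, s, o, window_snps=200).values
        pbs_s = windowed_pbs(g, s, r, o, window_snps=200).values
        pbs_o = windowed_pbs(g, o, r, s, window_snps=200).values
        # sum of the three branches = (T_RS + T_RO + T_SO) / 2
        from resistscan.selection import _clamped_branch, _fst_per_window
        slices = window_slices(g, 200)
        idx = {x: i for i, x in enumerate(ids)}
        gr = np.array([idx[x] for x in r])
        gs = np.array([idx[x] for x in s])
        go = np.array([idx[x] for x in o])
        t_rs = _clamped_branch(_fst_per_window(geno, gr, gs, slices))
        t_ro = _clamped_branch(_fst_per_window(geno, gr, go, slices))
        t_so = _clamped_branch(_fst_per_window(geno, gs, go, slices))
        np.testing.assert_allclose(pbs_r + pbs_s + pbs_o,
                                   (t_rs + t_ro + t_so) / 2, atol=1e-12)

    def test_symmetry_when_equidistant(self, rng):
        geno = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        far = np.clip(geno + rng.integers(0, 2, size=(8, 40)), 0, 2)
        g = make_genotype_data(
            np.vstack([geno, far, far]).astype(np.int8))
        ids = g.sample_ids
        a = windowed_pbs(g, ids[:8], ids[8:16], ids[16:], window_snps=40)
        b = windowed_pbs(g, ids[:8], ids[16:], ids[8:16], window_snps=40)
        np.testing.assert_allclose(a.values, b.values)


class TestH12:
    def test_all_identical_haplotypes_h12_one(self):
        hap = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (6, 1))
        assert h12_from_haplotypes(hap) == pytest.approx(1.0)

    def test_hand_enumeration_frequencies(self):
        # two identical + two distinct -> freqs (0.5, 0.25, 0.25)
        hap = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 1, 1]],
                       dtype=np.int8)
        assert h12_from_haplotypes(hap) == pytest.approx(0.625)

    def test_matches_frequency_spectrum_oracle(self, rng):
        for _ in range(5):
            hap = rng.integers(0, 2, size=(30, 8)).astype(np.int8)
            strings = ["".join(map(str, row)) for row in hap]
            from collections import Counter
            freqs = sorted(
                (c / 30 for c in Counter(strings).values()), reverse=True)
            expect = (freqs[0] + (freqs[1] if len(freqs) > 1 else 0)) ** 2 \
                + sum(f ** 2 for f in freqs[2:])
            assert h12_from_haplotypes(hap) == pytest.approx(expect)

    def test_h12_bounds_and_merge_monotonicity(self, rng):
        hap = rng.integers(0, 2, size=(40, 12)).astype(np.int8)
        h = h12_from_haplotypes(hap)
        assert 0 < h <= 1
        # relabelling the two most frequent classes identical never lowers H12
        vals, counts = np.unique(hap, axis=0, return_counts=True)
        top2 = np.argsort(counts)[-2:]
        merged = hap.copy()
        mask = (hap == vals[top2[0]]).all(axis=1)
        merged[mask] = vals[top2[1]]
        assert h12_from_haplotypes(merged) >= h - 1e-12

    def test_too_few_haplotypes_error(self):
        with pytest.raises(ValueError):
            h12_from_haplotypes(np.zeros((1, 5), dtype=np.int8))


class TestDeltaH12:
    def _phased_cohort(self, seed=0, sweep=None):
        specs = (sweep,) if sweep else ()
        return simulate_cohort(SimConfig(
            n_samples=60, n_variants=200, sweep_specs=specs,
            intercept=0.0, seed=seed))

    def test_identical_composition_delta_zero(self, rng):
        g, man, _ = self._phased_cohort()
        ids = g.sample_ids
        scan = delta_h12(g, ids[:30], ids[:30], window_snps=200)
        assert scan.values[0] == pytest.approx(0.0)

    def test_label_swap_antisymmetry(self):
        g, man, _ = self._phased_cohort(seed=3)
        ids = g.sample_ids
        a = delta_h12(g, ids[:30], ids[30:], window_snps=200)
        b = delta_h12(g, ids[30:], ids[:30], window_snps=200)
        np.testing.assert_allclose(a.values, -b.values)

    def test_resistant_only_sweep_positive_delta(self):
        sweep = SweepSpec(start=0, end=200, carrier_frac_resistant=0.6,
                          carrier_frac_susceptible=0.0, noise_rate=0.0)
        g, man, _ = self._phased_cohort(seed=4, sweep=sweep)
        pheno = man.phenotypes()
        res = [s for s, p in zip(g.sample_ids, pheno) if p == 1]
        sus = [s for s, p in zip(g.sample_ids, pheno) if p == 0]
        scan = delta_h12(g, res, sus, window_snps=200)
        assert scan.values[0] > 0.1


class TestOutlierWindows:
    def test_single_outlier_flagged(self, rng):
        values = np.concatenate([rng.normal(0, 0.01, 1000), [0.5]])
        flags = detect_outlier_windows(values)
        assert flags[-1]
        assert flags.sum() == 1

    def test_symmetric_sample_no_peaks(self, rng):
        values = rng.normal(0.2, 0.05, 500)
        m = estimate_mode(values)
        d = m - values.min()
        if values.max() < m + 3 * d:      # construction guard
            assert detect_outlier_windows(values).sum() == 0

    def test_translation_invariance(self, rng):
        values = np.concatenate([rng.normal(0, 0.01, 200), [0.3, 0.4]])
        f1 = detect_outlier_windows(values)
        f2 = detect_outlier_windows(values + 7.5)
        np.testing.assert_array_equal(f1, f2)

    def test_identical_values_no_peaks(self):
        flags = detect_outlier_windows(np.full(50, 0.3))
        assert flags.sum() == 0

    def test_requires_thirty_finite_values(self):
        with pytest.raises(ValueError):
            detect_outlier_windows(np.arange(10.0))

    def test_nan_windows_never_flagged(self, rng):
        values = np.concatenate([rng.normal(0, 0.01, 100), [np.nan, 0.5]])
        flags = detect_outlier_windows(values)
        assert not flags[-2]
        assert flags[-1]

    def test_histogram_mode_alternative(self, rng):
        values = np.concatenate([rng.normal(0, 0.01, 1000), [0.5]])
        flags = detect_outlier_windows(values, mode_method="histogram")
        assert flags[-1]


class TestPermutationFilter:
    def test_observed_above_all_permutations_retained(self, rng):
        observed = np.array([5.0, 0.0])
        provisional = np.array([True, True])

        def stat(perm):
            return rng.normal(0, 1, 2)

        retained, q = permutation_filter(stat, np.arange(10), observed,
                                         provisional, n_perm=200, seed=1)
        assert retained[0]
        assert not retained[1]
        assert np.isfinite(q).all()

    def test_observed_at_permutation_median_dropped(self, rng):
        observed = np.array([0.0])
        provisional = np.array([True])

        def stat(perm):
            return rng.normal(0, 1, 1)

        retained, _ = permutation_filter(stat, np.arange(10), observed,
                                         provisional, n_perm=200, seed=2)
        assert not retained[0]

    def test_centile_zero_retains_above_minimum(self, rng):
        draws = iter(rng.normal(0, 1, 300).reshape(300, 1))
        observed = np.array([0.0])
        provisional = np.array([True])
        collected = []

        def stat(perm):
            v = next(draws)
            collected.append(v[0])
            return v

        retained, q = permutation_filter(stat, np.arange(10), observed,
                                         provisional, n_perm=200,
                                         centile=0.0, seed=3)
        assert q[0] == pytest.approx(min(collected))
        assert retained[0] == (observed[0] > min(collected))

    def test_non_provisional_windows_have_nan_quantile(self, rng):
        observed = np.zeros(3)
        provisional = np.array([True, False, True])

        def stat(perm):
            return rng.normal(0, 1, 3)

        _, q = permutation_filter(stat, np.arange(10), observed, provisional,
                                  n_perm=50, seed=4)
        assert np.isnan(q[1])
        assert np.isfinite(q[0]) and np.isfinite(q[2])


class TestWindowing:
    def test_trailing_partial_window_dropped(self, rng):
        geno = rng.integers(0, 3, size=(4, 2500)).astype(np.int8)
        g = make_genotype_data(geno)
        slices = window_slices(g, 1000)
        assert len(slices) == 2

    def test_windows_per_chromosome(self, rng):
        import pandas as pd
        geno = rng.integers(0, 3, size=(4, 250)).astype(np.int8)
        g = make_genotype_data(geno)
        g.variants.loc[100:, "chrom"] = "3L"
        slices = window_slices(g, 100)
        assert [c for c, _ in slices] == ["2R", "3L"]
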