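"""Summary statistics against hand-computed and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demodfe import sumstats as ss


class TestTajimasD:
    def test_hand_computed_four_haplotype_toy(self, tiny_sample):
        # n=4, S=3, pi=5/3: D evaluates to +0.1677 from Tajima's constants
        d = ss.tajimas_d(tiny_sample, ss.WindowSpec(1_000, 1_000))
        assert d.shape == (1,)
        assert d[0] == pytest.approx(0.16766, abs=1e-4)

    def test_matches_tskit_on_simulated_data(self):
        import msprime
        import tskit

        ts = msprime.sim_ancestry(samples=10, population_size=1000,
                                  sequence_length=50_000, random_seed=5)
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=6,
                                   model=msprime.BinaryMutationModel(),
                                   discrete_genome=False)
        counts = ts.genotype_matrix().sum(axis=1)
        ours = ss.tajimas_d_counts(counts, 20)
        assert ours == pytest.approx(ts.Tajimas_D(), abs=1e-10)

    def test_two_haplotypes_give_zero_when_defined(self):
        geno = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.uint8)
        s = ss.HaplotypeSample(positions=[1.0, 2.0, 3.0], genotypes=geno,
                               populations=np.repeat("AFR", 2), length=10)
        d = ss.tajimas_d(s, ss.WindowSpec(10, 10))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_is_nan(self):
        s = ss.HaplotypeSample(positions=np.zeros(0), genotypes=np.zeros((4, 0)),
                               populations=np.repeat("AFR", 4), length=10_000)
        assert np.isnan(ss.tajimas_d(s, ss.WindowSpec(10_000, 10_000))).all()

    def test_single_haplotype_errors(self):
        s = ss.HaplotypeSample(positions=[1.0], genotypes=np.ones((1, 1)),
                               populations=np.array(["AFR"]), length=10)
        with pytest.raises(ValueError):
            ss.tajimas_d(s)


class TestSegregatingSites:
    def test_per_site_density(self):
        geno = np.zeros((4, 5), dtype=np.uint8)
        geno[0, :] = 1
        geno[:, 4] = 1  # fixed derived: not segregating
        s = ss.HaplotypeSample(positions=np.arange(5, dtype=float) * 10,
                               genotypes=geno, populations=np.repeat("AFR", 4),
                               length=10_000)
        assert ss.segregating_sites_per_site(s) == pytest.approx(4 / 10_000)

    def test_masked_site_excluded_from_numerator_and_denominator(self):
        geno = np.zeros((4, 6), dtype=np.uint8)
        geno[0, :] = 1
        s = ss.HaplotypeSample(positions=np.arange(6, dtype=float) * 100,
                               genotypes=geno, populations=np.repeat("AFR", 4),
                               length=6_000)
        masked = s.apply_mask(np.array([[0, 150]]))  # masks sites at 0 and 100
        assert masked.accessible_bp == 6_000 - 150
        assert ss.segregating_sites_per_site(masked) == pytest.approx(4 / 5_850)

    def test_zero_accessible_errors(self):
        s = ss.HaplotypeSample(positions=np.zeros(0), genotypes=np.zeros((2, 0)),
                               populations=np.repeat("AFR", 2), length=100,
                               accessible_bp=0)
        with pytest.raises(ValueError):
            ss.segregating_sites_per_site(s)


class TestLinkageDisequilibrium:
    @pytest.mark.parametrize(
        "haplotypes, expected",
        [
            ([[0, 0], [0, 0], [1, 1], [1, 1]], 1.0),       # perfect coupling
            ([[0, 0], [0, 1], [1, 0], [1, 1]], 0.0),       # all four gametes
            ([[0, 0], [0, 1], [1, 1], [1, 1]], 1.0 / 3.0), # D=0.125 hand case
        ],
    )
    def test_hand_computed_r2(self, haplotypes, expected):
        geno = np.asarray(haplotypes, dtype=np.uint8)
        s = ss.HaplotypeSample(positions=[10.0, 20.0], genotypes=geno,
                               populations=np.repeat("AFR", geno.shape[0]),
                               length=100)
        assert ss.mean_r2(s, ss.WindowSpec(100, 100))[0] == pytest.approx(expected)

    def test_single_site_window_is_nan(self):
        s = ss.HaplotypeSample(positions=[10.0], genotypes=np.array([[0], [1]]),
                               populations=np.repeat("AFR", 2), length=100)
        assert np.isnan(ss.mean_r2(s, ss.WindowSpec(100, 100))[0])


class TestFst:
    def _two_pop(self, c1, c2, n1=10, n2=10):
        geno = np.zeros((n1 + n2, 1), dtype=np.uint8)
        geno[:c1, 0] = 1
        geno[n1 : n1 + c2, 0] = 1
        pops = np.repeat(["A", "B"], [n1, n2])
        return ss.HaplotypeSample(positions=[5.0], genotypes=geno,
                                  populations=pops, length=10)

    def test_hand_computed_hudson_value(self):
        # p1=0.2, p2=0.8: numerator 0.324444..., denominator 0.68
        s = self._two_pop(2, 8)
        assert ss.hudson_fst(s, "A", "B") == pytest.approx(0.3244444 / 0.68, abs=1e-6)

    def test_identical_frequencies_give_near_zero(self):
        # equal counts leave only the O(1/(n-1)) finite-sample correction,
        # which is negative and vanishes with sample size
        s = self._two_pop(30, 30, n1=100, n2=100)
        f = ss.hudson_fst(s, "A", "B")
        assert f <= 0.0
        assert abs(f) < 0.02

    def test_fixed_difference_approaches_one(self):
        s = self._two_pop(100, 0, n1=100, n2=100)
        assert ss.hudson_fst(s, "A", "B") == pytest.approx(1.0, abs=0.02)

    def test_weir_cockerham_flag(self):
        s = self._two_pop(2, 8)
        wc = ss.fst(s, "A", "B", estimator="weir_cockerham")
        hudson = ss.fst(s, "A", "B", estimator="hudson")
        assert 0 < wc <= 1 and abs(wc - hudson) < 0.2

    def test_all_monomorphic_is_nan(self):
        geno = np.ones((20, 1), dtype=np.uint8)
        s = ss.HaplotypeSample(positions=[5.0], genotypes=geno,
                               populations=np.repeat(["A", "B"], 10), length=10)
        assert np.isnan(ss.hudson_fst(s, "A", "B"))


class TestDivergence:
    def test_hand_counted_fixed_differences(self):
        ref = "A" * 10_000
        anc = list(ref)
        for i in [3, 10, 20, 30, 40, 50, 60, 100, 200]:
            anc[i] = "G"
        # 9 differences, 2 of them at polymorphic (masked) sites
        d = ss.divergence_from_sequences(ref, "".join(anc), [3, 10], 10_000)
        assert d == pytest.approx(7 / 10_000)

    def test_identical_sequences(self):
        assert ss.divergence_from_sequences("ACGT" * 10, "ACGT" * 10, []) == 0.0

    def test_fixation_count_definition(self):
        assert ss.divergence_from_fixations(5, 1_000) == pytest.approx(5e-3)


class TestH12:
    def test_direct_formula_evaluation(self):
        assert ss.h12_from_frequencies([0.4, 0.3, 0.2, 0.1]) == pytest.approx(0.54)

    def test_all_identical_haplotypes(self):
        geno = np.ones((6, 3), dtype=np.uint8)
        s = ss.HaplotypeSample(positions=[10.0, 20.0, 30.0], genotypes=geno,
                               populations=np.repeat("AFR", 6), length=100)
        assert ss.h12(s, 20.0, 100) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_all_distinct_closed_form(self, n):
        # all p_i = 1/n: H12 = (2/n)^2 + (n-2)/n^2
        freqs = np.full(n, 1.0 / n)
        assert ss.h12_from_frequencies(freqs) == pytest.approx(
            (2.0 / n) ** 2 + (n - 2) / n**2)

    def test_empty_window_errors(self, tiny_sample):
        with pytest.raises(ValueError):
            ss.h12(tiny_sample, 900.0, 10)


class TestAggregation:
    def test_mean_of_region_sds(self):
        df = pd.DataFrame({
            "region": ["a"] * 2 + ["b"] * 2,
            "replicate": [0, 1, 0, 1],
            "value": [0.0, 0.2, 1.0, 1.6],  # SDs ~0.1414, 0.4243
        })
        point, bar, per_region = ss.aggregate_replicates(df)
        assert point == pytest.approx((0.1 + 1.3) / 2)
        assert bar == pytest.approx((np.std([0, 0.2], ddof=1) + np.std([1.0, 1.6], ddof=1)) / 2)

    def test_identical_replicates_have_zero_sd(self):
        df = pd.DataFrame({"region": ["a"] * 3, "replicate": range(3), "value": [2.0] * 3})
        _, bar, _ = ss.aggregate_replicates(df)
        assert bar == 0.0

    def test_region_sd_calibration_against_chi_square_bound(self):
        rng = np.random.default_rng(11)
        rows = []
        for region in range(10):
            for rep, v in enumerate(rng.normal(0, 1, size=100)):
                rows.append(dict(region=region, replicate=rep, value=v))
        _, bar, per_region = ss.aggregate_replicates(pd.DataFrame(rows))
        assert ((per_region["std"] > 0.8) & (per_region["std"] < 1.2)).all()


class TestStatVector:
    def test_vector_has_eighteen_named_entries(self, four_pop_sample):
        vec = ss.stat_vector(four_pop_sample)
        assert len(vec) == 18
        assert tuple(vec.index) == ss.STAT_NAMES
        assert vec.notna().all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_statistic_ranges(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(2, 30))
        geno = rng.integers(0, 2, size=(16, n_sites)).astype(np.uint8)
        pos = np.sort(rng.choice(10_000, size=n_sites, replace=False)).astype(float)
        s = ss.HaplotypeSample(positions=pos, genotypes=geno,
                               populations=np.repeat(["A", "B"], 8), length=10_000)
        r2 = ss.mean_r2(s, ss.WindowSpec(10_000, 10_000))[0]
        if not np.isnan(r2):
            assert 0.0 <= r2 <= 1.0 + 1e-12
        h = ss.h12(s, float(pos[0]), 20_000)
        assert 0.0 < h <= 1.0
        f = ss.hudson_fst(s, "A", "B")
        if not np.isnan(f):
            assert -0.5 <= f <= 1.0
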