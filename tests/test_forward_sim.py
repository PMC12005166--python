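"""Forward Wright–Fisher engine: DFE draws, layout arithmetic, calibration,
conditioned sweeps."""

import numpy as np
import pytest
from scipy import stats as sps

from demodfe import forward_sim as fs


class TestDFE:
    def test_neutral_only_class(self):
        dfe = fs.DFEModel(n_ref=5_000, f=(1.0, 0.0, 0.0, 0.0))
        rng = np.random.default_rng(1)
        for _ in range(50):
            s, label = fs.draw_fitness_effect(dfe, rng)
            assert label == "f0"
            assert -1.0 / (2 * 5_000) < s <= 0.0  # 2Ns < 1 -> effectively neutral

    def test_class_frequencies_pass_chi_square(self):
        dfe = fs.DFEModel(n_ref=5_000, f=(0.4, 0.3, 0.2, 0.1))
        rng = np.random.default_rng(2)
        labels = [fs.draw_fitness_effect(dfe, rng)[1] for _ in range(100_000)]
        counts = [labels.count(f"f{i}") for i in range(4)]
        _, p = sps.chisquare(counts, f_exp=np.array([0.4, 0.3, 0.2, 0.1]) * 100_000)
        assert p > 0.01

    def test_beneficial_unit_conversion(self):
        dfe = fs.DFEModel(n_ref=5_000, f=(0.9, 0.0, 0.0, 0.0), f_b=0.1,
                          beneficial_range=(100.0, 1_000.0))
        rng = np.random.default_rng(3)
        drawn = [fs.draw_fitness_effect(dfe, rng) for _ in range(2_000)]
        bene = [s for s, lab in drawn if lab == "beneficial"]
        assert bene and all(0.01 <= s < 0.1 for s in bene)

    def test_rebalancing_preserves_total(self):
        dfe = fs.DFEModel(n_ref=100)
        out = dfe.with_beneficial(0.01, (1.0, 10.0))
        assert sum(out.f) + out.f_b == pytest.approx(1.0)
        with pytest.raises(ValueError):
            dfe.with_beneficial(0.5, (1.0, 10.0))


class TestLayout:
    def test_sweep_chromosome_totals_198345(self):
        layout = fs.assemble_sweep_chromosome()
        assert layout.total_length == 198_345
        assert layout.exonic_bp() == 7 * 9 * 1_317

    def test_single_exon(self):
        layout = fs.ChromosomeLayout([("exon", 1_317)])
        assert layout.total_length == 1_317

    def test_coordinates_contiguous_and_disjoint(self):
        layout = fs.assemble_sweep_chromosome(n_functional=2)
        all_iv = np.vstack([layout.intervals(k) for k in ("exon", "intron", "intergenic")])
        all_iv = all_iv[np.argsort(all_iv[:, 0])]
        assert all_iv[0, 0] == 0
        assert (all_iv[1:, 0] == all_iv[:-1, 1]).all()
        assert all_iv[-1, 1] == layout.total_length

    def test_element_lookup(self):
        layout = fs.ChromosomeLayout([("exon", 100), ("intron", 50), ("intergenic", 100)])
        codes = layout.element_at(np.array([0, 99, 100, 149, 150, 249]))
        assert list(codes) == [fs.EXON, fs.EXON, fs.INTRON, fs.INTRON,
                               fs.INTERGENIC, fs.INTERGENIC]


class TestNeutralDynamics:
    def test_zero_mutation_rate_stays_empty(self):
        layout = fs.ChromosomeLayout([("intergenic", 10_000)])
        res = fs.run_forward(layout, None, 0.0, 1e-8, 50, divergence_generations=50,
                             sample_sizes={"AFR": 10}, seed=1)
        assert res.samples["AFR"].positions.size == 0
        assert len(res.fixations) == 0

    def test_determinism_under_fixed_seed(self):
        layout = fs.ChromosomeLayout([("intergenic", 5_000)])
        a = fs.run_forward(layout, None, 1e-6, 1e-7, 30, divergence_generations=30,
                           sample_sizes={"AFR": 5}, seed=42)
        b = fs.run_forward(layout, None, 1e-6, 1e-7, 30, divergence_generations=30,
                           sample_sizes={"AFR": 5}, seed=42)
        assert np.array_equal(a.samples["AFR"].positions, b.samples["AFR"].positions)
        assert np.array_equal(a.samples["AFR"].genotypes, b.samples["AFR"].genotypes)

    def test_neutral_fixation_probability(self):
        """A neutral allele at one copy fixes with probability ~ 1/(2N):
        conditioned restart counts are geometric with that success rate."""
        n = 20
        layout = fs.ChromosomeLayout([("intergenic", 1_000)])
        cfg = fs.SweepConfig(model_id=1, two_ns=0.0, restart_cap=2_000)
        restarts = []
        for seed in range(30):
            res = fs.run_conditioned_sweep(cfg, layout, None, 0.0, 0.0, n,
                                           divergence_generations=400,
                                           sample_sizes={"AFR": 5}, seed=seed)
            restarts.append(res.restarts)
        mean_restarts = np.mean(restarts)
        # expectation 2N - 1 = 39; generous 3x band per the small sample
        assert mean_restarts < 3 * 2 * n
        assert mean_restarts > 2 * n / 3


class TestPiecewiseRate:
    def test_mass_and_mean(self):
        pr = fs.PiecewiseRate(np.array([0.0, 100.0, 200.0]), np.array([1e-8, 3e-8]))
        assert pr.mass == pytest.approx(100 * 1e-8 + 100 * 3e-8)
        assert pr.mean_rate == pytest.approx(2e-8)

    def test_replicate_map_mean_is_exact(self):
        rng = np.random.default_rng(5)
        pr = fs.replicate_rate_map(198_345, 1.5e-8, rng, n_segments=20)
        assert pr.mean_rate == pytest.approx(1.5e-8, rel=1e-9)

    def test_positions_follow_rate_density(self):
        pr = fs.PiecewiseRate(np.array([0.0, 100.0, 200.0]), np.array([0.0, 1e-6]))
        rng = np.random.default_rng(6)
        pos = pr.sample_positions(rng, 500)
        assert (pos >= 100).all() and (pos < 200).all()


class TestConditionedSweeps:
    def test_strong_sweep_fixes_with_few_restarts(self):
        layout = fs.ChromosomeLayout([("exon", 5_000)])
        cfg = fs.SweepConfig(model_id=1, two_ns=10_000.0)
        res = fs.run_conditioned_sweep(cfg, layout, None, 1e-7, 1e-8, 50,
                                       divergence_generations=100,
                                       sample_sizes={"AFR": 10}, seed=7)
        assert res.restarts <= 10
        assert "AFR" in res.sweep_fixed_in

    def test_conditioning_sets_match_model_id(self):
        assert fs.SweepConfig(1).conditioning_populations == ("AFR", "EUR", "EAS", "SAS")
        assert fs.SweepConfig(2).conditioning_populations == ("EUR", "EAS", "SAS")
        assert fs.SweepConfig(3).conditioning_populations == ("EUR",)
        with pytest.raises(ValueError):
            fs.SweepConfig(4)

    def test_beneficial_fixations_logged_in_exonic_elements(self):
        layout = fs.ChromosomeLayout([("intergenic", 2_000), ("exon", 2_000),
                                      ("intergenic", 2_000)])
        cfg = fs.SweepConfig(model_id=1, two_ns=5_000.0)
        res = fs.run_conditioned_sweep(cfg, layout, None, 1e-7, 1e-8, 50,
                                       divergence_generations=150,
                                       sample_sizes={"AFR": 10}, seed=9)
        sweep_rows = res.fixations[res.fixations["s"] > 0]
        assert (sweep_rows["element"] == "exon").all()


class TestRecurrent:
    def test_zero_beneficial_rate_identical_to_plain_run(self):
        layout = fs.ChromosomeLayout([("exon", 5_000)])
        dfe = fs.DFEModel(n_ref=50)
        a = fs.run_forward(layout, dfe, 1e-6, 1e-8, 50, divergence_generations=60,
                           sample_sizes={"AFR": 5}, seed=3)
        b = fs.run_recurrent_sweeps(layout, dfe, 0.0, (100.0, 1_000.0), 1e-6, 1e-8,
                                    50, divergence_generations=60,
                                    sample_sizes={"AFR": 5}, seed=3)
        assert np.array_equal(a.samples["AFR"].genotypes, b.samples["AFR"].genotypes)


class TestScalingConsistency:
    def test_rescaled_runs_match_diversity(self):
        """kappa-rescaled runs (N/k, mu*k, r*k, t/k) agree on pi within
        sampling error."""
        layout = fs.ChromosomeLayout([("intergenic", 20_000)])
        means = {}
        for kappa, reps in ((1, 30), (2, 30)):
            n = 100 // kappa
            pis = []
            for rep in range(reps):
                res = fs.run_forward(layout, None, 1e-6 * kappa, 1e-7 * kappa, n,
                                     divergence_generations=100 // kappa,
                                     sample_sizes={"AFR": 10}, seed=100 + rep)
                s = res.samples["AFR"]
                nh = s.n_haplotypes
                c = s.genotypes.sum(axis=0)
                pis.append(np.sum(2.0 * c * (nh - c) / (nh * (nh - 1))) / s.length)
            means[kappa] = np.mean(pis)
        assert means[2] == pytest.approx(means[1], rel=0.35)
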