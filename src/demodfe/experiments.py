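"""Desk-scale study definitions shared by the analysis drivers and tests.

The empirical study behind this package ran cluster-scale simulations of
1000 Genomes-sized data; the experiments here reproduce its *procedures* at
desk scale: a known truth model generates synthetic data, and the same
machinery (curation, summary statistics, grid search, forward simulation,
sweep scans) is run against it.  Problem sizes are chosen so each experiment
runs in minutes on one CPU; docs/methods.md records the choices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import forward_sim as fs
from . import gridfit, sweepscan
from .demography import FREE_PARAMETERS, OOADemography, RegionSimRequest, simulate_region
from .sumstats import WindowSpec, stat_vector

#: diploid sample sizes for desk-scale experiments
DESK_SAMPLE_SIZES = {"AFR": 5, "EUR": 5, "EAS": 5, "SAS": 5}


def desk_truth_model() -> OOADemography:
    """The desk-scale OOA-like truth model used throughout the synthetic
    studies (sizes in the thousands, times in the low thousands of
    generations; qualitatively an out-of-Africa history).  The founding
    bottleneck of the Eurasian population is kept recent relative to the
    dispersal times so that its severity leaves a detectable signature at
    this scale."""
    return OOADemography(
        N_AFR_anc=2_000, tau_BANTU=200, r_AFR=0.002,
        tau_OOA=2_000, B_EURASI=0.05, N_EURASI=1_500,
        B_EUR=0.25, B_EAS=0.25, B_SAS=0.25,
        N_EUR=1_000, N_EAS=1_000, N_SAS=1_000,
        tau_EUR=800, tau_EAS=700, tau_SAS=700,
        r_EUR=0.002, r_EAS=0.002, r_SAS=0.002,
        m_AFR_EURASI=1e-4, m_AFR_EUR=2e-5, m_AFR_EAS=1e-5, m_AFR_SAS=1e-5,
        m_EUR_EAS=5e-5, m_EUR_SAS=5e-5, m_EAS_SAS=5e-5,
        bottleneck_duration=200.0,
    )


def collapse_to_single_population(n: float, model: OOADemography | None = None) -> OOADemography:
    """All structure removed: B = 1, r = 0, m = 0, splits pushed to the very
    recent past, every size n — coalescent-equivalent to one constant
    population of size n."""
    base = model or desk_truth_model()
    return base.with_parameters(
        N_AFR_anc=n, N_EURASI=n, N_EUR=n, N_EAS=n, N_SAS=n,
        B_EURASI=1.0, B_EUR=1.0, B_EAS=1.0, B_SAS=1.0,
        r_AFR=0.0, r_EUR=0.0, r_EAS=0.0, r_SAS=0.0,
        tau_BANTU=1.0, tau_OOA=3.0, tau_EUR=1.0, tau_EAS=1.0, tau_SAS=1.0,
        **{k: 0.0 for k in FREE_PARAMETERS if k.startswith("m_")},
    )


def make_region_requests(
    n_regions: int,
    replicates: int,
    seed: int,
    length: int = 20_000,
    sample_sizes: dict[str, int] | None = None,
) -> list[RegionSimRequest]:
    """Synthetic curated-region set with per-region rates drawn once."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_regions):
        out.append(RegionSimRequest(
            region_id=f"region{i:03d}", length=length,
            mean_mu=float(rng.uniform(1.2e-8, 1.8e-8)),
            mean_rec=float(rng.uniform(1e-8, 2e-8)),
            sample_sizes=dict(sample_sizes or DESK_SAMPLE_SIZES),
            replicates=replicates, seed=int(rng.integers(1, 2**31 - 1)),
        ))
    return out


def regions_stat_table(
    model: OOADemography,
    requests: list[RegionSimRequest],
    windows: WindowSpec | None = None,
) -> pd.DataFrame:
    """Per (region, replicate) 18-statistic rows."""
    windows = windows or WindowSpec()
    rows = []
    for req in requests:
        for rep, sample in enumerate(simulate_region(model, req)):
            vec = stat_vector(sample, windows)
            rows.append(dict(region=req.region_id, replicate=rep, **vec.to_dict()))
    return pd.DataFrame(rows)


def aggregate_stat_table(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(mean of region means, across-region SD of region means) per statistic."""
    stats = [c for c in table.columns if c not in ("region", "replicate")]
    per_region = table.groupby("region")[stats].mean()
    return per_region.mean(), per_region.std()


def recovery_evaluator(
    base_model: OOADemography,
    requests: list[RegionSimRequest],
    master_seed: int,
    eval_replicates: int | None = None,
    windows: WindowSpec | None = None,
):
    """Evaluation callback for the grid search.

    Candidate parameters are substituted into the base model and the
    aggregated 18-statistic vector is simulated.  Seeds derive from the
    master seed and the (region, replicate) pair only — common random
    numbers across candidate points — so that differences between evaluated
    points reflect the parameters rather than Monte Carlo noise.
    """
    windows = windows or WindowSpec()

    def evaluate(params: dict[str, float]) -> pd.Series:
        model = base_model.with_parameters(**params)
        reqs = [RegionSimRequest(
            r.region_id, r.length, r.mean_mu, r.mean_rec, dict(r.sample_sizes),
            eval_replicates or r.replicates,
            seed=(master_seed + 7919 * i) % (2**31 - 1) + 1)
            for i, r in enumerate(requests)]
        table = regions_stat_table(model, reqs)
        mean, _ = aggregate_stat_table(table)
        return mean

    return evaluate


#: the 3-free-parameter reduction used for desk-scale parameter recovery.
#: The truth sits on each grid away from the midpoint start, so the search
#: must move along every axis; grid resolution matches what 20 regions x 20
#: replicates of 20 kb can actually discriminate (about 1,000 generations /
#: 1,000 diploids / 0.2 in severity at the fine step).
RECOVERY_GRID_RANGES = {
    "N_AFR_anc": (2_000.0, 6_000.0),  # truth 2000 at the low edge
    "tau_OOA": (2_000.0, 6_000.0),    # truth 2000 at the low edge
    "B_EURASI": (0.05, 0.85),         # truth 0.05 at the low edge
}


def recovery_trial(
    trial_seed: int,
    n_regions: int = 20,
    replicates: int = 20,
    grid_points: int = 3,
    refinement_factor: int = 2,
    region_length: int = 20_000,
    coarse_replicates: int = 6,
    fine_replicates: int = 20,
) -> dict:
    """One seeded parameter-recovery trial on the 3-parameter reduction.

    Synthetic "empirical" data are simulated at the truth point (which lies
    on the grid); the coarse+fine search must return it.  The coarse
    factorial pass uses a cheap evaluator (large steps carry a large
    signal); the fine stage, whose steps are small, evaluates at the data's
    own replicate depth.
    """
    truth = desk_truth_model()
    assert all(
        np.isclose(np.linspace(lo, hi, grid_points), getattr(truth, k)).any()
        for k, (lo, hi) in RECOVERY_GRID_RANGES.items()
    ), "truth point must lie on the coarse grid"
    requests = make_region_requests(n_regions, replicates, seed=trial_seed,
                                    length=region_length)
    emp_table = regions_stat_table(truth, requests)
    emp_mean, emp_sd = aggregate_stat_table(emp_table)

    grid = gridfit.ParameterGrid.from_ranges(RECOVERY_GRID_RANGES, grid_points)
    eval_coarse = recovery_evaluator(truth, requests, master_seed=trial_seed + 10_007,
                                     eval_replicates=coarse_replicates)
    eval_fine = recovery_evaluator(truth, requests, master_seed=trial_seed + 10_007,
                                   eval_replicates=fine_replicates)
    coarse = gridfit.coarse_search(grid, emp_mean, emp_sd, eval_coarse)
    # re-anchor the coarse optimum's distance at the fine evaluator's depth
    coarse.distance = gridfit.distance(eval_fine(coarse.best_params), emp_mean, emp_sd)
    fine = gridfit.fine_search(coarse, grid, emp_mean, emp_sd, eval_fine,
                               refinement_factor=refinement_factor)
    truth_point = {k: float(getattr(truth, k)) for k in RECOVERY_GRID_RANGES}
    # recovered iff the fitted point is the truth grid point
    hit = all(np.isclose(fine.best_params[k], truth_point[k]) for k in truth_point)
    return dict(hit=bool(hit), best=fine.best_params, truth=truth_point,
                distance=fine.distance, evaluations=len(fine.trace))


def recovery_rate(n_trials: int, seed: int, **kwargs) -> tuple[float, list[dict]]:
    results = [recovery_trial(seed + 1_000 * t, **kwargs) for t in range(n_trials)]
    return float(np.mean([r["hit"] for r in results])), results


# ---------------------------------------------------------------------------
# neutral calibrations

def neutral_coalescent_calibration(
    n: int = 500, mu: float = 1e-8, rec: float = 1e-8, length: int = 100_000,
    replicates: int = 200, seed: int = 1, sample_haplotypes: int = 20,
) -> dict:
    """Single-population neutral equilibrium through the coalescent path:
    mean pi vs 4 N mu, and mean Tajima's D (whole region as one window)."""
    model = collapse_to_single_population(n)
    req = RegionSimRequest(
        "neutral", length, mu, rec,
        sample_sizes={"AFR": sample_haplotypes // 2, "EUR": 1, "EAS": 1, "SAS": 1},
        replicates=replicates, seed=seed)
    pis, Ds = [], []
    for sample in simulate_region(model, req):
        sub = sample.for_population("AFR")
        nh = sub.n_haplotypes
        c = sub.genotypes.sum(axis=0)
        pis.append(float(np.sum(2.0 * c * (nh - c) / (nh * (nh - 1))) / length))
        from .sumstats import tajimas_d
        D = tajimas_d(sub, WindowSpec(length, length))
        Ds.append(float(D[0]))
    return dict(mean_pi=float(np.mean(pis)), expected_pi=4 * n * mu,
                pi_ratio=float(np.mean(pis) / (4 * n * mu)),
                mean_tajimas_d=float(np.nanmean(Ds)))


def neutral_forward_calibration(
    n: int = 50, mu: float = 1e-7, rec: float = 1e-7, length: int = 100_000,
    replicates: int = 100, seed: int = 1, sample_haplotypes: int = 20,
    divergence_generations: int = 150,
) -> dict:
    """Same neutral scenario through the forward engine (kappa-scaled)."""
    layout = fs.ChromosomeLayout([("intergenic", length)])
    pis, Ss = [], []
    for rep in range(replicates):
        res = fs.run_forward(layout, None, mu, rec, n,
                             divergence_generations=divergence_generations,
                             sample_sizes={"AFR": sample_haplotypes // 2},
                             seed=seed + rep)
        s = res.samples["AFR"]
        nh = s.n_haplotypes
        c = s.genotypes.sum(axis=0)
        poly = (c > 0) & (c < nh)
        pis.append(float(np.sum(2.0 * c * (nh - c) / (nh * (nh - 1))) / length))
        Ss.append(float(poly.sum() / length))
    return dict(mean_pi=float(np.mean(pis)), expected_pi=4 * n * mu,
                pi_ratio=float(np.mean(pis) / (4 * n * mu)),
                mean_s_per_site=float(np.mean(Ss)))


# ---------------------------------------------------------------------------
# selection experiments (forward engine)

BGS_LAYOUT = fs.ChromosomeLayout([("intergenic", 4_000), ("exon", 6_000), ("intergenic", 4_000)])


def bgs_pi_by_deleterious_fraction(
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5),
    replicates: int = 50,
    n: int = 64,
    mu_exon: float = 2.5e-5,
    mu_flank: float = 2e-6,
    rec: float = 1e-7,
    seed: int = 1,
    divergence_generations: int = 150,
) -> pd.DataFrame:
    """pi at linked neutral intergenic sites as the deleterious DFE fraction
    rises; background selection should depress it monotonically.

    The deleterious input goes into the moderately deleterious class (f2),
    the classical background-selection regime (2Ns of tens, expected
    reduction B ~ exp(-U / 2 s-bar)); the exon carries an elevated mutation
    rate so the deleterious input U is large enough to measure against the
    coalescent noise of the linked flanks, which mutate at a neutral rate
    used only to expose pi.
    """
    rows = []
    inter = BGS_LAYOUT.intervals("intergenic")
    inter_bp = int((inter[:, 1] - inter[:, 0]).sum())
    ex_iv = BGS_LAYOUT.intervals("exon")
    breaks = np.array([0.0, float(ex_iv[0, 0]), float(ex_iv[0, 1]),
                       float(BGS_LAYOUT.total_length)])
    mu_map = fs.PiecewiseRate(breaks, np.array([mu_flank, mu_exon, mu_flank]))
    for frac in fractions:
        dfe = fs.DFEModel(n_ref=n, f=(1.0 - frac, 0.0, frac, 0.0))
        for rep in range(replicates):
            res = fs.run_forward(BGS_LAYOUT, dfe, mu_map, rec, n,
                                 divergence_generations=divergence_generations,
                                 sample_sizes={"AFR": 10},
                                 seed=seed + rep + int(frac * 1e6))
            s = res.samples["AFR"]
            nh = s.n_haplotypes
            keep = np.zeros(s.positions.size, dtype=bool)
            for a, b in inter:
                keep |= (s.positions >= a) & (s.positions < b)
            c = s.genotypes[:, keep].sum(axis=0)
            pi = float(np.sum(2.0 * c * (nh - c) / (nh * (nh - 1))) / inter_bp)
            rows.append(dict(deleterious_fraction=frac, replicate=rep, pi=pi))
    return pd.DataFrame(rows)


def divergence_by_beneficial_rate(
    rates: tuple[float, ...] = (0.0, 0.001, 0.01, 0.1),
    replicates: int = 50,
    n: int = 100,
    mu: float = 1e-6,
    rec: float = 1e-7,
    seed: int = 1,
    divergence_generations: int = 600,
    beneficial_range: tuple[float, float] = (100.0, 1_000.0),
) -> pd.DataFrame:
    """Exonic divergence versus the beneficial mutation rate f_b at fixed
    strong s_b; a larger beneficial input must raise divergence."""
    layout = fs.ChromosomeLayout([("exon", 10_000)])
    dfe = fs.DFEModel(n_ref=n, f=(0.25, 0.49, 0.04, 0.22))
    rows = []
    for f_b in rates:
        for rep in range(replicates):
            res = fs.run_recurrent_sweeps(
                layout, dfe, f_b, beneficial_range, mu, rec, n,
                divergence_generations=divergence_generations,
                sample_sizes={"AFR": 10}, seed=seed + rep + int(f_b * 1e7))
            rows.append(dict(beneficial_rate=f_b, replicate=rep,
                             divergence=res.divergence("exon"),
                             n_fixations=len(res.fixations)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep power

def sweep_power_study(
    n_sweep: int = 40,
    n_null: int = 40,
    two_ns: float = 10_000.0,
    n: int = 100,
    mu: float = 1.2e-6,
    rec: float = 2e-7,
    seed: int = 1,
    sample_haplotypes: int = 20,
    tp_radius: float = 5_000.0,
    h12_width: int = 20_000,
) -> dict:
    """Scaled-down model-3-style recent hard sweep versus sweep-free null.

    A two-epoch reduction of the OOA history (ancestral population, recent
    EUR founding bottleneck) is run forward; the sweep arm introduces a
    strongly beneficial mutation into EUR at its founding and conditions on
    fixation there.  CLR and H12 scans on the EUR sample are summarised as
    replicate-level ROC AUCs, plus a placebo AUC (null vs null).

    The CLR scan grid always includes the substitution positions (a hard
    sweep removes the SNPs around its site, so a SNP-only grid can miss it);
    the sweep-arm CLR score is the track maximum within ``tp_radius`` of the
    true site.  H12 uses wide windows — at this scale the swept haplotype
    spans most of the 28 kb region — and both arms score their global
    maximum.
    """
    layout = fs.assemble_sweep_chromosome(n_functional=1)
    # EUR founding (and hence the model-3 sweep) is very recent so the sweep
    # is sampled with little post-fixation recovery — the best-case scenario
    # this power analysis represents
    model = desk_truth_model().with_parameters(
        N_AFR_anc=n, N_EURASI=int(0.8 * n), N_EUR=int(0.8 * n),
        N_EAS=20, N_SAS=20, tau_OOA=int(3.0 * n), tau_EUR=int(0.2 * n),
        tau_EAS=int(0.15 * n), tau_SAS=int(0.15 * n), tau_BANTU=int(0.4 * n),
        r_AFR=0.0, r_EUR=0.0, r_EAS=0.0, r_SAS=0.0,
        B_EURASI=0.3, B_EUR=0.3, B_EAS=0.3, B_SAS=0.3,
    )
    model = dataclasses.replace(model, bottleneck_duration=10.0)
    T = int(3.2 * n)
    dfe = fs.DFEModel(n_ref=n, f=(0.25, 0.49, 0.04, 0.22))
    n_dip = sample_haplotypes // 2
    sizes = {"EUR": n_dip}

    def scan_replicate(res):
        s = res.samples["EUR"]
        nh = s.n_haplotypes
        c = s.genotypes.sum(axis=0).astype(int)
        # sites derived in the sample: c == nh are substitutions relative to
        # the ancestor (fixed in the sampled population, e.g. hitchhikers of a
        # local sweep), pooled with the globally fixed sites from the log
        seen = c > 0
        pos = np.concatenate([s.positions[seen], res.substitution_positions()])
        cnt = np.concatenate([c[seen], np.full(len(res.fixations), nh)])
        order = np.argsort(pos, kind="stable")
        # drop duplicate coordinates (substitution colliding with a SNP)
        pos, cnt = pos[order], cnt[order]
        keep = np.concatenate([[True], np.diff(pos) > 0])
        return pos[keep], cnt[keep], s, res.substitution_positions()

    sweep_data, null_data = [], []
    for i in range(max(n_sweep, n_null)):
        if i < n_null:
            res = fs.run_forward(layout, dfe, mu, rec, n, T, sizes, model=model,
                                 seed=seed + 2 * i)
            null_data.append(scan_replicate(res))
        if i < n_sweep:
            cfg = fs.SweepConfig(model_id=3, two_ns=two_ns)
            res = fs.run_conditioned_sweep(cfg, layout, dfe, mu, rec, n, T, sizes,
                                           model=model, seed=seed + 2 * i + 1)
            sweep_data.append((scan_replicate(res), res.sweep_position))
    # background SFS from the sweep-free arm
    nh = sample_haplotypes
    bg = sweepscan.build_background_sfs(
        [c for _, c, _, _ in null_data], nh,
        [0] * len(null_data), pseudocount=0.5)

    def tracks(data, grid_step=4):
        clr, h12t = [], []
        for pos, cnt, sample, subs in data:
            sub_pos = np.concatenate([pos[cnt == nh], subs])
            grid = np.unique(np.concatenate([pos[::grid_step], sub_pos]))
            clr.append(sweepscan.clr_scan(pos, cnt, bg, grid, rec))
            h12t.append(sweepscan.h12_scan(sample, widths=(h12_width,))[h12_width])
        return clr, h12t

    null_clr, null_h12 = tracks(null_data)
    sweep_clr, sweep_h12 = tracks([d for d, _ in sweep_data])
    truth_pos = [float(p) for _, p in sweep_data]

    out = {}
    curve = sweepscan.roc(sweep_clr, null_clr, truth_pos, tp_radius=tp_radius)
    out["clr_auc"] = curve.auc
    out["h12_auc"] = sweepscan.roc_from_scores(
        np.array([t.global_max() for t in sweep_h12]),
        np.array([t.global_max() for t in null_h12])).auc
    # placebo: split the null arm in two (even/odd interleave)
    placebo_scores_a = [t.global_max() for t in null_clr[0::2]]
    placebo_scores_b = [t.global_max() for t in null_clr[1::2]]
    out["placebo_auc"] = sweepscan.roc_from_scores(
        np.asarray(placebo_scores_a), np.asarray(placebo_scores_b)).auc
    return out
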