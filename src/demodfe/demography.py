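"""The 25-parameter, 5-population Out-of-Africa demographic model.

Populations: an ancestral African population (AFR, sampled at present after
the Bantu expansion), an unsampled ancestral Eurasian population (EURASI),
and the European (EUR), East Asian (EAS) and South Asian (SAS) populations
dispersing from EURASI.  Parameters cover sizes, founding-bottleneck
severities B (fraction of the source population's size), exponential growth
rates, split times in generations, and symmetric pairwise migration rates.

The module owns model semantics, validation, event ordering and seeding;
coalescent replicates of curated regions are generated through msprime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np

from .sumstats import HaplotypeSample

GENERATION_TIME_YEARS = 26.9

#: the 25 free parameters, in registry order
FREE_PARAMETERS = (
    "N_AFR_anc", "tau_BANTU", "r_AFR",
    "tau_OOA", "B_EURASI", "N_EURASI",
    "B_EUR", "B_EAS", "B_SAS",
    "N_EUR", "N_EAS", "N_SAS",
    "tau_EUR", "tau_EAS", "tau_SAS",
    "r_EUR", "r_EAS", "r_SAS",
    "m_AFR_EURASI", "m_AFR_EUR", "m_AFR_EAS", "m_AFR_SAS",
    "m_EUR_EAS", "m_EUR_SAS", "m_EAS_SAS",
)

SAMPLED_POPULATIONS = ("AFR", "EUR", "EAS", "SAS")


def years_to_generations(
    years: float,
    generation_time: float = GENERATION_TIME_YEARS,
    nearest: float | None = None,
) -> float:
    """Convert years to generations at the model's generation time.

    ``nearest`` rounds the result to the given multiple (e.g. 100), matching
    the convention used for the 12 My human–chimpanzee divergence window
    (12e6 / 26.9 rounded to the nearest 100 = 446,100 generations).
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    gens = years / generation_time
    if nearest is not None:
        gens = round(gens / nearest) * nearest
    return gens


@dataclass
class OOADemography:
    """Parameter container; times in generations before present, sizes diploid,
    growth and migration rates per generation."""

    N_AFR_anc: float = 12_000.0
    tau_BANTU: float = 200.0
    r_AFR: float = 0.004
    tau_OOA: float = 3_000.0
    B_EURASI: float = 0.2
    N_EURASI: float = 3_000.0
    B_EUR: float = 0.25
    B_EAS: float = 0.25
    B_SAS: float = 0.25
    N_EUR: float = 2_000.0
    N_EAS: float = 2_000.0
    N_SAS: float = 2_000.0
    tau_EUR: float = 1_300.0
    tau_EAS: float = 1_100.0
    tau_SAS: float = 1_100.0
    r_EUR: float = 0.003
    r_EAS: float = 0.003
    r_SAS: float = 0.003
    m_AFR_EURASI: float = 1e-4
    m_AFR_EUR: float = 2e-5
    m_AFR_EAS: float = 1e-5
    m_AFR_SAS: float = 1e-5
    m_EUR_EAS: float = 5e-5
    m_EUR_SAS: float = 5e-5
    m_EAS_SAS: float = 5e-5
    generation_time_years: float = GENERATION_TIME_YEARS
    bottleneck_duration: float = 100.0  # founding-epoch length, generations

    def free_parameters(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FREE_PARAMETERS}

    def with_parameters(self, **updates: float) -> "OOADemography":
        unknown = set(updates) - set(FREE_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return dataclasses.replace(self, **updates)

    def scaled(self, kappa: float) -> "OOADemography":
        """Rescale by kappa: sizes and times / kappa, rates x kappa (for
        desk-scale forward simulation; coalescent-invariant to first order)."""
        upd = {}
        for name in FREE_PARAMETERS:
            v = getattr(self, name)
            if name.startswith(("N_", "tau_")):
                upd[name] = v / kappa
            else:  # growth and migration rates are per generation
                upd[name] = v * kappa
        out = self.with_parameters(**upd)
        return dataclasses.replace(out, bottleneck_duration=max(1.0, self.bottleneck_duration / kappa))


def validate_model(model: OOADemography) -> list[tuple[float, str]]:
    """Check invariants and return the time-sorted event list (time ago, label)."""
    p = model
    for name in ("N_AFR_anc", "N_EURASI", "N_EUR", "N_EAS", "N_SAS"):
        if getattr(p, name) <= 0:
            raise ValueError(f"{name} must be positive")
    for name in ("B_EURASI", "B_EUR", "B_EAS", "B_SAS"):
        b = getattr(p, name)
        if not (0 < b <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {b}")
    for name in ("tau_BANTU", "tau_OOA", "tau_EUR", "tau_EAS", "tau_SAS"):
        if getattr(p, name) <= 0:
            raise ValueError(f"{name} must be positive")
    for name in FREE_PARAMETERS:
        if name.startswith("m_") and getattr(p, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    if p.tau_OOA <= max(p.tau_EUR, p.tau_EAS, p.tau_SAS):
        raise ValueError("tau_OOA must exceed all dispersal times (tau_EUR/EAS/SAS)")
    assert len(FREE_PARAMETERS) == 25
    events = [
        (p.tau_BANTU, "AFR growth onset (Bantu expansion)"),
        (p.tau_EUR, "EUR splits from EURASI"),
        (p.tau_EAS, "EAS splits from EURASI"),
        (p.tau_SAS, "SAS splits from EURASI"),
        (p.tau_OOA, "EURASI splits from AFR"),
    ]
    return sorted(events)


def to_msprime(model: OOADemography) -> msprime.Demography:
    """Build the msprime Demography.

    Founding bottlenecks are a founding epoch of ``bottleneck_duration``
    generations at size B x source size, followed by the population's own N
    with exponential growth r to the present (present size N e^{r tau}).
    """
    p = model
    validate_model(p)
    d = msprime.Demography()
    dur = p.bottleneck_duration

    # AFR is sampled at present *and* is the ancestral population of the OOA
    # split, so it must be explicitly active from time 0
    d.add_population(name="AFR", initial_size=p.N_AFR_anc * np.exp(p.r_AFR * p.tau_BANTU),
                     growth_rate=p.r_AFR, initially_active=True)
    d.add_population(name="EURASI", initial_size=p.N_EURASI)
    for pop, N, r, tau in (
        ("EUR", p.N_EUR, p.r_EUR, p.tau_EUR),
        ("EAS", p.N_EAS, p.r_EAS, p.tau_EAS),
        ("SAS", p.N_SAS, p.r_SAS, p.tau_SAS),
    ):
        grow_span = max(tau - min(dur, tau / 2), 0.0)
        d.add_population(name=pop, initial_size=N * np.exp(r * grow_span), growth_rate=r)

    # AFR: constant ancestral size before the Bantu expansion
    d.add_population_parameters_change(time=p.tau_BANTU, population="AFR",
                                       initial_size=p.N_AFR_anc, growth_rate=0.0)

    # daughter founding bottlenecks + splits from EURASI
    for pop, B, tau in (("EUR", p.B_EUR, p.tau_EUR), ("EAS", p.B_EAS, p.tau_EAS),
                        ("SAS", p.B_SAS, p.tau_SAS)):
        t_bot = tau - min(dur, tau / 2)
        d.add_population_parameters_change(time=t_bot, population=pop,
                                           initial_size=max(B * p.N_EURASI, 2.0),
                                           growth_rate=0.0)
        d.add_population_split(time=tau, derived=[pop], ancestral="EURASI")

    # EURASI founding bottleneck + split from AFR
    t_bot = p.tau_OOA - min(dur, (p.tau_OOA - max(p.tau_EUR, p.tau_EAS, p.tau_SAS)) / 2)
    d.add_population_parameters_change(time=t_bot, population="EURASI",
                                       initial_size=max(p.B_EURASI * p.N_AFR_anc, 2.0),
                                       growth_rate=0.0)
    d.add_population_split(time=p.tau_OOA, derived=["EURASI"], ancestral="AFR")

    # symmetric migration while both populations exist
    pair_rates = {
        ("AFR", "EUR"): p.m_AFR_EUR, ("AFR", "EAS"): p.m_AFR_EAS,
        ("AFR", "SAS"): p.m_AFR_SAS, ("EUR", "EAS"): p.m_EUR_EAS,
        ("EUR", "SAS"): p.m_EUR_SAS, ("EAS", "SAS"): p.m_EAS_SAS,
    }
    end_time = {"EUR": p.tau_EUR, "EAS": p.tau_EAS, "SAS": p.tau_SAS, "AFR": np.inf}
    for (a, b), rate in pair_rates.items():
        if rate <= 0:
            continue
        d.set_symmetric_migration_rate([a, b], rate)
        stop = min(end_time[a], end_time[b])
        if np.isfinite(stop):
            d.add_symmetric_migration_rate_change(time=stop, populations=[a, b], rate=0.0)
    # AFR <-> EURASI: EURASI active (backward) from the most recent dispersal
    if p.m_AFR_EURASI > 0:
        start = min(p.tau_EUR, p.tau_EAS, p.tau_SAS)
        d.add_symmetric_migration_rate_change(time=start, populations=["AFR", "EURASI"],
                                              rate=p.m_AFR_EURASI)
        d.add_symmetric_migration_rate_change(time=p.tau_OOA, populations=["AFR", "EURASI"],
                                              rate=0.0)
    d.sort_events()
    return d


def to_json(model: OOADemography, path: str | None = None) -> str:
    """Native JSON serialization of the free parameters (plus the fixed
    generation time and bottleneck-epoch duration)."""
    import json

    payload = dict(model.free_parameters(),
                   generation_time_years=model.generation_time_years,
                   bottleneck_duration=model.bottleneck_duration)
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def from_json(source: str) -> OOADemography:
    """Inverse of :func:`to_json`; ``source`` is a path or a JSON string."""
    import json
    import os

    if os.path.exists(source):
        with open(source) as fh:
            payload = json.load(fh)
    else:
        payload = json.loads(source)
    fixed = {k: payload.pop(k) for k in ("generation_time_years", "bottleneck_duration")
             if k in payload}
    model = OOADemography().with_parameters(**payload)
    return dataclasses.replace(model, **fixed)


def to_demes(model: OOADemography) -> "object":
    """Demes graph of the model (EURASI persists until its most recent
    daughter dispersal; founding bottlenecks appear as explicit epochs)."""
    import demes

    p = model
    validate_model(p)
    dur = p.bottleneck_duration
    b = demes.Builder(time_units="generations")
    b.add_deme("AFR", epochs=[
        dict(end_time=p.tau_BANTU, start_size=p.N_AFR_anc),
        dict(end_time=0, start_size=p.N_AFR_anc,
             end_size=p.N_AFR_anc * np.exp(p.r_AFR * p.tau_BANTU)),
    ])
    min_tau = min(p.tau_EUR, p.tau_EAS, p.tau_SAS)
    t_bot = p.tau_OOA - min(dur, (p.tau_OOA - max(p.tau_EUR, p.tau_EAS, p.tau_SAS)) / 2)
    b.add_deme("EURASI", ancestors=["AFR"], start_time=p.tau_OOA, epochs=[
        dict(end_time=t_bot, start_size=max(p.B_EURASI * p.N_AFR_anc, 2.0)),
        dict(end_time=min_tau, start_size=p.N_EURASI),
    ])
    for pop, B, N, r, tau in (
        ("EUR", p.B_EUR, p.N_EUR, p.r_EUR, p.tau_EUR),
        ("EAS", p.B_EAS, p.N_EAS, p.r_EAS, p.tau_EAS),
        ("SAS", p.B_SAS, p.N_SAS, p.r_SAS, p.tau_SAS),
    ):
        t_end_bot = tau - min(dur, tau / 2)
        b.add_deme(pop, ancestors=["EURASI"], start_time=tau, epochs=[
            dict(end_time=t_end_bot, start_size=max(B * p.N_EURASI, 2.0)),
            dict(end_time=0, start_size=N, end_size=N * np.exp(r * t_end_bot)),
        ])
    taus = {"EUR": p.tau_EUR, "EAS": p.tau_EAS, "SAS": p.tau_SAS}
    for (a, c), rate in {
        ("AFR", "EUR"): p.m_AFR_EUR, ("AFR", "EAS"): p.m_AFR_EAS,
        ("AFR", "SAS"): p.m_AFR_SAS, ("EUR", "EAS"): p.m_EUR_EAS,
        ("EUR", "SAS"): p.m_EUR_SAS, ("EAS", "SAS"): p.m_EAS_SAS,
    }.items():
        if rate > 0:
            b.add_migration(demes=[a, c], rate=rate,
                            start_time=min(taus.get(a, np.inf), taus[c]))
    if p.m_AFR_EURASI > 0:
        b.add_migration(demes=["AFR", "EURASI"], rate=p.m_AFR_EURASI,
                        start_time=p.tau_OOA, end_time=min_tau)
    return b.resolve()


def write_demes_yaml(model: OOADemography, path: str) -> None:
    """Demes-compatible YAML serialization of the model."""
    import demes

    demes.dump(to_demes(model), path)


@dataclass
class RegionSimRequest:
    """Replicate coalescent simulations of one curated region."""

    region_id: str
    length: int
    mean_mu: float
    mean_rec: float
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"AFR": 99, "EUR": 502, "EAS": 104, "SAS": 489}
    )  # diploid individuals per sampled population
    replicates: int = 100
    seed: int = 1
    masked_intervals: np.ndarray | None = None  # region-relative, parity masking

    def __post_init__(self):
        if self.length <= 0 or self.mean_mu < 0 or self.mean_rec < 0:
            raise ValueError("length must be positive and rates >= 0")


def ts_to_sample(ts, populations: np.ndarray, length: int) -> HaplotypeSample:
    """Convert a mutated tree sequence to a HaplotypeSample (derived coding)."""
    geno = ts.genotype_matrix().T.astype(np.uint8)  # haplotypes x sites
    pos = np.array([s.position for s in ts.sites()])
    return HaplotypeSample(positions=pos, genotypes=geno, populations=populations,
                           length=length)


def simulate_region(
    model: OOADemography, request: RegionSimRequest
) -> list[HaplotypeSample]:
    """Replicate HaplotypeSamples for one region under ``model``.

    Sites use the biallelic infinite-sites approximation (continuous
    positions, no recurrent hits).  When the request carries a region mask,
    simulated sites falling in masked intervals are masked to mirror the
    empirical data.
    """
    demog = to_msprime(model)
    pops = np.repeat(
        [p for p in SAMPLED_POPULATIONS if request.sample_sizes.get(p, 0) > 0],
        [2 * request.sample_sizes[p] for p in SAMPLED_POPULATIONS
         if request.sample_sizes.get(p, 0) > 0],
    )
    rng = np.random.default_rng(request.seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seeds = rng.integers(1, 2**31 - 1, size=request.replicates)
    out = []
    try:
        replicates = msprime.sim_ancestry(
            samples=request.sample_sizes,
            demography=demog,
            sequence_length=request.length,
            recombination_rate=request.mean_rec,
            random_seed=anc_seed,
            num_replicates=request.replicates,
            record_provenance=False,
        )
        for ts, mut_seed in zip(replicates, mut_seeds):
            ts = msprime.sim_mutations(
                ts, rate=request.mean_mu, model=msprime.BinaryMutationModel(),
                discrete_genome=False, random_seed=int(mut_seed),
                record_provenance=False,
            )
            sample = ts_to_sample(ts, pops, request.length)
            if request.masked_intervals is not None and len(request.masked_intervals):
                sample = sample.apply_mask(request.masked_intervals)
            out.append(sample)
    except Exception as err:  # surface the offending parameter set
        raise RuntimeError(
            f"coalescent backend failed for region {request.region_id} "
            f"with parameters {model.free_parameters()}"
        ) from err
    return out
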