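"""Synthetic genome + polymorphism generator with recorded ground truth.

Emulates every input the pipeline consumes — gene annotation (GFF3),
accessibility and conserved-element masks (BED), piecewise-constant mutation
and recombination rate maps (TSV), an ancestral-state sequence (FASTA), and
multi-population polymorphism data (VCF + sample panel) simulated under a
known demographic truth model.  The truth is serialised alongside every
dataset and is never consumed by inference code paths.

Inaccessible and conserved bases are drawn as geometric-length blocks rather
than independent bases, to mimic the clumping of real masks.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from . import vcfio
from .curation import MaskSet, intersect_intervals, normalize_intervals, subtract_intervals
from .demography import SAMPLED_POPULATIONS, OOADemography, to_msprime

_BASES = np.array(list("ACGT"))

#: 1000 Genomes-style continental sample sizes (diploid individuals)
DEFAULT_SAMPLE_SIZES = {"AFR": 99, "EUR": 502, "EAS": 104, "SAS": 489}

MASK_BLOCK_MEAN = 300  # bp, geometric block length for masks


@dataclass
class SyntheticGenomeSpec:
    """Geometry and rate parameters of the toy genome."""

    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    gene_density: float = 0.05
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    mask_fraction: float = 0.1
    conserved_fraction: float = 0.05
    mu_range: tuple[float, float] = (1e-8, 2e-8)
    rec_range: tuple[float, float] = (5e-9, 2e-8)
    seed: int = 1

    def __post_init__(self):
        for name in ("gene_density", "mask_fraction", "conserved_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.chrom_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (low, high)")


@dataclass
class TruthRecord:
    """Ground truth serialised with each dataset; inference never reads it."""

    model_parameters: dict[str, float]
    sample_sizes: dict[str, int]
    seed: int
    region_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    sweep_positions: list[float] = field(default_factory=list)
    sweep_fixation_times: list[float] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    chrom_lengths: dict[str, int]
    annotation: dict[str, np.ndarray]  # functional intervals, 0-based half-open
    masks: dict[str, MaskSet]
    mu_map: pd.DataFrame
    rec_map: pd.DataFrame
    ancestral: dict[str, str]

    def write(self, outdir: str) -> dict[str, str]:
        """Write all tracks in their standard formats; returns path map."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "gff": os.path.join(outdir, "annotation.gff3"),
            "accessibility_bed": os.path.join(outdir, "inaccessible.bed"),
            "conserved_bed": os.path.join(outdir, "conserved.bed"),
            "mu_map": os.path.join(outdir, "mutation_rate.tsv"),
            "rec_map": os.path.join(outdir, "recombination_rate.tsv"),
            "ancestral": os.path.join(outdir, "ancestral.fa"),
        }
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            gid = 0
            for chrom in sorted(self.annotation):
                for s, e in self.annotation[chrom]:
                    gid += 1
                    fh.write(f"{chrom}\tsynthetic\tgene\t{s + 1}\t{e}\t.\t+\t."
                             f"\tID=gene{gid:05d}\n")
        for key, attr in (("accessibility_bed", "inaccessible"), ("conserved_bed", "conserved")):
            with open(paths[key], "w") as fh:
                for chrom in sorted(self.masks):
                    for s, e in getattr(self.masks[chrom], attr):
                        fh.write(f"{chrom}\t{s}\t{e}\n")
        self.mu_map.to_csv(paths["mu_map"], sep="\t", header=False, index=False)
        self.rec_map.to_csv(paths["rec_map"], sep="\t", header=False, index=False)
        with open(paths["ancestral"], "w") as fh:
            for chrom in sorted(self.ancestral):
                fh.write(f">{chrom}\n")
                seq = self.ancestral[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return paths


def _place_genes(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping genes totalling ~gene_density x chrom_length bp."""
    L = spec.chrom_length
    target = spec.gene_density * L
    if target == 0:
        return np.zeros((0, 2), dtype=np.int64)
    lo, hi = spec.gene_length_range
    lengths: list[int] = []
    while sum(lengths) < target:
        lengths.append(int(rng.integers(lo, hi + 1)))
    n = len(lengths)
    free = L - sum(lengths) - (n + 1)  # 1 bp minimum gap between/around genes
    if free < 0:
        raise ValueError(
            f"impossible geometry: gene_density {spec.gene_density} cannot fit "
            f"{n} genes of {lo}-{hi} bp into {L} bp"
        )
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1))) + 1
    out, pos = [], 0
    for gap, length in zip(gaps[:-1], lengths):
        pos += int(gap)
        out.append((pos, pos + length))
        pos += length
    return np.asarray(out, dtype=np.int64)


def _block_mask(
    length: int, fraction: float, rng: np.random.Generator, block_mean: int = MASK_BLOCK_MEAN
) -> np.ndarray:
    """Geometric-length blocks covering ~fraction of [0, length)."""
    if fraction <= 0:
        return np.zeros((0, 2), dtype=np.int64)
    blocks, covered = [], 0
    while covered < fraction * length:
        size = int(rng.geometric(1.0 / block_mean))
        start = int(rng.integers(0, max(1, length - size)))
        blocks.append((start, min(start + size, length)))
        merged = normalize_intervals(np.asarray(blocks))
        covered = int((merged[:, 1] - merged[:, 0]).sum())
    return normalize_intervals(np.asarray(blocks, dtype=np.int64))


def _rate_segments(
    chroms: dict[str, int], rate_range: tuple[float, float], rng: np.random.Generator,
    segment_bp: int = 50_000,
) -> pd.DataFrame:
    rows = []
    for chrom, length in chroms.items():
        edges = np.unique(np.append(np.arange(0, length, segment_bp), length))
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, int(s), int(e), float(rng.uniform(*rate_range))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Annotation + masks + rate maps + ancestral track under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    chroms = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chromosomes)}
    annotation, masks, ancestral = {}, {}, {}
    for chrom, length in chroms.items():
        genes = _place_genes(spec, rng)
        annotation[chrom] = genes
        inacc = _block_mask(length, spec.mask_fraction, rng)
        cons_raw = _block_mask(length, spec.conserved_fraction, rng)
        noncoding = subtract_intervals(np.array([[0, length]]), genes)
        conserved = (intersect_intervals(cons_raw, noncoding)
                     if cons_raw.size else np.zeros((0, 2), dtype=np.int64))
        masks[chrom] = MaskSet(inacc, conserved)
        ancestral[chrom] = "".join(rng.choice(_BASES, size=length))
    mu_map = _rate_segments(chroms, spec.mu_range, rng)
    rec_map = _rate_segments(chroms, spec.rec_range, rng)
    return SyntheticGenome(spec, chroms, annotation, masks, mu_map, rec_map, ancestral)


def _msprime_rate_map(df: pd.DataFrame, chrom: str, length: int) -> msprime.RateMap:
    sub = df[df["chrom"] == chrom].sort_values("start")
    position = np.append(sub["start"].to_numpy(), length).astype(float)
    position[0] = 0.0
    return msprime.RateMap(position=position, rate=sub["rate"].to_numpy(dtype=float))


def generate_polymorphism(
    model: OOADemography,
    genome: SyntheticGenome,
    sample_sizes: dict[str, int] | None = None,
    seed: int = 1,
    outdir: str | None = None,
) -> tuple[dict[str, "object"], TruthRecord, dict[str, str]]:
    """Simulate polymorphism under ``model`` over the toy genome.

    Returns (per-chromosome HaplotypeSample of accessible biallelic sites,
    TruthRecord, written file paths).  One VCF per chromosome; population
    assignment travels in a sidecar sample panel.
    """
    sample_sizes = dict(sample_sizes or DEFAULT_SAMPLE_SIZES)
    present = {
        "AFR": model.N_AFR_anc * np.exp(model.r_AFR * model.tau_BANTU),
        "EUR": model.N_EUR * np.exp(model.r_EUR * model.tau_EUR),
        "EAS": model.N_EAS * np.exp(model.r_EAS * model.tau_EAS),
        "SAS": model.N_SAS * np.exp(model.r_SAS * model.tau_SAS),
    }
    for pop, n in sample_sizes.items():
        if n > present[pop]:
            raise ValueError(f"sample size {n} exceeds present size of {pop} "
                             f"({present[pop]:.0f} diploids)")
    demog = to_msprime(model)
    pops = np.repeat(list(SAMPLED_POPULATIONS),
                     [2 * sample_sizes[p] for p in SAMPLED_POPULATIONS])
    rng = np.random.default_rng(seed)
    samples, paths = {}, {}
    rates = {}
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    for chrom, length in genome.chrom_lengths.items():
        rec = _msprime_rate_map(genome.rec_map, chrom, length)
        mu = _msprime_rate_map(genome.mu_map, chrom, length)
        anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=sample_sizes, demography=demog, sequence_length=length,
            recombination_rate=rec, random_seed=int(anc_seed))
        ts = msprime.sim_mutations(ts, rate=mu, random_seed=int(mut_seed),
                                   model=msprime.BinaryMutationModel())
        positions, columns = [], []
        G = ts.genotype_matrix()
        for j, var in enumerate(ts.variants()):
            if len(var.alleles) != 2:
                continue  # recurrent hit -> rejected (biallelic only)
            positions.append(int(var.site.position))
            columns.append(G[j].astype(np.uint8))
        positions = np.asarray(positions)
        keep = np.ones(positions.size, dtype=bool)
        # unique integer positions (discrete VCF coordinates)
        keep[1:] &= np.diff(positions) > 0
        inacc = genome.masks[chrom].inaccessible
        for s, e in inacc:  # only accessible sites are retained
            keep &= ~((positions >= s) & (positions < e))
        positions = positions[keep]
        geno = (np.column_stack([c for c, k in zip(columns, keep) if k])
                if keep.any() else np.zeros((pops.size, 0), dtype=np.uint8))
        sample = vcfio.HaplotypeSample(
            positions=positions.astype(float), genotypes=geno, populations=pops,
            length=length)
        samples[chrom] = sample
        rates[chrom] = dict(
            mean_mu=float(mu.mean_rate), mean_rec=float(rec.mean_rate))
        if outdir:
            anc_seq = genome.ancestral[chrom]
            refs = np.array([anc_seq[p] for p in positions])
            alts = np.array([_BASES[(np.flatnonzero(_BASES == r)[0] + 1) % 4]
                             for r in refs])
            vcf_path = os.path.join(outdir, f"{chrom}.vcf")
            vcfio.write_vcf(sample, vcf_path, chrom=chrom, ref_alleles=refs,
                            alt_alleles=alts)
            paths[f"vcf_{chrom}"] = vcf_path
    truth = TruthRecord(
        model_parameters=model.free_parameters(), sample_sizes=sample_sizes,
        seed=seed, region_rates=rates)
    if outdir:
        panel_path = os.path.join(outdir, "samples.panel")
        vcfio.write_panel(pops, panel_path)
        paths["panel"] = panel_path
        truth_path = os.path.join(outdir, "truth.json")
        truth.to_json(truth_path)
        paths["truth"] = truth_path
    return samples, truth, paths
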