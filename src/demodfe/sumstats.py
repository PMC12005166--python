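"""Population-genetic summary statistics on haplotype samples.

All statistics are computed on a :class:`HaplotypeSample` — positions plus a
haplotype × site derived-allele matrix with population labels — so the same
code path serves both simulated samples and samples read back from VCF.  The
fitting currency is an 18-entry vector: per population the segregating-site
density, Tajima's D and mean r² (3 × 4 populations), plus Hudson F_ST for the
six unordered population pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

POPULATIONS = ("AFR", "EUR", "EAS", "SAS")

#: names of the 18 fitting statistics, in canonical order
STAT_NAMES = tuple(
    [f"{stat}_{pop}" for pop in POPULATIONS for stat in ("S", "D", "r2")]
    + [f"FST_{a}_{b}" for a, b in itertools.combinations(POPULATIONS, 2)]
)


@dataclass
class WindowSpec:
    """Sliding-window layout for windowed statistics.

    width/step defaults follow the 10 kb / 5 kb convention used for Tajima's D
    and mean r²; ``centered_on_snp`` selects SNP-centred windows (H12 scans)
    instead of a fixed tiling.
    """

    width: int = 10_000
    step: int = 5_000
    centered_on_snp: bool = False

    def __post_init__(self):
        if not (0 < self.step <= self.width):
            raise ValueError(f"require 0 < step <= width, got {self.step}, {self.width}")

    def windows(self, length: int) -> list[tuple[int, int]]:
        """Tiled (start, end) windows covering [0, length)."""
        if length <= self.width:
            return [(0, length)]
        starts = range(0, length - self.width + 1, self.step)
        return [(s, s + self.width) for s in starts]


@dataclass
class HaplotypeSample:
    """Positions + derived-allele matrix + population labels for one region.

    positions are bp offsets within the region, strictly increasing; the
    genotype matrix is haplotype × site in {0, 1} (derived indicator).
    ``accessible_bp`` is the statistic denominator after masking and
    ``site_masked`` flags sites excluded from every statistic.
    """

    positions: np.ndarray
    genotypes: np.ndarray
    populations: np.ndarray
    length: int
    accessible_bp: int | None = None
    site_masked: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        self.populations = np.asarray(self.populations)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != self.positions.size:
            raise ValueError("genotype matrix must be (n_haplotypes, n_sites)")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.accessible_bp is None:
            self.accessible_bp = int(self.length)
        if self.site_masked is None:
            self.site_masked = np.zeros(self.positions.size, dtype=bool)
        else:
            self.site_masked = np.asarray(self.site_masked, dtype=bool)

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    def unmasked(self) -> "HaplotypeSample":
        keep = ~self.site_masked
        return replace(
            self,
            positions=self.positions[keep],
            genotypes=self.genotypes[:, keep],
            site_masked=np.zeros(int(keep.sum()), dtype=bool),
        )

    def for_population(self, pop: str) -> "HaplotypeSample":
        rows = self.populations == pop
        if not rows.any():
            raise ValueError(f"no haplotypes labelled {pop!r}")
        return replace(self, genotypes=self.genotypes[rows], populations=self.populations[rows])

    def apply_mask(self, intervals: np.ndarray) -> "HaplotypeSample":
        """Mask sites falling in 0-based half-open ``intervals`` (within-region
        coordinates) and deduct the masked bases from ``accessible_bp``."""
        intervals = np.asarray(intervals, dtype=float).reshape(-1, 2)
        masked = self.site_masked.copy()
        masked_bp = 0
        for s, e in intervals:
            masked |= (self.positions >= s) & (self.positions < e)
            masked_bp += max(0.0, min(e, self.length) - max(s, 0.0))
        return replace(
            self,
            site_masked=masked,
            accessible_bp=max(0, int(round(self.accessible_bp - masked_bp))),
        )


def _derived_counts(sample: HaplotypeSample) -> np.ndarray:
    geno = sample.genotypes[:, ~sample.site_masked]
    return geno.sum(axis=0).astype(int)


def segregating_sites_per_site(sample: HaplotypeSample) -> float:
    """Count of polymorphic unmasked sites divided by accessible bp."""
    if sample.accessible_bp <= 0:
        raise ValueError("accessible_bp must be positive")
    counts = _derived_counts(sample)
    n = sample.n_haplotypes
    return float(np.count_nonzero((counts > 0) & (counts < n))) / sample.accessible_bp


def _tajima_constants(n: int) -> dict:
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return dict(a1=a1, e1=c1 / a1, e2=c2 / (a1**2 + a2))


def tajimas_d_counts(counts: np.ndarray, n: int) -> float:
    """Tajima's D from derived-allele counts of the S segregating sites in a
    sample of n haplotypes; nan when S = 0."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[(counts > 0) & (counts < n)]
    S = counts.size
    if S == 0 or n < 2:
        return float("nan")
    pi = np.sum(2.0 * counts * (n - counts) / (n * (n - 1)))
    k = _tajima_constants(n)
    num = pi - S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        # n = 2: pi = S and a1 = 1 force a zero numerator (D defined as 0)
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return float(num / np.sqrt(var))


def tajimas_d(sample: HaplotypeSample, windows: WindowSpec | None = None) -> np.ndarray:
    """Per-window Tajima's D; windows with S = 0 yield nan."""
    if sample.n_haplotypes < 2:
        raise ValueError("Tajima's D requires at least 2 haplotypes")
    windows = windows or WindowSpec()
    sub = sample.unmasked()
    counts = sub.genotypes.sum(axis=0)
    out = []
    for s, e in windows.windows(sample.length):
        inwin = (sub.positions >= s) & (sub.positions < e)
        out.append(tajimas_d_counts(counts[inwin], sample.n_haplotypes))
    return np.asarray(out)


def r2_matrix(geno: np.ndarray) -> np.ndarray:
    """Pairwise r² between derived-allele indicator columns (polymorphic only)."""
    g = geno.astype(float)
    g = g - g.mean(axis=0)
    denom = np.sqrt((g**2).sum(axis=0))
    keep = denom > 0
    g = g[:, keep] / denom[keep]
    r = g.T @ g
    return r**2


def mean_r2(sample: HaplotypeSample, windows: WindowSpec | None = None) -> np.ndarray:
    """Mean pairwise r² per window over sites polymorphic in this sample;
    windows with fewer than two polymorphic sites yield nan."""
    windows = windows or WindowSpec()
    sub = sample.unmasked()
    counts = sub.genotypes.sum(axis=0)
    n = sample.n_haplotypes
    poly = (counts > 0) & (counts < n)
    out = []
    for s, e in windows.windows(sample.length):
        cols = poly & (sub.positions >= s) & (sub.positions < e)
        m = int(cols.sum())
        if m < 2:
            out.append(float("nan"))
            continue
        rsq = r2_matrix(sub.genotypes[:, cols])
        iu = np.triu_indices(rsq.shape[0], k=1)
        out.append(float(rsq[iu].mean()))
    return np.asarray(out)


def hudson_fst(sample: HaplotypeSample, pop1: str, pop2: str) -> float:
    """Hudson's F_ST between two populations, combined as a ratio of sums of
    per-variant numerators and denominators (Bhatia-style)."""
    a = sample.unmasked().for_population(pop1)
    b = sample.unmasked().for_population(pop2)
    n1, n2 = a.n_haplotypes, b.n_haplotypes
    if n1 < 2 or n2 < 2:
        raise ValueError("Hudson F_ST needs >= 2 haplotypes per population")
    c1 = a.genotypes.sum(axis=0).astype(float)
    c2 = b.genotypes.sum(axis=0).astype(float)
    # variants segregating in the pooled pair
    tot = c1 + c2
    keep = (tot > 0) & (tot < n1 + n2)
    p1, p2 = c1[keep] / n1, c2[keep] / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den.sum() == 0:
        return float("nan")
    return float(num.sum() / den.sum())


def weir_cockerham_fst(sample: HaplotypeSample, pop1: str, pop2: str) -> float:
    """Weir & Cockerham (1984) theta for two populations of haploid allele
    counts, ratio of summed variance components across variants."""
    a = sample.unmasked().for_population(pop1)
    b = sample.unmasked().for_population(pop2)
    n1, n2 = a.n_haplotypes, b.n_haplotypes
    p1 = a.genotypes.sum(axis=0) / n1
    p2 = b.genotypes.sum(axis=0) / n2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    # haploid alleles: no heterozygosity term
    A = s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1)
    a_comp = nbar / nc * A
    b_comp = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    denom = (a_comp + b_comp).sum()
    if denom == 0:
        return float("nan")
    return float(a_comp.sum() / denom)


def fst(sample: HaplotypeSample, pop1: str, pop2: str, estimator: str = "hudson") -> float:
    if estimator == "hudson":
        return hudson_fst(sample, pop1, pop2)
    if estimator == "weir_cockerham":
        return weir_cockerham_fst(sample, pop1, pop2)
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


def divergence_from_sequences(
    reference: str | np.ndarray,
    ancestral: str | np.ndarray,
    polymorphic_positions: np.ndarray,
    region_length: int | None = None,
) -> float:
    """Fixed differences between reference and ancestral sequence, with
    polymorphic sites masked, relative to total region length."""
    ref = np.frombuffer(str(reference).upper().encode(), dtype="S1")
    anc = np.frombuffer(str(ancestral).upper().encode(), dtype="S1")
    if ref.size != anc.size:
        raise ValueError("reference and ancestral sequences differ in length")
    if region_length is None:
        region_length = ref.size
    fixed = ref != anc
    poly = np.asarray(polymorphic_positions, dtype=int)
    poly = poly[(poly >= 0) & (poly < ref.size)]
    fixed[poly] = False
    return float(fixed.sum()) / region_length


def divergence_from_fixations(n_fixations: int, region_length: int) -> float:
    """Simulated divergence: post-burn-in fixation count over region length."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    return n_fixations / region_length


def haplotype_frequencies(geno: np.ndarray) -> np.ndarray:
    """Sorted (descending) frequencies of exact haplotype classes."""
    if geno.shape[1] == 0:
        return np.array([1.0])
    _, counts = np.unique(geno, axis=0, return_counts=True)
    freqs = np.sort(counts / geno.shape[0])[::-1]
    return freqs


def h12_from_frequencies(freqs: np.ndarray) -> float:
    """H12 = (p1 + p2)² + Σ_{i≥3} p_i² for sorted haplotype frequencies."""
    f = np.sort(np.asarray(freqs, dtype=float))[::-1]
    if f.size == 1:
        return float(f[0] ** 2)
    return float((f[0] + f[1]) ** 2 + np.sum(f[2:] ** 2))


def h12(sample: HaplotypeSample, focal_position: float, width: int) -> float:
    """H12 in a window of ``width`` bp centred on ``focal_position``.

    Haplotype identity is exact match over the unmasked SNPs in the window.
    """
    sub = sample.unmasked()
    half = width / 2.0
    cols = (sub.positions >= focal_position - half) & (sub.positions <= focal_position + half)
    if not cols.any():
        raise ValueError("window contains no SNPs")
    return h12_from_frequencies(haplotype_frequencies(sub.genotypes[:, cols]))


def aggregate_replicates(values: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Aggregate a region × replicate table into a display point and bar.

    ``values`` has columns (region, replicate, value).  Per region the mean and
    SD across replicates are taken; the plotted point is the mean of region
    means and the bar is the mean of region SDs.
    """
    per_region = values.groupby("region")["value"].agg(["mean", "std"])
    if values.groupby("region").size().min() < 2:
        raise ValueError("need >= 2 replicates per region")
    return float(per_region["mean"].mean()), float(per_region["std"].mean()), per_region


def _nanmean(values: np.ndarray) -> float:
    """Mean over defined entries; nan (without warning) when none are."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return float(v.mean()) if v.size else float("nan")


def _hudson_from_counts(c1, c2, n1, n2):
    tot = c1 + c2
    keep = (tot > 0) & (tot < n1 + n2)
    p1, p2 = c1[keep] / n1, c2[keep] / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    dsum = den.sum()
    return float(num.sum() / dsum) if dsum > 0 else float("nan")


def stat_vector(
    sample: HaplotypeSample,
    windows: WindowSpec | None = None,
    populations: tuple[str, ...] = POPULATIONS,
    estimator: str = "hudson",
) -> pd.Series:
    """The 18-statistic fitting vector for a 4-population sample.

    Per population: segregating sites per accessible bp, mean windowed
    Tajima's D, mean windowed r²; per unordered pair: Hudson F_ST.  Window
    means use defined windows only (S = 0 windows are skipped).
    """
    windows = windows or WindowSpec()
    if estimator != "hudson":
        # general path through the per-statistic functions
        out = {}
        for pop in populations:
            sub = sample.for_population(pop)
            out[f"S_{pop}"] = segregating_sites_per_site(sub)
            out[f"D_{pop}"] = _nanmean(tajimas_d(sub, windows))
            out[f"r2_{pop}"] = _nanmean(mean_r2(sub, windows))
        for a, b in itertools.combinations(populations, 2):
            out[f"FST_{a}_{b}"] = fst(sample, a, b, estimator=estimator)
    else:
        # vectorised path avoiding per-population sample copies; results are
        # identical to the individual statistic functions
        if sample.accessible_bp <= 0:
            raise ValueError("accessible_bp must be positive")
        keep = ~sample.site_masked
        geno = sample.genotypes[:, keep]
        pos = sample.positions[keep]
        win_list = windows.windows(sample.length)
        win_masks = [(pos >= s) & (pos < e) for s, e in win_list]
        out = {}
        pop_counts = {}
        for pop in populations:
            rows = sample.populations == pop
            if not rows.any():
                raise ValueError(f"no haplotypes labelled {pop!r}")
            sub = geno[rows]
            n = int(rows.sum())
            counts = sub.sum(axis=0)
            pop_counts[pop] = (counts.astype(float), n)
            poly = (counts > 0) & (counts < n)
            out[f"S_{pop}"] = float(poly.sum()) / sample.accessible_bp
            if n < 2:
                raise ValueError("Tajima's D requires at least 2 haplotypes")
            Ds, r2s = [], []
            for wmask in win_masks:
                Ds.append(tajimas_d_counts(counts[wmask], n))
                cols = wmask & poly
                if cols.sum() < 2:
                    r2s.append(float("nan"))
                else:
                    rsq = r2_matrix(sub[:, cols])
                    iu = np.triu_indices(rsq.shape[0], k=1)
                    r2s.append(float(rsq[iu].mean()))
            out[f"D_{pop}"] = _nanmean(np.asarray(Ds))
            out[f"r2_{pop}"] = _nanmean(np.asarray(r2s))
        for a, b in itertools.combinations(populations, 2):
            (c1, n1), (c2, n2) = pop_counts[a], pop_counts[b]
            out[f"FST_{a}_{b}"] = _hudson_from_counts(c1, c2, n1, n2)
    names = tuple(
        [f"{s}_{p}" for p in populations for s in ("S", "D", "r2")]
        + [f"FST_{a}_{b}" for a, b in itertools.combinations(populations, 2)]
    )
    return pd.Series(out).reindex(list(names))
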