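"""Selective-sweep scans and power evaluation.

Two per-site scores are produced: a composite likelihood ratio (CLR) in the
SweepFinder tradition — each test position compares a sweep-distorted site
frequency spectrum against a genome-wide background SFS, maximised over the
sweep-intensity parameter — and windowed H12 haplotype homozygosity centred
on each SNP.  Detection power against sweep-free null replicates is
summarised as replicate-level ROC curves.

Sweep model: during a sweep each of the n sampled lineages escapes to the
pre-sweep background independently with probability p_e = 1 - exp(-alpha d),
where d is the recombination distance from the test position; lineages that
do not escape coalesce into a single ancestral lineage whose allelic state is
drawn from the background.  alpha -> infinity recovers the background (all
lineages escape), so the maximised log-ratio is nonnegative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HaplotypeSample, h12


@dataclass
class BackgroundSFS:
    """Unfolded derived-allele-frequency class probabilities for sample size n.

    ``probs[j - 1]`` is the probability of derived count j for j = 1..n; the
    j = n class holds substitutions (fixed derived), following the convention
    of fitting polymorphic and substitution data only.
    """

    n: int
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size != self.n:
            raise ValueError("need one probability per derived count 1..n")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")


def build_background_sfs(
    count_sets: list[np.ndarray], sample_size: int, n_substitutions: int | list[int] = 0,
    pseudocount: float = 0.0,
) -> BackgroundSFS:
    """Pool derived-allele counts from sweep-free samples into a background SFS.

    ``count_sets`` holds per-replicate arrays of derived counts (1..n-1 for
    polymorphic sites); substitutions contribute to the count-n class.
    ``pseudocount`` adds Laplace mass to every class so that frequency
    classes unobserved in a finite sweep-free set keep nonzero probability
    (scan likelihoods stay finite).
    """
    if not count_sets:
        raise ValueError("need at least one sweep-free sample")
    n = int(sample_size)
    hist = np.zeros(n, dtype=float)
    subs = np.atleast_1d(n_substitutions)
    if subs.size == 1:
        subs = np.repeat(subs, len(count_sets))
    for counts, n_sub in zip(count_sets, subs, strict=True):
        counts = np.asarray(counts, dtype=int)
        if counts.size and (counts.min() < 1 or counts.max() > n):
            raise ValueError("derived counts must lie in 1..n (consistent sample size)")
        hist += np.bincount(counts, minlength=n + 1)[1 : n + 1]
        hist[n - 1] += int(n_sub)
    if hist.sum() == 0:
        raise ValueError("no polymorphic or substitution data")
    hist += pseudocount
    return BackgroundSFS(n, hist / hist.sum())


def write_freq_file(path: str, positions: np.ndarray, counts: np.ndarray, n: int) -> None:
    """Allele-frequency file in the SweepFinder2 convention:
    position, derived count x, sample size n, folded flag (0 = unfolded)."""
    with open(path, "w") as fh:
        fh.write("position\tx\tn\tfolded\n")
        for p, c in zip(positions, counts):
            fh.write(f"{int(p)}\t{int(c)}\t{int(n)}\t0\n")


def read_freq_file(path: str) -> tuple[np.ndarray, np.ndarray, int]:
    rows = np.loadtxt(path, skiprows=1, ndmin=2)
    if rows.size == 0:
        raise ValueError(f"empty allele-frequency file: {path}")
    n = int(rows[0, 2])
    if not (rows[:, 2] == n).all():
        raise ValueError("mixed sample sizes in allele-frequency file")
    return rows[:, 0], rows[:, 1].astype(int), n


def write_grid_file(path: str, positions: np.ndarray) -> None:
    """Test-position grid file: one position per line."""
    np.savetxt(path, np.asarray(positions, dtype=float), fmt="%.3f")


def read_grid_file(path: str) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path))


@dataclass
class ScanTrack:
    """Per-position sweep scores from one scan method."""

    positions: np.ndarray
    scores: np.ndarray
    method: str

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def max_within(self, center: float, radius: float) -> float:
        near = np.abs(self.positions - center) <= radius
        if not near.any():
            return -np.inf
        return float(self.scores[near].max())

    def global_max(self) -> float:
        return float(self.scores.max()) if self.scores.size else -np.inf


def sweep_class_matrix(n: int, background: np.ndarray) -> np.ndarray:
    """M[k, j-1] = P(observed derived count j | k of n lineages escaped).

    The k escapees plus the single swept ancestral lineage form a size-(k+1)
    draw from the background sample; the swept lineage's state is copied to
    the n-k non-escapees.  Row k = n is the background itself.  Rows are
    renormalised to the observable classes j = 1..n.
    """
    bg = np.asarray(background, dtype=float)
    M = np.zeros((n + 1, n))
    M[n] = bg
    # probs over derived counts 0..n in the full background sample:
    full = np.zeros(n + 1)
    full[1:] = bg
    for k in range(n):
        m = k + 1  # subsample size: k escapees + the swept ancestral lineage
        row = np.zeros(n + 1)
        for i in range(1, n + 1):  # background derived count
            if full[i] == 0:
                continue
            d = np.arange(0, min(m, i) + 1)
            w = stats.hypergeom.pmf(d, n, i, m)
            for dt, wt in zip(d, w):
                if wt <= 1e-300:
                    continue
                p_swept_derived = dt / m
                if dt >= 1:
                    # swept lineage derived: its state is copied to the n-k
                    # non-escapees, so j = (dt - 1) + (n - k)
                    row[dt - 1 + (n - k)] += full[i] * wt * p_swept_derived
                if dt <= k:  # swept lineage ancestral: j = escaped derived = dt
                    row[dt] += full[i] * wt * (1.0 - p_swept_derived)
        obs = row[1:]
        tot = obs.sum()
        M[k] = obs / tot if tot > 0 else bg
    return M


def clr_scan(
    positions: np.ndarray,
    derived_counts: np.ndarray,
    background: BackgroundSFS,
    grid_positions: np.ndarray,
    rec_rate: float,
    alpha_grid: np.ndarray | None = None,
    max_distance: float | None = None,
) -> ScanTrack:
    """Composite likelihood ratio scan at each grid position.

    ``positions``/``derived_counts`` hold polymorphic sites (1..n-1) and
    substitutions (count n); ``rec_rate`` converts bp distance into
    recombination distance d = rec_rate * |x - g|.  The statistic is
    Lambda = 2 (max_alpha ln CL_sweep - ln CL_background), floored at 0.
    """
    positions = np.asarray(positions, dtype=float)
    counts = np.asarray(derived_counts, dtype=int)
    if positions.size == 0:
        raise ValueError("no polymorphic or substitution sites")
    n = background.n
    if counts.min() < 1 or counts.max() > n:
        raise ValueError("derived counts must lie in 1..n")
    if alpha_grid is None:
        # escape probabilities spanning ~0 to ~1 over plausible distances
        d_ref = max(rec_rate * (positions.max() - positions.min()) / 10.0, 1e-12)
        alpha_grid = np.geomspace(1e-3 / d_ref, 1e3 / d_ref, 40)
    log_bg = np.log(background.probs[counts - 1])
    M = sweep_class_matrix(n, background.probs)
    k_range = np.arange(n + 1)
    scores = np.zeros(len(grid_positions))
    for gi, g in enumerate(np.asarray(grid_positions, dtype=float)):
        d = rec_rate * np.abs(positions - g)
        use = np.ones(positions.size, dtype=bool)
        if max_distance is not None:
            use = d <= max_distance
            if not use.any():
                continue
        best = 0.0
        for alpha in alpha_grid:
            p_e = -np.expm1(-alpha * d[use])
            # P(k escapees | p_e) per site, then mix rows of M
            binom = stats.binom.pmf(k_range[None, :], n, p_e[:, None])
            probs = np.einsum("sk,kj->sj", binom, M)
            site_p = probs[np.arange(use.sum()), counts[use] - 1]
            ll = np.sum(np.log(np.maximum(site_p, 1e-300)) - log_bg[use])
            best = max(best, ll)
        scores[gi] = 2.0 * best
    return ScanTrack(np.asarray(grid_positions, dtype=float), scores, "CLR")


H12_WINDOW_WIDTHS = (1_000, 2_000, 5_000, 10_000, 20_000, 40_000)


def h12_scan(
    sample: HaplotypeSample, widths: tuple[int, ...] = H12_WINDOW_WIDTHS
) -> dict[int, ScanTrack]:
    """H12 at each SNP for each window width, SNP at the window centre."""
    sub = sample.unmasked()
    if sub.positions.size == 0:
        raise ValueError("sample has no SNPs")
    out = {}
    for width in widths:
        scores = np.array([h12(sub, p, width) for p in sub.positions])
        out[width] = ScanTrack(sub.positions.copy(), scores, f"H12_{width}")
    return out


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be nondecreasing")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def roc_from_scores(sweep_scores: np.ndarray, null_scores: np.ndarray) -> ROCCurve:
    """Replicate-level ROC: thresholds swept over the pooled scores."""
    sweep = np.asarray(sweep_scores, dtype=float)
    null = np.asarray(null_scores, dtype=float)
    if sweep.size == 0 or null.size == 0:
        raise ValueError("need scores from both sweep and null replicates")
    thresholds = np.unique(np.concatenate([sweep, null]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(sweep >= t)))
        fpr.append(float(np.mean(null >= t)))
    fpr.append(1.0)
    tpr.append(1.0)
    fpr, tpr = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, auc)


def mann_whitney_auc(sweep_scores: np.ndarray, null_scores: np.ndarray) -> float:
    """AUC as the Mann–Whitney U probability (ties credited 1/2)."""
    sweep = np.asarray(sweep_scores, dtype=float)[:, None]
    null = np.asarray(null_scores, dtype=float)[None, :]
    return float(np.mean((sweep > null) + 0.5 * (sweep == null)))


def roc(
    sweep_tracks: list[ScanTrack],
    null_tracks: list[ScanTrack],
    truth_positions: list[float],
    tp_radius: float = 1_000.0,
) -> ROCCurve:
    """ROC from replicate tracks: a sweep replicate scores its maximum within
    ``tp_radius`` of its true sweep site, a null replicate its genome-wide
    maximum."""
    if not truth_positions:
        raise ValueError("truth positions are required")
    if len(truth_positions) != len(sweep_tracks):
        raise ValueError("one truth position per sweep track")
    sweep_scores = np.array([t.max_within(p, tp_radius)
                             for t, p in zip(sweep_tracks, truth_positions)])
    null_scores = np.array([t.global_max() for t in null_tracks])
    return roc_from_scores(sweep_scores, null_scores)
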