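"""Region curation: select analysis regions from annotation, masks and rate maps.

Step 1 of the inference framework uses large nonfunctional regions far from
any annotated functional interval (to avoid background-selection effects);
step 2 uses the functional (exonic) intervals themselves.  Every retained
region carries length-weighted mean mutation and recombination rates from the
supplied rate maps; regions without rate coverage are dropped.

Coordinates: GFF3 is 1-based closed, BED and rate maps 0-based half-open;
everything internal is 0-based half-open numpy interval arrays (n, 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_DISTANCE = 10_000
DEFAULT_MIN_LENGTH = 15_000


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open, per chromosome)

def normalize_intervals(iv: np.ndarray, warn: bool = False) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals."""
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    if np.any(iv[:, 1] <= iv[:, 0]):
        raise ValueError("intervals must have end > start")
    order = np.argsort(iv[:, 0], kind="stable")
    iv = iv[order]
    merged = [iv[0].tolist()]
    overlapped = False
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            overlapped = overlapped or s < merged[-1][1]
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if overlapped and warn:
        warnings.warn("overlapping intervals were merged", stacklevel=2)
    return np.asarray(merged, dtype=np.int64)


def subtract_intervals(base: np.ndarray, remove: np.ndarray) -> np.ndarray:
    """Set difference base \\ remove, both normalized."""
    base = normalize_intervals(base)
    remove = normalize_intervals(remove)
    out = []
    for s, e in base:
        cur = s
        for rs, re in remove:
            if re <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = normalize_intervals(a)
    b = normalize_intervals(b)
    out = []
    for s, e in a:
        for bs, be in b:
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                out.append((lo, hi))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intervals_total(iv: np.ndarray) -> int:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    return int((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0


def pad_intervals(iv: np.ndarray, pad: int) -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    return normalize_intervals(np.column_stack([np.maximum(iv[:, 0] - pad, 0), iv[:, 1] + pad]))


# ---------------------------------------------------------------------------
# domain types

@dataclass
class MaskSet:
    """Accessibility + conserved-element masks (normalized interval arrays)."""

    inaccessible: np.ndarray
    conserved: np.ndarray

    def __post_init__(self):
        self.inaccessible = normalize_intervals(self.inaccessible)
        self.conserved = normalize_intervals(self.conserved)

    @property
    def masked(self) -> np.ndarray:
        """Union of both masks."""
        if self.inaccessible.size == 0:
            return self.conserved
        if self.conserved.size == 0:
            return self.inaccessible
        return normalize_intervals(np.vstack([self.inaccessible, self.conserved]))


@dataclass
class CuratedRegion:
    """An analysis region with its mean rates and post-mask accessible length."""

    chrom: str
    start: int
    end: int
    kind: str  # "nonfunctional" | "exonic"
    mean_mu: float
    mean_rec: float
    accessible_bp: int
    masked_intervals: np.ndarray | None = None  # region-relative, for parity masking

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not (np.isfinite(self.mean_mu) and np.isfinite(self.mean_rec)):
            raise ValueError("mean rates must be finite")
        if self.accessible_bp > self.end - self.start:
            raise ValueError("accessible_bp cannot exceed region length")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers / writers

def read_gff(path: str, feature_types: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
    """Read GFF3 features into per-chromosome 0-based half-open intervals."""
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, _, ftype, start, end = parts[:5]
            if feature_types is not None and ftype not in feature_types:
                continue
            per_chrom.setdefault(chrom, []).append((int(start) - 1, int(end)))
    return {c: np.asarray(v, dtype=np.int64) for c, v in per_chrom.items()}


def read_bed(path: str) -> dict[str, np.ndarray]:
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
    return {c: np.asarray(v, dtype=np.int64) for c, v in per_chrom.items()}


def read_rate_map(path: str) -> pd.DataFrame:
    """Tab-separated rate map: chrom, start, end, rate (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "rate"])
    if len(df) == 0:
        raise ValueError(f"empty rate map: {path}")
    return df


def write_regions(regions: list[CuratedRegion], path: str) -> None:
    pd.DataFrame(
        [
            dict(chrom=r.chrom, start=r.start, end=r.end, kind=r.kind,
                 mean_mu=r.mean_mu, mean_rec=r.mean_rec, accessible_bp=r.accessible_bp)
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_regions(path: str) -> list[CuratedRegion]:
    df = pd.read_csv(path, sep="\t")
    return [
        CuratedRegion(r.chrom, int(r.start), int(r.end), r.kind,
                      float(r.mean_mu), float(r.mean_rec), int(r.accessible_bp))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# operations

def region_mean_rate(
    start: int, end: int, rate_map: pd.DataFrame, chrom: str | None = None
) -> tuple[float, float] | None:
    """Length-weighted mean rate over the covered part of [start, end).

    Returns (mean_rate, covered_fraction), or None when the map covers zero bp
    of the region ("no rate information").
    """
    df = rate_map
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    lo = np.maximum(df["start"].to_numpy(), start)
    hi = np.minimum(df["end"].to_numpy(), end)
    w = np.maximum(hi - lo, 0).astype(float)
    covered = w.sum()
    if covered == 0:
        return None
    mean = float((w * df["rate"].to_numpy()).sum() / covered)
    return mean, float(covered / (end - start))


def _curate(
    chrom: str,
    intervals: np.ndarray,
    kind: str,
    masks: MaskSet,
    mu_map: pd.DataFrame,
    rec_map: pd.DataFrame,
) -> list[CuratedRegion]:
    regions = []
    for s, e in intervals:
        mu = region_mean_rate(int(s), int(e), mu_map, chrom)
        rec = region_mean_rate(int(s), int(e), rec_map, chrom)
        if mu is None or rec is None:
            continue  # no rate information -> region removed
        masked_here = intersect_intervals(masks.masked, [(s, e)])
        accessible = int(e - s) - intervals_total(masked_here)
        if accessible <= 0:
            continue
        rel = masked_here - s if masked_here.size else np.zeros((0, 2), dtype=np.int64)
        regions.append(
            CuratedRegion(chrom, int(s), int(e), kind, mu[0], rec[0], accessible,
                          masked_intervals=rel)
        )
    return regions


def select_nonfunctional(
    annotation: dict[str, np.ndarray],
    masks: dict[str, MaskSet],
    mu_map: pd.DataFrame,
    rec_map: pd.DataFrame,
    chrom_lengths: dict[str, int],
    min_distance: int = DEFAULT_MIN_DISTANCE,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[CuratedRegion]:
    """Nonfunctional regions at >= min_distance bp from any functional interval.

    The complement of the min_distance-padded annotation is taken per
    chromosome; spans shorter than min_length (before masking) are dropped;
    masked bases inside retained regions are recorded, not split out.
    """
    if len(mu_map) == 0 or len(rec_map) == 0:
        raise ValueError("empty rate map")
    out: list[CuratedRegion] = []
    for chrom, length in chrom_lengths.items():
        func = normalize_intervals(annotation.get(chrom, np.zeros((0, 2))), warn=True)
        exclude = pad_intervals(func, min_distance)
        candidates = subtract_intervals(np.array([[0, length]]), exclude)
        candidates = candidates[(candidates[:, 1] - candidates[:, 0]) >= min_length]
        mset = masks.get(chrom, MaskSet(np.zeros((0, 2)), np.zeros((0, 2))))
        out.extend(_curate(chrom, candidates, "nonfunctional", mset, mu_map, rec_map))
    return out


def select_exonic(
    annotation: dict[str, np.ndarray],
    mu_map: pd.DataFrame,
    rec_map: pd.DataFrame,
    masks: dict[str, MaskSet] | None = None,
) -> list[CuratedRegion]:
    """One region per (merged) exon cluster with mean rates; exons lacking
    rate-map coverage are dropped."""
    out: list[CuratedRegion] = []
    for chrom, iv in annotation.items():
        clusters = normalize_intervals(iv, warn=True)
        mset = (masks or {}).get(chrom, MaskSet(np.zeros((0, 2)), np.zeros((0, 2))))
        out.extend(_curate(chrom, clusters, "exonic", mset, mu_map, rec_map))
    return out
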