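"""VCF + sample-panel I/O for haplotype samples.

Writing emits plain-text VCF v4.2 with phased diploid genotypes and an ``AA``
INFO field carrying the ancestral allele (the derived-allele coding of the
matrix is preserved on a round trip).  Parsing goes through cyvcf2.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sumstats import HaplotypeSample

_HEADER = """\
##fileformat=VCFv4.2
##source=demodfe
##contig=<ID={chrom},length={length}>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def sample_names(populations: np.ndarray) -> list[str]:
    """Individual names for consecutive haplotype pairs, e.g. AFR_0001."""
    pops = np.asarray(populations)
    if pops.size % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    ind_pops = pops[::2]
    if not np.array_equal(ind_pops, pops[1::2]):
        raise ValueError("haplotype pairs must share a population label")
    names, seen = [], {}
    for p in ind_pops:
        seen[p] = seen.get(p, 0) + 1
        names.append(f"{p}_{seen[p]:04d}")
    return names


def write_vcf(
    sample: HaplotypeSample,
    path: str,
    chrom: str = "chr1",
    ref_alleles: np.ndarray | None = None,
    alt_alleles: np.ndarray | None = None,
) -> None:
    """Write a HaplotypeSample as VCF v4.2 (1-based positions, REF=ancestral)."""
    names = sample_names(sample.populations)
    refs = ref_alleles if ref_alleles is not None else np.full(sample.positions.size, "A")
    alts = alt_alleles if alt_alleles is not None else np.full(sample.positions.size, "T")
    with open(path, "w") as fh:
        fh.write(_HEADER.format(chrom=chrom, length=int(sample.length)))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        geno = sample.genotypes
        for j in range(sample.positions.size):
            if sample.site_masked[j]:
                continue
            col = geno[:, j]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(names)))
            fh.write(
                f"{chrom}\t{int(sample.positions[j]) + 1}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t"
                f"AA={refs[j]}\tGT\t{gts}\n"
            )


def write_panel(populations: np.ndarray, path: str) -> None:
    """Plain-text sample panel: sample_id <tab> population."""
    names = sample_names(np.asarray(populations))
    pops = np.asarray(populations)[::2]
    pd.DataFrame({"sample_id": names, "population": pops}).to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    if not {"sample_id", "population"} <= set(panel.columns):
        raise ValueError("panel needs sample_id and population columns")
    return panel


def read_vcf(
    vcf_path: str,
    panel_path: str | os.PathLike | None = None,
    region: tuple[str, int, int] | None = None,
    accessible_bp: int | None = None,
) -> HaplotypeSample:
    """Read biallelic variants into a HaplotypeSample.

    ``region`` is (chrom, start, end) 0-based half-open; positions in the
    returned sample are offsets from ``start``.  The derived allele is the one
    differing from the AA INFO field (falls back to ALT when AA is absent).
    """
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    if panel_path is not None:
        panel = read_panel(panel_path)
        pop_of = dict(zip(panel["sample_id"], panel["population"]))
        pops_ind = [pop_of[s] for s in samples]
    else:
        pops_ind = [s.rsplit("_", 1)[0] for s in samples]
    populations = np.repeat(pops_ind, 2)

    start, end, chrom = 0, None, None
    if region is not None:
        chrom, start, end = region
    positions, columns = [], []
    for var in vcf:
        if chrom is not None and (var.CHROM != chrom or var.POS - 1 < start or var.POS - 1 >= end):
            continue
        if len(var.ALT) != 1:
            continue
        aa = var.INFO.get("AA")
        # haplotype alleles in sample order
        gt = np.array(var.genotypes)[:, :2].reshape(-1)
        if aa is not None and aa == var.ALT[0]:
            gt = 1 - gt
        positions.append(var.POS - 1 - start)
        columns.append(gt.astype(np.uint8))
    length = (end - start) if end is not None else (
        int(vcf.seqlens[0]) if vcf.seqlens else int(max(positions, default=0)) + 1
    )
    geno = (
        np.column_stack(columns) if columns else np.zeros((populations.size, 0), dtype=np.uint8)
    )
    return HaplotypeSample(
        positions=np.asarray(positions, dtype=float),
        genotypes=geno,
        populations=populations,
        length=length,
        accessible_bp=accessible_bp,
    )
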