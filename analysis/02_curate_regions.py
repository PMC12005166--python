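"""Curate analysis regions from the synthetic tracks: distant nonfunctional
regions (>= 10 kb from genes, >= 15 kb long, accessibility- and
conservation-masked) for demographic inference, and exonic regions for DFE
inference.  Regions lacking rate-map coverage are dropped.

Reads results/synth/, writes results/curated/{nonfunctional,exonic}.tsv.
"""

import argparse
import pathlib

import numpy as np

from demodfe import curation as cu


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--inp", default="results/synth")
    ap.add_argument("--out", default="results/curated")
    ap.add_argument("--min-dist", type=int, default=10_000)
    ap.add_argument("--min-len", type=int, default=15_000)
    args = ap.parse_args()

    inp = pathlib.Path(args.inp)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    ann = cu.read_gff(inp / "annotation.gff3", feature_types=("gene",))
    inacc = cu.read_bed(inp / "inaccessible.bed")
    cons = cu.read_bed(inp / "conserved.bed")
    mu = cu.read_rate_map(inp / "mutation_rate.tsv")
    rec = cu.read_rate_map(inp / "recombination_rate.tsv")
    chrom_lengths = {c: int(mu[mu.chrom == c]["end"].max()) for c in mu.chrom.unique()}
    empty = np.zeros((0, 2), dtype=np.int64)
    masks = {c: cu.MaskSet(inacc.get(c, empty), cons.get(c, empty))
             for c in chrom_lengths}

    nonfunc = cu.select_nonfunctional(ann, masks, mu, rec, chrom_lengths,
                                      min_distance=args.min_dist,
                                      min_length=args.min_len)
    cu.write_regions(nonfunc, out / "nonfunctional.tsv")
    exonic = cu.select_exonic(ann, mu, rec,
                              masks={c: cu.MaskSet(inacc.get(c, empty), empty)
                                     for c in chrom_lengths})
    cu.write_regions(exonic, out / "exonic.tsv")

    kb = sum(r.length for r in nonfunc) / 1_000
    print(f"nonfunctional: {len(nonfunc)} regions, {kb:,.0f} kb total "
          f"(min distance {args.min_dist:,} bp, min length {args.min_len:,} bp)")
    print(f"exonic: {len(exonic)} regions")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
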