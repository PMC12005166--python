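"""Compute the fitting statistics on the curated nonfunctional regions from
the VCF: per population the segregating-site density, windowed Tajima's D and
mean r2, and Hudson F_ST per population pair — the 18-statistic vector of
step 1 — with per-region values written in long format.

Reads results/synth/ + results/curated/, writes results/stats/empirical.tsv
and the aggregated vector results/stats/empirical_vector.tsv.
"""

import argparse
import pathlib

import pandas as pd

from demodfe import curation as cu
from demodfe import vcfio
from demodfe.sumstats import WindowSpec, stat_vector


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--synth", default="results/synth")
    ap.add_argument("--curated", default="results/curated")
    ap.add_argument("--out", default="results/stats")
    ap.add_argument("--window", type=int, default=10_000)
    ap.add_argument("--step", type=int, default=5_000)
    args = ap.parse_args()

    synth = pathlib.Path(args.synth)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    regions = cu.read_regions(pathlib.Path(args.curated) / "nonfunctional.tsv")
    windows = WindowSpec(args.window, args.step)

    rows = []
    for r in regions:
        sample = vcfio.read_vcf(synth / f"{r.chrom}.vcf", synth / "samples.panel",
                                region=(r.chrom, r.start, r.end),
                                accessible_bp=r.accessible_bp)
        vec = stat_vector(sample, windows)
        rows.append(dict(region=f"{r.chrom}:{r.start}-{r.end}", **vec.to_dict()))
    table = pd.DataFrame(rows)
    long = table.melt(id_vars="region", var_name="statistic", value_name="value")
    long.to_csv(out / "empirical.tsv", sep="\t", index=False)

    stats = [c for c in table.columns if c != "region"]
    agg = pd.DataFrame({"mean": table[stats].mean(), "sd": table[stats].std()})
    agg.to_csv(out / "empirical_vector.tsv", sep="\t")
    print(f"{len(regions)} regions -> {len(stats)} statistics")
    print(agg.round(5).to_string())


if __name__ == "__main__":
    main()
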