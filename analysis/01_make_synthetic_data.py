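"""Generate the synthetic study inputs: a toy genome (annotation, masks, rate
maps, ancestral track) and multi-population polymorphism under the desk-scale
truth model, with the ground truth serialised alongside.

Writes results/synth/ with GFF3/BED/TSV/FASTA/VCF/panel files and prints a
short inventory of what was produced.
"""

import argparse
import pathlib

from demodfe import experiments, synthetic_data as sd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/synth")
    ap.add_argument("--chrom-length", type=int, default=600_000)
    ap.add_argument("--samples", type=int, nargs=4, default=[8, 8, 8, 8],
                    metavar=("AFR", "EUR", "EAS", "SAS"))
    args = ap.parse_args()

    out = pathlib.Path(args.out)
    spec = sd.SyntheticGenomeSpec(chrom_length=args.chrom_length, seed=args.seed)
    genome = sd.generate_genome(spec)
    paths = genome.write(out)

    model = experiments.desk_truth_model()
    sizes = dict(zip(("AFR", "EUR", "EAS", "SAS"), args.samples))
    samples, truth, more = sd.generate_polymorphism(model, genome, sizes,
                                                    seed=args.seed, outdir=out)
    paths.update(more)

    n_genes = sum(len(iv) for iv in genome.annotation.values())
    n_sites = sum(s.positions.size for s in samples.values())
    print(f"synthetic genome: {spec.n_chromosomes} chromosome(s) x "
          f"{spec.chrom_length:,} bp, {n_genes} genes")
    print(f"polymorphism: {n_sites:,} accessible biallelic sites for "
          f"{sum(sizes.values())} individuals")
    for key, p in sorted(paths.items()):
        print(f"  {key}: {p}")


if __name__ == "__main__":
    main()
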