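"""Step-2 forward simulations with the discrete-class DFE: the background-
selection effect of the deleterious classes on linked neutral diversity, and
the divergence cost of adding a beneficial class at increasing rates (the
diagnostic that rules out high beneficial input).

Writes results/dfe/bgs_pi.tsv and results/dfe/beneficial_divergence.tsv and
prints the two monotonicity summaries.
"""

import argparse
import pathlib

from demodfe import experiments as ex


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/dfe")
    ap.add_argument("--replicates", type=int, default=50)
    args = ap.parse_args()

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    bgs = ex.bgs_pi_by_deleterious_fraction(replicates=args.replicates,
                                            seed=args.seed)
    bgs.to_csv(out / "bgs_pi.tsv", sep="\t", index=False)
    by_frac = bgs.groupby("deleterious_fraction")["pi"].mean()
    print("linked neutral pi by deleterious fraction:")
    print(by_frac.round(7).to_string())

    div = ex.divergence_by_beneficial_rate(replicates=args.replicates,
                                           seed=args.seed)
    div.to_csv(out / "beneficial_divergence.tsv", sep="\t", index=False)
    by_rate = div.groupby("beneficial_rate")["divergence"].mean()
    print("exonic divergence by beneficial mutation rate:")
    print(by_rate.round(6).to_string())


if __name__ == "__main__":
    main()
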