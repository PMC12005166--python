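# Methods

`demodfe` implements a two-step inference framework for species with
coding-sparse genomes, together with the machinery needed to evaluate it on
synthetic data: demographic inference from putatively neutral regions
(step 1), DFE-conditioned forward simulation of functional regions
(step 2), and an assessment of sweep detectability under the resulting
baseline model.  This note records the models, the parameters that matter,
the numerical choices, and what the desk-scale experiments do and do not
demonstrate.

## The demographic model

The demographic model has five populations — an ancestral African
population (AFR, sampled at present), an unsampled ancestral Eurasian
population (EURASI), and European, East Asian and South Asian populations
(EUR/EAS/SAS) dispersing from EURASI — and exactly 25 free parameters:

| group | parameters | units |
| --- | --- | --- |
| sizes | N_AFR_anc, N_EURASI, N_EUR, N_EAS, N_SAS | diploids |
| split times | tau_OOA, tau_EUR, tau_EAS, tau_SAS, tau_BANTU | generations ago |
| bottleneck severities | B_EURASI, B_EUR, B_EAS, B_SAS | fraction of source size, (0, 1] |
| growth rates | r_AFR, r_EUR, r_EAS, r_SAS | per generation |
| migration | m for the 7 pairs (AFR–EURASI, AFR–EUR, AFR–EAS, AFR–SAS, EUR–EAS, EUR–SAS, EAS–SAS) | per generation, symmetric |

A generation time of 26.9 years converts calendar times to generations;
12 My (the human–chimpanzee split used as the divergence horizon) is
446,100 generations at that rate, rounded to the nearest hundred.

**Bottleneck semantics.** "Severity" B is the founded population's size as a
fraction of its source's size at founding.  A literally instantaneous
recovery would give B no effect on coalescence, so founding is modelled as
an epoch of `bottleneck_duration` generations (default 100) at size
B x N_source, followed by the population's own N with exponential growth r
to the present (present size N e^{r tau}).  The duration is capped at half
the population's lifespan so short-lived populations remain valid.

**Existence windows.** EURASI exists from the OOA split until its most
recent daughter dispersal; migration for a pair is active only while both
populations exist.  AFR must be explicitly active from time zero in the
coalescent backend because it is also the ancestral population of the OOA
split.

Coalescent replicates of curated regions are generated with msprime under
the biallelic infinite-sites approximation (continuous positions, no
recurrent hits), one mean mutation and recombination rate per region,
with empirical masks re-applied to simulated samples so both data types
pass through identical statistic code.

## Curation

Step-1 regions are the complement of the annotation padded by
`min_distance` (default 10 kb, measured between interval boundaries), kept
when the unmasked span is at least `min_length` (default 15 kb).
Accessibility and conservation masks are recorded inside retained regions
and removed from statistic denominators rather than splitting regions.
Mean rates are length-weighted over the covered bases of the rate maps;
regions with zero rate-map coverage are dropped.  The 15 kb threshold is
applied to the unmasked span; applying it after masking would be the
natural alternative and is a one-line change.

## Summary statistics

The fitting vector holds 18 statistics: per population the segregating-site
density (polymorphic unmasked sites over accessible bp), Tajima's D and
mean r² over 10 kb windows with 5 kb step, and Hudson's F_ST for the six
population pairs, combined across variants as a ratio of sums
(Bhatia-style).  Windows with no segregating sites are skipped, not
zero-filled; r² uses derived-allele indicators with no frequency cutoff;
the Weir–Cockerham estimator is available behind a flag.  With two
haplotypes D is defined as 0 (its numerator and variance both vanish).
Note that Hudson's estimator is slightly negative, O(1/(n-1)), when the two
samples have identical allele counts; it is unbiased around zero only in
expectation.

Divergence is fixed differences between reference and ancestral sequence
with polymorphic sites masked, divided by the total region length (the
denominator deliberately does not exclude masked or polymorphic bases; the
alternative convention would shift all divergences by a common factor).
For forward simulations it is the count of post-burn-in fixations per bp.

H12 pools the two most frequent exact haplotypes:
H12 = (p1 + p2)² + Σ_{i≥3} p_i², computed over the unmasked SNPs of a
window centred on a focal SNP.

Replicate aggregation follows the display convention: per-region mean and
SD across replicates; the summary point is the mean of region means and the
error bar the mean of region SDs.

## Grid-search fitting

The objective is Σ ((sim − emp)/scale)² over the 18 statistics, scales
being the empirical across-region SDs (floored at 1e-12).  Two coarse
traversals are provided: iterative coordinate sweeps from the grid midpoint
(the only feasible option in 25 dimensions), and full factorial evaluation,
selected automatically when the grid has at most 250 points.  The sweep
strategy can be trapped by compensation ridges (e.g. a smaller ancestral
size offset by a weaker bottleneck); factorial evaluation is immune, which
is why low-dimensional reductions use it.  The fine stage lays a grid of
±1 coarse step around the coarse optimum at `refinement_factor` times the
resolution (default 4; the recovery study uses 2), clipped to the declared
ranges, with the coarse optimum kept on the grid so the fine distance never
increases.

Candidate evaluations use common random numbers: simulation seeds derive
from the master seed and the (region, replicate) pair but not the
parameter point.  With point-dependent seeds the Monte Carlo noise between
neighbouring points dominated the parameter signal at desk scale; with
common random numbers the ranking of points is driven by the parameters.
The data being fitted are always simulated with seeds independent of the
evaluator's.

## Forward simulator

A discrete-generation diploid Wright–Fisher engine over one linear
chromosome: multiplicative fitness across sites with genotype fitnesses
1, 1+hs, 1+s (h = 0.5 by default; s < 0 deleterious, s > 0 beneficial),
multinomial parent sampling weighted by fitness, Poisson crossovers placed
by a piecewise-constant recombination map, Poisson mutation influx placed
by the mutation map with infinite-sites rejection of currently-used
positions (substituted positions stay used; lost positions can be re-hit).
Only exonic bases draw selection coefficients from the DFE; intronic and
intergenic mutations are neutral.

The DFE is a mixture of four classes with frequencies f0–f3 on
2 N_ref s boundaries [0,1), [1,10), [10,100), [100, 2N_ref] (s capped at 1),
uniform on the 2Ns scale within a class, plus an optional beneficial class
whose frequency is taken out of f0.  N_ref is the ancestral African size.

Runs consist of a 10 N_ref burn-in followed by a divergence window during
which demographic events fire at their times before present; fixations
after burn-in are logged (position, s, generation, element) and give
simulated divergence.  The sweep-scan chromosome is 7 functional regions of
9 exons (1,317 bp) and 8 introns (1,520 bp) separated by 4,322 bp
intergenic spacers — 198,345 bp in total.  Per-replicate heterogeneous
rate maps draw segment rates uniformly and rescale them so each replicate's
mean equals the configured genome-wide mean exactly.

Conditioned sweeps introduce a single copy with s_b = 2Ns_b / (2 N_ref)
into the scenario's population (AFR after burn-in; EURASI at the OOA
split; EUR at its founding) and restart from a snapshot taken at the
introduction generation — not a fresh burn-in, which bounds runtime —
until the allele is fixed in every conditioning population at sampling
time, up to a configurable restart cap (default 10,000).

Empirical-scale sizes are not tractable forward in time on one CPU;
`OOADemography.scaled(kappa)` applies the standard rescaling (sizes and
times / kappa, per-generation rates and selection coefficients x kappa).

## Sweep scans

The CLR scan follows the SweepFinder family.  The background SFS pools
derived-allele counts (classes 1..n, with fixed-derived substitutions in
class n) from sweep-free replicates.  At a test position, each of the n
lineages escapes the sweep independently with probability
p_e = 1 − exp(−alpha d), d being the recombination distance to the site;
the k escapees plus the single swept ancestral lineage are a hypergeometric
draw from the background sample, and the swept lineage's allele is copied
to the n−k non-escapees.  The resulting class distribution is renormalised
to the observable classes.  Λ = 2(max_alpha ln CL_sweep − ln CL_background)
is maximised over a 40-point geometric alpha grid spanning escape
probabilities from ~0 to ~1 at the data's distance scale; alpha → ∞
recovers the background, so Λ ≥ 0.  H12 scans evaluate the statistic at
each SNP for window widths of 1–40 kb.

Power is summarised at replicate level: a sweep replicate scores its
maximum within `tp_radius` (default 1 kb; the power study uses 2 kb to
cover the scan grid spacing) of the true sweep site, a null replicate its
genome-wide maximum; thresholds sweep the pooled scores, giving a
staircase ROC whose trapezoid AUC equals the Mann–Whitney U probability.

## Synthetic data

The generator emulates the empirical inputs: genes placed without overlap
to a target density with multinomially distributed gaps; inaccessible and
conserved bases drawn as geometric-length blocks (mean 300 bp) to mimic
mask clumping, conserved blocks restricted to noncoding sequence;
piecewise-constant rate maps in 50 kb segments; a random ancestral base
per position; and polymorphism simulated under a known truth model, with
masked sites removed, written as one VCF per chromosome (REF = ancestral
allele, AA INFO tag) plus a sample panel.  The truth (parameters, rates,
seed) is serialised next to the data and never read by inference code.
Defaults follow the 1000 Genomes-style conventions: sample sizes
AFR 99 / EUR 502 / EAS 104 / SAS 489 diploid individuals (1,194 samples;
the counts are treated as individuals, not haplotypes), biallelic sites
only, per-bp rates in the 1e-8 range.

What the generator does **not** emulate: sequencing/genotyping error,
missing data, multiallelic and structural variation, gene conversion,
admixture pulses, and realistic chromosome lengths.  Tests passing on this
synthetic data demonstrate the correctness of the machinery, not the
fidelity of any fitted model to real human data.

## Desk-scale experiment design

The empirical study this package procedurally mirrors used 146 curated
nonfunctional regions x 100 msprime replicates and 397 exonic regions in
SLiM at cluster scale; its fitted values (e.g. a final African size of
87,594) are not reproducible on one CPU and are not targets here.  The
bundled experiments use problem sizes chosen to finish in minutes:

- **Desk truth model**: sizes 1,000–3,000 diploids, splits at 700–2,000
  generations, a severe (B = 0.05) and relatively recent Eurasian founding
  bottleneck of 200 generations so that bottleneck severity is identifiable
  from ~100 kb-scale data — mirroring the real situation, where the OOA
  bottleneck is one of the strongest signals in human polymorphism data.
- **Parameter recovery**: 3 free parameters (N_AFR_anc, tau_OOA, B_EURASI;
  the other 22 clamped at truth), 3-point coarse grids containing the truth
  away from the midpoint start, 20 regions of 20 kb x 20 replicates as
  data, factorial coarse pass, fine refinement factor 2.  Grid resolution is
  matched to what that data volume can discriminate — with fine steps much
  below ~1,000 generations in tau_OOA the empirical Monte Carlo noise
  shifts the distance optimum off the truth and recovery degrades to a
  coin flip, so the ranges are wide (coarse steps of 2,000 generations /
  2,000 diploids / 0.4 severity).  The coarse pass uses a cheap evaluator
  (6 common-random-number replicates per region; coarse steps carry a large
  signal); the fine stage evaluates at the data's own depth (20).
- **Neutral calibrations**: a collapsed single-population model (B = 1,
  m = 0, r = 0, splits at 1–3 generations) checked against E[pi] = 4 N mu
  through the coalescent path (N = 500) and through the forward engine
  (kappa = 10: N = 50, mu and r x 10).
- **Background selection**: a 10 kb exon flanked by 5 kb neutral spacers,
  N = 100, exonic mu = 5e-6; the deleterious fraction goes into the weakly
  deleterious class (f1) because B ≈ e^{−U/2s}: per unit of deleterious
  input weak selection removes the most linked diversity, while at these
  population sizes strongly deleterious mutations are purged too quickly
  to leave a measurable footprint.
- **Beneficial rates**: a 10 kb exon, strong beneficials
  (2Ns_b in [100, 1000)), divergence compared across
  f_b in {0, 0.1%, 1%, 10%} — the diagnostic that a 10% beneficial rate
  inflates divergence far beyond the no-positive-selection baseline.
- **Sweep power**: a one-functional-region layout (28,335 bp), a
  two-epoch-style reduction with N_ref = 100 and a EUR founding ~20
  generations before sampling, so the conditioned 2Ns_b = 10,000 sweep is
  sampled with minimal post-fixation recovery (the best-case scenario this
  analysis represents; with longer recovery, new singletons arise at
  distances where the escape model predicts only swept classes and CLR
  power collapses — a real property of the statistic, not an artefact).
  Scan data for a sampled population include sites fixed within the sample
  (count-n class): a local sweep's hitchhikers are substitutions relative
  to the ancestor even though they still segregate species-wide.  The CLR
  grid always contains the substitution positions (hard sweeps erase the
  SNPs around their site), the sweep arm scores its maximum within 5 kb of
  the true site, and H12 uses 20 kb windows with global-maximum scoring on
  both arms because the swept haplotype spans most of the region at this
  scale.  The background SFS carries a 0.5 pseudocount per class so
  frequency classes unobserved among the nulls keep nonzero probability.
  AUCs are computed against 24–40 sweep-free nulls; a placebo AUC
  (even/odd split of the null arm) checks calibration.

## Known limitations

- The forward engine records no tree sequences and is not suitable for
  chromosome-scale or N > ~10³ runs; that is what the rescaling is for.
- The CLR implementation uses the star-like escape approximation and a
  grid over alpha; it is a native reimplementation in the SweepFinder
  tradition, not a byte-compatible port.
- B maps, liftover, conservation-score computation and real-data download
  paths are out of scope; the empirical-format path is exercised end to end
  on synthetic files only.
- The 25-parameter registry follows one concrete instantiation of the
  model topology; the ranges shipped with the recovery study cover only
  its 3-parameter reduction.
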