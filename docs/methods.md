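# Methods

## The demographic model

`triabc` models three closely related species (P1, P2, P3 — by default
labelled *helenor*, *achilles* and *deidamia* after the *Morpho*
butterflies the design is shaped on) as the product of two nested splits.
Backwards in time, P1 and P2 merge at `T_split12` into an ancestor of size
`N_anc12`; that ancestor merges with P3 at `T_split123` into a root
population of size `N_anc123`. Every split is accompanied by a size change
whose value is independent of the ancestral size, and each modern lineage
additionally undergoes one recent size change: lineage *i* has current
size `N_i` on `[0, T_change_i)` and founding size `N_found_i` earlier.
`T_change_P1/P2` are bounded by `T_split12` and `T_change_P3` by
`T_split123` — a lineage cannot change size before it exists. All sizes
are diploid individuals; all times are generations before present.

Gene flow may connect every pair of lineages, in `4Nm` units. The eight
scenario categories fix its temporal pattern:

* **Inner flow (P1–P2)** — *ancestral migration* (`AM`): flow on
  `[T_trans12, T_split12]`, none at present; or *secondary contact*
  (`SC`): flow on `[0, T_trans12]`, ongoing at present. The transition
  time is `T_trans12 = B * T_split12` with `B ~ Beta(5, 1)` under `AM`
  and `B ~ Beta(1, 5)` under `SC`. The asymmetric Beta shapes keep the
  two regimes from collapsing onto each other when the transition time
  approaches 0 or the split time; the shapes are used exactly as given,
  without truncation.
* **Outer flow (with P3)** — none (`SI`), with P1 only (`P3P1`), with P2
  only (`P3P2`), or with both (`P3BOTH`); active on `[0, T_split123]`.
  After the inner merge the P1/P2 ancestor carries the enabled outer
  migration at the same scaled rate (summed if both pairs are enabled);
  carrying outer flow through the ancestral epoch keeps `T_split123` the
  only time at which it can stop, which is the natural reading of
  "active until the outer split".

Migration epoch boundaries are applied exactly at
`T_trans12`/`T_split12`/`T_split123`, the boundary belonging to the older
epoch. Scaled rates are converted to per-generation backward rates using
the *recipient* lineage's current size, `m = M / (4 N)`; the scaled rate,
not the per-generation rate, is held fixed when a locus's effective size
is rescaled by a heterogeneity factor.

Each category is crossed with four sub-models of genomic heterogeneity
(a reduced model of linked selection): per-locus multiplicative factors
on effective size (Beta-distributed, rescaled to mean 1 across loci) and
on migration (Beta-distributed on `[0, 1]`), each switched on or off.
The Beta shape hyperparameters are themselves drawn per simulated
dataset, uniformly on `[0, 20]` (re-drawn if both shapes fall below 0.1,
which would put nearly all mass at the extremes); the bounds follow the
convention of the DILS family of pipelines. Locus factors rescale every
epoch of the locus, ancestral populations included.

## Priors

| parameter | prior | units |
|---|---|---|
| all 8 population sizes | Uniform(0, 1,000,000), re-drawn below 10 | diploid individuals |
| `T_split123` | Uniform(0, 8,000,000) | generations |
| `T_split12` | Uniform(0, `T_split123`) | generations |
| `T_change_i` | Uniform(0, origin of lineage *i*) | generations |
| `T_trans12 / T_split12` | Beta(5, 1) (`AM`) or Beta(1, 5) (`SC`) | — |
| `M12`, `M13`, `M23` | Uniform(0, 50); zero where the category blocks the pair | 4Nm |
| heterogeneity shapes | Uniform(0, 20) per shape | — |
| `mu` | fixed, 3e-9 | per bp per generation |

The re-draw floor of 10 diploids exists because a literal size of 0 is
not simulable; it removes 1e-5 of the prior mass.

## Simulation

Genealogies come from msprime's structured coalescent (one
non-recombining genealogy per locus; RAD loci are a few hundred bp, and
no intralocus recombination is modelled). Mutations are placed in-house
on the tskit trees under two modes:

* **theta mode** — `Poisson(mu * L * total branch length)` infinite-sites
  mutations, each landing on a branch with probability proportional to
  its length; the per-locus mutation input is therefore
  `theta = 4 N mu L` through the genealogy itself. Loci with no mutation
  are monomorphic and excluded (not re-simulated — re-simulation would
  condition tree lengths upwards), mirroring how the observed data, which
  contain only polymorphic loci, are ascertained. The segregating-site
  count is capped at L (finite locus).
* **fixed-SNP mode** — exactly the observed number of SNPs per locus is
  placed, branches again weighted by length. This conditions on the
  observed polymorphism directly and sidesteps monomorphic-locus
  bookkeeping.

Derived alleles are encoded 1 with the simulation root state 0, which
makes ABBA-BABA polarization exact for simulated data.

## Summary statistics

Per locus: nucleotide diversity, Watterson's theta and Tajima's D per
species; gross (`d_xy`) and net (`d_a`) divergence, F_ST, and per-site
proportions of shared polymorphisms, fixed differences and exclusive
polymorphisms per pair; ABBA-BABA numerator and denominator sums with
(P1, P2, P3) ordering. Conventions this implementation fixes:

* **F_ST estimator** — `1 - pi_within / pi_total` (pooled-sample
  denominator), the convention of the DILS family; Hudson's
  `1 - pi_within / d_xy` is available behind `estimator="hudson"`.
* **SD convention** — population SD (ddof = 0), applied identically to
  observed and simulated vectors, so the choice cancels in the ABC
  comparison.
* **Missing values** — statistics undefined at a locus (Tajima's D with
  S = 0, F_ST at a pair-monomorphic locus) are excluded from that
  statistic's mean/SD, never imputed; a statistic undefined at every
  locus contributes 0 to keep vectors finite.
* **Polarization of real data** — with no outgroup in the sampling
  design, observed data are polarized by the pooled-sample major allele,
  an explicit approximation (`polarization="major"`); simulated data
  round-trip exactly under `polarization="lex"` because the writer emits
  ancestral states as `A` and derived as `C`.

The ABC input is the mean and SD across loci of each per-locus statistic
(65 entries in a fixed canonical order, ending with the dataset-level
ABBA-BABA D as the ratio of summed numerators to denominators).

## Inference

Model choice is ABC-RF: a 500-tree random-forest classifier on the
labelled reference table, majority vote across trees for the winner, and
the posterior probability of the winner from a second regression forest
(minimum leaf size 5) fitted to the out-of-bag correctness indicator of
the classifier. Tables under 100 rows fall back to the raw winning vote
fraction. The two gene-flow questions are answered independently on
pooled labels — `AM` vs `SC` pooling over outer flow and sub-models, and
the four outer-flow variants pooling over inner flow and sub-models —
rather than sequentially conditioned; each category label therefore pools
its four heterogeneity sub-models.

Parameters are estimated with one 500-tree regression forest per
parameter; the central 90% interval is the 5%–95% quantile range of
per-tree predictions (widened if needed to contain the point estimate,
which is the forest mean). Estimation runs on the table restricted to the
winning category, pooling its sub-models, in line with the pooled model
choice. Relative reporting divides sizes by the estimated current P1 size
(so `N_P1 = 1` exactly) and expresses times in units of `4 N_P1`
generations; migration rates are already scale-free.

The posterior predictive check rebuilds a simulable draw from the point
estimates (clipping any nesting violations produced by the independent
per-parameter forests), simulates replicate datasets and reports the
two-sided empirical tail probability of each observed summary entry.

## The synthetic-data generator

Pseudo-observed datasets (PODs) emulate the empirical dataset shape:
20/26/16 allele sequences for P1/P2/P3 (10/13/8 diploid males), 2,740
polymorphic biallelic loci with lengths in [343, 908] bp (the fixed-SNP
preset exposes the alternative [339, 894] range). Lengths are uniform on
the range by default; a truncated-geometric option reproduces the
empirical mean length of 463.12 bp, which a uniform cannot. POD SNP
counts arise from theta-mode simulation itself rather than being imposed,
so the fixed-SNP inference mode can be tested against data whose counts
it must match; simulation rounds continue until the target number of
polymorphic loci is collected, reproducing the polymorphism conditioning
of the observed data. A plain-text sidecar (category, sub-model, full
draw, seed, preset) regenerates any POD byte-identically.

What the generator does *not* emulate: sequencing error, missing data
(sites with any non-ACGT base are dropped locus-wide on reading, matching
a dataset reported to have none), linkage between loci, selection beyond
the rescaling factors, and reference-assembly artefacts. Passing tests
therefore demonstrate the estimator's statistical behaviour under the
model, not robustness to real-data pathologies upstream of the SNP
matrices.

## Problem sizes and numerical choices

The full-scale design (50,000 simulations per model, 2,740 loci per
dataset) is what the production drivers are written for; the shipped
test-suite and acceptance runs use reduced sizes chosen to keep a
single-CPU run in minutes while leaving the statistical checks
well-powered: 50 draws per (category x sub-model) — 200 datasets per
category — with 80 loci per dataset for model choice and parameter
recovery; 10,000 loci for the Watterson/Tajima calibration; 100,000
placements for the fixed-SNP branch test; 500 loci per grid point for the
monotonicity checks. Held-out classification accuracy is measured
out-of-bag, which uses every table row as a validation point without
extra simulation.

Other numerical conventions: simulations that yield zero polymorphic loci
(possible in theta mode under near-degenerate draws) are logged and
re-drawn, with a run error if they exceed 1% of attempts; per-locus Ne
factors are floored at 1e-4 to keep sizes positive; random seeds derive
from `numpy.random.SeedSequence` so every stage is reproducible
bit-for-bit, and forest training is seeded through the same stream.

## Known limitations

* The eight categories are the full model space; cyclic
  contact/isolation histories and models with more than three populations
  are out of scope, so "best model" means best within this set.
* Absolute sizes and times are weakly identified when only polymorphic
  loci are analysed; relative reporting (`N_P1 = 1`) is the robust output.
* The major-allele polarization of real data biases ABBA-BABA D towards 0
  at sites where the derived allele is in the majority; simulated-data
  checks use exact polarization instead.
* Theta-mode reference tables let the surviving locus count vary across
  simulated datasets; the summary vector is insensitive to the count, but
  very small surviving sets produce noisy vectors and are part of what
  the classifier must absorb.
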