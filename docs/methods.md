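# Methods

`biogasnet` re-implements, as a tested library, the computational chain used
to analyse replicated metaproteomes of full-scale biogas plants: dominant
methanogenic-pathway classification from KO-level protein abundances,
CoNet-style ensemble co-occurrence network inference with resampling
significance, Guimerà–Amaral topological-role analysis, and
environmental-parameter screens. This note records the models, the parameter
choices, and the places where the design was genuinely open.

## Data model

An abundance table is a samples × features `DataFrame` (rows indexed by
`(plant, replicate)`), holding nonnegative relative abundances; absence is a
zero, never a missing value, and "present" means strictly positive. On disk
the transposed TSV layout (rows = protein groups, columns = `plant:replicate`)
is used. Annotations map each protein group to a species id (`S` + 4 digits),
species name, family, and KO/EC identifier sets.

Preprocessing follows the study design: a protein group is kept when at least
3 of a plant's 5 replicates observe it (in any one plant; a per-plant masking
variant is available), and every sample is closed to 100%. A protein group
annotated with k KO terms contributes its full abundance to each KO by
default (`multi_ko="full"`), because per-KO reference abundances are reported
unpartitioned; an even-split variant is provided.

## Pathway classification (factor F)

For a KO-level profile, the abundances of the KO terms *unique* to
acetoclastic methanogenesis (ackA, pta, ACSS, the cdh subunits; 6 terms) and
to hydrogenotrophic methanogenesis (fmd subunits, ftr, mch, mtd, hmd, mer;
11 terms) are summed and

F = acetoclastic-unique sum / hydrogenotrophic-unique sum.

`F ≥ 2.5` calls the unit acetoclastic, `F ≤ 0.4` hydrogenotrophic, otherwise
"both" (thresholds inclusive, exposed as parameters). The mtr complex
(shared by the two routes), the terms common to all routes (mcr, hdr, mvh,
fdh) and the methylotrophic mta terms are excluded from F by construction but
reported. `F = ∞` (no hydrogenotrophic signal) classifies as acetoclastic;
both sums zero is treated as a data error, not a "both" call. Classification
runs per replicate (for network partitioning) or per plant (replicate means
re-closed to 100%).

The package ships a reference per-KO abundance table for a published panel of
16 agricultural biogas plants; re-summing it reproduces the printed pathway
sums to their printed precision and re-classifying it reproduces all 16
published pathway calls (8 hydrogenotrophic, 5 acetoclastic, 3 both). Note
the printed per-KO values round-trip to the printed sums only within 0.002
(rounding of the printed components); tests assert at printed precision where
the sums match exactly.

## Ensemble co-occurrence networks

Networks are inferred separately for the replicate set of each pathway class,
on species-level tables:

1. **Prevalence filter.** Species present in ≥ 60% of the replicate set
   (⌈0.6·n⌉ samples) are scored.
2. **Five association measures** per unordered pair: Pearson, Spearman and
   Kendall (tau-b) correlation, Bray-Curtis dissimilarity, and symmetrized
   Kullback-Leibler divergence. KL needs distributions: each species vector
   is normalized to sum 1 after adding a 10⁻⁶ pseudocount. Correlations
   signal co-presence when positive; dissimilarities when *below* their
   permutation-mean null value.
3. **Candidate selection.** Per method, the 2,500 strongest co-presence and
   2,500 strongest exclusion pairs (capped at the pair count for small
   tables; rank ties break lexicographically by pair id).
4. **Support filter.** An edge survives when ≥ 3 of the 5 methods selected
   the pair in the same direction; the edge direction is the majority
   direction among selecting methods, and a tie drops the edge.
5. **Per-method significance.** The p-value of the observed score is the
   two-sided tail under a Normal fit to the score's *permutation null*
   (every involved species' vector permuted independently). For the three
   correlations the permutation-null moments are exact in closed form —
   mean 0 and Var(r) = 1/(n−1) for Pearson and Spearman, Kendall's
   2(2n+5)/(9n(n−1)) — so no sampling error enters; Bray-Curtis and KL use
   the empirical permutation mean and sd (100 rounds). A bootstrap
   distribution of the score (column resampling, 100 rounds, same stream)
   guards stability: a degenerate bootstrap (sd = 0, e.g. a perfectly
   monotone pair) short-circuits the p-value to 0 off the null and 1 at it.
   A one-sided variant (tail opposite the effect direction) is available;
   the two-sided default is the calibrated choice, because a tail chosen by
   the observed sign folds onto (0, 0.5) under the null and is not a valid
   input to Brown's method.
6. **Brown's method** merges the supporting methods' p-values, accounting
   for their dependence: with X = −2Σln pᵢ over k methods, X ≈ c·χ²_f with
   E[X] = 2k, Var[X] = 4k + 2Σᵢ<ⱼ covᵢⱼ, c = Var/2E, f = 2E²/Var. The
   covariance of the −2 ln p terms is estimated per method pair as the
   Spearman correlation of the p-value vectors across all candidate edges,
   mapped through the Kost–McDermott polynomial 3.263r + 0.710r² + 0.027r³
   (exact at the independence and total-dependence limits; the rank
   correlation is immune to the near-zero p-values of strong edges, which
   otherwise dominate a raw covariance). Zero covariance reduces exactly to
   Fisher's method; total dependence returns the shared p.
7. **Benjamini–Hochberg** across edges; edges with q < 0.05 form the
   undirected, signed, simple graph.

All randomness descends from one master seed through named substreams
(`zlib.crc32` of "purpose|method|pair"), so results are independent of
evaluation order; within `CooccurrenceNetwork.fit` all pairs of a method
share each resampling round (vectorized), while the single-pair
`bootstrap_pvalue` derives its stream from (seed, method, pair).

Measured behaviour at the study's design size (30 species, 40 replicates,
100 iterations): per-method p-values are uniform under an independent-pairs
null (KS p between 0.12 and 0.82 per method), a fully permuted table retains
0 of 435 tested candidate edges, and the planted benchmark below is
recovered at 100% recall / 94% precision.

## Topology and roles

Module detection is greedy modularity maximization (networkx) on the
unsigned, unweighted skeleton — a deterministic stand-in for interactive
community-detection plugins, so module *counts* are not expected to match any
particular tool. Edge signs feed only the summary counts. Per node:
within-module degree z (own-module link count standardized against the
module, population sd; sd = 0 ⇒ z = 0) and participation coefficient
P = 1 − Σₛ(kᵢₛ/kᵢ)² (isolated node ⇒ 0). Roles use the standard cuts:
peripheral (z ≤ 2.5, P ≤ 0.62), connector (z ≤ 2.5, P > 0.62), module hub
(z > 2.5, P ≤ 0.62), network hub (z > 2.5, P > 0.62); the network-hub
participation cut is exposed as a flag. Summaries count nodes, signed edges,
in/out-of-module edges, modules and roles.

## Environmental screens

Features floored at a mean relative abundance of 0.1% (inclusive) are
screened against per-plant process parameters with Spearman's rho at
p ≤ 0.01; replicates inherit their plant's metadata (a plant-mean mode is
provided, since which of the two the original analysis used is not stated).
No multiple-testing correction is applied by default, matching the original
raw-p screen. Metadata collinearity uses VIF = 1/(1−R²) from least-squares
regressions, removing variables ≥ 10 iteratively, highest first; perfect
collinearity yields infinite VIF and is removed first. The screen requires
more plants than variables and is skipped (with a warning) otherwise.

## Synthetic data generator

The generator emulates the study design — default 16 plants × 5 replicates,
~40 species expanding to a few hundred protein groups — with fully known
ground truth. The generative model:

- Non-methanogen species: log-normal base abundance (sd 1.0 across species)
  plus an independent per-sample log-normal fluctuation (sd 0.7 ≈ 80% CV).
- **Planted associations** are realized by shared per-sample latent factors.
  Planted edges are validated to form *complete, sign-consistent groups*
  (each species loads once, with sign, on its group's factor; edge sign =
  product of endpoint signs; all within-group pairs planted), which is the
  only layout one factor per group can realize without leaking unplanted
  structure. Loadings are ±√ρ, so a planted pair's latent log-abundances
  correlate at ≈ ±ρ.
- **Methanogenesis mass**: four carrier species (two Methanosarcina-like,
  two Methanoculleus-like) hold the KO mass. Per sample, the
  acetoclastic-unique : hydrogenotrophic-unique budget ratio equals the
  plant's F_true *exactly* before noise; within each budget group the
  individual KO features fluctuate (sd 0.7) and are renormalized to the
  group budget. Keeping group totals stable relative to the panel-mean
  background both preserves F and damps the closure denominator; early
  designs that let the block swing coherently wrote spurious correlations
  into every pair through the shared denominator.
- Species mass splits over 2–6 protein groups with fixed Dirichlet weights;
  a third of bacterial groups carry an irrelevant housekeeping KO to
  exercise KO-level aggregation.
- Multiplicative log-normal replicate noise (sd 0.3), dropout (a
  feature-replicate cell zeroed with probability 0.05; 0.02 in the network
  benchmark), then compositional closure to 100%.
- Metadata: temperature, pH, VFA, C/N and six substrate fractions per plant;
  a planted link makes a variable a monotone function of the per-plant
  latent that also drives the linked species.

Because closure is applied last, planted correlations are specified on the
latent scale; `GroundTruth.realized_rho` reports the realized post-closure
Spearman of every planted pair, and recovery tests compare against realized
values. With the defaults, ≥ 90% of planted co-presence pairs at ρ = 0.9
realize Spearman ≥ 0.6 (the generator's self-check); exclusion pairs realize
≈ −0.4 to −0.7 because noise and closure dilute negative associations more
than positive ones. The carrier species are listed in
`GroundTruth.carrier_species`; edges touching them are excluded from
planted-edge precision/recall, since the carriers hold the designed pathway
signal and the generator makes no independence claim about them.

The default network benchmark (`benchmark_network_config`, seed 1) is a
30-species, 8-plant × 5-replicate, single-pathway-class table with 10 planted
co-presence and 5 planted exclusion pairs at ρ = 0.9, laid out as 8 disjoint
co-presence pairs, two (+, +, −) triples and one disjoint exclusion pair
(15 disjoint pairs would need more non-carrier species than a 30-species
table has).

What the generator does *not* emulate: peptide/protein inference artifacts,
shared peptides, intensity-dependent missingness (dropout is uniform),
taxonomic correlation structure beyond the planted groups, and
plant-level community composition differences. Passing recovery tests
therefore demonstrate correctness of the inference chain under a
known-truth compositional model, not performance on real metaproteomes.

## Numerical and procedural choices

- p = 0 is clamped to 10⁻³⁰⁰ before Brown merging (logged).
- Brown covariances are clipped to [−4, 4] (the theoretical range).
- Candidate thresholds scale down to the pair count automatically.
- Rank ties in candidate selection break lexicographically by pair id;
  direction ties in the support filter drop the edge.
- Constant vectors under a correlation are undefined: the pair is skipped
  and logged; a resample that turns a needed vector constant is redrawn (at
  most 10 times).
- The replicate partition of the pipeline is exhaustive and exclusive;
  classes with fewer than 3 replicates skip network inference with a
  warning; replicates with no methanogenesis signal at all are excluded from
  the partition with a warning.
- Problem sizes in the test-suite and acceptance script (30–40 species,
  40 replicates, 100 resampling rounds, 100-seed label sweeps) are the
  study's own design sizes; the oracle checks run on ≤ 10-feature tables
  where brute-force enumeration is exact.

## Known limitations

- Module counts from greedy modularity will generally differ from plugin-
  based community detection on the same graph; summaries are property-based,
  not count-matched.
- Brown's χ² moment-matching is approximate in the extreme tail under
  strong inter-method dependence; the BH threshold operates in that tail, so
  the realized FDR on dense candidate sets can exceed the nominal 5%
  slightly (observed ≈ 2× at p ≈ 0.002).
- The Kendall null variance ignores tie corrections (ties arise only from
  dropout zeros and are rare after the prevalence filter).
- The Spearman environmental screen is reported uncorrected by design; a BH
  option exists but is off by default.
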