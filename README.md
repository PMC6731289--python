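# biogasnet

Methanogenic-pathway classification and ensemble co-occurrence network
analysis for biogas-plant metaproteomes.

Anaerobic digesters make methane by two main routes: splitting acetate
(acetoclastic methanogenesis, *Methanosarcina*-type) or reducing CO₂ with H₂
(hydrogenotrophic methanogenesis, *Methanoculleus*-type). Given a replicated
protein-group relative-abundance table with KO/species annotations — the
standard output of a quantitative metaproteomics workflow — this package

1. **classifies the dominant pathway** of each sample or plant from the ratio

   *F* = Σ abundance(acetoclastic-unique KO) / Σ abundance(hydrogenotrophic-unique KO),

   with *F* ≥ 2.5 → acetoclastic, *F* ≤ 0.4 → hydrogenotrophic, otherwise
   "both";
2. **infers a signed co-occurrence network** per pathway class with a
   five-method ensemble (Pearson, Spearman, Kendall, Bray-Curtis, symmetrized
   Kullback-Leibler), a ≥3-of-5 direction-consensus support filter,
   resampling-based per-method p-values, Brown's method for dependent
   p-values, and Benjamini-Hochberg control at q < 0.05;
3. **assigns topological roles** (peripheral / connector / module hub /
   network hub) from within-module degree *z* and participation coefficient
   *P*ᵢ = 1 − Σₛ(kᵢₛ/kᵢ)² with the standard cuts z = 2.5, P = 0.62; and
4. **screens process parameters** (temperature, pH, VFA, substrates, C/N)
   against abundances with Spearman's rho at p ≤ 0.01 plus a VIF < 10
   collinearity screen.

A synthetic-data generator with fully known ground truth (planted pathway
ratios, planted co-presence/exclusion pairs, planted metadata links)
backs every stage with recovery tests, and a packaged reference KO-abundance
table for 16 full-scale biogas plants provides a worked example against
published numbers. The estimators follow scikit-learn conventions
(`fit`/`transform`/`predict`, `get_params`, fitted `_` attributes) and
compose with sklearn pipelines.

## Worked example 1: pathway calls on the packaged reference panel

```python
import biogasnet as bn
from biogasnet.pathways import pathway_sums, compute_F, classify_F

table, groups = bn.load_reference_ko_table()   # KO x 16-plant % abundances
for plant in ["BP01", "BP04", "BP06", "BP09"]:
    s = pathway_sums(table[plant])
    F = compute_F(s["aceto_sum"], s["hydro_sum"])
    print(f"{plant}: aceto={s['aceto_sum']:.3f}%  hydro={s['hydro_sum']:.3f}%  "
          f"F={F:.3f}  ->  {classify_F(F)}")
```

prints

```
BP01: aceto=9.385%  hydro=2.764%  F=3.395  ->  acetoclastic
BP04: aceto=1.325%  hydro=13.295%  F=0.100  ->  hydrogenotrophic
BP06: aceto=2.103%  hydro=9.853%  F=0.213  ->  hydrogenotrophic
BP09: aceto=5.234%  hydro=4.405%  F=1.188  ->  both
```

The acetoclastic sum for BP01 (9.385%) is the summed abundance of the six
KO terms unique to the acetate route; F = 9.385/2.764 ≈ 3.4 ≥ 2.5 calls the
plant acetoclastic. Across all 16 plants the calls reproduce the published
panel: 8 hydrogenotrophic, 5 acetoclastic, 3 mixed.

## Worked example 2: network recovery on synthetic data

```python
from biogasnet.abundance import aggregate

cfg = bn.benchmark_network_config(seed=1)      # 30 species, 8 plants x 5 reps,
X, ann, meta, truth = bn.simulate_dataset(cfg) # 10 + 5 planted pairs, rho=0.9
species = aggregate(X, ann, level="species")
net = bn.CooccurrenceNetwork(seed=1).fit(species)
report = bn.recovery_report(truth, graph=net.graph_)
print(f"candidates tested: {net.n_candidates_tested_}, "
      f"edges kept: {net.graph_.number_of_edges()}")
print(f"planted-edge recall: {report['edge_recall']:.2f}, "
      f"precision: {report['edge_precision']:.2f}")
```

prints

```
candidates tested: 435, edges kept: 16
planted-edge recall: 1.00, precision: 0.94
```

All 15 planted associations are recovered with the correct sign and one
chance correlation slips through — the behaviour expected of a
BH-controlled screen at q < 0.05.

## Command line

```bash
biogasnet simulate --seed 1 --outdir data/          # synthetic dataset + truth
biogasnet classify-pathway data/abundance.tsv data/annotation.tsv \
    --level plant --out calls.tsv
biogasnet infer-network data/abundance.tsv data/annotation.tsv \
    --seed 1 --out edges.tsv --graphml net.graphml
biogasnet analyze-topology edges.tsv --roles-out roles.tsv --summary-out summary.tsv
biogasnet env-correlate data/abundance.tsv data/annotation.tsv data/metadata.tsv \
    --out corr.tsv --vif-out vif.tsv
biogasnet run --config pipeline.yaml                # full chain + manifest
```

`biogasnet run` executes preprocess → per-replicate classification →
partition into acetoclastic/hydrogenotrophic/mixed replicate sets → one
network per set → roles/summary → environmental screens, and writes a
`manifest.json` with the config, seed, per-stage counts and output digests.

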