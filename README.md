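# bentho

Seasonal dynamics, assembly mechanisms, co-occurrence networks, and
stability of benthic microbial communities, from sample-by-taxon count
tables.

`bentho` is a post-denoising analysis pipeline for amplicon studies of
sediment (or any) microbial communities sampled repeatedly over time. It
takes an ASV/OTU count table with per-sample dates or season labels and an
optional environmental table, and computes, reproducibly and from a single
config:

- **Rarefaction and transforms** — even-depth subsampling without
  replacement, relative-abundance and Hellinger transforms, prevalence
  filtering; TSV/CSV and BIOM 1.0 (JSON) I/O.
- **Diversity** — Shannon (−Σ p ln p) and observed richness per sample,
  Kruskal–Wallis seasonal tests with compact-letter displays, shared/unique
  taxon (Venn region) counts.
- **Community structure** — Bray–Curtis and Jaccard dissimilarity,
  one-way PERMANOVA (R² = SS_between/SS_total, pseudo-F, permutation p),
  and the Baselga partition of Jaccard dissimilarity into species
  **turnover** β_jtu = 2·min(b,c)/(a + 2·min(b,c)) and **nestedness**
  β_jne = β_jac − β_jtu.
- **Environmental drivers** — canonical correspondence analysis (CCA) of
  the Hellinger-transformed table, envfit-style permutation R² per
  variable, and Pearson screens against dominant taxa and alpha indices.
- **Assembly mechanisms** — the Sloan neutral community model: a taxon
  with metacommunity mean relative abundance p has stationary local
  abundance x ~ Beta(N·m·p, N·m·(1−p)), so its occurrence frequency across
  samples of size N is predictable from p alone; the migration rate m is
  fitted by least squares and R² measures how neutral the community looks.
  The **modified stochasticity ratio** MST = min(D, E)/max(D, E) compares
  each within-season pair's observed Bray–Curtis dissimilarity D with its
  expectation E under a constrained null model (richness, totals, and
  regional occupancy structure preserved); MST > 0.5 reads as predominantly
  stochastic assembly, < 0.5 as deterministic.
- **Co-occurrence networks** — Spearman edges (|ρ| > 0.7, p < 0.05 on taxa
  present in >25% of samples), topology (average degree, density,
  clustering, path length, diameter, modularity) against 1000 Erdős–Rényi
  G(V,E) nulls, the small-world coefficient
  r = (CC/CC_rand)/(APL/APL_rand), Louvain modules, and Guimerà–Amaral
  node roles: within-module degree z-score Zi and participation
  coefficient Pi = 1 − Σ_s (k_is/k_i)², with connectors/hubs
  (Zi ≥ 2.5 or Pi ≥ 0.62) flagged as keystone taxa.
- **Stability** — the average variation degree
  AVD_j = (1/n) Σ_i |a_ij − ā_ig| / δ_ig per sample, lower meaning more
  stable, with seasonal group tests.

A first-class synthetic-data module generates neutral, niche-structured,
and full seasonal-study tables (35 samples over a year, temperature and
anti-phase oxygen cycles, nutrient pulses, planted correlated taxon
modules) with ground truth recorded, so every stage of the pipeline can be
verified without any sequencing data.

## Worked example

```python
from bentho import (SeasonalStudySpec, simulate_seasonal_study,
                    PipelineConfig, run_pipeline)

table, env = simulate_seasonal_study(
    SeasonalStudySpec(S=2000, depth=20_000, fraction_neutral=0.85, seed=11)
)
cfg = PipelineConfig(output_dir="demo_out", seed=11,
                     n_permutations=999, n_null=200, n_random_graphs=50)
summary = run_pipeline(cfg, table=table, env=env)
```

prints nothing, but `demo_out/summary.json` (and the per-stage CSVs next to
it) contain, for this seed:

```
shannon_mean 5.49 ± 0.09, observed_mean 825
PERMANOVA by season: R2 = 0.222, p = 0.001
beta partition: turnover 0.445, nestedness 0.019
NCM: m = 0.105, R2 = 0.918
MST overall 0.751  (Spr 0.696, Sum 0.775, Aut 0.705, Win 0.818)
CCA axes 1–2: 9.7% and 4.9% of total inertia; envfit significant:
  Temp, DO, NH4, Sal, EC
network: 247 nodes, 5150 edges, modularity 0.397, small-world r = 4.00,
  64.7% positive edges
AVD by season: Spr 0.721, Sum 0.714, Aut 0.734, Win 0.716 (p = 0.56)
```

Read: this community was generated 85% neutral, and the analysis recovers
that — the fitted migration rate (0.105) matches the generator's 0.1, the
neutral fit is excellent (R² = 0.92), and MST sits well above the 0.5
boundary in every season, i.e. stochastic assembly dominates. Seasonality
is still detectable (PERMANOVA p = 0.001) because the remaining 15% of taxa
track the temperature cycle, and replacement (turnover), not richness loss
(nestedness), carries nearly all of the between-sample dissimilarity.

The same stages are available from the shell:

```bash
bentho simulate study --seed 11 --out table.tsv --env env.csv \
    --metadata md.csv --truth truth.json
bentho alpha table.tsv --metadata md.csv --out alpha.csv
bentho assembly ncm table.tsv
bentho network table.tsv --r-threshold 0.7 --p-threshold 0.05
bentho run --config study.yaml
```

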