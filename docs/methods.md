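# Methods

This note documents the models implemented in `bentho`, the choices made
where the methods literature leaves latitude, what the synthetic generators
do and do not emulate, and known limitations.

## Data model and preprocessing

A `CommunityTable` is a samples × taxa matrix of non-negative counts (or
transformed reals) with per-sample metadata (ISO date, season, group) and
optional taxonomy. Rarefaction draws a single multivariate-hypergeometric
subsample per sample (subsampling without replacement, seeded); samples
below the target depth are dropped, not padded, and the depth and seed are
recorded in provenance. Averaging over repeated rarefactions is deliberately
not done — a single recorded draw keeps every downstream statistic exactly
reproducible.

Seasons follow the meteorological convention (Mar–May spring, Jun–Aug
summer, Sep–Nov autumn, Dec–Feb winter). The prevalence filter keeps taxa
whose occupancy strictly exceeds `min_fraction × n_samples` ("present in
more than 25% of samples" means 9 of 35 passes, 8 does not). The Hellinger
transform is the square root of row-wise proportions, giving each sample a
unit-norm profile that damps dominant taxa before ordination.

BIOM support is a self-contained reader/writer for the BIOM 1.0 JSON
schema (sparse or dense); HDF5 BIOM is out of scope.

## Neutral community model

Under neutral dynamics with migration, the local relative abundance x of a
taxon with metacommunity mean p is stationary-distributed

    x ~ Beta(N·m·p, N·m·(1−p)),

where N is the local community size (reads per sample after rarefaction)
and m the migration rate. The classic occurrence-frequency prediction is
the survival function of this Beta at the detection limit d = 1/N
(`ncm_predict`).

For fitting (`fit_ncm`) the default predicted frequency is instead the
exact beta-binomial detection probability

    P(count > 0) = 1 − B(a, b+N)/B(a, b),   a = N·m·p, b = N·m·(1−p),

because when communities are observed through N sampled reads, taxa whose
latent abundance is slightly below 1/N are still detected with substantial
probability; the sharp-threshold approximation therefore overestimates
occurrence at the rare end and biases the fitted m upward by roughly
15–30% across m ∈ {0.02, 0.1, 0.5} in our recovery experiments, while the
exact form recovers m to within a few percent. The sharp-threshold fit
remains available (`detection="threshold"`), as does a logit-scale loss.
m is fitted by bounded scalar least squares on the frequency scale,
m ∈ (1e−6, 1]; R² = 1 − SSE/SST over taxa. The 95% envelope uses Wilson
binomial intervals around the fitted frequency at n_samples trials; taxa
are classed above/within/below. With ~50 samples roughly a quarter of taxa
fall outside the envelope even for perfectly neutral synthetic data —
per-taxon p is estimated from the same samples, and that errors-in-variables
scatter is widest for rare taxa — so envelope fractions should be read
comparatively, not as absolute goodness-of-fit.

## Null model and modified stochasticity ratio

The null model (`taxa_shuffle_proportional`) preserves, per sample, the
observed richness and total count. Taxa are drawn without replacement with
probability proportional to their regional occurrence frequency
(exponential-key weighted sampling), and abundances are assigned
proportionally to regional mean relative abundance among the drawn taxa,
integerized by largest remainder with one guaranteed read per drawn taxon
so richness is conserved exactly.

MST for a within-group pair is the symmetric ratio

    MST_ij = min(D_ij, E_ij) / max(D_ij, E_ij),

with D the observed Bray–Curtis dissimilarity and E its mean over
`n_null` randomizations (default 1000); identical-by-construction pairs
(D = E = 0) score 1. Group values average the group's pairs; the overall
value pools within-group pairs. Values above 0.5 are read as predominantly
stochastic assembly. Two calibration facts, measured on synthetic data,
are worth knowing:

- Fully neutral tables score ~0.8–0.9 and strongly niche-structured tables
  ~0.4, so the 0.5 boundary separates the regimes cleanly.
- Even a table generated by the null model itself scores ~0.65–0.70, not
  1: each observed D is a single draw that fluctuates around the averaged
  E, and the expectation of min/max under exchangeability is below 1 by an
  amount governed by D's coefficient of variation. MST values should be
  compared against this operating range, not against an idealized 1.0.

## Beta diversity

Bray–Curtis is Σ|x−y|/Σ(x+y); Jaccard operates on presence/absence. The
turnover/nestedness partition is the Baselga Jaccard family (Sørensen
available): with a shared and b, c unique presences,
β_jac = (b+c)/(a+b+c), β_jtu = 2·min(b,c)/(a+2·min(b,c)),
β_jne = β_jac − β_jtu. The triplet (similarity, turnover, nestedness) sums
to 1 to machine precision, nested subsets give turnover exactly 0, and
equal-richness pairs give nestedness exactly 0.

PERMANOVA is the one-way Adonis form: SS_total = Σ_{i<j} d²_ij / n,
SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g, pseudo-F with (a−1, n−a) df,
R² = SS_between/SS_total, and p = (#{F_perm ≥ F_obs}+1)/(n_perm+1) under
free label permutation (no strata). The permutation engine is vectorized
(batched group-indicator einsum), which is what makes the 2000-replicate
type-I calibration in the acceptance suite affordable.

## CCA and environmental screening

CCA follows the standard chi-square formulation: the doubly-centered,
chi-square standardized community matrix is projected (row-weighted QR)
onto the environmental columns and the fitted matrix decomposed by SVD.
Axis shares are reported **both** as fractions of total inertia and of
constrained inertia, because published axis percentages are quoted either
way. Collinear environmental columns (condition number > 1e10) are an
error naming the worst pair; taxa absent from every fitted sample are
dropped with a warning. The implementation agrees with an independent
reference ordination to 1e−6 on random tables (tested), and per the
study convention it is applied to the Hellinger-transformed relative
abundance matrix (a raw-abundance flag exists).

envfit regresses each variable on the first two axis scores; R² is the
squared multiple correlation and p comes from permuting the variable
(default 999). Pearson screens report product-moment r with two-sided t
p-values (n−2 df); no multiple-testing correction by default, matching the
raw-star convention, with Benjamini–Hochberg behind a flag. "Top 15
phyla" means the 15 largest mean relative abundances.

## Networks

Edges require Spearman |ρ| > 0.7 AND p < 0.05 (t approximation, average
ranks) between taxa passing the 25% prevalence filter, computed on
relative abundances of the rarefied table by default. Isolated nodes are
dropped; positive/negative edge fractions are reported.

Topology: AD = 2E/V, GD = 2E/(V(V−1)), CC = mean local clustering (degree
< 2 contributes 0), APL = mean shortest path over connected pairs, ND =
longest shortest path within components (disconnected graphs are handled
component-wise; this choice is recorded in output). All metrics are
computed from the adjacency matrix (BLAS triangle counting, BFS distances)
so that the 1000-graph Erdős–Rényi ensembles stay fast; they match
brute-force references exactly on random graphs (tested). The null is
uniform G(V, E) with the observed V and E; the small-world coefficient is
r = (CC/CC_rand)/(APL/APL_rand).

Modules are Louvain at resolution 1.0 on unweighted edges with a recorded
seed; modularity is Newman–Girvan. Node roles use Zi (within-module degree
z-score, population sd; a module with zero spread gives Zi = 0, flagged)
and Pi = 1 − Σ_s (k_is/k_i)², with the conventional thresholds 2.5 / 0.62
defining peripherals, connectors, module hubs, and network hubs;
everything but peripherals is flagged keystone.

## Stability (AVD)

For sample j in group g, over the n_g taxa with nonzero within-group
variance,

    AVD_j = (1/n_g) Σ_i |a_ij − ā_ig| / δ_ig,

on relative abundances, with the sample (n−1) standard deviation by
default. Zero-variance taxa are excluded (not scored 0) so that constant
taxa cannot dilute the statistic; a rounding-level tolerance treats
numerically identical replicates as zero-variance. Two structural facts
follow directly from the formula and shape how it should be read:

- Groups of exactly two samples always score 1/√2 per sample, whatever the
  abundances — the deviation |a−b|/2 and the sd |a−b|/√2 share their scale.
- More generally the per-taxon standardization makes AVD scale-free:
  multiplying a taxon's within-group values by any positive constant
  changes nothing, so uniformly inflating multiplicative noise does not
  raise group-mean AVD (heavy-tailed noise can even lower it, since sd
  grows faster than the mean absolute deviation). What AVD does respond
  to, monotonically, is displacement structure: a sample pushed away from
  its group's composition gains AVD steadily, and a group split between a
  baseline and a disturbed state gains mean AVD as the split widens. It is
  an instability-of-samples measure, not a variance meter.

Group differences are tested by Kruskal–Wallis with uncorrected pairwise
compact letters at α = 0.05.

## Synthetic data

`simulate_neutral` draws per-sample Beta stationary proportions and then N
multinomial reads — the Beta shortcut replaces explicit birth–death
dynamics because it is the stationary distribution the NCM itself assumes,
making m an exact recovery target. Metacommunity abundances are log-normal
(σ = 2), renormalized.

`simulate_niche` gives each taxon a Gaussian response
exp(−(env−optimum)²/2τ²) on a scalar gradient (default strongly bimodal),
log-normal noise, and multinomial reads.

`simulate_seasonal_study` emulates a year of ~semimonthly benthic sampling:
35 samples from 2020-09-11 to 2021-08-27 spanning all four seasons;
temperature a 4.10–23.95 °C annual sinusoid; dissolved oxygen anti-phase
(5.45–11.42 mg/L); ammonium pulsing in summer; salinity/conductivity,
nitrogen, phosphate, and nitrate with season-shifted cycles. A fraction of
taxa (default 0.5) assemble neutrally; the rest respond to the temperature
cycle; planted modules (default three sets of 20 moderately abundant taxa)
share a latent per-sample factor with correlation 0.9, giving module
detection a known target. Ground truth — per-taxon assembly class, module
membership, true m — is stored in table provenance and exportable as JSON.

What the generators do **not** emulate: taxonomic structure, sequencing
error and chimeras, compositional coupling beyond the shared simplex,
phylogenetic signal, within-season autocorrelation beyond the smooth
environmental cycles, and the long-tailed sparsity of real sediment tables
(real networks of this kind are far sparser than the synthetic ones, whose
niche blocks share one gradient and therefore correlate heavily). Passing
the recovery tests demonstrates the estimators are correct and
well-calibrated on data satisfying their assumptions; it does not certify
behaviour on real amplicon data.

## Problem sizes and numerics

Default analysis constants: 999 permutations (PERMANOVA, envfit), 1000
null randomizations (MST), 1000 random graphs (ER ensemble), thresholds
0.25 / 0.7 / 0.05 / 2.5 / 0.62, MST boundary 0.5. The test and acceptance
runs use scaled-down study dimensions chosen as the package's own
verification sizes — e.g. S = 500–2000 taxa, 30–50 samples, depths
15,000–20,000, 200 nulls, calibration at 199 permutations × 1000–2000
replicates (at 199 permutations the achievable p-values make the nominal
0.05 level exact). The NCM optimizer is bounded scalar minimization;
degenerate fits (all frequencies equal) are flagged non-informative rather
than reported as numbers. All random draws flow through
`numpy.random.default_rng` seeds recorded in provenance; pipeline stages
derive named sub-seeds from the config seed, and re-running a config is
byte-identical.

## Limitations

- One-way PERMANOVA only (no strata or multi-factor designs).
- The MST null algorithm is the one documented above; published
  stochasticity ratios computed with other null families or weighting are
  not expected to match numerically, only directionally.
- CCA assumes complete environmental data for fitted samples; missing
  values are flagged, never imputed.
- Louvain is stochastic-by-tie-break even when seeded across library
  versions; module *identity* is stable in our tests but label order is
  meaningful only within a run.
- AVD comparisons across groups of very different sizes inherit the usual
  small-sample bias of standardized deviations (the n = 2 closed form is
  the extreme case).
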