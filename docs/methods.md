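# Methods

## Data model

The pipeline operates on gene-by-sample FPKM matrices with per-sample
metadata (variety, tissue, day post-sowing, replicate pool). Replicate
pools are averaged per sampling day before any downstream analysis, so
every variety/tissue contributes one expression vector per day
(`TimePointProfile`). All downstream computation runs on these raw,
replicate-collapsed FPKM values; an analysis on another scale (e.g.
log2(FPKM+1)) can be obtained by transforming the input tables, since
every stage is a pure function of the profile matrix.

A gene is *expressed* when its maximum over the time series is at least
2.0 FPKM — the boundary is inclusive. A gene is *variety-specific* (for a
tissue) when it is expressed in exactly one of the two varieties.

## Transcriptome alignment

For two profiles (one per variety, same tissue) the alignment is the
matrix of Euclidean distances between every pair of time-point vectors
over a common, identically ordered gene set (optionally a subset such as
flowering genes). Day grids need not match: missing days shrink one axis
and nothing is imputed. The minimum traces take, per row day, the column
day at minimal distance and vice versa; ties break towards the earliest
day — the paper's figures never need a tie rule, but determinism does.

## SOM prefilter

Three stages, in this order, each applied to the survivors of the
previous one:

1. *detected* in at least half of the time points. "Detected" means FPKM
   strictly above a detection floor (default 0; quantification pipelines
   emit exact zeros for undetected genes). With `T` time points the rule
   is `count > floor-exceedances >= T/2` with real division, so odd `T`
   requires `ceil(T/2)` detections.
2. expressed (max ≥ 2.0 FPKM, inclusive);
3. present in the crop→model-organism homology mapping.

Per-stage survivor counts are reported and are non-increasing by
construction.

## Copy-number bias

Homologue families group crop genes sharing the same best-scoring model
gene hit (highest bitscore; ties to the lexicographically smallest model
gene ID). Per family, expressed copies are counted per variety; bias is
the absolute difference, with direction toward the variety with more
expressed copies. A family is *compensatory* when the counts are equal
but each variety expresses at least one member the other does not.
Families with zero expressed copies in both varieties are excluded from
the percentage denominators. Directional bias is tested with an exact
two-sided binomial test at p₀ = 0.5 over families with non-zero bias,
using the minimum-likelihood two-sided convention (the sum of outcome
probabilities no larger than the observed outcome's), matching R's
`binom.test`.

## Toroidal SOM

Input profiles are per-gene z-scaled (mean 0, population SD 1) so units
cluster profile *shape*, not expression level; zero-variance genes cannot
be scaled and are dropped with a logged count.

The map is a rows × cols rectangular grid with torus topology: grid
distance uses the wrap-around minimum in each axis, making opposite
boundaries adjacent and eliminating edge effects. The aspect ratio
approximates λ₁/λ₂ of the scaled data's feature covariance
(rows = √(n·λ₁/λ₂), cols = n/rows, both ≥ 2, rows ≥ cols). When no unit
count is given, candidates {25, 36, 49, 64, 81, 100, 121} are each
trained briefly (10 epochs) and the first whose relative quantization-
error improvement over the previous candidate falls under 5% is chosen;
the pipeline default fixes a 10×10 grid instead, which keeps runs
comparable across varieties and tissues.

Training is classic online Kohonen: codebooks initialise from a random
sample of the data; per presentation the best-matching unit (BMU) is the
Euclidean-nearest codebook and every unit updates as
`w ← w + α·h·(x − w)` with `h = exp(−d²_grid(BMU, u) / (2r²))`. The
learning rate decays linearly 0.5 → 0.01 and the radius
`max(rows, cols)/2 → 0.1` over all presentations (default 30 epochs).
The late schedule deliberately ends in a near-BMU-only regime: because
random-sample initialisation already yields a low quantization error
(every codebook *is* a data point), a larger final radius leaves residual
neighbourhood smoothing that can push the trained error above the initial
one. With this schedule the mean gene-to-BMU distance after training is
at or below its initialisation value on every seed we test, which the
test suite asserts.

Everything is seeded and deterministic: sample order is a seeded
permutation per epoch, and argmin ties resolve to the lowest unit index.

Codebook *labels* ("early/vernalisation responsive", "treatment
responsive", "late", "treatment responsive/late") are descriptive only:
each codebook is correlated against the unit-amplitude archetype shapes
on the model's day grid and named for the best match.

## Enrichment

Per SOM cluster, a 2×2 table of (variety-specific in/out of cluster) ×
(rest in/out) is tested with the one-sided (greater) hypergeometric
p-value — "enriched" is a directional claim, so the one-sided alternative
is the faithful reading; a two-sided variant is available via flag. The
FDR family is the set of clusters of one map (one variety/tissue);
q-values are Benjamini–Hochberg. The same machinery serves generic term
enrichment over a gene → term annotation, testing each term with at least
one annotated background gene.

## Distance-correlation AUC

Per gene, the between-variety distance matrix on the global day axes
reduces to `|x_g(t_i) − y_g(t_j)|`. Its Pearson correlation with the
flattened global matrix measures how closely the gene's own trajectory
difference mirrors the global one; Pearson's location/scale invariance
makes explicit matrix normalisation unnecessary. Genes whose flattened
matrix has zero variance have no defined correlation and are excluded
from both numerator and denominator. Per cluster, the survival curve
`P(r ≥ t)` is evaluated on 201 uniform thresholds over [−1, 1] (the
"below" cumulative form is available via flag; either form yields the
same ranking up to orientation) and the trapezoidal area divided by the
range width 2 gives an AUC in [0, 1] that ranks clusters.

## Synthetic data

The generator emulates the processed data of the study design, not reads:

- **Design** — varieties Tapidor/Westar, tissues apex/leaf, days
  {22, 43, 64, 65, 67, 72, 83} for Tapidor, {22, 43, 64, 65, 67, (69), 72}
  for Westar (69 apex-only; no Westar day 83), two pools per point except
  days 65 and 69 (one pool). Cold window: days 23–64 (transfer to cold on
  day 22 plus six weeks).
- **Families** — copy counts 1–6 drawn with weights
  (0.05, 0.30, 0.10, 0.35, 0.08, 0.12), biased to 2 and 4 expressed
  copies as expected from an A/C-genome amphidiploid; 5% of genes carry
  no model-organism homologue so the third filter stage has work to do.
- **Archetypes** — early_vern (starts at amplitude, ≤ 45% from the cold
  window start onwards), treatment (Gaussian bump centred mid-window),
  late (quadratic rise to the final day), treatment_late (bump + cubic
  rise), flat; default mix (0.20, 0.20, 0.20, 0.10, 0.30). Per-gene
  amplitudes are log-normal around 10 FPKM (σ = 0.8 on the log scale,
  floored at 0.5), so a realistic minority of genes never reaches the
  2.0-FPKM threshold.
- **Noise** — multiplicative log-normal, `x = profile · exp(N(0, σ))`,
  σ = 0.2 by default; the simplest noise model consistent with strictly
  positive FPKM. The paper states none, so this is a free, documented
  choice.
- **Variety-specific genes** (10% by default) — in the other variety,
  values are drawn per day uniformly below 1.0 FPKM with about one third
  exact zeros (emulating undetected genes) and replicated across pools
  *without* the noise multiplier. This keeps them strictly under the
  2.0-FPKM rule, so the planted truth flag and the threshold rule agree
  exactly; with the multiplier, rare noise excursions would cross the
  threshold and make truth labels ambiguous.
- **Tissue-preferential genes** (10%) — ×0.15 amplitude in the
  non-preferred tissue.
- **Scenario knobs** (defaults off) — `specific_archetype` ties
  variety-specific genes to one archetype (the planted-enrichment
  scenario); `specific_variety_prob` skews which variety specific genes
  belong to (the planted directional-bias scenario); `late_shift_variety`
  delays "late" genes by `late_shift` sampling positions in one variety
  (the developmental-offset scenario behind the alignment and AUC
  recovery checks).

What the generator does **not** emulate: read-level sampling noise,
library-size or length biases between genes, batch effects, isoform
structure, or correlated noise across genes. Tests passing on this data
therefore demonstrate that the pipeline recovers the targeted structure
under the stated statistical assumptions, not that those assumptions hold
for any particular real dataset.

## Problem sizes and numerical choices

The default synthetic design uses 1,350 families (~4,700 genes), the
scale at which the full pipeline runs in seconds per stage; recovery
checks use 500–1,500 families. Distances and correlations are exact
double-precision computations; the SOM is the only stochastic component
and is fully seeded. Tolerances in tests: 1e-9 for distance round trips,
1e-12 for exact-test oracles and scale-invariance identities. Degenerate
inputs are defined behaviour: empty survivor sets are allowed, clusters
with no defined-correlation genes are omitted from curves with a log
entry, zero-variance genes are dropped before SOM scaling, and a
zero-biased-family input to the binomial test raises rather than
returning an arbitrary p-value.

## Known limitations

- The SOM is rectangular-toroidal only; hexagonal lattices and batch
  training are out of scope.
- Grid sizing by the elbow rule is heuristic and sensitive to the brief
  training budget; fixed shapes are recommended for comparability (and
  are the pipeline default).
- Enrichment treats clusters independently; spatial correlation between
  neighbouring SOM units is ignored.
- The generator's even-copy bias is planted directly rather than emerging
  from a genome-duplication model.
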