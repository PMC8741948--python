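# Methods

This note documents the statistical procedures implemented in
`milletmyco`, the design of the synthetic-data generator, the numerical
choices made where the field's conventions leave room, and what the test
suite does and does not establish about real data.

## Rarefaction and α-diversity

Libraries are normalized by a single without-replacement subsample to a
common depth (default 25,556 reads, the smallest library of the emulated
design). Subsampling is multivariate-hypergeometric — drawing reads
without replacement from the observed pool — rather than multinomial,
matching classic "rarefy" semantics; samples below the target depth are
dropped with a logged warning. One draw with a recorded seed is used, not
an average over repeated draws, because the pipeline mirrors a workflow
that analyzed a single normalized table. A closed-form check is available:
the expected rarefied richness of a sample is Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)),
and the Monte-Carlo mean over many draws must match it (tested to 2 SE
over 1,000 draws).

Shannon diversity is reported in nats and Simpson as Gini–Simpson
(1 − Σ pᵢ²), the R-ecosystem defaults; the raw dominance D is exported
alongside. `alpha_table` emits the tidy per-sample table (indices joined
with site / plant type / plot) that a linear-mixed-model refit would
consume; the LME fitting itself is out of scope here.

## Ordination and permutation statistics

**Bray–Curtis** distances are computed on the rarefied counts (equal
depths make this equivalent to using relative abundances).

**NMDS** wraps non-metric SMACOF (scikit-learn) with monotone regression,
20 seed-derived random restarts and a fresh Kruskal stress-1 evaluation —
√(Σ(d−d̂)²/Σd²) with d̂ the isotonic fit of configuration distances to the
input dissimilarity order — used both to select the best restart and as
the reported stress. A cross-implementation test checks the attained
stress against vegan's `metaMDS` (within 0.02) on a random matrix.

**PERMANOVA** partitions the Gower-centered inner-product matrix
G = −½·J·D²·J sequentially (Type-I) over the terms in order — site, plant
type, site×plant-type by default, matching the classic `adonis`
behaviour. Each term's SS is tr((H_k − H_{k−1})·G) for the nested
projection hats; pseudo-F uses the residual mean square; p-values come
from unrestricted whole-sample permutations with the add-one convention
p = (#{F* ≥ F} + 1)/(n_perm + 1), so p never reaches 0. The partition is
verified against vegan's `adonis2` to 1e-8 and the permutation p against
a full-enumeration oracle on 6-sample toys. Permutations are not
restricted by plot: the emulated design nests replicates in plots, but
the reference analysis did not state restricted permutations, so the
unrestricted default was kept (explicit permutation sets can be supplied).

**betadisper** embeds samples by principal coordinates, retaining
negative eigenvalues as imaginary axes whose squared contribution is
subtracted from real squared distances to the *group centroid* (this is
vegan's `type="centroid"` variant, chosen for its closed-form centroid;
distances match vegan to machine precision). The F statistic on the
distances is tested by permuting group labels.

**envfit** regresses each soil variable onto the 2-D NMDS scores (the
displayed configuration, not the full distance matrix); r² is the squared
multiple correlation, the arrow is the unit-normalized coefficient
vector, and significance comes from permuting the variable across
samples. Null p-values are verified uniform by simulation.

**BH-FDR** is the Benjamini–Hochberg step-up (statsmodels behind a thin
validated wrapper), used for the network edge screen and exported
alongside raw p wherever per-cell stars are shown.

## Guild assignment and soil correlations

OTUs are matched against a FUNGuild-style flat lookup at the most
specific lineage rank with an entry (species > genus > family > …),
case-insensitively. Only confidence ranks "Highly Probable" and
"Probable" are accepted; anything else — including unmatched OTUs — is
Unassigned. Multi-trophic strings collapse order-invariantly into the
seven canonical groups. Relative abundances are read-weighted and
computed over assigned OTUs only (rows sum to 1 over assigned groups); an
OTU-tally mode exists behind a flag. Soil × trophic-group association
uses Pearson r within each site with two-sided t-tests (n−2 df), stars on
unadjusted p at 0.05/0.01/0.001 plus a BH-adjusted column; cells with
fewer than 3 complete pairs or constant vectors are NA, and incomplete
samples are dropped pairwise with a logged count.

The packaged lookup (`data/guild_db_synthetic.tsv`) is a synthetic
mini-database of ~40 common root-fungal genera spanning all seven groups
and the three confidence tiers; it exists so tests and simulations
resolve without the full external database.

## Core mycobiome and co-occurrence networks

The core set keeps OTUs with nonzero counts in ≥ 75% of all pooled
samples (boundary inclusive); richness and read shares are reported
against the full table. Networks are built per plant-type stratum on the
core-restricted rarefied counts: Spearman ρ with average-rank ties for
every OTU pair, two-sided p, BH-FDR over all pairs *within that network*
(networks are interpreted separately), and edges kept when |ρ| > 0.6 and
q < 0.01. Constant OTUs are excluded with a warning; nodes without a
surviving edge are dropped.

Topology is computed on the unweighted, sign-blind graph (correlation
magnitudes stay on the edges as attributes): unnormalized shortest-path
betweenness, classic closeness per connected component, eigenvector
centrality on the largest component (0 elsewhere), average path length
and diameter over the largest component, density 2E/(N(N−1)), mean local
clustering, and modularity as the best of 10 seeded Louvain runs at
resolution 1 (networkx's implementation; its run-to-run spread is checked
< 0.02 on structured test graphs).

Hubs are the intersection of the top-⌈2%·N⌉ sets by degree and by
betweenness; ties at the rank-k value are included before intersecting,
so under ties the called set can exceed k — the union rule is available
behind a flag. Node-metric distributions of the two networks are compared
with two-sided Wilcoxon rank-sum tests, exact by enumeration when both
networks have ≤ 10 nodes and no ties, otherwise normal approximation with
tie correction.

A documented limitation: correlations are plain Spearman on rarefied
counts, not a compositionality-aware estimator (SparCC/SPIEC-EASI-style).
Closure effects are real — see the generator discussion below — and edge
signs near the threshold should be read accordingly.

## The synthetic-data generator

`generate_dataset` emulates one survey: 3 sites with a 2/3/1 plot split
(any partition is accepted), 2 plant types × 5 replicates per plot = 60
samples, library sizes log-uniform in 25,556–154,517, and 600 OTUs by
default. Counts for each sample follow a Gaussian copula: z ~ MVN(0, Σ) →
u = Φ(z) → negative-binomial quantile per OTU (mean from the sample's
composition × library size, dispersion k, variance m + m²/k) → one
multinomial subsample to the exact library size. The copula approximately
preserves rank correlations, which is what the Spearman-based analysis
consumes; non-PSD targets are projected to the nearest PSD correlation
matrix with a warning.

Planted structure and defaults (the defaults are the study conditions the
tests run under):

- **Correlation blocks** are one-factor equicorrelated groups (loadings
  ±√ρ; a negative sign alternates loadings, giving mixed ±ρ pairs);
  **hubs** are hub-and-spoke one-factor structures (hub↔partner ρ,
  partner↔partner ρ²).
- **Abundance profile**: lognormal with σ = 1.0, giving a top-OTU share
  near 2% at 600 OTUs — the level the emulated study reports for its most
  abundant core taxa. Planted OTUs are mapped to abundance ranks starting
  at the 10% quantile: prevalent, core-taxon-level abundances. This
  matters because the closure step (dividing by the read total) injects
  shared noise from the dominant taxa; planting structure *on* the
  dominant taxa couples their idiosyncratic noise into every proportion
  and destroys the very rank correlations being planted. A stage-wise
  audit (latent → raw NB → proportions → subsampled counts) shows planted
  ρ = 0.85 realizing as sample Spearman ≈ 0.79 under the defaults.
- **Dispersion** k = 2 (CV ≈ 0.75 above Poisson), moderate amplicon-level
  overdispersion.
- **Site and plant effects** are per-OTU log-normal multipliers
  (site_effect_sd = 0.5, plant_effect_sd = 0.2). These magnitudes were
  calibrated so the simulated PERMANOVA partition and NMDS stress land
  near the study's printed values (R² ≈ 0.21 site / 0.03–0.04 plant,
  stress ≈ 0.19); they are zeroed explicitly in all calibration and
  recovery tests, which require exchangeability or isolated structure.
- **Trophic composition** per plant type is imposed by reweighting OTU
  means by target group shares (pathotroph-skewed in cultivated,
  saprotroph-skewed in wild, matching the emulated contrast); ~75% of
  OTUs resolve in the guild lookup.
- **Soil covariates** are built per site as r·z + √(1−r²)·e with z the
  standardized group abundance and e orthogonalized noise, so the planted
  within-site Pearson correlation is hit exactly; unlisted variables are
  independent normals around site-specific means with realistic sandy-
  tropical baselines (pH ≈ 6.2, total P ≈ 70 mg/kg, …).
- **Seeding**: one global seed expands into fixed-index child streams
  (taxonomy, effects, counts, soil), so identical configurations are
  byte-for-byte reproducible.

Everything planted is returned in a `GroundTruth` object (block
membership, hub ids, pairwise ρ, effect table, realized soil links) and
serialized as JSON by the pipeline.

## What the synthetic tests do and do not show

The generator reproduces the design geometry, depth unevenness, long-tail
abundances, rank-correlation structure, trophic contrasts and soil
couplings of a real survey, and the suite demonstrates that the pipeline
recovers planted structure (block edges, hubs, soil links, effect signs)
at ≈ nominal error rates. It does not emulate sequencing-level artifacts
(chimeras, taxonomy error), per-OTU dispersion heterogeneity, or true
ecological sparsity: at 600 OTUs and real depths even rare simulated OTUs
receive tens of reads per sample, so prevalence saturates and the
75%-prevalence core contains most of the community (≈ 95% of richness),
unlike a real 5,524-OTU table where the core is a few percent. Core
*extraction* is therefore exercised by dedicated small fixtures and
brute-force oracles, while the full-scale run exercises its arithmetic;
the printed-counts share formula (260/5,524 → 4.7%) is checked exactly.
Recovery rates quoted by the tests (e.g. planted hub called in ≥ 90% of
replicates) hold under the stated simulation conditions — 30 samples, one
stratum, no confounding effects — and should not be read as field
sensitivities: in the full design, site-driven covariation competes with
planted hubs, and a planted hub need not top a pooled network, which the
analysis drivers report honestly.

## Problem sizes

Default runs use 600 OTUs × 60 samples with 999 permutations for the
permutation tests and 20 NMDS restarts; the acceptance script completes
in well under a minute on one CPU. Test simulations use 100–600 OTUs and
49–199 permutations with replicate counts of 50–1,000 chosen per check;
these sizes are the package's own verification design.
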