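# Methods notes

This note records the models implemented in `endfootnet`, the defaults and
why they hold, what the synthetic cohorts do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Network model

For each brain region the pipeline builds an unsigned weighted co-expression
network on the FPKM-filtered gene set (a gene is dropped when its FPKM is
below 10 in ≥ 90% of samples; the comparison is strict on the value and
inclusive on the fraction, and both knobs are exposed). "90% of samples" is
our reading of the filter's intent; it yields gene counts in the expected
range for regional bulk RNAseq and makes the filter idempotent.

Pairwise similarity is the biweight midcorrelation with the standard
9-MAD tuning: `u_i = (x_i − med)/(9·MAD)`, weights `(1 − u_i²)² · 1[|u_i|<1]`.
When MAD = 0 the variable falls back to Pearson weighting (per-variable
fallback, with a warning); an exactly constant vector yields correlation 0.
The scalar entry point evaluates `⟨gx,gy⟩/√(⟨gx,gx⟩⟨gy,gy⟩)` on the weighted
deviations so that identical and anti-identical vectors return exactly ±1.

The soft-threshold power β is selected automatically because a deterministic
pipeline cannot depend on visual inspection: for each candidate power the
connectivities `k_i = Σ|r_ij|^β` are split into 10 equal-occupancy bins, the
log10 density (count/bin width) is regressed on the log10 mean connectivity,
and the signed fit index is `−sign(slope)·R²` (a decreasing, scale-free-like
density scores positively). The chosen β is the smallest candidate reaching
signed R² ≥ 0.8, constrained to the 4–7 band used for all regional analyses;
if no candidate qualifies the best-fitting power inside the band is taken
with a warning, and `--power` reproduces any manual choice exactly.

Topological overlap uses the standard unsigned formula with
`L = A·A − 2A` (removing the u = i and u = j terms of the matrix product) and
`min(k_i,k_j) + 1 − a_ij` in the denominator; values are clipped to [0, 1]
against rounding. The consensus network across dementia status is the
component-wise minimum of the group TOMs over an identical gene set.

## Module detection

Modules are branches of the average-linkage dendrogram of `1 − TOM`, cut at
a fixed fraction of the dendrogram's maximum merge height (static cut), with
branches under 30 genes pooled into label 0. The static cut was chosen over
dynamic branch-cutting because it is exactly reproducible and has a single
interpretable parameter. The default cut fraction is **0.90**: in TOM
dissimilarity, genes without co-expression partners merge into genuine
branches only within the top decile of the height range, so a cut below that
decile separates planted/biological modules from background attachment. (At
a 0.99 cut, simulated modules absorb dozens of background genes; at 0.90,
recovery of planted modules is essentially exact — mean Jaccard ≈ 0.98 and
adjusted Rand index ≈ 0.98 across 10 simulated cohorts.) The fraction is a
config knob; raising it merges background into modules, lowering it orphans
weakly-loaded members into label 0.

Eigengenes are the first right singular vector of the per-gene standardized
member matrix, unit norm, sign-oriented so the mean correlation with member
expression is non-negative. Genes whose spread is at rounding level
(sd ≤ 1e−12 relative) are treated as constant and dropped with a warning.
kME is the Pearson correlation of every gene with every module eigengene;
kWithin sums a gene's adjacency over same-module peers.

## Endfoot screen

The endfoot-enriched cluster of a region is the module containing the most
established endfoot genes (AQP4, SNTA1, DTNA, DAG1, DMD). Ties break by the
higher mean own-module kME of the bait genes, then by module size. A region
is *incoherent* — excluded from the screen, as observed for white matter —
when no bait gene is assigned, or the baits scatter across ≥ 4 distinct
modules.

The candidate universe is the union, over coherent regions, of
endfoot-cluster members minus the baits themselves. A candidate passes when
its astrocyte expression fraction is ≥ 0.5 (genes missing from the cell-type
reference fail conservatively), and it shows Pearson r > 0.65 with at least
2 of the 5 bait genes in at least 2 regions. The screen deliberately uses
Pearson — not bicor — mirroring the split between network construction and
candidate thresholding; AQP4 counts toward the bait support, and DMD's
inclusion in the bait set is configurable (it is the one established gene
that is not astrocyte-predominant). The screen is monotone by construction:
raising any threshold can only shrink the pass set.

## Association models

Discovery-cohort models use the covariate set {age as ordinal 5-year
increments treated as continuous, APOE ε4 carrier, TBI history}; sex can be
added by configuration (the two descriptions of the adjustment set differ on
it, so it is a flag rather than a hard default). Dementia is modelled by
maximum-likelihood logistic regression (complete separation yields a flagged
record, not an exception); pathology outcomes by OLS. A pathology outcome is
log-transformed as `log(y + c)` with `c` = half the smallest positive value
whenever its sample skewness exceeds 1 — a formalization of "transform when
right-skewed" — and always/never modes are selectable. The derived ratios
Aβ42/Aβ40 and P-tau/total-tau are defined only where the denominator is
positive. Interaction contrasts add an expression × dementia term and report
its Wald t. Influence diagnostics report Cook's distance (flag at 4/n) and
DFBETAS.

Correction is two-stage over the complete record set of a run:
Benjamini–Hochberg across all models jointly gives `p_fdr`; records with
`p_fdr < 0.05` form the selection set, re-adjusted per region by step-down
Holm–Šidák `p_adj(i) = max_{j≤i}[1 − (1 − p_j)^(m−j+1)]`. Records outside
the selection set carry missing `p_adj`. Validation-cohort fits use no
covariates and dichotomize ordinal pathology at Braak ≥ 5, neuritic
plaques ≥ 3, CAA ≥ 3. Demographics comparisons use the two-sided
Mann–Whitney U with tie correction, reported as median (Q1, Q3).

## Synthetic cohorts

Expression follows a latent factor model: module m has a standard-normal
eigengene `E_m` per region, correlated 0.6 across regions for the same
module; member gene g has `z_g = λ_g·E_m + ε`, `ε ~ N(0, noise_sd)`; FPKM is
`exp(μ_g + 0.5·z_g)` with `μ_g ~ N(log 30, 0.5)`, giving right-skewed
positive marginals so the FPKM filter and the skewness-triggered log
transform stay meaningful. Defaults: 100 subjects, 3 regions, 2000 genes,
6 modules (sizes 40–120), a 60-gene endfoot module holding the 5 established
genes, 11 planted candidates (astro fraction drawn ≥ 0.6) and astro-poor
decoys with equally strong loadings (so specificity is actually tested),
noise sd 0.4, endfoot loadings 0.8–0.95 and other-module loadings 0.4–0.95.
A block of near-silent genes (μ = 0) exercises the filter. Dementia is
Bernoulli under a logistic model of standardized hippocampal log-expression
of AQP4 and DTNA (coefficient 1 each); temporal-cortex P-tau is log-linear
in the endfoot eigengene (slope 0.8); Braak/plaque/CAA ordinals are
quantile-monotone in that latent severity. Effect sizes for the gene–
pathology links are not published quantities; these defaults were chosen
once for testability at n = 100 and are deliberately stronger than one
should expect from tissue data.

What the generator does **not** emulate: count noise and library-size
effects, batch structure, cell-composition drift between dementia groups,
spatially varying module membership, missing data patterns, and realistic
effect sizes. Passing recovery tests therefore demonstrates correctness of
the machinery under the assumed factor model — not expected performance on
real cohorts. The validation-cohort degrader (subsample 30 subjects, keep
AQP4/DTNA/MLC1/FXYD1, shift AD ages upward ~10 years) reproduces the
age-confounded, uncorrected validation setting only in structure.

Randomness: one integer seed, split into named substreams (structure,
expression, covariates, pathology, celltype), so changing the gene count
does not perturb the covariate draw.

## Problem sizes and determinism

Default analyses run on 2000-gene, 100-subject cohorts, where a full
3-region pipeline completes in seconds on one CPU; the dense TOM product is
the dominant cost and scales as O(n³), comfortable up to the ~7000-gene
matrices regional bulk data produce after filtering. All stages are pure
functions of inputs + config + seed; reruns give byte-identical outputs.

## Known limitations

- Static-cut clustering cannot split nested modules that merge below the
  cut; dynamic tree cutting is out of scope.
- The soft-power rule can only approximate a judgment call made by eye;
  `--power` exists precisely to reproduce such choices.
- No imputation: records with missing covariates are dropped and counted.
- Exact replication of published module counts from archival cohorts is not
  guaranteed by any faithful reimplementation, because cut height and
  linkage were not part of the published parameter set.
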