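# Methods

This note documents the models and procedures implemented in `cd8niche`,
the parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signature scoring and the transition score

Scores are computed on log-normalized expression (counts scaled to a
library size of 10⁴, then log1p) unless the caller disables
normalization. For a signature *S*, genes are first binned by
cohort-average expression into `n_bins` rank bins (default 25); for each
signature gene, `n_ctrl` control genes (default 50, capped at bin
occupancy) are drawn from the same bin, excluding all genes of every
signature being scored in the same run. The cell's score is the mean over
signature genes of (gene expression − mean control expression). The
control subtraction makes scores invariant to adding a constant to every
gene, and excluding companion-signature genes from the control pool
prevents one state's markers from silently becoming another state's
baseline — an important correction on small, marker-dense panels.

The stem→exhausted **transition score** is defined as the mid-rank
empirical CDF position of the raw statistic (exhausted score − stem
score) across the scored CD8 population, scaled to [0, 1]. By
construction sorted values fall on the grid (2i−1)/(2n) up to ties, a
fully tied input maps to 0.5, and the score is strictly monotone in the
raw difference. A signature-based score was chosen over pseudotime
because it is scale-free, deterministic, and needs no graph inference;
both constructions order cells along the same axis when states are
separable.

**Discrete state labels** use a margin-argmax rule: the top-scoring
signature wins if it beats the runner-up by at least `margin` (default 0,
with "other" only on exact ties). This replaces graph clustering plus
majority vote with a transparent, order-independent rule whose failure
modes (boundary cells between adjacent states) are easy to reason about.

## Consensus NMF and anchor rankings

For each candidate rank k, `n_restarts` (default 30) randomly initialized
Frobenius-loss NMF fits are run; each restart's loading rows are
L2-normalized and pooled. Pooled factors whose nearest neighbor exceeds a
cosine distance of `outlier_threshold` (default 0.3) are dropped; the
rest are clustered into k groups by average linkage on cosine distance.
Consensus loadings are the component-wise median of each cluster,
re-normalized; usages are refit by nonnegative least squares with the
loadings held fixed. Stability per k is the silhouette (cosine metric) of
the pooled-factor clustering.

Rank selection offers two rules. The default, `selection="stability"`,
takes the **largest** k whose silhouette is within `stability_tol`
(default 0.01) of the maximum: sub-factorizations of a stable rank are
themselves highly stable, so a plain argmax systematically under-selects.
`selection="elbow"` instead takes the knee of the reconstruction-error
curve (largest distance above the endpoint chord). On planted-factor data
the two agree; on real data stability is the more conservative guide and
is therefore the default. For the ccRCC CD8 program analysis the
package provides `CCRCC_DEFAULT_K = 13` as a fixed preset.

Anchor rankings score every gene by the cosine of its loading column
against the anchor's (CXCL13 and CXCR5 are run separately, matching the
two published ranking panels); ties break lexicographically so results
are deterministic. With nonnegative loadings, similarities lie in [0, 1]
and the anchor itself scores exactly 1.

## Enrichment statistics

The ranked-list statistic is the GSEA-style weighted Kolmogorov–Smirnov
running sum with hit weight |similarity|^p, p = 1: ES is the signed
maximum deviation between the weighted hit CDF and the uniform miss CDF,
so |ES| ≤ 1 always. The null permutes set membership over ranked genes
(`n_perm` ≥ 100, default 1000); p is the add-one-corrected same-sign
tail and NES divides ES by the mean |null ES| of the same sign. A set
covering the whole ranking has no complement to step against and is
reported as the degenerate ES = 0 with a warning. BH-FDR is computed
across a supplied gene-set family, never across unrelated calls.

Over-representation uses the one-sided hypergeometric tail (equivalent to
one-sided Fisher), BH-corrected across sets, reporting overlap counts and
the fraction of module genes covered by each set.

## Spatial niches

**Detection** implements DBSCAN semantics with deterministic tie-breaks:
a cell is core when it has ≥ `min_samples` neighbors within `eps_um`
(self included); clusters are connected components of core cells; border
cells join the lowest-id reachable core cluster; clusters below
`min_size` are discarded and cluster ids are renumbered by smallest
member index. Defaults — eps 50 µm, min_samples 10, min_size 20 — are
scaled to lymphocyte aggregates of tens to hundreds of cells and are
config-exposed; no published parameter values exist for this step. A
brute-force O(n²) BFS reference in the test suite must produce an
identical partition on random instances.

**Classification** is a fixed decision list over aggregate summaries:
(1) T-cell fraction < 0.20 → Unclassified (the 20% floor mirrors the
composition rule for the published aggregate classes); (2) aggregate mean
CXCL13 *and* mean CXCR5 both above the cohort `coexpr_quantile` (default
0.75) quantile of aggregate-level means → Lymphoid; (3) exhausted-CD8
fraction ≥ `exhausted_cut` (default 0.4) → Stimulated; (4) else
Quiescent. Co-expression was described only qualitatively in the source
analysis; the cohort-quantile flag keeps the rule scale-free (invariant
to uniform expression rescaling and to cell order). With fewer than two
aggregates the quantiles are replaced by fixed cutoffs from
configuration, logged.

**Spatial statistics.** Stromal area is estimated by an occupancy grid
(tile 50 µm; tiles containing ≥ 1 stromal cell count toward the area) —
reproducible without image segmentation, with a documented
grid-resolution sensitivity. Moran's I uses user-supplied weights (kNN
k = 6, row-standardized, index-broken ties by default) with the
permutation null; the analytic expectation −1/(n−1) is reported
alongside. ECDF contrasts between aggregate classes use a common grid,
pointwise 5–95% bootstrap bands from within-class resampling, and
two-sample KS statistics on the raw values; any display weighting is
never applied to statistics. Aggregate-size contrasts report
median(A) − median(B) with an exact Mann–Whitney p for small untied
samples and a rank-sum label-permutation p otherwise. Localization
reports each aggregate's stromal member fraction with a two-sided
binomial test against the slide-wide stromal fraction of immune cells;
no multiplicity correction is applied across aggregates by default.

## Clonotypes

A clonotype is an exact-match paired-chain TCR string; no fuzzy CDR3
matching is attempted because no edit-distance rule is published for this
analysis. "Expanding" means ≥ 3 cells; "multiple stem-like members"
means ≥ 2 (both configurable). The headline statistic is the fraction of
expanding clones with multiple stem-like members; with no expanding
clones it is reported as explicitly not computable rather than NaN.
Clone-level association between mean CXCL13 expression and stem fraction
uses Kendall τ-b.

## Association models

The **ZINB** model is `y ~ π·δ₀ + (1−π)·NB(μ = e^{xβ}, θ)` with NB2
variance μ + μ²/θ and a shared scalar π (a covariate-dependent logistic
gate is deliberately out of scope — the simple mixture is what the
validation analyses need). Fitting is generalized EM: the E-step computes
the posterior that each zero is structural; the M-step updates π in
closed form and takes a warm-started L-BFGS step on (β, log θ) for the
weighted NB log-likelihood, with a guard that rejects any update that
would decrease the observed log-likelihood — so the trace is
non-decreasing by construction (asserted in tests). Convergence is
|ΔL| < 1e-6 or 500 iterations; non-convergence flags the fit rather than
raising. Covariate effects are tested by LRT against the intercept-only
model with a χ² reference (df = number of slopes).

**Quadratic vs linear** fits both OLS models and reports R² for each, the
large-sample LRT n·log(RSS₁/RSS₂) with df 1, and its χ² p-value; nesting
guarantees R²_quad ≥ R²_lin on every input.

**rank_de** is a per-gene two-sided Mann–Whitney screen with BH
correction and log2 fold change of group means (pseudocount 1). It is a
deliberately simple rank-based utility for contrasting cell groups (e.g.
lymphoid-aggregate cells against surrounding immune cells); it is not a
latent-variable differential-expression model and its gene lists are not
expected to reproduce ones produced by such models.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream property is validated.

*Counts.* Each CD8 cell draws a state from `state_mixture` and a latent
coordinate u inside that state's quarter of [0, 1] (stem-like <
effector-memory < effector < exhausted; memory precedes full effector
differentiation so stem-associated genes decline and exhaustion genes
rise monotonically along u). `state_purity` shrinks the within-state
spread of u toward the interval center. Per-gene means interpolate
log-linearly between per-state archetype means with knots at the state
centers; the archetype table sets markers at 8× the 0.5-count baseline in
their home state (e.g. TCF7/IL7R/CCR7/CXCR5 high in stem-like,
TOX/HAVCR2/PDCD1/CXCL13 high in exhausted), values chosen once to make
the four states separable by signature scoring at default sample sizes.
Counts are negative binomial with dispersion θ and independent dropout
with probability `zero_inflation`; θ → ∞ recovers the Poisson limit.
`expression_scale` multiplies all means (sequencing depth).

*Clonotypes.* Clone sizes follow a geometric (default p = 0.5) or zipf
law. Among clones of size ≥ 3, a fraction `frac_expanding_with_stem`
(default 0.477) is designated stem-maintained and seeded with two
stem-like cells; the remaining expanding clones fill exclusively from
non-stem cells (before unbiased clones can deplete that pool), so the
planted fraction is recovered in expectation. Clonotype strings are
`TRA:<id>|TRB:<id>` surrogates — the statistics depend only on string
identity, not sequence realism.

*Tissue.* Tumor regions are a thresholded smoothed Gaussian noise field
occupying `tumor_area_fraction` of the slide; tumor cells and background
immune cells are homogeneous Poisson within their compartments.
Aggregates are 2-D Gaussian clusters (σ = 40 µm) whose centers are
rejection-sampled to sit in stroma (probe-circle tumor overlap ≤ 10%)
and ≥ 8σ from each other; placement failure after `max_aggregate_retries`
raises. Default composition per class: Quiescent (45% CD8, mixed
low-exhaustion states), Stimulated (50% CD8, 70% exhausted), Lymphoid
(35% B cells, 60% stem-like CD8, CXCL13/CXCR5 means scaled 4×). All
classes have ≥ 20% T cells. Cell-type expression profiles give B cells
high MS4A1 and CXCR5, and non-T cells near-zero CD8A.

The *well-separated preset* (θ = 15, dropout 0.05, purity 0.85, depth 4×
... 5×, equal state mixture) is the condition under which ground-truth
recovery is asserted. What passing these tests shows is that the
algorithms are correct and well-calibrated — not that real tissue attains
this separability: the generator omits doublets, segmentation error,
ambient RNA, batch effects, continuous cell-type mixtures, and spatial
gradients within aggregates.

## Problem sizes and numerical choices

Validation studies use 50 tissue simulations (~2,000 cells each), 2,000
cells for transition-score checks, 200×100 matrices for planted-factor
NMF, 1,000 permutations × 200 draws for enrichment calibration, n = 5,000
(50 replicates) for ZINB recovery and n = 400 (200 replicates) for its
null calibration, and ~9,000 cells for the clonotype statistic (≥ 1,000
expanding clones) — sizes chosen so each study is informative while the
whole suite runs in a few minutes on one CPU. Permutation p-values use
the add-one correction (1+k)/(1+B). All randomness flows through
explicit seeds; identical configurations are byte-reproducible, and the
pipeline driver derives per-stage seeds by hashing the stage name so
adding stages never perturbs earlier ones.

## Known limitations

- Aggregate classification thresholds (co-expression quantile 0.75,
  exhausted cut 0.4) are tunable scalars standing in for rules the source
  analysis stated only qualitatively; sensitivity to them should be
  checked on real data.
- The ZINB EM uses a quasi-Newton inner step; it is robust for the
  intended design sizes but not optimized for genome-wide fitting.
- `rank_de` ignores covariates and batch structure.
- The DBSCAN implementation is exact but O(n log n) per query via k-d
  trees; slides beyond ~10⁶ cells would need a streaming approach.
- Stromal-area estimates depend on tile size when stroma is sparsely
  populated; the grid-coverage behavior is characterized in tests.
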