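# cd8niche

Analysis toolkit for the spatial and transcriptional organization of CD8⁺
T cells in tumors — built around the CXCL13–CXCR5 chemokine axis in clear
cell renal cell carcinoma (ccRCC), where stem-like (progenitor) CD8⁺ T
cells concentrate in B-cell-rich stromal niches while exhausted cells
express CXCL13.

It is aimed at computational immunologists working with single-cell and
cell-resolved spatial transcriptomics who need the following pieces as
tested, composable components rather than one-off notebook code:

- **State scoring** — per-cell gene-signature scores with expression-bin-
  matched control genes; a continuous *transition score*
  `T_i = rank(score_exh(i) − score_stem(i)) / n ∈ [0, 1]` ordering CD8 cells
  along the stem→exhausted axis; margin-argmax discrete state labels.
- **Expression programs** — consensus non-negative matrix factorization
  (`X ≈ UH`, restarts pooled, outliers dropped, cluster medians as consensus
  loadings), anchor-gene rankings by cosine similarity of loading columns
  `sim(g) = cos(H[:,g], H[:,anchor])`, a weighted Kolmogorov–Smirnov
  running-sum enrichment statistic (ES/NES with a gene-permutation null),
  and hypergeometric over-representation with Benjamini–Hochberg control.
- **Spatial niches** — deterministic density-based clustering (DBSCAN
  semantics) of immune cells into aggregates; a decision-list classifier
  into **Quiescent / Stimulated / Lymphoid** classes from T-cell fraction,
  CXCL13·CXCR5 co-expression, and exhausted-CD8 fraction; stromal-area
  densities, Moran's I (`E[I] = −1/(n−1)` null), ECDF contrasts with
  bootstrap bands, and rank-based aggregate-size comparisons.
- **Clonotypes** — paired-chain TCR clonotypes by exact string match,
  expansion (size ≥ 3), and the fraction of expanding clones that retain
  multiple (≥ 2) stem-like members.
- **Association models** — Kendall τ-b, zero-inflated negative binomial
  regression fit by EM (`y ~ π·δ₀ + (1−π)·NB(e^{xβ}, θ)`) with
  likelihood-ratio covariate tests, and quadratic-vs-linear model
  comparison (`LRT = n·log(RSS₁/RSS₂)`).
- **Synthetic data** — a generator that plants a CD8 differentiation
  continuum, clonal structure, and tissue maps with immune aggregates of
  known class, so every statistic above can be validated against ground
  truth.

Fit-shaped components (`SignatureScorer`, `ConsensusNMF`,
`AggregateDetector`, `ZINBRegressor`) follow scikit-learn estimator
conventions and compose with sklearn tooling.

## Worked example

Simulate a tissue with six planted aggregates (two per class), score the
CD8 cells, detect and classify the niches:

```python
from cd8niche import (SignatureScorer, default_signatures, detect_aggregates,
                      classify_aggregates, simulate_tissue,
                      well_separated_config)
from cd8niche.scoring import log_normalize

cfg = well_separated_config(seed=11)
cell_map, counts, truth = simulate_tissue(cfg)

cd8 = cell_map.loc[cell_map["cell_type"] == "CD8 T", "cell_id"]
scores = SignatureScorer(default_signatures(), random_state=0) \
    .fit(counts.loc[cd8]).score_table(counts.loc[cd8])

aggs = detect_aggregates(cell_map, eps_um=50, min_samples=10, min_size=20)
aggs = classify_aggregates(aggs, cell_map, log_normalize(counts),
                           state_labels=scores["state_label"])
print(aggs.table[["aggregate_id", "size", "T_fraction",
                  "exhausted_CD8_fraction", "coexpression_flag",
                  "class_label"]].round(2).to_string(index=False))
```

prints

```
 aggregate_id  size  T_fraction  exhausted_CD8_fraction  coexpression_flag class_label
            0   161        0.71                    0.67              False  Stimulated
            1   241        0.56                    0.08               True    Lymphoid
            2   203        0.71                    0.65              False  Stimulated
            3   202        0.53                    0.07               True    Lymphoid
            4   180        0.69                    0.17              False   Quiescent
            5   219        0.69                    0.10              False   Quiescent
```

All six planted aggregates are recovered and correctly classified: the two
Lymphoid niches are flagged by CXCL13·CXCR5 co-expression (both aggregate
means above the cohort 75th percentile), the two Stimulated niches by
their high exhausted-CD8 fraction (≥ 0.4), and the rest are Quiescent.
Every aggregate satisfies the ≥ 20% T-cell composition rule.

A CLI mirrors the library (`cd8niche simulate|score|cnmf|niches|clones|assoc|run`);
`cd8niche run --config cfg.yaml` drives the whole pipeline and writes a
hash manifest for reproducibility.

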