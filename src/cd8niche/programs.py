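"""Consensus NMF expression programs, anchor-gene rankings, enrichment.

Consensus NMF runs many randomly initialized NMF restarts per factor count
k, pools the L2-normalized loading rows, drops outlier factors (nearest-
neighbor cosine distance above a threshold), clusters the survivors into k
groups by average-linkage on cosine distance, and takes the component-wise
median of each cluster as the consensus loading. Usages are refit by
nonnegative least squares against the consensus loadings. Stability per k
is the silhouette of the consensus clustering; k can be selected either by
the stability maximum or by the elbow of the reconstruction-error curve.

Anchor rankings order genes by cosine similarity between their loading
column and the anchor gene's loading column (e.g. CXCL13 or CXCR5), and the
ranked list feeds a weighted Kolmogorov–Smirnov running-sum enrichment
statistic with a gene-label permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF, non_negative_factorization
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "ConsensusNMF",
    "CCRCC_DEFAULT_K",
    "fit_cnmf",
    "anchor_similarity",
    "ranked_enrichment",
    "enrich_gene_sets",
    "overrepresentation",
]

#: Factor count used for the ccRCC CD8 program analysis.
CCRCC_DEFAULT_K = 13


@dataclass
class FactorModel:
    """One consensus factorization: usages (cells x k), loadings (k x genes,
    unit-L2 rows), reconstruction error, and stability diagnostics."""

    k: int
    usages: pd.DataFrame
    loadings: pd.DataFrame
    reconstruction_error: float
    stability: float
    worst_restart_error: float
    n_restarts: int
    n_outliers_dropped: int
    seed: int


def _l2_normalize_rows(H: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(H, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return H / norms


def _frobenius_error(X: np.ndarray, U: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(X - U @ H, "fro"))


def _refit_usages(X: np.ndarray, H: np.ndarray, seed: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        U, _, _ = non_negative_factorization(
            X, H=H, n_components=H.shape[0], update_H=False,
            init="custom", W=None, solver="cd", max_iter=500,
            random_state=seed, tol=1e-6)
    return U


def _consensus_for_k(X: np.ndarray, k: int, n_restarts: int, seed: int,
                     outlier_threshold: float, max_iter: int) -> dict:
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    pooled = []
    restart_errors = []
    for rs in restart_seeds:
        try:
            model = NMF(n_components=k, init="random", solver="cd",
                        max_iter=max_iter, random_state=int(rs), tol=1e-5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(X)
            Hn = _l2_normalize_rows(model.components_)
            pooled.append(Hn)
            restart_errors.append(_frobenius_error(X, W, model.components_))
        except Exception as exc:  # pragma: no cover - solver failure is rare
            logger.warning("NMF restart failed (k=%d, seed=%d): %s", k, rs, exc)
    if not pooled:
        raise RuntimeError(f"all NMF restarts failed for k={k}")
    P = np.vstack(pooled)  # (n_restarts*k) x genes, unit rows

    # outlier filtering by nearest-neighbor cosine distance
    n_out = 0
    if P.shape[0] > k and len(pooled) > 1:
        D = squareform(pdist(P, metric="cosine"))
        np.fill_diagonal(D, np.inf)
        nn = D.min(axis=1)
        keep = nn <= outlier_threshold
        if keep.sum() >= k:
            n_out = int((~keep).sum())
            P = P[keep]

    if P.shape[0] > k:
        Z = linkage(P, method="average", metric="cosine")
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) > 1 and P.shape[0] > len(np.unique(labels)):
            try:
                stability = float(silhouette_score(P, labels, metric="cosine"))
            except ValueError:
                stability = float("nan")
        else:
            stability = float("nan")
    else:
        labels = np.arange(1, P.shape[0] + 1)
        stability = float("nan")

    H_cons = np.vstack([np.median(P[labels == c], axis=0)
                        for c in np.unique(labels)])
    H_cons = _l2_normalize_rows(np.maximum(H_cons, 0.0))
    U = _refit_usages(X, H_cons, seed)
    return {
        "H": H_cons, "U": U,
        "error": _frobenius_error(X, U, H_cons),
        "worst_restart_error": float(max(restart_errors)),
        "stability": stability,
        "n_outliers": n_out,
        "n_restarts_ok": len(pooled),
    }


def _elbow_k(ks: np.ndarray, errors: np.ndarray) -> int:
    """Kneedle-style elbow: k farthest below the endpoint chord."""
    if len(ks) == 1:
        return int(ks[0])
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    e = (errors - errors[-1]) / max(errors[0] - errors[-1], 1e-12)
    gap = x + e  # distance above the descending diagonal
    return int(ks[int(np.argmax(gap))])


class ConsensusNMF(BaseEstimator, TransformerMixin):
    """Consensus non-negative matrix factorization over a grid of k.

    Parameters
    ----------
    k : fixed factor count, or None to select from ``k_grid``
    k_grid : candidate factor counts (ignored when k is fixed)
    n_restarts : NMF restarts pooled per k
    selection : "stability" (largest k whose consensus silhouette is within
        ``stability_tol`` of the maximum — sub-factorizations of a stable
        rank are themselves stable, so the argmax alone under-selects) or
        "elbow" (reconstruction-error elbow)
    outlier_threshold : cosine distance above which a pooled factor with no
        near neighbor is dropped
    random_state : master seed for restart initializations

    Fitted attributes: ``models_`` (k -> FactorModel), ``selected_k_``,
    ``loadings_``, ``usages_``, ``reconstruction_error_``.
    """

    def __init__(self, k: int | None = None,
                 k_grid: Sequence[int] = (2, 3, 4, 5, 6, 7, 8, 9, 10),
                 n_restarts: int = 30, selection: str = "stability",
                 stability_tol: float = 0.01,
                 outlier_threshold: float = 0.3, max_iter: int = 400,
                 random_state: int = 0):
        self.k = k
        self.k_grid = k_grid
        self.n_restarts = n_restarts
        self.selection = selection
        self.stability_tol = stability_tol
        self.outlier_threshold = outlier_threshold
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "ConsensusNMF":
        if isinstance(X, pd.DataFrame):
            genes = list(X.columns)
            cells = X.index
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            genes = [f"g{j}" for j in range(Xv.shape[1])]
            cells = pd.RangeIndex(Xv.shape[0])
        if (Xv < 0).any():
            raise ValueError("matrix must be nonnegative")
        ks = [self.k] if self.k is not None else sorted(self.k_grid)
        lim = min(Xv.shape) - 1
        bad = [k for k in ks if not 2 <= k <= max(lim, 2) and k != 1]
        if any(k < 1 or k > min(Xv.shape) for k in ks):
            raise ValueError(f"k values out of range [1, {min(Xv.shape)}]: {ks}")
        del bad, lim

        self.models_ = {}
        for k in ks:
            res = _consensus_for_k(Xv, k, self.n_restarts, self.random_state,
                                   self.outlier_threshold, self.max_iter)
            self.models_[k] = FactorModel(
                k=k,
                usages=pd.DataFrame(res["U"], index=cells,
                                    columns=[f"factor{j}" for j in range(res["H"].shape[0])]),
                loadings=pd.DataFrame(res["H"], columns=genes,
                                      index=[f"factor{j}" for j in range(res["H"].shape[0])]),
                reconstruction_error=res["error"],
                stability=res["stability"],
                worst_restart_error=res["worst_restart_error"],
                n_restarts=res["n_restarts_ok"],
                n_outliers_dropped=res["n_outliers"],
                seed=self.random_state,
            )
        if self.k is not None:
            self.selected_k_ = self.k
        elif self.selection == "stability":
            stab = {k: m.stability for k, m in self.models_.items()
                    if np.isfinite(m.stability)}
            if stab:
                best = max(stab.values())
                self.selected_k_ = max(k for k, v in stab.items()
                                       if v >= best - self.stability_tol)
            else:
                self.selected_k_ = _elbow_k(
                    np.array(ks), np.array([self.models_[k].reconstruction_error
                                            for k in ks]))
        elif self.selection == "elbow":
            self.selected_k_ = _elbow_k(
                np.array(ks), np.array([self.models_[k].reconstruction_error
                                        for k in ks]))
        else:
            raise ValueError(f"unknown selection rule {self.selection!r}")
        best = self.models_[self.selected_k_]
        self.loadings_ = best.loadings
        self.usages_ = best.usages
        self.reconstruction_error_ = best.reconstruction_error
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return _refit_usages(Xv, self.loadings_.to_numpy(), self.random_state)


def fit_cnmf(matrix, k_grid=(2, 3, 4, 5, 6, 7, 8, 9, 10), n_restarts: int = 30,
             seed: int = 0, k: int | None = None,
             selection: str = "stability") -> tuple[dict, int]:
    """Functional wrapper: returns ({k: FactorModel}, selected_k)."""
    est = ConsensusNMF(k=k, k_grid=k_grid, n_restarts=n_restarts,
                       selection=selection, random_state=seed)
    est.fit(matrix)
    return est.models_, est.selected_k_


# --------------------------------------------------------------------------
# Anchor similarity ranking

def anchor_similarity(model: FactorModel, anchor: str) -> pd.Series:
    """Cosine similarity of every gene's loading column to the anchor's.

    Returns a Series indexed by gene, sorted descending with lexicographic
    tie-break, named after the anchor. The anchor itself scores 1.
    """
    L = model.loadings
    if anchor not in L.columns:
        raise KeyError(f"anchor gene {anchor!r} not in loadings")
    A = L.to_numpy(dtype=float)
    a = A[:, L.columns.get_loc(anchor)]
    na = np.linalg.norm(a)
    if na == 0:
        raise ValueError(f"anchor gene {anchor!r} has zero loading vector")
    norms = np.linalg.norm(A, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (A.T @ a) / (norms * na)
    sims = np.where(norms == 0, 0.0, sims)
    s = pd.Series(sims, index=L.columns, name=anchor)
    return s.sort_values(ascending=False, kind="mergesort").reindex(
        sorted(s.index, key=lambda g: (-s[g], g)))


# --------------------------------------------------------------------------
# Ranked (running-sum) enrichment

@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list
    n_overlap: int


def _running_sum_es(weights: np.ndarray, hits: np.ndarray) -> tuple[float, int]:
    """Signed max deviation of the weighted KS running sum.

    ``weights`` are the |similarity|^p values in ranked order, ``hits`` a
    boolean mask of set membership. Returns (ES, argmax position).
    """
    n = weights.size
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        return 0.0, 0
    wh = weights * hits
    denom = wh.sum()
    if denom == 0:
        # all hit weights zero: fall back to unweighted steps
        wh = hits.astype(float)
        denom = float(nh)
    p_hit = np.cumsum(wh) / denom
    p_miss = np.cumsum(~hits) / (n - nh)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def ranked_enrichment(ranking: pd.Series, gene_set: Sequence[str],
                      n_perm: int = 1000, seed: int = 0, p_exp: float = 1.0,
                      set_name: str = "gene_set") -> EnrichmentResult:
    """Weighted KS enrichment of ``gene_set`` in an anchor-similarity ranking.

    ``ranking`` is a gene-indexed Series sorted in descending similarity.
    Weight = |similarity|^p_exp. The null permutes set membership over the
    ranked genes; NES divides ES by the mean |null ES| of the same sign and
    p is the same-sign permutation tail (add-one corrected). FDR is filled
    by :func:`enrich_gene_sets` when a family is scored together.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranking.index.to_numpy()
    weights = np.abs(ranking.to_numpy(dtype=float)) ** p_exp
    hits = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError(f"gene set {set_name!r} has no overlap with ranking")
    if nh == len(genes):
        logger.warning("gene set %r covers the entire ranking; ES degenerate 0",
                       set_name)
        return EnrichmentResult(set_name, 0.0, 0.0, 1.0, 1.0, [], nh)

    es, i_max = _running_sum_es(weights, hits)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_hits = np.zeros(len(genes), dtype=bool)
        perm_hits[rng.choice(len(genes), size=nh, replace=False)] = True
        null[b], _ = _running_sum_es(weights, perm_hits)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size:
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
        nes = es / max(np.abs(same).mean(), 1e-12)
    else:
        p = 1.0 / (1 + n_perm)
        nes = float("inf") * np.sign(es)
    leading = (genes[: i_max + 1][hits[: i_max + 1]] if es >= 0
               else genes[i_max:][hits[i_max:]])
    return EnrichmentResult(set_name, es, float(nes), float(p), float("nan"),
                            list(leading), nh)


def enrich_gene_sets(ranking: pd.Series, gene_sets: Mapping[str, Sequence[str]],
                     n_perm: int = 1000, seed: int = 0,
                     p_exp: float = 1.0) -> pd.DataFrame:
    """Run ranked enrichment over a gene-set family; BH-FDR across sets."""
    rows = []
    rng = np.random.default_rng(seed)
    for name, gs in gene_sets.items():
        res = ranked_enrichment(ranking, gs, n_perm=n_perm,
                                seed=int(rng.integers(2**31 - 1)),
                                p_exp=p_exp, set_name=name)
        rows.append(res)
    df = pd.DataFrame({
        "gene_set": [r.gene_set for r in rows],
        "es": [r.es for r in rows],
        "nes": [r.nes for r in rows],
        "p": [r.p for r in rows],
        "n_overlap": [r.n_overlap for r in rows],
        "leading_edge": [",".join(r.leading_edge) for r in rows],
    })
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# --------------------------------------------------------------------------
# Over-representation analysis (hypergeometric / Fisher tail)

def overrepresentation(module_genes: Sequence[str],
                       gene_sets: Mapping[str, Sequence[str]],
                       universe: Sequence[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene module.

    Equivalent to the one-sided Fisher exact test per set; BH correction
    across sets. Reports overlap count and the fraction of module genes
    overlapping each set.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    module = set(module_genes) & uni
    if set(module_genes) - uni:
        raise ValueError("module_genes must be a subset of the universe")
    M, n_mod = len(uni), len(module)
    rows = []
    for name, gs in gene_sets.items():
        s = set(gs) & uni
        k = len(module & s)
        p = float(hypergeom.sf(k - 1, M, len(s), n_mod)) if s else 1.0
        rows.append((name, k, len(s),
                     k / n_mod if n_mod else 0.0, p))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                     "module_fraction", "p"])
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df
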