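"""Immune aggregate detection, classification, and spatial statistics.

Aggregates are detected among immune cells with density-based clustering
(DBSCAN semantics): a core cell has at least ``min_samples`` neighbors
(self included) within ``eps_um``; clusters are connected components of
core cells, border cells join the lowest-id reachable core cluster, noise
is discarded, and clusters below ``min_size`` are dropped. The rule set is
fully deterministic in the input.

Classification follows a decision list over aggregate composition and
chemokine co-expression: aggregates under 20% T cells are Unclassified;
aggregates whose mean CXCL13 *and* CXCR5 both exceed the cohort upper
quantile are Lymphoid; remaining aggregates with a high exhausted-CD8
fraction are Stimulated, else Quiescent.

Also here: stromal-area-normalized densities (occupancy-grid area),
Moran's I with a permutation null, ECDF comparisons with bootstrap bands,
rank-based aggregate-size contrasts, and stroma-vs-tumor localization
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree, ConvexHull, QhullError
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

__all__ = [
    "AggregateSet",
    "AggregateDetector",
    "SpatialWeights",
    "DEFAULT_IMMUNE_TYPES",
    "detect_aggregates",
    "classify_aggregates",
    "stromal_density",
    "knn_weights",
    "radius_weights",
    "morans_i",
    "compare_transition_ecdf",
    "compare_aggregate_sizes",
    "tumor_vs_stroma_localization",
]

DEFAULT_IMMUNE_TYPES = frozenset({"B", "CD8 T", "CD4 T", "myeloid"})


# --------------------------------------------------------------------------
# Density-based aggregate detection

class AggregateDetector(BaseEstimator, ClusterMixin):
    """Deterministic DBSCAN-style clusterer for planar cell coordinates.

    Neighbor counts include the point itself. Cluster ids are renumbered
    0..m-1 in order of each cluster's smallest member index; border points
    attach to the lowest-id reachable core cluster. ``fit`` sets
    ``labels_`` (-1 = noise).
    """

    def __init__(self, eps_um: float = 50.0, min_samples: int = 10,
                 min_size: int = 20):
        self.eps_um = eps_um
        self.min_samples = min_samples
        self.min_size = min_size

    def fit(self, X: np.ndarray, y=None) -> "AggregateDetector":
        if self.eps_um <= 0:
            raise ValueError("eps_um must be positive")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")
        xy = np.asarray(X, dtype=float)
        n = xy.shape[0]
        labels = np.full(n, -1, dtype=np.int64)
        if n == 0:
            self.labels_ = labels
            return self
        tree = cKDTree(xy)
        counts = np.array([len(nb) for nb in tree.query_ball_point(xy, self.eps_um)])
        core = counts >= self.min_samples
        core_idx = np.flatnonzero(core)
        if core_idx.size:
            sub = cKDTree(xy[core_idx])
            pairs = sub.query_pairs(self.eps_um, output_type="ndarray")
            m = core_idx.size
            adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                             shape=(m, m))
            _, comp = connected_components(adj, directed=False)
            # renumber components by smallest original index
            order = {}
            for local, orig in enumerate(core_idx):
                c = comp[local]
                order.setdefault(c, orig)
            ranked = sorted(order, key=lambda c: order[c])
            remap = {c: i for i, c in enumerate(ranked)}
            labels[core_idx] = [remap[c] for c in comp]
            # border points: lowest-id reachable core cluster
            core_tree = cKDTree(xy[core_idx])
            for i in np.flatnonzero(~core):
                nb = core_tree.query_ball_point(xy[i], self.eps_um)
                if nb:
                    labels[i] = min(labels[core_idx[j]] for j in nb)
        # size filter + final renumbering by smallest member index
        keep = []
        for c in np.unique(labels[labels >= 0]):
            members = np.flatnonzero(labels == c)
            if members.size >= self.min_size:
                keep.append((members[0], c))
            else:
                labels[members] = -1
        final = np.full(n, -1, dtype=np.int64)
        for new, (_, c) in enumerate(sorted(keep)):
            final[labels == c] = new
        self.labels_ = final
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class AggregateSet:
    """Detected aggregates: per-aggregate table + per-cell assignment."""

    table: pd.DataFrame          # one row per aggregate
    cell_assignment: pd.Series   # cell_id -> aggregate id (-1 = none)
    eps_um: float
    min_samples: int
    min_size: int

    def __len__(self) -> int:
        return len(self.table)


def _hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # 2-D: volume == area
    except QhullError:
        return 0.0


def detect_aggregates(cell_map: pd.DataFrame, eps_um: float = 50.0,
                      min_samples: int = 10, min_size: int = 20,
                      immune_types: frozenset | set = DEFAULT_IMMUNE_TYPES,
                      ) -> AggregateSet:
    """Detect immune aggregates in a cell map (columns x_um, y_um, cell_type).

    Only cells whose type is in ``immune_types`` participate. Returns an
    :class:`AggregateSet` with per-aggregate size, centroid, convex-hull
    area, and cell-type composition columns (``frac_<type>``), plus the
    T-cell fraction (CD8 T + CD4 T).
    """
    immune = cell_map[cell_map["cell_type"].isin(immune_types)]
    assignment = pd.Series(-1, index=cell_map["cell_id"], name="aggregate_id")
    if immune.empty:
        logger.info("no immune cells in map; returning empty aggregate set")
        table = pd.DataFrame(columns=["aggregate_id", "size", "centroid_x_um",
                                      "centroid_y_um", "area_um2", "T_fraction"])
        return AggregateSet(table, assignment, eps_um, min_samples, min_size)
    xy = immune[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("coordinates must be finite")
    labels = AggregateDetector(eps_um, min_samples, min_size).fit_predict(xy)
    assignment.loc[immune["cell_id"].to_numpy()] = labels

    rows = []
    types_seen = sorted(set(immune["cell_type"]))
    for c in np.unique(labels[labels >= 0]):
        sel = labels == c
        sub = immune.iloc[np.flatnonzero(sel)]
        comp = sub["cell_type"].value_counts(normalize=True)
        row = {
            "aggregate_id": int(c),
            "size": int(sel.sum()),
            "centroid_x_um": float(sub["x_um"].mean()),
            "centroid_y_um": float(sub["y_um"].mean()),
            "area_um2": _hull_area(xy[sel]),
        }
        for t in types_seen:
            row[f"frac_{t}"] = float(comp.get(t, 0.0))
        row["T_fraction"] = float(comp.get("CD8 T", 0.0) + comp.get("CD4 T", 0.0))
        rows.append(row)
    table = pd.DataFrame(rows)
    return AggregateSet(table, assignment, eps_um, min_samples, min_size)


# --------------------------------------------------------------------------
# Aggregate classification

def classify_aggregates(aggs: AggregateSet, cell_map: pd.DataFrame,
                        expr: pd.DataFrame, state_labels: pd.Series | None = None,
                        coexpr_quantile: float = 0.75,
                        exhausted_cut: float = 0.4,
                        min_t_fraction: float = 0.20,
                        fallback_cutoffs: tuple = (0.5, 0.5)) -> AggregateSet:
    """Classify aggregates as Quiescent / Stimulated / Lymphoid / Unclassified.

    ``expr`` is a cell-indexed expression table containing CXCL13 and CXCR5
    (log-normalized values recommended); ``state_labels`` maps CD8 cell ids
    to discrete state labels and feeds the exhausted-CD8 fraction. Decision
    list, in order: T fraction < ``min_t_fraction`` -> Unclassified; both
    chemokine aggregate means above the cohort ``coexpr_quantile`` quantile
    -> Lymphoid; exhausted CD8 fraction >= ``exhausted_cut`` -> Stimulated;
    else Quiescent. With fewer than two aggregates the quantile thresholds
    fall back to the fixed ``fallback_cutoffs`` (CXCL13, CXCR5), logged.
    """
    for g in ("CXCL13", "CXCR5"):
        if g not in expr.columns:
            raise ValueError(f"expression table lacks {g}")
    table = aggs.table.copy()
    if table.empty:
        table["class_label"] = pd.Series(dtype=object)
        return AggregateSet(table, aggs.cell_assignment, aggs.eps_um,
                            aggs.min_samples, aggs.min_size)

    assign = aggs.cell_assignment
    cd8_ids = set(cell_map.loc[cell_map["cell_type"] == "CD8 T", "cell_id"])
    mean_cxcl13, mean_cxcr5, exh_frac = [], [], []
    for c in table["aggregate_id"]:
        members = assign.index[assign.to_numpy() == c]
        sub = expr.loc[expr.index.intersection(members)]
        mean_cxcl13.append(float(sub["CXCL13"].mean()) if len(sub) else 0.0)
        mean_cxcr5.append(float(sub["CXCR5"].mean()) if len(sub) else 0.0)
        cd8_members = [m for m in members if m in cd8_ids]
        if state_labels is not None and cd8_members:
            labs = state_labels.reindex(cd8_members)
            exh_frac.append(float((labs == "exhausted").mean()))
        else:
            exh_frac.append(0.0)
    table["mean_CXCL13"] = mean_cxcl13
    table["mean_CXCR5"] = mean_cxcr5
    table["exhausted_CD8_fraction"] = exh_frac

    if len(table) >= 2:
        thr13 = float(np.quantile(table["mean_CXCL13"], coexpr_quantile))
        thr5 = float(np.quantile(table["mean_CXCR5"], coexpr_quantile))
    else:
        thr13, thr5 = fallback_cutoffs
        logger.info("fewer than 2 aggregates: using fixed chemokine cutoffs "
                    "(%.3g, %.3g)", thr13, thr5)
    table["coexpression_flag"] = ((table["mean_CXCL13"] >= thr13)
                                  & (table["mean_CXCR5"] >= thr5))

    labels = []
    for _, row in table.iterrows():
        if row["T_fraction"] < min_t_fraction:
            labels.append("Unclassified")
        elif row["coexpression_flag"]:
            labels.append("Lymphoid")
        elif row["exhausted_CD8_fraction"] >= exhausted_cut:
            labels.append("Stimulated")
        else:
            labels.append("Quiescent")
    table["class_label"] = labels
    return AggregateSet(table, aggs.cell_assignment, aggs.eps_um,
                        aggs.min_samples, aggs.min_size)


# --------------------------------------------------------------------------
# Stromal density

def stromal_density(cell_map: pd.DataFrame, cell_type: str,
                    tile_um: float = 50.0) -> float:
    """Stromal-area-normalized density (cells per mm²) of one cell type.

    Stromal area is estimated by an occupancy grid: the number of
    ``tile_um`` x ``tile_um`` tiles containing at least one
    stromal-compartment cell, times the tile area.
    """
    if tile_um <= 0:
        raise ValueError("tile_um must be positive")
    stroma = cell_map[cell_map["compartment"] == "stroma"]
    tiles = set(zip((stroma["x_um"] // tile_um).astype(int),
                    (stroma["y_um"] // tile_um).astype(int)))
    area_mm2 = len(tiles) * (tile_um / 1000.0) ** 2
    if area_mm2 == 0:
        raise ValueError("zero stromal area: no stromal cells in map")
    n = int((stroma["cell_type"] == cell_type).sum())
    return n / area_mm2


# --------------------------------------------------------------------------
# Spatial weights and Moran's I

@dataclass
class SpatialWeights:
    """Sparse neighbor weights: parallel index arrays i, j and weights."""

    i: np.ndarray
    j: np.ndarray
    w: np.ndarray
    n: int
    scheme: str
    row_standardized: bool


def knn_weights(xy: np.ndarray, k: int = 6,
                row_standardize: bool = True) -> SpatialWeights:
    """k-nearest-neighbor binary weights; distance ties broken by index."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    tree = cKDTree(xy)
    # query k+1 (self included); cKDTree breaks distance ties by index
    _, idx = tree.query(xy, k=k + 1)
    ii = np.repeat(np.arange(n), k)
    jj = np.empty(n * k, dtype=np.int64)
    for a in range(n):
        nb = [b for b in idx[a] if b != a][:k]
        jj[a * k:(a + 1) * k] = nb
    w = np.full(n * k, 1.0 / k if row_standardize else 1.0)
    return SpatialWeights(ii, jj, w, n, "knn", row_standardize)


def radius_weights(xy: np.ndarray, radius: float,
                   row_standardize: bool = True) -> SpatialWeights:
    """Binary weights for all pairs within ``radius`` (no self-weights)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
    jj = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = np.ones(len(ii))
    if row_standardize:
        deg = np.bincount(ii, minlength=n).astype(float)
        deg[deg == 0] = 1.0
        w = w / deg[ii]
    return SpatialWeights(ii, jj, w, n, "radius", row_standardize)


def _moran_stat(z: np.ndarray, wts: SpatialWeights) -> float:
    W = wts.w.sum()
    num = float((wts.w * z[wts.i] * z[wts.j]).sum())
    den = float((z ** 2).sum())
    return (wts.n / W) * num / den


def morans_i(values: np.ndarray, weights: SpatialWeights,
             n_perm: int = 999, seed: int = 0) -> dict:
    """Global Moran's I with permutation p-value.

    I = (n/W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z centered values and
    W the total weight. Expected value under no autocorrelation is
    -1/(n-1). The permutation p is two-sided (doubled one-sided tail,
    add-one corrected, capped at 1).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if v.size != weights.n:
        raise ValueError("values and weights disagree on n")
    z = v - v.mean()
    if np.allclose(z, 0):
        raise ValueError("values are constant; Moran's I undefined")
    i_obs = _moran_stat(z, weights)
    e_i = -1.0 / (v.size - 1)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        zp = rng.permutation(z)
        perm[b] = _moran_stat(zp, weights)
    p_hi = (1 + (perm >= i_obs).sum()) / (1 + n_perm)
    p_lo = (1 + (perm <= i_obs).sum()) / (1 + n_perm)
    return {"I": i_obs, "expected_I": e_i,
            "p": float(min(1.0, 2 * min(p_hi, p_lo))),
            "permutations": perm}


# --------------------------------------------------------------------------
# ECDF comparison with bootstrap bands

def compare_transition_ecdf(scores_by_class: Mapping[str, Sequence[float]],
                            grid: np.ndarray | None = None,
                            n_boot: int = 500, seed: int = 0,
                            n_min: int = 20,
                            band: tuple = (5.0, 95.0)) -> dict:
    """ECDFs per class on a common grid with pointwise bootstrap bands.

    Classes with fewer than ``n_min`` observations are excluded (logged).
    Returns ``{"grid", "ecdf": {cls: curve}, "band_lo", "band_hi",
    "ks": {(a, b): KS distance}, "ks_p": {(a, b): p}}``. Bands are the
    ``band`` percentiles over ``n_boot`` within-class resamples of cells.
    """
    kept = {}
    for cls, v in scores_by_class.items():
        v = np.asarray(v, dtype=float)
        if v.size < n_min:
            logger.info("class %r excluded from ECDF comparison (n=%d < %d)",
                        cls, v.size, n_min)
            continue
        kept[cls] = v
    if len(kept) < 2:
        raise ValueError("need at least 2 classes with enough cells")
    if grid is None:
        allv = np.concatenate(list(kept.values()))
        grid = np.linspace(allv.min(), allv.max(), 101)
    grid = np.asarray(grid, dtype=float)

    rng = np.random.default_rng(seed)
    ecdf, lo, hi = {}, {}, {}
    for cls, v in kept.items():
        ecdf[cls] = np.searchsorted(np.sort(v), grid, side="right") / v.size
        boot = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            res = np.sort(rng.choice(v, size=v.size, replace=True))
            boot[b] = np.searchsorted(res, grid, side="right") / v.size
        lo[cls] = np.percentile(boot, band[0], axis=0)
        hi[cls] = np.percentile(boot, band[1], axis=0)
    ks, ks_p = {}, {}
    names = sorted(kept)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            res = stats.ks_2samp(kept[names[a]], kept[names[b]])
            ks[(names[a], names[b])] = float(res.statistic)
            ks_p[(names[a], names[b])] = float(res.pvalue)
    return {"grid": grid, "ecdf": ecdf, "band_lo": lo, "band_hi": hi,
            "ks": ks, "ks_p": ks_p}


# --------------------------------------------------------------------------
# Size contrasts and localization

def compare_aggregate_sizes(sizes_a: Sequence[float], sizes_b: Sequence[float],
                            n_perm: int = 9999, seed: int = 0,
                            exact_max_n: int = 20) -> dict:
    """median(A) − median(B) with a two-sided rank-based p.

    Exact Mann–Whitney for small samples (total n <= ``exact_max_n``, no
    ties across groups required by scipy's exact path), label-permutation
    of the rank-sum statistic otherwise.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = float(np.median(a) - np.median(b))
    if a.size + b.size <= exact_max_n and np.unique(np.concatenate([a, b])).size == a.size + b.size:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return {"median_difference": diff, "p": float(res.pvalue),
                "method": "exact"}
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = ranks[: a.size].sum()
    rng = np.random.default_rng(seed)
    cnt = 0
    mu = a.size * (pooled.size + 1) / 2.0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[: a.size].sum() - mu) >= abs(obs - mu) - 1e-12:
            cnt += 1
    return {"median_difference": diff, "p": float((1 + cnt) / (1 + n_perm)),
            "method": "permutation"}


def tumor_vs_stroma_localization(cell_map: pd.DataFrame,
                                 aggs: AggregateSet,
                                 immune_types: frozenset | set = DEFAULT_IMMUNE_TYPES,
                                 ) -> pd.DataFrame:
    """Per-aggregate stromal fraction and binomial test vs the background.

    The background rate is the stromal fraction among all immune cells in
    the map; each aggregate's member count in stroma is tested two-sided
    against it.
    """
    if len(aggs.table) == 0:
        return pd.DataFrame(columns=["aggregate_id", "stromal_fraction", "p"])
    immune = cell_map[cell_map["cell_type"].isin(immune_types)]
    background = float((immune["compartment"] == "stroma").mean())
    comp = cell_map.set_index("cell_id")["compartment"]
    rows = []
    assign = aggs.cell_assignment
    for c in aggs.table["aggregate_id"]:
        members = assign.index[assign.to_numpy() == c]
        in_stroma = int((comp.reindex(members) == "stroma").sum())
        n = len(members)
        p = float(stats.binomtest(in_stroma, n, background).pvalue) if n else 1.0
        rows.append((int(c), in_stroma / n if n else np.nan, p))
    return pd.DataFrame(rows, columns=["aggregate_id", "stromal_fraction", "p"])
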