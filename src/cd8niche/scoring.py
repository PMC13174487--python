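"""Per-cell signature scores, stem→exhausted transition score, state labels.

A signature score for a cell is the mean, over signature genes, of the
cell's (log-normalized) expression minus the mean expression of control
genes drawn from the same average-expression bin — so scores are invariant
to adding a constant to every gene, and near zero for signatures that
behave like background.

The *transition score* places each CD8 cell on the stem→exhausted axis: the
raw statistic is (exhausted score − stem score) and the reported score is
its mid-rank empirical CDF position, so transition values are uniform on
[0, 1] over the scored population by construction.

Discrete state labels use a transparent margin-argmax rule over the four
signature scores instead of graph clustering: the top-scoring state wins if
it beats the runner-up by at least ``margin``, else the cell is "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GeneSignature",
    "SignatureScorer",
    "log_normalize",
    "score_signature",
    "transition_score",
    "assign_states",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with optional per-gene direction (+1/-1)."""

    name: str
    genes: tuple
    direction: tuple = ()

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.direction and len(self.direction) != len(self.genes):
            raise ValueError("direction must match genes in length")

    def directions(self) -> np.ndarray:
        if self.direction:
            return np.asarray(self.direction, dtype=float)
        return np.ones(len(self.genes))

    def present_in(self, columns: Sequence[str]) -> list[str]:
        cols = set(columns)
        return [g for g in self.genes if g in cols]


def log_normalize(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """log1p of library-size-normalized counts (counts-per-``target_sum``)."""
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    return np.log1p(counts.div(lib, axis=0) * target_sum)


def score_signature(matrix: pd.DataFrame, sig: GeneSignature,
                    n_bins: int = 25, n_ctrl: int = 50,
                    seed: int = 0,
                    exclude: Sequence[str] = ()) -> pd.Series:
    """Expression-bin-matched control score for one signature.

    ``matrix`` is cells x genes (already normalized/log-transformed as the
    caller prefers). For each signature gene, ``n_ctrl`` control genes are
    drawn (without replacement, capped at bin size) from the same
    average-expression bin; the cell's score is the mean over signature
    genes of (gene expression − mean control expression), with per-gene
    direction applied.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    present = sig.present_in(matrix.columns)
    if not present:
        raise ValueError(
            f"no genes of signature {sig.name!r} present in matrix; "
            f"missing: {sorted(sig.genes)}")
    dirs = {g: d for g, d in zip(sig.genes, sig.directions())}
    rng = np.random.default_rng(seed)

    gene_mean = matrix.mean(axis=0)
    # rank-based binning into n_bins of (near-)equal occupancy
    order = gene_mean.rank(method="first").to_numpy() - 1
    bin_of = (order * n_bins / len(gene_mean)).astype(int)
    bin_of = pd.Series(np.minimum(bin_of, n_bins - 1), index=gene_mean.index)

    X = matrix.to_numpy(dtype=float)
    col = {g: j for j, g in enumerate(matrix.columns)}
    sig_set = set(present) | set(exclude)
    per_gene = np.zeros((X.shape[0], len(present)))
    for j, g in enumerate(present):
        b = bin_of[g]
        candidates = [c for c in bin_of.index[(bin_of == b).to_numpy()]
                      if c not in sig_set]
        if not candidates:  # bin holds only signature genes: widen to all
            candidates = [c for c in matrix.columns if c not in sig_set]
        k = min(n_ctrl, len(candidates))
        chosen = rng.choice(np.array(candidates, dtype=object), size=k, replace=False)
        ctrl = X[:, [col[c] for c in chosen]].mean(axis=1)
        per_gene[:, j] = dirs.get(g, 1.0) * (X[:, col[g]] - ctrl)
    return pd.Series(per_gene.mean(axis=1), index=matrix.index,
                     name=sig.name)


def transition_score(stem_scores: pd.Series | np.ndarray,
                     exh_scores: pd.Series | np.ndarray) -> pd.Series:
    """Rank-normalized (exhausted − stem) score in [0, 1].

    transition_i = (midrank(raw_i) − 0.5) / n, so sorted values fall on the
    grid (2i−1)/(2n) up to ties and all-tied input maps to 0.5.
    """
    stem = pd.Series(stem_scores)
    exh = pd.Series(exh_scores)
    if len(stem) != len(exh):
        raise ValueError("stem and exhausted score vectors differ in length")
    if len(stem) < 2:
        raise ValueError("need at least 2 cells to rank")
    raw = exh.to_numpy(dtype=float) - stem.to_numpy(dtype=float)
    ranks = stats.rankdata(raw, method="average")
    out = (ranks - 0.5) / raw.size
    index = exh.index if isinstance(exh_scores, pd.Series) else None
    return pd.Series(out, index=index, name="transition")


def assign_states(scores: pd.DataFrame, margin: float = 0.0) -> pd.Series:
    """Margin-argmax state labels from a cells x signatures score table.

    The argmax signature name is assigned when it exceeds the runner-up by
    at least ``margin`` (strictly more than a tie when margin is 0);
    otherwise the label is "other".
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two signature columns")
    vals = scores.to_numpy(dtype=float)
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, -1]]
    second = vals[np.arange(len(vals)), order[:, -2]]
    names = scores.columns.to_numpy()
    labels = names[order[:, -1]].astype(object)
    gap = top - second
    labels[(gap < margin) | (gap == 0.0)] = "other"
    return pd.Series(labels, index=scores.index, name="state_label")


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Scores cells against a collection of gene signatures.

    Parameters
    ----------
    signatures : mapping of name -> gene list, or list of GeneSignature
    n_bins, n_ctrl : control-gene binning parameters
    log_normalize_input : treat input as raw counts and log-normalize first
    margin : margin for discrete state assignment
    random_state : seed for control-gene draws

    After ``fit`` (which just validates and freezes the signature set),
    ``transform`` returns the cells x signatures score table;
    ``score_table`` additionally appends ``transition`` (when both
    ``stem_signature`` and ``exhausted_signature`` are present) and the
    discrete ``state_label``.
    """

    def __init__(self, signatures: Mapping[str, Sequence[str]] | Sequence[GeneSignature],
                 n_bins: int = 25, n_ctrl: int = 50,
                 log_normalize_input: bool = True,
                 stem_signature: str = "stem-like",
                 exhausted_signature: str = "exhausted",
                 margin: float = 0.0, random_state: int = 0):
        self.signatures = signatures
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.log_normalize_input = log_normalize_input
        self.stem_signature = stem_signature
        self.exhausted_signature = exhausted_signature
        self.margin = margin
        self.random_state = random_state

    def _sig_list(self) -> list[GeneSignature]:
        if isinstance(self.signatures, Mapping):
            return [GeneSignature(name=k, genes=tuple(v))
                    for k, v in self.signatures.items()]
        return list(self.signatures)

    def fit(self, X: pd.DataFrame, y=None) -> "SignatureScorer":
        sigs = self._sig_list()
        if not sigs:
            raise ValueError("no signatures supplied")
        self.signatures_ = sigs
        self.present_genes_ = {s.name: s.present_in(X.columns) for s in sigs}
        absent = [s.name for s in sigs if not self.present_genes_[s.name]]
        if absent:
            raise ValueError(f"signatures with no genes in matrix: {absent}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "signatures_"):
            self.fit(X)
        M = log_normalize(X) if self.log_normalize_input else X
        all_sig_genes = sorted({g for s in self.signatures_ for g in s.genes})
        cols = {s.name: score_signature(M, s, self.n_bins, self.n_ctrl,
                                        seed=self.random_state,
                                        exclude=all_sig_genes)
                for s in self.signatures_}
        return pd.DataFrame(cols, index=X.index)

    def score_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Scores + transition + discrete state label for a count matrix."""
        table = self.transform(X)
        names = set(table.columns)
        if {self.stem_signature, self.exhausted_signature} <= names:
            table["transition"] = transition_score(
                table[self.stem_signature], table[self.exhausted_signature])
        table["state_label"] = assign_states(
            table[[c for c in table.columns if c not in ("transition",)]],
            margin=self.margin)
        return table
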