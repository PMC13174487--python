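"""Consensus NMF, anchor ranking, running-sum enrichment, and ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from cd8niche import (CCRCC_DEFAULT_K, ConsensusNMF, anchor_similarity,
                      enrich_gene_sets, fit_cnmf, overrepresentation,
                      ranked_enrichment)
from cd8niche.programs import FactorModel, _running_sum_es

from conftest import running_sum_bruteforce


def _planted(k, n=150, g=80, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    W = rng.gamma(1.0, 1.0, (n, k)) * (rng.random((n, k)) < 0.5)
    H = rng.gamma(1.0, 1.0, (k, g)) * (rng.random((k, g)) < 0.3)
    H[H.sum(1) == 0, 0] = 1.0
    X = W @ H + noise * rng.random((n, g))
    return X, H


def _min_matched_cosine(H_true, L):
    Hn = H_true / np.linalg.norm(H_true, axis=1, keepdims=True)
    Ln = L / np.linalg.norm(L, axis=1, keepdims=True)
    cos = Hn @ Ln.T
    ri, ci = linear_sum_assignment(-cos)
    return cos[ri, ci].min()


def test_rank2_planted_recovery_exact():
    X, H = _planted(2, seed=1, noise=0.0)
    models, k = fit_cnmf(X, k_grid=(2,), n_restarts=6, seed=0, k=2)
    m = models[2]
    assert m.reconstruction_error < 1e-4 * np.linalg.norm(X)
    assert _min_matched_cosine(H, m.loadings.to_numpy()) >= 0.99


def test_rank1_consensus_matches_svd():
    rng = np.random.default_rng(2)
    X = np.abs(rng.normal(2.0, 1.0, (40, 15)))
    est = ConsensusNMF(k=1, n_restarts=5, random_state=0).fit(X)
    s = np.linalg.svd(X, compute_uv=False)
    best_rank1 = np.sqrt((s[1:] ** 2).sum())
    assert abs(est.reconstruction_error_ - best_rank1) < 1e-8


def test_consensus_error_not_worse_than_worst_restart():
    X, _ = _planted(4, seed=3, noise=0.05)
    est = ConsensusNMF(k=4, n_restarts=6, random_state=1).fit(X)
    m = est.models_[4]
    assert m.reconstruction_error <= m.worst_restart_error + 1e-9


def test_stability_selection_recovers_planted_k():
    for k in (3, 5):
        X, _ = _planted(k, seed=k, noise=0.01)
        est = ConsensusNMF(k_grid=range(2, 9), n_restarts=6,
                           random_state=0).fit(X)
        assert est.selected_k_ == k


def test_ccrcc_preset_factor_count():
    """The ccRCC program analysis preset fixes k = 13."""
    assert CCRCC_DEFAULT_K == 13
    X, _ = _planted(3, n=60, g=40, seed=5, noise=0.05)
    est = ConsensusNMF(k=CCRCC_DEFAULT_K, n_restarts=3, random_state=0).fit(X)
    assert est.selected_k_ == 13
    assert est.loadings_.shape[0] == 13


def test_loadings_rows_unit_norm():
    X, _ = _planted(3, seed=6, noise=0.02)
    est = ConsensusNMF(k=3, n_restarts=5, random_state=0).fit(X)
    norms = np.linalg.norm(est.loadings_.to_numpy(), axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)


def _toy_model():
    loadings = pd.DataFrame(
        [[1.0, 0.0, 0.5, 0.0],
         [0.0, 1.0, 0.5, 0.0],
         [0.0, 0.0, 0.0, 1.0]],
        columns=["anchor", "other", "mix", "ortho"],
        index=["factor0", "factor1", "factor2"])
    return FactorModel(k=3, usages=pd.DataFrame(), loadings=loadings,
                       reconstruction_error=0.0, stability=1.0,
                       worst_restart_error=0.0, n_restarts=1,
                       n_outliers_dropped=0, seed=0)


def test_anchor_similarity_hand_cosines():
    model = _toy_model()
    sims = anchor_similarity(model, "anchor")
    assert sims["anchor"] == pytest.approx(1.0)
    assert sims["ortho"] == pytest.approx(0.0)
    # cos([1,0,0],[0.5,0.5,0]) = 0.5/ (1 * sqrt(0.5)) = 1/sqrt(2)
    assert sims["mix"] == pytest.approx(1 / np.sqrt(2))
    assert sims["other"] == pytest.approx(0.0)
    assert list(sims.index[:2]) == ["anchor", "mix"]
    with pytest.raises(KeyError):
        anchor_similarity(model, "missing")


def test_enrichment_top_set_matches_bruteforce():
    rng = np.random.default_rng(0)
    sims = np.sort(rng.random(120))[::-1]
    ranking = pd.Series(sims, index=[f"G{i:03d}" for i in range(120)])
    top = ranking.index[:15].tolist()
    res = ranked_enrichment(ranking, top, n_perm=200, seed=0)
    hits = np.isin(ranking.index.to_numpy(), top)
    brute = running_sum_bruteforce(np.abs(ranking.to_numpy()), hits)
    assert res.es > 0
    assert res.es == pytest.approx(brute, abs=1e-12)
    assert abs(res.es) <= 1.0


def test_enrichment_es_equals_bruteforce_random_sets():
    rng = np.random.default_rng(1)
    sims = rng.random(90)
    ranking = pd.Series(np.sort(sims)[::-1],
                        index=[f"g{i}" for i in range(90)])
    w = np.abs(ranking.to_numpy())
    for rep in range(20):
        hits = np.zeros(90, dtype=bool)
        hits[rng.choice(90, size=12, replace=False)] = True
        es, _ = _running_sum_es(w, hits)
        assert es == pytest.approx(running_sum_bruteforce(w, hits), abs=1e-12)
        assert abs(es) <= 1.0


def test_enrichment_full_ranking_degenerate():
    ranking = pd.Series([0.9, 0.5, 0.1], index=["a", "b", "c"])
    res = ranked_enrichment(ranking, ["a", "b", "c"], n_perm=100, seed=0)
    assert res.es == 0.0
    with pytest.raises(ValueError, match="no overlap"):
        ranked_enrichment(ranking, ["zzz"], n_perm=100, seed=0)


def test_enrichment_reproducible_and_family_fdr():
    rng = np.random.default_rng(2)
    ranking = pd.Series(np.sort(rng.random(60))[::-1],
                        index=[f"g{i}" for i in range(60)])
    sets = {"top": ranking.index[:8].tolist(),
            "rand": ranking.index[::7].tolist()}
    a = enrich_gene_sets(ranking, sets, n_perm=200, seed=5)
    b = enrich_gene_sets(ranking, sets, n_perm=200, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert ((a["fdr"] >= 0) & (a["fdr"] <= 1)).all()


def test_overrepresentation_closed_form():
    module = [f"m{i}" for i in range(10)]
    others = [f"u{i}" for i in range(100)]
    universe = module + others
    res = overrepresentation(module, {"exact": module}, universe)
    # P(X >= 10) drawing 10 from 110 with 10 marked = 1/C(110,10)
    expected = 1.0 / comb(110, 10)
    assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)
    assert res.loc[0, "overlap"] == 10
    assert res.loc[0, "module_fraction"] == pytest.approx(1.0)


def test_overrepresentation_disjoint_and_symmetry():
    universe = [f"g{i}" for i in range(50)]
    module = universe[:10]
    sets = {"disjoint": universe[40:], "a": universe[5:15], "b": universe[:10][5:] + universe[10:15]}
    res = overrepresentation(module, sets, universe).set_index("gene_set")
    assert res.loc["disjoint", "p"] == pytest.approx(1.0)
    # a and b have identical overlap structure (5 of 10) -> identical p
    assert res.loc["a", "p"] == pytest.approx(res.loc["b", "p"])
    with pytest.raises(ValueError, match="universe"):
        overrepresentation(["not_in"], sets, universe)
    with pytest.raises(ValueError, match="empty"):
        overrepresentation([], sets, [])
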