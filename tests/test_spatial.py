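"""Aggregate detection/classification and spatial statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cd8niche import (AggregateDetector, classify_aggregates,
                      compare_aggregate_sizes, compare_transition_ecdf,
                      detect_aggregates, knn_weights, morans_i,
                      radius_weights, stromal_density,
                      tumor_vs_stroma_localization)
from cd8niche.spatial import SpatialWeights

from conftest import dbscan_bruteforce


def _map_from_xy(xy, cell_type="CD8 T", compartment="stroma"):
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(xy))],
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "compartment": compartment, "cell_type": cell_type,
    })


def test_detector_matches_bruteforce_reference():
    rng = np.random.default_rng(0)
    for rep in range(20):
        xy = rng.uniform(0, 600, size=(200, 2))
        eps = rng.uniform(20, 80)
        ms = int(rng.integers(3, 8))
        got = AggregateDetector(eps_um=eps, min_samples=ms, min_size=5).fit_predict(xy)
        ref = dbscan_bruteforce(xy, eps, ms, 5)
        assert np.array_equal(got, ref), rep


def test_two_separated_blobs_recovered_exactly():
    rng = np.random.default_rng(1)
    a = rng.normal((0, 0), 15, size=(100, 2))
    b = rng.normal((1000, 0), 15, size=(100, 2))
    cm = _map_from_xy(np.vstack([a, b]))
    aggs = detect_aggregates(cm, eps_um=50, min_samples=5, min_size=20)
    assert len(aggs) == 2
    labels = aggs.cell_assignment.to_numpy()
    assert set(labels[:100]) == {0} and set(labels[100:]) == {1}


def test_sparse_scatter_yields_no_aggregates():
    rng = np.random.default_rng(2)
    cm = _map_from_xy(rng.uniform(0, 10_000, size=(150, 2)))
    aggs = detect_aggregates(cm, eps_um=30, min_samples=8, min_size=10)
    assert len(aggs) == 0
    assert (aggs.cell_assignment == -1).all()


def test_non_immune_cells_ignored_and_empty_ok():
    rng = np.random.default_rng(3)
    cm = _map_from_xy(rng.normal(0, 10, size=(100, 2)), cell_type="tumor")
    aggs = detect_aggregates(cm, eps_um=50, min_samples=5, min_size=10)
    assert len(aggs) == 0


def _aggset_with(table_rows, assign):
    from cd8niche.spatial import AggregateSet
    return AggregateSet(pd.DataFrame(table_rows), assign, 50.0, 5, 10)


def test_classification_decision_list():
    rng = np.random.default_rng(4)
    # three tight blobs of 30 immune cells each
    blobs = [rng.normal((c, 0), 5, size=(30, 2)) for c in (0, 500, 1000)]
    xy = np.vstack(blobs)
    cm = _map_from_xy(xy)
    cm.loc[:29, "cell_type"] = "myeloid"          # blob 0: no T cells
    aggs = detect_aggregates(cm, eps_um=50, min_samples=5, min_size=10)
    assert len(aggs) == 3
    expr = pd.DataFrame(
        {"CXCL13": 0.1, "CXCR5": 0.1}, index=cm["cell_id"], dtype=float)
    # blob 2 (ids c60..c89) has maximal chemokine means
    expr.loc[[f"c{i}" for i in range(60, 90)], ["CXCL13", "CXCR5"]] = 5.0
    # all CD8 cells exhausted -> high exhausted fraction everywhere
    states = pd.Series("exhausted", index=cm["cell_id"])
    out = classify_aggregates(aggs, cm, expr, state_labels=states)
    t = out.table.set_index("aggregate_id")
    assert t.loc[0, "class_label"] == "Unclassified"   # T fraction 0
    assert t.loc[2, "class_label"] == "Lymphoid"       # co-expression wins
    assert t.loc[1, "class_label"] == "Stimulated"     # exhausted >= 0.4


def test_classification_order_and_scale_invariance():
    rng = np.random.default_rng(5)
    blobs = [rng.normal((c, 0), 5, size=(40, 2)) for c in (0, 400, 800)]
    cm = _map_from_xy(np.vstack(blobs))
    expr = pd.DataFrame(rng.gamma(1, 1, size=(120, 2)),
                        columns=["CXCL13", "CXCR5"], index=cm["cell_id"])
    states = pd.Series(rng.choice(["stem-like", "exhausted"], 120),
                       index=cm["cell_id"])
    aggs = detect_aggregates(cm, eps_um=50, min_samples=5, min_size=10)
    base = classify_aggregates(aggs, cm, expr, state_labels=states)
    perm = rng.permutation(len(cm))
    cm2 = cm.iloc[perm].reset_index(drop=True)
    aggs2 = detect_aggregates(cm2, eps_um=50, min_samples=5, min_size=10)
    scaled = classify_aggregates(aggs2, cm2, expr * 3.7, state_labels=states)
    merged = base.table.merge(scaled.table, on="size", suffixes=("_a", "_b"))
    assert (merged["class_label_a"] == merged["class_label_b"]).all()


def test_stromal_density_hand_arithmetic():
    # 10 CD8 cells across exactly 4 occupied 50um tiles
    xs = np.array([10, 20, 30, 40, 60, 70, 110, 120, 160, 170], dtype=float)
    ys = np.full(10, 25.0)
    cm = _map_from_xy(np.column_stack([xs, ys]))
    got = stromal_density(cm, "CD8 T", tile_um=50.0)
    assert got == pytest.approx(10 / (4 * 0.0025))
    assert stromal_density(cm, "B", tile_um=50.0) == 0.0
    tumor_only = _map_from_xy(np.column_stack([xs, ys]), compartment="tumor")
    with pytest.raises(ValueError, match="stromal"):
        stromal_density(tumor_only, "CD8 T")


def test_stromal_density_grid_coverage_of_disk():
    """Occupancy-grid area of a dense disk approaches pi r^2 as tiles shrink."""
    rng = np.random.default_rng(6)
    r = 500.0
    pts = rng.uniform(-r, r, size=(60_000, 2))
    pts = pts[(pts ** 2).sum(1) <= r ** 2] + r
    cm = _map_from_xy(pts)
    # area implied by density of all cells: n / density
    for tile, tol in ((20.0, 0.06), (50.0, 0.12)):
        dens = stromal_density(cm, "CD8 T", tile_um=tile)
        area = len(pts) / dens  # mm^2
        assert area == pytest.approx(np.pi * 0.25, rel=tol)


def _chain_weights(n):
    i = np.array([a for a in range(n - 1)] + [a + 1 for a in range(n - 1)])
    j = np.array([a + 1 for a in range(n - 1)] + [a for a in range(n - 1)])
    return SpatialWeights(i, j, np.ones(2 * (n - 1)), n, "chain", False)


def test_morans_i_equals_direct_double_sum():
    vals = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    w = _chain_weights(6)
    res = morans_i(vals, w, n_perm=99, seed=0)
    z = vals - vals.mean()
    direct = (6 / w.w.sum()) * sum(
        wij * z[a] * z[b] for a, b, wij in zip(w.i, w.j, w.w)) / (z ** 2).sum()
    assert res["I"] == pytest.approx(direct, abs=1e-12)
    assert res["I"] < 0  # alternating pattern: negative autocorrelation
    assert res["expected_I"] == pytest.approx(-1 / 5)


def test_morans_i_positive_on_gradient():
    n = 30
    res = morans_i(np.linspace(0, 1, n), _chain_weights(n), n_perm=199, seed=1)
    assert res["I"] > 0
    assert res["p"] < 0.05


def test_morans_null_mean_matches_expectation():
    rng = np.random.default_rng(7)
    n = 40
    vals = rng.normal(size=n)
    xy = rng.uniform(0, 100, size=(n, 2))
    res = morans_i(vals, knn_weights(xy, k=5), n_perm=500, seed=2)
    perm = res["permutations"]
    se = perm.std(ddof=1) / np.sqrt(perm.size)
    assert abs(perm.mean() - (-1 / (n - 1))) < 3 * se
    with pytest.raises(ValueError, match="constant"):
        morans_i(np.ones(10), knn_weights(xy[:10], k=3))


def test_weight_schemes_shapes():
    rng = np.random.default_rng(8)
    xy = rng.uniform(0, 100, size=(25, 2))
    w = knn_weights(xy, k=6)
    assert np.all(np.bincount(w.i, minlength=25) == 6)
    assert not np.any(w.i == w.j)
    rw = radius_weights(xy, radius=30.0)
    assert not np.any(rw.i == rw.j)


def test_ecdf_identity_and_degenerate_bootstrap():
    v = np.linspace(0, 1, 120)
    out = compare_transition_ecdf({"a": v, "b": v.copy()}, n_boot=50, seed=0)
    assert out["ks"][("a", "b")] == 0.0
    assert np.all(out["band_lo"]["a"] <= out["band_hi"]["b"])
    single = compare_transition_ecdf({"a": v, "b": v + 0.01}, n_boot=1, seed=1)
    # n_boot=1: both band edges equal the single resample's ECDF
    np.testing.assert_allclose(single["band_lo"]["a"], single["band_hi"]["a"])


def test_ecdf_disjoint_supports_ks_near_one():
    rng = np.random.default_rng(9)
    a = rng.uniform(0, 0.5, 500)
    b = rng.uniform(0.5, 1.0, 500)
    out = compare_transition_ecdf({"a": a, "b": b}, n_boot=20, seed=0)
    assert out["ks"][("a", "b")] >= 0.95


def test_ecdf_small_class_excluded():
    rng = np.random.default_rng(10)
    with pytest.raises(ValueError, match="2 classes"):
        compare_transition_ecdf({"a": rng.random(100), "b": rng.random(3)},
                                n_boot=10, seed=0, n_min=20)


def test_ecdf_band_coverage_near_nominal():
    """Pointwise 5-95% bootstrap bands cover the true CDF at grid midpoints
    at roughly nominal rate."""
    rng = np.random.default_rng(11)
    grid = np.array([0.25, 0.5, 0.75])
    hits = 0
    total = 0
    for rep in range(100):
        a = rng.random(150)
        out = compare_transition_ecdf({"a": a, "b": rng.random(150)},
                                      grid=grid, n_boot=120, seed=rep)
        for gi, g in enumerate(grid):
            total += 1
            if out["band_lo"]["a"][gi] <= g <= out["band_hi"]["a"][gi]:
                hits += 1
    assert 0.85 <= hits / total <= 0.99


def test_aggregate_size_contrast_identity_and_exact():
    out = compare_aggregate_sizes([10, 20, 30], [10, 20, 30], seed=0)
    assert out["median_difference"] == 0.0
    assert out["p"] >= 0.99
    out = compare_aggregate_sizes([100, 110, 120, 130], [10, 20, 30, 40], seed=0)
    assert out["median_difference"] == pytest.approx(115 - 25)
    assert out["p"] == pytest.approx(2 / 70)
    assert out["method"] == "exact"


def test_aggregate_size_translation_equivariance():
    rng = np.random.default_rng(12)
    a = rng.gamma(5, 10, 30)
    b = rng.gamma(5, 10, 25)
    d0 = compare_aggregate_sizes(a, b, n_perm=200, seed=0)["median_difference"]
    d1 = compare_aggregate_sizes(a + 13.5, b, n_perm=200, seed=0)["median_difference"]
    assert d1 == pytest.approx(d0 + 13.5)


def test_localization_binomial_closed_form():
    rng = np.random.default_rng(13)
    # 20-cell aggregate fully in stroma; background immune half in tumor
    agg_xy = rng.normal((0, 0), 5, size=(20, 2))
    bg_xy = rng.uniform(500, 1000, size=(20, 2))
    cm = _map_from_xy(np.vstack([agg_xy, bg_xy]))
    cm.loc[20:29, "compartment"] = "tumor"  # 10 of 20 background in tumor
    aggs = detect_aggregates(cm, eps_um=50, min_samples=5, min_size=10)
    assert len(aggs) == 1
    out = tumor_vs_stroma_localization(cm, aggs)
    background = 30 / 40  # stroma fraction among immune cells
    expected = stats.binomtest(20, 20, background).pvalue
    assert out.loc[0, "stromal_fraction"] == 1.0
    assert out.loc[0, "p"] == pytest.approx(expected)
    # empty aggregate set -> empty report
    empty = detect_aggregates(cm.iloc[20:], eps_um=10, min_samples=5, min_size=10)
    assert tumor_vs_stroma_localization(cm, empty).empty
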