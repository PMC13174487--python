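"""Generator contracts: determinism, count marginals, clonal and spatial
ground-truth structure."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cd8niche import (SimConfig, archetype_means, simulate_cd8_counts,
                      simulate_clonotypes, simulate_tissue,
                      well_separated_config)
from cd8niche.simulate import STATES, AggregateSpec


def test_same_seed_bitwise_identical():
    cfg = SimConfig(seed=7, n_cells=300)
    m1, t1 = simulate_cd8_counts(cfg)
    m2, t2 = simulate_cd8_counts(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    assert np.array_equal(t1.u, t2.u)
    c1 = simulate_clonotypes(cfg, t1)
    c2 = simulate_clonotypes(cfg, t2)
    pd.testing.assert_frame_equal(c1, c2)
    map1, cnt1, _ = simulate_tissue(cfg)
    map2, cnt2, _ = simulate_tissue(cfg)
    pd.testing.assert_frame_equal(map1, map2)
    pd.testing.assert_frame_equal(cnt1, cnt2)


def test_poisson_limit_matches_archetype_means():
    """With no dropout and dispersion -> inf, gene means approach the
    archetype table (3 SE at n=10,000, single pure state)."""
    cfg = SimConfig(seed=1, n_cells=10_000,
                    state_mixture={"stem-like": 1.0},
                    nb_dispersion=math.inf, zero_inflation=0.0,
                    state_purity=1.0)
    m, _ = simulate_cd8_counts(cfg)
    expected = archetype_means().loc["stem-like"]
    for gene in ("CXCR5", "TCF7", "GZMB", "CD8A", "FILLER001"):
        mu = expected[gene]
        se = math.sqrt(mu / cfg.n_cells)  # Poisson SE of the mean
        assert abs(m[gene].mean() - mu) < 3 * se + 1e-9, gene


def test_stem_only_mixture_cxcr5_exceeds_havcr2():
    cfg = SimConfig(seed=2, n_cells=5000, state_mixture={"stem-like": 1.0},
                    state_purity=1.0)
    m, _ = simulate_cd8_counts(cfg)
    assert m["CXCR5"].mean() > m["HAVCR2"].mean()


def test_nb_dispersion_reflected_in_variance():
    """var/mean ratio for a constant-mean gene matches 1 + mu/theta."""
    cfg = SimConfig(seed=3, n_cells=10_000, state_mixture={"exhausted": 1.0},
                    nb_dispersion=2.0, zero_inflation=0.0, state_purity=1.0)
    m, _ = simulate_cd8_counts(cfg)
    g = m["CD8A"].to_numpy(dtype=float)  # state-independent mean
    mu = g.mean()
    expected_ratio = 1 + mu / cfg.nb_dispersion
    boot = np.random.default_rng(0).choice(g, size=(200, g.size), replace=True)
    ratios = boot.var(axis=1) / boot.mean(axis=1)
    lo, hi = np.percentile(ratios, [0.5, 99.5])
    assert lo <= expected_ratio <= hi


@pytest.mark.parametrize("bad, field_name", [
    ({"state_mixture": {"stem-like": 0.6, "exhausted": 0.2}}, "state_mixture"),
    ({"state_mixture": {"stem-like": 1.2, "exhausted": -0.2}}, "state_mixture"),
    ({"zero_inflation": 1.5}, "zero_inflation"),
    ({"nb_dispersion": 0.0}, "nb_dispersion"),
    ({"clone_size_law": {"law": "pareto"}}, "clone_size_law"),
])
def test_invalid_config_rejected_naming_field(bad, field_name):
    cfg = replace(SimConfig(), **bad)
    with pytest.raises(ValueError, match=field_name):
        cfg.validate()


def test_clonotypes_zero_stem_fraction_boundary():
    cfg = replace(well_separated_config(seed=5, n_cells=3000),
                  frac_expanding_with_stem=0.0)
    m, t = simulate_cd8_counts(cfg)
    assign = simulate_clonotypes(cfg, t)
    states = pd.Series(t.state_label, index=m.index)
    merged = assign.assign(state=states.loc[assign["cell_id"]].to_numpy())
    by_clone = merged.groupby("clonotype_id")["state"].agg(
        size="count", stem=lambda s: (s == "stem-like").sum())
    expanded = by_clone[by_clone["size"] >= 3]
    assert len(expanded) > 0
    assert (expanded["stem"] < 2).all()


def test_clonotypes_stem_fraction_recovered():
    cfg = replace(well_separated_config(seed=6, n_cells=4000),
                  frac_expanding_with_stem=0.5)
    m, t = simulate_cd8_counts(cfg)
    assign = simulate_clonotypes(cfg, t)
    states = pd.Series(t.state_label, index=m.index)
    merged = assign.assign(state=states.loc[assign["cell_id"]].to_numpy())
    by_clone = merged.groupby("clonotype_id")["state"].agg(
        size="count", stem=lambda s: (s == "stem-like").sum())
    expanded = by_clone[by_clone["size"] >= 3]
    assert len(expanded) >= 400
    k = int((expanded["stem"] >= 2).sum())
    ci = stats.binomtest(k, len(expanded)).proportion_ci(0.95)
    assert ci.low <= 0.5 <= ci.high


def test_singleton_clone_not_expanding():
    cfg = SimConfig(seed=8, n_cells=50,
                    clone_size_law={"law": "geometric", "p": 0.95})
    m, t = simulate_cd8_counts(cfg)
    simulate_clonotypes(cfg, t)
    sizes = t.clone_sizes[t.clone_sizes > 0]
    assert (sizes == 1).any()  # overwhelmingly singletons at p=0.95


def test_tissue_cell_conservation_without_background():
    spec = AggregateSpec(class_label="Quiescent", n_cells=200,
                         composition={"B": 0.1, "CD8 T": 0.5, "CD4 T": 0.2,
                                      "myeloid": 0.2},
                         cd8_state_mix={s: 0.25 for s in STATES})
    cfg = replace(SimConfig(seed=9), aggregate_specs=(spec,),
                  background_immune_density_per_mm2=0.0)
    cell_map, counts, truth = simulate_tissue(cfg)
    n_tumor = int((cell_map["cell_type"] == "tumor").sum())
    assert len(cell_map) == 200 + n_tumor
    assert len(counts) == len(cell_map)
    assert (truth.aggregate_id[cell_map["cell_type"] != "tumor"] == 0).all()


def test_tissue_aggregate_centers_separated_and_in_bounds():
    cfg = well_separated_config(seed=10)
    cell_map, _, truth = simulate_tissue(cfg)
    centers = truth.aggregate_center.to_numpy()
    W, H = cfg.tissue_width_um, cfg.tissue_height_um
    assert ((centers >= 0) & (centers <= max(W, H))).all()
    sigma = cfg.aggregate_specs[0].radius_um
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            assert np.hypot(*(centers[i] - centers[j])) >= 8 * sigma
    # every planted cell within tissue bounds
    assert cell_map["x_um"].between(0, W).all()
    assert cell_map["y_um"].between(0, H).all()


def test_tissue_composition_within_multinomial_ci():
    spec = AggregateSpec(class_label="Lymphoid", n_cells=400,
                         composition={"B": 0.3, "CD8 T": 0.3, "CD4 T": 0.2,
                                      "myeloid": 0.2},
                         cd8_state_mix={s: 0.25 for s in STATES})
    cfg = replace(SimConfig(seed=11), aggregate_specs=(spec,),
                  background_immune_density_per_mm2=0.0)
    cell_map, _, truth = simulate_tissue(cfg)
    members = cell_map[truth.aggregate_id == 0]
    for t, frac in spec.composition.items():
        k = int((members["cell_type"] == t).sum())
        # 99% marginal CIs: four simultaneous comparisons
        ci = stats.binomtest(k, len(members)).proportion_ci(0.99)
        assert ci.low <= frac <= ci.high, (t, k)


def test_tissue_lymphoid_chemokines_elevated():
    cfg = well_separated_config(seed=12)
    cell_map, counts, truth = simulate_tissue(cfg)
    agg_means = {}
    for a, cls in truth.aggregate_class.items():
        sel = truth.aggregate_id == a
        agg_means.setdefault(cls, []).append(
            counts.loc[cell_map.loc[sel, "cell_id"], ["CXCL13", "CXCR5"]].mean())
    lymph = pd.DataFrame(agg_means["Lymphoid"]).mean()
    for other in ("Quiescent", "Stimulated"):
        oth = pd.DataFrame(agg_means[other]).mean()
        assert lymph["CXCR5"] > oth["CXCR5"]
        assert lymph["CXCL13"] > oth["CXCL13"]


def test_tissue_placement_failure_raises():
    spec = AggregateSpec(class_label="Quiescent", n_cells=50,
                         composition={"CD8 T": 1.0},
                         cd8_state_mix={s: 0.25 for s in STATES},
                         radius_um=40.0)
    cfg = replace(SimConfig(seed=13), aggregate_specs=(spec,),
                  tumor_area_fraction=0.99, tumor_overlap_tolerance=0.0,
                  max_aggregate_retries=10)
    with pytest.raises(RuntimeError, match="could not place aggregate"):
        simulate_tissue(cfg)
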