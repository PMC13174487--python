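"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cd8niche import (SignatureScorer, default_signatures, simulate_cd8_counts,
                      well_separated_config)


@pytest.fixture(scope="session")
def cd8_sim():
    """One well-separated CD8 simulation shared across tests."""
    cfg = well_separated_config(seed=42, n_cells=1500)
    counts, truth = simulate_cd8_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def cd8_scores(cd8_sim):
    _, counts, _ = cd8_sim
    scorer = SignatureScorer(default_signatures(), random_state=0).fit(counts)
    return scorer.score_table(counts)


def dbscan_bruteforce(xy: np.ndarray, eps: float, min_samples: int,
                      min_size: int) -> np.ndarray:
    """O(n^2) reference density clustering: pairwise distances, BFS over the
    core-point graph, border points to the lowest-id reachable core cluster.

    Independent of the package implementation (no trees, no union-find).
    """
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    within = d2 <= eps ** 2  # includes self
    core = within.sum(1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # BFS over core points
        queue = [i]
        labels[i] = cluster
        while queue:
            a = queue.pop(0)
            for b in np.flatnonzero(within[a] & core):
                if labels[b] == -1:
                    labels[b] = cluster
                    queue.append(b)
        cluster += 1
    # renumber clusters by smallest member index
    order = {}
    for i in range(n):
        if labels[i] >= 0 and labels[i] not in order:
            order[labels[i]] = i
    remap = {c: r for r, (c, _) in enumerate(sorted(order.items(), key=lambda t: t[1]))}
    labels = np.array([remap[l] if l >= 0 else -1 for l in labels])
    # border points
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        cand = [labels[j] for j in np.flatnonzero(within[i] & core)]
        if cand:
            labels[i] = min(cand)
    # min_size filter and final renumbering
    keep = []
    for c in sorted(set(labels[labels >= 0])):
        members = np.flatnonzero(labels == c)
        if members.size >= min_size:
            keep.append((members[0], c))
        else:
            labels[members] = -1
    final = np.full(n, -1, dtype=int)
    for new, (_, c) in enumerate(sorted(keep)):
        final[labels == c] = new
    return final


def kendall_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """O(n^2) tau-b by direct pair enumeration with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else np.nan


def running_sum_bruteforce(weights: np.ndarray, hits: np.ndarray) -> float:
    """Plain-loop weighted KS running sum; signed max deviation."""
    wsum = weights[hits].sum()
    nmiss = (~hits).sum()
    best = 0.0
    cur_hit = cur_miss = 0.0
    for i in range(len(weights)):
        if hits[i]:
            cur_hit += weights[i] / wsum
        else:
            cur_miss += 1.0 / nmiss
        dev = cur_hit - cur_miss
        if abs(dev) > abs(best):
            best = dev
    return best


def match_aggregate_classes(detected, cell_map, planted_id, truth_classes):
    """Pair each detected aggregate with the majority planted aggregate and
    return (n_correct, n_total) class agreement."""
    correct = total = 0
    assign = detected.cell_assignment
    for _, row in detected.table.iterrows():
        members = assign.index[assign.to_numpy() == row["aggregate_id"]]
        pid = pd.Series(planted_id[np.isin(cell_map["cell_id"], members)])
        pid = pid[pid >= 0]
        if pid.empty:
            continue
        total += 1
        if truth_classes[pid.mode()[0]] == row.get("class_label"):
            correct += 1
    return correct, total
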