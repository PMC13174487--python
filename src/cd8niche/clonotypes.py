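"""Clonotype construction and stem-content statistics.

A clonotype is the set of cells sharing an identical paired-chain TCR
string (exact match; no fuzzy CDR3 matching). A clone is *expanding* when
it holds at least ``expansion_threshold`` (default 3) cells, and
*stem-maintained* when at least ``stem_multiplicity_cut`` (default 2) of
its members carry the stem-like state label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import kendall_tau

__all__ = [
    "ClonotypeTable",
    "build_clonotypes",
    "stem_content_statistic",
    "clone_program_association",
]

EXPANSION_THRESHOLD = 3


@dataclass
class ClonotypeTable:
    """Per-clone table plus the cell -> clone mapping used to build it."""

    table: pd.DataFrame        # clonotype_id, size, expanding, per-state counts
    cell_to_clone: pd.Series   # cell_id -> clonotype_id
    n_cells_without_tcr: int

    def __len__(self) -> int:
        return len(self.table)


def build_clonotypes(assignments: pd.DataFrame,
                     states: Optional[pd.Series] = None,
                     expansion_threshold: int = EXPANSION_THRESHOLD,
                     all_cells: Optional[pd.Index] = None) -> ClonotypeTable:
    """Group cells into clonotypes by exact TCR-string match.

    ``assignments`` needs columns ``cell_id`` and ``clonotype_id`` (AIRR-
    flavored ``junction_aa`` columns are accepted and concatenated).
    ``states`` maps cell ids to discrete state labels; per-state member
    counts and ``stem_multiplicity`` are joined in when provided.
    ``all_cells`` (optional) is used to count cells without a TCR.
    """
    df = assignments.copy()
    if "clonotype_id" not in df.columns:
        junction_cols = [c for c in df.columns if c.startswith("junction_aa")]
        if not junction_cols:
            raise ValueError("assignments need clonotype_id or junction_aa columns")
        df["clonotype_id"] = df[junction_cols].astype(str).agg("|".join, axis=1)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id in assignments: {dup!r}")
    if (df["clonotype_id"].astype(str).str.len() == 0).any():
        raise ValueError("empty TCR string for an assigned cell")

    n_missing = 0
    if all_cells is not None:
        n_missing = int(len(set(all_cells) - set(df["cell_id"])))

    cell_to_clone = df.set_index("cell_id")["clonotype_id"]
    groups = df.groupby("clonotype_id", sort=True)["cell_id"].apply(list)
    rows = []
    state_names = sorted(states.dropna().unique()) if states is not None else []
    for clone, members in groups.items():
        row = {"clonotype_id": clone, "size": len(members),
               "expanding": len(members) >= expansion_threshold}
        if states is not None:
            labs = states.reindex(members)
            for s in state_names:
                row[f"n_{s}"] = int((labs == s).sum())
            row["stem_multiplicity"] = int((labs == "stem-like").sum())
        rows.append(row)
    table = pd.DataFrame(rows)
    return ClonotypeTable(table, cell_to_clone, n_missing)


def stem_content_statistic(clones: ClonotypeTable,
                           stem_multiplicity_cut: int = 2) -> dict:
    """Fraction of expanding clones holding multiple stem-like cells.

    Numerator: expanding clones with ``stem_multiplicity`` >=
    ``stem_multiplicity_cut``; denominator: all expanding clones. Returns
    ``computable=False`` with a reason when there are no expanding clones.
    Also reports the maximum stem multiplicity across clones.
    """
    t = clones.table
    if t.empty:
        raise ValueError("clonotype table is empty")
    if "stem_multiplicity" not in t.columns:
        raise ValueError("clonotype table lacks state information")
    exp = t[t["expanding"]]
    if exp.empty:
        return {"computable": False, "reason": "no expanding clones",
                "n_expanding": 0}
    num = int((exp["stem_multiplicity"] >= stem_multiplicity_cut).sum())
    return {
        "computable": True,
        "fraction": num / len(exp),
        "n_expanding": int(len(exp)),
        "n_with_multiple_stem": num,
        "max_stem_multiplicity": int(t["stem_multiplicity"].max()),
    }


def clone_program_association(clones: ClonotypeTable, expr: pd.DataFrame,
                              gene: str = "CXCL13",
                              min_clones: int = 5) -> dict:
    """Kendall association between per-clone mean expression of ``gene``
    and the clone's stem-like fraction.

    On exhaustion-skewed repertoires (stem-poor clones expressing CXCL13)
    the expected association is negative.
    """
    if gene not in expr.columns:
        raise ValueError(f"gene {gene!r} not in expression table")
    t = clones.table
    if "stem_multiplicity" not in t.columns:
        raise ValueError("clonotype table lacks state information")
    means, fracs = [], []
    for _, row in t.iterrows():
        members = clones.cell_to_clone.index[
            clones.cell_to_clone.to_numpy() == row["clonotype_id"]]
        sub = expr.loc[expr.index.intersection(members), gene]
        if len(sub) == 0:
            continue
        means.append(float(sub.mean()))
        fracs.append(row["stem_multiplicity"] / row["size"])
    if len(means) < min_clones:
        return {"computable": False,
                "reason": f"fewer than {min_clones} clones with expression"}
    res = kendall_tau(np.array(means), np.array(fracs))
    if not res["computable"]:
        return res
    return {"computable": True, "tau": res["tau"], "p": res["p"],
            "n_clones": len(means)}
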