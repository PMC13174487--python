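"""End-to-end pipeline driver: simulate/score/factorize/niches/clones/assoc.

A single global seed is expanded into per-stage seeds by hashing the stage
name, so adding a stage never perturbs the randomness of earlier ones.
Every output file is recorded with its SHA-256 content hash in a JSON
manifest, making reruns byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .clonotypes import build_clonotypes, stem_content_statistic, clone_program_association
from .models import quadratic_vs_linear, rank_de
from .programs import ConsensusNMF, anchor_similarity, enrich_gene_sets
from .scoring import SignatureScorer, log_normalize
from .simulate import (SimConfig, default_signatures, simulate_cd8_counts,
                       simulate_clonotypes, simulate_tissue, well_separated_config)
from .spatial import (classify_aggregates, compare_transition_ecdf,
                      detect_aggregates, tumor_vs_stroma_localization)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]

_STAGES = ("simulate", "score", "cnmf", "niches", "clones", "assoc")

_KNOWN_KEYS = {
    "seed", "out_dir", "simulate", "matrix_dir", "cell_map_csv", "gmt",
    "clonotype_csv", "n_cells", "score", "cnmf", "niches", "clones", "assoc",
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of (global seed, stage name), < 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    When ``simulate`` is true the input matrices/tables are generated with
    the synthetic module; otherwise the referenced paths must exist.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: bool = True
    matrix_dir: str | None = None
    cell_map_csv: str | None = None
    gmt: str | None = None
    clonotype_csv: str | None = None
    n_cells: int = 2000
    score: dict = field(default_factory=dict)
    cnmf: dict = field(default_factory=lambda: {"k_grid": [3, 5, 8], "n_restarts": 10})
    niches: dict = field(default_factory=dict)
    clones: dict = field(default_factory=dict)
    assoc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for name in ("matrix_dir", "cell_map_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} required and must exist "
                                            f"when simulate is false: {p}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise FileNotFoundError(f"gmt path does not exist: {self.gmt}")
        if self.clonotype_csv is not None and not Path(self.clonotype_csv).exists():
            raise FileNotFoundError(
                f"clonotype_csv path does not exist: {self.clonotype_csv}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(str(path.relative_to(out)))

    current = "simulate"
    try:
        # ---- inputs
        if config.simulate:
            sim_cfg = well_separated_config(
                seed=stage_seed(config.seed, "simulate"), n_cells=config.n_cells)
            counts, truth = simulate_cd8_counts(sim_cfg)
            clono = simulate_clonotypes(sim_cfg, truth)
            tissue_map, tissue_counts, tissue_truth = simulate_tissue(sim_cfg)
            mdir = nio.write_expression(counts, out / "matrix")
            for f in mdir.iterdir():
                record("simulate", f)
            tissue_map.to_csv(out / "cell_map.csv", index=False)
            record("simulate", out / "cell_map.csv")
            clono.to_csv(out / "clonotypes_input.csv", index=False)
            record("simulate", out / "clonotypes_input.csv")
            gene_sets = default_signatures()
        else:
            counts = nio.read_expression(config.matrix_dir)
            tissue_map = nio.read_cell_map(config.cell_map_csv)
            tissue_counts = counts
            clono = (pd.read_csv(config.clonotype_csv)
                     if config.clonotype_csv else None)
            gene_sets = (nio.read_gmt(config.gmt) if config.gmt
                         else default_signatures())

        # ---- score
        current = "score"
        scorer = SignatureScorer(gene_sets,
                                 random_state=stage_seed(config.seed, "score"),
                                 **config.score)
        scores = scorer.fit(counts).score_table(counts)
        scores.reset_index().to_csv(out / "state_scores.csv", index=False)
        nio.validate_schema(scores.reset_index(), "state_scores")
        record("score", out / "state_scores.csv")

        # ---- cnmf
        current = "cnmf"
        norm = log_normalize(counts)
        cn = ConsensusNMF(random_state=stage_seed(config.seed, "cnmf"),
                          **config.cnmf)
        cn.fit(norm)
        cn.loadings_.to_csv(out / "cnmf_loadings.csv")
        cn.usages_.to_csv(out / "cnmf_usages.csv")
        record("cnmf", out / "cnmf_loadings.csv")
        record("cnmf", out / "cnmf_usages.csv")
        model = cn.models_[cn.selected_k_]
        rankings = {}
        for anchor in ("CXCL13", "CXCR5"):
            if anchor in cn.loadings_.columns:
                r = anchor_similarity(model, anchor)
                rankings[anchor] = r
                rdf = r.reset_index()
                rdf.columns = ["gene", "similarity"]
                nio.validate_schema(rdf, "anchor_ranking")
                rdf.to_csv(out / f"ranking_{anchor}.csv", index=False)
                record("cnmf", out / f"ranking_{anchor}.csv")
        enrich_tables = {}
        for anchor, r in rankings.items():
            try:
                e = enrich_gene_sets(r, gene_sets, n_perm=500,
                                     seed=stage_seed(config.seed, f"enrich:{anchor}"))
                nio.validate_schema(e, "enrichment")
                e.to_csv(out / f"enrichment_{anchor}.csv", index=False)
                record("cnmf", out / f"enrichment_{anchor}.csv")
                enrich_tables[anchor] = e
            except ValueError as exc:
                logger.warning("enrichment skipped for %s: %s", anchor, exc)

        # ---- niches
        current = "niches"
        aggs = detect_aggregates(tissue_map, **{k: v for k, v in config.niches.items()
                                                if k in ("eps_um", "min_samples", "min_size")})
        tissue_norm = log_normalize(tissue_counts)
        cd8_map = tissue_map[tissue_map["cell_type"] == "CD8 T"]
        cd8_counts = tissue_counts.loc[tissue_counts.index.intersection(cd8_map["cell_id"])]
        tissue_scores = (SignatureScorer(gene_sets,
                                         random_state=stage_seed(config.seed, "score"))
                         .fit(cd8_counts).score_table(cd8_counts))
        aggs = classify_aggregates(aggs, tissue_map, tissue_norm,
                                   state_labels=tissue_scores["state_label"])
        nio.validate_schema(aggs.table, "aggregates")
        aggs.table.to_csv(out / "aggregates.csv", index=False)
        record("niches", out / "aggregates.csv")
        assign = aggs.cell_assignment.reset_index()
        assign.columns = ["cell_id", "aggregate_id"]
        nio.validate_schema(assign, "aggregate_assignment")
        assign.to_csv(out / "aggregate_assignment.csv", index=False)
        record("niches", out / "aggregate_assignment.csv")
        niche_stats: dict = {}
        loc = tumor_vs_stroma_localization(tissue_map, aggs)
        niche_stats["stromal_fraction_mean"] = (
            float(loc["stromal_fraction"].mean()) if len(loc) else None)
        by_class = {}
        cls_of = aggs.table.set_index("aggregate_id")["class_label"]
        for cid, sub in tissue_scores.join(
                aggs.cell_assignment.rename("aggregate_id"), how="inner").groupby(
                    "aggregate_id"):
            if cid < 0:
                continue
            by_class.setdefault(cls_of.get(cid, "Unclassified"), []).extend(
                sub["transition"].dropna().tolist())
        try:
            ecdf = compare_transition_ecdf(
                by_class, n_boot=200, seed=stage_seed(config.seed, "ecdf"))
            niche_stats["ks"] = {f"{a}|{b}": v for (a, b), v in ecdf["ks"].items()}
        except ValueError as exc:
            logger.info("ECDF comparison skipped: %s", exc)
        (out / "niche_stats.json").write_text(json.dumps(niche_stats, indent=2))
        record("niches", out / "niche_stats.json")

        # ---- clones
        current = "clones"
        if clono is not None:
            clones = build_clonotypes(clono, states=scores["state_label"],
                                      all_cells=counts.index)
            nio.validate_schema(clones.table, "clonotypes")
            clones.table.to_csv(out / "clonotype_table.csv", index=False)
            record("clones", out / "clonotype_table.csv")
            stat = stem_content_statistic(clones)
            assoc = clone_program_association(clones, log_normalize(counts))
            (out / "clone_stats.json").write_text(json.dumps(
                {"stem_content": stat, "cxcl13_association": assoc}, indent=2))
            record("clones", out / "clone_stats.json")

        # ---- assoc
        current = "assoc"
        scored = scores.dropna(subset=["transition"])
        comp = quadratic_vs_linear(scored["transition"],
                                   log_normalize(counts).loc[scored.index, "CXCL13"])
        assoc_out = {"quadratic_vs_linear": {
            "r2_linear": comp.r2_linear, "r2_quadratic": comp.r2_quadratic,
            "lrt_stat": comp.lrt_stat, "p": comp.p}}
        (out / "assoc_stats.json").write_text(json.dumps(assoc_out, indent=2))
        record("assoc", out / "assoc_stats.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
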