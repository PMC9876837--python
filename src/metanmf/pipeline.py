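"""End-to-end orchestration and cross-dataset validation.

``run_pipeline`` executes, in order: differential expression on the primary
dataset → NMF target construction → rank selection by the knee of the RSS
curve → Kim-Park metagene extraction → per-metagene enrichment → interaction
subnetwork and hub ranking → differential expression on the second dataset
→ cross-dataset validation of common DEGs → gene-disease and TF-target
reports.  Every stage writes a TSV into the run directory and records its
parameters and headline numbers in ``manifest.json``.  A single master seed
drives all stochastic stages, so a run is reproducible byte-for-byte.

Cross-dataset validation intersects the two DEG symbol sets, compares fold
change signs, and flags which common genes are hubs or metagene members in
the primary dataset — the "common hub gene" report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deg as deg_mod
from . import enrichment as enrich_mod
from . import networks as net_mod
from . import nmf as nmf_mod
from .io import (
    ExpressionDataset,
    GeneSetCollection,
    read_association,
    read_edge_list,
    read_expression,
    read_gmt,
)
from .metagenes import MetageneSet, kim_park_scores, rank_metagenes, \
    select_metagene_genes

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run.

    ``dataset1``/``dataset2`` are dicts with keys ``matrix_path``,
    ``groups_path`` and (optionally) ``annotation_path``, passed straight
    to :func:`metanmf.io.read_expression`; the same DEG thresholds apply
    to both datasets.
    """

    dataset1: dict
    dataset2: dict | None = None
    gene_sets: str | None = None
    edges: str | None = None
    gene_disease: str | None = None
    tf_targets: str | None = None
    outdir: str = "metanmf_run"

    p_cut: float = 0.05
    lfc_cut: float = 0.5
    use_adjusted: bool = False
    low_expr_quantile: float = 0.2
    moderation: bool = True

    rank_min: int = 3
    rank_max: int = 30
    n_restarts: int = 10
    max_iter: int = 2000
    tol: float = 1e-5

    top_members: int = 15
    min_score: float = 0.9
    network_order: str = "first"
    top_hubs: int = 10
    min_shared: int = 2
    min_gda_score: float = 0.0
    require_hub_in_both: bool = False

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dataset1" not in raw:
            raise ValueError("config must define dataset1")
        return cls(**raw)


@dataclass
class ValidationReport:
    """Common DEGs of two datasets with sign consistency and hub flags."""

    table: pd.DataFrame
    common_genes: list[str] = field(default_factory=list)

    @property
    def hub_overlap(self) -> list[str]:
        if self.table.empty or "in_hubs" not in self.table:
            return []
        return list(self.table.loc[self.table["in_hubs"], "gene"])


def cross_validate(deg1: pd.DataFrame, deg2: pd.DataFrame,
                   hubs1: pd.DataFrame | None = None,
                   metagenes1: MetageneSet | None = None) -> ValidationReport:
    """Intersect two DEG tables and assess each common gene.

    For every gene differentially expressed in both datasets the report
    carries mean expression, logFC and p from each dataset, whether the
    fold-change signs agree, and whether the gene is a hub or a metagene
    member in the primary dataset.
    """
    d1 = deg1.set_index("gene")
    d2 = deg2.set_index("gene")
    common = sorted(set(d1.index) & set(d2.index))
    if not common:
        log.warning("no common DEGs between the two datasets")
        return ValidationReport(table=pd.DataFrame(), common_genes=[])
    hub_set = set(hubs1["gene"]) if hubs1 is not None else set()
    mg_set = set(metagenes1.members["gene"]) if metagenes1 is not None else set()
    table = pd.DataFrame({
        "gene": common,
        "expression_1": d1.loc[common, "mean_expr"].to_numpy(),
        "logFC_1": d1.loc[common, "logFC"].to_numpy(),
        "p_1": d1.loc[common, "p"].to_numpy(),
        "expression_2": d2.loc[common, "mean_expr"].to_numpy(),
        "logFC_2": d2.loc[common, "logFC"].to_numpy(),
        "p_2": d2.loc[common, "p"].to_numpy(),
    })
    table["sign_consistent"] = np.sign(table["logFC_1"]) == np.sign(
        table["logFC_2"])
    table["in_hubs"] = table["gene"].isin(hub_set)
    table["in_metagenes"] = table["gene"].isin(mg_set)
    return ValidationReport(table=table, common_genes=common)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _run_deg(ds: ExpressionDataset, cfg: PipelineConfig):
    filtered = deg_mod.filter_low_expression(ds, cfg.low_expr_quantile)
    collapsed = deg_mod.collapse_probes(filtered)
    table = deg_mod.moderated_t(collapsed, moderation=cfg.moderation)
    degs = deg_mod.select_degs(table, p_cut=cfg.p_cut, lfc_cut=cfg.lfc_cut,
                               use_adjusted=cfg.use_adjusted)
    return collapsed, table, degs


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name and cause.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(cfg), "stages": {}}
    timings: dict[str, float] = {}
    t_stage = time.perf_counter()

    def _tick(name: str) -> None:
        nonlocal t_stage
        timings[name] = round(time.perf_counter() - t_stage, 3)
        log.info("stage %s finished in %.2fs", name, timings[name])
        t_stage = time.perf_counter()

    stage = "load"
    try:
        ds1 = read_expression(**cfg.dataset1)

        _tick("load")
        stage = "deg_dataset1"
        collapsed1, table1, degs1 = _run_deg(ds1, cfg)
        table1.to_csv(out / "deg_full_1.tsv", sep="\t", index=False)
        degs1.to_csv(out / "deg_1.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_genes": len(table1), "n_degs": len(degs1),
            "n_up": int((degs1["direction"] == "up").sum()),
            "n_down": int((degs1["direction"] == "down").sum()),
        }

        _tick("deg_dataset1")
        stage = "rank_selection"
        rank_max = min(cfg.rank_max, len(degs1) - 1,
                       len(collapsed1.matrix.columns))
        if rank_max < cfg.rank_min + 2:
            raise ValueError(
                f"rank grid [{cfg.rank_min}, {rank_max}] too short for knee "
                "selection (need at least 3 points)")
        grid = range(cfg.rank_min, rank_max + 1)
        v, gene_index, shift = nmf_mod.build_target(
            collapsed1, degs1["gene"], max_rank=max(grid))
        curve = nmf_mod.select_rank(
            v, rank_grid=grid, n_restarts=cfg.n_restarts,
            base_seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol)
        pd.DataFrame({
            "rank": curve.ranks,
            "rss": curve.rss_values,
            "chosen": [int(r == curve.chosen_rank) for r in curve.ranks],
        }).to_csv(out / "rank_curve.tsv", sep="\t", index=False)
        fit = curve.factorizations[curve.chosen_rank]
        pd.DataFrame(fit.W, index=gene_index,
                     columns=[f"MG{q:02d}" for q in range(fit.r)]).to_csv(
            out / "W.tsv", sep="\t", index_label="gene")
        pd.DataFrame(fit.H, index=[f"MG{q:02d}" for q in range(fit.r)],
                     columns=collapsed1.matrix.columns).to_csv(
            out / "H.tsv", sep="\t", index_label="metagene")
        manifest["stages"][stage] = {
            "chosen_rank": int(curve.chosen_rank),
            "grid": [int(cfg.rank_min), int(rank_max)],
            "rss_at_chosen": float(fit.rss),
            "target_shift": shift,
        }

        _tick("rank_selection")
        stage = "metagenes"
        scores = kim_park_scores(fit.W)
        mset = select_metagene_genes(fit.W, scores, gene_names=gene_index)
        mset = rank_metagenes(mset, top=cfg.top_members)
        mset.members.to_csv(out / "metagenes.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_members": len(mset.members),
            "n_metagenes": len(mset.activation),
            "metagene_order": [int(q) for q in mset.order],
        }

        _tick("metagenes")
        stage = "enrichment"
        if cfg.gene_sets:
            collection = read_gmt(cfg.gene_sets)
            universe = list(collapsed1.matrix.index)
            frames = []
            for q in mset.metagene_ids:
                res = enrich_mod.enrich(mset.genes_of(q), collection, universe)
                res.insert(0, "metagene", q)
                frames.append(res)
            enr = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame())
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"n_rows": len(enr)}

        _tick("enrichment")
        stage = "network"
        hubs = None
        if cfg.edges:
            edges = read_edge_list(cfg.edges)
            g = net_mod.build_subnetwork(
                list(degs1["gene"]), edges, min_score=cfg.min_score,
                order=cfg.network_order)
            net_mod.centralities(g)
            hubs = net_mod.rank_hubs(g, k=cfg.top_hubs, deg_table=degs1)
            hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
            nodes_df = pd.DataFrame({
                "gene": list(g.nodes),
                "is_seed": [g.nodes[v]["is_seed"] for v in g.nodes],
                "degree": [g.nodes[v]["degree"] for v in g.nodes],
                "betweenness": [g.nodes[v]["betweenness"] for v in g.nodes],
            }).sort_values("gene", kind="mergesort")
            nodes_df.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
            }

        _tick("network")
        stage = "validation"
        report = None
        if cfg.dataset2:
            ds2 = read_expression(**cfg.dataset2)
            _, table2, degs2 = _run_deg(ds2, cfg)
            table2.to_csv(out / "deg_full_2.tsv", sep="\t", index=False)
            degs2.to_csv(out / "deg_2.tsv", sep="\t", index=False)
            report = cross_validate(degs1, degs2, hubs1=hubs, metagenes1=mset)
            report.table.to_csv(out / "validation.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_common": len(report.common_genes),
                "n_sign_consistent": int(report.table["sign_consistent"].sum())
                if not report.table.empty else 0,
                "hub_overlap": report.hub_overlap,
            }

        _tick("validation")
        stage = "associations"
        if report is not None and report.common_genes:
            targets = report.common_genes
        elif hubs is not None:
            targets = list(hubs["gene"])
        else:
            targets = list(degs1["gene"])
        if cfg.gene_disease:
            gda = read_association(cfg.gene_disease)
            gda_report = net_mod.bipartite_report(
                targets, gda, min_score=cfg.min_gda_score,
                min_shared=cfg.min_shared)
            gda_report.to_csv(out / "gene_disease.tsv", sep="\t", index=False)
        if cfg.tf_targets:
            tf = read_association(cfg.tf_targets)
            tf_report = net_mod.bipartite_report(
                targets, tf, min_score=0.0, min_shared=1,
                rank_entities=True)
            tf_report.to_csv(out / "tf_interactions.tsv", sep="\t",
                             index=False)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _tick("associations")
    manifest["timings_s"] = timings
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return out
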