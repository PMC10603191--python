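"""End-to-end orchestration: simulate/ingest -> DE -> GO similarity ->
score combination -> clustering -> enrichment -> prioritization ->
interaction -> ETL, with a manifest of artifact hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    clustering,
    de_selection,
    enrichment,
    go_similarity,
    interaction,
    prioritization,
    score_combination,
    synthetic_data,
    warehouse,
)
from .errors import ConfigurationError, MgtiError, PipelineError

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "de",
    "gosim",
    "combine",
    "cluster",
    "enrich",
    "prioritize",
    "interact",
    "etl",
)


@dataclass
class PipelineConfig:
    """Single source of truth for one pipeline run."""

    out_dir: str = "mgti_out"
    seed: int = 0
    # simulation conditions (ignored when explicit input paths are given)
    simulation: synthetic_data.SimulationConfig | None = None
    expression: str | None = None
    design: str | None = None
    obo: str | None = None
    annotation: str | None = None
    tissue_expr: str | None = None
    evidence_freq: str | None = None
    evidence_scores: str | None = None
    evidence_bp: str | None = None
    evidence_gwas: str | None = None
    evidence_tf: str | None = None
    thresholds: de_selection.ThresholdSet = field(default_factory=de_selection.ThresholdSet)
    namespace: str = "BP"
    k: int = 4
    auto_k: bool = False
    selection_threshold: float = 0.1
    expr_score: str = "neglog10p"
    frequency_mode: str = "multiplicative"
    eq4_normalized: bool = True
    standardize_components: bool = False
    sp_floor: float = 1.000001

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = synthetic_data.SimulationConfig(**sim)
        if thr is not None:
            cfg.thresholds = de_selection.ThresholdSet(**thr)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest (also written to
    ``out_dir/manifest.json``). Any stage failure raises a
    :class:`PipelineError` naming the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def run_stage(stage: str, fn):
        try:
            result = fn()
        except MgtiError as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(stage, str(exc)) from exc
        except Exception as exc:  # noqa: BLE001 - attribute failures to stages
            raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc
        manifest["stages"].append(stage)
        return result

    # --- stage: simulate | ingest -------------------------------------
    state: dict = {}

    def stage_simulate():
        if config.expression is not None:
            required = {
                "design": config.design,
                "obo": config.obo,
                "annotation": config.annotation,
                "tissue_expr": config.tissue_expr,
                "evidence_freq": config.evidence_freq,
                "evidence_scores": config.evidence_scores,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ConfigurationError(f"ingest mode needs paths for: {missing}")
            for name, p in {"expression": config.expression, **required}.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"{name} path does not exist: {p}")
            expr_df = pd.read_csv(config.expression, sep="\t", index_col=0)
            design = pd.read_csv(config.design, sep="\t")
            groups = dict(zip(design["sample_id"].astype(str), design["group"].astype(str)))
            state["expr"] = synthetic_data.ExpressionMatrix(
                gene_ids=[str(g) for g in expr_df.index],
                sample_ids=[str(s) for s in expr_df.columns],
                values=expr_df.to_numpy(dtype=float),
                groups=groups,
            )
            state["truth"] = None
            state["obo_path"] = Path(config.obo)
            state["annot"] = _read_annotation(config.annotation)
            tissue_expr = pd.read_csv(config.tissue_expr, sep="\t", index_col=0)
            freq = pd.read_csv(config.evidence_freq, sep="\t", index_col=0)
            scores = pd.read_csv(config.evidence_scores, sep="\t", index_col=0)
            term_lists = {}
            for cat, p in (
                ("BP", config.evidence_bp),
                ("GWAS", config.evidence_gwas),
                ("TF", config.evidence_tf),
            ):
                if p is None:
                    continue
                df = pd.read_csv(p, sep="\t")
                per_gene: dict[str, list[str]] = {}
                for g, t in zip(df["gene_id"].astype(str), df["term"].astype(str)):
                    per_gene.setdefault(g, []).append(t)
                term_lists[cat] = {g: tuple(sorted(ts)) for g, ts in per_gene.items()}
            state["evidence"] = synthetic_data.EvidenceBundle(
                tissue_expr=tissue_expr,
                categories=list(freq.columns),
                freq_means=freq,
                norm_scores=scores,
                term_lists=term_lists,
            )
            return
        sim = config.simulation or synthetic_data.SimulationConfig(seed=config.seed)
        paths = synthetic_data.write_bundle(out / "inputs", sim)
        expr, truth = synthetic_data.simulate_expression(sim)
        graph = synthetic_data.simulate_ontology(sim)
        state.update(
            expr=expr,
            truth=truth,
            graph=graph,
            annot=synthetic_data.simulate_annotations(sim, graph, truth),
            evidence=synthetic_data.simulate_evidence(sim, truth),
            obo_path=paths["obo"],
            sim=sim,
        )
        for name, p in paths.items():
            artifact(f"inputs/{name}", p)

    run_stage("simulate", stage_simulate)

    def stage_de():
        expr = state["expr"]
        groups = sorted(set(expr.groups.values()))
        results = de_selection.fit_moderated_t(expr, (groups[0], groups[-1]))
        state["de_results"] = results
        funnel = de_selection.apply_funnel(results, config.thresholds, state["annot"])
        state["funnel"] = de_selection.merge_datasets([funnel])
        state["freq"] = de_selection.compute_frequencies(state["funnel"], 1)
        p = out / "de_results.tsv"
        de_selection.results_to_frame(results).to_csv(p, sep="\t", index=False)
        artifact("de_results", p)
        p = out / "funnel.tsv"
        state["funnel"].to_frame().to_csv(p, sep="\t", index=False)
        artifact("funnel", p)

    run_stage("de", stage_de)

    def stage_gosim():
        graph = state.get("graph") or go_similarity.parse_obo(state["obo_path"])
        state["graph"] = graph
        selected = state["funnel"].levels[config.thresholds.p3].selected_gene_ids
        if len(selected) < 3:  # tiny runs: fall back to the loosest cutoff
            selected = state["funnel"].levels[config.thresholds.p1].selected_gene_ids
        simm = go_similarity.gene_sim_matrix(graph, state["annot"], selected, config.namespace)
        state["simm"] = simm
        p = out / "gene_similarity.tsv"
        simm.bma.to_csv(p, sep="\t")
        artifact("gene_similarity", p)

    run_stage("gosim", stage_gosim)

    def stage_combine():
        table = score_combination.combine_scores(
            state["de_results"],
            state["simm"],
            state["freq"],
            expr_score=config.expr_score,
            frequency_mode=config.frequency_mode,
        )
        state["scores"] = table
        truth = state["truth"]
        selected, metrics = score_combination.select_by_threshold(
            table,
            config.selection_threshold,
            truth.de_gene_ids if truth is not None else None,
        )
        state["selected"] = selected
        if metrics:
            logger.info("selection sensitivity=%.3f specificity=%.3f", *metrics.values())
        p = out / "combined_scores.tsv"
        table.table.to_csv(p, sep="\t")
        artifact("combined_scores", p)

    run_stage("combine", stage_combine)

    def stage_cluster():
        feats = state["scores"].table.loc[
            state["selected"], ["final", "m_expr", "m_simsc", "frequency"]
        ]
        k = config.k
        if config.auto_k:
            k = clustering.choose_k(feats, range(2, min(7, len(feats) - 1)), seed=config.seed)
        k = min(k, len(feats))
        assign = clustering.cluster_genes(feats, k, seed=config.seed)
        state["assign"] = assign
        p = out / "clusters.tsv"
        assign.to_frame().to_csv(p, sep="\t", index=False)
        artifact("clusters", p)

    run_stage("cluster", stage_cluster)

    def stage_enrich():
        results = enrichment.enrich_cluster(
            state["assign"],
            state["annot"],
            universe=state["scores"].gene_ids,
            graph=state["graph"],
        )
        names = {t: name for t, (name, _) in state["graph"].terms.items()}
        p = out / "enrichment.tsv"
        enrichment.results_to_frame(results, names).to_csv(p, sep="\t", index=False)
        artifact("enrichment", p)

    run_stage("enrich", stage_enrich)

    def stage_prioritize():
        records = prioritization.prioritize(
            state["evidence"],
            genes=state["selected"],
            standardize=config.standardize_components,
        )
        state["prio"] = records
        fit = prioritization.fit_membership(records, state["assign"], seed=config.seed)
        p = out / "prioritization.tsv"
        prioritization.records_to_frame(records).to_csv(p, sep="\t", index=False)
        artifact("prioritization", p)
        p = out / "tissue_membership.tsv"
        fit.probabilities.rename_axis("gene_id").to_csv(p, sep="\t")
        artifact("tissue_membership", p)

    run_stage("prioritize", stage_prioritize)

    def stage_interact():
        records = interaction.score_all_pairs(
            state["prio"],
            within="cluster",
            cluster=state["assign"],
            sp_floor=config.sp_floor,
            normalized=config.eq4_normalized,
        )
        state["inter"] = records
        p = out / "interactions.tsv"
        interaction.records_to_frame(records).to_csv(p, sep="\t", index=False)
        artifact("interactions", p)

    run_stage("interact", stage_interact)

    def stage_etl():
        evidence = state["evidence"]
        outputs = warehouse.PipelineOutputs(
            prioritization=prioritization.records_to_frame(state["prio"]).rename(
                columns={"rank": "rank"}
            )[["gene_id", "tissue", "score_p", "rank"]],
            interaction=interaction.records_to_frame(state["inter"]),
            clusters=state["assign"].to_frame(),
            evidence_bp=_terms_frame(evidence.term_lists.get("BP", {})),
            evidence_gwas=_terms_frame(evidence.term_lists.get("GWAS", {})),
            evidence_tf=_terms_frame(evidence.term_lists.get("TF", {})),
            thresholds=list(config.thresholds.as_tuple()),
        )
        db = out / "warehouse.sqlite"
        report = warehouse.etl_load(outputs, db)
        manifest["warehouse"] = report

    run_stage("etl", stage_etl)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _read_annotation(path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for g, t in zip(df["gene_id"], df["go_id"]):
        out.setdefault(str(g), []).append(str(t))
    return {g: tuple(sorted(ts)) for g, ts in out.items()}


def _terms_frame(per_gene: dict[str, tuple[str, ...]]) -> pd.DataFrame:
    rows = [(g, t) for g, ts in per_gene.items() for t in ts]
    return pd.DataFrame(rows, columns=["gene_id", "term"])
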