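"""Synthetic inputs with known ground truth for every pipeline stage.

Emulated inputs:

* a normalized log2-intensity expression matrix with a planted set of
  differentially expressed genes (i.i.d. Gaussian noise, one linear model
  per gene — the assumption the moderated-t stage makes);
* a Gene Ontology-like DAG per namespace, grown by preferential attachment
  with an 80/20 is_a / part_of edge mix;
* gene -> term annotations correlated within ground-truth clusters (genes
  of a cluster draw from a shared term pool) so GO-similarity structure
  exists by construction;
* evidence tables: per-tissue mean expression (elevated in each gene's
  tissue of origin) and BP / GWAS / TF term lists with per-category
  occurrence frequencies.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` generator per product, so every output is reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .go_similarity import GOGraph

DEFAULT_TISSUES = ("kidney", "urine", "immune_system", "blood", "embryonic_dev")
EVIDENCE_CATEGORIES = ("BP", "GWAS", "TF")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    n_genes: int = 2000
    n_samples_per_group: int = 10
    n_groups: int = 2
    frac_de: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_go_terms: int = 150
    dag_depth: int = 5
    annotations_per_gene: int = 5
    n_tissues: int = 5
    n_clusters: int = 4
    annotation_overlap: float = 0.6
    part_of_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_groups": self.n_groups,
            "n_go_terms": self.n_go_terms,
            "dag_depth": self.dag_depth,
            "annotations_per_gene": self.annotations_per_gene,
            "n_tissues": self.n_tissues,
            "n_clusters": self.n_clusters,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError(f"frac_de must lie in [0, 1], got {self.frac_de}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be positive, got {self.noise_sd}")
        if not 0.0 <= self.annotation_overlap <= 1.0:
            raise ConfigurationError("annotation_overlap must lie in [0, 1]")
        if self.n_go_terms < self.dag_depth:
            raise ConfigurationError("n_go_terms must be >= dag_depth")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, named random stream derived from the master seed."""
        # zlib.crc32 is stable across processes, unlike builtin hash()
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What was planted: DE genes, annotation clusters, tissue of origin."""

    de_gene_ids: set[str]
    cluster_labels: dict[str, int]
    tissue_of_origin: dict[str, str] = field(default_factory=dict)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities with a sample -> group design."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ConfigurationError("expression values must be finite")
        counts = pd.Series([self.groups[s] for s in self.sample_ids]).value_counts()
        if (counts < 2).any():
            raise ConfigurationError("every condition needs >= 2 samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def design(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": [self.groups[s] for s in self.sample_ids]}
        )


@dataclass
class EvidenceBundle:
    """Evidence tables feeding prioritization and enrichment.

    ``tissue_expr``: genes x tissues mean normalized expression (mu0).
    ``freq_means``: genes x categories mean occurrence frequency (mu_j).
    ``norm_scores``: genes x categories normalized evidence value (X_j).
    ``term_lists``: category -> gene -> tuple of term labels.
    """

    tissue_expr: pd.DataFrame
    categories: list[str]
    freq_means: pd.DataFrame
    norm_scores: pd.DataFrame
    term_lists: dict[str, dict[str, tuple[str, ...]]]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{str(i).zfill(width)}" for i in range(1, n + 1)]


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a seeded expression matrix with ``frac_de * n_genes`` planted
    DE genes whose between-group mean difference equals ``effect_size``.

    With more than two groups the effect is planted on the last group
    against the first; intermediate groups stay at baseline.
    """
    rng = cfg.rng("expression")
    genes = _gene_ids(cfg.n_genes)
    group_names = [f"group{i + 1}" for i in range(cfg.n_groups)]
    samples, groups = [], {}
    for gname in group_names:
        for j in range(cfg.n_samples_per_group):
            sid = f"{gname}_s{j + 1}"
            samples.append(sid)
            groups[sid] = gname

    n_de = int(round(cfg.frac_de * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)

    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples)))
    values += baseline[:, None]
    last_group = np.array([groups[s] == group_names[-1] for s in samples])
    values[np.ix_(de_idx, np.where(last_group)[0])] += cfg.effect_size

    expr = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values, groups=groups)

    cl_rng = cfg.rng("clusters")
    cluster_labels = {
        g: int(c) for g, c in zip(genes, cl_rng.integers(1, cfg.n_clusters + 1, cfg.n_genes))
    }
    tissues = list(DEFAULT_TISSUES[: cfg.n_tissues]) + [
        f"tissue_{i + 1}" for i in range(len(DEFAULT_TISSUES), cfg.n_tissues)
    ]
    tissue_of_origin = {
        g: tissues[t] for g, t in zip(genes, cl_rng.integers(0, cfg.n_tissues, cfg.n_genes))
    }
    truth = GroundTruth(
        de_gene_ids={genes[i] for i in de_idx},
        cluster_labels=cluster_labels,
        tissue_of_origin=tissue_of_origin,
    )
    return expr, truth


def simulate_ontology(cfg: SimulationConfig) -> GOGraph:
    """Grow a rooted DAG per namespace by preferential attachment.

    Terms are split ~60/20/20 over BP/MF/CC. Each non-root term attaches
    to one or two already-existing terms (probability proportional to
    1 + degree, depth capped at ``dag_depth``), so acyclicity and
    root-reachability hold by construction. Edges are ``is_a`` with
    probability ``1 - part_of_fraction``, else ``part_of``.
    """
    rng = cfg.rng("ontology")
    n_bp = max(cfg.dag_depth, int(round(0.6 * cfg.n_go_terms)))
    n_mf = max(1, int(round(0.2 * cfg.n_go_terms)))
    n_cc = max(1, cfg.n_go_terms - n_bp - n_mf)

    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    counter = 0
    for ns, size in (
        ("biological_process", n_bp),
        ("molecular_function", n_mf),
        ("cellular_component", n_cc),
    ):
        existing: list[str] = []
        depth: dict[str, int] = {}
        degree: dict[str, int] = {}
        for i in range(size):
            counter += 1
            tid = f"GO:{counter:07d}"
            terms[tid] = (f"{ns} term {i}" if i else f"{ns} root", ns)
            parents[tid] = []
            if i == 0:
                depth[tid] = 0
            else:
                eligible = [t for t in existing if depth[t] < cfg.dag_depth]
                weights = np.array([1.0 + degree.get(t, 0) for t in eligible])
                weights /= weights.sum()
                n_par = 1 if len(eligible) == 1 else int(rng.integers(1, 3))
                chosen = rng.choice(len(eligible), size=min(n_par, len(eligible)), replace=False)
                for ci in chosen:
                    parent = eligible[int(ci)]
                    etype = "part_of" if rng.random() < cfg.part_of_fraction else "is_a"
                    parents[tid].append((parent, etype))
                    degree[parent] = degree.get(parent, 0) + 1
                depth[tid] = max(depth[parents[tid][0][0]], *(depth[p] for p, _ in parents[tid])) + 1
            existing.append(tid)
    return GOGraph(terms=terms, parents=parents)


def simulate_annotations(
    cfg: SimulationConfig, graph: GOGraph, truth: GroundTruth
) -> dict[str, tuple[str, ...]]:
    """Gene -> BP term annotations, correlated within truth clusters.

    Each cluster owns a shared pool of BP terms; a gene draws each of its
    ``annotations_per_gene`` terms from its cluster pool with probability
    ``annotation_overlap`` and from the whole BP namespace otherwise.
    """
    rng = cfg.rng("annotations")
    bp_terms = np.array(graph.terms_in_namespace("biological_process"))
    pool_size = max(cfg.annotations_per_gene, math.ceil(len(bp_terms) / (2 * cfg.n_clusters)))
    pools = {
        c: rng.choice(bp_terms, size=min(pool_size, len(bp_terms)), replace=False)
        for c in sorted(set(truth.cluster_labels.values()))
    }
    annot: dict[str, tuple[str, ...]] = {}
    for gene, cluster in truth.cluster_labels.items():
        chosen: set[str] = set()
        while len(chosen) < min(cfg.annotations_per_gene, len(bp_terms)):
            source = pools[cluster] if rng.random() < cfg.annotation_overlap else bp_terms
            chosen.add(str(rng.choice(source)))
        annot[gene] = tuple(sorted(chosen))
    return annot


def simulate_evidence(cfg: SimulationConfig, truth: GroundTruth) -> EvidenceBundle:
    """Evidence tables consistent with the planted tissue/cluster structure.

    Tissue means are drawn uniform on [2, 5) with a +6 elevation in each
    gene's tissue of origin (non-negative, and > 1 so downstream log-scale
    scores are well-defined). Category term lists reuse the cluster-pool
    construction; frequencies are per-term occurrence fractions.
    """
    rng = cfg.rng("evidence")
    genes = sorted(truth.cluster_labels)
    tissues = list(DEFAULT_TISSUES[: cfg.n_tissues]) + [
        f"tissue_{i + 1}" for i in range(len(DEFAULT_TISSUES), cfg.n_tissues)
    ]
    expr = rng.uniform(2.0, 5.0, size=(len(genes), len(tissues)))
    tissue_expr = pd.DataFrame(expr, index=genes, columns=tissues)
    for g in genes:
        origin = truth.tissue_of_origin.get(g)
        if origin in tissue_expr.columns:
            tissue_expr.loc[g, origin] += 6.0

    categories = list(EVIDENCE_CATEGORIES)
    clusters = sorted(set(truth.cluster_labels.values()))
    term_lists: dict[str, dict[str, tuple[str, ...]]] = {}
    freq = pd.DataFrame(0.0, index=genes, columns=categories)
    for cat in categories:
        vocab = np.array([f"{cat.lower()}_term_{i}" for i in range(20 * len(clusters))])
        pools = {c: rng.choice(vocab, size=12, replace=False) for c in clusters}
        per_gene: dict[str, tuple[str, ...]] = {}
        for g in genes:
            pool = pools[truth.cluster_labels[g]]
            k = int(rng.integers(2, 7))
            chosen: set[str] = set()
            while len(chosen) < k:
                src = pool if rng.random() < cfg.annotation_overlap else vocab
                chosen.add(str(rng.choice(src)))
            per_gene[g] = tuple(sorted(chosen))
        term_lists[cat] = per_gene
        counts = pd.Series([t for ts in per_gene.values() for t in ts]).value_counts()
        term_freq = counts / len(genes)
        freq[cat] = [float(np.mean([term_freq[t] for t in per_gene[g]])) for g in genes]

    norm = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(len(genes), len(categories))), index=genes, columns=categories
    )
    return EvidenceBundle(
        tissue_expr=tissue_expr,
        categories=categories,
        freq_means=freq,
        norm_scores=norm,
        term_lists=term_lists,
    )


def write_bundle(out_dir, cfg: SimulationConfig) -> dict[str, Path]:
    """Simulate everything and write the pipeline's on-disk inputs.

    Returns a name -> path map (expression, design, obo, annotation,
    tissue_expr, evidence per category, truth tables).
    """
    from .go_similarity import write_obo

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_expression(cfg)
    graph = simulate_ontology(cfg)
    annot = simulate_annotations(cfg, graph, truth)
    evidence = simulate_evidence(cfg, truth)

    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, **kw) -> None:
        paths[name] = out / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", **kw)

    save("expression", expr.to_frame().rename_axis("gene_id"))
    save("design", expr.design(), index=False)
    paths["obo"] = out / "ontology.obo"
    write_obo(graph, paths["obo"])
    annot_rows = [(g, t) for g, ts in annot.items() for t in ts]
    save("annotation", pd.DataFrame(annot_rows, columns=["gene_id", "go_id"]), index=False)
    save("tissue_expr", evidence.tissue_expr.rename_axis("gene_id"))
    save("evidence_freq", evidence.freq_means.rename_axis("gene_id"))
    save("evidence_scores", evidence.norm_scores.rename_axis("gene_id"))
    for cat, per_gene in evidence.term_lists.items():
        rows = [(g, t) for g, ts in per_gene.items() for t in ts]
        save(f"evidence_{cat.lower()}", pd.DataFrame(rows, columns=["gene_id", "term"]), index=False)
    save(
        "truth",
        pd.DataFrame(
            {
                "gene_id": sorted(truth.cluster_labels),
                "is_de": [int(g in truth.de_gene_ids) for g in sorted(truth.cluster_labels)],
                "cluster": [truth.cluster_labels[g] for g in sorted(truth.cluster_labels)],
                "tissue": [truth.tissue_of_origin[g] for g in sorted(truth.cluster_labels)],
            }
        ),
        index=False,
    )
    return paths
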