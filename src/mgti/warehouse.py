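"""Star-schema persistence of pipeline results in an embedded SQLite file.

A central fact table holds prioritization rows (gene x tissue, score_p)
and interaction rows (gene pair, score_inter + regulation band), keyed by
surrogate integers into gene / tissue / cluster / threshold / evidence
dimensions. Loads are idempotent: dimensions upsert on their natural
keys, facts insert-or-ignore on a natural-key unique index, and any
constraint violation rolls the whole transaction back.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DomainError
from .interaction import classify_band

logger = logging.getLogger(__name__)


@dataclass
class PipelineOutputs:
    """The result tables the warehouse persists.

    ``prioritization``: gene_id, tissue, score_p, rank (cluster optional)
    ``interaction``: gene1, gene2, sp1, sp2, score, band
    ``clusters``: gene_id, cluster
    ``evidence_bp`` / ``evidence_gwas`` / ``evidence_tf``: gene_id, term
    ``thresholds``: list of p-value cutoffs
    """

    prioritization: pd.DataFrame = field(default_factory=pd.DataFrame)
    interaction: pd.DataFrame = field(default_factory=pd.DataFrame)
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    evidence_bp: pd.DataFrame = field(default_factory=pd.DataFrame)
    evidence_gwas: pd.DataFrame = field(default_factory=pd.DataFrame)
    evidence_tf: pd.DataFrame = field(default_factory=pd.DataFrame)
    thresholds: list[float] = field(default_factory=list)


def schema_sql() -> str:
    return resources.files("mgti").joinpath("schema.sql").read_text()


def _connect(db_path) -> sqlite3.Connection:
    conn = sqlite3.connect(str(db_path))
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def init_db(db_path) -> None:
    with _connect(db_path) as conn:
        conn.executescript(schema_sql())


def _upsert_dim(conn, table: str, key_col: str, nat_col: str, values) -> dict:
    for v in values:
        conn.execute(
            f"INSERT OR IGNORE INTO {table} ({nat_col}) VALUES (?)", (v,)
        )
    rows = conn.execute(f"SELECT {nat_col}, {key_col} FROM {table}").fetchall()
    return dict(rows)


def etl_load(outputs: PipelineOutputs, db_path) -> dict[str, int]:
    """Load all result tables; returns per-table row counts.

    Dimensions load first, facts second; the load is one transaction and
    rolls back completely on any integrity violation.
    """
    init_db(db_path)
    conn = _connect(db_path)
    try:
        with conn:  # single transaction
            genes: set[str] = set()
            if not outputs.prioritization.empty:
                genes |= set(outputs.prioritization["gene_id"])
            if not outputs.interaction.empty:
                genes |= set(outputs.interaction["gene1"]) | set(outputs.interaction["gene2"])
            if not outputs.clusters.empty:
                genes |= set(outputs.clusters["gene_id"])
            gene_keys = _upsert_dim(conn, "dim_gene", "gene_key", "gene_id", sorted(genes))

            tissues = (
                sorted(set(outputs.prioritization["tissue"]))
                if not outputs.prioritization.empty
                else []
            )
            tissue_keys = _upsert_dim(conn, "dim_tissue", "tissue_key", "name", tissues)

            cluster_keys: dict[int, int] = {}
            cluster_of: dict[str, int] = {}
            if not outputs.clusters.empty:
                cluster_of = dict(
                    zip(outputs.clusters["gene_id"], outputs.clusters["cluster"].astype(int))
                )
                cluster_keys = _upsert_dim(
                    conn, "dim_cluster", "cluster_key", "label", sorted(set(cluster_of.values()))
                )
            _upsert_dim(conn, "dim_threshold", "threshold_key", "p_value", outputs.thresholds)

            for table, nat, bridge, fk, df in (
                ("dim_bp_term", "term_id", "bridge_gene_bp", "term_key", outputs.evidence_bp),
                ("dim_gwas_trait", "trait", "bridge_gene_gwas", "trait_key", outputs.evidence_gwas),
                ("dim_tf", "name", "bridge_gene_tf", "tf_key", outputs.evidence_tf),
            ):
                if df.empty:
                    continue
                keys = _upsert_dim(conn, table, fk, nat, sorted(set(df["term"])))
                for _, row in df.iterrows():
                    gk = gene_keys.get(row["gene_id"])
                    if gk is None:
                        continue  # evidence for genes outside the scored cohort
                    conn.execute(
                        f"INSERT OR IGNORE INTO {bridge} (gene_key, {fk}) VALUES (?, ?)",
                        (gk, keys[row["term"]]),
                    )

            for _, row in outputs.prioritization.iterrows():
                conn.execute(
                    """INSERT OR IGNORE INTO fact_prioritization_interaction
                       (kind, gene1_key, tissue_key, cluster_key, score_p, rank_in_tissue)
                       VALUES ('prioritization', ?, ?, ?, ?, ?)""",
                    (
                        gene_keys[row["gene_id"]],
                        tissue_keys[row["tissue"]],
                        cluster_keys.get(cluster_of.get(row["gene_id"])),
                        float(row["score_p"]),
                        int(row["rank"]) if "rank" in row and pd.notna(row["rank"]) else None,
                    ),
                )
            for _, row in outputs.interaction.iterrows():
                g1, g2 = sorted((row["gene1"], row["gene2"]))
                conn.execute(
                    """INSERT OR IGNORE INTO fact_prioritization_interaction
                       (kind, gene1_key, gene2_key, cluster_key, score_p, score_p2,
                        score_inter, band)
                       VALUES ('interaction', ?, ?, ?, ?, ?, ?, ?)""",
                    (
                        gene_keys[g1],
                        gene_keys[g2],
                        cluster_keys.get(cluster_of.get(g1)),
                        float(row["sp1"]),
                        float(row["sp2"]),
                        float(row["score"]),
                        str(row["band"]),
                    ),
                )
    except sqlite3.IntegrityError as exc:
        raise DomainError(f"ETL rolled back on integrity violation: {exc}") from exc
    report = {}
    for table in (
        "dim_gene",
        "dim_tissue",
        "dim_cluster",
        "dim_threshold",
        "dim_bp_term",
        "dim_gwas_trait",
        "dim_tf",
        "fact_prioritization_interaction",
    ):
        report[table] = conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
    conn.close()
    return report


def query_top(db_path, tissue: str, n: int) -> pd.DataFrame:
    """Top-n genes by prioritization score for one tissue."""
    conn = _connect(db_path)
    df = pd.read_sql_query(
        """SELECT g.gene_id, t.name AS tissue, f.score_p, f.rank_in_tissue,
                  c.label AS cluster
           FROM fact_prioritization_interaction f
           JOIN dim_gene g ON g.gene_key = f.gene1_key
           JOIN dim_tissue t ON t.tissue_key = f.tissue_key
           LEFT JOIN dim_cluster c ON c.cluster_key = f.cluster_key
           WHERE f.kind = 'prioritization' AND t.name = ?
           ORDER BY f.score_p DESC, g.gene_id ASC
           LIMIT ?""",
        conn,
        params=(tissue, int(n)),
    )
    conn.close()
    if df.empty:
        logger.warning("no prioritization rows for tissue %r", tissue)
    return df


def export_tables(db_path) -> PipelineOutputs:
    """Read the warehouse back into result tables (round-trip check)."""
    conn = _connect(db_path)
    prio = pd.read_sql_query(
        """SELECT g.gene_id, t.name AS tissue, f.score_p, f.rank_in_tissue AS rank
           FROM fact_prioritization_interaction f
           JOIN dim_gene g ON g.gene_key = f.gene1_key
           JOIN dim_tissue t ON t.tissue_key = f.tissue_key
           WHERE f.kind = 'prioritization'""",
        conn,
    )
    inter = pd.read_sql_query(
        """SELECT g1.gene_id AS gene1, g2.gene_id AS gene2, f.score_p AS sp1,
                  f.score_p2 AS sp2, f.score_inter AS score, f.band
           FROM fact_prioritization_interaction f
           JOIN dim_gene g1 ON g1.gene_key = f.gene1_key
           JOIN dim_gene g2 ON g2.gene_key = f.gene2_key
           WHERE f.kind = 'interaction'""",
        conn,
    )
    clusters = pd.read_sql_query(
        """SELECT DISTINCT g.gene_id, c.label AS cluster
           FROM fact_prioritization_interaction f
           JOIN dim_gene g ON g.gene_key = f.gene1_key
           JOIN dim_cluster c ON c.cluster_key = f.cluster_key""",
        conn,
    )
    conn.close()
    return PipelineOutputs(prioritization=prio, interaction=inter, clusters=clusters)


def validate_integrity(db_path) -> dict[str, tuple[bool, str]]:
    """Referential-integrity, uniqueness and band/score consistency checks."""
    if not Path(db_path).exists():
        raise DomainError(f"database {db_path} does not exist")
    conn = _connect(db_path)
    report: dict[str, tuple[bool, str]] = {}

    orphans = conn.execute("PRAGMA foreign_key_check").fetchall()
    report["foreign_keys"] = (
        (True, "all foreign keys resolve")
        if not orphans
        else (False, f"orphaned rows: {orphans[:5]}")
    )

    dup_msgs = []
    for table, nat in (
        ("dim_gene", "gene_id"),
        ("dim_tissue", "name"),
        ("dim_cluster", "label"),
        ("dim_threshold", "p_value"),
        ("dim_bp_term", "term_id"),
        ("dim_gwas_trait", "trait"),
        ("dim_tf", "name"),
    ):
        dups = conn.execute(
            f"SELECT {nat}, COUNT(*) c FROM {table} GROUP BY {nat} HAVING c > 1"
        ).fetchall()
        if dups:
            dup_msgs.append(f"{table}: {dups[:3]}")
    report["unique_keys"] = (
        (True, "all natural keys unique") if not dup_msgs else (False, "; ".join(dup_msgs))
    )

    mismatches = []
    for fact_key, score, band in conn.execute(
        """SELECT fact_key, score_inter, band FROM fact_prioritization_interaction
           WHERE kind = 'interaction'"""
    ):
        try:
            expected = classify_band(score)
        except DomainError:
            expected = "out_of_range"
        if band != expected:
            mismatches.append((fact_key, score, band, expected))
    report["band_consistency"] = (
        (True, "all bands consistent with scores")
        if not mismatches
        else (False, f"band/score mismatches: {mismatches[:5]}")
    )
    conn.close()
    return report
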