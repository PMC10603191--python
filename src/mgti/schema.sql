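-- Star schema: one fact table of prioritization / interaction scores,
-- surrogate-keyed dimension tables around it. Schema version 1.
PRAGMA foreign_keys = ON;

CREATE TABLE IF NOT EXISTS dim_gene (
    gene_key   INTEGER PRIMARY KEY,
    gene_id    TEXT NOT NULL UNIQUE,
    symbol     TEXT
);

CREATE TABLE IF NOT EXISTS dim_tissue (
    tissue_key INTEGER PRIMARY KEY,
    name       TEXT NOT NULL UNIQUE
);

CREATE TABLE IF NOT EXISTS dim_cluster (
    cluster_key INTEGER PRIMARY KEY,
    label       INTEGER NOT NULL UNIQUE
);

CREATE TABLE IF NOT EXISTS dim_threshold (
    threshold_key INTEGER PRIMARY KEY,
    p_value       REAL NOT NULL UNIQUE
);

CREATE TABLE IF NOT EXISTS dim_bp_term (
    term_key INTEGER PRIMARY KEY,
    term_id  TEXT NOT NULL UNIQUE,
    name     TEXT
);

CREATE TABLE IF NOT EXISTS dim_gwas_trait (
    trait_key INTEGER PRIMARY KEY,
    trait     TEXT NOT NULL UNIQUE
);

CREATE TABLE IF NOT EXISTS dim_tf (
    tf_key INTEGER PRIMARY KEY,
    name   TEXT NOT NULL UNIQUE
);

-- Bridge tables: many-to-many gene <-> evidence dimensions.
CREATE TABLE IF NOT EXISTS bridge_gene_bp (
    gene_key INTEGER NOT NULL REFERENCES dim_gene(gene_key),
    term_key INTEGER NOT NULL REFERENCES dim_bp_term(term_key),
    UNIQUE (gene_key, term_key)
);

CREATE TABLE IF NOT EXISTS bridge_gene_gwas (
    gene_key  INTEGER NOT NULL REFERENCES dim_gene(gene_key),
    trait_key INTEGER NOT NULL REFERENCES dim_gwas_trait(trait_key),
    UNIQUE (gene_key, trait_key)
);

CREATE TABLE IF NOT EXISTS bridge_gene_tf (
    gene_key INTEGER NOT NULL REFERENCES dim_gene(gene_key),
    tf_key   INTEGER NOT NULL REFERENCES dim_tf(tf_key),
    UNIQUE (gene_key, tf_key)
);

-- Fact rows carry either a prioritization score (gene2_key NULL) or an
-- interaction score for a gene pair (tissue_key NULL).
CREATE TABLE IF NOT EXISTS fact_prioritization_interaction (
    fact_key      INTEGER PRIMARY KEY,
    kind          TEXT NOT NULL CHECK (kind IN ('prioritization', 'interaction')),
    gene1_key     INTEGER NOT NULL REFERENCES dim_gene(gene_key),
    gene2_key     INTEGER REFERENCES dim_gene(gene_key),
    tissue_key    INTEGER REFERENCES dim_tissue(tissue_key),
    cluster_key   INTEGER REFERENCES dim_cluster(cluster_key),
    threshold_key INTEGER REFERENCES dim_threshold(threshold_key),
    score_p       REAL,
    score_p2      REAL,
    score_inter   REAL,
    band          TEXT,
    rank_in_tissue INTEGER
);

CREATE UNIQUE INDEX IF NOT EXISTS ux_fact_natural ON fact_prioritization_interaction (
    kind, gene1_key, ifnull(gene2_key, -1), ifnull(tissue_key, -1)
);
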