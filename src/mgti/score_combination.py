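"""Fuse expression and GO-similarity evidence into one selection score.

The combined score for a gene g is linear in the two evidence channels,

    CombSc(g) = n_expr * M_expr(g) + n_sel * M_simsc(g)

where n_expr counts the expression-selected genes, n_sel counts the
similarity-scored genes, M_expr(g) is the min-max-normalized -log10
p-value (|moderated t| available as an alternative) and M_simsc(g) is the
row mean of the pairwise similarity statistic. The combined score is
min-max normalized to [0, 1] and multiplied by the gene's frequency of
occurrence across input datasets to give the final association score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PipelineError
from .de_selection import DEResult
from .go_similarity import GeneSimMatrix, m_simsc_matrix


@dataclass
class CombinedScoreTable:
    """Per-gene fused scores; ``table`` is indexed by gene id and carries
    columns m_expr, m_simsc, frequency, combined, final, rank."""

    table: pd.DataFrame
    n_expr: int
    n_sel: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.ones_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def combine_scores(
    de: Sequence[DEResult],
    simm: GeneSimMatrix,
    freq: Mapping[str, float],
    expr_score: str = "neglog10p",
    frequency_mode: str = "multiplicative",
    n_expr: int | None = None,
    n_sel: int | None = None,
) -> CombinedScoreTable:
    """Build the combined score table on the DE x similarity intersection.

    Genes must appear in both channels; a gene missing a frequency entry
    defaults to 1.0 (single-source run). ``n_expr`` / ``n_sel`` override
    the cohort-size weights (e.g. for a merged multi-dataset cohort);
    they default to the sizes of the two input gene sets.
    """
    if expr_score not in ("neglog10p", "abs_t"):
        raise ConfigurationError(f"unknown expr_score {expr_score!r}")
    if frequency_mode not in ("multiplicative", "additive"):
        raise ConfigurationError(f"unknown frequency_mode {frequency_mode!r}")

    de_by_gene = {r.gene_id: r for r in de}
    sim_genes = set(simm.gene_ids)
    common = sorted(de_by_gene.keys() & sim_genes)
    if not common:
        raise PipelineError(
            "score_combination",
            f"no overlap between {len(de_by_gene)} DE-selected genes and "
            f"{len(sim_genes)} similarity-scored genes",
        )

    if expr_score == "neglog10p":
        raw_expr = np.array(
            [-np.log10(max(de_by_gene[g].p_value, 1e-300)) for g in common]
        )
    else:
        raw_expr = np.array([abs(de_by_gene[g].t_mod) for g in common])
    m_expr = _minmax(raw_expr)

    pairwise = m_simsc_matrix(simm)
    m_sim = pairwise.loc[common, :].mean(axis=1, skipna=True).to_numpy()

    n_expr = len(de_by_gene) if n_expr is None else int(n_expr)
    n_sel = len(sim_genes) if n_sel is None else int(n_sel)
    combined = n_expr * m_expr + n_sel * m_sim
    frequency = np.array([float(freq.get(g, 1.0)) for g in common])
    norm = _minmax(combined)
    if frequency_mode == "multiplicative":
        final = norm * frequency
    else:
        final = _minmax(norm + frequency)

    table = pd.DataFrame(
        {
            "m_expr": m_expr,
            "m_simsc": m_sim,
            "frequency": frequency,
            "combined": combined,
            "final": final,
        },
        index=pd.Index(common, name="gene_id"),
    )
    # rank by final descending, ties broken lexicographically by gene id
    table = table.sort_values(["final", "gene_id"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return CombinedScoreTable(table=table, n_expr=n_expr, n_sel=n_sel)


def select_by_threshold(
    table: CombinedScoreTable,
    threshold: float,
    truth_de: Iterable[str] | None = None,
) -> tuple[list[str], dict[str, float] | None]:
    """Genes whose final score reaches ``threshold``; optional metrics.

    When the planted DE gene set is supplied, sensitivity and specificity
    of the selection against it (within the scored cohort) are reported.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must lie in [0, 1], got {threshold}")
    if table.table.empty:
        raise ConfigurationError("empty combined-score table")
    selected = sorted(table.table.index[table.table["final"] >= threshold])
    metrics = None
    if truth_de is not None:
        truth = set(truth_de)
        cohort = set(table.gene_ids)
        pos = truth & cohort
        neg = cohort - truth
        sel = set(selected)
        tp = len(sel & pos)
        tn = len(neg - sel)
        metrics = {
            "sensitivity": tp / len(pos) if pos else float("nan"),
            "specificity": tn / len(neg) if neg else float("nan"),
        }
    return selected, metrics
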