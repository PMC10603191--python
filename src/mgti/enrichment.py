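"""Hypergeometric over-representation of annotation terms per gene cluster.

For a cluster of n genes drawn from a universe of N genes of which K are
annotated to a term, the enrichment p-value is the upper tail
P(X >= x) of the hypergeometric(N, K, n) distribution, where x is the
observed overlap. Gene -> GO annotations are propagated to all ancestor
terms before counting (the true-path rule). Benjamini-Hochberg q-values
are computed within each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .clustering import ClusterAssignment
from .go_similarity import GOGraph


@dataclass
class EnrichmentResult:
    term_id: str
    cluster: int
    x: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    significant: bool


def hypergeom_test(x: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= x)."""
    if not (0 <= x <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise DomainError(f"inconsistent counts x={x}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(x - 1, N, K, n))


def propagate_annotations(
    annot: Mapping[str, Iterable[str]], graph: GOGraph
) -> dict[str, set[str]]:
    """Extend each gene's annotation set with all ancestors of its terms."""
    out: dict[str, set[str]] = {}
    cache: dict[str, set[str]] = {}
    for gene, terms in annot.items():
        full: set[str] = set()
        for t in terms:
            if t not in graph.terms:
                continue
            if t not in cache:
                cache[t] = graph.ancestors(t) | {t}
            full |= cache[t]
        out[gene] = full
    return out


def enrich_cluster(
    assign: ClusterAssignment,
    annot: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    graph: GOGraph | None = None,
    pooled_correction: bool = False,
) -> list[EnrichmentResult]:
    """Per-(cluster, term) over-representation tests with BH correction.

    The universe is the background gene set; clusters must be subsets of
    it. When an ontology graph is given, annotations are ancestor-
    propagated first.
    """
    universe = set(universe)
    if not universe:
        raise DomainError("empty universe")
    missing = set(assign.labels) - universe
    if missing:
        raise DomainError(f"clustered genes outside the universe: {sorted(missing)[:5]}")

    ann = propagate_annotations(annot, graph) if graph is not None else {
        g: set(ts) for g, ts in annot.items()
    }
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in ann.get(g, ()):
            term_genes.setdefault(t, set()).add(g)

    N = len(universe)
    results: list[EnrichmentResult] = []
    clusters = sorted(set(assign.labels.values()))
    for c in clusters:
        members = {g for g, lab in assign.labels.items() if lab == c}
        n = len(members)
        rows = []
        for term, genes_with_term in sorted(term_genes.items()):
            K = len(genes_with_term)
            x = len(members & genes_with_term)
            rows.append((term, x, K, hypergeom_test(x, n, K, N)))
        if not rows:
            continue
        pvals = [r[3] for r in rows]
        if not pooled_correction:
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for (term, x, K, p), q in zip(rows, qvals):
                results.append(
                    EnrichmentResult(term, c, x, n, K, N, p, float(q), bool(q <= alpha))
                )
        else:
            results.extend(
                EnrichmentResult(term, c, x, n, K, N, p, float("nan"), False)
                for term, x, K, p in rows
            )
    if pooled_correction and results:
        _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
            r.significant = bool(q <= alpha)
    return results


def results_to_frame(
    results: list[EnrichmentResult], term_names: Mapping[str, str] | None = None
) -> pd.DataFrame:
    term_names = term_names or {}
    return pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "term_id": [r.term_id for r in results],
            "term_name": [term_names.get(r.term_id, "") for r in results],
            "x": [r.x for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
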