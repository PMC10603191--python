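"""Gene Ontology semantic similarity: Wang S-values, term similarity, BMA
gene similarity and the pairwise matrix-similarity statistic.

The Wang measure represents a GO term by the weighted contributions
(S-values) of its ancestor closure: the anchor term contributes 1 and each
ancestor contributes the best product of edge weights along a path back to
the anchor (``is_a`` edges weigh 0.8, ``part_of`` edges 0.6, the GOSemSim
defaults). Two terms are compared by the overlap of their S-value maps, and
two genes by the best-match average (BMA) of the term-term similarity
matrix between their annotation sets.

On top of the BMA gene-by-gene matrix, :func:`m_simsc` computes a pairwise
statistic combining the two genes' similarity-row means and spreads:

    M_simsc(g1, g2) = 1/2 * (d1^2/d2^2 + d2^2/d1^2) * ((m1 + m2) / 2)^2

with ``m_i``/``d_i`` the sample mean/SD of gene i's similarity row
(self-entry excluded). The variance ratio factor is >= 1 by AM-GM, with
equality when the two rows are equally dispersed, so the statistic rewards
gene pairs that are both strongly and comparably connected to the cohort.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
NAMESPACE_ALIASES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}

#: Wang semantic-contribution edge weights (GOSemSim defaults).
DEFAULT_EDGE_WEIGHTS: Mapping[str, float] = {"is_a": 0.8, "part_of": 0.6}

#: Floor applied to similarity-row standard deviations in :func:`m_simsc`.
SD_FLOOR = 1e-8


def _canonical_namespace(ns: str) -> str:
    return NAMESPACE_ALIASES.get(ns, ns)


@dataclass
class GOGraph:
    """An ontology DAG with typed child->parent edges, one root per namespace.

    ``parents[child]`` lists ``(parent_id, edge_type)`` with edge types
    restricted to ``is_a`` and ``part_of``.
    """

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)
    parents: dict[str, list[tuple[str, str]]]
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, plist in self.parents.items():
            for parent, etype in plist:
                if etype not in DEFAULT_EDGE_WEIGHTS:
                    raise FormatError(f"unsupported edge type {etype!r} on {child}")
                if parent not in self.terms:
                    raise FormatError(f"edge {child}->{parent} points outside the graph")
                self._children[parent].append((child, etype))
        if not self.roots:
            self.roots = self._find_roots()
        self.validate()

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for tid, (_, ns) in self.terms.items():
            if not self.parents.get(tid):
                if ns in roots:
                    raise FormatError(f"namespace {ns} has multiple roots")
                roots[ns] = tid
        return roots

    def validate(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("ontology graph contains a cycle")
        for tid in self.terms:
            ns = self.namespace(tid)
            root = self.roots.get(ns)
            if root is None:
                raise FormatError(f"namespace {ns} has no root")
            if tid != root and root not in self.ancestors(tid):
                raise FormatError(f"term {tid} cannot reach its namespace root {root}")

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for tid, (name, ns) in self.terms.items():
            g.add_node(tid, name=name, namespace=ns)
        for child, plist in self.parents.items():
            for parent, etype in plist:
                g.add_edge(child, parent, key=etype)
        return g

    def namespace(self, term: str) -> str:
        try:
            return self.terms[term][1]
        except KeyError:
            raise KeyError(f"unknown term {term!r}") from None

    def children(self, term: str) -> list[tuple[str, str]]:
        return self._children[term]

    def ancestors(self, term: str) -> set[str]:
        """Ancestor closure of ``term`` excluding the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        seen: set[str] = set()
        stack = [p for p, _ in self.parents.get(term, [])]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(p for p, _ in self.parents.get(t, []))
        return seen

    def terms_in_namespace(self, namespace: str) -> list[str]:
        ns = _canonical_namespace(namespace)
        return [t for t, (_, n) in self.terms.items() if n == ns]


@dataclass
class SValueMap:
    """Wang semantic contributions of an anchor term's ancestor closure."""

    anchor_term: str
    svalues: dict[str, float]

    @property
    def semantic_value(self) -> float:
        return float(sum(self.svalues.values()))


@dataclass
class GeneSimMatrix:
    """Symmetric gene-by-gene BMA similarity for one sub-ontology."""

    gene_ids: list[str]
    bma: pd.DataFrame  # square, index/columns = gene_ids
    namespace: str

    def row(self, gene: str, exclude_self: bool = True) -> pd.Series:
        r = self.bma.loc[gene]
        return r.drop(gene) if exclude_self else r


@dataclass
class SimStats:
    """Row means and sample SDs feeding the pairwise statistic."""

    mu1: float
    mu2: float
    delta1: float
    delta2: float


def parse_obo(path) -> GOGraph:
    """Parse an OBO 1.2 file into a :class:`GOGraph`.

    Obsolete terms are dropped; ``is_a`` and ``relationship: part_of``
    edges are kept, every other relationship type is ignored.
    """
    try:
        net = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # malformed stanza, bad header ...
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, list[tuple[str, str]]] = {}
    for tid, data in net.nodes(data=True):
        terms[tid] = (data.get("name", tid), data.get("namespace", "biological_process"))
        parents[tid] = []
    for child, parent, key in net.edges(keys=True):
        if key in DEFAULT_EDGE_WEIGHTS and parent in terms:
            parents[child].append((parent, key))
    return GOGraph(terms=terms, parents=parents)


def write_obo(graph: GOGraph, path) -> None:
    """Serialize a :class:`GOGraph` to minimal OBO 1.2."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(graph.terms):
            name, ns = graph.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
            for parent, etype in sorted(graph.parents.get(tid, [])):
                if etype == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {etype} {parent}\n")


def wang_svalues(
    graph: GOGraph, term: str, weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS
) -> SValueMap:
    """Propagate Wang S-values from ``term`` to its ancestor closure.

    S(anchor) = 1; for an ancestor t, S(t) is the maximum over children c
    of t lying on a path toward the anchor of w(edge) * S(c).
    """
    closure = graph.ancestors(term) | {term}
    svalues: dict[str, float] = {term: 1.0}

    def s(t: str) -> float:
        if t in svalues:
            return svalues[t]
        best = 0.0
        for child, etype in graph.children(t):
            if child in closure:
                best = max(best, weights[etype] * s(child))
        svalues[t] = best
        return best

    for t in closure:
        s(t)
    return SValueMap(anchor_term=term, svalues=svalues)


def wang_term_sim(
    graph: GOGraph,
    t1: str,
    t2: str,
    weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS,
    _cache: dict | None = None,
) -> float:
    """Wang similarity of two terms from the same sub-ontology.

    sim = sum over shared closure terms of (S1 + S2), divided by the sum
    of the two semantic values.
    """
    if graph.namespace(t1) != graph.namespace(t2):
        raise DomainError(
            f"terms {t1} ({graph.namespace(t1)}) and {t2} ({graph.namespace(t2)}) "
            "belong to different sub-ontologies"
        )
    if _cache is None:
        _cache = {}
    sv1 = _cache.get(t1) or _cache.setdefault(t1, wang_svalues(graph, t1, weights))
    sv2 = _cache.get(t2) or _cache.setdefault(t2, wang_svalues(graph, t2, weights))
    shared = sv1.svalues.keys() & sv2.svalues.keys()
    if not shared:
        return 0.0
    num = sum(sv1.svalues[t] + sv2.svalues[t] for t in shared)
    return float(num / (sv1.semantic_value + sv2.semantic_value))


class WangSimilarity:
    """Wang term similarity with S-value caching, for batch gene scoring."""

    def __init__(self, graph: GOGraph, weights: Mapping[str, float] = DEFAULT_EDGE_WEIGHTS):
        self.graph = graph
        self.weights = dict(weights)
        self._svalue_cache: dict[str, SValueMap] = {}

    def term_sim(self, t1: str, t2: str) -> float:
        return wang_term_sim(self.graph, t1, t2, self.weights, self._svalue_cache)


def bma_gene_sim(
    graph: GOGraph,
    annot: Mapping[str, Iterable[str]],
    g1: str,
    g2: str,
    namespace: str = "BP",
    sim: WangSimilarity | None = None,
) -> float:
    """Best-match-average Wang similarity between two genes' annotation sets.

    Builds the |T1| x |T2| term-similarity matrix and averages the mean of
    row maxima with the mean of column maxima.
    """
    ns = _canonical_namespace(namespace)
    sim = sim or WangSimilarity(graph)
    t1 = sorted(t for t in annot.get(g1, ()) if graph.namespace(t) == ns)
    t2 = sorted(t for t in annot.get(g2, ()) if graph.namespace(t) == ns)
    if not t1 or not t2:
        missing = g1 if not t1 else g2
        raise DomainError(f"gene {missing!r} has no {ns} annotation")
    mat = np.array([[sim.term_sim(a, b) for b in t2] for a in t1])
    return float((mat.max(axis=1).mean() + mat.max(axis=0).mean()) / 2.0)


def gene_sim_matrix(
    graph: GOGraph,
    annot: Mapping[str, Iterable[str]],
    genes: Iterable[str],
    namespace: str = "BP",
) -> GeneSimMatrix:
    """Symmetric BMA gene-by-gene matrix over ``genes``.

    Genes without annotations in ``namespace`` are dropped (logged), not
    zero-filled, so every retained diagonal entry is exactly 1.
    """
    ns = _canonical_namespace(namespace)
    sim = WangSimilarity(graph)
    kept, dropped = [], []
    for g in genes:
        terms = [t for t in annot.get(g, ()) if t in graph.terms and graph.namespace(t) == ns]
        (kept if terms else dropped).append(g)
    if dropped:
        logger.warning(
            "dropping %d genes with no %s annotation (e.g. %s)", len(dropped), ns, dropped[:5]
        )
    n = len(kept)
    mat = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = bma_gene_sim(graph, annot, kept[i], kept[j], ns, sim)
    return GeneSimMatrix(
        gene_ids=kept, bma=pd.DataFrame(mat, index=kept, columns=kept), namespace=ns
    )


def _row_stats(simm: GeneSimMatrix, g1: str, g2: str) -> SimStats:
    for g in (g1, g2):
        if g not in simm.bma.index:
            raise DomainError(f"gene {g!r} not present in the similarity matrix")
    r1 = simm.row(g1).to_numpy(dtype=float)
    r2 = simm.row(g2).to_numpy(dtype=float)
    if r1.size < 1 or r2.size < 1:
        raise DomainError(
            "only the self-similarity is available: the row statistics need "
            "at least one other gene in the matrix"
        )

    def sd(r: np.ndarray) -> float:
        return float(r.std(ddof=1)) if r.size >= 2 else 0.0

    return SimStats(mu1=float(r1.mean()), mu2=float(r2.mean()), delta1=sd(r1), delta2=sd(r2))


def m_simsc(simm: GeneSimMatrix, g1: str, g2: str) -> float:
    """Pairwise matrix-similarity statistic for one gene pair.

    Row means/SDs exclude the diagonal self-entry; SDs are floored at
    ``SD_FLOOR`` so constant rows do not blow up the variance ratio.
    """
    st = _row_stats(simm, g1, g2)
    d1 = max(st.delta1, SD_FLOOR)
    d2 = max(st.delta2, SD_FLOOR)
    var_factor = 0.5 * (d1**2 / d2**2 + d2**2 / d1**2)
    return float(var_factor * ((st.mu1 + st.mu2) / 2.0) ** 2)


def m_simsc_matrix(simm: GeneSimMatrix) -> pd.DataFrame:
    """All pairwise statistics as a symmetric matrix with NaN diagonal.

    This is the double sum over n = 1..Lengthx, n' = n+1 populating the
    upper triangle, mirrored for convenience.
    """
    genes = simm.gene_ids
    out = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    for g1, g2 in itertools.combinations(genes, 2):
        v = m_simsc(simm, g1, g2)
        out.loc[g1, g2] = out.loc[g2, g1] = v
    return out
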