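"""Mixed-gene tissue interaction (MGTI) scoring and regulation bands.

A gene pair's interaction strength is built from the two prioritization
scores S_p on a log10 scale. The default, normalized form divides the
mean log-score by the log of the cohort-wide maximum prioritization
score,

    Score_inter(g1, g2) = ((log10 S_p(g1) + log10 S_p(g2)) / 2) / log10(max S_p)

which is bounded in (0, 1], reaching 1 only when both genes attain the
cohort maximum. The raw additive form
(log10 S_p(g1) + log10 S_p(g2)) / 2 + log10 max(S_p(g1), S_p(g2))
is available via ``normalized=False``; it is unbounded above and kept
only for comparison.

Scores classify into regulation bands at fixed cutpoints: >= 0.31
increased regulation, [0.1, 0.31) reduced regulation, < 0.1 below the
selection floor (pairs there should not occur for genes that passed
prioritization, and are flagged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import log10
from typing import Literal, Sequence

from .errors import DomainError
from .clustering import ClusterAssignment
from .prioritization import PrioritizationRecord

logger = logging.getLogger(__name__)

INCREASED_CUTPOINT = 0.31
FLOOR_CUTPOINT = 0.1

BAND_INCREASED = "increased_regulation"
BAND_REDUCED = "reduced_regulation"
BAND_BELOW_FLOOR = "below_floor"


@dataclass
class InteractionRecord:
    gene1: str
    gene2: str
    sp1: float
    sp2: float
    sp_max_global: float
    score_inter: float
    band: str


def mgti_score(
    sp1: float, sp2: float, sp_max_global: float, normalized: bool = True
) -> float:
    """Interaction score of one pair of prioritization scores.

    All scores must exceed 1 (log-positivity) and may not exceed the
    global maximum.
    """
    if min(sp1, sp2, sp_max_global) <= 1.0:
        raise DomainError(
            f"prioritization scores must exceed 1 for log-scale interaction "
            f"(got sp1={sp1}, sp2={sp2}, sp_max={sp_max_global}); floor the "
            "scores above 1 before pairing"
        )
    if sp_max_global < max(sp1, sp2):
        raise DomainError(
            f"sp_max_global={sp_max_global} is smaller than max(sp1, sp2)={max(sp1, sp2)}"
        )
    mean_log = (log10(sp1) + log10(sp2)) / 2.0
    if normalized:
        return mean_log / log10(sp_max_global)
    return mean_log + log10(max(sp1, sp2))


def classify_band(score: float) -> str:
    """Map an interaction score in (0, 1) onto its regulation band.

    Increased regulation is a closed-from-below decision at 0.31; scores
    below 0.1 contradict the upstream selection guarantee and are flagged.
    """
    if not 0.0 < score <= 1.0:
        raise DomainError(f"interaction score must lie in (0, 1], got {score}")
    if score >= INCREASED_CUTPOINT:
        return BAND_INCREASED
    if score >= FLOOR_CUTPOINT:
        return BAND_REDUCED
    logger.warning("interaction score %.4f below the %.2f selection floor", score, FLOOR_CUTPOINT)
    return BAND_BELOW_FLOOR


def score_all_pairs(
    records: Sequence[PrioritizationRecord],
    within: Literal["all", "tissue", "cluster"] = "all",
    cluster: ClusterAssignment | None = None,
    sp_floor: float | None = None,
    normalized: bool = True,
) -> list[InteractionRecord]:
    """Score every unordered gene pair inside the chosen scope.

    Scope "all" and "cluster" use each gene's maximum S_p across its
    tissues; scope "tissue" pairs genes within each tissue at the
    tissue-local S_p. ``sp_floor`` (> 1) clips sub-unit prioritization
    scores instead of raising. Results are sorted by score descending.
    """
    if within == "cluster" and cluster is None:
        raise DomainError("scope 'cluster' needs a ClusterAssignment")
    if sp_floor is not None and sp_floor <= 1.0:
        raise DomainError("sp_floor must exceed 1")

    def effective(sp: float) -> float:
        if sp <= 1.0:
            if sp_floor is None:
                raise DomainError(
                    f"prioritization score {sp} <= 1: pass sp_floor > 1 to clip"
                )
            return sp_floor
        return sp

    scopes: dict[object, dict[str, float]] = {}
    if within == "tissue":
        for r in records:
            scopes.setdefault(r.tissue, {})[r.gene_id] = effective(r.score_p)
    else:
        per_gene: dict[str, float] = {}
        for r in records:
            per_gene[r.gene_id] = max(per_gene.get(r.gene_id, 0.0), effective(r.score_p))
        if within == "all":
            scopes["all"] = per_gene
        else:
            for g, sp in per_gene.items():
                scopes.setdefault(cluster.labels.get(g), {})[g] = sp

    out: list[InteractionRecord] = []
    for scope, sp_map in sorted(scopes.items(), key=lambda kv: str(kv[0])):
        if len(sp_map) < 2:
            logger.warning("scope %r has < 2 genes: no pairs scored", scope)
            continue
        sp_max = max(sp_map.values())
        for g1, g2 in itertools.combinations(sorted(sp_map), 2):
            score = mgti_score(sp_map[g1], sp_map[g2], sp_max, normalized=normalized)
            band = classify_band(score) if 0.0 < score <= 1.0 else "unbounded"
            out.append(
                InteractionRecord(
                    gene1=g1,
                    gene2=g2,
                    sp1=sp_map[g1],
                    sp2=sp_map[g2],
                    sp_max_global=sp_max,
                    score_inter=score,
                    band=band,
                )
            )
    out.sort(key=lambda r: (-r.score_inter, r.gene1, r.gene2))
    return out


def records_to_frame(records: Sequence[InteractionRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene1": [r.gene1 for r in records],
            "gene2": [r.gene2 for r in records],
            "sp1": [r.sp1 for r in records],
            "sp2": [r.sp2 for r in records],
            "score": [r.score_inter for r in records],
            "band": [r.band for r in records],
        }
    )
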