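"""Per-tissue gene prioritization and tissue-membership classification.

The prioritization score of gene i in tissue t is a linear evidence sum

    S_p(i, t) = mu0(i, t) + mu1 * X1 + mu2 * X2 + ... + mun * Xn

where mu0 is the gene's mean normalized expression in the tissue, the
mu_j are its mean frequencies of occurrence per evidence category
(biological processes, GWAS traits, transcription factors, ...) and the
X_j its normalized evidence values in [0, 1]. The raw sum is the ranking
object; a standardized variant (each component z-scored across genes)
is available when components live on incommensurate scales.

A multinomial logistic layer on the per-tissue score profiles gives each
gene a tissue-membership probability vector, fitted on a seeded
train/validation/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, DomainError
from .clustering import ClusterAssignment
from .synthetic_data import EvidenceBundle

logger = logging.getLogger(__name__)


@dataclass
class PrioritizationRecord:
    gene_id: str
    tissue: str
    score_p: float
    components: dict[str, float] = field(default_factory=dict)
    rank_in_tissue: int = 0


def records_to_frame(records: Sequence[PrioritizationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "tissue": r.tissue, "score_p": r.score_p,
               "rank": r.rank_in_tissue}
        row.update({f"component_{k}": v for k, v in r.components.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def prioritize(
    evidence: EvidenceBundle,
    genes: Iterable[str] | None = None,
    tissues: Iterable[str] | None = None,
    standardize: bool = False,
) -> list[PrioritizationRecord]:
    """Score and rank genes within each tissue.

    Genes missing a tissue-expression or category entry contribute 0 for
    that component (logged). Ranking is per tissue by score descending,
    ties broken lexicographically by gene id.
    """
    if not evidence.categories:
        raise ConfigurationError("evidence bundle declares no categories")
    genes = sorted(genes) if genes is not None else sorted(evidence.tissue_expr.index)
    tissues = list(tissues) if tissues is not None else list(evidence.tissue_expr.columns)
    if not genes or not tissues:
        raise ConfigurationError("need at least one gene and one tissue")

    mu0 = evidence.tissue_expr.reindex(index=genes, columns=tissues)
    if mu0.isna().any().any():
        logger.warning("missing tissue-expression entries set to 0")
        mu0 = mu0.fillna(0.0)
    freq = evidence.freq_means.reindex(index=genes, columns=evidence.categories).fillna(0.0)
    xval = evidence.norm_scores.reindex(index=genes, columns=evidence.categories).fillna(0.0)
    contrib = freq * xval  # per gene x category: mu_j * X_j

    if standardize:
        def z(df: pd.DataFrame) -> pd.DataFrame:
            sd = df.std(ddof=0).replace(0.0, 1.0)
            return (df - df.mean()) / sd

        mu0, contrib = z(mu0), z(contrib)

    evidence_sum = contrib.sum(axis=1)
    records: list[PrioritizationRecord] = []
    for tissue in tissues:
        scores = mu0[tissue] + evidence_sum
        order = sorted(genes, key=lambda g: (-scores[g], g))
        ranks = {g: i + 1 for i, g in enumerate(order)}
        for g in genes:
            comps = {"tissue_expr": float(mu0.loc[g, tissue])}
            comps.update({c: float(contrib.loc[g, c]) for c in evidence.categories})
            records.append(
                PrioritizationRecord(
                    gene_id=g,
                    tissue=tissue,
                    score_p=float(scores[g]),
                    components=comps,
                    rank_in_tissue=ranks[g],
                )
            )
    return records


@dataclass
class MembershipFit:
    probabilities: pd.DataFrame  # genes x tissues, rows sum to 1
    accuracy: dict[str, float]  # split -> accuracy (empty if degenerate)


def fit_membership(
    records: Sequence[PrioritizationRecord],
    cluster: ClusterAssignment | None = None,
    labels: Mapping[str, str] | None = None,
    seed: int = 0,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> MembershipFit:
    """Multinomial logistic tissue membership from per-tissue score profiles.

    Features are the standardized S_p profile across tissues, augmented
    with the cluster label (one-hot) when an assignment is supplied.
    Training labels default to each gene's argmax-score tissue. A seeded
    60/20/20 train/validation/test split reports held-out accuracy.
    Degenerate cases (single tissue, or identical profiles for all genes)
    return the uninformative uniform answer.
    """
    df = records_to_frame(records)
    if df.empty:
        raise DomainError("no prioritization records")
    if not np.isfinite(df["score_p"]).all():
        raise DomainError("non-finite prioritization scores")
    profile = df.pivot(index="gene_id", columns="tissue", values="score_p").sort_index()
    tissues = list(profile.columns)
    genes = list(profile.index)
    if len(tissues) == 1:
        probs = pd.DataFrame(1.0, index=genes, columns=tissues)
        return MembershipFit(probabilities=probs, accuracy={})

    if labels is None:
        labels = {g: profile.loc[g].idxmax() for g in genes}
    y = np.array([labels[g] for g in genes])

    x = profile.to_numpy(dtype=float)
    if cluster is not None:
        lab = np.array([cluster.labels.get(g, 0) for g in genes])
        onehot = (lab[:, None] == np.unique(lab)[None, :]).astype(float)
        x = np.hstack([x, onehot])
    sd = x.std(axis=0)
    if np.all(sd == 0) or len(np.unique(y)) < 2:
        probs = pd.DataFrame(1.0 / len(tissues), index=genes, columns=tissues)
        return MembershipFit(probabilities=probs, accuracy={})
    x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    n_train = max(int(round(split[0] * len(genes))), len(np.unique(y)))
    n_val = int(round(split[1] * len(genes)))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    if len(np.unique(y[idx_train])) < 2:  # tiny cohorts: train on everything
        idx_train = np.arange(len(genes))

    model = LogisticRegression(max_iter=2000, random_state=seed)
    model.fit(x[idx_train], y[idx_train])
    raw = pd.DataFrame(model.predict_proba(x), index=genes, columns=model.classes_)
    probs = raw.reindex(columns=tissues, fill_value=0.0)
    probs = probs.div(probs.sum(axis=1), axis=0)

    accuracy = {}
    for name, idx in (("train", idx_train), ("validation", idx_val), ("test", idx_test)):
        if len(idx):
            accuracy[name] = float((model.predict(x[idx]) == y[idx]).mean())
    return MembershipFit(probabilities=probs, accuracy=accuracy)
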