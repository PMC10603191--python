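"""Moderated-t differential expression and the multi-threshold selection funnel.

Per-gene two-group linear models are moderated by empirical-Bayes variance
shrinkage: residual variances s_g^2 on d degrees of freedom are assumed to
follow a scaled F prior with parameters (d0, s0^2) estimated by the
method of moments on log variances (the Smyth estimator). The posterior
variance

    s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t-statistic, which then carries d0 + d degrees of
freedom. Genes are selected at three nested p-value cutoffs
(p1 = 0.01 > p2 = 0.001 > p3 = 0.0001 by default) and pushed through a
selection funnel: total passing -> duplicate-symbol collapsed ->
annotated -> selected by the downstream combined score. Funnels from
several datasets merge by gene union, keeping per-gene occurrence counts
that become the frequency-of-occurrence weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError, DomainError
from .synthetic_data import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    gene_id: str
    log_fold_change: float
    t_mod: float
    p_value: float
    df_total: float


@dataclass(frozen=True)
class ThresholdSet:
    """Nested significance cutoffs, least to most stringent."""

    p1: float = 0.01
    p2: float = 0.001
    p3: float = 0.0001

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2, self.p3):
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"thresholds must lie in (0, 1), got {p}")
        if not self.p1 > self.p2 > self.p3:
            raise ConfigurationError("thresholds must satisfy p1 > p2 > p3")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


@dataclass
class FunnelLevel:
    """One threshold's row of the selection funnel."""

    total: int = 0
    not_duplicated: int = 0
    annotated: int = 0
    selected: int = 0
    selected_gene_ids: list[str] = field(default_factory=list)
    occurrence: dict[str, int] = field(default_factory=dict)


@dataclass
class SelectionFunnel:
    thresholds: ThresholdSet
    levels: dict[float, FunnelLevel]
    n_sources: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, lvl in self.levels.items():
            rows.append(
                {
                    "threshold": p,
                    "total": lvl.total,
                    "not_duplicated": lvl.not_duplicated,
                    "annotated": lvl.annotated,
                    "selected": lvl.selected,
                }
            )
        return pd.DataFrame(rows)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior.

    Returns (d0, s0^2); d0 = inf when the log-variances show no excess
    dispersion beyond sampling noise (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def fit_moderated_t(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    prior_df: float | None = None,
) -> list[DEResult]:
    """Moderated two-group t-test for every gene.

    ``contrast = (reference, treatment)``; the log-fold-change is
    treatment minus reference. ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary two-sample pooled t-test). Genes that are
    constant across all samples when no shrinkage is available get
    t = 0, p = 1 and a log warning.
    """
    ref, trt = contrast
    sample_groups = np.array([expr.groups[s] for s in expr.sample_ids])
    mask_ref = sample_groups == ref
    mask_trt = sample_groups == trt
    for cond, mask in ((ref, mask_ref), (trt, mask_trt)):
        if mask.sum() < 2:
            raise ConfigurationError(f"condition {cond!r} needs >= 2 samples")

    x1 = expr.values[:, mask_ref]
    x2 = expr.values[:, mask_trt]
    n1, n2 = x1.shape[1], x2.shape[1]
    df_resid = n1 + n2 - 2
    lfc = x2.mean(axis=1) - x1.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    d0, s0_2 = fit_f_dist(s2, df_resid) if prior_df is None else (prior_df, 0.0)
    if prior_df is not None and prior_df > 0:
        # explicit prior df still needs a prior variance; reuse the moment fit
        _, s0_2 = fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d constant genes with no shrinkage: p set to 1", degenerate.sum())
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate, 1.0, p)

    return [
        DEResult(
            gene_id=g,
            log_fold_change=float(lfc[i]),
            t_mod=float(t[i]),
            p_value=float(min(p[i], 1.0)),
            df_total=float(df_total),
        )
        for i, g in enumerate(expr.gene_ids)
    ]


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "lfc": [r.log_fold_change for r in results],
            "t": [r.t_mod for r in results],
            "p": [r.p_value for r in results],
            "df": [r.df_total for r in results],
        }
    )


def apply_funnel(
    results: Sequence[DEResult],
    thresholds: ThresholdSet,
    annotation: Mapping[str, object],
    symbols: Mapping[str, str] | None = None,
    final_selected: Iterable[str] | None = None,
) -> SelectionFunnel:
    """Run the per-threshold selection funnel.

    ``symbols`` maps gene ids to symbols for duplicate collapse (identity
    when omitted); duplicates keep the smallest p. ``annotation`` marks
    which deduplicated genes carry annotations. The ``selected`` row is
    the intersection with ``final_selected`` — the combined-score pass —
    and equals the annotated set until that second pass supplies it.
    """
    if not results:
        raise DomainError("no DE results to funnel")
    if not annotation:
        logger.warning("empty annotation map: 'annotated' will be 0 at every threshold")
    symbols = symbols or {}
    final_set = set(final_selected) if final_selected is not None else None

    levels: dict[float, FunnelLevel] = {}
    for p_cut in thresholds.as_tuple():
        passing = [r for r in results if r.p_value < p_cut]
        best: dict[str, DEResult] = {}
        for r in passing:
            sym = symbols.get(r.gene_id, r.gene_id)
            if sym not in best or r.p_value < best[sym].p_value:
                best[sym] = r
        dedup = list(best.values())
        annotated = [r for r in dedup if r.gene_id in annotation]
        if final_set is None:
            selected = annotated
        else:
            selected = [r for r in annotated if r.gene_id in final_set]
        ids = sorted(r.gene_id for r in selected)
        levels[p_cut] = FunnelLevel(
            total=len(passing),
            not_duplicated=len(dedup),
            annotated=len(annotated),
            selected=len(selected),
            selected_gene_ids=ids,
            occurrence={g: 1 for g in ids},
        )
    return SelectionFunnel(thresholds=thresholds, levels=levels, n_sources=1)


def merge_datasets(funnels: Sequence[SelectionFunnel]) -> SelectionFunnel:
    """Union the per-threshold selections of several datasets.

    Counts are summed across datasets (each analyzed separately, then
    combined); per-gene occurrence counts are retained for frequency
    weighting.
    """
    if not funnels:
        raise DomainError("need at least one funnel to merge")
    thresholds = funnels[0].thresholds
    for f in funnels[1:]:
        if f.thresholds != thresholds:
            raise ConfigurationError("cannot merge funnels with different thresholds")
    levels: dict[float, FunnelLevel] = {}
    for p_cut in thresholds.as_tuple():
        merged = FunnelLevel()
        occ: dict[str, int] = {}
        for f in funnels:
            lvl = f.levels[p_cut]
            merged.total += lvl.total
            merged.not_duplicated += lvl.not_duplicated
            merged.annotated += lvl.annotated
            for g, c in lvl.occurrence.items():
                occ[g] = occ.get(g, 0) + c
        merged.occurrence = occ
        merged.selected_gene_ids = sorted(occ)
        merged.selected = len(merged.selected_gene_ids)
        levels[p_cut] = merged
    return SelectionFunnel(
        thresholds=thresholds, levels=levels, n_sources=sum(f.n_sources for f in funnels)
    )


def compute_frequencies(
    merged: SelectionFunnel, n_sources: int, threshold: float | None = None
) -> dict[str, float]:
    """Per-gene frequency of occurrence = occurrences / n_sources in (0, 1].

    Uses the most stringent threshold's selection unless one is given.
    """
    if n_sources < 1:
        raise ConfigurationError("n_sources must be >= 1")
    p_cut = threshold if threshold is not None else merged.thresholds.p3
    lvl = merged.levels[p_cut]
    freqs = {g: c / n_sources for g, c in lvl.occurrence.items()}
    bad = {g: f for g, f in freqs.items() if not 0.0 < f <= 1.0}
    if bad:
        raise DomainError(f"occurrence counts exceed n_sources for {sorted(bad)[:5]}")
    return freqs
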