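"""Assessor-side evaluation harness.

Computes the observed target scores of a model population against a native
structure — interface quality as the mean of ICS and IPS, fold quality as
the mean of oligo-lDDT and TM-score — and the correlation / ranking metrics
used to compare predictors: Pearson and Spearman correlations, ROC-AUC for
recovering good models, top-1 loss, the combined assessor formula
0.5*Pearson + 0.5*Spearman + AUC - Loss per observed score, and sums of
per-group Z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import (
    DEFAULT_PARAMS,
    MetricParams,
    NoInterfaceError,
    build_pair_context,
    compute_contact_map,
    compute_oligo_lddt,
    compute_tm,
    interface_similarity,
)
from .structures import StructureModel

__all__ = [
    "ObservedTargetScores",
    "EvaluationReport",
    "GroupScores",
    "UndefinedCorrelationError",
    "AucUndefinedError",
    "observed_scores",
    "correlation_suite",
    "ranking_metrics",
    "evaluation_report",
    "assessor_rank",
    "DEFAULT_GOOD_THRESHOLD",
]

log = logging.getLogger(__name__)

DEFAULT_GOOD_THRESHOLD = 0.6  # observed score above which a model counts as "good"


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant vector or too few points)."""


class AucUndefinedError(ValueError):
    """ROC-AUC undefined (all labels in one class)."""


@dataclass
class ObservedTargetScores:
    """Per-model observed quality vs the native structure."""

    model_ids: list[str]
    ics: list[float]
    ips: list[float]
    oligo_lddt: list[float]
    tm: list[float]

    @property
    def interface_obs(self) -> list[float]:
        return [(a + b) / 2 for a, b in zip(self.ics, self.ips)]

    @property
    def fold_obs(self) -> list[float]:
        return [(a + b) / 2 for a, b in zip(self.oligo_lddt, self.tm)]


@dataclass
class EvaluationReport:
    """Correlation / ranking summary of one predictor on one target."""

    pearson: float
    spearman: float
    roc_auc: float
    top1_loss: float
    assessor_formula_value: float
    zscore_sum: float | None = None


@dataclass
class GroupScores:
    """One predictor group's inputs to the assessor ranking."""

    name: str
    fold_predicted: list[float]
    fold_observed: list[float]
    interface_predicted: list[float]
    interface_observed: list[float]
    # raw per-score values entering the Z-score sum, e.g. mean observed
    # {"ics": ..., "ips": ..., "oligo_lddt": ..., "tm": ...}
    raw_scores: dict[str, float] = field(default_factory=dict)


def observed_scores(models: list[StructureModel], native: StructureModel,
                    params: MetricParams = DEFAULT_PARAMS) -> ObservedTargetScores:
    """ICS/IPS/oligo-lDDT/TM of every model vs the native, plus their means."""
    if not compute_contact_map(native, params.contact_heavy_cutoff).contacts:
        raise NoInterfaceError("native structure has no inter-chain contacts")
    out = ObservedTargetScores([], [], [], [], [])
    for model in models:
        ctx = build_pair_context(model, native)
        ics, ips = interface_similarity(model, native, params=params, ctx=ctx)
        lddt = compute_oligo_lddt(model, native, params=params, ctx=ctx)
        tm = compute_tm(model, native, ctx=ctx)
        out.model_ids.append(model.model_id)
        out.ics.append(ics)
        out.ips.append(ips)
        out.oligo_lddt.append(lddt)
        out.tm.append(tm)
    return out


def correlation_suite(predicted: list[float], observed: list[float]
                      ) -> tuple[float, float]:
    """Pearson and Spearman correlation of predicted vs observed scores."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if len(p) != len(o):
        raise ValueError("predicted and observed differ in length")
    if len(p) < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise UndefinedCorrelationError("constant score vector")
    pearson = float(stats.pearsonr(p, o).statistic)
    spearman = float(stats.spearmanr(p, o).statistic)
    return pearson, spearman


def _roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal ROC-AUC over all cut points, ties grouped."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    return float(np.trapezoid(tpr, fpr))


def ranking_metrics(predicted: list[float], observed: list[float],
                    good_threshold: float = DEFAULT_GOOD_THRESHOLD,
                    model_ids: list[str] | None = None) -> tuple[float, float]:
    """ROC-AUC for recovering good models and the top-1 ranking loss.

    A model is "good" when its observed score reaches ``good_threshold``.
    Top-1 loss is the gap between the best observed score and the observed
    score of the model the predictor ranks first (predicted ties broken by
    model id).
    """
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if len(p) != len(o) or len(p) < 3:
        raise ValueError("need equal-length score vectors with >= 3 entries")
    if not 0.0 < good_threshold < 1.0:
        raise ValueError("good_threshold must lie in (0, 1)")
    labels = (o >= good_threshold).astype(int)
    if labels.min() == labels.max():
        raise AucUndefinedError("observed labels are single-class at this threshold")
    auc = _roc_auc(p, labels)
    ids = model_ids if model_ids is not None else [str(i) for i in range(len(p))]
    top1 = min(range(len(p)), key=lambda i: (-p[i], ids[i]))
    loss = float(o.max() - o[top1])
    return auc, loss


def evaluation_report(predicted: list[float], observed: list[float],
                      good_threshold: float = DEFAULT_GOOD_THRESHOLD,
                      model_ids: list[str] | None = None) -> EvaluationReport:
    """All per-target predictor metrics plus the combined assessor formula."""
    pearson, spearman = correlation_suite(predicted, observed)
    auc, loss = ranking_metrics(predicted, observed, good_threshold, model_ids)
    return EvaluationReport(
        pearson=pearson,
        spearman=spearman,
        roc_auc=auc,
        top1_loss=loss,
        assessor_formula_value=0.5 * pearson + 0.5 * spearman + auc - loss,
    )


def assessor_rank(groups: list[GroupScores],
                  good_threshold: float = DEFAULT_GOOD_THRESHOLD
                  ) -> list[tuple[str, float, float]]:
    """Rank predictor groups as assessors do.

    Per group the formula value sums, over the fold and interface observed
    scores, 0.5*Pearson + 0.5*Spearman + AUC - Loss.  Separately, a Z-score
    sum standardises each ``raw_scores`` column over groups ((x - mean)/sd;
    a zero-spread column contributes 0 with a warning).  Returns
    ``(name, formula_value, zscore_sum)`` sorted by formula value descending,
    ties broken by name.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to rank")
    formula: dict[str, float] = {}
    for g in groups:
        total = 0.0
        for pred, obs in ((g.fold_predicted, g.fold_observed),
                          (g.interface_predicted, g.interface_observed)):
            rep = evaluation_report(pred, obs, good_threshold)
            total += rep.assessor_formula_value
        formula[g.name] = total

    keys = sorted({k for g in groups for k in g.raw_scores})
    zsum = {g.name: 0.0 for g in groups}
    for key in keys:
        vals = np.array([g.raw_scores.get(key, np.nan) for g in groups], float)
        mean, sd = np.nanmean(vals), np.nanstd(vals)
        if sd == 0 or not np.isfinite(sd):
            log.warning("raw score %r has zero spread over groups; Z set to 0", key)
            continue
        for g, v in zip(groups, vals):
            if np.isfinite(v):
                zsum[g.name] += float((v - mean) / sd)

    ranked = sorted(groups, key=lambda g: (-formula[g.name], g.name))
    return [(g.name, formula[g.name], zsum[g.name]) for g in ranked]
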