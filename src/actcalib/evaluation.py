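"""Intensity classification from counts and agreement with calorimetry.

Energy expenditure in METs partitions into four intensity classes:
light [0, 3), moderate [3, 6), vigorous [6, 9) and very vigorous [9, inf),
with left-closed boundaries (a value exactly on a boundary belongs to the
higher class).  Observations are classified twice — from measured METs
(truth) and from counts via the cut-point table (prediction) — and scored
with one-vs-rest sensitivity, specificity, balanced accuracy and AUC.

The one-vs-rest AUC uses the model's continuous predicted-MET score via
the Mann-Whitney rank formulation.  For interior classes a monotone score
cannot cleanly separate a middle band from both sides, so those AUCs are
structurally depressed; this mirrors the published evaluation and is kept
as the default (a distance-to-band score is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .calibration import StratumEquation, predict_met

__all__ = [
    "CLASS_LABELS",
    "MET_BOUNDARIES",
    "met_to_class",
    "counts_to_class",
    "score_classification",
    "auc_one_vs_rest",
    "stratified_reports",
    "ClassificationReport",
    "classify_observations",
]

CLASS_LABELS = ("light", "moderate", "vigorous", "very_vigorous")
MET_BOUNDARIES = (3.0, 6.0, 9.0)


@dataclass
class ClassificationReport:
    """Confusion matrix and per-class one-vs-rest metrics."""

    confusion: pd.DataFrame  # 4x4 counts, rows = true class, cols = predicted
    metrics: pd.DataFrame  # index = class; sensitivity/specificity/balanced_accuracy/auc
    n: int
    scope: str = "pooled"

    @property
    def confusion_row_normalised(self) -> pd.DataFrame:
        totals = self.confusion.sum(axis=1)
        return self.confusion.div(totals.replace(0, np.nan), axis=0)


def met_to_class(met):
    """Map MET values to intensity classes (left-closed boundaries)."""
    arr = np.asarray(met, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MET must be non-negative")
    idx = np.digitize(arr, MET_BOUNDARIES, right=False)
    out = np.asarray(CLASS_LABELS)[idx]
    return str(out) if arr.ndim == 0 else out


def counts_to_class(activity_cpm, cutpoints):
    """Map counts/min to intensity classes via a stratum's three cut-points.

    ``cutpoints`` is the (cp3, cp6, cp9) triple for one stratum; boundary
    ties go to the higher class, so this is exactly
    met_to_class(predict_met(activity)) by the inversion identity.
    """
    cp = np.asarray(cutpoints, dtype=float)
    if cp.shape != (3,) or not np.all(np.diff(cp) > 0):
        raise ValueError("cut-points must be three strictly increasing values")
    arr = np.asarray(activity_cpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("activity must be non-negative")
    idx = np.digitize(arr, cp, right=False)
    out = np.asarray(CLASS_LABELS)[idx]
    return str(out) if arr.ndim == 0 else out


def _confusion(true_class, pred_class) -> pd.DataFrame:
    t = pd.Categorical(true_class, categories=CLASS_LABELS)
    p = pd.Categorical(pred_class, categories=CLASS_LABELS)
    return pd.crosstab(t, p, dropna=False).reindex(
        index=CLASS_LABELS, columns=CLASS_LABELS, fill_value=0
    )


def auc_one_vs_rest(scores, true_class) -> pd.Series:
    """Per-class one-vs-rest AUC of a continuous score (rank formulation).

    AUC_c = P(score in class c > score outside c), computed from average
    ranks (Mann-Whitney).  The score direction is chosen automatically per
    class (the usual ROC convention): for the lowest band the raw score
    ranks members *below* non-members, so the orientation giving AUC >= 0.5
    is reported.  Classes with no members or no complement are reported as
    NaN (undefined, never coerced to 0).
    """
    scores = np.asarray(scores, dtype=float)
    true_class = np.asarray(true_class)
    ranks = rankdata(scores)
    out = {}
    for c in CLASS_LABELS:
        pos = true_class == c
        n1 = int(pos.sum())
        n0 = scores.size - n1
        if n1 == 0 or n0 == 0:
            out[c] = np.nan
            continue
        auc = float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
        out[c] = max(auc, 1.0 - auc)
    return pd.Series(out, name="auc")


def score_classification(
    true_class, pred_class, scores=None, scope: str = "pooled"
) -> ClassificationReport:
    """Confusion matrix plus per-class sensitivity/specificity/BA (and AUC).

    One-vs-rest per class c: sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP), balanced accuracy = their mean.  Empty classes yield NaN
    metrics.  ``scores`` (continuous predicted METs) enables the AUC
    column.
    """
    cm = _confusion(true_class, pred_class)
    n = int(cm.to_numpy().sum())
    rows = {}
    total = cm.to_numpy().sum()
    for c in CLASS_LABELS:
        tp = cm.loc[c, c]
        fn = cm.loc[c].sum() - tp
        fp = cm[c].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": (sens + spec) / 2,
        }
    metrics = pd.DataFrame(rows).T
    if scores is not None:
        metrics["auc"] = auc_one_vs_rest(scores, np.asarray(true_class))
    return ClassificationReport(cm, metrics, n, scope)


def classify_observations(
    obs: pd.DataFrame,
    cutpoint_table: pd.DataFrame,
    equations: dict[str, StratumEquation] | None = None,
) -> pd.DataFrame:
    """Attach true class, predicted class and prediction score per row.

    True class comes from the measured MET; predicted class from the
    stratum's cut-points applied to counts/min; the score is the
    continuous predicted MET (used for AUC) when equations are given,
    otherwise the cut-point classification alone.
    """
    work = obs.copy()
    work["true_class"] = met_to_class(work["met"].to_numpy())
    pred = np.empty(len(work), dtype=object)
    score = np.full(len(work), np.nan)
    ct = cutpoint_table.assign(stratum=cutpoint_table["device"] + "_" + cutpoint_table["placement"])
    for s, sub in work.groupby("stratum"):
        cps = (
            ct[ct["stratum"] == s]
            .sort_values("threshold_met")["cutpoint"]
            .to_numpy()
        )
        if cps.size != 3:
            raise ValueError(f"cut-point table lacks the three thresholds for {s}")
        idx = work.index.get_indexer(sub.index)
        pred[idx] = counts_to_class(sub["activity_cpm"].to_numpy(), cps)
        if equations is not None and s in equations:
            score[idx] = predict_met(equations[s], sub["activity_cpm"].to_numpy())
    work["pred_class"] = pred
    work["score"] = score
    return work


def stratified_reports(
    classified: pd.DataFrame, by: str = "none", min_group_size: int = 5
) -> dict[str, ClassificationReport]:
    """Pooled report plus one per group of ``by`` in {sex, stratum, none}.

    Groups below ``min_group_size`` observations are skipped with a
    warning.  The same scoring pipeline is applied to each group.
    """
    if by not in ("none", "sex", "stratum"):
        raise ValueError("by must be one of 'none', 'sex', 'stratum'")
    has_scores = classified["score"].notna().all()

    def _report(df, scope):
        return score_classification(
            df["true_class"].to_numpy(),
            df["pred_class"].to_numpy(),
            scores=df["score"].to_numpy() if has_scores else None,
            scope=scope,
        )

    reports = {"pooled": _report(classified, "pooled")}
    if by != "none":
        for g, sub in classified.groupby(by):
            if len(sub) < min_group_size:
                warnings.warn(f"group {g!r} below minimum size {min_group_size}; skipped")
                continue
            reports[str(g)] = _report(sub, str(g))
    return reports
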