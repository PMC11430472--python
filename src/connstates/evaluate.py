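"""Evaluation: balanced accuracy with threshold search, AUC, transfer, importance.

Balanced accuracy is (sensitivity + specificity)/2, with the score
threshold searched in [-1, +1] (201 evenly spaced candidates plus all
midpoints of adjacent sorted scores, clipped to the range); AUC is the
rank-based (Mann-Whitney) statistic with ties counted 1/2.  Transfer
applies every fold-model of a training condition to all scans of a test
condition; feature importance averages sum-normalized |beta| over the
feature-integration models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .blocks import FAMILIES
from .classify import INTEGRATION, NestedCVResult, TrainedModel, hard_vote, soft_vote

ENSEMBLES = ("integration", "hard_voting", "soft_voting")
N_THRESHOLD_GRID = 201


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2."""
    if c.positives == 0 or c.negatives == 0:
        raise ValueError("balanced accuracy needs at least one sample of each class")
    return 0.5 * (c.TP / c.positives + c.TN / c.negatives)


def confusion_at_threshold(scores: np.ndarray, labels: np.ndarray,
                           threshold: float) -> ConfusionCounts:
    """Counts with the rule: score >= threshold predicts the positive class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int((pred & pos).sum()),
        FN=int((~pred & pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FP=int((pred & ~pos).sum()),
    )


def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Maximize balanced accuracy over thresholds in [-1, +1].

    Candidates: 201 evenly spaced values plus midpoints of adjacent sorted
    scores clipped to the range.  Returns (threshold, balanced accuracy),
    the smallest maximizing threshold on ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    grid = np.linspace(-1.0, 1.0, N_THRESHOLD_GRID)
    srt = np.sort(scores)
    mids = np.clip((srt[:-1] + srt[1:]) / 2.0, -1.0, 1.0)
    candidates = np.unique(np.concatenate([grid, mids]))
    best_t, best_ba = candidates[0], -np.inf
    for t in candidates:
        ba = balanced_accuracy(confusion_at_threshold(scores, labels, t))
        if ba > best_ba + 1e-12:
            best_t, best_ba = float(t), float(ba)
    return best_t, best_ba


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class EvaluationResult:
    """Performance of one model family (or ensemble) on one condition pair."""

    family: str
    train_condition: str
    test_condition: str
    balanced_accuracy: float  # pooled scores, threshold searched once
    auc: float
    threshold: float
    confusion: ConfusionCounts
    per_repeat_ba: np.ndarray  # threshold searched within each repetition
    per_repeat_auc: np.ndarray

    @property
    def mean_repeat_ba(self) -> float:
        return float(self.per_repeat_ba.mean())

    @property
    def mean_repeat_auc(self) -> float:
        return float(self.per_repeat_auc.mean())


def _evaluate_score_matrix(score_mat: np.ndarray, y: np.ndarray, family: str,
                           condition: str) -> EvaluationResult:
    """score_mat: (n_repeats, n_samples) outer-test scores."""
    per_ba, per_auc = [], []
    for rep_scores in score_mat:
        _, ba = optimize_threshold(rep_scores, y)
        per_ba.append(ba)
        per_auc.append(auc(rep_scores, y))
    pooled_scores = score_mat.ravel()
    pooled_y = np.tile(y, score_mat.shape[0])
    thr, ba_pooled = optimize_threshold(pooled_scores, pooled_y)
    return EvaluationResult(
        family=family, train_condition=condition, test_condition=condition,
        balanced_accuracy=ba_pooled, auc=auc(pooled_scores, pooled_y),
        threshold=thr, confusion=confusion_at_threshold(pooled_scores, pooled_y, thr),
        per_repeat_ba=np.array(per_ba), per_repeat_auc=np.array(per_auc),
    )


def evaluate_result(result: NestedCVResult, condition: str = "") -> dict[str, EvaluationResult]:
    """Within-condition performance of the 5 base families and 3 ensembles."""
    y = result.y
    out: dict[str, EvaluationResult] = {}
    base_mats = {fam: result.repeat_scores(fam) for fam in FAMILIES}
    for fam in FAMILIES:
        out[fam] = _evaluate_score_matrix(base_mats[fam], y, fam, condition)
    out["integration"] = _evaluate_score_matrix(
        result.repeat_scores(INTEGRATION), y, "integration", condition)

    n_rep = result.plan.n_repeats
    soft_mat = np.stack([
        soft_vote({f: base_mats[f][r] for f in FAMILIES}) for r in range(n_rep)
    ])
    out["soft_voting"] = _evaluate_score_matrix(soft_mat, y, "soft_voting", condition)

    # hard voting has discrete votes: BA at the majority rule, vote fraction for AUC
    per_ba, per_auc = [], []
    frac_rows = []
    for r in range(n_rep):
        labels_by = {f: (base_mats[f][r] >= 0).astype(int) for f in FAMILIES}
        voted, frac = hard_vote(labels_by)
        frac_rows.append(frac)
        per_ba.append(balanced_accuracy(ConfusionCounts(
            TP=int(((voted == 1) & (y == 1)).sum()),
            FN=int(((voted == 0) & (y == 1)).sum()),
            TN=int(((voted == 0) & (y == 0)).sum()),
            FP=int(((voted == 1) & (y == 0)).sum()),
        )))
        per_auc.append(auc(frac, y))
    frac_all = np.concatenate(frac_rows)
    y_all = np.tile(y, n_rep)
    voted_all = (frac_all > 0.5).astype(int)
    conf = ConfusionCounts(
        TP=int(((voted_all == 1) & (y_all == 1)).sum()),
        FN=int(((voted_all == 0) & (y_all == 1)).sum()),
        TN=int(((voted_all == 0) & (y_all == 0)).sum()),
        FP=int(((voted_all == 1) & (y_all == 0)).sum()),
    )
    out["hard_voting"] = EvaluationResult(
        family="hard_voting", train_condition=condition, test_condition=condition,
        balanced_accuracy=balanced_accuracy(conf), auc=auc(frac_all, y_all),
        threshold=0.5, confusion=conf,
        per_repeat_ba=np.array(per_ba), per_repeat_auc=np.array(per_auc),
    )
    return out


def summary_table(evals: Mapping[str, EvaluationResult]) -> pd.DataFrame:
    rows = []
    for fam, ev in evals.items():
        rows.append({
            "family": fam,
            "balanced_accuracy": ev.balanced_accuracy,
            "mean_repeat_ba": ev.mean_repeat_ba,
            "auc": ev.auc,
            "threshold": ev.threshold,
            "TP": ev.confusion.TP, "FN": ev.confusion.FN,
            "TN": ev.confusion.TN, "FP": ev.confusion.FP,
        })
    return pd.DataFrame(rows).set_index("family")


# --------------------------------------------------------------------------- #
# Cross-condition transfer
# --------------------------------------------------------------------------- #


def transfer_cell(result: NestedCVResult,
                  features_by_family: Mapping[str, pd.DataFrame],
                  y_test: np.ndarray, mode: str = "soft") -> tuple[float, float]:
    """Mean (balanced accuracy, AUC) of condition A's fold-models on cohort B.

    Every trained fold-model scores ALL scans of the test condition using
    the training condition's scalers.
    """
    for fam in FAMILIES:
        if fam not in features_by_family:
            raise ValueError(f"test features missing family {fam!r}")
    expected = {fam: result.folds[0].models[fam].feature_names for fam in FAMILIES}
    for fam in FAMILIES:
        got = tuple(features_by_family[fam].columns)
        if got != expected[fam]:
            missing = sorted(set(expected[fam]) - set(got))
            raise ValueError(f"feature names mismatch in {fam!r}; missing: {missing[:5]}")
    y_test = np.asarray(y_test, dtype=int)
    bas, aucs = [], []
    for rec in result.folds:
        if mode == "soft":
            scores = soft_vote({
                f: rec.models[f].decision_function(
                    features_by_family[f].to_numpy(dtype=float)) for f in FAMILIES
            })
        elif mode == "integration":
            joined = pd.concat([features_by_family[f] for f in FAMILIES], axis=1)
            scores = rec.models[INTEGRATION].decision_function(joined.to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown transfer mode {mode!r}")
        _, ba = optimize_threshold(scores, y_test)
        bas.append(ba)
        aucs.append(auc(scores, y_test))
    return float(np.mean(bas)), float(np.mean(aucs))


def transfer_matrix(
    results: Mapping[str, NestedCVResult],
    features: Mapping[str, Mapping[str, pd.DataFrame]],
    labels: Mapping[str, np.ndarray],
    mode: str = "soft",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train x test grids of balanced accuracy and AUC.

    Diagonal cells reuse the within-condition nested-CV result; off-diagonal
    cells apply all fold-models of the training condition to the test cohort.
    """
    conds = list(results)
    ba = pd.DataFrame(index=conds, columns=conds, dtype=float)
    au = pd.DataFrame(index=conds, columns=conds, dtype=float)
    diag_key = "soft_voting" if mode == "soft" else mode
    for a in conds:
        within = evaluate_result(results[a], a)[diag_key]
        for b in conds:
            if a == b:
                ba.loc[a, b] = within.balanced_accuracy
                au.loc[a, b] = within.auc
            else:
                cell_ba, cell_auc = transfer_cell(results[a], features[b], labels[b], mode)
                ba.loc[a, b] = cell_ba
                au.loc[a, b] = cell_auc
    return ba, au


# --------------------------------------------------------------------------- #
# Feature importance
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ImportanceTable:
    table: pd.Series  # feature name -> mean normalized |beta|, descending
    n_models_averaged: int
    meta_condition: str = ""

    def top(self, n: int = 10) -> pd.Series:
        return self.table.head(n)


def feature_importance(models: Sequence[TrainedModel],
                       meta_condition: str = "") -> ImportanceTable:
    """Mean over models of per-model sum-normalized |beta|.

    All models must share feature names (feature-integration models).
    """
    if not models:
        raise ValueError("no models supplied")
    names = models[0].feature_names
    rows = []
    for m in models:
        if m.feature_names != names:
            raise ValueError("models disagree on feature names")
        ab = np.abs(m.beta)
        total = ab.sum()
        if total < 1e-300:
            rows.append(np.full(ab.shape, 1.0 / ab.size))  # flat model: uniform weight
        else:
            rows.append(ab / total)
    mean = np.mean(rows, axis=0)
    table = pd.Series(mean, index=list(names)).sort_values(ascending=False)
    return ImportanceTable(table=table, n_models_averaged=len(models),
                           meta_condition=meta_condition)
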