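"""Linear max-margin classification under repeated nested cross-validation.

Five base models (one per feature family) and a feature-integration model
(all 324 features) are trained per outer fold.  The outer loop is a
subject-grouped 10-fold split (a subject's paired scans never straddle
train/test); hyperparameters — box constraint C in {10^-6..10^3} and
kernel scale s in {10^-4..10^2} (features divided by s before the linear
kernel) — are chosen per outer fold by exhaustive grid search minimizing
mean hinge loss over a subject-grouped inner 3-fold split.  The whole
procedure is repeated ``n_repeats`` times with re-randomized folds.

For a linear kernel, (C, s) produces the same decision function as
C_eff = C / s^2 on unscaled features, and the inner hinge loss depends
only on C_eff; the search therefore fits one model per distinct C_eff per
inner fold and maps losses back onto the full grid, breaking ties toward
smaller C and then smaller s.  This is exact, not an approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .blocks import FAMILIES

# Iteration cap for libsvm: at extreme effective C (up to 1e11 on this grid)
# the dual solver may otherwise cycle near machine precision on inseparable
# data.  The cap is deterministic for fixed input, so reproducibility holds.
MAX_ITER = 200_000


def _fit_svc(X, y, C):
    svc = SVC(kernel="linear", C=C, tol=1e-7, max_iter=MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    return svc


C_GRID: tuple[float, ...] = tuple(10.0**e for e in range(-6, 4))  # 10 values
SCALE_GRID: tuple[float, ...] = tuple(10.0**e for e in range(-4, 3))  # 7 values
INTEGRATION = "integration"


@dataclass(frozen=True)
class HyperParams:
    box_constraint: float
    kernel_scale: float

    def __post_init__(self) -> None:
        if not (1e-6 - 1e-12 <= self.box_constraint <= 1e3 + 1e-9):
            raise ValueError("box constraint outside [1e-6, 1e3]")
        if not (1e-4 - 1e-12 <= self.kernel_scale <= 1e2 + 1e-9):
            raise ValueError("kernel scale outside [1e-4, 1e2]")

    @property
    def effective_c(self) -> float:
        return self.box_constraint / self.kernel_scale**2


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    sd: np.ndarray  # zero-variance features clamped to 1
    clamped: np.ndarray  # bool flags of clamped features

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def standardize_fit(X: np.ndarray) -> Scaler:
    """Column means/SDs from training data only; constant columns clamp SD to 1."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    clamped = sd < 1e-12
    sd = np.where(clamped, 1.0, sd)
    return Scaler(mean=mean, sd=sd, clamped=clamped)


@dataclass(frozen=True)
class TrainedModel:
    """Linear SVM with its scaler, on the raw-feature scale.

    score(x) = <beta, ((x - mean)/sd) / kernel_scale> + bias
    """

    beta: np.ndarray
    bias: float
    hyper: HyperParams
    scaler: Scaler
    feature_names: tuple[str, ...]
    family: str

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.apply(X) / self.hyper.kernel_scale
        return Xs @ self.beta + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def hinge_loss(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean hinge loss; y in {0, 1} mapped to {-1, +1}."""
    ypm = 2.0 * np.asarray(y) - 1.0
    return float(np.maximum(0.0, 1.0 - ypm * scores).mean())


def train_linear_svm(X: np.ndarray, y: np.ndarray, hyper: HyperParams,
                     feature_names: Sequence[str] = (), family: str = "",
                     scaler: Scaler | None = None) -> TrainedModel:
    """Fit a soft-margin linear SVM on standardized, kernel-scaled features.

    ``X`` is raw; the scaler (fit on ``X`` unless provided) and the kernel
    scale are applied internally and stored with the model.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if scaler is None:
        scaler = standardize_fit(X)
    Xs = scaler.apply(X) / hyper.kernel_scale
    svc = _fit_svc(Xs, y, hyper.box_constraint)
    return TrainedModel(
        beta=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        hyper=hyper,
        scaler=scaler,
        feature_names=tuple(feature_names) if len(feature_names) else tuple(
            f"f{i}" for i in range(X.shape[1])),
        family=family,
    )


# --------------------------------------------------------------------------- #
# Fold construction (subject-grouped)
# --------------------------------------------------------------------------- #


def subject_folds(subjects: Sequence[str], k: int, rng: np.random.Generator) -> list[list[str]]:
    """Shuffle unique subjects and split them into ``k`` near-equal folds."""
    uniq = list(dict.fromkeys(subjects))
    if len(uniq) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(uniq)}")
    perm = [uniq[i] for i in rng.permutation(len(uniq))]
    return [list(f) for f in np.array_split(perm, k)]


def _mask_for(subject_ids: np.ndarray, fold_subjects: Sequence[str]) -> np.ndarray:
    return np.isin(subject_ids, list(fold_subjects))


# --------------------------------------------------------------------------- #
# Inner grid search
# --------------------------------------------------------------------------- #


def inner_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    inner_k: int,
    rng: np.random.Generator,
    c_grid: Sequence[float] = C_GRID,
    scale_grid: Sequence[float] = SCALE_GRID,
) -> HyperParams:
    """Exhaustive grid search minimizing mean inner-fold hinge loss.

    ``X`` must already be standardized with the outer-training scaler.
    Ties are broken toward smaller C, then smaller kernel scale.
    """
    grid = [HyperParams(c, s) for c in c_grid for s in scale_grid]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = subject_folds(subject_ids, inner_k, rng)
    eff_cs = sorted({hp.effective_c for hp in grid})

    losses_by_eff = {c_eff: [] for c_eff in eff_cs}
    n_used = 0
    for fold in folds:
        val_mask = _mask_for(subject_ids, fold)
        tr_mask = ~val_mask
        y_tr, y_val = y[tr_mask], y[val_mask]
        if len(np.unique(y_tr)) < 2 or val_mask.sum() == 0:
            continue  # skip degenerate folds
        n_used += 1
        for c_eff in eff_cs:
            svc = _fit_svc(X[tr_mask], y_tr, c_eff)
            scores = svc.decision_function(X[val_mask])
            losses_by_eff[c_eff].append(hinge_loss(scores, y_val))
    if n_used == 0:
        raise ValueError("all inner folds degenerate (single-class)")

    mean_loss = {c_eff: float(np.mean(v)) for c_eff, v in losses_by_eff.items()}
    best = None
    best_loss = np.inf
    for hp in sorted(grid, key=lambda h: (h.box_constraint, h.kernel_scale)):
        loss = mean_loss[hp.effective_c]
        if loss < best_loss - 1e-12:
            best, best_loss = hp, loss
    assert best is not None
    return best


# --------------------------------------------------------------------------- #
# Nested cross-validation
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CVPlan:
    outer_k: int = 10
    inner_k: int = 3
    n_repeats: int = 50
    seed: int = 0


@dataclass(frozen=True)
class FoldRecord:
    repeat: int
    fold: int
    test_index: np.ndarray  # scan row indices of the outer test set
    models: Mapping[str, TrainedModel]  # family -> model (5 base + integration)
    scores: Mapping[str, np.ndarray]  # family -> outer-test decision scores


@dataclass(frozen=True)
class NestedCVResult:
    plan: CVPlan
    families: tuple[str, ...]
    folds: tuple[FoldRecord, ...]
    y: np.ndarray
    subject_ids: np.ndarray
    n_samples: int

    def repeat_scores(self, family: str) -> np.ndarray:
        """(n_repeats, n_samples) outer-test scores (each scan scored once per repeat)."""
        out = np.full((self.plan.n_repeats, self.n_samples), np.nan)
        for rec in self.folds:
            out[rec.repeat, rec.test_index] = rec.scores[family]
        if np.isnan(out).any():
            raise AssertionError("outer folds do not cover every scan")
        return out

    def models_of(self, family: str) -> list[TrainedModel]:
        return [rec.models[family] for rec in self.folds]


def nested_cv(
    features_by_family: Mapping[str, pd.DataFrame],
    y: np.ndarray,
    subject_ids: np.ndarray,
    plan: CVPlan,
    include_integration: bool = True,
) -> NestedCVResult:
    """Repeated subject-grouped nested CV over all families.

    Per outer fold and family: scaler fit on the outer-training rows,
    inner search on the standardized outer-training data, final refit on
    the full outer-training set (inner training + validation), scores on
    the outer test set.
    """
    y = np.asarray(y, dtype=int)
    subject_ids = np.asarray(subject_ids)
    n = y.shape[0]
    families = list(features_by_family)
    mats = {fam: df.to_numpy(dtype=float) for fam, df in features_by_family.items()}
    names = {fam: tuple(df.columns) for fam, df in features_by_family.items()}
    if include_integration and INTEGRATION not in mats:
        joined = pd.concat([features_by_family[f] for f in families], axis=1)
        mats[INTEGRATION] = joined.to_numpy(dtype=float)
        names[INTEGRATION] = tuple(joined.columns)
        families.append(INTEGRATION)

    uniq_subjects = list(dict.fromkeys(subject_ids.tolist()))
    if len(uniq_subjects) < plan.outer_k:
        raise ValueError(
            f"nested CV needs >= {plan.outer_k} subjects, got {len(uniq_subjects)}"
        )

    rng = np.random.default_rng(plan.seed)
    records: list[FoldRecord] = []
    for rep in range(plan.n_repeats):
        outer = subject_folds(uniq_subjects, plan.outer_k, rng)
        for fold_idx, fold_subjects in enumerate(outer):
            test_mask = _mask_for(subject_ids, fold_subjects)
            train_mask = ~test_mask
            test_index = np.where(test_mask)[0]
            inner_rngs = {fam: np.random.default_rng(rng.integers(0, 2**31 - 1))
                          for fam in families}
            models: dict[str, TrainedModel] = {}
            scores: dict[str, np.ndarray] = {}
            for fam in families:
                X = mats[fam]
                scaler = standardize_fit(X[train_mask])
                X_tr = scaler.apply(X[train_mask])
                hyper = inner_grid_search(
                    X_tr, y[train_mask], subject_ids[train_mask],
                    plan.inner_k, inner_rngs[fam],
                )
                model = train_linear_svm(
                    X[train_mask], y[train_mask], hyper,
                    feature_names=names[fam], family=fam, scaler=scaler,
                )
                models[fam] = model
                scores[fam] = model.decision_function(X[test_mask])
            records.append(FoldRecord(repeat=rep, fold=fold_idx, test_index=test_index,
                                      models=models, scores=scores))
    return NestedCVResult(
        plan=plan, families=tuple(families), folds=tuple(records),
        y=y, subject_ids=subject_ids, n_samples=n,
    )


# --------------------------------------------------------------------------- #
# Ensembles
# --------------------------------------------------------------------------- #


def soft_vote(base_scores: Mapping[str, np.ndarray],
              families: Sequence[str] = FAMILIES) -> np.ndarray:
    """Sum of base-model scores, divided by the number of base models so the
    result lives on the base-score scale for the [-1, 1] threshold search."""
    stack = np.stack([np.asarray(base_scores[f], dtype=float) for f in families])
    return stack.sum(axis=0) / stack.shape[0]


def hard_vote(base_labels: Mapping[str, np.ndarray],
              families: Sequence[str] = FAMILIES) -> tuple[np.ndarray, np.ndarray]:
    """Majority label over the (odd number of) base models.

    Returns (labels, vote_fraction); the fraction doubles as a score for AUC.
    """
    if len(families) % 2 == 0:
        raise ValueError("hard voting requires an odd number of base models")
    stack = np.stack([np.asarray(base_labels[f], dtype=int) for f in families])
    frac = stack.mean(axis=0)
    return (frac > 0.5).astype(int), frac


def ensemble_predict(models: Mapping[str, TrainedModel],
                     features_by_family: Mapping[str, pd.DataFrame | np.ndarray],
                     mode: str) -> np.ndarray:
    """Apply fold-matched base models (or the integration model) to new data.

    mode "integration" -> scores of the 324-feature model;
    mode "soft" -> mean of the 5 base scores; mode "hard" -> majority labels.
    """
    def matrix(fam: str) -> np.ndarray:
        X = features_by_family[fam]
        return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)

    if mode == "integration":
        return models[INTEGRATION].decision_function(matrix(INTEGRATION))
    base = {f: models[f].decision_function(matrix(f)) for f in FAMILIES}
    if mode == "soft":
        return soft_vote(base)
    if mode == "hard":
        labels, _ = hard_vote({f: (s >= 0).astype(int) for f, s in base.items()})
        return labels
    raise ValueError(f"unknown ensemble mode {mode!r}")
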