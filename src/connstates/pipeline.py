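"""End-to-end study drivers: named synthetic conditions, features, CV, evaluation.

These are the desk-scale study conditions used throughout the analysis
scripts and the acceptance checks: 98 parcels (14 per network), uniform
baseline coupling 0.30, global amplitude 0.5, network amplitude 0.8,
unit noise; the planted condition raises the VIS-SMN coupling of the
atypical state by +0.4, the anti condition lowers it by 0.4, and the
null condition uses identical baseline and atypical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import CVPlan, NestedCVResult, nested_cv
from .evaluate import EvaluationResult, evaluate_result, summary_table
from .features import extract_cohort_features, family_columns
from .gradients import GradientEmbedding
from .partition import NetworkPartition, make_partition
from .synth import CohortDataset, StateParams, simulate_condition

DEFAULT_PARCELS = 98  # 14 per network
BASE_COUPLING = 0.3
PLANTED_SHIFT = 0.4


def default_partition(parcel_count: int = DEFAULT_PARCELS) -> NetworkPartition:
    return make_partition(parcel_count)


def condition_params(name: str) -> tuple[StateParams, StateParams]:
    """(baseline, atypical) parameters of a named synthetic condition."""
    base = StateParams.uniform(global_amp=0.5, net_amp=0.8,
                               coupling_offdiag=BASE_COUPLING, noise_sd=1.0)
    if name == "null":
        return base, base
    if name == "planted":
        return base, base.with_coupling("VIS", "SMN", BASE_COUPLING + PLANTED_SHIFT)
    if name == "anti":
        return base, base.with_coupling("VIS", "SMN", BASE_COUPLING - PLANTED_SHIFT)
    raise ValueError(f"unknown condition {name!r}")


def simulate_named_condition(name: str, n_subjects: int, t_points: int, seed: int,
                             partition: NetworkPartition | None = None) -> CohortDataset:
    baseline, atypical = condition_params(name)
    if partition is None:
        partition = default_partition()
    return simulate_condition(baseline, atypical, partition, n_subjects, t_points,
                              seed, condition=name)


@dataclass(frozen=True)
class StudyResult:
    """Everything one within-condition study produces."""

    cohort: CohortDataset
    features: pd.DataFrame
    meta: pd.DataFrame
    by_family: Mapping[str, pd.DataFrame]
    reference: GradientEmbedding
    cv: NestedCVResult
    evals: Mapping[str, EvaluationResult]

    @property
    def summary(self) -> pd.DataFrame:
        return summary_table(self.evals)


def run_study(cohort: CohortDataset, plan: CVPlan,
              reference: GradientEmbedding | None = None) -> StudyResult:
    """Extract features, run repeated nested CV, and evaluate all models."""
    features, meta, ref = extract_cohort_features(cohort, reference)
    cols = family_columns(features)
    by_family = {fam: features[cols[fam]] for fam in cols}
    cv = nested_cv(by_family, cohort.labels(), cohort.subject_ids(), plan)
    evals = evaluate_result(cv, cohort.condition)
    return StudyResult(cohort=cohort, features=features, meta=meta, by_family=by_family,
                       reference=ref, cv=cv, evals=evals)
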