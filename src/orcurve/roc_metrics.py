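"""Per-cutoff classification metrics: sensitivity, specificity, Youden J,
and the binary-classifier ROC area.

Treating each dichotomization as a binary classifier of case status, its ROC
"curve" is the two-segment polyline through (0, 0), (1-specificity,
sensitivity), (1, 1); the trapezoidal area under it is (sens + spec) / 2,
which is also the c-statistic of a logistic model with that single binary
predictor.  The identity ``auc = (J + 1) / 2`` makes the AUC-maximizing
cutoff and the Youden-J-maximizing cutoff coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_scan import CutoffGrid, sweep_cells
from .effects import AnalyticSample, TwoByTwoTable

__all__ = [
    "ClassificationPoint",
    "classification_metrics",
    "binary_auc",
    "roc_polyline",
    "auc_by_cutoff",
    "continuous_auc",
]


@dataclass(frozen=True)
class ClassificationPoint:
    """Classifier metrics for one cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    binary_auc: float


def classification_metrics(table: TwoByTwoTable) -> tuple[float, float, float]:
    """(sensitivity, specificity, Youden J) of a 2x2 table.

    sensitivity = a/(a+c), specificity = d/(b+d), J = sens + spec - 1.
    """
    if table.a + table.c == 0:
        raise ValueError("no cases: sensitivity undefined")
    if table.b + table.d == 0:
        raise ValueError("no non-cases: specificity undefined")
    sens = table.a / (table.a + table.c)
    spec = table.d / (table.b + table.d)
    return sens, spec, sens + spec - 1.0


def binary_auc(sensitivity: float, specificity: float) -> float:
    """Trapezoidal area under the two-segment ROC polyline.

    Equals (sensitivity + specificity) / 2.
    """
    return 0.5 * (sensitivity + specificity)


def _metric_arrays(sample: AnalyticSample, grid: CutoffGrid):
    a, b, c, d = sweep_cells(sample, grid.cutoffs)
    n_case, n_ctrl = sample.n_cases, sample.n - sample.n_cases
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("sample must contain both cases and non-cases")
    sens = a / n_case
    spec = d / n_ctrl
    return sens, spec


def roc_polyline(sample: AnalyticSample, grid: CutoffGrid) -> pd.DataFrame:
    """ROC points (1-specificity, sensitivity) tagged by cutoff, in cutoff
    order; the path runs monotonically from near (1, 1) down to near (0, 0)
    as the cutoff increases."""
    sens, spec = _metric_arrays(sample, grid)
    return pd.DataFrame({
        "cutoff": grid.cutoffs,
        "fpr": 1.0 - spec,
        "sensitivity": sens,
    })


def auc_by_cutoff(sample: AnalyticSample, grid: CutoffGrid) -> pd.DataFrame:
    """Per-cutoff sensitivity, specificity, Youden J, and binary AUC."""
    sens, spec = _metric_arrays(sample, grid)
    return pd.DataFrame({
        "cutoff": grid.cutoffs,
        "sensitivity": sens,
        "specificity": spec,
        "youden_j": sens + spec - 1.0,
        "auc": 0.5 * (sens + spec),
    })


def continuous_auc(sample: AnalyticSample) -> float:
    """Whole-sample AUC of the *continuous* exposure (Mann–Whitney form).

    This is the probability that a random case has higher exposure than a
    random non-case (ties counted half).  It is a context statistic for the
    undichotomized exposure and is distinct from the per-cutoff binary AUC
    series, which never exceeds it.
    """
    case = sample.case.astype(bool)
    x1, x0 = sample.exposure[case], sample.exposure[~case]
    if x1.size == 0 or x0.size == 0:
        raise ValueError("sample must contain both cases and non-cases")
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(x1, x0, alternative="two-sided").statistic
    return float(u / (x1.size * x0.size))
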