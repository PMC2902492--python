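"""Cutoff-selection strategies: theory-driven rule evaluation and every
common data-driven selector.

Data-driven selectors fall into two groups.  The first is independent of the
exposure-outcome association: univariate statistics of the exposure (mean,
median, a percentile), the case-median cutoff that balances cases across
exposure groups, the minimum-standard-error cutoff, and the maximum-AUC /
maximum-Youden cutoff.  The second is association-driven — choosing the
cutoff that maximizes, minimizes, or nullifies the odds ratio — which is the
abusable practice this package exists to make visible.  Selecting a cutoff
from the association and reporting it alone biases the estimate and
invalidates the nominal frequentist coverage of its confidence interval;
these selectors are provided for audit and demonstration, not endorsement.

All argmax/argmin selectors break ties toward the smallest cutoff and record
a ``tie_note`` when a tie occurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import roc_metrics
from .curve_scan import CutoffGrid, ORCurve
from .effects import (AnalyticSample, CutoffRule, EffectEstimate,
                      TwoByTwoTable, build_table, odds_ratio)

__all__ = [
    "StrategyResult",
    "evaluate_rules",
    "select_univariate",
    "select_equal_cases",
    "select_min_se",
    "select_extreme_or",
    "select_max_auc",
    "strategy_table",
]

STRATEGIES = (
    "theory", "mean", "median", "percentile", "equal_cases",
    "min_se", "max_auc", "max_youden", "max_or", "min_or", "closest_to_null",
)


@dataclass(frozen=True)
class StrategyResult:
    """One selection strategy's chosen rule and resulting effect estimate.

    ``effect`` is always recomputed from the sample and the chosen rule (or,
    for curve-based selectors, taken from a curve whose entries equal that
    recomputation exactly), never cached from an earlier pass.
    """

    strategy: str
    rule: CutoffRule
    effect: EffectEstimate
    table: TwoByTwoTable
    search_window: tuple[float, float] | None = None
    tie_note: str | None = None

    @property
    def cutoff(self) -> float | None:
        """Scalar cutoff when the rule is scalar, else None."""
        return self.rule.scalar_cutoff


def _result(sample, rule, strategy, window=None, tie_note=None) -> StrategyResult:
    table = build_table(sample, rule)
    return StrategyResult(
        strategy=strategy, rule=rule, effect=odds_ratio(table), table=table,
        search_window=window, tie_note=tie_note,
    )


def evaluate_rules(
    sample: AnalyticSample, rules: list[CutoffRule]
) -> list[StrategyResult]:
    """Evaluate externally chosen (theory-driven) rules, in input order.

    Pure evaluation: no selection happens here.
    """
    return [_result(sample, rule, "theory") for rule in rules]


def select_univariate(
    sample: AnalyticSample, statistic: str, p: float | None = None
) -> StrategyResult:
    """Cutoff at a univariate statistic of the exposure distribution.

    ``statistic`` is ``"mean"``, ``"median"``, or ``"percentile"`` (then
    ``p`` gives the percentile, e.g. 75).
    """
    x = sample.exposure
    if statistic == "mean":
        cutoff = float(np.mean(x))
    elif statistic == "median":
        cutoff = float(np.median(x))
    elif statistic == "percentile":
        if p is None:
            raise ValueError("percentile statistic requires p")
        cutoff = float(np.percentile(x, p))
    else:
        raise ValueError(f"unknown univariate statistic {statistic!r}")
    if np.min(x) == np.max(x):
        raise ValueError("degenerate sample: all exposures equal")
    label = statistic if p is None else f"{p:g}th percentile"
    rule = CutoffRule.scalar(cutoff, label=f"{label} ({cutoff:g})")
    return _result(sample, rule, statistic)


def select_equal_cases(sample: AnalyticSample) -> StrategyResult:
    """Cutoff at the median exposure among cases.

    Splits the cases as evenly as possible between the exposure groups, so
    both groups contribute similar precision.  With an even number of
    distinct case exposures the two central order statistics are averaged
    (so the split is exact); with an odd count the >=-cutoff convention
    places the middle case in the exposed group.
    """
    case_x = sample.exposure[sample.case.astype(bool)]
    if case_x.size < 2:
        raise ValueError("equal-cases selection needs at least two cases")
    cutoff = float(np.median(case_x))
    rule = CutoffRule.scalar(cutoff, label=f"case median ({cutoff:g})")
    return _result(sample, rule, "equal_cases")


def _pick(curve: ORCurve, scores: np.ndarray, strategy: str) -> StrategyResult:
    """Smallest-cutoff argmin over ``scores`` (NaN = ineligible)."""
    if np.all(np.isnan(scores)):
        raise ValueError("curve has no estimable points")
    best = np.nanmin(scores)
    idxs = np.flatnonzero(scores == best)
    i = int(idxs[0])
    tie = None
    if idxs.size > 1:
        tie = (f"{idxs.size} cutoffs tie; smallest "
               f"({curve.cutoffs[i]:g}) selected")
    rule = CutoffRule.scalar(float(curve.cutoffs[i]), label=strategy)
    est = curve.estimate_at(i)
    return StrategyResult(
        strategy=strategy, rule=rule, effect=est, table=curve.table_at(i),
        search_window=curve.grid.window, tie_note=tie,
    )


def select_min_se(curve: ORCurve) -> StrategyResult:
    """The estimable curve point with the smallest log-OR standard error."""
    scores = np.where(curve.estimable, curve.se_log_or, np.nan)
    return _pick(curve, scores, "min_se")


def select_extreme_or(curve: ORCurve, mode: str) -> StrategyResult:
    """Association-driven selection: ``max_or``, ``min_or``, or
    ``closest_to_null`` (smallest |log OR|, symmetric on the log scale)."""
    est = curve.estimable
    if mode == "max_or":
        scores = np.where(est, -curve.or_value, np.nan)
    elif mode == "min_or":
        scores = np.where(est, curve.or_value, np.nan)
    elif mode == "closest_to_null":
        scores = np.where(est, np.abs(curve.log_or), np.nan)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _pick(curve, scores, mode)


def select_max_auc(sample: AnalyticSample, grid: CutoffGrid) -> StrategyResult:
    """The grid cutoff maximizing the binary-classifier AUC.

    By the identity auc = (J + 1)/2 this is also the Youden-J-maximizing
    cutoff; the result is labelled ``max_auc``.
    """
    frame = roc_metrics.auc_by_cutoff(sample, grid)
    auc = frame["auc"].to_numpy()
    best = auc.max()
    idxs = np.flatnonzero(auc == best)
    i = int(idxs[0])
    tie = None
    if idxs.size > 1:
        tie = (f"{idxs.size} cutoffs tie on AUC; smallest "
               f"({frame['cutoff'].iloc[i]:g}) selected")
    cutoff = float(frame["cutoff"].iloc[i])
    rule = CutoffRule.scalar(cutoff, label=f"max AUC ({cutoff:g})")
    res = _result(sample, rule, "max_auc", window=grid.window, tie_note=tie)
    return res


def strategy_table(results: list[StrategyResult]) -> pd.DataFrame:
    """Comparison table: strategy, rule label, cutoff, OR, 95% CI.

    Stored estimates are unrounded; the ``display`` column applies the
    conventional one-decimal OR / two-decimal cutoff presentation.
    """
    rows = []
    for r in results:
        cutoff = r.cutoff
        rows.append({
            "strategy": r.strategy,
            "rule": r.rule.label,
            "cutoff": cutoff,
            "or": r.effect.or_value,
            "ci_low": r.effect.ci_low,
            "ci_high": r.effect.ci_high,
            "estimable": r.effect.estimable,
            "tie_note": r.tie_note or "",
            "display": (
                (f"{cutoff:.2f}: " if cutoff is not None else "")
                + r.effect.format()
            ),
        })
    return pd.DataFrame(rows)
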