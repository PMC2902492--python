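"""Cutoff grids and the odds-ratio curve over them.

The OR curve maps every candidate cutoff to the odds ratio (with pointwise
95% CI) obtained by dichotomizing at that cutoff.  Grids are generated on an
integerized scale — cutoffs are stored internally as integer multiples of the
increment — so an ~11,700-step 0.01-spaced grid accumulates no floating-point
drift; real exposure units appear only at the boundary.

Tables along a grid are computed by sorting the exposures once and sweeping
cumulative case counts; a per-cutoff brute-force path exists in the test
suite as the independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .effects import Z95, AnalyticSample, EffectEstimate, TwoByTwoTable

__all__ = [
    "CutoffGrid",
    "ORCurve",
    "StabilitySummary",
    "make_full_grid",
    "make_window_grid",
    "explicit_grid",
    "scan",
    "stability_profile",
]


@dataclass(frozen=True)
class CutoffGrid:
    """Strictly increasing cutoff values with constant step.

    ``provenance`` records how the grid was built: ``"full_range"``
    (min+increment to max-increment), ``"percentile_window"`` (between two
    exposure percentiles), or ``"explicit"``.
    """

    cutoffs: np.ndarray
    increment: float
    provenance: str = "explicit"
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        cutoffs = np.asarray(self.cutoffs, dtype=float)
        if cutoffs.ndim != 1 or cutoffs.size == 0:
            raise ValueError("grid must contain at least one cutoff")
        if np.any(np.diff(cutoffs) <= 0):
            raise ValueError("grid cutoffs must be strictly increasing")
        object.__setattr__(self, "cutoffs", cutoffs)

    def __len__(self) -> int:
        return int(self.cutoffs.size)


def _int_units(value: float, increment: float) -> int:
    return int(np.rint(value / increment))


def make_full_grid(sample: AnalyticSample, increment: float = 0.01) -> CutoffGrid:
    """Grid from min(exposure)+increment to max(exposure)-increment.

    Both endpoints are included; e.g. exposures spanning [13.36, 130.21] at
    increment 0.01 give a grid from 13.37 to 130.20.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    lo, hi = float(sample.exposure.min()), float(sample.exposure.max())
    if hi - lo <= increment:
        raise ValueError(
            f"exposure range [{lo}, {hi}] does not exceed the increment"
        )
    ilo, ihi = _int_units(lo, increment), _int_units(hi, increment)
    units = np.arange(ilo + 1, ihi)
    return CutoffGrid(units * increment, increment, provenance="full_range")


def make_window_grid(
    sample: AnalyticSample,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
    increment: float = 0.01,
    percentile_method: str = "linear",
) -> CutoffGrid:
    """Grid spanning the [low_pct, high_pct] exposure percentiles.

    ``percentile_method`` is any method accepted by :func:`numpy.percentile`;
    the default ``"linear"`` is the spreadsheet/"type 7" convention
    (interpolation between order statistics).  SAS and other software use
    different conventions (``"weibull"``, ``"averaged_inverted_cdf"``, ...),
    which can shift percentile cutoffs in the last reported digit, so the
    method is a documented option rather than a constant.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if not (0.0 <= low_pct < high_pct <= 100.0):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    p_lo, p_hi = np.percentile(
        sample.exposure, [low_pct, high_pct], method=percentile_method
    )
    ilo = math.ceil(round(p_lo / increment, 9))
    ihi = math.floor(round(p_hi / increment, 9))
    if ihi <= ilo:
        raise ValueError(
            f"window [{p_lo:g}, {p_hi:g}] collapses to fewer than two cutoffs"
        )
    units = np.arange(ilo, ihi + 1)
    return CutoffGrid(
        units * increment, increment,
        provenance="percentile_window", window=(float(low_pct), float(high_pct)),
    )


def explicit_grid(cutoffs, increment: float | None = None) -> CutoffGrid:
    """Wrap user-supplied cutoffs (must be strictly increasing)."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if increment is None:
        increment = float(np.min(np.diff(cutoffs))) if cutoffs.size > 1 else 1.0
    return CutoffGrid(cutoffs, increment, provenance="explicit")


def sweep_cells(
    sample: AnalyticSample, cutoffs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """2x2 cell counts (a, b, c, d) at every cutoff, by a single sort.

    With exposures sorted ascending and cumulative case counts precomputed,
    the number of cases below any cutoff is a binary search away; the four
    cells follow from the case/non-case margins, which are constant.
    """
    order = np.argsort(sample.exposure, kind="stable")
    x_sorted = sample.exposure[order]
    case_sorted = sample.case[order].astype(np.int64)
    cum_cases = np.concatenate([[0], np.cumsum(case_sorted)])
    n, n_case = sample.n, sample.n_cases

    idx = np.searchsorted(x_sorted, cutoffs, side="left")  # records below cutoff
    cases_below = cum_cases[idx]
    a = n_case - cases_below            # exposed cases
    c = cases_below                     # unexposed cases
    b = (n - idx) - a                   # exposed non-cases
    d = idx - cases_below               # unexposed non-cases
    return a, b, c, d


@dataclass(frozen=True)
class ORCurve:
    """Ordered per-cutoff effect estimates and cell counts over a grid.

    Parallel arrays aligned to ``grid.cutoffs``: integer cells ``a, b, c, d``;
    float ``or_value, log_or, se_log_or, ci_low, ci_high`` (NaN where not
    estimable); boolean ``estimable`` and ``correction_applied``.
    """

    grid: CutoffGrid
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    or_value: np.ndarray
    log_or: np.ndarray
    se_log_or: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    estimable: np.ndarray
    correction_applied: np.ndarray
    sample_n: int
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def cutoffs(self) -> np.ndarray:
        return self.grid.cutoffs

    def table_at(self, i: int) -> TwoByTwoTable:
        return TwoByTwoTable(int(self.a[i]), int(self.b[i]),
                             int(self.c[i]), int(self.d[i]))

    def estimate_at(self, i: int) -> EffectEstimate:
        if not self.estimable[i]:
            return EffectEstimate(math.nan, math.nan, math.nan, math.nan,
                                  math.nan, False,
                                  bool(self.correction_applied[i]))
        return EffectEstimate(
            float(self.or_value[i]), float(self.log_or[i]),
            float(self.se_log_or[i]), float(self.ci_low[i]),
            float(self.ci_high[i]), True, bool(self.correction_applied[i]),
        )


def scan(
    sample: AnalyticSample,
    grid: CutoffGrid,
    correction: str = "flag",
    metadata: dict[str, Any] | None = None,
) -> ORCurve:
    """Compute the OR curve over ``grid``.

    Every grid point is kept: cutoffs whose table has a zero cell are carried
    as flagged non-estimable entries (policy ``"flag"``, default) or receive
    the Haldane–Anscombe +0.5 correction (policy ``"haldane"``), so tail
    instability stays visible rather than silently disappearing.
    """
    if correction not in ("flag", "haldane"):
        raise ValueError(f"unknown zero-cell policy {correction!r}")
    a, b, c, d = sweep_cells(sample, grid.cutoffs)

    af, bf, cf, df = (x.astype(float) for x in (a, b, c, d))
    has_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    if correction == "haldane":
        for arr in (af, bf, cf, df):
            arr[has_zero] += 0.5
        corrected = has_zero.copy()
        estimable = np.ones_like(has_zero)
    else:
        corrected = np.zeros_like(has_zero)
        estimable = ~has_zero

    with np.errstate(divide="ignore", invalid="ignore"):
        log_or = np.log(af) + np.log(df) - np.log(bf) - np.log(cf)
        se = np.sqrt(1.0 / af + 1.0 / bf + 1.0 / cf + 1.0 / df)
    log_or[~estimable] = np.nan
    se[~estimable] = np.nan
    return ORCurve(
        grid=grid, a=a, b=b, c=c, d=d,
        or_value=np.exp(log_or), log_or=log_or, se_log_or=se,
        ci_low=np.exp(log_or - Z95 * se), ci_high=np.exp(log_or + Z95 * se),
        estimable=estimable, correction_applied=corrected,
        sample_n=sample.n, metadata=dict(metadata or {}),
    )


@dataclass(frozen=True)
class StabilitySummary:
    """Headline numbers from :func:`stability_profile`."""

    min_se_cutoff: float
    min_se: float
    max_jump: float
    max_jump_interval: tuple[float, float]
    non_estimable_runs: tuple[tuple[float, float], ...]


def stability_profile(curve: ORCurve) -> tuple["pd.DataFrame", StabilitySummary]:
    """Per-cutoff tail-instability diagnostics.

    Returns a frame aligned to the grid with ``delta_log_or`` (absolute change
    in log OR from the previous cutoff, NaN where either endpoint is not
    estimable), ``se_log_or``, and ``estimable``; plus a summary holding the
    minimum-SE cutoff, the largest consecutive jump with its cutoff interval,
    and the cutoff intervals of every non-estimable run.
    """
    import pandas as pd

    est = np.asarray(curve.estimable, dtype=bool)
    if est.sum() < 2:
        raise ValueError("stability profile needs at least two estimable points")

    jumps = np.full(len(curve), np.nan)
    both = est[1:] & est[:-1]
    jumps[1:][both] = np.abs(np.diff(curve.log_or))[both]

    frame = pd.DataFrame({
        "cutoff": curve.cutoffs,
        "delta_log_or": jumps,
        "se_log_or": curve.se_log_or,
        "estimable": est,
    })

    se_masked = np.where(est, curve.se_log_or, np.inf)
    i_min = int(np.argmin(se_masked))
    if np.all(np.isnan(jumps)):
        i_jump, max_jump = 1, math.nan
    else:
        i_jump = int(np.nanargmax(jumps))
        max_jump = float(jumps[i_jump])

    runs: list[tuple[float, float]] = []
    in_run = False
    start = 0.0
    for cut, ok in zip(curve.cutoffs, est):
        if not ok and not in_run:
            in_run, start = True, float(cut)
        elif ok and in_run:
            in_run = False
            runs.append((start, prev))
        prev = float(cut)
    if in_run:
        runs.append((start, prev))

    summary = StabilitySummary(
        min_se_cutoff=float(curve.cutoffs[i_min]),
        min_se=float(curve.se_log_or[i_min]),
        max_jump=max_jump,
        max_jump_interval=(float(curve.cutoffs[i_jump - 1]),
                           float(curve.cutoffs[i_jump])),
        non_estimable_runs=tuple(runs),
    )
    return frame, summary
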