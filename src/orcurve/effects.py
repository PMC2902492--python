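"""Dichotomization, 2x2 tables, and closed-form odds-ratio estimation.

A continuous exposure is split at a cutoff into "exposed" (value >= cutoff)
and "unexposed"; the association with a binary outcome is then summarized by
the cross-product odds ratio of the induced 2x2 table with a Wald confidence
interval on the log scale.  The cross-product estimate is algebraically
identical to the maximum-likelihood coefficient of a logistic regression with
the single binary exposure indicator, so no iterative fit is needed.

The ``exposed = exposure >= cutoff`` convention is fixed, not configurable:
every downstream module (curve scans, selectors, ROC metrics) relies on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Z95",
    "AnalyticSample",
    "CutoffRule",
    "TwoByTwoTable",
    "EffectEstimate",
    "dichotomize",
    "build_table",
    "odds_ratio",
]

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for every Wald interval in the package.
Z95 = 1.959964


@dataclass(frozen=True)
class AnalyticSample:
    """Paired continuous exposures and binary case indicators.

    Parameters
    ----------
    exposure
        Continuous measurement per record (exposure units, e.g. kg/m^2).
    case
        Binary outcome indicator per record; 1 marks a case.
    stratum
        Optional categorical label per record (e.g. ``"M"`` / ``"F"``),
        required only by stratum-specific cutoff rules.
    age
        Optional non-negative age in years per record, required only by
        age-band cutoff rules.
    """

    exposure: np.ndarray
    case: np.ndarray
    stratum: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        exposure = np.asarray(self.exposure, dtype=float)
        case = np.asarray(self.case)
        if exposure.ndim != 1 or case.ndim != 1:
            raise ValueError("exposure and case must be one-dimensional")
        if exposure.size != case.size:
            raise ValueError(
                f"exposure has {exposure.size} records but case has {case.size}"
            )
        if exposure.size < 1:
            raise ValueError("sample must contain at least one record")
        if not np.all(np.isfinite(exposure)):
            raise ValueError("exposure contains missing or non-finite values")
        if not np.isin(case, (0, 1)).all():
            raise ValueError("case indicators must be 0 or 1")
        object.__setattr__(self, "exposure", exposure)
        object.__setattr__(self, "case", case.astype(np.int8))
        if self.stratum is not None:
            stratum = np.asarray(self.stratum)
            if stratum.size != exposure.size:
                raise ValueError("stratum labels must match record count")
            object.__setattr__(self, "stratum", stratum)
        if self.age is not None:
            age = np.asarray(self.age, dtype=float)
            if age.size != exposure.size:
                raise ValueError("age must match record count")
            if np.any(age < 0) or not np.all(np.isfinite(age)):
                raise ValueError("ages must be finite and non-negative")
            object.__setattr__(self, "age", age)

    @property
    def n(self) -> int:
        return int(self.exposure.size)

    @property
    def n_cases(self) -> int:
        return int(self.case.sum())


@dataclass(frozen=True)
class CutoffRule:
    """A scalar, stratum-specific, or age-specific dichotomization rule.

    Build instances with :meth:`scalar`, :meth:`by_stratum`, or
    :meth:`by_age_bands` rather than the raw constructor.
    """

    kind: str
    scalar_cutoff: float | None = None
    stratum_map: Mapping[str, float] | None = None
    age_bands: tuple[tuple[tuple[float, float], float], ...] | None = None
    label: str = ""

    @classmethod
    def scalar(cls, cutoff: float, label: str = "") -> "CutoffRule":
        if not math.isfinite(cutoff):
            raise ValueError("cutoff must be finite")
        return cls(kind="scalar", scalar_cutoff=float(cutoff),
                   label=label or f"{cutoff:g}")

    @classmethod
    def by_stratum(cls, mapping: Mapping[str, float], label: str = "") -> "CutoffRule":
        if not mapping:
            raise ValueError("stratum_map must not be empty")
        if not all(math.isfinite(v) for v in mapping.values()):
            raise ValueError("all stratum cutoffs must be finite")
        return cls(kind="by_stratum", stratum_map=dict(mapping),
                   label=label or str(dict(mapping)))

    @classmethod
    def by_age_bands(
        cls,
        bands: Sequence[tuple[tuple[float, float], float]],
        label: str = "",
    ) -> "CutoffRule":
        """``bands`` is an ordered list of ((age_low, age_high), cutoff) with
        closed, non-overlapping, increasing intervals; ``inf`` is allowed as
        the final upper bound (open-ended "older than" band)."""
        bands = tuple(((float(lo), float(hi)), float(c)) for (lo, hi), c in bands)
        if not bands:
            raise ValueError("age_bands must not be empty")
        for (lo, hi), c in bands:
            if lo > hi:
                raise ValueError(f"age band ({lo}, {hi}) is inverted")
            if not math.isfinite(c):
                raise ValueError("all age-band cutoffs must be finite")
        for ((_, hi_prev), _), ((lo_next, _), _) in zip(bands, bands[1:]):
            if lo_next <= hi_prev:
                raise ValueError("age bands must be ordered and non-overlapping")
        return cls(kind="by_age_band", age_bands=bands,
                   label=label or "age-specific")

    def cutoffs_for(self, sample: AnalyticSample) -> np.ndarray:
        """Per-record applicable cutoff under this rule."""
        if self.kind == "scalar":
            return np.full(sample.n, self.scalar_cutoff, dtype=float)
        if self.kind == "by_stratum":
            if sample.stratum is None:
                raise ValueError(
                    f"rule {self.label!r} is stratum-specific but the sample "
                    "has no stratum labels"
                )
            out = np.empty(sample.n, dtype=float)
            labels = sample.stratum
            for s in np.unique(labels):
                key = s.item() if hasattr(s, "item") else s
                if key not in self.stratum_map:
                    raise KeyError(
                        f"stratum {key!r} present in sample but missing from "
                        f"rule {self.label!r}"
                    )
                out[labels == s] = self.stratum_map[key]
            return out
        if self.kind == "by_age_band":
            if sample.age is None:
                raise ValueError(
                    f"rule {self.label!r} is age-specific but the sample has "
                    "no ages"
                )
            return self._age_band_cutoffs(sample.age)
        raise ValueError(f"unknown rule kind {self.kind!r}")

    def _age_band_cutoffs(self, age: np.ndarray) -> np.ndarray:
        lows = np.array([lo for (lo, _), _ in self.age_bands])
        highs = np.array([hi for (_, hi), _ in self.age_bands])
        cuts = np.array([c for _, c in self.age_bands])
        # distance 0 inside a band; otherwise distance to the nearer edge
        dist = np.maximum.reduce([
            lows[None, :] - age[:, None],
            age[:, None] - highs[None, :],
            np.zeros((age.size, lows.size)),
        ])
        band_idx = np.argmin(dist, axis=1)
        outside = dist[np.arange(age.size), band_idx] > 0
        if outside.any():
            logger.warning(
                "%d record(s) have ages outside every band of rule %r; "
                "assigned to the nearest band",
                int(outside.sum()), self.label,
            )
        return cuts[band_idx]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Cell counts induced by one dichotomization.

    ``a`` exposed cases, ``b`` exposed non-cases, ``c`` unexposed cases,
    ``d`` unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with Wald 95% CI on the log scale.

    ``estimable`` is False when a zero cell makes the cross-product ratio or
    its standard error undefined and no continuity correction was applied; the
    numeric fields are then NaN.  Stored values are never rounded; display
    rounding happens only in report layers.
    """

    or_value: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    estimable: bool
    correction_applied: bool = False

    def format(self) -> str:
        """Display form, ORs and CI bounds to one decimal."""
        if not self.estimable:
            return "not estimable"
        return f"{self.or_value:.1f} ({self.ci_low:.1f}, {self.ci_high:.1f})"


_NOT_ESTIMABLE = EffectEstimate(
    or_value=math.nan, log_or=math.nan, se_log_or=math.nan,
    ci_low=math.nan, ci_high=math.nan, estimable=False,
)


def dichotomize(sample: AnalyticSample, rule: CutoffRule) -> np.ndarray:
    """Boolean exposed indicator: ``exposure >= applicable cutoff``."""
    return sample.exposure >= rule.cutoffs_for(sample)


def build_table(sample: AnalyticSample, rule: CutoffRule) -> TwoByTwoTable:
    """Tabulate the dichotomization against case status."""
    exposed = dichotomize(sample, rule)
    case = sample.case.astype(bool)
    a = int(np.count_nonzero(exposed & case))
    b = int(np.count_nonzero(exposed & ~case))
    c = int(np.count_nonzero(~exposed & case))
    d = int(np.count_nonzero(~exposed & ~case))
    return TwoByTwoTable(a, b, c, d)


def odds_ratio(table: TwoByTwoTable, correction: str = "flag") -> EffectEstimate:
    """Cross-product odds ratio ``ad/bc`` with a Wald 95% CI.

    ``se_log_or = sqrt(1/a + 1/b + 1/c + 1/d)`` (Woolf), and the interval is
    ``exp(log OR +/- 1.959964 * se)``.  Zero-cell policy:

    - ``"flag"`` (default): any zero cell yields a non-estimable result;
    - ``"haldane"``: 0.5 is added to all four cells first
      (Haldane–Anscombe) and ``correction_applied`` is set.
    """
    if correction not in ("flag", "haldane"):
        raise ValueError(f"unknown zero-cell policy {correction!r}")
    a, b, c, d = (float(x) for x in table.cells())
    corrected = False
    if min(a, b, c, d) == 0.0:
        if correction == "flag":
            return _NOT_ESTIMABLE
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(
        or_value=math.exp(log_or),
        log_or=log_or,
        se_log_or=se,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        estimable=True,
        correction_applied=corrected,
    )
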