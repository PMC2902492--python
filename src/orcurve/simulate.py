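"""Synthetic exposure-outcome generators and selection-bias experiments.

The generators emulate the structure of a large cross-sectional sample with
a right-skewed, BMI-like continuous exposure and a roughly balanced binary
outcome, so every analytic module is testable without any external download.
Three outcome mechanisms are supported:

- ``logistic``: P(case | x) = expit(beta0 + beta1 * g(x)) for a monotone
  transform g (identity, or a saturating ramp that plateaus above a knot —
  the saturation is what makes the dichotomized OR attenuate as the cutoff
  rises);
- ``threshold``: a step in risk at an exposure value tau, whose large-sample
  2x2 odds ratio at cutoff tau is known in closed form;
- ``null``: constant case probability, no association.

Randomness discipline: every generator is a pure function of its config,
whose integer ``seed`` feeds ``numpy.random.default_rng``.  Replicated
experiments derive the seed for replicate ``r`` from
``SeedSequence([root_seed, r])``, so replicates are independent,
reproducible, and order-insensitive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .curve_scan import make_window_grid, scan
from .effects import AnalyticSample, CutoffRule, build_table, odds_ratio
from .selectors import select_extreme_or

__all__ = [
    "LognormalExposure",
    "LogisticOutcome",
    "ThresholdOutcome",
    "NullOutcome",
    "SimulationConfig",
    "simulate_sample",
    "nhanes_like_fixture",
    "NHANES_LIKE_N",
    "pbis_experiment",
]

#: Scale of the large cross-sectional sample the default fixture emulates.
NHANES_LIKE_N = 19_340


@dataclass(frozen=True)
class LognormalExposure:
    """Shifted lognormal: ``shift + LogNormal(mu_log, sigma_log)``.

    Median = shift + exp(mu_log); mean = shift + exp(mu_log + sigma_log^2/2).
    """

    mu_log: float
    sigma_log: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.shift + rng.lognormal(self.mu_log, self.sigma_log, size=n)


@dataclass(frozen=True)
class LogisticOutcome:
    """P(case | x) = expit(beta0 + beta1 * g(x)).

    ``transform``: ``"identity"`` (g(x) = x) or ``"saturating"``
    (g(x) = min(x, knot), risk flat above the knot).
    """

    beta0: float
    beta1: float
    transform: str = "identity"
    knot: float | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "saturating"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "saturating" and self.knot is None:
            raise ValueError("saturating transform requires a knot")

    def case_prob(self, x: np.ndarray) -> np.ndarray:
        g = x if self.transform == "identity" else np.minimum(x, self.knot)
        return expit(self.beta0 + self.beta1 * g)


@dataclass(frozen=True)
class ThresholdOutcome:
    """Step risk: P(case) = p_low below tau, p_high at or above tau.

    The population odds ratio of the 2x2 table dichotomized exactly at tau is
    ``(p_high / (1 - p_high)) / (p_low / (1 - p_low))``.
    """

    p_low: float
    p_high: float
    tau: float

    def __post_init__(self) -> None:
        for p in (self.p_low, self.p_high):
            if not 0.0 < p < 1.0:
                raise ValueError("probabilities must be in (0, 1)")

    def case_prob(self, x: np.ndarray) -> np.ndarray:
        return np.where(x >= self.tau, self.p_high, self.p_low)

    @property
    def true_or(self) -> float:
        return (self.p_high / (1 - self.p_high)) / (self.p_low / (1 - self.p_low))


@dataclass(frozen=True)
class NullOutcome:
    """Constant case probability: no exposure-outcome association."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")

    def case_prob(self, x: np.ndarray) -> np.ndarray:
        return np.full(x.shape, self.p)


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    exposure: LognormalExposure
    outcome: LogisticOutcome | ThresholdOutcome | NullOutcome
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")


def simulate_sample(config: SimulationConfig) -> AnalyticSample:
    """Draw one sample; deterministic given the config (seed included)."""
    rng = np.random.default_rng(config.seed)
    x = config.exposure.draw(config.n, rng)
    p = config.outcome.case_prob(x)
    case = (rng.random(config.n) < p).astype(np.int8)
    return AnalyticSample(exposure=x, case=case)


# Frozen calibration of the BMI-like fixture.  The exposure is a shifted
# lognormal with median ~27 and mean ~28 (long right tail); the outcome risk
# rises with exposure and saturates above the knot, which makes the windowed
# OR curve fall as the cutoff increases.  Parameters are constants in source,
# never re-fit at test time, so fixture assertions are stable.
_FIXTURE_EXPOSURE = LognormalExposure(
    mu_log=float(np.log(14.0)), sigma_log=0.3716, shift=13.0
)
_FIXTURE_OUTCOME = LogisticOutcome(
    beta0=-5.487, beta1=0.22, transform="saturating", knot=25.0
)


def nhanes_like_fixture(seed: int, n: int = NHANES_LIKE_N) -> AnalyticSample:
    """The package's standard large-sample fixture.

    Right-skewed exposure (mean ~28, median ~27), case prevalence ~0.46, and
    a positive association that attenuates as the cutoff rises (the windowed
    OR curve decreases from the 25th- toward the 75th-percentile cutoff).
    ``n`` defaults to the full cross-sectional scale and may be reduced.
    """
    return simulate_sample(SimulationConfig(
        n=n, exposure=_FIXTURE_EXPOSURE, outcome=_FIXTURE_OUTCOME, seed=seed,
    ))


def _child_seed(root_seed: int, r: int) -> int:
    # documented counter scheme: replicate r draws from SeedSequence([seed, r])
    return int(np.random.SeedSequence([root_seed, r]).generate_state(1)[0] % (2**31))


def pbis_experiment(
    config: SimulationConfig,
    window: tuple[float, float] = (25.0, 75.0),
    replicates: int = 100,
    seed: int = 0,
    fixed_cutoff: float | str = "median",
    true_or: float | None = None,
    increment: float = 0.05,
) -> pd.DataFrame:
    """Quantify selection inflation versus an honest pre-registered cutoff.

    Per replicate: draw a fresh sample, scan the OR curve over the
    ``window`` percentile grid, record the window-maximizing and -minimizing
    ORs and their cutoffs, and the OR/CI at a *fixed* cutoff chosen without
    looking at the association (an exposure value, or ``"median"`` for the
    per-replicate exposure median).  ``covers_truth`` flags whether the
    fixed-cutoff CI contains the generating model's odds ratio (``true_or``;
    defaults to 1 for a null outcome, the step odds ratio for a threshold
    outcome at its tau).

    Under a null model the fixed-cutoff CI covers 1 at its nominal 95% rate
    while the max-OR selection averages above 1 — the selection-bias
    mechanism made measurable.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    if true_or is None:
        if isinstance(config.outcome, NullOutcome):
            true_or = 1.0
        elif isinstance(config.outcome, ThresholdOutcome):
            true_or = config.outcome.true_or
        else:
            raise ValueError("true_or must be given for a logistic outcome")

    rows = []
    for r in range(replicates):
        rep_cfg = dataclasses.replace(config, seed=_child_seed(seed, r))
        sample = simulate_sample(rep_cfg)
        grid = make_window_grid(sample, window[0], window[1], increment)
        curve = scan(sample, grid)
        hi = select_extreme_or(curve, "max_or")
        lo = select_extreme_or(curve, "min_or")
        cut = (float(np.median(sample.exposure))
               if fixed_cutoff == "median" else float(fixed_cutoff))
        fixed = odds_ratio(build_table(sample, CutoffRule.scalar(cut)))
        rows.append({
            "replicate": r,
            "max_or": hi.effect.or_value,
            "max_or_cutoff": hi.cutoff,
            "min_or": lo.effect.or_value,
            "min_or_cutoff": lo.cutoff,
            "fixed_cutoff": cut,
            "fixed_or": fixed.or_value,
            "fixed_ci_low": fixed.ci_low,
            "fixed_ci_high": fixed.ci_high,
            "covers_truth": bool(
                fixed.estimable
                and fixed.ci_low <= true_or <= fixed.ci_high
            ),
        })
    return pd.DataFrame(rows)
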