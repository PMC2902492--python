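"""Independent oracles for the test suite.

Everything here is deliberately written without reusing the package's
computational paths: the logistic fit is a hand-rolled IRLS on the aggregated
2x2 data, and the table counter is a per-record Python loop.
"""

from __future__ import annotations

import math

import numpy as np


def irls_logistic_or(a: int, b: int, c: int, d: int,
                     tol: float = 1e-12, max_iter: int = 200):
    """Logistic MLE for a single binary covariate, by Newton/IRLS.

    Model: logit P(case) = beta0 + beta1 * exposed, fitted on the two
    aggregated rows (exposed: a of a+b are cases; unexposed: c of c+d).
    Returns (or_hat, se_beta1) where se is the Wald standard error from the
    inverse observed information.
    """
    X = np.array([[1.0, 1.0], [1.0, 0.0]])
    y = np.array([float(a), float(c)])
    m = np.array([float(a + b), float(c + d)])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = m * p * (1.0 - p)
        grad = X.T @ (y - m * p)
        info = X.T @ (X * w[:, None])
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = m * p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return math.exp(beta[1]), math.sqrt(cov[1, 1])


def loop_count_table(exposure, case, cutoff: float):
    """Per-record loop tabulation of the 2x2 table at one cutoff."""
    a = b = c = d = 0
    for x, y in zip(exposure, case):
        if x >= cutoff:
            if y:
                a += 1
            else:
                b += 1
        else:
            if y:
                c += 1
            else:
                d += 1
    return a, b, c, d


def loop_or_ci(a, b, c, d, z: float = 1.959964):
    """Direct cross-product OR and Wald CI, no shared code with the package."""
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, se, lo, hi
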