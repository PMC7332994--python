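"""Shared nonlinear-regression statistics.

Linearized (Jacobian-based) confidence intervals for least-squares
estimates: with residual vector e (n points, p parameters), the error
variance is s2 = SSE/(n-p), the covariance of the estimates is
s2 * (J'J)^-1, and the 100(1-alpha)% interval on parameter i is
beta_i +/- t_{1-alpha/2, n-p} * se_i.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or produced an inadmissible result."""


def jacobian_ci(
    params: np.ndarray,
    jac: np.ndarray,
    residuals: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-parameter confidence intervals from the estimated Jacobian.

    Returns an array of shape (p, 2) of (lower, upper) bounds. Degenerate
    problems (n <= p, or a numerically singular J'J) yield infinite bounds
    for the affected parameters rather than raising.
    """
    params = np.asarray(params, dtype=float)
    jac = np.asarray(jac, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    n, p = jac.shape
    dof = n - p
    if dof <= 0:
        return np.column_stack([np.full(p, -np.inf), np.full(p, np.inf)])
    sse = float(residuals @ residuals)
    s2 = sse / dof
    # pinv guards against Jacobian columns that became degenerate at the optimum
    cov = s2 * np.linalg.pinv(jac.T @ jac)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    tval = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return np.column_stack([params - tval * se, params + tval * se])
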