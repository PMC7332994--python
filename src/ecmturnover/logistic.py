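"""Logistic characterization of protein accumulation curves.

The background-subtracted signal F(t) of each embryo is fitted with the
four-parameter Hill form

    F(t) = Span / (1 + 10^(HillSlope * (LogEC50 - t))) + Bottom

which is mathematically equivalent to a logistic with baseline:

    F(t) = K / (1 + exp(r * (t_i - t))) + B

under K = Span, t_i = LogEC50, r = HillSlope * ln(10), B = Bottom.
B absorbs residual background after control subtraction, so the protein
level proper is the baseline-free logistic

    P_L(t) = K / (1 + exp(r * (t_i - t)))

which runs from 0 to the carrying capacity K with inflection (and maximal
accumulation rate r*K/4) at t = t_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._stats import FitError, jacobian_ci
from .traces import FluorescenceTrace

LN10 = math.log(10.0)


@dataclass
class LogisticFit:
    """Fitted logistic parameters with the raw Hill-form estimates.

    ``ci95`` maps parameter names (``k``, ``r``, ``t_i``, ``b``) to
    (lower, upper) 95% confidence bounds obtained from the estimated
    Jacobian at the optimum.
    """

    k: float
    r: float
    t_i: float
    b: float
    hill_span: float
    hill_slope: float
    hill_logec50: float
    hill_bottom: float
    sse: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_points: int = 0


def hill_curve(t, span, slope, logec50, bottom):
    """The four-parameter Hill form evaluated at times t."""
    t = np.asarray(t, dtype=float)
    return span / (1.0 + 10.0 ** (slope * (logec50 - t))) + bottom


def logistic_params_from_hill(span, slope, logec50, bottom):
    """(K, r, t_i, B) from (Span, HillSlope, LogEC50, Bottom)."""
    return span, slope * LN10, logec50, bottom


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    span0 = float(np.max(y) - np.min(y))
    bottom0 = float(np.min(y))
    half = bottom0 + span0 / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        # linear interpolation of the half-range crossing time
        t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
        tc = t0 + (half - y0) * (t1 - t0) / (y1 - y0) if y1 != y0 else t1
    elif len(above) and above[0] == 0:
        tc = float(t[0])  # rise mostly before the record: inflection at/before start
    else:
        tc = float(t[len(t) // 2])
    # slope of the range-normalized curve at the crossing; logistic slope
    # there is r/4, hence HillSlope = 4 * dFn/dt / ln10
    dt = max((t[-1] - t[0]) / 10.0, np.min(np.diff(t)))
    sel = (t >= tc - dt) & (t <= tc + dt)
    if np.count_nonzero(sel) >= 2 and span0 > 0:
        g = np.polyfit(t[sel], y[sel], 1)[0] / span0
        slope0 = max(4.0 * g / LN10, 1e-3)
    else:
        slope0 = 0.2
    return np.array([max(span0, 1e-9), slope0, tc, bottom0])


def fit_logistic(
    trace: FluorescenceTrace, fix_bottom: float | None = None
) -> LogisticFit:
    """Least-squares Hill/logistic fit of a background-subtracted trace.

    Span and HillSlope are constrained positive (accumulation curves are
    increasing by construction); a trace whose best fit pins the slope at
    its lower bound is reported as a failed fit. Confidence intervals for
    the logistic parameters are linearized intervals transformed from the
    Hill-form estimates (the r interval is the HillSlope interval scaled
    by ln 10).

    ``fix_bottom`` pins the baseline B (e.g. at 0 for background-free
    simulated curves, whose saturating shape can otherwise push the
    unconstrained fit onto the exponential-limit ridge K -> inf,
    B -> -inf).
    """
    t, y = trace.time_h, trace.intensity
    if len(t) < 10:
        raise ValueError(f"logistic fit needs >= 10 points, got {len(t)}")
    x0 = _initial_guess(t, y)

    if fix_bottom is None:
        lb = np.array([1e-12, 1e-12, -np.inf, -np.inf])

        def resid(p):
            return hill_curve(t, *p) - y
    else:
        x0 = x0[:3]
        lb = np.array([1e-12, 1e-12, -np.inf])

        def resid(p):
            return hill_curve(t, p[0], p[1], p[2], fix_bottom) - y

    res = least_squares(resid, np.clip(x0, lb + 1e-11, None),
                        bounds=(lb, np.inf), max_nfev=5000)
    if not res.success:
        raise FitError("logistic fit did not converge")
    span, slope, logec50 = res.x[:3]
    bottom = fix_bottom if fix_bottom is not None else res.x[3]
    if slope <= 1e-10 or span <= 1e-10:
        raise FitError(
            "logistic fit degenerate (non-increasing trace: fitted r <= 0)"
        )
    ci = jacobian_ci(res.x, res.jac, res.fun)
    k, r, t_i, b = logistic_params_from_hill(span, slope, logec50, bottom)
    ci95 = {
        "k": (ci[0, 0], ci[0, 1]),
        "r": (ci[1, 0] * LN10, ci[1, 1] * LN10),
        "t_i": (ci[2, 0], ci[2, 1]),
        "b": (ci[3, 0], ci[3, 1]) if fix_bottom is None else (bottom, bottom),
    }
    return LogisticFit(
        k=float(k), r=float(r), t_i=float(t_i), b=float(b),
        hill_span=float(span), hill_slope=float(slope),
        hill_logec50=float(logec50), hill_bottom=float(bottom),
        sse=float(res.fun @ res.fun), ci95=ci95, n_points=len(t),
    )


def protein_curve(fit: LogisticFit, t_grid) -> np.ndarray:
    """Baseline-free protein level P_L(t) = K / (1 + exp(r (t_i - t)))."""
    t = np.asarray(t_grid, dtype=float)
    return fit.k / (1.0 + np.exp(fit.r * (fit.t_i - t)))
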