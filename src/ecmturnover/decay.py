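"""Intervention-based half-life estimators used to validate the model.

Once synthesis has ceased (S_p = 0) the turnover ODE reduces to pure
first-order decay dP/dt = -D_p P, so D_p can be read out from

* a pulse-chase trace: a line fitted through the post-peak window gives
  the slope dP/dt, and D_p = -slope / P(window start);
* two retention timepoints: D_p = ln(level_a/level_b) / (t_b - t_a);
* a photoconverted-channel decay trace: an exponential fit c0 e^(-d t).

Pulse-chase tends to underestimate turnover (residual synthesis from
driver perdurance); photoconversion decay conflates degradation with
unbinding/diffusion and tends to overestimate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from ._stats import FitError, jacobian_ci
from .traces import FluorescenceTrace

LN2 = math.log(2.0)


@dataclass
class DecayFit:
    """A decay-rate estimate with its provenance.

    ``decaying`` is False when the data show no decay (non-negative
    slope / rate pinned at zero); ``d_p`` and ``half_life_h`` are NaN in
    that case.
    """

    d_p: float
    half_life_h: float
    method: str  # "pulse_chase_linear" | "two_point" | "exponential"
    window: tuple[float, float]
    slope: float = float("nan")
    p0: float = float("nan")
    ci95: tuple[float, float] | None = None
    decaying: bool = True


def pulse_chase_rate(
    trace: FluorescenceTrace,
    window: tuple[float, float] = (15.0, 20.0),
    reference: str = "start",
) -> DecayFit:
    """Linear decay-rate estimate over a post-peak window (default 15-20 h).

    The trace values in the window are fitted with a line and
    D_p = -slope / p0, where p0 is the fitted level at the window start
    (``reference="start"``, the rate at t = window start) or the mean
    level over the window (``reference="mean"``). For an exponential
    decay the secant slope matches -D_p times the *mean* level exactly,
    so "mean" is unbiased for pure decay while "start" underestimates
    D_p by ~D_p*(t_hi-t_lo)/2 — a conservative rate readout. A
    non-negative slope is flagged (``decaying=False``) with an undefined
    half-life. The CI on D_p propagates the slope's standard error at
    fixed p0.
    """
    t_lo, t_hi = window
    if t_lo >= t_hi:
        raise ValueError("window start must precede window end")
    if trace.time_h[0] > t_lo or trace.time_h[-1] < t_hi:
        raise ValueError(
            f"trace [{trace.time_h[0]}, {trace.time_h[-1]}] h does not cover "
            f"the window [{t_lo}, {t_hi}] h"
        )
    sel = (trace.time_h >= t_lo) & (trace.time_h <= t_hi)
    t, y = trace.time_h[sel], trace.intensity[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 samples inside the window")
    if reference not in ("start", "mean"):
        raise ValueError(f"unknown reference {reference!r}")
    lin = stats.linregress(t, y)
    if reference == "start":
        p0 = lin.intercept + lin.slope * t_lo
    else:
        p0 = float(np.mean(y))
    if p0 <= 0:
        raise ValueError(f"level at window start must be positive, got {p0:.3g}")
    if lin.slope >= 0:
        return DecayFit(
            d_p=float("nan"), half_life_h=float("nan"),
            method="pulse_chase_linear", window=window,
            slope=float(lin.slope), p0=float(p0), decaying=False,
        )
    d_p = -lin.slope / p0
    se_d = lin.stderr / p0
    tval = stats.t.ppf(0.975, len(t) - 2)
    return DecayFit(
        d_p=float(d_p), half_life_h=LN2 / d_p,
        method="pulse_chase_linear", window=window,
        slope=float(lin.slope), p0=float(p0),
        ci95=(float(d_p - tval * se_d), float(d_p + tval * se_d)),
    )


def two_point_half_life(
    level_a: float, level_b: float, t_a: float = 24.0, t_b: float = 36.0
) -> float:
    """Half-life from the retention between two timepoints.

    half-life = (t_b - t_a) * ln2 / ln(level_a / level_b). Defaults match
    the dissected-tissue comparison at 24 and 36 h after egg laying;
    invariant under common rescaling of both levels.
    """
    if t_b <= t_a:
        raise ValueError("t_b must exceed t_a")
    if level_a <= 0 or level_b <= 0:
        raise ValueError("levels must be positive")
    if level_b >= level_a:
        raise ValueError("no decay: level_b must be below level_a")
    return (t_b - t_a) * LN2 / math.log(level_a / level_b)


def exp_decay_half_life(
    trace: FluorescenceTrace, floor: bool = False
) -> DecayFit:
    """Exponential fit of the post-peak decay of a photoconverted channel.

    Fits c0 * exp(-d (t - t_peak)) (plus an optional constant floor for
    an immobile fraction) to the segment from the trace maximum onward;
    needs at least 6 post-peak points. A rate pinned at zero (constant or
    increasing signal) is flagged with ``decaying=False``.
    """
    i0 = int(np.argmax(trace.intensity))
    t = trace.time_h[i0:] - trace.time_h[i0]
    y = trace.intensity[i0:]
    if len(t) < 6:
        raise ValueError(f"need >= 6 post-conversion points, got {len(t)}")
    c00 = max(float(y[0]), 1e-9)
    tail = float(np.mean(y[-max(2, len(y) // 5):]))
    if 0 < tail < c00:
        d0 = math.log(c00 / tail) / float(t[-1])
    else:
        d0 = 0.1

    if floor:
        def model(p):
            return p[0] * np.exp(-p[1] * t) + p[2]
        x0 = np.array([c00 - max(tail, 0.0), max(d0, 1e-3), max(tail, 0.0)])
        lb = [1e-12, 0.0, 0.0]
    else:
        def model(p):
            return p[0] * np.exp(-p[1] * t)
        x0 = np.array([c00, max(d0, 1e-3)])
        lb = [1e-12, 0.0]

    res = least_squares(lambda p: model(p) - y, x0, bounds=(lb, np.inf))
    if not res.success:
        raise FitError("exponential decay fit did not converge")
    d = float(res.x[1])
    window = (float(trace.time_h[i0]), float(trace.time_h[-1]))
    # no meaningful decay if the fitted loss over the whole window is ~zero
    if d * (window[1] - window[0]) < 1e-4:
        return DecayFit(
            d_p=float("nan"), half_life_h=float("nan"), method="exponential",
            window=window, p0=float(res.x[0]), decaying=False,
        )
    ci = jacobian_ci(res.x, res.jac, res.fun)
    return DecayFit(
        d_p=d, half_life_h=LN2 / d, method="exponential", window=window,
        p0=float(res.x[0]), ci95=(float(ci[1, 0]), float(ci[1, 1])),
    )
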