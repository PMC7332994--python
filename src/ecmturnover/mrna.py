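"""Developmental mRNA series: stage-label time conversion and interpolation.

Stage-binned RNA-seq series (2-h embryonic bins plus larval stage labels,
in the style of the modENCODE temporal expression data) are converted onto
the protein-imaging time axis, whose origin t = 0 h is embryonic stage 15
(~11 h 20 min after egg laying). Embryo birth is t = -10 h ("embryo
00-02h"), first instar is t = 14 h and second instar t = 38 h.

The coarse series is then interpolated by a ramp-blended pair of
Gaussians,

    M(t) = (1 - q(t)) * M1(t) + q(t) * M2(t)
    M1(t) = a1 * exp(-((t - b1)/c1)^2)
    M2(t) = a2 * exp(-((t - b2)/c2)^2) + d2

with q(t) a ramp from 0 to 1 between two breakpoints, yielding a smooth
M(t) at the 2-min resolution of the protein movies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._stats import FitError

_EMBRYO_RE = re.compile(r"^embryo (\d{2})-(\d{2})h$")

#: Larval stage labels on the converted time axis (hours from stage 15).
LARVAL_TIMES = {"larva L1": 14.0, "larva L2": 38.0}

#: The standard label vocabulary: twelve 2-h embryonic bins plus L1 and L2.
MODENCODE_LABELS = tuple(
    f"embryo {lo:02d}-{lo + 2:02d}h" for lo in range(0, 24, 2)
) + ("larva L1", "larva L2")


def convert_modencode_time(label: str) -> float:
    """Convert a stage label to hours from embryonic stage 15.

    An embryonic bin "embryo XX-YYh" maps to its lower bound minus 10 h
    (so "embryo 00-02h" -> -10 h and "embryo 10-12h" -> 0 h); "larva L1"
    maps to 14 h and "larva L2" to 38 h. Unknown labels raise ValueError.
    """
    m = _EMBRYO_RE.match(label)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi - lo != 2:
            raise ValueError(f"embryonic bins are 2 h wide, got {label!r}")
        return float(lo - 10)
    if label in LARVAL_TIMES:
        return LARVAL_TIMES[label]
    raise ValueError(f"unsupported stage label {label!r}")


@dataclass
class MrnaSeries:
    """Stage-binned mRNA levels with converted times (hours from stage 15)."""

    labels: list[str]
    t_h: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if not (len(self.labels) == len(self.t_h) == len(self.M)):
            raise ValueError("labels, t_h and M must have equal length")
        if len(self.t_h) > 1 and not np.all(np.diff(self.t_h) > 0):
            raise ValueError("converted times must be strictly increasing")
        if np.any(self.M < 0):
            raise ValueError("mRNA levels must be non-negative")

    @classmethod
    def from_labels(cls, labels: list[str], M) -> "MrnaSeries":
        t = np.array([convert_modencode_time(lab) for lab in labels])
        order = np.argsort(t)
        labels = [labels[i] for i in order]
        return cls(labels, t[order], np.asarray(M, dtype=float)[order])

    def __len__(self) -> int:
        return len(self.t_h)


@dataclass
class MrnaInterpolant:
    """Continuous ramp-blended double-Gaussian mRNA model.

    Parameters (a1, b1, c1) are the early-Gaussian amplitude (Mu), center
    (h) and width (h); (a2, b2, c2, d2) the late Gaussian plus constant
    offset; (ramp_lo, ramp_hi) the ramp breakpoints of the blend q(t).
    """

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    d2: float
    ramp_lo: float
    ramp_hi: float
    sse: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("Gaussian widths c1, c2 must be positive")
        if not self.ramp_lo < self.ramp_hi:
            raise ValueError("ramp_lo must be below ramp_hi")

    def ramp(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.clip((t - self.ramp_lo) / (self.ramp_hi - self.ramp_lo), 0.0, 1.0)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        q = self.ramp(t)
        m1 = self.a1 * np.exp(-(((t - self.b1) / self.c1) ** 2))
        m2 = self.a2 * np.exp(-(((t - self.b2) / self.c2) ** 2)) + self.d2
        return (1.0 - q) * m1 + q * m2


def eval_interpolant(interp: MrnaInterpolant, t_grid) -> np.ndarray:
    """Evaluate M(t) on a time grid (hours)."""
    return interp(t_grid)


N_PARAMS = 9  # a1 b1 c1 a2 b2 c2 d2 ramp_lo ramp_width


def _pack(p) -> MrnaInterpolant:
    a1, b1, c1, a2, b2, c2, d2, lo, width = p
    return MrnaInterpolant(a1, b1, c1, a2, b2, c2, d2, lo, lo + width)


def _initial_guesses(series: MrnaSeries) -> list[np.ndarray]:
    """Candidate starts: early-peak Gaussian-1 plus several placements of
    the late component, at two width scales (the fit surface has local
    minima, so a small multistart is cheap insurance)."""
    t, y = series.t_h, series.M
    bin_w = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    # the largest local maximum (endpoints count) seeds the early center
    peaks = [i for i in range(len(y)) if
             (i == 0 or y[i] >= y[i - 1]) and (i == len(y) - 1 or y[i] >= y[i + 1])]
    peaks.sort(key=lambda i: -y[i])
    i1 = peaks[0] if peaks else int(np.argmax(y))
    b1, a1 = t[i1], max(y[i1], 1e-9)
    d2 = max(y[-1], 1e-9)
    b2_cands = {t[-1], b1 + 0.5 * (t[-1] - b1), b1 + 10.0}
    guesses = []
    for c in (2.0 * bin_w, span / 4.0):
        for b2 in sorted(b2_cands):
            if b2 - b1 < bin_w:
                continue
            yb2 = float(np.interp(b2, t, y))
            a2 = max(yb2 - d2, 0.1 * a1)
            guesses.append(np.array(
                [a1, b1, c, a2, b2, c, d2, b1, max(b2 - b1, 1.0)]))
    return guesses


def fit_interpolant(series: MrnaSeries, refine_ramp: bool = True) -> MrnaInterpolant:
    """Least-squares fit of the ramp-blended double-Gaussian model.

    The ramp breakpoints default to the two Gaussian centers and are
    refined as free parameters unless ``refine_ramp`` is False. Requires
    at least 8 data points; raises FitError on non-convergence.
    """
    if len(series) < 8:
        raise ValueError(
            f"interpolant fit needs >= 8 points "
            f"({N_PARAMS} free parameters), got {len(series)}"
        )
    t, y = series.t_h, series.M
    span = t[-1] - t[0]
    lb = np.array([0.0, t[0] - span, 0.1, 0.0, t[0] - span, 0.1, 0.0, t[0] - span, 0.1])
    ub = np.array([np.inf, t[-1] + span, 10 * span, np.inf, t[-1] + span, 10 * span,
                   np.inf, t[-1] + span, 10 * span])

    best = None
    for x0 in _initial_guesses(series):
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        if refine_ramp:
            def resid(p):
                return _pack(p)(t) - y
            try:
                res = least_squares(resid, x0, bounds=(lb, ub))
            except Exception:
                continue
            cand, cost = res.x, res.cost
        else:
            fixed_lo, fixed_w = x0[7], x0[8]

            def resid(p):
                q = np.concatenate([p, [fixed_lo, fixed_w]])
                return _pack(q)(t) - y
            try:
                res = least_squares(resid, x0[:7], bounds=(lb[:7], ub[:7]))
            except Exception:
                continue
            cand = np.concatenate([res.x, [fixed_lo, fixed_w]])
            cost = res.cost
        if best is None or cost < best[1]:
            best = (cand, cost)
    if best is None:
        raise FitError("mRNA interpolant fit did not converge from any start")
    interp = _pack(best[0])
    interp.sse = float(2.0 * best[1])
    return interp
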