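"""Raw-trace preprocessing: smoothing, background subtraction, normalization.

The measured whole-embryo signal F_Raw is the sum of tagged-protein
fluorescence and embryonic autofluorescence. The analysis quantity is
F(t) = F_Raw(t) - <F_NoFP(t)>, where the angle brackets average at least
five no-fluorophore control embryos at the same developmental time.
Three unit-free normalizations are provided for display and for the
photoconversion analysis.
"""

from __future__ import annotations

import numpy as np

from .traces import FluorescenceTrace

MIN_CONTROL_EMBRYOS = 5


def smooth_moving_average(trace: FluorescenceTrace, window: int = 15) -> FluorescenceTrace:
    """Centered moving average with an odd window (default 15 frames).

    At the boundaries the window shrinks symmetrically (partial windows),
    so the output has the same length as the input and the t=0 sample is
    preserved for downstream anchored normalization. The processing stage
    is unchanged.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    n = len(trace)
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    half = window // 2
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate([[0.0], np.cumsum(trace.intensity)])
    lo = idx - k
    hi = idx + k + 1
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return trace.with_values(smoothed)


def control_mean(
    controls: list[FluorescenceTrace], time_h: np.ndarray
) -> np.ndarray:
    """Mean no-fluorophore intensity, linearly interpolated onto ``time_h``.

    Control embryos are imaged on their own acquisition clocks, so each
    control is interpolated onto the target grid before averaging.
    """
    if len(controls) < MIN_CONTROL_EMBRYOS:
        raise ValueError(
            f"background subtraction requires >= {MIN_CONTROL_EMBRYOS} "
            f"control embryos, got {len(controls)}"
        )
    time_h = np.asarray(time_h, dtype=float)
    stack = []
    for ctl in controls:
        if ctl.time_h[-1] < time_h[0] or ctl.time_h[0] > time_h[-1]:
            raise ValueError(
                f"control {ctl.embryo_id!r} time range "
                f"[{ctl.time_h[0]}, {ctl.time_h[-1]}] h is disjoint from the "
                f"trace range [{time_h[0]}, {time_h[-1]}] h"
            )
        stack.append(np.interp(time_h, ctl.time_h, ctl.intensity))
    return np.mean(stack, axis=0)


def subtract_autofluorescence(
    trace: FluorescenceTrace, controls: list[FluorescenceTrace]
) -> FluorescenceTrace:
    """F(t) = F_Raw(t) - mean control intensity at the same timepoint.

    Negative values are permitted: residual background from genetic-
    background differences is later absorbed by the logistic baseline
    parameter B.
    """
    bg = control_mean(controls, trace.time_h)
    return trace.with_values(trace.intensity - bg, stage="subtracted")


def normalize_unit_interval(
    trace: FluorescenceTrace, mode: str = "anchored_first"
) -> FluorescenceTrace:
    """Map a trace onto [0, 1] (up to noise overshoot).

    ``anchored_first``: F_n(t) = (F(t) - F(0)) / (F_max - F(0)), anchoring
    the first sample at 0 and the maximum at 1.
    ``minmax``: I_n(t) = (I(t) - I_min) / (I_max - I_min).
    """
    y = trace.intensity
    if mode == "anchored_first":
        lo, hi = y[0], np.max(y)
    elif mode == "minmax":
        lo, hi = np.min(y), np.max(y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = hi - lo
    if denom == 0:
        raise ValueError("flat trace: normalization denominator is zero")
    return trace.with_values((y - lo) / denom, stage="normalized")


def normalize_percent_baseline(
    trace: FluorescenceTrace, baseline_frames: int = 5
) -> FluorescenceTrace:
    """Percent normalization against the first ``baseline_frames`` samples.

    I_n(t) = 100 * (I(t) - I_min) / (I_max - I_min) with I_min, I_max the
    extrema over the first ``baseline_frames`` acquisitions only — the
    pre-photoconversion baseline. Values outside [0, 100] are allowed
    (signal may fall below the baseline minimum after conversion).
    """
    if len(trace) <= baseline_frames:
        raise ValueError(
            f"trace length {len(trace)} must exceed baseline_frames {baseline_frames}"
        )
    base = trace.intensity[:baseline_frames]
    i_min, i_max = np.min(base), np.max(base)
    if i_max == i_min:
        raise ValueError("flat baseline: cannot normalize")
    return trace.with_values(
        100.0 * (trace.intensity - i_min) / (i_max - i_min), stage="normalized"
    )
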