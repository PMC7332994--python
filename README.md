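# ecmturnover

Intervention-free inference of basement-membrane (BM) protein turnover
during embryogenesis, from live-imaging accumulation curves and
stage-binned developmental mRNA data.

## The problem

Classical half-life measurements perturb the system (pulse labeling,
photoconversion) and assume a pre-existing steady state. For embryonic
extracellular-matrix proteins such as Collagen IV and Perlecan there is a
better window: their expression can be live-imaged *de novo*, from
induction until homeostasis. The approach implemented here exploits that
window. Whole-embryo fluorescence of a GFP-trapped BM component is a
sigmoid well described by a logistic,

$$P_L(t) = \frac{K}{1 + e^{\,r(t_i - t)}},$$

with carrying capacity $K$, intrinsic rate $r$ and inflection time $t_i$.
Protein dynamics are modeled by first-order production-degradation
kinetics driven by the measured mRNA level $M(t)$:

$$\frac{dP}{dt} = S_p\,M(t) - D_p\,P,$$

where $S_p$ (Pu·Mu⁻¹·h⁻¹) and $D_p$ (h⁻¹) are the synthesis and
degradation rate constants and the protein half-life is $\ln 2 / D_p$.
The rates are inferred in two independent directions:

* **anterograde** — numerically integrate the ODE from the interpolated
  mRNA curve ($P^*(-10\,\mathrm{h}) = 0$, 2-min steps, $-10 \le t \le 16$ h)
  and least-squares match $P^*(t)$ to the fitted logistic $P_L(t)$;
* **retrograde** — solve the ODE analytically for the mRNA level using
  the logistic derivative $dP/dt = rP(K-P)/K$,
  $$M^*(t) = \frac{(r + D_p)KP - rP^2}{S_p K},$$
  and match $M^*(t)$ to the interpolated mRNA on $-10 \le t \le 30$ h.

Agreement between the two directions is the model's internal-consistency
check. Orthogonal validation comes from pulse-chase decay (linear fit on
a 15–20 h window, $D_p = -\mathrm{slope}/P$), two-timepoint retention
($t_{1/2} = \Delta t \ln 2 / \ln(P_a/P_b)$), and fluorescence decay
after photoconversion (exponential fit). Nonlinear fits use
Levenberg-Marquardt-style least squares with linearized (Jacobian-based)
95% confidence intervals.

Because no raw imaging data are deposited for this system, the package
ships a first-class synthetic-data module: embryo ensembles driven by
the turnover ODE with explicit ground truth, modENCODE-style stage-binned
mRNA tables, pulse-chase and photoconversion traces. Every estimator is
validated closed-loop against that ground truth.

**Audience:** quantitative developmental biologists measuring protein
turnover from accumulation dynamics, and methodologists who want a
tested reference implementation of the anterograde/retrograde estimator
pair.

## Worked example

```python
from ecmturnover import (fit_anterograde, fit_logistic, fit_retrograde,
                         generate_embryo_traces, smooth_moving_average,
                         subtract_autofluorescence)
from ecmturnover.synthetic import perl_scenario

sc = perl_scenario(7.0, seed=0)            # Perlecan-like truth: half-life 7 h
ds = generate_embryo_traces(sc)            # 10 embryos + 5 no-FP controls
controls = [smooth_moving_average(c) for c in ds.controls]

tr = subtract_autofluorescence(smooth_moving_average(ds.embryos[0]), controls)
lf = fit_logistic(tr)
print(f"K={lf.k:.1f} Pu  r={lf.r:.3f}/h  t_i={lf.t_i:.2f} h")
a = fit_anterograde(sc.mrna_program, lf)
r = fit_retrograde(lf, sc.mrna_program)
print(f"anterograde half-life {a.half_life_h:.2f} h, "
      f"retrograde {r.half_life_h:.2f} h")
```

prints

```
K=100.2 Pu  r=0.396/h  t_i=6.05 h
anterograde half-life 7.10 h, retrograde 7.11 h
```

— the logistic phenotype of the first simulated embryo and both
turnover estimates, each within ~2% of the 7 h generating truth.

The numbered drivers under `analysis/` run the full study on synthetic
datasets (generation, logistic characterization, turnover inference,
decay-estimator validation, perturbation scan), writing tables under
`results/`:

```bash
python analysis/01_simulate_embryos.py
python analysis/02_characterize_accumulation.py
python analysis/03_infer_turnover.py
python analysis/04_validate_with_decay_estimators.py
python analysis/05_perturbation_scan.py
```

A `ecmturnover` CLI with subcommands (`synth`, `preprocess`,
`fit-logistic`, `fit-mrna`, `fit-turnover`, `fit-decay`, `pipeline`,
`benchmark`) wraps the same operations for shell use.

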