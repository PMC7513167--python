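# amhsurv

Bayesian estimation for **bivariate right-censored survival data** under
an **Ali–Mikhail–Haq (AMH) copula with Weibull margins** — for
biostatisticians analysing paired lifetimes (two eyes, two kidneys, twin
engines) whose association is weak enough for the AMH family
(Kendall's τ between about −0.18 and 1/3).

The joint survival function is

    S(t1, t2) = S1(t1) S2(t2) / [1 − φ (1 − S1(t1)) (1 − S2(t2))],
    Sj(t) = exp(−βj t^αj),      φ ∈ [−1, 1),

and each subject enters the likelihood through its censoring pattern:
the joint density, a negative partial derivative of S, or S itself.
Note the rate-type Weibull scale (βj multiplies t^αj directly).

The package provides:

* the model layer (`amhsurv.model`): survival/density/partials, the
  censored-data log-likelihood, Gamma/uniform priors, conditional
  kernels, and closed-form/quadrature Kendall's τ and Spearman's ρ;
* three MCMC algorithms (`amhsurv.samplers`) differing in the shape
  updates — **A1** independent MH (prior proposal), **A2** random-walk
  Metropolis, **A3** slice sampling — with a natural Gamma MH candidate
  for the scales and a grid independence sampler for φ;
* a conditional-inversion simulator with censoring calibration and a
  replicate RMSE benchmark (`amhsurv.simulate`);
* diagnostics (`amhsurv.diagnostics`): parameter RMSE, Kaplan–Meier
  distributional RMSE, IAT, ESS, Gelman–Rubin PSRF;
* CSV/JSON IO and a CLI (`amhsurv.io`, `amhsurv.cli`).

## Worked example

Simulate 100 subjects from the D1 design (α1=2, β1=1, α2=3, β2=1,
φ=0.5) with 20% censoring per margin, then fit with slice sampling:

```sh
amhsurv simulate --design D1 --n 100 --censor 20 --seed 7 --outdir demo
amhsurv fit demo/data_r0.csv --algorithm A3 \
    --iterations 11000 --burnin 1000 --thin 10 --seed 1 --out demo/fit
```

which prints

```
 alpha1:  1.9924  95% CI ( 1.6609,  2.3326)
  beta1:  0.9878  95% CI ( 0.7839,  1.2144)
 alpha2:  3.0029  95% CI ( 2.5258,  3.5182)
  beta2:  0.9396  95% CI ( 0.7391,  1.1820)
    phi:  0.2029  95% CI (-0.3722,  0.6173)
KM-RMSE: 0.0398
```

Each line is a posterior mean with an equal-tailed 95% credible
interval: the Weibull shapes and scales are recovered close to their
true values, while φ — weakly identified at n=100 — has a wide interval
that still covers the truth. `KM-RMSE` measures the distance between
the fitted marginal Weibull CDFs and the Kaplan–Meier curves at the
observed times (smaller is better). The run also writes the thinned
draws (`demo/fit.csv`), a JSON sidecar with config/seed/acceptance
rates, and per-parameter ESS/IAT diagnostics.

The same machinery is available as a library:

```python
from amhsurv import TABLE_DESIGNS, SimulationDesign, simulate_dataset
from amhsurv import MCMCConfig, run_chain

data = simulate_dataset(SimulationDesign(params=TABLE_DESIGNS["D1"], n=100, seed=7))
out = run_chain(data, config=MCMCConfig(alpha_algorithm="A3", seed=1))
print(out.estimates, out.acceptance_rates)
```

`amhsurv benchmark` reproduces the simulation-study RMSE grid
(designs D1–D4 × sample size × censoring × algorithm), and
`amhsurv diagnose` reports ESS/IAT/PSRF for saved chains. The real
paired-eye diabetic retinopathy dataset (from R's `survival` package)
is not bundled; `amhsurv.io.convert_retinopathy_table` converts its
long-format export to the 4-column input format.

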