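# sepmed — separable-effects mediation analysis for longitudinal data

`sepmed` estimates how much of a treatment's effect on a repeatedly
measured outcome travels through a repeatedly measured mediator. It is
written for biostatisticians and epidemiologists working with panel
data — a binary baseline exposure `X`, a mediator `M_t` and an outcome
`Y_t` observed at waves `t = 1..T` — where the classical *natural*
direct/indirect effects are unattractive: earlier mediators and
outcomes are post-treatment confounders, and natural effects demand
interventions on the mediator and untestable cross-world assumptions.

The package instead targets **separable effects**. The exposure is
decomposed into a component `X^M` acting only on the mediator process
and a component `X^Y` acting only on the outcome process (think of
breastfeeding's metabolic vs neurological components). Switching one
component at a time defines, at each wave,

```
SDE_t = E[Y_t(X^Y=1, X^M=0)] − E[Y_t(X^Y=0, X^M=0)]   (direct)
SIE_t = E[Y_t(X^Y=1, X^M=1)] − E[Y_t(X^Y=1, X^M=0)]   (indirect)
```

whose sum is the total effect, and whose identification needs only
single-world conditional independencies. `sepmed` provides:

- **Simulators** for two longitudinal mediation mechanisms: a
  cross-lagged linear mixed-effect model (subject-level random
  intercepts and random mediator slopes) and a parallel-process latent
  growth model (latent intercepts/slopes linked structurally), plus
  unobserved-confounder variants for assumption-violation studies.
- **Truth oracles**: exact closed forms for the latent growth model
  (`SDE_t = (γ01 + γ11 λ_t)Δx`, `SIE_t = λ_t(β01 γ12 + β11 γ13)Δx`),
  closed forms for the mixed model at waves 1–2 (including the
  `Var(gM)` second-moment correction for the squared random slope) and
  a large-sample Monte-Carlo oracle for later waves.
- **A parametric mediational g-formula estimator**: per-wave GLM,
  mixed-model or latent-growth backends, forward Monte-Carlo
  simulation with the mediator models under `x_m` and the outcome
  models under `x_y`, and cluster-bootstrap percentile intervals.
- **A replication harness** reporting relative bias, RMSE and CI
  coverage over K simulated replicates under correct, moderately and
  severely misspecified fitting, and under confounding.

An identifiability checker classifies random-effect covariance
structures: diagonal → non-parametrically identified; within-block
correlation → identified only through the Gaussian assumptions; any
mediator-outcome cross-block correlation → not identified (a
recanting district), and the oracles refuse to run.

## Worked example

```python
import sepmed as sp

spec = sp.simulation_study_lgm_spec()          # 5-wave latent growth design
panel = sp.simulate_lgm(
    spec, sp.ScenarioConfig(mechanism="lgm", n=1000, T=5, seed=7)
)
est = sp.estimate_effects(
    panel, sp.EstimatorConfig(backend="lgm", S=10_000, B=200, seed=11)
)
print(est.to_frame().round(3).to_string(index=False))
```

```
 wave   sde   sie  sde_se  sie_se  sde_ci_low  sde_ci_high  sie_ci_low  sie_ci_high  prop_mediated
    1 0.254 0.000   0.079   0.000       0.090        0.412       0.000        0.000          0.000
    2 0.530 0.198   0.104   0.044       0.338        0.721       0.108        0.283          0.272
    3 0.806 0.396   0.159   0.088       0.557        1.096       0.216        0.567          0.329
    4 1.083 0.594   0.223   0.133       0.738        1.532       0.324        0.850          0.354
    5 1.359 0.792   0.290   0.177       0.948        1.941       0.432        1.133          0.368
```

Each row is one wave. The direct effect of the exposure on the outcome
grows linearly with the time loading (truth 0.14, 0.41, …, 1.22 under
this design; this particular n = 1000 draw runs somewhat high), the
indirect effect through the mediator process grows from exactly zero
at wave 1 (the wave-1 loading is zero, so no mediated path is open
yet) towards its truth of 0.639, and by wave 5 roughly a third of the
total effect is mediated. The bootstrap columns are percentile
intervals from 200 cluster resamples; every interval from wave 2 on
excludes zero and contains the corresponding truth.

The same panel can be analysed with the other backends
(`backend="glm"` for sequential GLMs, `backend="mixed"` for the
mixed-model backend), and `sp.lgm_effects(spec, wave, contrast)`
returns the exact truth to compare against.

A command-line interface mirrors the library:

```sh
sepmed simulate --config cfg.yaml --seed 7 --out panel.csv
sepmed truth    --config cfg.yaml --seed 7 --out truth.csv
sepmed estimate --panel panel.csv --backend lgm --seed 11 --out effects.csv
sepmed study    --config study.yaml --seed 3 --out metrics.csv
```

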