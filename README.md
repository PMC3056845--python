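# mcrtsim

Monte Carlo comparison of six statistical models for estimating a treatment
effect on a continuous outcome in **multicentre randomized controlled trials
(RCTs)**, for biostatisticians and trialists deciding how (or whether) to
adjust an analysis for centre.

## The problem

In a multicentre RCT, outcomes of patients treated at the same centre are
often more alike than outcomes across centres. Data are generated from the
random-intercept model

```
Y_ij = β0 + b_0j + β1 X_ij + e_ij,    b_0j ~ N(0, σb²),  e_ij ~ N(0, σe²),
```

where `X_ij ∈ {0, 1}` is the treatment arm, `b_0j` the shared centre effect,
and the intraclass correlation `ICC = σb² / (σb² + σe²)` measures clustering.
Patients are allocated 1:1 by one of three mechanisms: exact within-centre
balance, a trial-wide permutation of a fixed 1:1 label vector (within-centre
arm counts then drift by chance), or within-centre permuted blocks.

Six estimators of β1 are applied to every simulated trial:

| Model | Analysis | Interval |
|-------|----------|----------|
| A | simple linear regression (two-sample t-test), centres ignored | t, df = N − 2 |
| B | fixed centre intercepts (single-arm centres dropped) | t, df = N − J − 1 |
| C | random-intercept linear mixed model, REML | t, df = N − J − 1 |
| D | GEE, exchangeable working correlation, sandwich variance | Wald |
| E-1 | centre-level fixed-effect inverse-variance pooling | Wald |
| E-2 | centre-level DerSimonian–Laird random-effects pooling | Wald |

A harness runs (scenario × ICC × replicate) grids over a nine-scenario
catalogue — from 45 centres of 4 patients to 6 centres of 30, plus a
46-centre composition copied from a real 511-patient primary-care trial —
and reports bias, empirical SD, average estimated SE, MSE, 95%-interval
coverage and power per model. Replicates on which the GEE fails to converge
are excluded for all models and replaced.

## Worked example

Simulate one balanced 18-centre trial at ICC 0.20 and analyze it:

```python
import mcrtsim as m

spec = m.scenario(2)                      # 18 centres x 10 patients, balanced
params = spec.params.with_icc(0.20)       # beta1 = 0.5, sigma_e2 = 1
data = m.generate_trial(spec.design, params, m.RngStream(42, (2, 200000, 0)))
for model in ("A", "C"):
    r = m.fit(data, model)
    print(f"{model}: estimate={r.estimate:.3f}  se={r.se:.3f}  "
          f"95% CI=({r.ci_low:.3f}, {r.ci_high:.3f})")
```

prints

```
A: estimate=0.496  se=0.172  95% CI=(0.156, 0.836)
C: estimate=0.496  se=0.150  95% CI=(0.200, 0.792)
```

Both models recover the true effect 0.5 (balanced allocation makes the point
estimates identical), but the naive model A pays for ignoring clustering with
a ~15% larger standard error — exactly the `1/(1 − ICC)` variance inflation
the mixed model avoids.

The same comparison over 200 replicates from the command line:

```sh
mcrt run --scenario 1 --icc 0.01,0.20 --n-sims 200 --seed 42 --out results.csv
```

yields (selected rows)

```
scenario,icc,model,n_reps,mean_estimate,emp_sd,avg_se,mse,coverage,power,n_excluded
1,0.01,A,200,0.488286,0.152299,0.149488,0.0232161,0.94,0.9,0
1,0.2,A,200,0.487042,0.146942,0.165341,0.0216518,0.97,0.865,0
1,0.2,C,200,0.487042,0.146942,0.147866,0.0216518,0.945,0.905,0
```

At ICC 0.20 model A's average SE (0.165) overshoots the true sampling SD
(≈0.149): its intervals over-cover (0.97) and its power sags (0.865), while
the mixed model C stays at nominal coverage with an accurate SE. Other
commands: `mcrt table` pivots such a CSV into the wide report tables,
`mcrt fit` analyzes a user-supplied `centre,arm,y` CSV with any of the six
models, `mcrt design` does t-test sample-size arithmetic with the clustering
inflation factor, and `mcrt scenarios` exports the scenario catalogue.

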