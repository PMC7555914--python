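# damu — diagnostic accuracy measures under measurement uncertainty

`damu` calculates, optimizes, differentiates and compares diagnostic
accuracy measures and the corresponding expected-loss risk of binary
screening or diagnostic tests that measure a normally distributed measurand
— as explicit functions of the standard measurement uncertainty *u* of the
test. It is aimed at laboratory-medicine and clinical-epidemiology users who
want to ask questions like: *how much does analytical imprecision move my
optimal cutoff, my likelihood ratios, or my expected loss?*

## Model

The measurand is normal in each population (diseased: mean μ_D, SD σ_D;
non-diseased: μ_D̄, σ_D̄; prevalence v). Measurement error with standard
uncertainty u inflates each SD in quadrature, σ_eff = √(σ² + u²). A
measurement above the threshold d is test-positive, so

    Se(d) = 1 − Φ(d; μ_D, √(σ_D² + u²)),   Sp(d) = Φ(d; μ_D̄, √(σ_D̄² + u²))

and every other measure is algebraic in (Se, Sp, v):

| measure | definition |
|---|---|
| PPV, NPV | Se·v / (Se·v + (1−Sp)(1−v)),  Sp(1−v) / (Sp(1−v) + (1−Se)v) |
| ODA | Se·v + Sp·(1−v) |
| LR+, LR−, DOR | Se/(1−Sp),  (1−Se)/Sp,  LR+/LR− |
| J, ED, CZ | Se+Sp−1,  √((1−Se)²+(1−Sp)²),  Se·Sp |
| risk R | l0 + lTN·Sp(1−v) + lFN(1−Se)v + lTP·Se·v + lFP(1−Sp)(1−v) |

The ROC curve and its area are closed-form,
AUC = Φ((μ_D−μ_D̄)/√(σ_D̄²+σ_D²+2u²)); the predictive ROC curve (PPV vs
1−NPV) is traced by threshold parametrization. Optimal thresholds maximize J
or CZ, or minimize ED or R. See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

The bundled case study models two-hour post-load blood glucose during an
OGTT (log-transformed, normalized to the non-diseased SD) with diabetes
prevalence 0.067 and compares a precise test (u = 0.023, 1% CV) with a noisy
one (u = 0.23, 10% CV); losses (l0, lTN, lFN, lTP, lFP) = (1, 0, 100, 0, 76).

```python
from damu import case_study, dam_table, optimize_threshold

cfg = case_study()
row = dam_table(cfg.d, cfg.test1, cfg.loss)   # clinical threshold d = 2.26
print(f"Se={row.se:.3f} Sp={row.sp:.3f} LR+={row.lr_pos:.1f} R={row.r:.3f}")
res = optimize_threshold("R", cfg.test1, cfg.loss)
print(f"risk-optimal threshold: {res.d_opt:.3f}")
```

prints

```
Se=0.835 Sp=0.988 LR+=70.0 R=2.953
risk-optimal threshold: 2.258
```

i.e. at the clinical cutoff the precise test detects 83.5% of diabetics with
a 1.2% false-positive rate, and the loss-minimizing cutoff (2.258) sits just
below the clinical one. The same via the CLI, for both tests at once:

```sh
$ damu optimize --config src/damu/data/case_study.yaml --objective all
objective    sense  d_opt_1  d_opt_2  relative_difference
        J maximize    1.637    1.623                0.009
       ED minimize    1.676    1.663                0.008
       CZ maximize    1.640    1.627                0.008
        R minimize    2.258    2.290               -0.014
```

Tenfold more measurement uncertainty moves the J/ED/CZ-optimal cutoffs by
under 1%, but moves the risk-optimal cutoff the other way by 1.4% — the
loss-weighted objective is the most uncertainty-sensitive of the four.
Other subcommands: `damu calc` (all measures of both tests at a threshold,
with difference/relative difference/ratio), `damu roc` (ROC/PROC curves,
CSV + plot + AUC/AOC summary), `damu sweep` (any measure, its ∂/∂u, or the
two-test comparison against threshold, prevalence, uncertainty, Se or Sp).

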