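# Methods

## Model

A quantitative screening or diagnostic test measures a single measurand — a
measured analyte concentration or a transform of it (here, a log transform)
— whose values are assumed normally distributed within each of the diseased
and non-diseased populations, with known parameters:

- diseased: mean `mu_d`, SD `sigma_d`
- non-diseased: mean `mu_nd`, SD `sigma_nd`
- disease prevalence `v`

The measurement process adds normal, homoscedastic error summarised by the
standard measurement uncertainty `u` (an SD-scale parameter that may fold in
bias treated as an uncertainty component). Because biological variation and
measurement error are independent, the observed value in a population with
biological SD `sigma_p` is normal with SD

    sigma_eff = sqrt(sigma_p**2 + u**2)

This quadrature combination is the only place `u` enters the model, so every
measure depends on `u` smoothly (and evenly: only `u**2` appears).

A subject is test-positive when the measurement exceeds the diagnostic
threshold `d`. The opposite orientation is obtained by swapping the two
populations; there is no flag, which keeps every formula in one form.

With `Phi` the normal CDF,

    Se(d) = 1 - Phi(d; mu_d,  sqrt(sigma_d**2  + u**2))
    Sp(d) =     Phi(d; mu_nd, sqrt(sigma_nd**2 + u**2))

All other measures are algebraic in (Se, Sp, v) and, for risk, the five loss
constants; see the table in the README. Risk

    R = l0 + lTN*Sp*(1-v) + lFN*(1-Se)*v + lTP*Se*v + lFP*(1-Sp)*(1-v)

is the expected loss of applying the test, with all five constants on one
common (unit-agnostic) scale; lower is better.

The ROC curve has the closed binormal form `roc(t) = S_D(S_ND^{-1}(t))`
(normal survival functions of the observed distributions), with

    AUC = Phi( (mu_d - mu_nd) / sqrt(sigma_nd**2 + sigma_d**2 + 2u**2) )

so AUC strictly decreases in `u` whenever the diseased mean exceeds the
non-diseased mean. The predictive ROC (PROC) curve — PPV against 1−NPV — has
no elementary closed form; it is traced by sweeping the threshold,
`d -> (1-NPV(d), PPV(d))`, which is equivalent to the composition
`PPV(NPV^{-1}(1-t))` wherever NPV is monotone in `d` but requires no branch
choice when it is not. An explicit `npv_inverse` (bracketed Brent root
finding) is provided to validate the composition form on monotone stretches.

## Uncertainty derivatives

Every measure's partial derivative with respect to `u` at fixed threshold is
computed by the chain rule: with `z = (mu - d)/sigma_eff`,

    dPhi(z)/du = -phi(z) * z * u / sigma_eff**2

for each population, combined with the closed-form partials of the measure
with respect to Se and Sp. A central finite difference with one Richardson
extrapolation level is available as an independent fallback
(`h = max(1e-6, 1e-3*u)` by default). Because measures are even in `u`, the
symmetric difference is valid at `u = 0`, where every derivative vanishes.

When validating the analytic path against the finite difference, note the
oracle's noise floor: for near-flat measures (NPV on this case study has
`|dNPV/du| ~ 4e-6`) a step of `1e-5` leaves subtractive-cancellation noise of
order `eps*|m|/(2h|dm/du|) ~ 3e-5` relative. The test suite uses `h = 1e-3`,
which keeps both cancellation (~3e-8) and Richardson-corrected truncation
below the 1e-6 relative agreement asserted.

## Threshold optimization

Four objective/loss functions are supported: maximize Youden's `J = Se+Sp-1`
or the concordance probability `CZ = Se*Sp`; minimize the Euclidean distance
`ED = sqrt((1-Se)**2 + (1-Sp)**2)` from the perfect point or the risk `R`.
The solver is deterministic and derivative-free: a 1001-point coarse grid on
`[min(mu) - 6*sigma_eff_max, max(mu) + 6*sigma_eff_max]` locates the global
basin (risk can be multimodal under extreme loss ratios), then bounded
scalar minimization (SciPy's Brent-type bounded method, `xatol = 1e-8`)
refines the optimum — comfortably below the 1e-6 accuracy the optimum is
reported at. `J`, `ED` and `CZ` optima are invariant to prevalence and to
the loss constants; the risk optimum moves down as `lFN/lFP` grows (missed
cases become costlier, so the test is made more sensitive).

A flat objective — e.g. `J` when the two populations coincide, which is
identically zero — is reported as the midpoint of the search interval with a
`non_unique` flag rather than an error.

## Numerical choices

- All normal CDF/survival/quantile evaluations route through one erf/erfc
  primitive pair (`scipy.special.erfc`, `erfcinv`), accurate in both tails,
  so the closed forms agree with each other to machine precision.
- Thresholds `d = ±inf` are accepted and return exact limit values (0/1);
  `roc` returns exact endpoints at `t = 0, 1` instead of evaluating the
  quantile at its singularities.
- Boundary values of ratio measures follow the conventions `Sp = 1 =>
  LR+ = DOR = +inf`, `Se = 1 => LR- = 0, DOR = +inf`; genuine 0/0
  indeterminacies return NaN with a `MeasureBoundaryWarning`, never an
  exception, so sweeps and optimizers can cross boundaries freely.
- Curve tracing uses a threshold grid spanning both populations to beyond
  six observed SDs (default 512 points), so traced ROC endpoints reach the
  corners to ~1e-9.
- Precision limit of the inverse relations: `se_given_sp(specificity(d))`
  recovers `sensitivity(d)` to better than 1e-10 only while the intermediate
  probability is representable, i.e. roughly `|z| < 4.7` (probabilities in
  about `[1e-6, 1 - 1e-6]`). Once Se or Sp saturates toward 1 in float64,
  the (0,1)-valued interface simply no longer carries the threshold
  information (at `d = -3` on the case-study population the recovery error
  is ~3e-5); this is a property of double precision, not of the algorithm.
  Property tests therefore assert the 1e-10 round trips inside the
  non-saturated region.

## Case study defaults

The bundled configuration models two-hour post-load blood glucose in an
adult population screened for diabetes, log-transformed and expressed in
units of the non-diseased SD of the log measurand: `mu_d = 2.99`,
`sigma_d = 0.75`, `mu_nd = 0`, `sigma_nd = 1`, prevalence `v = 0.067`,
clinical threshold `d = 2.26` (the ADA 11.1 mmol/L cutoff on this scale),
and two tests with `u = 0.023` and `u = 0.23` (1% and 10% CV). The losses
`(l0, lTN, lFN, lTP, lFP) = (1, 0, 100, 0, 76)` encode a missed diabetic
being somewhat costlier than a false alarm, with correct results costless
beyond the procedure itself. These values are fixtures, not tunables: the
package itself is unit-agnostic and the normalization lives entirely in the
configuration.

On this configuration, raising `u` tenfold barely moves the probability-like
measures (AUC, Se, Sp, ODA, PPV, NPV, ED, CZ — relative changes 0.1–7%) but
moves the odds/likelihood/loss family much more (DOR ~20%, LR+ ~15%, R ~7%);
as a group contrast this is robust (means differ ~6-fold), though it is not
element-wise: ED, sitting near zero, has a larger *relative* change than J.
Correspondingly the J/ED/CZ-optimal thresholds shift by <0.015 while the
risk-optimal threshold shifts by ~0.03 in the opposite direction.

## Limitations

- Population parameters, prevalence and `u` are taken as known; nothing is
  estimated from samples and no confidence intervals are produced.
- Normality (possibly after transformation) and homoscedastic measurement
  uncertainty across the threshold range are assumed; heteroscedastic error
  models and transformations that restore homoscedasticity are out of scope.
- No bias→uncertainty combination rule is provided; `u` is supplied already
  combined.
- Optimization is over the threshold only, one objective at a time.
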