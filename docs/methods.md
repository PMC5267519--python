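# Methods

## Model and assumptions

The package implements the correlation-based workflow for predicting
clinical CYP3A4 induction from in vitro concentration-response data. Its
assumptions, in order of appearance in the pipeline:

- **Normalization.** Enzyme-activity fold induction is the ratio of the
  treated replicate mean to the vehicle-control replicate mean; mRNA fold
  induction is 2^(−ΔΔCT). Fold increase (fold induction − 1) is the
  response variable for curve fitting, so a vehicle-level response maps to
  zero.
- **Replicate QC.** A concentration point enters fitting only when its two
  or three replicates have a coefficient of variation below 40%. CV is the
  sample (n−1) standard deviation over the mean. For activity it is
  computed on the raw replicate signals; for mRNA it is computed on the
  per-replicate linear quantities 2^(−ΔΔCT), because a CV on the ΔΔCT
  (log) scale is not scale-meaningful — ΔΔCT values near zero or of mixed
  sign make SD/mean unusable, while the multiplicative replicate noise
  lives on the linear scale on both endpoints.
- **Dose-response.** Fold increase follows the Hill 4-parameter model
  y = E_min + (E_max − E_min)/(1 + (EC50/x)^b), monotone in x for b > 0.
  A fit is accepted only when R² = 1 − SS_res/SS_tot > 0.85. A data set is
  fit-eligible only when it is concentration dependent and its maximum
  fold induction exceeds 1.4.
- **Exposure weighting.** RIS = E_max·C_max,ub/(EC50 + C_max,ub), with
  E_max and EC50 on the fold-increase scale and C_max,ub the unbound
  clinical maximum plasma concentration (µM). RIS is monotone increasing
  in E_max and C_max,ub and decreasing in EC50, and bounded by E_max.
- **Clinical calibration.** Observed % midazolam AUC decrease vs RIS
  follows a Hill-3 curve f = a·x^b/(c^b + x^b), fitted per lot × endpoint
  on untransformed pairs for the designated calibration compounds. The
  RIS cutoff at a t% AUC change is the closed-form inverse
  x = c·(t/(a − t))^(1/b); predict(cutoff(t)) = t by construction.
- **Accuracy.** RMSE is computed on the fractional AUC-change scale
  (percent/100). GMFE = 10^(mean |log10(pred/obs)|) over pairs where both
  values are positive; pairs with a nonpositive member (a compound
  predicted 0, or an observed AUC increase) carry no defined fold error
  and are excluded and logged.

## Decisions where the procedure was genuinely open

- **Concentration dependence** is operationalized as: ≥3 accepted points,
  positive Spearman rank correlation between concentration and (floored)
  fold increase, and the maximum response occurring above the lowest
  tested concentration. Any monotone-trend test would do; Spearman is
  threshold-free and robust to the response scale.
- **Plateau criterion** for the observed-max fallback: a plateau exists
  when the fitted E_max ≤ 1.2 × the observed maximum fold increase *and*
  the fitted response at the top tested concentration reaches ≥ 90% of the
  fitted E_max. Both constants are exposed in `PipelineConfig`. Ranges
  that stop below ~9×EC50 therefore fall back by design — the same
  behaviour a bench scientist applies when a curve has no visible top.
- **Fallback EC50** is re-derived by refitting the curve with E_max fixed
  at the observed maximum (E_min, EC50, b free, same multi-start). The
  alternative — solving the unconstrained fit for the concentration at
  half the observed max — gives similar values but can land outside the
  tested range; the constrained refit keeps the reported curve and its R²
  self-consistent.
- **Negative fold increases** (fold induction < 1) are retained for curve
  fitting but floored at 0 for classification, so mild assay noise below
  vehicle level cannot generate a spurious "decreasing" trend call.
- **Optimization.** Hill-4: bounded trust-region least squares,
  multi-start over b ∈ {0.5, 1, 2, 4} × EC50 at the log-quartiles of the
  tested range, E_max starting at the observed maximum, E_min at 0; bounds
  E_min ∈ [0, obs max], E_max ∈ (0, 5×obs max], b ∈ (0.1, 10], EC50 within
  two decades of the tested range. Hill-3 calibration: a starts at the
  maximum observed AUC change, c at the RIS quartiles, b ∈ {1, 2, 4};
  bounds a ∈ (20, 120], b ∈ (0.1, 10], c > 0. The best of all starts by
  SSE is kept; tolerances 1e-12 make the result reproducible to well below
  reporting precision, with no randomness anywhere in fitting.
- **Calibration set.** Exactly the compounds flagged
  `in_calibration_set` in the compound metadata (six midazolam-study
  inducers spanning strong to non-inducer). Negative observed AUC changes
  are allowed in evaluation but never in calibration.
- **Stratified accuracy.** The midazolam subset is the calibration set;
  the non-midazolam subset is the six compounds whose clinical studies
  used other victim drugs. Clotrimazole is excluded from the
  non-midazolam metrics by default (`nonmidazolam_exclude`): it has no
  activity-based RIS (enzyme inhibition masks its activity signal), so
  including it would make the two endpoints' metrics incomparable.

## Synthetic panels

`synthetic.generate_panel` emulates the study design the analysis assumes:
a panel of compounds (default 18), each at 8 log-spaced concentrations
over its own tested range, in triplicate, across 3 lots, on both
endpoints. Each treated well is vehicle_mean × (1 + Hill4(conc; truth)) ×
a multiplicative log-normal factor with unit mean and CV = `noise_cv`
(default 0.10 — replicate noise magnitude is a modeling choice; typical
well-level assay CVs sit near 10%, and at that level fewer than 1% of
triplicates fail the 40% CV filter). mRNA wells carry the equivalent
per-replicate ΔΔCT. Vehicle wells share the noise model. Above an optional
toxicity threshold the response collapses to 10% of the vehicle signal and
wells are flagged `is_toxic_truth`, which the pipeline converts into
toxicity exclusions.

Default truths: per-compound (E_max, EC50) and concentration ranges follow
the packaged lot-2B fit table, slopes default to 1, non-responders have
E_max = 0, and each compound's unbound C_max is back-solved so its true
RIS matches the packaged lot-2B value where one exists. Per-compound
"observed" AUC changes come from a reference Hill-3 curve
(a = 98, b = 2.5, c = 0.35 — central among the fitted lots), closing the
loop so calibration recovery is testable.

What the generator does **not** emulate: plate-layout or edge effects,
correlated (batch) noise between concentrations, qPCR efficiency
deviations from 2, partial toxicity gradients, or lot-to-lot biological
variation in E_max/EC50 (lots differ only by noise realization). Passing
tests therefore demonstrate correctness of the computational procedure
under its stated noise model, not robustness to real-world assay
artifacts.

## Numerical notes and degenerate inputs

- Fits require ≥4 accepted points; all-equal responses, empty vehicle
  data, nonpositive vehicle means, duplicate concentrations and <2
  replicates raise typed errors (exit codes: 1 data, 2 configuration).
- The Hill-4 fit is equivariant under concentration rescaling (EC50
  rescales, E_max and b unchanged).
- Cutoff inversion requires the threshold to lie strictly below the
  fitted plateau a; otherwise the curve never reaches it and the inversion
  raises rather than extrapolating.
- Reported tables round to 2 significant figures (RMSE, GMFE) and integer
  percent (%CV); all internal computation is full precision.

## Problem sizes

The test suite's parameter-recovery simulation uses 100 seeded single-lot
panels of 2 plateau-spanning compounds at noise_cv = 0.1 (200 fits), a
size at which the median-error statistics are stable across seeds. The
analysis drivers use the full 18-compound × 3-lot × 2-endpoint panel
(2,916 wells).

## Known limitations

- The calibration transfers poorly to compounds whose clinical studies
  used non-midazolam victim drugs — reproduced here as ~10× higher RMSE
  and order-of-magnitude GMFE — so predictions should be read as
  midazolam-equivalent AUC changes.
- Cross-lot %CV summaries recomputed from rounded per-lot RIS tables can
  differ by a few points from summaries computed on unrounded values;
  the package always recomputes from its inputs.
- Slope factors (b) are estimated and reported but deliberately not used
  in prediction, and time-weighted average exposure corrections are not
  implemented; both follow standard industry practice for this workflow.
- The observed-max fallback reports E_max at the top of the tested range;
  for truncated ranges this systematically underestimates the true E_max
  (and with it RIS), which is the intended conservative behaviour.
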