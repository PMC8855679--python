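# Methods

`assayrsm` implements the statistical workflow behind an optimized
phenol–sulfuric acid assay for tissue glycogen: design the optimization
experiment, model the absorbance response, select robust reaction
conditions, quality-control the calibration curves, and convert plate
readings into tissue glycogen content. This note records the models,
the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Response-surface model

The assay's 490 nm absorbance is modeled as a polynomial in three coded
reagent volumes — 5% phenol solution, concentrated sulfuric acid, and
water. Coding maps each volume *v* to *(v − center)/half-range*, so
the factorial low/high volumes sit at ∓1 and a rotatable
central composite design (CCD) places axial points at ±(2³)^(1/4) =
±1.682. A three-factor CCD with six center replicates has
2³ + 2·3 + 6 = 20 runs; run order is randomized by a recorded seed with
one center point pinned first and one last so process drift (e.g.
chromophore decay over the plate) is monitorable throughout.

The full model is the quadratic with all interactions — 11 terms for
k = 3: intercept, three linear terms, three squares, three two-way
products, and the three-way product. Fitting is ordinary least squares
(via `statsmodels`), with per-coefficient two-sided t-tests of
H₀: β = 0. Model reduction removes terms whose estimates are
consistent with zero (p ≥ α, default α = 0.05) while preserving
hierarchy: a linear term is kept whenever a retained square or
interaction involves its factor, because interactions are
uninterpretable without their main effects. Hierarchy deliberately
does *not* protect two-way terms under a retained three-way term; only
their own test keeps them. On the packaged experiment this drops the
phenol square and the phenol:water interaction and keeps linear phenol
(p ≈ 0.49) by hierarchy, leaving the 9-term selected model.

Competing models are scored by the small-sample corrected AIC in its
least-squares form,

    AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n − K − 1),

with K counting the fitted coefficients **plus one** variance
parameter. This convention matters: it is what common curve-fitting
software uses, and only with it does the selected-vs-full comparison on
the packaged data give ΔAICc = −20.93 and a "selected model correct"
probability 1/(1 + e^(Δ/2)) > 99.99%. The convention is configurable
(`count_variance=False` drops the variance parameter).

Confidence intervals (coefficients and predictions) are t-based on the
residual degrees of freedom — asymptotic, not profile; no
robust/sandwich covariance. Predictions outside the axial sphere warn
about extrapolation rather than refusing: the workflow itself pins
water at coded −1.682 and evaluates conditions slightly outside the
fitted region, accepting that those predictions degrade.

Center-point stability is summarized as the mean absolute deviation of
the center replicates around their mean, relative to that mean; the
run passes below 5%. The packaged experiment gives mean 0.2918, MAD
0.0082, ratio 2.8%.

## Condition selection by error propagation

Pipetting errors Δxᵢ propagate into the absorbance through the fitted
surface R(x). Linearizing and taking the worst case — all error terms
adding — gives the relative-error objective

    |ΔR/R| ≈ |1/R| · Σᵢ |∂R/∂xᵢ| · Δxᵢ ,

with analytic partials of the polynomial. The default perturbation is
0.05 coded units per factor, the coded image of a 1% pipetting error on
a typical 50 µl volume with a 10 µl half-range. The objective is
scale-invariant in R, monotone in each Δ, and zero at stationary
points; it matches an exhaustive enumeration of the 2^k perturbation
sign patterns to within the O(‖Δ‖²) remainder (about 0.1 percentage
points on the fitted surface at Δ = 0.05).

Two searches are provided, both seeded 32-start local optimizations
(L-BFGS-B for signal maximization, SLSQP for the constrained precision
search) — a quadratic surface has few basins, so this is ample, and
determinism under a fixed seed is required for reproducible run sheets.
Constraints supported are the protocol's: factors pinned to fixed coded
levels (water at −1.682 = 0 µl, one fewer pipetting step) and a
minimum total reaction volume, which requires the uncoded coding map.
The published chosen condition (45 µl phenol / 300 µl acid / 0 µl
water) cannot be checked numerically because the uncoded volume grid
was never published; the optimizer is instead validated against dense
grid and closed-form oracles on synthetic surfaces with the same
constraint structure. Ties within numerical tolerance break toward the
smaller response-gradient norm, and an all-zero perturbation
degenerates the objective — the search then returns the
lowest-gradient feasible point with a warning. The wording of the
original precision criterion ("derivatives summing to the smallest
amount") is ambiguous; this package interprets it as minimizing the
worst-case relative error above, which reduces to minimizing
Σ|∂R/∂xᵢ| at fixed R and equal deltas.

## Standard curves

Calibration is a Beer's-law line of blank-corrected absorbance against
analyte mass per well (0–25 µg range); the slope is the assay's
proportionality constant in A.U./µg. Readings above a 1.6 A.U. cap
are excluded as off-linear-range; the cap is inclusive (a reading of
exactly 1.6 is the boundary of the usable region) and configurable.

Outlier screening is a ROUT-style procedure rebuilt from its published
description, the original being proprietary: a robust line by
iteratively reweighted least squares (Tukey biweight), a robust
residual scale of 1.4826 × median|residual| with a √(n/(n−2))
small-sample correction, then Benjamini–Hochberg at FDR Q (default 1%)
on two-sided t tail probabilities of the studentized residuals. Flags
are deliberately advisory: the fit never auto-drops a flagged point,
because a statistical flag plus an experimental-log explanation — not
the flag alone — is the standard for removal. Exclusion is an explicit
`exclude` mask.

Precision is the intra-assay %CV, 100·sd/mean per level of
blank-corrected replicates, and a replicate-count-weighted average
across levels (the weighting scheme is this package's choice; "weighted"
was otherwise unspecified). %CV presupposes a ratio scale — zero must
mean zero — hence blank correction first, and the curve summary skips
the 0 µg blank, whose corrected mean hovers at zero and makes sd/mean
arbitrarily large. Levels with non-positive means are flagged
undefined rather than averaged.

## Quantification and stoichiometry

Tissue content is
(m_curve/V_assayed)·V_sample/m_tissue in µg glycogen per mg tissue:
the curve mass scaled from the assayed aliquot up to the dissolution
volume and down by tissue mass. Technical replicate wells are averaged
per sample before inverting the curve.

Stoichiometry uses 180 g/mol for free glucose and 162 g/mol for a
glucosyl residue (water lost on polymerization), so a particle of N
units weighs 162N + 18 g/mol; at an assumed 10⁶ g/mol particle this
gives ⌊(10⁶ − 18)/162⌋ = 6172 units. Fractional yields (glucose-curve
readout over glycogen-curve readout) are computed on a mass scale or a
molar scale, the latter recomputing N from the configured particle mass
rather than fixing 6172.

Verification comparisons (prediction vs. experiment, sodium-sulfate
interference) use the difference of means with a two-sample t interval,
pooled-variance by default (Welch optional). When one side is a model
prediction, the prediction's own uncertainty is not propagated — a
known limitation inherited from the original analysis.

## Synthetic generators

The generators reproduce the statistical structure each stage assumes,
not the chemistry:

* **Surface runs**: true quadratic surface (defaulting to the published
  selected-model coefficients) plus additive iid Gaussian noise,
  sd 0.013 A.U. — the standard deviation of the packaged experiment's
  six center replicates, computed here rather than quoted. Additive
  noise matches how replicate scatter is summarized for surface runs.
  Readings are floored at zero (negligible inside the design region).
* **Standard curves**: multiplicative noise, absorbance =
  line × (1 + ε), ε ~ N(0, cv), because curve precision is reported as
  %CV; default cv 0.07, the middle of the reported 5–10% intra-assay
  band. At the default slope (0.07279 A.U./µg) and intercept (0.02)
  the 25 µg standard crosses the 1.6 cap, exercising the cap filter.
* **Extraction**: per precipitation/centrifugation round, free glucose
  is multiplied by a carryover fraction (default 0.005 — one spin
  removes essentially all of it, as the protocol's validation found)
  and glycogen by a recovery fraction (default 0.93, midpoint of the
  91–95% yield band). Defaults start from the 60 mg/dl glucose +
  40 mg/dl glycogen control mixture. The true per-spin carryover was
  never quantified; 0.005 is a synthetic choice leaving <1% after one
  spin.
* **Tissue panel**: a liver-like panel (25 µg/mg content, ~25 mg
  samples, 1 ml dissolution, 5 µl assayed in duplicate) plus an
  extraction control of known glycogen mass (20 µg in 250 µl, 50 µl
  assayed) run through the same recovery. The quantification stage
  estimates recovery from the control and divides it out — mirroring
  the real protocol, which runs control mixtures alongside tissue —
  which also cancels most of the standard curve's estimation error,
  since the same curve reads control and samples.

What the generators do **not** emulate: furfural reaction kinetics and
spectra, plate-position or batch effects, pipetting correlations across
wells, heteroscedasticity of surface runs, and real outlier mechanisms
(outliers must be injected explicitly). Passing simulation-based tests
therefore demonstrates the statistical machinery is correct under the
assumed noise structure, not that real plates behave this way.

## Numerical choices and degenerate inputs

Problem sizes in the test suite — 100–500 Monte-Carlo replicates for
coverage, removal-rate, %CV and end-to-end bands — were chosen so
binomial/sampling error is small against each band's width while the
full suite stays fast. OLS fits are cross-checked against a direct
normal-equations oracle to machine precision. Rank-deficient design
matrices raise immediately; AICc is NaN on saturated fits (n − K − 1 ≤
0) and raises only when requested. Axial levels quoted at 3 d.p.
(±1.682) are treated as inside the design region via a 10⁻³ tolerance.
Decoding a coded point to a negative volume warns rather than errors,
since axial points of a volume factor can legitimately be infeasible
and the protocol's answer (pin water at the axial point = 0 µl) is a
constraint, not an exception.

## Known limitations

* The uncoded volume grid of the original experiment is unrecoverable,
  so the packaged fixture carries coded levels only and the chosen
  45/300/0 µl condition is reproduced in constraint structure, not
  numerically.
* ROUT here is the linear-model special case; curved calibration
  (4PL etc.) is out of scope, as are inter-assay CV and lack-of-fit
  F-tests.
* The difference-of-means intervals ignore prediction uncertainty when
  one group is a model estimate, exactly as in the original analysis.
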