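# assayrsm

Response-surface optimization and quantification toolkit for the
phenol–sulfuric acid glycogen assay.

Measuring tissue glycogen matters wherever glucose metabolism is
studied — fasting, exercise, glycogen-storage phenotypes — and the
phenol–sulfuric acid method is the cheap, sensitive way to do it:
sulfuric acid dehydrates carbohydrate to furfurals that condense with
phenol into a chromophore read near 490 nm. But the assay's precision
and sensitivity depend strongly on the reagent volumes, and one-factor-
at-a-time tuning misses their interactions. `assayrsm` implements the
multifactor route for metabolic researchers optimizing such assays:

* **doe** — rotatable central composite designs (CCD) over coded
  reagent volumes: 2^k factorial ±1 points, 2k axial points at
  ±(2^k)^(1/4), replicated center points bracketing a seeded random run
  order.
* **rsm** — ordinary-least-squares fitting of the quadratic response
  surface A₄₉₀ = β₀ + Σβᵢxᵢ + Σβᵢᵢxᵢ² + Σβᵢⱼxᵢxⱼ + …, hierarchy-
  preserving model reduction, AICc model comparison
  (AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n−K−1), K = coefficients + 1),
  prediction with t-based confidence intervals, and center-point drift
  diagnostics.
* **optimizer** — condition selection by worst-case first-order error
  propagation, |ΔR/R| ≈ |1/R|·Σ|∂R/∂xᵢ·Δxᵢ|, under protocol
  constraints (minimum reaction volume, factors pinned to fixed coded
  levels).
* **curves** — standard-curve fitting with a 1.6 A.U. linear-range
  cap, ROUT-style robust outlier flagging (advisory, FDR Q = 1%),
  blank correction, and intra-assay %CV.
* **quantify** — tissue content (m_curve/V_assayed)·V_sample/m_tissue,
  glycogen stoichiometry (162N + 18 g/mol particles), fractional
  yields, recovery calibration from extraction controls, and
  difference-of-means intervals.
* **synth** — seeded generators for surface runs, standard curves,
  ethanol-precipitation extractions, and whole tissue panels, so the
  entire pipeline runs and is tested with no external data.
* **datasets** — the published 20-run optimization experiment (coded
  levels + absorbances) ships with the package.

## Worked example

Fit the full quadratic to the packaged experiment, reduce it, and pick
a precise condition with water pinned at its axial point (0 µl):

```python
import numpy as np
import assayrsm as ar

ms = ar.datasets.load_optimization_experiment()
full = ar.fit_measurements(ms, ar.datasets.FULL_TERMS)
kept = ar.reduce_model(full, alpha=0.05)       # drops phenol², phenol:water
fit = ar.fit_measurements(ms, kept)
delta, prob = ar.compare_aicc(fit, full)

names = ["phenol", "h2so4", "water"]
for t, b, (lo, hi) in zip(kept.labels(names), fit.beta, fit.ci95()):
    print(f"{t:20s} {b:+.5f}  [{lo:+.5f}, {hi:+.5f}]")
print(f"r2 = {fit.r2:.4f}   r2_adj = {fit.r2_adj:.4f}")
print(f"delta AICc (selected - full) = {delta:.2f}   P(selected correct) = {prob:.4%}")

d = ar.center_point_drift(ms)
print(f"center points: mean = {d.mean:.3f}, MAD = {d.mad:.4f}, "
      f"MAD/mean = {d.mad_over_mean:.1%} -> {'stable' if d.passed else 'unstable'}")

res = ar.find_precise_condition(
    fit, ar.PerturbationSpec.uniform(3, 0.05), fixed={2: -1.682}, seed=0
)
print("precise condition (coded):", np.round(res.coded_point, 3),
      f"worst-case rel. error = {res.objective_value:.2%}")
```

prints

```
intercept            +0.28694  [+0.27364, +0.30024]
phenol               +0.00351  [-0.00689, +0.01390]
h2so4                +0.04769  [+0.03730, +0.05809]
water                -0.08491  [-0.09531, -0.07452]
h2so4^2              -0.05295  [-0.06302, -0.04289]
water^2              -0.02061  [-0.03068, -0.01054]
phenol:h2so4         +0.02100  [+0.00742, +0.03458]
h2so4:water          +0.04700  [+0.03342, +0.06058]
phenol:h2so4:water   -0.01800  [-0.03158, -0.00442]
r2 = 0.9834   r2_adj = 0.9713
delta AICc (selected - full) = -20.93   P(selected correct) = 99.9971%
center points: mean = 0.292, MAD = 0.0082, MAD/mean = 2.8% -> stable
precise condition (coded): [ 0.47  -0.068 -1.682] worst-case rel. error = 0.24%
```

Reading this: absorbance falls sharply with added water (−0.085 per
coded unit) and curves in acid (negative square term); model reduction
keeps the linear phenol term only because the phenol:acid interaction
needs it; the 9-term model beats the full quadratic by ~21 AICc units;
the six center replicates drifted by under 3% of their mean, so the
plate was stable; and with water fixed at 0 µl, a ~1% pipetting error
(0.05 coded units per factor) perturbs the predicted signal by only
~0.24% at the selected condition.

The same workflow is scriptable from the shell:

```bash
assayrsm --seed 1 design --factor phenol:50:10 --factor h2so4:250:50 \
         --factor water:45:27 --out runsheet.csv
assayrsm reduce --data measurements.csv --out fit.json
assayrsm optimize --fit fit.json --fix water=-1.682 --delta 0.05
```

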