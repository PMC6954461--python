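# Methods

## Scope and model

`petdose` implements organ-level internal dosimetry for a positron-emitting
tracer measured with serial quantitative PET.  The chain is:

1. **VOI quantification.**  Organ activity = mean activity concentration
   over the organ mask × VOI volume (Bq → MBq).  Images and masks live on
   one congruent voxel grid (0-based index space); no resampling or
   registration is performed — the intended use is a single-session study
   with co-registered CT-derived masks.  Negative reconstruction artifacts
   are clipped to zero at load, with the clipped-voxel count logged.
2. **Kidney→pancreas spillover correction.**  Renal uptake of this tracer
   class is one to two orders of magnitude above pancreatic uptake, so the
   scanner point-spread function contaminates the pancreatic tail.  The
   left-kidney mask is dilated by a physical margin (default 9 mm; sphere in
   mm, converted to per-axis voxel radii rounded to the nearest voxel, so
   anisotropic voxels keep the margin isotropic); pancreatic voxels inside
   the dilated margin are discarded and re-imputed at the mean concentration
   of the remaining pancreas.  The corrected activity is that clean mean ×
   the *full* pancreas volume — the correction changes the imputed mean,
   never the organ volume.
3. **Remainder of body.**  Mean concentration over (scanned region minus
   source organs) × (total-body volume minus source volumes), assuming a
   homogeneous distribution outside the sources.  Total-body volume uses
   body weight at soft-tissue density (1.05 g/mL); height is recorded for
   provenance but does not enter the rule, because no height-based formula
   is standard enough to prefer.  The estimate is capped at the physically
   decayed injected activity minus the source activities (cap logged).
4. **Kinetics.**  Cumulated activity Ã = head + trapezoid + tail on the
   *physical* (non-decay-corrected) curve; a decay-corrected curve reaching
   the integrator is a hard error, and `to_physical` / `decay_correct`
   convert explicitly.  Head (0 → first scan at ~30 min): instantaneous
   uptake at injection followed by pure physical decay consistent with the
   first sample, integrated analytically — a conservative rule that never
   under-counts the unobserved early phase; a linear-from-zero alternative
   is available (`head_rule="linear_from_zero"`) for sensitivity analysis.
   Tail: A(t_last)/λ (physical decay only after the last measurement).
   TIAC = Ã/A₀ in hours; every TIAC set is validated against the physical
   budget Σ τ ≤ T½/ln 2 = 97.686 min = 1.62808 h for ⁶⁸Ga.
5. **Dose engine.**  MIRD schema with the remainder-of-body S value derived
   by mass-correcting the total-body row; negative remainder algebra
   (possible with approximate tables) clamps to zero with a logged warning.
   Effective dose uses ICRP-60 weights (w_R = 1 for photons and
   electrons/positrons).  Pediatric reports apply adult TIACs to the child
   phantom unchanged.

## Tunable parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| half-life (⁶⁸Ga) | 67.71 | min | standard decay tables |
| Δ_np (⁶⁸Ga) | 0.740 | MeV/decay | β⁺ branch 88.9% × mean 0.836 MeV + conversion electrons |
| photon spectrum | 2×0.511 MeV @ 0.889, 1.077 MeV @ 0.0322 | — | annihilation + principal γ |
| dilation margin | 9 | mm | spillover exclusion radius around the left kidney |
| soft-tissue density | 1.05 | g/mL | body-volume rule |
| head rule | decay_from_first | — | conservative early-phase assumption |
| adult administration | 100 | MBq | standard injected activity |
| newborn / 1-y / 5-y administration | 20 / 20 / 30 | MBq | pediatric activity schedule (<12.5 kg → 20 MBq) |

Only internally consistent quantities are asserted about the nuclear data
(λ·T½ = ln 2, mean lifetime = T½/ln 2); the raw constants are config, not
code.

## S-value provenance

The packaged per-phantom S tables are generated by
`scripts/build_smatrices.py` from transparent approximate physics:
non-penetrating energy absorbed entirely in the source organ (Δ_np/m),
photon self-absorption via a sphere-equivalent absorbed fraction
φ = 1 − exp(−μ_en·0.75R), photon cross-fire via a point-pair kernel with
linear buildup at representative inter-organ distances scaled by cube-root
body mass, and a uniform-distribution total-body row.  They reproduce the
right magnitudes and orderings (kidney self-dose dominant; child doses
rising steeply as organ mass falls) but run roughly 1.5–2× above
study-grade dose-factor tables; they are intended for testing the algebra
and the pipeline, and are labeled approximate in the files themselves.
Nothing in the test suite asserts agreement between these tables and any
published dose-factor library.  The `np_only` mode drops photons entirely
and is exactly self-consistent (S = Δ_np/m), which makes mass-ratio
identities testable in closed form; reports built in this mode carry an
explicit warning flag in their provenance.

Published cohort dose coefficients for the tracer (adult pooled table and
the pediatric extrapolations) are packaged as a reference fixture
(`published_dose_coefficients.csv`) and used for per-administration
scalings and examination budgets.  Two typographic anomalies in the source
tables are handled explicitly: the adult spleen coefficient follows the
results text (0.011 ± 0.001 mGy/MBq) rather than the tabulated 0.001, and
the identical 1-y/5-y small-intestine values (0.047 ± 0.007) are carried
as printed but flagged here as anomalous.

## ICRP-60 weighting details

Weights are config (`icrp60_weights.yaml`), Σw_T = 1 enforced to 1e−9.
Resolution rules where the phantom has no direct row: colon = mass-weighted
mean of upper+lower large-intestine walls; oesophagus → thymus surrogate;
bone surface → osteogenic cells; gonads sex-matched (testes on the male
model, ovaries on the female and on the two-sex pediatric models).  The
remainder (w = 0.05) is the mass-weighted mean dose of the configured
remainder tissues present in the phantom; the ICRP-60 "split rule" for a
remainder tissue receiving the highest dose is not implemented.  Adults are
computed on their sex-matched phantom and pooled into one mixed-sex cohort
table (sex-specific targets averaged over the patients that have them).

## Synthetic data: what it emulates, what it does not

The generator emulates the features the estimators rely on: four scans at
the study schedule (verbatim per-patient times from the packaged six-patient
table, including injected activities whose mean is 105.55 MBq),
kidney-dominated mono-exponential kinetics with slow washout (defaults:
kidneys f = 0.30, pancreas 0.0025, duodenum 0.002, background 0.55; λ_bio
0.3–1 × 10⁻³ min⁻¹; illustrative only, chosen qualitatively), uniform
activity in ellipsoidal organs with the pancreatic tail abutting the left
kidney, Gaussian PSF (default 6 mm FWHM), Poisson noise applied on a counts
scale (concentration × voxel volume × 0.05 counts/Bq, then divided back),
and a ~18 L two-bed-position field of view so the remainder extrapolation
has the geometry it assumes.  Per-patient log-normal jitter (σ = 0.10) on
uptake fractions and clearance rates individualizes the cohort; fractions
are rescaled if a draw would exceed unity.  Randomness flows from one seed
through per-patient substreams, so cohorts are bitwise reproducible and
extensible.

Not emulated: sinogram-level reconstruction, attenuation/scatter,
anatomical realism beyond ellipsoids, respiratory motion, inter-scan
misregistration.  Passing recovery tests therefore demonstrates the
correctness of the estimators under their own assumptions, not robustness
to those real-data effects.

Known estimator biases on the synthetic truth, by design rather than by
defect: the remainder estimator under-counts by the source-volume fraction
of the body (~0.5% here); under PSF blur, kidney spill-out inflates the
scanned-region background and hence the remainder (capped at the physical
budget); the uncorrected pancreas reads ~15% high under 6-mm blur and the
9-mm correction brings it to within a few percent.

## Numerical choices

- Trapezoid integration of a convex decaying exponential *overestimates*;
  at the coarse 30/60/120/240-min schedule the overestimate is ≈3.5% of
  Ã for pure ⁶⁸Ga decay (up to ~4% with slow washout and the real
  per-patient schedules), vanishing with denser sampling.  This
  discretization floor is intrinsic to the stated integration rule and is
  frozen into the unit tests; end-to-end TIAC recovery on clean synthetic
  cohorts is accurate to exactly this floor.
- Strictly increasing sample times are enforced; duplicate time points are
  rejected rather than averaged.
- Times are minutes internally; TIACs are reported in hours to match the
  mGy/(MBq·h) S-value unit.
- Missing S-matrix pairs read as 0 with a one-shot logged warning;
  malformed rows fail loudly with the line number.
- Full precision is kept internally; rounding (3 decimals for per-MBq
  coefficients, 1–2 decimals for per-administration doses) happens only at
  serialization.
- Examination budgets use floor(limit/dose) with a 1e−9 relative epsilon so
  exact ratios are not lost to floating-point.

## Limitations

- Organ-level dosimetry only; no sub-organ (e.g. islet-level) model, no
  bladder-voiding kinetics, no tumor dosimetry.
- The packaged S tables are approximate (above); studies requiring
  regulatory-grade coefficients must supply their own dose-factor CSVs via
  `--smatrix`/`smatrix_file`.
- ICRP-60 weighting only (matching the era of the reference workflow);
  ICRP-103 would be a config addition.
- Masks are assumed co-registered across time points; duodenal activity is
  booked under the small-intestine source region, the closest region
  available in the phantom tables.
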