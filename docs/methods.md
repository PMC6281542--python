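# Methods

## The calibration model

A Centiloid calibration relates two tracers scanned in the same subjects.
centikit models the observed SUVRs as

```
SUVR_tracer,i = m · SUVR_PiB,i + b + ε_i ,     ε_i ~ N(0, σ²)
```

and estimates (m, b) by ordinary least squares with PiB as the independent
variable. OLS — not Deming or orthogonal regression — is used because the
standard Centiloid workflow defines the calibration this way; the reported
R² is the squared Pearson correlation of the pairs. Pairing is strictly by
subject id, so table row order never matters.

The anchor transform `CL = 100·(SUVR − yc0)/(ad100 − yc0)` is exact at its
anchors by construction (CL(yc0) = 0, CL(ad100) = 100, no floating-point
slack, since both are computed as a single affine expression). The direct
tracer-SUVR→CL conversion is the analytic composition

```
slope     = 100 / (m · (ad100 − yc0))
intercept = −(100 / (ad100 − yc0)) · (b/m + yc0)
```

which agrees with the two-step path (invert the fit, then apply the anchor
transform) to 1e−10 over the whole SUVR range — this identity is tested.

### Anchors and rounding

Default anchors are the published GAAIN PiB group means printed to two
decimals, YC-0 = 1.01 and AD-100 = 2.08 SUVR. Composing the published
flutemetamol fit (0.77, 0.22) with these rounded anchors gives
121.37 / −121.09, within 0.1% of the published 121.42 / −121.16; the
residual is presentation rounding in the inputs, so unrounded anchors can
be supplied wherever `CentiloidAnchors` is accepted. Internally all math
is full precision; coefficients are rounded to two decimals only when
printed.

### Standardization direction

Cross-pipeline correction maps are fitted as *reference-on-pipeline*
(standard CL regressed on pipeline CL), so applying the fitted map to
pipeline values puts them on the standard scale. Because the published
correction "0.997x + 0.146" is ambiguous about which variable is x, the
`LinearMap.inverse()` of every fitted map is exposed so either convention
can be applied downstream.

## Image quantification

Volumes and masks must already share one template grid; a shape mismatch
is a hard error, never a silent resample, because spatial normalization is
the job of upstream registration tools and re-implementing it here would
hide mis-registered inputs. Two cheap guards remain: affine headers are
compared and a warning is raised when they differ by more than 1e−3 in any
element, and masks are binarized at 0.5 so probabilistic VOI maps behave
sensibly (the threshold is a package choice; distributed VOI sets do not
document whether they are binary).

Non-finite voxels are excluded from regional means (numerator and
denominator); a warning fires when more than 1% of in-mask voxels are
non-finite, and an all-non-finite or empty region is an error. SUVR is a
ratio of two regional means and is therefore invariant under any global
positive rescaling of the volume — a property test, since it is what makes
SUVR robust to scanner calibration factors.

## QC thresholds

Level-1 validation checks slope ∈ [0.98, 1.02] (inclusive), intercept ∈
[−2, 2] CL (inclusive) and R² > 0.98 (strict); tracer suitability requires
R² > 0.70 (strict). Inclusive bounds for the ranges and strict bounds for
the R² cutoffs mirror the wording of the criteria ("between … and" versus
"> 0.98"); the source criteria do not state boundary handling, so this is
a documented package choice. Cohort-composition checks (≥ 25 subjects,
≥ 10 young controls, ≥ 15 higher-burden subjects) emit warnings rather
than errors because they are recommendations about study design, not
mathematical preconditions.

## Repeatability metrics

Test-retest % difference is signed, per subject, with the test value as
denominator: `100·(retest − test)/test`, applied to SUVR, to SUVR−1, and
to the CL values obtained through the supplied conversion. The defining
formula is not standardized in the field; a mean-of-pair denominator is
available via `denominator="mean"`. A zero denominator (e.g. SUVR exactly
1 for the SUVR−1 measure) yields a per-subject NaN with a warning, and
summary statistics use NaN-aware means/SDs. All SDs in the package use the
sample (n−1) convention.

The variance ratio SD(tracer CL)/SD(PiB CL) recomputed from printed group
SDs reproduces published values only for rows whose printed SDs are
self-consistent under rounding (e.g. 7.2/6.3 → 1.14); a row whose printed
ratio was computed from unrounded SDs can disagree in the last digit
(7.2/6.1 = 1.18 vs a printed 1.19), so tests assert only on the
self-consistent rows.

## Synthetic-data generator

`simulate_cohort` emulates the structure of a real calibration cohort:

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | 24 YHC + 50 other | the 74-subject flutemetamol calibration cohort |
| YHC true PiB SUVR | Normal(1.01, 0.065) | printed young-control group mean/SD |
| "other" true PiB SUVR | Normal(1.57, 0.53), truncated below at 0.85 | printed mixed-group mean/SD; truncation keeps draws in the physical SUVR range |
| tracer response | 0.77·SUVR_PiB + 0.22 | published inter-tracer fit |
| tracer noise σ | 0.08 SUVR | chosen so the population R² of the mixture matches the published 0.96 via the variance decomposition R² = m²·Var(SUVR_PiB) / (m²·Var(SUVR_PiB) + σ²) |
| PiB measurement noise | 0.02 SUVR | small observation noise so observed ≠ true PiB |
| test-retest base model | Normal(1.80, 0.18), rescan noise 0.02 | printed test-session mean/SD; rescan noise gives ~1% SUVR differences, the observed repeatability magnitude |

The left truncation of the mixed group (needed to keep SUVRs physical)
reduces its variance slightly below the untruncated 0.53², so the realized
mean R² over 200 replicates is ≈ 0.953 rather than exactly 0.96 — within
the 0.01 recovery band the tests assert. Simulated SUVRs are floored at
0.05 so that extreme user-supplied noise levels cannot produce invalid
(non-positive) tables; the floor is unreachable at the default settings.

The generator reproduces the *statistical* structure of a calibration
study — group means, spread, linear tracer response, seeded determinism —
but none of the physics of PET: no scatter, point-spread, partial-volume
effects, attenuation, or anatomical geometry. Passing recovery tests
therefore demonstrate that the estimation chain is correct and unbiased
under the assumed model, not that any specific scanner or reconstruction
will achieve these error levels.

Phantoms are abstract boxes (a cortex slab over disjoint reference boxes
in the lower band of a 32³ grid, each region ≥ 50 voxels) with voxel noise
expressed as a fraction of the regional mean (default 2%). The calibration
math never sees geometry, only regional means, so box phantoms exercise
exactly the same code paths an anatomical atlas would.

## Problem sizes

The test suite uses 6³ volumes for oracle comparisons, 32³ phantoms, and
200-replicate simulations of the 74-subject cohort (the end-to-end phantom
test uses one 200-subject cohort, 400 rendered volumes). These sizes give
Monte-Carlo error comfortably below the asserted tolerances; the whole
suite runs in a few seconds.

## Known limitations

- No spatial normalization, registration, brain extraction or
  partial-volume correction: inputs must be on the atlas grid already.
- The "other" group is one truncated normal, not an AD/aMCI/OHC mixture;
  per-subgroup SUVR distributions are not published per tracer, so
  subgroup structure would be invented detail.
- Published PMOD/FSL equations ship as constants; re-deriving them
  requires the original scans.
- Group-difference hypothesis tests (t tests, Kruskal–Wallis) are out of
  scope; per-subject values are exported so any statistics library can be
  applied.
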