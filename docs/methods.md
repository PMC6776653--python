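# Methods

This note documents the models, the synthetic data generator, the numerical
choices and the known limitations of `morpet`.  Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself recompute.

## SRTM quantification

The simplified reference tissue model describes a target-region TAC as

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · [C_R ⊗ exp(−k2a t)](t),
    k2a = k2 / (1 + BP_ND),

assuming (i) the reference region is well described by one tissue
compartment and has negligible specific binding, (ii) target and reference
share the non-displaceable distribution volume, and (iii) target kinetics
are effectively one-compartment.  Validity of the reference region
(occipital grey matter for carfentanil) is checked operationally by the
10–90 min SUV AUC, which must not differ between groups.

**Continuous-time reconstruction.** Measured frame values are frame
*averages* of the underlying activity curve.  The continuous reference curve
is therefore reconstructed by a mean-preserving piecewise-linear rule: frame
boundary values b satisfy (b[i] + b[i+1])/2 = v[i] with b[0] = 0
(pre-injection), so the reconstruction averages back to the data exactly.
Two consequences drove this choice over midpoint interpolation: the forward
model becomes an exact identity at R1 = 1, BP_ND = 0 (the model then simply
returns the measured reference), and the basis-fit regressor for the R1 term
is exactly the measured reference vector.  The reconstruction can
under/overshoot on noisy data (the recurrence alternates measurement error
between adjacent boundaries); the convolution smooths this, and fits are
weighted towards long late frames where the effect is negligible.

**Evaluation grid.** Model curves are evaluated on a 1-second uniform grid
(the 15 s early frames need sub-frame resolution), convolved analytically —
the exponential convolution of a piecewise-linear input has a closed-form
per-step update, implemented as an IIR filter, so there is no quadrature
error beyond the piecewise-linear representation — and averaged over each
frame.  An independent ODE-solver evaluation of the differential form
dC_T/dt = R1 dC_R/dt + k2 C_R − k2a C_T agrees with this path to ~1e−8
relative per frame (tested).

**Estimation.** The basis-function method solves, for each candidate k2a on
a 128-point log-spaced grid over [0.006, 1.0] min⁻¹, the weighted
least-squares problem in the two linear coefficients (R1, k2 − R1·k2a); the
best grid point is then refined by bounded scalar minimisation of the
profile RSS between its neighbours, because the bare 4%-spaced grid alone
limits BP_ND accuracy to worse than the package's 0.02 round-trip target.
Weights default to frame durations (approximating inverse variance of
count-limited frames); fits are invariant to rescaling the activity units.
BP_ND = k2/k2a − 1.  Negative fitted BP_ND is allowed but flagged, as is a
solution at the grid boundary.  A three-parameter nonlinear least-squares
fit (trust-region reflective, bounded) is kept as an independent
cross-check; on noiseless data the two agree to ~1e−7 in BP_ND.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis chain is
designed to detect, not the imaging physics.

* **Regional baselines** (control group): striatal regions at carfentanil
  scale with the canonical dorsal:ventral ratio (≈1.5 : 2.7), rescaled so
  the striatal mean equals the configured control value (default 1.70);
  named extrastriatal regions at literature-like values (thalamus 1.5,
  amygdala 1.6, cortex ≈1); unnamed parcels deterministically spread over
  [0.4, 1.4]; reference region ≈0.02.
* **Group deficit**: the configured striatal mean difference (default
  1.54 − 1.70 = −0.16) is applied additively to the striatal and hedonic
  regions of patients.
* **Covariance structure**: per subject, regional BP_ND deviations are
  sd · (λ_g·u + √(1−λ_g²)·ε) with a shared standard-normal factor u and
  independent ε; the loading λ_g (default 0.5 patients, 0.2 controls) sets
  the inter-regional correlation λ_g² while leaving every region's marginal
  SD equal to `between_subject_sd` (default 0.45).  A larger patient loading
  produces the global covariance elevation; loadings can be restricted to a
  named region subset to plant block-structured (focal) covariance.
  Defaults were chosen so the striatal-mean comparison lands near the
  targeted effect size d ≈ 0.7 at n = 19/20.
* **TACs**: the reference is a two-component gamma-variate template (peak
  ≈16 kBq/mL near 5 min plus a slow washout component); each region's TAC
  is the SRTM forward model of the subject's BP_ND (R1 = 1, k2 = 0.1 min⁻¹)
  against that reference, with Gaussian noise of variance ∝
  activity/frame-duration (count-statistics approximation; default relative
  level 0.05).  At noise 0 the TACs refit to the configured BP_ND exactly.
* **Covariates**: group-specific Gaussian (age, BMI, anhedonia scores,
  non-negative scores clipped at 0) and zero-inflated gamma
  (cigarettes/day) draws at demographic-table scales; independent of BP_ND
  by default, with an optional coupling knob.

What it does **not** emulate: scanner physics (resolution, scatter, motion,
partial volume), arterial input variability, genotype effects on binding,
realistic spatial correlation of noise between neighbouring regions, or any
mechanistic model of why patient covariance is elevated.  Passing tests
therefore validate the *inference chain* — calibration, power, recovery —
under a structurally faithful but idealised data-generating process; they
do not certify performance on real scanner data.

## Covariance network and NBS

Edge statistics are Fisher-z differences z_A − z_B with both correlation
matrices recomputed under every permutation of group labels; one-sided
(patients > controls) by default.  p-values carry +1 smoothing,
p = (1 + #{perm ≥ obs}) / (P + 1), so the minimum attainable p is
1/(P + 1) and never 0.  When the requested permutation count exceeds the
number of distinct relabellings C(n, n_A), the test enumerates all of them
(the identity labelling is then part of the ensemble and no smoothing is
added).  Permutation statistics are stored float32, and observed statistics
are compared at float32, so the identity relabelling ties with itself
exactly.

NBS correction reuses the *same* relabellings as the edge test, so the
component null is consistent with the edge p-values.  Per-permutation edge
p-values are obtained by ranking each permuted statistic within the
ensemble (exchangeable with the observed p by construction, which is what
guarantees family-wise error control); edges below the primary threshold
form a graph whose connected components are measured by *extent* (number of
supra-threshold edges), and the observed component sizes are referred to
the permutation distribution of the maximal component size.

**Choice of primary threshold.**  Because the per-permutation threshold is
rank-calibrated, every permuted graph carries ≈α supra-threshold edge
density.  At α = 0.05 this places the null graph near its percolation
threshold for typical region counts: the null maximal component reaches 3
edges in roughly 10% of permutations, so very small focal structures cannot
attain component-level significance at that threshold no matter how strong
the effect — the 0.05 threshold is sensitive to *extended* differences
(hundreds of edges), which is what it detects on the default effect cohort.
Isolating a focal structure (e.g. a planted 3-region clique) requires the
conservative primary threshold α = 0.001, at which the null graph is almost
empty and a 3-edge clique is decisively significant.  The calibration and
recovery experiments in `morpet.evaluation` quantify both regimes.

The correction implemented is component-level family-wise error control; an
edge-level false-discovery-rate correction answers a different question and
is deliberately not provided (descriptions of this analysis style sometimes
conflate the two).

## Group statistics

Pooled-variance t-tests are primary (df = n_A + n_B − 2; Welch available by
flag).  Cohen's d uses the pooled SD with (n − 1) weights, so d computed
from summary tables (means, SEMs, n) agrees exactly with d from raw values.
The two-way ANOVA uses type-II sums of squares (efficient when the
interaction is null, robust to mild imbalance) and reports F, numerator df
and residual df per factor from first principles: with 2 groups and an
8-region hedonic network the group factor has 1 numerator df and the ROI
factor 7.  Shapiro–Wilk is a gate that logs a warning rather than switching
tests.  Secondary per-ROI comparisons are reported uncorrected by default
(a Benjamini–Hochberg option exists in statsmodels and can be applied to
the comparison table by callers).

## Problem sizes used in the shipped experiments

Calibration and recovery run at deliberately scaled sizes chosen as
adequate for their Monte-Carlo error, not as statements about the method:
null calibration uses 200 replicate 19/20-subject cohorts on 20 regions
with 2000 permutations (Monte-Carlo SE on a 5% rate ≈ 1.5 percentage
points); planted-clique recovery uses 50 replicates of 40/40 subjects on 8
regions; effect-direction uses 100 replicate cohorts plus 10 paired
effect/null cohorts on 20 regions.  The full-size worked example
(125 regions, 7750 edges, 5000 permutations) runs in about a minute.

## Known limitations

* ROI-level only: no voxel-wise parametric maps, no image-domain processing
  (registration, motion, partial-volume correction), no plasma-input models.
* The basis-function fitter assumes the k2a grid brackets the truth; fits
  at the grid boundary are flagged rather than auto-extended.
* Permutation storage is O(P × edges) in float32; 100 000 permutations on
  7750 edges need ~3 GB.  The defaults (≤10 000) are calibrated to the
  cohort sizes involved, where p-value granularity of 1e−4 is ample.
* The exhaustive-enumeration switch treats relabellings, not unordered
  splits, as the unit; for equal group sizes each split and its complement
  are both enumerated (harmless, slightly conservative in runtime).
* Under-powered single cohorts: at d ≈ 0.7 and n = 19/20, a single
  simulated cohort rejects the striatal null only about half the time; all
  directional claims in the shipped experiments are made in aggregate
  across replicates.
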