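# morpet

Reference-tissue PET quantification and covariance-network group inference,
with a synthetic cohort generator.

`morpet` re-implements, as a tested and reusable pipeline, the analysis chain
of a mu-opioid receptor (MOR) PET case-control study with the agonist tracer
[11C]-carfentanil: kinetic quantification of regional binding by the
simplified reference tissue model (SRTM), ROI-level group statistics, and a
group comparison of the inter-regional covariance network of binding
potential with permutation-based network-based-statistic (NBS) correction.
Because subject-level PET data of this kind are rarely shareable, the package
ships a first-class synthetic cohort generator that emulates the study
conditions — a 19-patient / 20-control cohort, a 26-frame 90-minute
acquisition, striatal-scale binding values with a patient deficit, and a
tunable elevation of inter-regional covariance in the patient group — so the
whole chain can be exercised, calibrated and validated end to end.

It is aimed at PET methodologists and psychiatry-imaging researchers who want
a transparent, scriptable ROI-level implementation of this analysis, or a
simulation harness for planning similar studies.

## The models

**SRTM.** A target-region time-activity curve (TAC) C_T(t) is modelled from a
reference-region TAC C_R(t) with negligible specific binding (occipital grey
matter for carfentanil):

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · [C_R ⊗ exp(−k2a·t)](t),
    k2a = k2 / (1 + BP_ND)

with delivery ratio R1, efflux rate k2 (1/min) and non-displaceable binding
potential BP_ND, the measure of receptor availability.  Estimation uses the
basis-function method (closed-form weighted least squares on a log-spaced
k2a grid with local refinement); an independent nonlinear least-squares fit
serves as a cross-check.  A 10–90 min SUV area-under-curve utility supports
the reference-region validity check.

**Group statistics.** Pooled-variance two-sample t-tests with Cohen's d
(pooled SD, (n−1) weights), a two-way group × ROI ANOVA over the hedonic
network (orbitofrontal, cingulate and insular cortices, midbrain, amygdala,
striatum), Pearson correlations and Shapiro–Wilk normality checks.

**Covariance network.** Within each group, the subjects × regions BP_ND
matrix gives a region-by-region Pearson correlation matrix, Fisher
z-transformed (z = arctanh r).  Each of the n(n−1)/2 edges is compared
between groups (statistic z_patient − z_control, one-sided by default) by
permuting group labels and recomputing both matrices under every
relabelling.  Family-wise error over edges is controlled by the NBS: edges
supra-threshold at a primary alpha form a graph whose connected components
are measured by edge count and referred to the permutation null of the
maximal component size.

## Worked example

The numbered scripts under `analysis/` run the full chain on the default
synthetic cohort (125 regions, 19 patients / 20 controls, striatal means
1.54 vs 1.70, patient/control covariance loadings 0.5 / 0.2):

```bash
python analysis/01_simulate_cohort.py    # TACs, subject table, atlas
python analysis/02_fit_kinetics.py       # SRTM -> bpnd.csv
python analysis/03_roi_group_stats.py    # t-tests, ANOVA
python analysis/04_covariance_network.py # permutation + NBS at 0.05 / 0.001
```

which prints (seeded, reproducible):

```
fitted striatal BP_ND, patients: 1.556 +/- 0.072 (n=19)
fitted striatal BP_ND, controls: 1.694 +/- 0.060 (n=20)
striatum: 1.56 +/- 0.07 vs 1.69 +/- 0.06, t = -1.48, df = 37, p = 0.148, d = 0.47
ANOVA group: F(1, 296) = 15.62, p = 9.69e-05
ANOVA group:roi: F(7, 296) = 1.20, p = 0.305
alpha = 0.05: 1241/7750 edges with elevated patient covariance; 1 significant
  component(s), largest 1241 edges (p = 0.0002)
alpha = 0.001: 36/7750 edges with elevated patient covariance; 1 significant
  component(s), largest 13 edges (p = 0.0024)
```

Reading this: the SRTM fits recover the generator's striatal group means
(1.54/1.70) to within sampling noise; a single cohort of this size is
under-powered for the striatal deficit (d ≈ 0.5, p ≈ 0.15 here — the effect
is detected reliably only in aggregate, see `analysis/05_calibration.py`),
while the ANOVA detects the group effect across the hedonic network with no
group × ROI interaction; and the covariance comparison finds a global
increase in patient inter-regional coupling spanning 1241 of 7750 edges at
the 0.05 primary threshold, narrowing to a focal 13-edge component at the
conservative 0.001 threshold.

The same chain is available as a CLI (`morpet simulate|fit|roistats|network|
run-all|report`) driven by a YAML config; `run-all` writes a manifest with a
config hash and per-file checksums sufficient to reproduce a run
byte-identically.

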