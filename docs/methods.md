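# Methods

## Scope and data model

The package implements a quantitative-CT analysis chain for predicting
the need for veno-venous ECMO in ARDS patients: lung aeration
quantification, cross-validated feature-signature discovery, logistic
risk modelling, and a competing-risk evaluation of predicted risk
groups. Clinical CT cohorts of this kind are not publicly shareable, so
the package ships a first-class synthetic-data module and all empirical
claims in the test suite are about recovery of known ground truth on
synthetic inputs, not about clinical performance.

Volumes are 3D arrays of Hounsfield units with per-axis voxel spacing in
mm. The axis convention is fixed throughout: axis 0 transversal
(right → left), axis 1 sagittal (ventral → dorsal), axis 2 longitudinal
(caudal → cranial). NIfTI I/O goes through nibabel with the spacing on
the affine diagonal.

## Phantoms

`generate_phantom` builds the lung as the union of two ellipsoids
(defaults scale with the grid: semi-axes (0.20, 0.34, 0.39) of the
physical extent, centred at 0.30/0.70 of the transversal extent).
Voxels inside the lung draw a compartment label from a categorical
distribution and then an HU value from that compartment's Gaussian,
truncated to [−1024, 100]:

| compartment        | HU mean | HU sd |
|--------------------|---------|-------|
| hyperinflated      | −950    | 25    |
| normally aerated   | −750    | 80    |
| poorly aerated     | −300    | 110   |
| non-aerated        | +20     | 40    |

The means sit centrally inside the aeration intervals used downstream,
so labels survive threshold-based reclassification up to tail overlap
(a few percent of mass per neighbouring interval). Background voxels
get soft-tissue HU (Gaussian mean 40, sd 10, clipped to [0, 60]).

Gravity-dependent atelectasis is modelled by adding
`gradient_strength · (depth − 0.5)` to the non-aerated log-odds, where
`depth` is the normalized ventral→dorsal position inside the lung
bounding box. The baseline log-odds are recalibrated by a deterministic
bisection so that the *mean* non-aerated probability over the actual
lung voxels equals its target fraction; the other compartments share
the remainder proportionally, so all four lung-wide fractions are
unbiased regardless of the gradient. Default fractions are
(0.05, 0.45, 0.25, 0.25) with gradient strength 2 — a moderately
diseased ARDS-like lung; the realized threshold-based fractions stay
within ±0.05 of target on ≥ 64³ grids (typically within ±0.02 at 96³).

The phantom deliberately omits airways, vessels, scanner reconstruction
kernels and acquisition-protocol heterogeneity. Consequently, passing
tests demonstrate correctness of the feature definitions and recovery
machinery, not robustness to real-scanner variability.

## Cohorts

`generate_cohort` draws clinical covariates from truncated normals
matched to an ICU ARDS population (age 62 ± 11 y, Pmean 13.6 ± 2.7
cmH₂O, lactate 1.6 ± 1.2 mmol/L, CRP 174 ± 108 mg/L, normally aerated
fraction 0.492 ± 0.15). Each subject's ECMO probability p comes from a
ground-truth logistic model (default: the published combined model).
Event times use cause-specific exponential hazards: the ECMO rate is
−log(1−p)/horizon (so that, absent death and early censoring, the
probability of an ECMO event by the horizon equals p exactly — this is
what makes logistic-recovery tests well-posed), death is an independent
exponential (default 0.012/day ≈ 51 % 60-day mortality), and follow-up
is administratively censored at the horizon (default 60 days).

`generate_planted_signal` builds the benchmark for signature discovery:
one causal standard-normal feature driving a Bernoulli outcome (slope
2.5, intercept −0.5 → roughly balanced classes), plus 50 decoys in five
blocks sharing latent factors (pairwise ρ ≈ 0.6) that carry a weak
loading (0.2) on the causal feature — decoys are marginally informative
and mutually redundant, exactly the structure the clustering + MRMR +
Borda pipeline is meant to see through.

## Mask processing

Threshold segmentation (HU < −200 by default) stands in for learned
segmentation on phantoms; externally supplied masks are accepted
anywhere a mask is an input. Post-processing applies one binary closing
with a 3×3×3 structuring element followed by retention of the largest
K = 2 connected components at 26-connectivity — the smallest standard
choices consistent with "fill small holes, remove isolated artifacts".
Closing runs on an edge-replicated padding so masks touching the grid
boundary are not eroded. Resampling is centre-aligned nearest-neighbour
with spacing rescaled to preserve physical extent.

## ROI registry

Exactly 42 ROIs: 8 spatial, 4 functional, 30 intersections
({left,right} × {cs2, cs3} ventral–dorsal compartments = 10,
{left,right} × 4 aeration compartments = 8, cs3 thirds × 4 aeration
compartments = 12). Conventions chosen where the construction is
underdetermined:

- the two-compartment split places the coronal plane at the unweighted
  voxel centroid; plane voxels go dorsal;
- the three-compartment split divides the bounding-box depth into
  near-equal thirds with remainder slices assigned dorsal-most
  (depth 10 → 3/3/4);
- aeration intervals are right-open except the last (−900 HU counts as
  normally aerated) and HUs are clamped to [−1000, 100] first;
- left/right assignment is by connected component and transversal
  centroid, with an optional midline-plane fallback for fused masks.

## Features

Per-voxel gas volume is (HU/−1000)·V_voxel with HU clamped to
[−1000, 0] — without the clamp, HU > 0 would give negative gas and
HU < −1000 more gas than the voxel holds. Water is the exact remainder
(V_gas + V_water = V_ROI holds to the last bit) and tissue weight is
V_water · 9.933·10⁻⁴ g/mm³ (density of water at 37 °C). HU statistics
use sample conventions: sd with ddof = 1, adjusted Fisher–Pearson
skewness, bias-corrected excess kurtosis (normal → 0); degenerate cases
(fewer than 3–4 voxels, zero variance) are reported as missing, never
as zero. The centre of gravity weights voxels by HU + 1000 clamped at
zero — proportional to physical density under the gas–water model,
resolving the ambiguity of "HU-weighted" for negative HUs — and is
normalized to [0, 1] between the lung bounding-box faces per axis.
Empty ROIs yield zero volumes/dimensions and missing distribution
statistics, keeping the 592-column schema rectangular.

## Signature discovery

Five-times repeated five-fold stratified cross-validation (single seed).
Per fold, fitted on development data only: Yeo–Johnson maximum-
likelihood λ per feature, then z-normalization (constant features
dropped); complete-linkage HAC on the distance 1 − |Spearman ρ| cut at
0.25 so within-cluster pairs satisfy |ρ| ≥ 0.75; cluster
representatives by largest absolute rank-biserial effect (ties
lexicographic); Mann–Whitney exclusion at p > 0.2; greedy MRMR with the
mutual-information difference criterion on 4-bin equal-frequency
discretized features (ties resolve to earlier column order, making the
ranking deterministic); unpenalized logistic development on the top 5
ranked features with AUROC logged on the held-out fold. Borda points
are k − position per fold (length-k ranking, 1-based position; unranked
features 0). Dense rank groups over Borda scores feed the finalization:
max-Wald per group, then a rank-ordered scan dropping candidates with
|ρ| > 0.5 to an already-retained feature.

MRMR variants and Borda conventions differ across implementations; the
variant here (MID, 4 bins, k − position) is config-exposed and fixed by
the defaults above.

## Risk models and evaluation

Logistic fits use statsmodels maximum likelihood; the per-term table
reports B, SE, Wald = (B/SE)², p, OR = exp(B) and the 95 % Wald CI.
Singular designs and non-convergence raise with the offending covariate
names. The three published fixed-coefficient models (imaging, clinical,
combined) live in a versioned JSON constants file guarded by a checksum
test. The Youden cutoff scans observed
probabilities and breaks ties at the lower threshold. AUROC is the
trapezoidal/U-statistic value; its CI uses a class-stratified bootstrap
(2000 reps, seeded) by default with DeLong available behind a switch.
The 2×2-table chi-square is computed without continuity correction.

## Competing risks

Event codes: 0 censored, 1 ECMO initiation, 2 death without prior ECMO.
The Aalen–Johansen CIF satisfies CIF₁ + CIF₂ + S = 1 at every event
time. Gray's test is computed in its score form: a weighted log-rank
statistic over inverse-probability-of-censoring-weighted (IPCW)
subdistribution risk sets — subjects with a competing event at s remain
at risk at t > s with weight G(t⁻)/G(s⁻), where G is the pooled
censoring Kaplan–Meier. This form is asymptotically equivalent to the
classical variance construction (the test suite checks agreement with
R's `cmprsk` within 20 % on the statistic with matching significance
calls) and reduces exactly to the log-rank test when no competing
events exist. Fine–Gray regression maximizes the Breslow-tied partial
likelihood on the same weighted risk sets by Newton–Raphson
(single covariate); SE, CI and p come from the observed information.
Divergent estimates (monotone likelihood) raise rather than return a
spurious SHR. Without competing events the fit coincides with the
cause-specific Cox model to numerical precision.

## Problem sizes and tolerances

Defaults used by the tests and the acceptance script: phantoms at 64³
(unit tests) and 96³ (calibration checks, 10 seeds, ±0.05), signature
recovery on n = 200 with 51 features over 10 seeds (≥ 9/10 top-Borda
hits required), logistic recovery at n = 5000 within 3 SEs on all
terms over 10 seeds, Fine–Gray recovery of a true SHR 2.0 at n = 2000
within 3 SEs over 10 seeds, a scaled-down CI-coverage simulation (120
reps at n = 250, accepted range 88–99 %), and exact (≤ 1e-6 / 1e-9)
checks for the conservation laws, partition laws and brute-force
equivalences. The end-to-end pipeline default is 60 subjects at 64³,
chosen as a desk-scale cohort.

## Known limitations

- The 42-ROI composition and several conventions (closing kernel,
  centroid rule, COG weighting, MRMR variant) are reasonable fixed
  choices among several defensible ones; alternative conventions would
  change individual feature values but not the schema or the pipeline.
- Gray's test uses the score-form variance, not the classical one; at
  small samples the two can differ by ~10–20 % in the statistic.
- Fine–Gray supports a single covariate (the predicted risk group),
  which is all the evaluation needs; multivariable subdistribution
  regression is out of scope.
- The phantom and cohort generators share no anatomy or physiology
  beyond what is stated above; results on them bound software
  correctness, not clinical validity.
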