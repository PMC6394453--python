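# Methods

`petstrat` implements a whole-tumor-burden FDG-PET quantification and
outcome-stratification pipeline for TKI-treated cohorts (the motivating
setting is advanced medullary thyroid cancer under vandetanib): SUV
statistics and volumetric burden, intratumoral texture features, baseline →
follow-up change, and ROC/Youden-dichotomized Kaplan–Meier and Cox survival
analysis, together with a synthetic phantom/cohort generator that makes the
whole chain testable without patient data.

## Image quantification

**SUV conversion.** Activity concentration c(v) in kBq/ml becomes the
body-weight standardized uptake value SUV(v) = c(v) / (D_corr / W), where
D_corr = A·2^(−Δt/T½) is the injected activity decay-corrected from
injection to scan time (T½ = 109.77 min for ¹⁸F, overridable) and W is body
weight in grams under the conventional 1 g/ml tissue density, so kg→ml is a
numeric identity. The decay reference time is the injection time, the
standard SUV-bw convention.

**VOI model.** Masks are binary grids on the volume's voxel lattice; the
per-patient analysis mask is the voxel-wise union of all lesion masks (the
whole tumor burden). MTV is the mask voxel count times voxel volume — the
delineation *is* the metabolic volume, with no thresholded
sub-segmentation — and TLG = MTV × SUVmean, which is algebraically the
voxel-wise SUV integral over the VOI. Baseline and follow-up scans are
quantified independently; no registration or resampling is performed
because only scalar feature values are compared between timepoints, via
Δ% = ((follow-up / baseline) − 1)·100.

## Texture features

All texture is computed on one VOI at a time after **fixed-bin-count
quantization** over the in-mask min–max range: level = min(G, ⌊(x − min) /
((max − min)/G)⌋ + 1), with G = 64 by default (a config knob that reports
must record; commercial radiomics tools rarely disclose their binning, so
absolute feature values are only comparable within one configuration). A
constant VOI maps to a single level. Min–max binning makes every quantized
feature invariant to adding a constant to the VOI.

**First order.** Population standard deviation and Fisher *excess*
kurtosis (m₄/m₂² − 3) of the raw in-mask SUVs. A zero-variance VOI reports
kurtosis 0 with a degenerate flag.

**GLCM.** Voxel pairs at Chebyshev distance 1 (13 unique offsets, both
orderings, both voxels in-mask) are pooled into a single G×G symmetric
matrix and normalized once — a pooled matrix rather than per-direction
feature averaging. Entropy = −Σ m·log₂ m (bits); Homogeneity =
Σ m(i,j)/(1 + |i−j|).

**NGTDM.** For each in-mask voxel with level i and at least one in-mask
26-neighbor, the deviation |i − Ā| from the mean level Ā of its in-mask
neighbors accumulates into s(i); p_i is the level occupancy among those
valid voxels. Edge handling uses the variable in-mask neighbor count, never
zero padding, so background cannot contaminate tumor texture and features
are independent of how much background surrounds a lesion (verified by a
padding-independence test). The Amadasun–King features follow:

* Coarseness = 1 / (ε + Σ p_i s_i), ε = 1e-9; a uniform VOI therefore
  reports 1/ε with a degenerate flag.
* Contrast = [ΣΣ p_i p_j (i−j)² / (N_gp(N_gp−1))]·[Σ s_i / N], 0 when only
  one level is occupied.
* Busyness = Σ p_i s_i / ΣΣ_{i≠j} |i·p_i − j·p_j|, 0 for a zero denominator.
* Complexity = ΣΣ |i−j| (p_i s_i + p_j s_j) / (N (p_i + p_j)) over occupied
  level pairs.

The neighborhood is 26-connected in voxel space; physical anisotropy is
ignored in the neighbor definition (a recorded limitation for strongly
anisotropic grids). Every matrix and feature is checked against naive
loop-based reference implementations to 1e-9 relative error on random
fixtures, and against hand-worked values on a 1×1×4 line fixture.

## Survival analysis

**Endpoints.** PFS = progression (event) or censor date minus treatment
start; OS = death (event) or censor date minus start; durations in years
(365.25 d/y).

**ROC labelling.** For OS the positive class is "death observed during
follow-up", for PFS "progression observed". No landmark time is imposed —
with small cohorts and long follow-up this is the pragmatic choice, but it
mixes follow-up length into the label and is flagged as a limitation. AUC
is the tie-aware Mann–Whitney concordance (ties ½), and the reported ROC
p-value is the two-sided Mann–Whitney test of AUC = 0.5.

**Youden cutoff.** J = sensitivity + specificity − 1 is maximized by
exhaustive scan over the midpoints between consecutive sorted unique
values plus ±∞; ties in J break toward the lowest cutoff; "high risk"
means strictly greater than the cutoff, so values tied with the cutoff go
low. An all-equal feature yields J = 0 with a degenerate flag.

**Kaplan–Meier / log-rank.** Product-limit curves, medians (smallest t
with S(t) ≤ 0.5, undefined if never reached) and the two-sided log-rank
test are delegated to lifelines; median follow-up uses reverse KM.

**Cox model.** The partial likelihood is maximized by Newton iteration
with step halving, converging at gradient max-norm < 1e-8. Tied event
times use the Breslow approximation by default (Efron available); Wald
CIs are exp(β ± 1.96·SE) from the observed information. Monotone
likelihood (perfect separation) is detected via |β| > 20 or
non-convergence and flagged on the result — no silent estimate. The fit is
cross-checked in tests against lifelines on tie-free data and against a
brute-force grid maximization of the directly-summed Breslow likelihood on
a tied fixture. The stratification report runs univariate Cox per
feature × endpoint on the dichotomized groups and one multivariate Cox per
endpoint over the ROC-significant features (entered dichotomized, since
cutoffs are the quantity of clinical interest here). Raw p-values are
reported with an explicit no-multiplicity-correction note, mirroring
small-cohort exploratory practice.

**Doubling time.** ln 2 over the least-squares slope of ln(marker) vs
time; slopes below 1e-10/y report "flat" (infinite DT), negative slopes a
"declining" flag.

## Synthetic data

**Phantoms** are background grids (default 0.5 SUV) with additive Gaussian
noise (clipped at 0) and spherical lesions filled by pattern: uniform,
checkerboard (mean ± amplitude by voxel parity), Gaussian noise, or radial
gradient (mean + amplitude at center falling linearly to mean at the
rim). Lesion fills overwrite the background noise, so uniform lesions are
*exactly* uniform and drive every texture feature to its analytic
degenerate value regardless of background noise — intra-lesion noise is
modelled explicitly via the Gaussian-noise pattern. Overlapping lesions
warn and the earlier lesion keeps the shared voxels. What phantoms do
*not* emulate: Poisson projection noise, scanner PSF/reconstruction
effects, non-spherical lesion geometry, or inter-scanner variability —
passing phantom tests therefore validates the arithmetic of the feature
chain, not robustness to acquisition physics.

**Cohorts** draw a latent low/high-risk group (Bernoulli, default 55%
high), features from group-conditional log-normals (complexity, TLG and
contrast carry the group signal; the other nine are identical across
groups), and event times from exponential distributions with hazard
λ·HR^group — constant hazards make proportional hazards hold exactly, so
Cox recovery of the generative HR is an unambiguous oracle. Defaults
emulate an 18-patient advanced-MTC cohort: OS hazard 0.17/y in the
low-risk group (median ≈ 4 y), progression hazard twice the death hazard,
HR = 6, per-patient administrative censoring uniform between 3 and 10.3
years of follow-up (staggered accrual), and 2/18 patients lacking
follow-up feature records (round(fraction·n), drawn without replacement).
Follow-up feature values are baseline times a log-normal multiplier whose
medians reproduce cohort-level declines under therapy (everything falls
except homogeneity). All randomness flows through one seeded numpy
Generator per call; identical spec + seed gives bit-identical output.

## Calibration and problem sizes

The test suite and `scripts/acceptance.py` check, under the simulator's
own generative model: type-I error of log-rank and Cox Wald tests (1000
null cohorts of n = 200, acceptance band 5% ± 2%); Cox HR recovery at
n = 2000 without censoring (band [5.0, 7.2] around HR = 6); and
full-pipeline recovery — ROC cutoff → dichotomized groups → Cox — with the
median estimated HR over 100 cohorts of n = 500 within 25% of the
generative HR = 6. The pipeline estimate sits below the generative value
(typically ≈ 5.2): cutoff estimation misclassifies a few percent of
patients and dichotomization attenuates the group contrast, which is
exactly the behavior the recovery band is meant to bound. Texture oracle
equivalence uses 100 random 8³ masked volumes at G = 6; these sizes keep
the default suite fast while leaving the brute-force oracles tractable.

## Known limitations

* Quantization (G), ε and tie conventions differ between radiomics
  implementations; absolute texture values are not comparable across tools
  and reports must record the configuration.
* Neighbor definitions ignore voxel anisotropy.
* No scanner harmonization or partial-volume handling is attempted.
* The ROC outcome label has no landmark time (see above).
* The multivariate Cox enters features dichotomized; continuous entry
  would be a reasonable alternative and typically yields different HRs.
* On mostly-uniform synthetic lesions, Σ p_i s_i can approach zero and
  coarseness approaches its ε-limited ceiling; cohort means of coarseness
  are then dominated by the degenerate value — a property of the
  statistic, flagged in the per-patient output.
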