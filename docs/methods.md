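# Methods

## Signal model and units

All tensors are symmetric 3×3 matrices in units of 10⁻³ mm²/s; b-values in
s/mm². The forward model is monoexponential, S = S₀·exp(−b·gᵀDg), evaluated
per scheme entry. The acquisition emulated throughout is a single shell at
b = 1000 s/mm² with 64 approximately uniform unit directions (normalised
Gaussian draws, redrawn if the 6-column tensor design is rank-deficient)
plus one b = 0 volume. Axes follow the RAS convention: x = right–left,
y = anterior–posterior, z = inferior–superior. Gradient tables are written
in the FSL dialect (one-row `bval`, 3×N `bvec` with zero columns for b = 0).

## Phantom

Each subject is a cubic grid (default 64³ at 1 mm isotropic; the "smoke"
profile uses 32³) partitioned into disjoint homogeneous regions: a
projection-fiber block (tensor diagonal-dominant on z), an
association-fiber block (dominant on y), a quasi-spherical ventricle of
free water (isotropic 3.0), WMH lesions (isotropic 1.2), and background
parenchyma (isotropic 0.8), all inside a quasi-spherical intracranial (ICV)
mask; signal outside the head is zero. Region positions scale linearly from
a 32-voxel template, and the two template ROI centers sit at the fiber-block
centroids in the left hemisphere (low x).

Anatomical volumes are represented at a declared 1:100 scale
(`volume_scale = 0.01`): a ~1.45 L intracranial volume cannot be voxelised
inside a grid small enough for the index math, so masks carry scaled voxel
counts and volumetry divides by the scale when reporting millilitres. All
volume *ratios* (VV/ICV, WMHv/ICV) are preserved up to the voxel quantum
(0.1 mL at default settings). Noise is Rician: each voxel value S becomes
√((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, (S₀/SNR)²). The default SNR of 40 is a
package choice — a typical value for 3-T single-shot EPI diffusion data —
not a quantity the emulated protocol reports.

## Cohort generator

Defaults reproduce the reference study conditions: 41 patients (iNPH) and
40 controls. Per group the generator draws

- **true ALPS** ~ Normal(1.074, 0.225) for patients, Normal(1.559, 0.161)
  for controls;
- **six region diffusivities** ~ Normal with the published group means/SDs,
  after which the two numerator terms (Dx in both blocks) are rescaled by a
  common factor so the subject's four formula diffusivities reproduce the
  drawn true ALPS *exactly*. Draws producing any nonpositive diffusivity
  are rejected and resampled (warning; hard error after 200 tries). A
  consequence worth knowing: the cohort means of the two Dx terms drift
  from their configured values because of the rescaling — the generator
  anchors on the index distribution, which is the quantity every downstream
  analysis consumes. (The published per-axis group means are not jointly
  consistent with the published index means, so both cannot be anchored.)
- **VV/ICV** log-normal (median 8.6 %, log-SD 0.24 for patients; median
  2.3 %, log-SD 0.30 for controls — control ventricles are not reported in
  the reference cohort and use a normal-elderly value); **ICV** ~ Normal
  (1450, 130) mL truncated above 1 L (implied by VV 125 mL at VV/ICV
  8.6 %); VV = (VV/ICV)·ICV. The log-SDs are matched so the expected sample
  range over ~40 subjects spans the published ranges.
- **WMH volume** log-normal (median 36.8 mL, log-SD 0.66 patients; median
  1.03 mL, log-SD 0.22 controls), matched the same way.
- **age** ~ Normal(68.6, 5.9) / Normal(67.4, 4.6) truncated below 60;
  **sex** Bernoulli with the published male fractions (23/41, 17/40).
- **Fazekas grades** are generator metadata, not an imaging computation:
  ordinal 0–3 from fixed lesion-volume thresholds (periventricular
  0.9/15/50 mL, deep 0.7/12/45 mL, declared in config), chosen so the
  implied grade frequencies resemble the published tables.

The dependence between true ALPS and VV/ICV uses a Gaussian copula: the two
normal scores are correlated at r_Pearson = 2·sin(π·r_Spearman/6) and the
VV/ICV score is transformed through its log-normal quantile function, which
controls Spearman's ρ exactly (default target −0.446, applied within each
group, measured on the patient group). With any group SD set to zero the
draws collapse to identical subjects and records carry a `degenerate` flag.

## Tensor fit and maps

Per voxel, ordinary least squares of log-signal on the 6-element tensor
design plus log-S₀ — exact on noiseless data, which gives the pipeline its
end-to-end identity (noiseless fit→ROI→index recovers true ALPS to well
under 10⁻⁶). Weighted least squares is deliberately not the default; the
fit choice is isolated behind `fit_tensor` if an alternative is wanted.
Nonpositive samples are excluded from that voxel's fit; a voxel with fewer
than 7 usable measurements (or a rank-deficient reduced design) is marked
invalid. Dx, Dy, Dz are the laboratory-frame diagonal elements clamped at
zero for map reporting (the raw tensor is retained); FA uses eigenvalues
clamped at zero, keeping it in [0, 1]. No spatial smoothing anywhere.

## ROIs and readers

Spherical ROIs (default diameter 5 mm) include every voxel whose *center*
lies within the radius — no partial volumes, so ROI membership is exact and
a brute-force lattice enumeration is the test oracle (81 voxels at 1 mm).
ROI centers are fixed template coordinates in the synthetic space, standing
in for colour-FA-guided manual placement, which would require registration
machinery that is out of scope. Reader variability is modelled purely as an
independent uniform displacement of both ROI centers within a ball of
radius `reader_jitter_mm` per simulated reader (two readers). The two
readers' diffusivities are averaged component-wise and the index is
recomputed from the averages; the mean of the two per-reader indexes is
also emitted since the two conventions differ in general. Because the
fiber blocks are homogeneous, jitter only affects measurements when the
sphere approaches a region boundary: between-reader ICC in the phantom is
therefore near 1 (comfortably in the > 0.7 regime) — real-world placement
disagreement over heterogeneous tissue would be larger.

## Statistics

- Normality gate: Shapiro–Wilk at α = 0.05 on each sample; both normal →
  Welch's (unequal-variance) t-test, otherwise Mann–Whitney U. Constant
  samples route to Mann–Whitney. For n ≤ 8 in both groups the U test is an
  exact full enumeration over all group assignments computed on midranks
  (valid under ties); otherwise the tie-corrected normal approximation
  without continuity correction.
- Chi-square: Pearson, no continuity correction, 2×c tables; all-zero
  grade columns are dropped before testing (zero marginals are an error).
- ICC: two-way random effects, single measures, absolute agreement —
  ICC(2,1) from mean squares, with a 95 % CI by the F-distribution method
  (Satterthwaite df for the rater term). Chosen as the stricter standard
  form for interobserver reliability; the consistency form is exercised
  only as a test oracle. Zero between-subject variance returns ICC 0 with
  a degenerate flag.
- Spearman: average ranks for ties; p from the t-approximation on n−2 df.
- Regression: OLS with intercept, t-based 95 % CIs, two-sided p. The two
  study models are ln(VV/ICV) on {ALPS, age, sex, WMHv} and ln(WMHv/ICV)
  on {ALPS, age, sex, VV/ICV} in the patient group (the asymmetric
  normalisation of the adjusting volume is reproduced as specified, not
  harmonised). Sex is coded 1 = male. Rank-deficient designs raise an
  error naming the collinear columns.
- ROC: the score is oriented so a lower index flags disease. AUC is the
  tie-corrected Mann–Whitney estimator (equal to the all-pairs concordance
  fraction, which is the test oracle). The cutoff maximises Youden's J
  over midpoints between adjacent observed scores (plus the observed
  values and sentinels beyond the extremes); J-ties break toward higher
  sensitivity, then the lower cutoff; classification is index ≤ cutoff →
  disease. Sensitivity/specificity are reported in percent at the cutoff.
- Two-sided tests throughout, α = 0.05, no multiplicity correction; every
  table cell reports its raw p.

## Determinism and problem sizes

All randomness descends from one root `numpy` `SeedSequence`; the cohort,
the gradient scheme and the reader jitter use spawned substreams, and each
subject carries its own noise seed drawn inside the cohort stream. Report
floats are written at fixed precision, so identical config + seed yield
byte-identical artifacts.

Two measurement profiles exist. The full-grid profile builds the complete
phantom per subject (used for single-cohort analyses; the 41+40 cohort at
32³ takes about a minute and a half on one CPU). The replicate profile
simulates each fiber block as a small homogeneous patch just large enough
for the jittered sphere — identical forward model, noise, fit and ROI code
on a smaller grid — and is used where hundreds of replicate cohorts are
needed (the 200-cohort Spearman average, reader-agreement Monte-Carlo).

## What the generator does not emulate

No real anatomy: no crossing or curving fibers, no partial-volume mixing at
region boundaries, no susceptibility/eddy/motion artefacts, no registration
step (phantoms are born in a common space), no FLAIR contrast (lesion masks
are ground truth, not segmentations), and visual WMH grading is replaced by
a declared threshold rule. Passing tests therefore demonstrate that the
*computational chain* — index formula, tensor fit, ROI extraction,
volumetry, statistics — is correct and stable under realistic noise, not
that the pipeline segments or registers real images. Per-subject volumes
are stored at a 1:100 anatomical scale, so absolute mask volumes in the
NIfTI artifacts must be read together with `volume_scale`.
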