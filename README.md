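# alps-glymph

Synthetic-cohort pipeline for **DTI-ALPS** analysis of glymphatic function —
the diffusion-MRI index used to compare perivascular water diffusion between
idiopathic normal pressure hydrocephalus (iNPH) patients and healthy
controls, and to relate it to ventriculomegaly and white-matter
hyperintensity (WMH) burden.

## The science

At the level of the lateral-ventricle body, medullary perivascular spaces
run right–left (the scanner *x*-axis), perpendicular both to projection
fibers (inferior–superior, *z*) and association fibers (anterior–posterior,
*y*). Diffusivity along *x* measured inside those two fiber regions
therefore carries a perivascular component, and the ALPS index

```
ALPS = (Dx_proj + Dx_assoc) / (Dy_proj + Dz_assoc)
```

contrasts it with diffusivities perpendicular to both the fibers and the
perivascular space. An index near 1.0 means no perivascular-direction
excess; larger values mean freer perivascular diffusion. In iNPH the index
is markedly reduced and correlates negatively with normalised ventricular
volume (VV/ICV).

Because no patient data can ship with an analysis pipeline, this package
generates its own ground truth: voxelised DWI phantoms (single shell,
b = 1000 s/mm², 64 directions, Rician noise) whose fiber-block tensors are
constructed so each synthetic subject's true ALPS is known exactly, whose
group distributions follow the published iNPH/control cohort (41 vs 40
subjects, ALPS 1.074 ± 0.225 vs 1.559 ± 0.161), and whose true ALPS is
coupled to VV/ICV by a Gaussian copula at Spearman ρ = −0.446. Everything
downstream — log-linear tensor fitting, 5-mm spherical ROIs, two-reader
averaging, mask-based volumetry, and the statistics battery (Shapiro–Wilk
gate, Welch t / Mann–Whitney U, chi-square, ICC(2,1), Spearman, adjusted
OLS, ROC with Youden cutoff) — is then validated against that known truth.

## Worked example

```python
from alps_glymph import RunConfig, PhantomSettings, run_pipeline

cfg = RunConfig(seed=17, phantom=PhantomSettings(grid_n=32),
                reader_jitter_mm=0.0, verbosity=0)
report = run_pipeline(cfg, "results/demo")
for row in report["table3_groups"]:
    print(row["metric"], "|", row["nc"], "|", row["inph"], "| p =", row["p"])
print(report["roc_summary"])
```

prints (seed 17, smoke 32³ grid):

```
dx_proj | 0.681 (0.132) | 0.616 (0.256) | p = 0.156588
dx_assoc | 0.655 [0.389-1.142] | 0.419 [0.079-1.291] | p = 1.1e-05
dy_proj | 0.446 (0.126) | 0.562 (0.248) | p = 0.009989
dy_assoc | 0.587 (0.058) | 0.607 (0.159) | p = 0.439257
dz_proj | 0.606 (0.068) | 0.690 (0.247) | p = 0.040247
dz_assoc | 0.448 (0.097) | 0.442 (0.212) | p = 0.871003
alps | 1.527 (0.147) | 1.090 (0.204) | p = 0.0
{'auc': 0.9683, 'cutoff': 1.2844, 'sensitivity_pct': 92.68,
 'specificity_pct': 92.5, 'orientation': 'lower score = disease'}
```

Reading this: the measured group ALPS means (1.527 controls, 1.090
patients; mean (SD) or median [range] depending on the normality gate)
recover the generating distributions through the full fit→ROI→index chain,
the groups separate at p ≪ 0.001, and the ROC of the index (oriented so a
*lower* index flags disease) discriminates the groups with AUC ≈ 0.97 at a
Youden-optimal cutoff of ≈ 1.28. The run directory also receives the
per-subject cohort table, the five analysis tables (clinical comparison,
interobserver ICC, group diffusivities, patient-group Spearman matrix,
adjusted regression), the ROC summary, and a manifest with the config hash
and seed; identical config + seed reproduce every artifact byte for byte.

The same run is available from the shell:

```bash
alps-glymph all --seed 17 --out results/demo        # defaults: 41+40, 64³
alps-glymph simulate --seed 17 --out results/sim --n-subjects 2
alps-glymph fit --dwi results/sim/P001/dwi.nii.gz \
    --bval results/sim/P001/dwi.bval --bvec results/sim/P001/dwi.bvec \
    --mask results/sim/P001/mask_icv.nii.gz --out results/maps
alps-glymph stats --cohort results/demo/cohort.tsv --out results/stats
```

with an optional YAML config (`--config run.yaml`) controlling cohort
sizes, distribution parameters, grid, SNR, scheme, ROI diameter and reader
jitter; unknown keys are rejected and a seed is mandatory.

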