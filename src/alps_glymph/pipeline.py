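"""End-to-end orchestration: simulate -> fit -> ALPS -> volumetry -> stats.

A run is fully described by a `RunConfig` (YAML-loadable, strict keys) and a
seed; all randomness descends from one seeded root generator with per-stage
substreams, so a given config + seed reproduces every output byte (floating
point text is written at fixed precision).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionScheme, make_scheme, write_fsl_gradients
from .alps import ROISpec, ALPSResult, average_readers, subject_alps
from .cohort import (
    CohortParams,
    GroupParams,
    PhantomSettings,
    SubjectRecord,
    phantom_spec_for,
    sample_records,
)
from .io import write_nifti, write_table
from .phantom import add_rician_noise, build_phantom, roi_template_centers
from .stats import (
    chi_square,
    compare_groups,
    icc_absolute,
    ols_adjusted,
    roc_analysis,
    spearman,
)
from .tensor import derive_maps, fit_tensor
from .volumetry import volume_report

__all__ = [
    "RunConfig",
    "ConfigError",
    "validate_config",
    "measure_subject",
    "measure_subject_patch",
    "run_cohort",
    "compute_stat_report",
    "run_pipeline",
]

log = logging.getLogger("alps_glymph")

DIFF_KEYS = ("dx_proj", "dx_assoc", "dy_proj", "dy_assoc", "dz_proj", "dz_assoc")


class ConfigError(ValueError):
    """Raised with an aggregated list of configuration violations."""


@dataclass(frozen=True)
class RunConfig:
    seed: int
    cohort: CohortParams = CohortParams()
    phantom: PhantomSettings = PhantomSettings()
    n_directions: int = 64
    b_value: float = 1000.0
    roi_diameter_mm: float = 5.0
    reader_jitter_mm: float = 1.0
    save_volumes: bool = False
    verbosity: int = 1


_SCHEMA = {
    "seed": None,
    "save_volumes": None,
    "verbosity": None,
    "scheme": {"n_directions", "b"},
    "phantom": {"grid_n", "voxel_size", "s0", "snr", "volume_scale"},
    "roi": {"diameter_mm", "reader_jitter_mm"},
    "cohort": {
        "n_patients",
        "n_controls",
        "target_spearman",
        "age_floor",
        "pwmh_thresholds",
        "dwmh_thresholds",
        "patients",
        "controls",
    },
}
_GROUP_KEYS = {
    "alps", "dx_proj", "dx_assoc", "dy_proj", "dy_assoc", "dz_proj", "dz_assoc",
    "vv_icv_pct", "icv_ml", "wmhv_ml", "age", "p_male",
}


def _override_group(base: GroupParams, spec: dict, errors: list[str], where: str) -> GroupParams:
    fields = {}
    for key, value in spec.items():
        if key not in _GROUP_KEYS:
            errors.append(f"{where}: unknown key {key!r}")
            continue
        fields[key] = tuple(value) if isinstance(value, (list, tuple)) else value
    return replace(base, **fields)


def validate_config(path: str | Path | None = None, data: dict | None = None,
                    seed: int | None = None) -> RunConfig:
    """Parse a YAML config file into a RunConfig, filling defaults.

    Unknown keys are errors (strict mode); every violation found is listed in
    one aggregated ConfigError. Seeds are mandatory: either in the file or
    passed explicitly.
    """
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) if path else {}
        data = data or {}
    errors: list[str] = []
    for key in data:
        if key not in _SCHEMA:
            errors.append(f"unknown top-level key {key!r}")
    for section, allowed in _SCHEMA.items():
        if allowed is None or section not in data:
            continue
        for key in data.get(section, {}):
            if key not in allowed:
                errors.append(f"{section}: unknown key {key!r}")

    cfg_seed = data.get("seed", seed)
    if cfg_seed is None:
        errors.append("seed is mandatory (set `seed:` in the config or pass --seed)")

    cohort_spec = data.get("cohort", {})
    patients = GroupParams(**{**asdict(CohortParams().patients)})
    controls = GroupParams(**{**asdict(CohortParams().controls)})
    if "patients" in cohort_spec:
        patients = _override_group(patients, cohort_spec["patients"], errors, "cohort.patients")
    if "controls" in cohort_spec:
        controls = _override_group(controls, cohort_spec["controls"], errors, "cohort.controls")
    if "n_patients" in cohort_spec:
        patients = replace(patients, n=int(cohort_spec["n_patients"]))
    if "n_controls" in cohort_spec:
        controls = replace(controls, n=int(cohort_spec["n_controls"]))

    phantom_spec = data.get("phantom", {})
    scheme_spec = data.get("scheme", {})
    roi_spec = data.get("roi", {})

    snr = float(phantom_spec.get("snr", 40.0))
    if snr <= 0:
        errors.append(f"phantom.snr must be > 0 (got {snr})")
    grid_n = int(phantom_spec.get("grid_n", 64))
    if grid_n < 32:
        errors.append(f"phantom.grid_n must be >= 32 (got {grid_n})")
    n_dir = int(scheme_spec.get("n_directions", 64))
    if n_dir < 6:
        errors.append(f"scheme.n_directions must be >= 6 (got {n_dir})")
    jitter = float(roi_spec.get("reader_jitter_mm", 1.0))
    if jitter < 0:
        errors.append(f"roi.reader_jitter_mm must be >= 0 (got {jitter})")
    for g in (patients, controls):
        if g.n < 2:
            errors.append(f"cohort group {g.name!r} size must be >= 2 (got {g.n})")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))

    cohort = CohortParams(
        patients=patients,
        controls=controls,
        target_spearman=float(cohort_spec.get("target_spearman", -0.446)),
        age_floor=float(cohort_spec.get("age_floor", 60.0)),
        pwmh_thresholds=tuple(cohort_spec.get("pwmh_thresholds", (0.9, 15.0, 50.0))),
        dwmh_thresholds=tuple(cohort_spec.get("dwmh_thresholds", (0.7, 12.0, 45.0))),
        seed=int(cfg_seed),
    )
    settings = PhantomSettings(
        grid_n=grid_n,
        voxel_size=float(phantom_spec.get("voxel_size", 1.0)),
        s0=float(phantom_spec.get("s0", 1000.0)),
        snr=snr,
        volume_scale=float(phantom_spec.get("volume_scale", 0.01)),
    )
    return RunConfig(
        seed=int(cfg_seed),
        cohort=cohort,
        phantom=settings,
        n_directions=n_dir,
        b_value=float(scheme_spec.get("b", 1000.0)),
        roi_diameter_mm=float(roi_spec.get("diameter_mm", 5.0)),
        reader_jitter_mm=jitter,
        save_volumes=bool(data.get("save_volumes", False)),
        verbosity=int(data.get("verbosity", 1)),
    )


# --------------------------------------------------------------------------
# Per-subject measurement

def measure_subject(
    record: SubjectRecord,
    settings: PhantomSettings,
    scheme: AcquisitionScheme,
    roi_diameter_mm: float = 5.0,
    reader_jitter_mm: float = 0.0,
    jitter_seed: int | np.random.Generator = 0,
    noiseless: bool = False,
    out_dir: Path | None = None,
) -> dict:
    """Run one subject through the full grid pipeline, returning a flat row
    of ground truth plus measured diffusivities, index and volumes."""
    spec = phantom_spec_for(record, settings)
    phantom = build_phantom(spec, scheme)
    stack = phantom.stack
    if not noiseless:
        stack = add_rician_noise(stack, settings.snr, spec.seed, s0=settings.s0)

    field = fit_tensor(stack, scheme, mask=spec.icv_mask)
    maps = derive_maps(field)

    centers = roi_template_centers(settings.grid_n)
    proj_roi = ROISpec("projection", tuple(centers["projection"]), roi_diameter_mm)
    assoc_roi = ROISpec("association", tuple(centers["association"]), roi_diameter_mm)
    r1, r2 = subject_alps(
        maps, proj_roi, assoc_roi,
        voxel_size=settings.voxel_size,
        reader_jitter=reader_jitter_mm,
        seed=jitter_seed,
    )
    averaged, index_reader_mean = average_readers(r1, r2)

    vols = volume_report(
        spec.regions["ventricle"], spec.icv_mask, spec.regions["wmh"],
        settings.voxel_size, record.pwmh_grade, record.dwmh_grade,
        volume_scale=settings.volume_scale,
    )

    row = record.as_dict()
    for reader, res in (("reader1", r1), ("reader2", r2)):
        for k, v in res.diffusivities().items():
            row[f"{reader}_{k}"] = v
        row[f"{reader}_alps"] = res.alps_index
    for k, v in averaged.diffusivities().items():
        row[f"meas_{k}"] = v
    row["alps_measured"] = averaged.alps_index
    row["alps_reader_mean"] = index_reader_mean
    row["meas_vv_ml"] = vols.vv_ml
    row["meas_icv_ml"] = vols.icv_ml
    row["meas_wmhv_ml"] = vols.wmhv_ml
    row["meas_vv_icv_pct"] = vols.vv_icv_pct
    row["meas_wmhv_icv_pct"] = vols.wmhv_icv_pct

    if out_dir is not None:
        sub = Path(out_dir) / record.subject_id
        sub.mkdir(parents=True, exist_ok=True)
        write_nifti(sub / "dwi.nii.gz", stack, settings.voxel_size)
        write_fsl_gradients(scheme, sub / "dwi.bval", sub / "dwi.bvec")
        for name, mask in spec.regions.items():
            write_nifti(sub / f"mask_{name}.nii.gz", mask, settings.voxel_size)
        write_nifti(sub / "mask_icv.nii.gz", spec.icv_mask, settings.voxel_size)
        for mname, arr in (("dx", maps.dx), ("dy", maps.dy), ("dz", maps.dz), ("fa", maps.fa)):
            write_nifti(sub / f"{mname}.nii.gz", arr, settings.voxel_size)
        write_nifti(sub / "v1.nii.gz", maps.principal_direction, settings.voxel_size)
    return row


def measure_subject_patch(
    record: SubjectRecord,
    scheme: AcquisitionScheme,
    snr: float = 40.0,
    s0: float = 1000.0,
    voxel_size: float = 1.0,
    roi_diameter_mm: float = 5.0,
    reader_jitter_mm: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> tuple[ALPSResult, ALPSResult, ALPSResult]:
    """Replicate-profile measurement: each fiber block is simulated as a
    small homogeneous patch just large enough for the jittered sphere ROI.

    Same forward model, noise, fit and ROI operations as the full grid, at a
    fraction of the cost; used for Monte-Carlo studies with hundreds of
    replicate cohorts. Returns (reader1, reader2, averaged).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    half = int(np.ceil((roi_diameter_mm / 2.0 + reader_jitter_mm) / voxel_size))
    p = 2 * half + 3
    grid = (2 * p, p, p)
    stack = np.zeros(grid + (scheme.n_volumes,))
    from .acquisition import forward_signal  # local import avoids cycle at module load

    proj_tensor = np.diag([record.dx_proj, record.dy_proj, record.dz_proj])
    assoc_tensor = np.diag([record.dx_assoc, record.dy_assoc, record.dz_assoc])
    stack[:p] = forward_signal(proj_tensor, scheme, s0)
    stack[p:] = forward_signal(assoc_tensor, scheme, s0)
    stack = add_rician_noise(stack, snr, rng, s0=s0)

    field = fit_tensor(stack, scheme)
    maps = derive_maps(field)
    c = (p - 1) / 2.0
    proj_roi = ROISpec("projection", (c, c, c), roi_diameter_mm)
    assoc_roi = ROISpec("association", (p + c, c, c), roi_diameter_mm)
    r1, r2 = subject_alps(
        maps, proj_roi, assoc_roi,
        voxel_size=voxel_size, reader_jitter=reader_jitter_mm, seed=rng,
    )
    averaged, _ = average_readers(r1, r2)
    return r1, r2, averaged


def run_cohort(config: RunConfig, out_dir: Path | None = None,
               noiseless: bool = False) -> pd.DataFrame:
    """Simulate and measure every subject; returns the cohort table."""
    root = np.random.SeedSequence(config.seed)
    cohort_seed, scheme_seed, reader_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(3)
    )
    cohort = replace(config.cohort, seed=cohort_seed)
    scheme = make_scheme(config.n_directions, config.b_value, scheme_seed)
    records = sample_records(cohort)
    rows = []
    t0 = time.perf_counter()
    for i, record in enumerate(records):
        rows.append(
            measure_subject(
                record, config.phantom, scheme,
                roi_diameter_mm=config.roi_diameter_mm,
                reader_jitter_mm=config.reader_jitter_mm,
                jitter_seed=np.random.default_rng([reader_seed, i]),
                noiseless=noiseless,
                out_dir=out_dir if config.save_volumes else None,
            )
        )
    log.info("simulated and measured %d subjects in %.1f s",
             len(rows), time.perf_counter() - t0)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Statistics stage

def _fmt_ci(ci: tuple[float, float]) -> str:
    return f"{ci[0]:.3f}-{ci[1]:.3f}"


def _grade_table(df: pd.DataFrame, col: str) -> np.ndarray:
    counts = np.zeros((2, 4), dtype=int)
    for gi, group in enumerate(("nc", "inph")):
        sub = df[df.group == group]
        for g in range(4):
            counts[gi, g] = int((sub[col] == g).sum())
    return counts[:, counts.sum(axis=0) > 0]   # drop empty grades (zero marginal)


def compute_stat_report(df: pd.DataFrame) -> dict:
    """The full statistics battery on a measured cohort table.

    Returns a dict with the five analysis tables (clinical comparison,
    interobserver ICC, group diffusivity comparison, patient-group Spearman
    correlations, adjusted regression) plus the ROC summary.
    """
    nc = df[df.group == "nc"]
    inph = df[df.group == "inph"]
    report: dict = {}

    # -- Table 1: clinical / structural characteristics
    rows = []
    for label, col in [
        ("Age, years", "age"),
        ("WMHv, mL", "meas_wmhv_ml"),
        ("WMHv/ICV, %", "meas_wmhv_icv_pct"),
        ("Total VV, mL", "meas_vv_ml"),
        ("VV/ICV, %", "meas_vv_icv_pct"),
    ]:
        cmp = compare_groups(nc[col].to_numpy(), inph[col].to_numpy())
        rows.append(dict(characteristic=label, nc=cmp.summary_a, inph=cmp.summary_b,
                         test=cmp.test, statistic=round(cmp.statistic, 4),
                         p=round(cmp.p, 6)))
    sex_table = np.array(
        [[int(nc.sex_male.sum()), int((1 - nc.sex_male).sum())],
         [int(inph.sex_male.sum()), int((1 - inph.sex_male).sum())]]
    )
    cmp = chi_square(sex_table)
    rows.append(dict(characteristic="Sex, male n", nc=f"{int(nc.sex_male.sum())}",
                     inph=f"{int(inph.sex_male.sum())}", test=cmp.test,
                     statistic=round(cmp.statistic, 4), p=round(cmp.p, 6)))
    for label, col in [("pWMH grade", "pwmh_grade"), ("dWMH grade", "dwmh_grade")]:
        cmp = chi_square(_grade_table(df, col))
        rows.append(dict(
            characteristic=label,
            nc="/".join(str(int((nc[col] == g).sum())) for g in range(4)),
            inph="/".join(str(int((inph[col] == g).sum())) for g in range(4)),
            test=cmp.test, statistic=round(cmp.statistic, 4), p=round(cmp.p, 6)))
    report["table1_clinical"] = rows

    # -- Table 2: interobserver agreement per metric and group
    metrics = list(DIFF_KEYS) + ["alps"]
    rows = []
    for group, sub in (("nc", nc), ("inph", inph)):
        for m in metrics:
            pair = sub[[f"reader1_{m}", f"reader2_{m}"]].to_numpy()
            try:
                icc = icc_absolute(pair)
                icc_val, ci, degen = round(icc.icc, 4), _fmt_ci(icc.ci95), icc.degenerate
            except ValueError:
                icc_val, ci, degen = "NA", "NA", True
            rows.append(dict(
                group=group, metric=m,
                reader1=f"{pair[:, 0].mean():.3f} ({pair[:, 0].std(ddof=1):.3f})",
                reader2=f"{pair[:, 1].mean():.3f} ({pair[:, 1].std(ddof=1):.3f})",
                icc=icc_val, ci95=ci, degenerate=degen))
    report["table2_icc"] = rows

    # -- Table 3: group comparison of averaged diffusivities and the index
    rows = []
    for m in metrics:
        col = "alps_measured" if m == "alps" else f"meas_{m}"
        cmp = compare_groups(nc[col].to_numpy(), inph[col].to_numpy())
        rows.append(dict(metric=m, nc=cmp.summary_a, inph=cmp.summary_b,
                         test=cmp.test, statistic=round(cmp.statistic, 4),
                         p=round(cmp.p, 6)))
    report["table3_groups"] = rows

    # -- Table 4: Spearman correlations within the patient group
    targets = {
        "alps": "alps_measured",
        **{k: f"meas_{k}" for k in DIFF_KEYS},
    }
    covars = {
        "age": "age", "sex": "sex_male",
        "vv": "meas_vv_ml", "vv_icv": "meas_vv_icv_pct",
        "wmhv": "meas_wmhv_ml", "wmhv_icv": "meas_wmhv_icv_pct",
        "pwmh": "pwmh_grade", "dwmh": "dwmh_grade",
    }
    rows = []
    for cname, ccol in covars.items():
        row = dict(covariate=cname)
        for tname, tcol in targets.items():
            try:
                r, p = spearman(inph[ccol].to_numpy(), inph[tcol].to_numpy())
                row[tname] = f"{r:.3f} ({p:.3f})"
            except ValueError:
                row[tname] = "NA"
        rows.append(row)
    report["table4_correlations"] = rows

    # -- Table 5: adjusted regression in the patient group
    rows = []
    model_a = ols_adjusted(
        np.log(inph.meas_vv_icv_pct.to_numpy()),
        {
            "alps": inph.alps_measured.to_numpy(),
            "age": inph.age.to_numpy(),
            "sex": inph.sex_male.to_numpy(),
            "wmhv": inph.meas_wmhv_ml.to_numpy(),
        },
        outcome_label="ln VV/ICV",
    )
    model_b = ols_adjusted(
        np.log(inph.meas_wmhv_icv_pct.to_numpy()),
        {
            "alps": inph.alps_measured.to_numpy(),
            "age": inph.age.to_numpy(),
            "sex": inph.sex_male.to_numpy(),
            "vv_icv": inph.meas_vv_icv_pct.to_numpy(),
        },
        outcome_label="ln WMHv/ICV",
    )
    for model in (model_a, model_b):
        for e in model.effects:
            rows.append(dict(outcome=model.outcome, predictor=e.name,
                             beta=round(e.beta, 4), ci95=_fmt_ci(e.ci95),
                             p=round(e.p, 6), n=model.n))
    report["table5_regression"] = rows

    # -- ROC of the measured index (lower = disease)
    roc = roc_analysis(df.alps_measured.to_numpy(),
                       (df.group == "inph").to_numpy())
    report["roc_summary"] = dict(
        auc=round(roc.auc, 4), cutoff=round(roc.cutoff, 4),
        sensitivity_pct=round(roc.sensitivity_pct, 2),
        specificity_pct=round(roc.specificity_pct, 2),
        orientation=roc.orientation,
    )
    return report


# --------------------------------------------------------------------------
# Full run

def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 noiseless: bool = False) -> dict:
    """Execute the whole study end-to-end and write all artifacts.

    Writes cohort.tsv, the five analysis tables, roc_summary.tsv,
    report.json and a run manifest under `out_dir`; returns the report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbosity else logging.WARNING,
        format="%(asctime)s %(name)s %(message)s",
    )
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        df = run_cohort(config, out_dir=out / "subjects", noiseless=noiseless)
        write_table(df, out / "cohort.tsv")
        log.info("stage simulate done (%.1f s)", time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        report = compute_stat_report(df)
        log.info("stage stats done (%.1f s)", time.perf_counter() - t0)

        stage = "report"
        for name in ("table1_clinical", "table2_icc", "table3_groups",
                     "table4_correlations", "table5_regression"):
            write_table(pd.DataFrame(report[name]), out / f"{name}.tsv")
        write_table(pd.DataFrame([report["roc_summary"]]), out / "roc_summary.tsv")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
        )
        manifest = dict(
            package="alps-glymph",
            version=__version__,
            seed=config.seed,
            config_hash=_config_hash(config),
            n_subjects=int(len(df)),
            noiseless=bool(noiseless),
        )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return report
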