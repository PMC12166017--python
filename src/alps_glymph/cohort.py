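"""Two-group synthetic cohort sampling with known ground truth.

The generator emulates a case-control diffusion-MRI study: 41 hydrocephalus
(iNPH) patients and 40 matched controls whose true perivascular-diffusivity
(ALPS) indexes, regional diffusivities, ventricular / intracranial / lesion
volumes, ages and sexes follow the published group distributions.  Each
subject's fiber-region tensors are constructed so that the four diffusivities
entering the index reproduce that subject's true ALPS exactly, and a Gaussian
copula couples true ALPS to the normalised ventricular volume at a target
Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .phantom import PhantomSpec, cohort_geometry, default_region_tensors

__all__ = [
    "GroupParams",
    "CohortParams",
    "SubjectRecord",
    "PhantomSettings",
    "spearman_to_pearson",
    "sample_records",
    "phantom_spec_for",
    "sample_cohort",
    "fazekas_grade",
]

MAX_RETRIES = 200


@dataclass(frozen=True)
class GroupParams:
    """Ground-truth distribution parameters for one study group.

    Diffusivities in 1e-3 mm^2/s, volumes in mL, VV/ICV in percent.
    `vv_icv_pct` and `wmhv_ml` are log-normal (median, log-SD); the rest are
    normal (mean, SD). Ages are truncated below at `age_floor` years.
    """

    name: str
    n: int
    alps: tuple[float, float]
    dx_proj: tuple[float, float]
    dx_assoc: tuple[float, float]
    dy_proj: tuple[float, float]
    dy_assoc: tuple[float, float]
    dz_proj: tuple[float, float]
    dz_assoc: tuple[float, float]
    vv_icv_pct: tuple[float, float]
    icv_ml: tuple[float, float]
    wmhv_ml: tuple[float, float]
    age: tuple[float, float]
    p_male: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for f in ("alps", "dx_proj", "dx_assoc", "dy_proj", "dy_assoc",
                  "dz_proj", "dz_assoc", "vv_icv_pct", "icv_ml", "wmhv_ml", "age"):
            if getattr(self, f)[1] < 0:
                raise ValueError(f"{f} SD must be >= 0")


# Defaults reproduce the published study conditions: group sizes 41/40,
# Table-1/Table-3 distributions, ALPS-vs-VV/ICV Spearman -0.446 (Table 4).
# ICV is not printed; ~1450 mL is implied by VV 125.0 mL at VV/ICV median
# 8.6%. Control VV/ICV (not printed) is set to a normal-elderly 2.3% median.
INPH_DEFAULTS = GroupParams(
    name="inph", n=41,
    alps=(1.074, 0.225),
    dx_proj=(0.597, 0.236), dx_assoc=(0.465, 0.204),
    dy_proj=(0.541, 0.239), dy_assoc=(0.598, 0.191),
    dz_proj=(0.700, 0.242), dz_assoc=(0.479, 0.216),
    vv_icv_pct=(8.6, 0.24), icv_ml=(1450.0, 130.0),
    wmhv_ml=(36.8, 0.66), age=(68.6, 5.9), p_male=23 / 41,
)
NC_DEFAULTS = GroupParams(
    name="nc", n=40,
    alps=(1.559, 0.161),
    dx_proj=(0.475, 0.058), dx_assoc=(0.466, 0.065),
    dy_proj=(0.457, 0.118), dy_assoc=(0.587, 0.054),
    dz_proj=(0.580, 0.073), dz_assoc=(0.435, 0.111),
    vv_icv_pct=(2.3, 0.30), icv_ml=(1450.0, 130.0),
    wmhv_ml=(1.03, 0.223), age=(67.4, 4.6), p_male=17 / 40,
)

# Lesion-volume thresholds (mL) mapping WMH burden onto ordinal 0-3 grades;
# generator metadata standing in for visual Fazekas rating.
PWMH_THRESHOLDS = (0.9, 15.0, 50.0)
DWMH_THRESHOLDS = (0.7, 12.0, 45.0)


@dataclass(frozen=True)
class CohortParams:
    """Full two-group cohort specification."""

    patients: GroupParams = INPH_DEFAULTS
    controls: GroupParams = NC_DEFAULTS
    target_spearman: float = -0.446
    age_floor: float = 60.0
    pwmh_thresholds: tuple[float, float, float] = PWMH_THRESHOLDS
    dwmh_thresholds: tuple[float, float, float] = DWMH_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.target_spearman) < 1:
            raise ValueError("|target rank correlation| must be < 1")


@dataclass(frozen=True)
class PhantomSettings:
    """Imaging-side settings shared by every subject of a cohort."""

    grid_n: int = 64
    voxel_size: float = 1.0
    s0: float = 1000.0
    snr: float = 40.0
    volume_scale: float = 0.01


@dataclass
class SubjectRecord:
    """Ground truth for one synthetic subject (the generator's 'chart')."""

    subject_id: str
    group: str
    age: float
    sex_male: int
    alps_true: float
    dx_proj: float
    dx_assoc: float
    dy_proj: float
    dy_assoc: float
    dz_proj: float
    dz_assoc: float
    vv_ml: float
    icv_ml: float
    wmhv_ml: float
    vv_icv_pct: float
    wmhv_icv_pct: float
    pwmh_grade: int
    dwmh_grade: int
    noise_seed: int
    degenerate: bool = False   # set when a zero-SD parameter collapses a draw

    def as_dict(self) -> dict:
        return asdict(self)


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation yielding Spearman `rho_s`."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def fazekas_grade(wmhv_ml: float, thresholds: tuple[float, float, float]) -> int:
    """Ordinal 0-3 grade: number of thresholds the lesion volume reaches."""
    return int(sum(wmhv_ml >= t for t in thresholds))


def _truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _sample_group(group: GroupParams, params: CohortParams,
                  rng: np.random.Generator, id_prefix: str) -> list[SubjectRecord]:
    n = group.n
    rho_p = spearman_to_pearson(params.target_spearman)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    chol = np.linalg.cholesky(cov)

    records: list[SubjectRecord] = []
    for i in range(n):
        for attempt in range(MAX_RETRIES):
            z = chol @ rng.standard_normal(2)
            alps_true = group.alps[0] + group.alps[1] * z[0]
            # Log-normal quantile transform of the coupled normal score keeps
            # the Gaussian-copula rank correlation exact.
            med, sig = group.vv_icv_pct
            vv_icv = med * np.exp(sig * z[1])
            icv = _truncated_normal(rng, *group.icv_ml, 1000.0, ())
            vv = vv_icv / 100.0 * icv
            med_w, sig_w = group.wmhv_ml
            wmhv = med_w * np.exp(sig_w * rng.standard_normal())

            d = {}
            for k in ("dx_proj", "dx_assoc", "dy_proj", "dy_assoc", "dz_proj", "dz_assoc"):
                m, s = getattr(group, k)
                d[k] = m + s * rng.standard_normal()
            num = d["dx_proj"] + d["dx_assoc"]
            den = d["dy_proj"] + d["dz_assoc"]
            if alps_true <= 0 or num <= 0 or den <= 0:
                warnings.warn("infeasible diffusivity draw; resampling", stacklevel=2)
                continue
            # Rescale the numerator pair so this subject's index is exact.
            f = alps_true * den / num
            d["dx_proj"] *= f
            d["dx_assoc"] *= f
            if min(d.values()) <= 0 or vv >= icv or wmhv >= icv:
                warnings.warn("infeasible diffusivity draw; resampling", stacklevel=2)
                continue
            break
        else:
            raise RuntimeError(f"could not draw a feasible subject after {MAX_RETRIES} tries")

        age = float(_truncated_normal(rng, *group.age, params.age_floor, ()))
        sex = int(rng.random() < group.p_male)
        degenerate = group.alps[1] == 0 or group.vv_icv_pct[1] == 0
        records.append(
            SubjectRecord(
                subject_id=f"{id_prefix}{i + 1:03d}",
                group=group.name,
                age=round(age, 2),
                sex_male=sex,
                alps_true=alps_true,
                vv_ml=vv,
                icv_ml=float(icv),
                wmhv_ml=wmhv,
                vv_icv_pct=vv_icv,
                wmhv_icv_pct=100.0 * wmhv / icv,
                pwmh_grade=fazekas_grade(wmhv, params.pwmh_thresholds),
                dwmh_grade=fazekas_grade(wmhv, params.dwmh_thresholds),
                noise_seed=int(rng.integers(0, 2**31 - 1)),
                degenerate=degenerate,
                **d,
            )
        )
    return records


def sample_records(params: CohortParams) -> list[SubjectRecord]:
    """Draw the cohort's ground-truth table (no imaging involved)."""
    rng = np.random.default_rng(params.seed)
    recs = _sample_group(params.patients, params, rng, "P")
    recs += _sample_group(params.controls, params, rng, "C")
    return recs


def phantom_spec_for(record: SubjectRecord, settings: PhantomSettings) -> PhantomSpec:
    """Materialise the imaging phantom for one subject's ground truth."""
    voxel_ul = settings.voxel_size**3  # microlitres per voxel
    to_vox = lambda ml: int(round(ml * 1000.0 * settings.volume_scale / voxel_ul))
    regions = cohort_geometry(
        settings.grid_n,
        vv_voxels=to_vox(record.vv_ml),
        wmh_voxels=to_vox(record.wmhv_ml),
        icv_voxels=to_vox(record.icv_ml),
    )
    icv = regions.pop("icv")
    tensors = default_region_tensors(
        proj_diag=(record.dx_proj, record.dy_proj, record.dz_proj),
        assoc_diag=(record.dx_assoc, record.dy_assoc, record.dz_assoc),
    )
    return PhantomSpec(
        shape=(settings.grid_n,) * 3,
        voxel_size=settings.voxel_size,
        regions=regions,
        tensors=tensors,
        s0=settings.s0,
        snr=settings.snr,
        volume_scale=settings.volume_scale,
        seed=record.noise_seed,
        icv_mask=icv,
    )


def sample_cohort(
    params: CohortParams, settings: PhantomSettings = PhantomSettings()
) -> list[tuple[PhantomSpec, SubjectRecord]]:
    """Draw the cohort and materialise every subject's phantom spec."""
    return [(phantom_spec_for(r, settings), r) for r in sample_records(params)]
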