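"""Synthetic knee phantoms and synthetic cohorts.

Phantoms
--------
Bones are parametric solids (cylinders along the medial–lateral slice axis,
or spheres) voxelised on an anisotropic MR-like grid (default 0.5 x 0.5 mm
in-plane, 3 mm slices). Each bone's cartilage is the shell of voxels whose
physical distance to that bone lies in ``(0, t]``, where ``t`` is the
specified thickness profile at that position — so the true thickness of the
shell is known analytically everywhere and is returned as a parallel
ground-truth map. Shells are restricted to an angular coverage arc (the
articular facet) and to voxels strictly nearer their own bone than any
other, which keeps cartilages of different bones disjoint by construction.

Cohorts
-------
Per-subject region thickness is drawn as

    Normal(baseline + slope * (age - age_mean) + sex_offset * I(male)
           + side_offset * I(left)
           + slope_sex * (age - age_mean) * I(male)
           + slope_side * (age - age_mean) * I(left),  SD)

with exact sex and side stratum counts and a truncated-normal age
distribution. Default calibration reproduces the cohort structure and the
per-region thickness means/SDs of a large healthy-knee MR study
(n = 2,481, ages 15–64, 1,355 male / 1,126 female, 1,228 left / 1,253 right).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .thickness import FACE_STRUCTURE, boundary_voxels
from .volume import DEFAULT_CODES, InputError, LabelVolume

logger = logging.getLogger(__name__)

REGION_NAMES = (
    "FMA", "FMC", "FMP", "FLA", "FLC", "FLP",
    "TMA", "TMC", "TMP", "TLA", "TLC", "TLP",
    "PM", "PL",
)

COHORT_COLUMNS = ("subject_id", "age", "sex", "side") + REGION_NAMES


# --------------------------------------------------------------------------
# Phantoms
# --------------------------------------------------------------------------

@dataclass
class BoneGeometry:
    """Parametric bone core: a cylinder along the ML axis or a sphere.

    ``facing_mm`` is the in-plane (SI, AP) unit direction the articular
    facet points toward; together with ``coverage_halfangle_deg`` it selects
    the arc of the bone surface that carries cartilage. ``None`` means the
    full surface is covered (used for calibration annuli).
    """

    shape: str  # "cylinder" | "sphere"
    center_mm: tuple[float, float, float]
    radius_mm: float
    half_length_mm: float = np.inf  # cylinder extent along ML
    facing: tuple[float, float] | None = None  # (SI, AP) direction
    coverage_halfangle_deg: float = 180.0


def constant_profile(thickness_mm: float):
    """Thickness profile that is the same everywhere on the facet."""

    def profile(si_mm, ap_mm, ml_mm):
        return np.full(np.broadcast(si_mm, ap_mm, ml_mm).shape, float(thickness_mm))

    return profile


def ap_step_profile(bounds_ap_mm, values_mm):
    """Piecewise-constant profile along the anterior→posterior axis.

    ``bounds_ap_mm`` are the interior step positions (len = len(values)-1);
    segment ``i`` covers AP positions in ``[bounds[i-1], bounds[i})``.
    """
    bounds = np.asarray(bounds_ap_mm, dtype=float)
    values = np.asarray(values_mm, dtype=float)
    if len(values) != len(bounds) + 1:
        raise InputError("need one more value than interior bounds")

    def profile(si_mm, ap_mm, ml_mm):
        seg = np.searchsorted(bounds, np.asarray(ap_mm, dtype=float), side="right")
        return values[seg]

    return profile


@dataclass
class PhantomSpec:
    """Geometry + cartilage thickness profiles for a synthetic knee."""

    grid_shape: tuple[int, int, int] = (160, 160, 30)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 3.0)
    bones: dict[str, BoneGeometry] = field(default_factory=dict)
    profiles: dict[str, object] = field(default_factory=dict)  # bone -> callable
    codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise InputError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise InputError("spacing must be positive")
        if not self.bones:
            raise InputError("phantom needs at least one bone")
        for bone in self.bones:
            if bone not in ("femur", "tibia", "patella"):
                raise InputError(f"unknown bone {bone!r}")
            if bone not in self.profiles:
                raise InputError(f"no cartilage profile for bone {bone!r}")
            if self.bones[bone].radius_mm <= 0:
                raise InputError(f"bone {bone!r} has nonpositive radius")


CARTILAGE_NAME = {
    "femur": "femoral_cartilage",
    "tibia": "tibial_cartilage",
    "patella": "patellar_cartilage",
}


def default_knee_spec() -> PhantomSpec:
    """Three-bone knee phantom at MR-like spacing.

    Femur above, tibia below with a joint-space gap, patella anterior to the
    femur; each facet faces its opposing structure. Default shell
    thicknesses are round values in the physiological range.
    """
    return PhantomSpec(
        bones={
            "femur": BoneGeometry(
                "cylinder", (28.0, 45.0, 45.0), 15.0, half_length_mm=40.0,
                facing=(1.0, 0.0), coverage_halfangle_deg=120.0,
            ),
            "tibia": BoneGeometry(
                "cylinder", (63.0, 42.0, 45.0), 14.0, half_length_mm=38.0,
                facing=(-1.0, 0.0), coverage_halfangle_deg=55.0,
            ),
            "patella": BoneGeometry(
                "cylinder", (28.0, 12.0, 45.0), 10.0, half_length_mm=13.0,
                facing=(0.0, 1.0), coverage_halfangle_deg=80.0,
            ),
        },
        profiles={
            "femur": constant_profile(2.0),
            "tibia": constant_profile(1.5),
            "patella": constant_profile(2.2),
        },
    )


def _physical_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _bone_mask_and_distance(geom: BoneGeometry, si, ap, ml):
    """Voxelised bone mask and analytic in/near-plane context for coverage."""
    if geom.shape == "cylinder":
        r = np.hypot(si - geom.center_mm[0], ap - geom.center_mm[1])
        along = np.abs(ml - geom.center_mm[2])
        mask = (r <= geom.radius_mm) & (along <= geom.half_length_mm)
    elif geom.shape == "sphere":
        r = np.sqrt(
            (si - geom.center_mm[0]) ** 2
            + (ap - geom.center_mm[1]) ** 2
            + (ml - geom.center_mm[2]) ** 2
        )
        mask = r <= geom.radius_mm
    else:
        raise InputError(f"unknown bone shape {geom.shape!r}")
    return mask


def _coverage(geom: BoneGeometry, si, ap):
    if geom.facing is None or geom.coverage_halfangle_deg >= 180.0:
        return np.ones(si.shape, dtype=bool)
    v_si = si - geom.center_mm[0]
    v_ap = ap - geom.center_mm[1]
    norm = np.hypot(v_si, v_ap)
    norm[norm == 0] = 1.0
    f = np.asarray(geom.facing, dtype=float)
    f = f / np.linalg.norm(f)
    cosang = (v_si * f[0] + v_ap * f[1]) / norm
    return cosang >= np.cos(np.deg2rad(geom.coverage_halfangle_deg))


def make_phantom(spec: PhantomSpec) -> tuple[LabelVolume, np.ndarray]:
    """Voxelise a phantom; returns the label volume and the ground-truth
    thickness map (true thickness at cartilage voxels, NaN elsewhere).

    Raises on overlapping bones; warns when a nonzero profile is thinner
    than one in-plane voxel (quantisation then dominates the shell).
    """
    spec.validate()
    si, ap, ml = _physical_grids(spec.grid_shape, spec.spacing_mm)

    bone_masks: dict[str, np.ndarray] = {}
    for name, geom in spec.bones.items():
        bone_masks[name] = _bone_mask_and_distance(geom, si, ap, ml)
    names = list(bone_masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (bone_masks[a] & bone_masks[b]).any():
                raise InputError(f"bones {a!r} and {b!r} overlap")

    # physical distance from every voxel to each bone (EDT outside the mask)
    dist = {
        name: ndimage.distance_transform_edt(~m, sampling=spec.spacing_mm)
        for name, m in bone_masks.items()
    }

    data = np.zeros(spec.grid_shape, dtype=np.int16)
    truth = np.full(spec.grid_shape, np.nan, dtype=float)
    for name, m in bone_masks.items():
        data[m] = spec.codes[name]

    min_inplane = min(spec.spacing_mm[0], spec.spacing_mm[1])
    for name, geom in spec.bones.items():
        t = np.asarray(spec.profiles[name](si, ap, ml), dtype=float)
        if (t < 0).any():
            raise InputError(f"negative cartilage thickness for {name!r}")
        cover = _coverage(geom, si, ap)
        thin = cover & (t > 0) & (t < min_inplane)
        if thin.any():
            warnings.warn(
                f"{name} cartilage profile thinner than one in-plane voxel "
                f"({min_inplane} mm) over part of its facet; quantisation "
                "error will dominate there",
                stacklevel=2,
            )
        nearest_own = np.ones(spec.grid_shape, dtype=bool)
        for other in spec.bones:
            if other != name:
                nearest_own &= dist[name] < dist[other]
        shell = (
            (dist[name] > 0)
            & (dist[name] <= t)
            & cover
            & nearest_own
            & (data == 0)
        )
        data[shell] = spec.codes[CARTILAGE_NAME[name]]
        truth[shell] = t[shell]

    return LabelVolume(data, spec.spacing_mm, dict(spec.codes)), truth


def annulus_phantom(
    thickness_mm: float,
    inner_radius_mm: float = 15.0,
    spacing_mm=(0.5, 0.5, 3.0),
    grid_shape=(160, 160, 10),
    bone: str = "femur",
) -> tuple[LabelVolume, np.ndarray]:
    """Single-bone calibration phantom: a cylindrical core with a uniform
    full-circumference cartilage shell of exactly known thickness."""
    center = tuple(
        (n - 1) * s / 2 for n, s in zip(grid_shape[:2], spacing_mm[:2])
    ) + ((grid_shape[2] - 1) * spacing_mm[2] / 2,)
    spec = PhantomSpec(
        grid_shape=tuple(grid_shape),
        spacing_mm=tuple(spacing_mm),
        bones={bone: BoneGeometry("cylinder", center, inner_radius_mm)},
        profiles={bone: constant_profile(thickness_mm)},
    )
    return make_phantom(spec)


def perturb_mask(volume: LabelVolume, severity: float, seed: int) -> LabelVolume:
    """Morphologically perturb every structure's boundary.

    Boundary voxels are deleted and face-adjacent background voxels added,
    each independently with probability ``severity``. The random draws are
    a function of ``seed`` only, so for a fixed seed the flipped sets are
    nested across severities and the Dice coefficient against the original
    decreases monotonically in severity.
    """
    if not 0.0 <= severity <= 1.0:
        raise InputError(f"severity must be in [0, 1], got {severity}")
    rng = np.random.default_rng(seed)
    data = volume.data.copy()
    for structure, code in volume.codes.items():
        mask = volume.data == code
        if not mask.any():
            rng.random(volume.shape)  # keep the stream aligned across inputs
            rng.random(volume.shape)
            continue
        u_rm = rng.random(volume.shape)
        u_add = rng.random(volume.shape)
        remove = boundary_voxels(mask) & (u_rm < severity)
        add = (
            ndimage.binary_dilation(mask, structure=FACE_STRUCTURE)
            & ~mask
            & (volume.data == 0)
            & (u_add < severity)
        )
        data[remove] = 0
        data[add & (data == 0)] = code
    return LabelVolume(data, volume.spacing_mm, dict(volume.codes))


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class RegionParams:
    """Generating parameters for one region's thickness distribution."""

    mean: float  # baseline mm (at the cohort mean age, reference strata)
    sd: float  # mm
    age_slope: float = 0.0  # mm / year
    sex_offset: float = 0.0  # mm, added for males
    side_offset: float = 0.0  # mm, added for left knees
    age_slope_sex: float = 0.0  # mm / year added to the slope for males
    age_slope_side: float = 0.0  # mm / year added to the slope for left knees
    calibrated: bool = True  # False where no published value backs the default


def default_region_params() -> dict[str, RegionParams]:
    """Per-region baseline means and SDs of healthy knees (mm).

    PL has no published value; its default is PM − 0.1 with PM's SD and is
    flagged ``calibrated=False`` so it is never treated as ground truth.
    """
    printed = {
        "FMA": (2.06, 0.20), "FMC": (1.75, 0.12), "FMP": (1.59, 0.16),
        "FLA": (2.15, 0.24), "FLC": (1.77, 0.13), "FLP": (1.61, 0.22),
        "TMA": (1.48, 0.10), "TMC": (1.60, 0.12), "TMP": (1.44, 0.08),
        "TLA": (1.51, 0.11), "TLC": (1.66, 0.13), "TLP": (1.40, 0.11),
        "PM": (2.18, 0.32),
    }
    params = {r: RegionParams(m, s) for r, (m, s) in printed.items()}
    params["PL"] = RegionParams(2.08, 0.32, calibrated=False)
    return params


@dataclass
class CohortSpec:
    """Cohort structure: strata counts, age distribution, region params."""

    n_subjects: int = 2481
    age_mean: float = 35.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (15.0, 64.0)
    n_male: int = 1355
    n_female: int = 1126
    n_left: int = 1228
    n_right: int = 1253
    region_params: dict[str, RegionParams] = field(
        default_factory=default_region_params
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise InputError("n_subjects must be positive")
        if self.n_male + self.n_female != self.n_subjects:
            raise InputError("sex counts must sum to n_subjects")
        if self.n_left + self.n_right != self.n_subjects:
            raise InputError("side counts must sum to n_subjects")
        if self.age_range[0] >= self.age_range[1]:
            raise InputError("age range must be increasing")
        missing = [r for r in REGION_NAMES if r not in self.region_params]
        if missing:
            raise InputError(f"region params missing for {missing}")
        bad = [r for r, p in self.region_params.items() if p.sd <= 0]
        if bad:
            raise InputError(f"nonpositive SD for {bad}")


def sex_calibrated_spec(seed: int = 0) -> CohortSpec:
    """Default cohort with FMC and FMP generated from the published
    sex-specific means/SDs (female baseline + male offset)."""
    params = default_region_params()
    # male 1.80 +/- 0.11 vs female 1.70 +/- 0.11
    params["FMC"] = RegionParams(1.70, 0.11, sex_offset=0.10)
    # male 1.63 +/- 0.16 vs female 1.54 +/- 0.15
    params["FMP"] = RegionParams(1.54, 0.15, sex_offset=0.09)
    return CohortSpec(region_params=params, seed=seed)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: one row per subject, exact stratum counts,
    truncated-normal ages, Normal region thicknesses (redrawn if negative).
    Deterministic under ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    lo, hi = spec.age_range
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )

    sex = np.array(["M"] * spec.n_male + ["F"] * spec.n_female)
    rng.shuffle(sex)
    side = np.array(["L"] * spec.n_left + ["R"] * spec.n_right)
    rng.shuffle(side)

    is_male = (sex == "M").astype(float)
    is_left = (side == "L").astype(float)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "side": side,
        }
    )
    n_redraws = 0
    for region in REGION_NAMES:
        p = spec.region_params[region]
        age_c = age - spec.age_mean
        mu = (
            p.mean
            + p.age_slope * age_c
            + p.sex_offset * is_male
            + p.side_offset * is_left
            + p.age_slope_sex * age_c * is_male
            + p.age_slope_side * age_c * is_left
        )
        vals = rng.normal(mu, p.sd)
        neg = vals < 0
        while neg.any():  # truncation at zero by redraw keeps the SD honest
            n_redraws += int(neg.sum())
            vals[neg] = rng.normal(mu[neg], p.sd)
            neg = vals < 0
        df[region] = vals
    if n_redraws:
        logger.info("redrew %d negative thickness values", n_redraws)
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"cohort CSV missing columns: {missing}")
    bad = df[df[list(REGION_NAMES)].isna().all(axis=1)]
    if len(bad):
        raise InputError(f"malformed cohort rows: {list(bad.index[:5])}")
    return df
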