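"""End-to-end orchestration: label volume -> thickness -> regions -> cohort
statistics, with a YAML-configurable, hashable run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .regions import (
    AffineTransform,
    RegionAtlas,
    align_atlas,
    assign_points,
    build_geometric_atlas,
)
from .stats import (
    ci_band,
    comparisons_frame,
    fit_interaction_model,
    summarize_group_means,
    tukey_pairwise,
)
from .synthetic import REGION_NAMES, read_cohort_csv
from .thickness import compute_thickness, per_region_thickness
from .volume import DEFAULT_CODES, InputError, LabelVolume

logger = logging.getLogger(__name__)

_BONE_OF_PREFIX = {"F": "femur", "T": "tibia", "P": "patella"}


@dataclass
class PipelineConfig:
    """Every knob of a pipeline run; hashed into output headers."""

    codes: dict = field(default_factory=lambda: dict(DEFAULT_CODES))
    spacing_override: tuple | None = None
    mode: str = "3d"  # or "2d-slice"
    smoothing: bool = True  # Gaussian smoothing of SDFs before gradients
    atlas_source: str = "geometric"  # or path to a NIfTI atlas
    atlas_sidecar: str | None = None
    transform_path: str | None = None  # 4x4 affine text file
    acp_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)
    alpha: float = 0.05
    factors: tuple = ("sex", "side")
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if self.mode not in ("3d", "2d-slice"):
            raise InputError(f"unknown thickness mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _load_volume(volume, config: PipelineConfig) -> LabelVolume:
    if isinstance(volume, LabelVolume):
        vol = volume
    else:
        vol = LabelVolume.from_nifti(volume, codes=config.codes)
    if config.spacing_override is not None:
        vol = LabelVolume(vol.data, config.spacing_override, vol.codes)
    return vol


def _subject_atlas(vol: LabelVolume, config: PipelineConfig) -> RegionAtlas:
    if config.atlas_source == "geometric":
        return build_geometric_atlas(vol, acp_fractions=config.acp_fractions)
    atlas = RegionAtlas.load(config.atlas_source, config.atlas_sidecar)
    transform = (
        AffineTransform.from_file(config.transform_path)
        if config.transform_path
        else None
    )
    return align_atlas(atlas, vol, transform=transform)


def run_subject(
    volume, config: PipelineConfig | None = None, return_points: bool = False
):
    """Measure one subject: 14-region mean-thickness record (pd.Series, mm).

    Regions whose cartilage is absent come back NaN (missing, never zero).
    All three bones must be present (the atlas needs them); missing bones
    raise with their names listed.
    """
    config = config or PipelineConfig()
    vol = _load_volume(volume, config)
    missing = [b for b in ("femur", "tibia", "patella") if not vol.has(b)]
    if missing:
        raise InputError(f"volume is missing bone structures: {missing}")

    atlas = _subject_atlas(vol, config)
    sigma = 1.0 if config.smoothing else 0.0

    values: dict[str, float] = {r: float("nan") for r in REGION_NAMES}
    point_rows = []
    for prefix, bone in _BONE_OF_PREFIX.items():
        cart = {"femur": "femoral_cartilage", "tibia": "tibial_cartilage",
                "patella": "patellar_cartilage"}[bone]
        if not vol.has(cart):
            logger.warning("%s absent; its regions reported missing", cart)
            continue
        points = compute_thickness(
            vol, bone, mode=config.mode, smooth_sigma_vox=sigma
        )
        assigned = assign_points(points, atlas)
        # region codes must respect bone identity: an inner point of this
        # bone's cartilage falling under another bone's code is unassigned
        assigned = np.array(
            [a if a.startswith(prefix) else "" for a in assigned], dtype=object
        )
        bone_regions = [r for r in REGION_NAMES if r.startswith(prefix)]
        means = per_region_thickness(points, assigned, bone_regions)
        values.update(means)
        if return_points:
            mm = points.inner_mm
            for i, r in enumerate(assigned):
                point_rows.append(
                    (mm[i, 0], mm[i, 1], mm[i, 2], r or "unassigned",
                     points.thickness_mm[i])
                )
    record = pd.Series(values, name="thickness_mm")[list(REGION_NAMES)]
    if return_points:
        pts = pd.DataFrame(
            point_rows, columns=["x_mm", "y_mm", "z_mm", "region", "thickness_mm"]
        )
        return record, pts
    return record


def run_cohort(cohort, config: PipelineConfig | None = None) -> dict:
    """Full statistics bundle for a cohort table (DataFrame or CSV path).

    Returns a dict of DataFrames: overall/sex/side group means, the
    all-region Tukey table, per-region two-group Tukey tables for each
    factor, interaction regressions and CI bands per factor. Stages that
    cannot run (e.g. a single-sex cohort) are recorded under ``"errors"``
    and do not stop the remaining stages.
    """
    config = config or PipelineConfig()
    df = cohort if isinstance(cohort, pd.DataFrame) else read_cohort_csv(cohort)
    regions = [r for r in REGION_NAMES if r in df.columns]
    bundle: dict = {"errors": []}

    bundle["group_means_overall"] = summarize_group_means(df, regions)

    long = df.melt(
        id_vars=[c for c in ("subject_id", "age", "sex", "side") if c in df],
        value_vars=regions, var_name="region", value_name="thickness",
    )
    bundle["tukey_region"] = comparisons_frame(
        tukey_pairwise(long, "region", "thickness", alpha=config.alpha)
    )

    age_grid = np.linspace(df["age"].min(), df["age"].max(), 25)
    for factor in config.factors:
        if factor not in df.columns:
            bundle["errors"].append(f"factor {factor!r} not in cohort table")
            continue
        try:
            bundle[f"group_means_{factor}"] = summarize_group_means(
                df, regions, grouping=factor
            )
        except InputError as exc:
            bundle["errors"].append(f"group means by {factor}: {exc}")
        tukey_rows, reg_rows, band_frames = [], [], []
        for region in regions:
            try:
                res = tukey_pairwise(df, factor, region, alpha=config.alpha)
                frame = comparisons_frame(res)
                frame.insert(0, "region", region)
                tukey_rows.append(frame)
            except InputError as exc:
                bundle["errors"].append(f"tukey {factor}/{region}: {exc}")
            try:
                fit = fit_interaction_model(df, region, factor, alpha=config.alpha)
                reg_rows.append(
                    {
                        "region": region,
                        "age_coef": fit.age_coef,
                        "age_p": float(fit.pvalues["age"]),
                        "interaction_coef": fit.interaction_coef,
                        "interaction_p": fit.interaction_p,
                        "consistent": fit.consistent,
                    }
                )
                band = ci_band(fit, age_grid, alpha=config.alpha)
                band.insert(0, "region", region)
                band_frames.append(band)
            except InputError as exc:
                bundle["errors"].append(f"regression {factor}/{region}: {exc}")
        if tukey_rows:
            bundle[f"tukey_{factor}"] = pd.concat(tukey_rows, ignore_index=True)
        if reg_rows:
            bundle[f"regression_{factor}"] = pd.DataFrame(reg_rows)
        if band_frames:
            bundle[f"bands_{factor}"] = pd.concat(band_frames, ignore_index=True)
    for err in bundle["errors"]:
        logger.warning("cohort stage skipped: %s", err)
    return bundle


def write_bundle(bundle: dict, outdir, config: PipelineConfig) -> list[Path]:
    """Write every table to CSV with a provenance header comment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# carthick v{__version__} config={config.hash()}\n"
    written = []
    for name, obj in bundle.items():
        if not isinstance(obj, (pd.DataFrame, pd.Series)):
            continue
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            obj.to_csv(fh)
        written.append(path)
    return written
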