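"""Parcellation of the knee into the 14 WORMS cartilage regions.

Region nomenclature: femur (F), tibia (T), patella (P); medial (M) / lateral
(L); anterior (A) / central (C) / posterior (P). Femur and tibia each carry
six regions (FMA … FLP, TMA … TLP); the patella carries two (PM, PL) —
fourteen in total.

The geometric atlas partitions the *whole* grid: every voxel is assigned to
its nearest bone, split medial/lateral at the parasagittal plane through the
tibial (femur/tibia) or patellar (patella) centroid, and split
anterior/central/posterior by configurable fractions (default equal thirds)
of the anteroposterior extent of that bone's cartilage. WORMS defines the
regions anatomically; equal thirds is a reproducible convention, not an
anatomical reproduction. An alignment hook (identity or 4x4 affine, with
nearest-label resampling) stands in for subject-to-atlas registration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .thickness import BoundaryPointSet
from .volume import InputError, LabelVolume

logger = logging.getLogger(__name__)

REGION_CODES: dict[str, int] = {
    name: i + 1
    for i, name in enumerate(
        (
            "FMA", "FMC", "FMP", "FLA", "FLC", "FLP",
            "TMA", "TMC", "TMP", "TLA", "TLC", "TLP",
            "PM", "PL",
        )
    )
}
CODE_TO_REGION = {v: k for k, v in REGION_CODES.items()}

_BONE_PREFIX = {"femur": "F", "tibia": "T", "patella": "P"}


@dataclass
class RegionAtlas:
    """Integer region-label grid with its code table and provenance."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    code_map: dict[int, str]
    provenance: str = "builtin_geometric"

    def region_codes_present(self) -> set[str]:
        present = np.unique(self.labels)
        return {self.code_map[int(c)] for c in present if int(c) in self.code_map}

    def save(self, nifti_path, sidecar_path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(nifti_path))
        with open(sidecar_path, "w") as fh:
            json.dump({str(k): v for k, v in self.code_map.items()}, fh, indent=1)

    @classmethod
    def load(cls, nifti_path, sidecar_path) -> "RegionAtlas":
        img = nib.load(str(nifti_path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        with open(sidecar_path) as fh:
            code_map = {int(k): v for k, v in json.load(fh).items()}
        return cls(labels, spacing, code_map, provenance="user_supplied")


class AffineTransform:
    """4x4 affine mapping subject physical coordinates (mm) to atlas
    physical coordinates; text format is a whitespace-separated 4x4 matrix."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise InputError("affine transform must be a 4x4 matrix")
        self.matrix = matrix

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_file(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path))

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def _acp_bounds(extent_lo: int, extent_hi: int, fractions) -> tuple[float, float]:
    span = extent_hi - extent_lo + 1
    b1 = extent_lo + fractions[0] * span
    b2 = extent_lo + (fractions[0] + fractions[1]) * span
    return b1, b2


def build_geometric_atlas(
    volume: LabelVolume, acp_fractions=(1 / 3, 1 / 3, 1 / 3)
) -> RegionAtlas:
    """Rule-based 14-region partition of the whole grid.

    Every voxel goes to its nearest bone (physical EDT); femur/tibia voxels
    split medial/lateral at the tibial-centroid parasagittal plane and A/C/P
    along the AP extent of that bone's cartilage (falling back to the bone
    itself if the cartilage is absent); patella voxels split medial/lateral
    at the patellar centroid. Yields exactly 14 codes on any grid that
    contains all three bones.
    """
    if abs(sum(acp_fractions) - 1.0) > 1e-9 or any(f <= 0 for f in acp_fractions):
        raise InputError("A/C/P fractions must be positive and sum to 1")
    bones = ("femur", "tibia", "patella")
    missing = [b for b in bones if not volume.has(b)]
    if missing:
        raise InputError(f"atlas construction requires bones: missing {missing}")

    masks = {b: volume.mask(b).voxels for b in bones}
    dist = np.stack(
        [
            ndimage.distance_transform_edt(~masks[b], sampling=volume.spacing_mm)
            for b in bones
        ]
    )
    nearest = np.argmin(dist, axis=0)  # 0 femur, 1 tibia, 2 patella

    ml_idx = np.arange(volume.shape[2])[None, None, :]
    ap_idx = np.arange(volume.shape[1])[None, :, None]

    tibia_ml = ndimage.center_of_mass(masks["tibia"])[2]
    patella_ml = ndimage.center_of_mass(masks["patella"])[2]

    labels = np.zeros(volume.shape, dtype=np.int16)
    for bi, bone in enumerate(bones):
        sel = nearest == bi
        split_ml = patella_ml if bone == "patella" else tibia_ml
        medial = ml_idx < split_ml  # smaller ML index = medial by convention
        prefix = _BONE_PREFIX[bone]
        if bone == "patella":
            labels[sel & np.broadcast_to(medial, volume.shape)] = REGION_CODES["PM"]
            labels[sel & np.broadcast_to(~medial, volume.shape)] = REGION_CODES["PL"]
            continue
        cart_name = {"femur": "femoral_cartilage", "tibia": "tibial_cartilage"}[bone]
        ref = (
            volume.mask(cart_name).voxels
            if volume.has(cart_name)
            else masks[bone]
        )
        ap_where = np.where(ref.any(axis=(0, 2)))[0]
        b1, b2 = _acp_bounds(int(ap_where[0]), int(ap_where[-1]), acp_fractions)
        anterior = ap_idx < b1
        central = (ap_idx >= b1) & (ap_idx < b2)
        for side_name, side in (("M", medial), ("L", ~medial)):
            side_b = np.broadcast_to(side, volume.shape)
            for acp_name, acp in (
                ("A", anterior),
                ("C", central),
                ("P", ~(anterior | central)),
            ):
                acp_b = np.broadcast_to(acp, volume.shape)
                labels[sel & side_b & acp_b] = REGION_CODES[
                    f"{prefix}{side_name}{acp_name}"
                ]
    return RegionAtlas(
        labels, volume.spacing_mm, dict(CODE_TO_REGION), provenance="builtin_geometric"
    )


def align_atlas(
    atlas: RegionAtlas, subject: LabelVolume, transform=None
) -> RegionAtlas:
    """Resample atlas labels onto the subject grid by nearest-label lookup.

    ``transform`` maps subject physical coordinates to atlas physical
    coordinates: ``None`` (identity), an :class:`AffineTransform`, or any
    callable on (N, 3) mm coordinates. Subject voxels that map outside the
    atlas domain become unassigned (code 0); their count is logged.
    """
    if transform is None and atlas.labels.shape == subject.shape and np.allclose(
        atlas.spacing_mm, subject.spacing_mm
    ):
        return RegionAtlas(
            atlas.labels.copy(), subject.spacing_mm, dict(atlas.code_map),
            atlas.provenance,
        )
    if transform is None:
        transform = AffineTransform.identity()
    idx = np.indices(subject.shape).reshape(3, -1).T
    phys = idx * np.asarray(subject.spacing_mm)
    mapped = np.asarray(transform(phys), dtype=float)
    vox = mapped / np.asarray(atlas.spacing_mm)
    resampled = ndimage.map_coordinates(
        atlas.labels, vox.T, order=0, mode="constant", cval=0
    ).reshape(subject.shape)
    n_unassigned = int((resampled == 0).sum())
    if n_unassigned:
        logger.info("%d subject voxels map outside the atlas", n_unassigned)
    return RegionAtlas(
        resampled.astype(np.int16), subject.spacing_mm, dict(atlas.code_map),
        atlas.provenance,
    )


def assign_points(points: BoundaryPointSet, atlas: RegionAtlas) -> np.ndarray:
    """Region name per inner boundary point (empty string = unassigned).

    The point takes whatever code occupies its voxel in the subject-space
    atlas; interface voxels therefore resolve deterministically.
    """
    codes = atlas.labels[tuple(points.inner_idx.T)]
    names = np.array(
        [atlas.code_map.get(int(c), "") if c != 0 else "" for c in codes],
        dtype=object,
    )
    n_un = int((names == "").sum())
    if n_un:
        logger.info("%d inner points unassigned by the atlas", n_un)
    return names
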