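"""Label volumes, masks and scalar fields on anisotropic voxel grids.

Axis convention used throughout the package (documented, overridable nowhere —
phantoms and atlases are built in this frame):

* axis 0 — superior→inferior (SI), fine in-plane resolution
* axis 1 — anterior→posterior (AP), fine in-plane resolution
* axis 2 — medial→lateral (ML), the slice direction (coarse, e.g. 3 mm)

All physical quantities are millimetres. Voxel ``(i, j, k)`` sits at physical
position ``(i*s0, j*s1, k*s2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical structure names and default integer codes for the six segmented
#: structures (three bones and their articular cartilages).
STRUCTURES = (
    "femur",
    "tibia",
    "patella",
    "femoral_cartilage",
    "tibial_cartilage",
    "patellar_cartilage",
)

DEFAULT_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(STRUCTURES)}

#: Which cartilage belongs to which bone.
CARTILAGE_OF_BONE = {
    "femur": "femoral_cartilage",
    "tibia": "tibial_cartilage",
    "patella": "patellar_cartilage",
}


class InputError(ValueError):
    """Malformed or missing input (CLI exit code 2)."""


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate to measure (CLI exit code 3)."""


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InputError(f"spacing must be 3 positive reals, got {spacing_mm!r}")
    return spacing


@dataclass
class LabelMask:
    """A single structure's boolean occupancy grid with physical spacing."""

    voxels: np.ndarray
    structure: str
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise InputError("mask must be a 3-D grid")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_compatible(self, other: "LabelMask") -> None:
        if self.voxels.shape != other.voxels.shape:
            raise InputError(
                f"mask shapes differ: {self.voxels.shape} vs {other.voxels.shape}"
            )
        if self.structure != other.structure:
            raise InputError(
                f"structure codes differ: {self.structure!r} vs {other.structure!r}"
            )


@dataclass
class LabelVolume:
    """Integer label grid holding all segmented structures of one knee."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError("label volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InputError("label volume must hold integer codes")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if len(set(self.codes.values())) != len(self.codes):
            raise InputError("label codes must be distinct")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def has(self, structure: str) -> bool:
        code = self.codes.get(structure)
        return code is not None and bool((self.data == code).any())

    def mask(self, structure: str) -> LabelMask:
        if structure not in self.codes:
            raise InputError(f"no code declared for structure {structure!r}")
        return LabelMask(
            self.data == self.codes[structure], structure, self.spacing_mm
        )

    def missing_structures(self, required=STRUCTURES) -> list[str]:
        return [s for s in required if not self.has(s)]

    # ---- NIfTI round trip ------------------------------------------------
    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.int16), affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, codes: dict[str, int] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise InputError(f"{path}: voxel values are not integer labels")
            data = rounded.astype(np.int32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, spacing, dict(codes or DEFAULT_CODES))


def save_scalar_nifti(values: np.ndarray, spacing_mm, path) -> None:
    """Write a float scalar field (e.g. ground-truth thickness) as NIfTI-1."""
    spacing = _check_spacing(spacing_mm)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def voxel_to_physical(idx: np.ndarray, spacing_mm) -> np.ndarray:
    """Map (N, 3) voxel indices to physical mm coordinates."""
    return np.asarray(idx, dtype=float) * np.asarray(spacing_mm, dtype=float)
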