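"""Voxel-grid structure representation and morphological operations.

Structures (targets, organs at risk, planning auxiliaries) are boolean
masks on a shared anisotropic voxel grid.  Morphological expansion and
contraction are Euclidean, computed in physical millimetres through the
distance transform of the mask (or of its complement), so a 5 mm margin
means 5 mm regardless of voxel spacing.  A voxel belongs to a structure
by its centre point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

log = logging.getLogger(__name__)

#: The seven protocol target volumes.
TARGET_NAMES = (
    "GTV_T_P",
    "CTV1_P",
    "CTV2_P",
    "GTV_NL_P",
    "GTV_NR_P",
    "CTV_NL_P",
    "CTV_NR_P",
)

#: The ten protocol organs at risk.
OAR_NAMES = (
    "left parotid",
    "right parotid",
    "brainstem",
    "spinal cord",
    "left optic lens",
    "right optic lens",
    "left optic nerve",
    "right optic nerve",
    "pituitary",
    "optic chiasm",
)

#: Auxiliary structures derivable from the targets and the body contour.
AUXILIARY_NAMES = (
    "CTV1_GTV",
    "CTV2_CTV1",
    "CTV_GTV_NL_P",
    "CTV_GTV_NR_P",
    "CTV_ALL",
    "R5200",
    "R4500",
    "R3600",
    "R3100",
)


class StructureError(ValueError):
    """Raised for empty structures, grid mismatches, or missing names."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice with anisotropic physical spacing.

    Parameters
    ----------
    shape
        Number of voxels along each axis, ``(nx, ny, nz)``.
    spacing_mm
        Physical voxel size along each axis in mm; all components > 0.
    origin_mm
        Physical coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz / 1000.0

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays (broadcastable, mm)."""
        axes = [
            self.origin_mm[i] + self.spacing_mm[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm coordinates."""
        aff = np.diag([*self.spacing_mm, 1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class StructureMask:
    """A named boolean mask on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise StructureError(
                f"mask {self.name!r} shape {self.voxels.shape} does not match "
                f"grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def with_name(self, name: str) -> "StructureMask":
        return StructureMask(name, self.grid, self.voxels)


@dataclass
class StructureSet:
    """All delineated structures of one patient on a shared grid."""

    patient_id: str
    grid: VoxelGrid
    masks: dict[str, StructureMask] = field(default_factory=dict)

    def add(self, mask: StructureMask) -> None:
        if mask.grid != self.grid:
            raise StructureError(
                f"mask {mask.name!r} is on a different grid than structure set "
                f"{self.patient_id!r}"
            )
        if mask.name in self.masks:
            raise StructureError(f"duplicate structure name {mask.name!r}")
        self.masks[mask.name] = mask

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise StructureError(
                f"structure {name!r} missing from set {self.patient_id!r}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)


def _check_same_grid(masks: Iterable[StructureMask]) -> VoxelGrid:
    masks = list(masks)
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise StructureError(
                f"grid mismatch between {masks[0].name!r} and {m.name!r}; "
                "masks are never resampled implicitly"
            )
    return grid


def distance_from_structure(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the structure.

    Zero on structure voxels.  Honors anisotropic spacing.
    """
    if mask.is_empty:
        raise StructureError(f"empty structure {mask.name!r}")
    return ndimage.distance_transform_edt(
        ~mask.voxels, sampling=mask.grid.spacing_mm
    )


def distance_from_complement(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the complement.

    Zero outside the structure; the structure's interior depth inside.
    Distances are computed within the grid (no padding), so a structure
    touching the grid edge keeps its in-grid depth.
    """
    if mask.is_empty:
        raise StructureError(f"empty structure {mask.name!r}")
    return ndimage.distance_transform_edt(
        mask.voxels, sampling=mask.grid.spacing_mm
    )


def expand(mask: StructureMask, distance_mm: float) -> StructureMask:
    """Uniform Euclidean expansion by ``distance_mm`` (mm).

    The result contains every voxel whose centre lies within
    ``distance_mm`` of the structure; it is always a superset of the
    input.  Expansion by 0 is the identity.
    """
    if distance_mm < 0:
        raise ValueError("expansion distance must be non-negative")
    if mask.is_empty:
        raise StructureError(f"empty structure {mask.name!r}")
    if distance_mm == 0:
        return StructureMask(mask.name, mask.grid, mask.voxels.copy())
    out = distance_from_structure(mask) <= distance_mm
    if _touches_boundary(out) and not _touches_boundary(mask.voxels):
        log.warning(
            "expansion of %r by %g mm is truncated by the grid edge",
            mask.name, distance_mm,
        )
    return StructureMask(mask.name, mask.grid, out)


def contract(mask: StructureMask, distance_mm: float) -> StructureMask:
    """Uniform Euclidean contraction by ``distance_mm`` (mm).

    Keeps the voxels whose distance to the structure's complement
    exceeds ``distance_mm``; always a subset of the input and possibly
    empty (over-contraction is not an error).
    """
    if distance_mm < 0:
        raise ValueError("contraction distance must be non-negative")
    if mask.is_empty:
        raise StructureError(f"empty structure {mask.name!r}")
    if distance_mm == 0:
        return StructureMask(mask.name, mask.grid, mask.voxels.copy())
    out = distance_from_complement(mask) > distance_mm
    return StructureMask(mask.name, mask.grid, out)


def _touches_boundary(voxels: np.ndarray) -> bool:
    return bool(
        voxels[0].any() or voxels[-1].any()
        or voxels[:, 0].any() or voxels[:, -1].any()
        or voxels[:, :, 0].any() or voxels[:, :, -1].any()
    )


def subtract(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Set difference ``a \\ b`` (voxelwise ``a AND NOT b``)."""
    _check_same_grid([a, b])
    return StructureMask(name or a.name, a.grid, a.voxels & ~b.voxels)


def union(masks: list[StructureMask], name: str | None = None) -> StructureMask:
    """Voxelwise OR of one or more masks on a shared grid."""
    if not masks:
        raise StructureError("union of an empty list of masks")
    grid = _check_same_grid(masks)
    out = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        out |= m.voxels
    return StructureMask(name or masks[0].name, grid, out)


def intersect(a: StructureMask, b: StructureMask, name: str | None = None) -> StructureMask:
    """Voxelwise AND."""
    _check_same_grid([a, b])
    return StructureMask(name or a.name, a.grid, a.voxels & b.voxels)


def make_auxiliary_structures(s: StructureSet, body_name: str = "BODY") -> StructureSet:
    """Derive the planning auxiliaries from the protocol targets.

    Adds, on a copy of the input set:

    * ``CTV1_GTV``     = CTV1_P minus GTV_T_P
    * ``CTV2_CTV1``    = CTV2_P minus CTV1_P
    * ``CTV_GTV_NL_P`` = CTV_NL_P minus GTV_NL_P (same for the right side)
    * ``CTV_ALL``      = CTV2_P union CTV_NL_P union CTV_NR_P
    * ``R5200``        = 5 mm..10 mm shell around CTV_ALL
    * ``R4500``        = 10 mm..15 mm shell
    * ``R3600``        = 15 mm..25 mm shell
    * ``R3100``        = body minus the 25 mm expansion

    All rings are clipped to the body contour.  Raises
    :class:`StructureError` naming the first missing required structure.
    """
    for required in (*TARGET_NAMES, body_name):
        if required not in s:
            raise StructureError(
                f"structure {required!r} missing from set {s.patient_id!r}"
            )
    out = StructureSet(s.patient_id, s.grid, dict(s.masks))
    body = s[body_name]

    out.add(subtract(s["CTV1_P"], s["GTV_T_P"], "CTV1_GTV"))
    out.add(subtract(s["CTV2_P"], s["CTV1_P"], "CTV2_CTV1"))
    out.add(subtract(s["CTV_NL_P"], s["GTV_NL_P"], "CTV_GTV_NL_P"))
    out.add(subtract(s["CTV_NR_P"], s["GTV_NR_P"], "CTV_GTV_NR_P"))

    ctv_all = union([s["CTV2_P"], s["CTV_NL_P"], s["CTV_NR_P"]], "CTV_ALL")
    out.add(ctv_all)

    # one distance field serves all four expansions (expand == threshold)
    dist = distance_from_structure(ctv_all)
    shells = {
        d: StructureMask("CTV_ALL", s.grid, dist <= d)
        for d in (5.0, 10.0, 15.0, 25.0)
    }
    if _touches_boundary(shells[25.0].voxels):
        log.warning(
            "25 mm expansion of CTV_ALL for %r is truncated by the grid edge",
            s.patient_id,
        )
    out.add(intersect(subtract(shells[10.0], shells[5.0], "R5200"), body, "R5200"))
    out.add(intersect(subtract(shells[15.0], shells[10.0], "R4500"), body, "R4500"))
    out.add(intersect(subtract(shells[25.0], shells[15.0], "R3600"), body, "R3600"))
    out.add(subtract(body, shells[25.0], "R3100"))
    return out


# ---------------------------------------------------------------------------
# NIfTI input/output


def grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return VoxelGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), origin)


def read_structure_nifti(path: str, name: str, grid: VoxelGrid | None = None) -> StructureMask:
    """Read one boolean (0/1) structure volume from a NIfTI file."""
    img = nib.load(path)
    file_grid = grid_from_nifti(img)
    if grid is not None and (
        file_grid.shape != grid.shape or file_grid.spacing_mm != grid.spacing_mm
    ):
        raise StructureError(
            f"grid mismatch reading {path}: file {file_grid.shape}/"
            f"{file_grid.spacing_mm}, expected {grid.shape}/{grid.spacing_mm}"
        )
    data = np.asarray(img.dataobj)
    return StructureMask(name, grid or file_grid, data > 0.5)


def write_structure_nifti(mask: StructureMask, path: str) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, path)


def read_structure_set_labelmap(
    labelmap_path: str, labels_yaml_path: str, patient_id: str = ""
) -> StructureSet:
    """Read a single NIfTI label map plus a YAML name->label mapping."""
    img = nib.load(labelmap_path)
    grid = grid_from_nifti(img)
    data = np.asarray(img.dataobj)
    with open(labels_yaml_path) as fh:
        mapping: Mapping[str, int] = yaml.safe_load(fh)
    s = StructureSet(patient_id, grid)
    for name, label in mapping.items():
        s.add(StructureMask(str(name), grid, data == int(label)))
    return s


def read_structure_set_dir(
    directory: str, names_yaml_path: str | None = None, patient_id: str = ""
) -> StructureSet:
    """Read one NIfTI file per structure from ``directory``.

    Without a YAML alias table, file stems are taken as structure names
    (underscores in place of spaces are normalised for the protocol OAR
    names).  A YAML file maps structure name -> file name.
    """
    import os

    grid: VoxelGrid | None = None
    s: StructureSet | None = None
    if names_yaml_path is not None:
        with open(names_yaml_path) as fh:
            name_to_file: Mapping[str, str] = yaml.safe_load(fh)
        items = [(name, os.path.join(directory, fn)) for name, fn in name_to_file.items()]
    else:
        items = []
        for fn in sorted(os.listdir(directory)):
            if not (fn.endswith(".nii") or fn.endswith(".nii.gz")):
                continue
            stem = fn[: -len(".nii.gz")] if fn.endswith(".nii.gz") else fn[: -len(".nii")]
            name = _canonical_name(stem)
            items.append((name, os.path.join(directory, fn)))
    for name, path in items:
        mask = read_structure_nifti(path, name, grid)
        if s is None:
            grid = mask.grid
            s = StructureSet(patient_id, grid)
        s.add(mask)
    if s is None:
        raise StructureError(f"no NIfTI structures found in {directory}")
    return s


_SPACE_NAMES = {n.replace(" ", "_"): n for n in OAR_NAMES}


def _canonical_name(stem: str) -> str:
    return _SPACE_NAMES.get(stem, stem)


def write_structure_set_dir(s: StructureSet, directory: str) -> None:
    import os

    os.makedirs(directory, exist_ok=True)
    for name, mask in s.masks.items():
        fn = name.replace(" ", "_") + ".nii.gz"
        write_structure_nifti(mask, os.path.join(directory, fn))
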