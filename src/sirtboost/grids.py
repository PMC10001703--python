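"""Dose grids, structure masks and their on-disk representation.

The common spatial substrate for the whole pipeline is a regular 3-D voxel
lattice with physical spacing in millimetres.  Absorbed dose (Gy) lives on
the lattice as a float array; anatomical structures (liver, lesion GTVs,
normal liver tissue, PTVs) are boolean masks on the *same* lattice.  All
downstream dose metrics are voxel-wise, so masks must share the dose grid's
shape and spacing exactly — resampling between mismatched lattices is out of
scope and raises.

Axis convention: (x, y, z) = (left->right, posterior->anterior,
inferior->superior), voxel-centre origin.  On-disk format is NIfTI-1 via
nibabel; a JSON sidecar manifest groups the masks of one case into a
:class:`StructureSet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DoseGrid",
    "StructureMask",
    "StructureSet",
    "GeometryError",
    "load_dose_grid",
    "save_dose_grid",
    "load_mask",
    "save_mask",
    "load_structure_set",
    "save_structure_set",
    "volume_cc",
    "derive_nlt",
]

DEFAULT_AXIS_LABELS = ("left-right", "posterior-anterior", "inferior-superior")

# loader tolerance for tiny negative doses from float round-off
_NEG_TOL = 1e-6


class GeometryError(ValueError):
    """Raised when two objects do not share one voxel lattice."""


@dataclass(frozen=True)
class Geometry:
    """Lattice geometry shared by a dose grid and its masks."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, first voxel centre
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid must be 3-D with >=1 voxel per axis, got {self.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def matches(self, other: "Geometry") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        ) and np.allclose(self.origin, other.origin)

    def require_match(self, other: "Geometry", what: str = "mask") -> None:
        if not self.matches(other):
            raise GeometryError(
                f"{what} lattice {other.shape}@{other.spacing} does not match "
                f"dose lattice {self.shape}@{self.spacing}; resampling is not supported"
            )


def _as_geometry(obj) -> Geometry:
    return obj if isinstance(obj, Geometry) else obj.geometry


@dataclass
class DoseGrid:
    """3-D absorbed-dose field in Gy on a regular lattice.

    ``values[i, j, k]`` is the dose at voxel centre
    ``origin + (i, j, k) * spacing``.  Doses must be finite and non-negative.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"dose grid must be 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.geometry  # validate shape/spacing
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(self.values < -_NEG_TOL):
            raise ValueError(
                f"dose grid contains negative values (min {self.values.min():g} Gy)"
            )
        np.clip(self.values, 0.0, None, out=self.values)

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.values.shape, self.spacing, self.origin, self.axis_labels)

    @property
    def voxel_volume_cc(self) -> float:
        return self.geometry.voxel_volume_cc


@dataclass
class StructureMask:
    """Boolean structure mask on a dose-grid lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.geometry  # validate

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.values.shape, self.spacing, self.origin, self.axis_labels)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        return volume_cc(self)

    def is_empty(self) -> bool:
        return not self.values.any()

    def with_values(self, values: np.ndarray, name: str | None = None) -> "StructureMask":
        return StructureMask(values, self.spacing, self.origin,
                             self.name if name is None else name, self.axis_labels)


@dataclass
class StructureSet:
    """Named masks of one case; requires a liver and at least one ``gtv_*``."""

    case_id: str
    structures: dict[str, StructureMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.structures)) != len(self.structures):
            raise ValueError("structure names must be unique")

    def __getitem__(self, name: str) -> StructureMask:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def add(self, mask: StructureMask) -> None:
        if not mask.name:
            raise ValueError("mask must be named to join a StructureSet")
        self.structures[mask.name] = mask

    @property
    def liver(self) -> StructureMask:
        return self.structures["liver"]

    @property
    def gtv_names(self) -> list[str]:
        return sorted(n for n in self.structures if n.startswith("gtv"))

    @property
    def gtvs(self) -> list[StructureMask]:
        return [self.structures[n] for n in self.gtv_names]

    def validate(self) -> None:
        if "liver" not in self.structures:
            raise ValueError(f"case {self.case_id!r} has no 'liver' structure")
        if not self.gtv_names:
            raise ValueError(f"case {self.case_id!r} has no 'gtv_*' structures")
        geo = self.structures["liver"].geometry
        for name, mask in self.structures.items():
            geo.require_match(mask.geometry, what=name)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _load_volume(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid spacing metadata {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return np.asarray(data), tuple(float(z) for z in zooms), origin


def load_dose_grid(path) -> DoseGrid:
    """Load a NIfTI dose volume (Gy).

    Values in ``(-1e-6, 0)`` are clamped to zero; anything more negative
    raises, since absorbed dose cannot be negative.
    """
    data, spacing, origin = _load_volume(path)
    return DoseGrid(data.astype(float), spacing, origin)


def save_dose_grid(grid: DoseGrid, path) -> None:
    img = nib.Nifti1Image(grid.values.astype(np.float32),
                          _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def load_mask(path, name: str = "") -> StructureMask:
    data, spacing, origin = _load_volume(path)
    return StructureMask(data > 0.5, spacing, origin, name or Path(path).stem)


def save_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_structure_set(manifest_path) -> StructureSet:
    """Read a case manifest ``{"case_id", "structures": {name: file}, "spacing_mm"}``."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    sset = StructureSet(case_id=str(manifest["case_id"]))
    for name, fname in manifest["structures"].items():
        sset.add(load_mask(manifest_path.parent / fname, name=name))
    if "spacing_mm" in manifest:
        want = tuple(float(s) for s in manifest["spacing_mm"])
        for name, mask in sset.structures.items():
            if not np.allclose(mask.spacing, want):
                raise GeometryError(
                    f"{name}: spacing {mask.spacing} != manifest spacing {want}")
    sset.validate()
    return sset


def save_structure_set(sset: StructureSet, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, mask in sset.structures.items():
        fname = f"{name}.nii.gz"
        save_mask(mask, out_dir / fname)
        files[name] = fname
    any_mask = next(iter(sset.structures.values()))
    manifest = {
        "case_id": sset.case_id,
        "structures": files,
        "spacing_mm": list(any_mask.spacing),
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


# ---------------------------------------------------------------------------
# geometry arithmetic


def volume_cc(mask: StructureMask) -> float:
    """Volume of a mask in cc: true-voxel count times voxel volume."""
    return mask.voxel_count * mask.geometry.voxel_volume_cc


def union_masks(masks: list[StructureMask], name: str = "union") -> StructureMask:
    if not masks:
        raise ValueError("need at least one mask")
    geo = masks[0].geometry
    out = np.zeros(geo.shape, dtype=bool)
    for m in masks:
        geo.require_match(m.geometry, what=m.name or "mask")
        out |= m.values
    return masks[0].with_values(out, name=name)


def derive_nlt(liver: StructureMask, lesions: list[StructureMask]) -> StructureMask:
    """Normal liver tissue: liver minus the union of all lesion masks.

    Every segmented lesion is subtracted regardless of whether it is later
    targeted for a boost.
    """
    out = liver.values.copy()
    for lesion in lesions:
        liver.geometry.require_match(lesion.geometry, what=lesion.name or "lesion")
        out &= ~lesion.values
    return liver.with_values(out, name="nlt")
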