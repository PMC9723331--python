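"""Volumetric data model, NIfTI I/O, warping, morphology and distance maps.

Everything downstream (phantom synthesis, multi-atlas labeling, the random
walker, metrics) works on two containers defined here: :class:`Volume`
(a 3D scalar image with physical voxel spacing in mm) and :class:`LabelMap`
(an integer-coded segmentation on the same grid).  Grids are axis-aligned:
world coordinate = origin + index * spacing, voxel indices 0-based, bounding
boxes half-open.  Direction cosines are not handled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class ImagingError(ValueError):
    """Base class for grid / I/O contract violations."""


class GridMismatchError(ImagingError):
    """Two objects expected on the same grid are not."""


class NonVolumetricError(ImagingError):
    """A NIfTI file did not contain a 3D image."""


#: Canonical integer codes.  1-5 are the five main cardiovascular structures
#: (blood pools of the four chambers plus the LV myocardium); 6-10 are
#: auxiliary thoracic tissues used as scaffolding during corrective
#: segmentation and never reported in final outputs.
STRUCTURE_CODES: dict[str, int] = {
    "background": 0,
    "LV": 1,
    "RV": 2,
    "LA": 3,
    "RA": 4,
    "LVM": 5,
    "lung": 6,
    "chest_wall": 7,
    "liver": 8,
    "spine": 9,
    "desc_aorta": 10,
}

#: The five structures that are evaluated and predicted.
MAIN_STRUCTURES: tuple[str, ...] = ("LV", "RV", "LA", "RA", "LVM")

#: Tie-break / combination precedence used everywhere a single voxel must be
#: assigned one of several competing structures.
LABEL_PRIORITY: tuple[str, ...] = ("LV", "LA", "RV", "RA", "LVM")

AUX_STRUCTURES: tuple[str, ...] = ("lung", "chest_wall", "liver", "spine", "desc_aorta")


def _check_grid(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    if data.ndim != 3:
        raise NonVolumetricError(f"expected a 3D array, got {data.ndim} axes")
    if min(data.shape) < 1:
        raise ImagingError("every axis must have length >= 1")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ImagingError("spacing and origin must have 3 components")
    if any(s <= 0 for s in spacing):
        raise ImagingError(f"spacing components must be > 0, got {spacing}")
    return spacing, origin


@dataclass
class Volume:
    """3D scalar image on an axis-aligned grid.

    Parameters
    ----------
    data
        3D float array, HU-like intensity units.
    spacing
        Voxel size (sx, sy, sz) in mm along the three array axes.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def world_coordinates(self) -> np.ndarray:
        """(3, nx, ny, nz) array of world coordinates (mm) of voxel centers."""
        idx = np.indices(self.shape, dtype=np.float64)
        sp = np.asarray(self.spacing).reshape(3, 1, 1, 1)
        og = np.asarray(self.origin).reshape(3, 1, 1, 1)
        return og + idx * sp


@dataclass
class LabelMap:
    """Integer-coded segmentation sharing a Volume's grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    code_table: dict[str, int] = field(default_factory=lambda: dict(STRUCTURE_CODES))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int16)
            else:
                raise ImagingError("label data must be integer-valued")
        if self.data.min() < 0:
            raise ImagingError("label codes must be non-negative")
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)
        present = set(np.unique(self.data)) - {0}
        known = set(self.code_table.values())
        unknown = present - known
        if unknown:
            raise ImagingError(f"label codes {sorted(unknown)} missing from code_table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    same_grid = Volume.same_grid
    world_coordinates = Volume.world_coordinates

    def mask(self, structure: str) -> np.ndarray:
        """Binary mask of one named structure."""
        return self.data == self.code_table[structure]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open index box: lo inclusive, hi exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ImagingError(f"empty bounding box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def to_json(self) -> str:
        return json.dumps({"lo": list(self.lo), "hi": list(self.hi)})

    @classmethod
    def from_json(cls, text: str) -> "BoundingBox":
        d = json.loads(text)
        return cls(tuple(d["lo"]), tuple(d["hi"]))


@dataclass
class DisplacementField:
    """Per-voxel 3D displacement (mm) defined on the fixed grid.

    ``disp`` has shape (3, nx, ny, nz); a zero field is the identity mapping.
    Warping samples the moving image at world position
    ``x_fixed + disp(x_fixed)``.
    """

    disp: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ImagingError("displacement field must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.disp)):
            raise ImagingError("displacement field must be finite")
        self.spacing, self.origin = _check_grid(
            self.disp[0], self.spacing, self.origin
        )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.disp.shape[1:]

    @classmethod
    def zero(cls, shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        return cls(np.zeros((3, *shape)), spacing, origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing, volume.origin)
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NonVolumetricError(f"{path} is non-3D (ndim={data.ndim})")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, zooms, origin


def read_volume(path) -> Volume:
    data, spacing, origin = _load_nifti(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_labelmap(label: LabelMap, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(label.data, dtype=np.int16), _affine(label.spacing, label.origin)
    )
    img.header.set_zooms(label.spacing)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(label.code_table, indent=0))


def _sidecar_path(path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".codes.json")
    return path.with_suffix(".codes.json")


def read_labelmap(path) -> LabelMap:
    data, spacing, origin = _load_nifti(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ImagingError(f"{path} contains non-integer data for a label map")
        data = np.round(data)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        code_table = {k: int(v) for k, v in json.loads(sidecar.read_text()).items()}
    else:
        code_table = dict(STRUCTURE_CODES)
    return LabelMap(data.astype(np.int16), spacing, origin, code_table)


# ---------------------------------------------------------------------------
# Warping


def warp(image, field: DisplacementField, mode: str = "linear"):
    """Resample ``image`` onto the field's (fixed) grid through ``field``.

    The output voxel at index i takes the moving image's value at world
    position ``origin_f + i*spacing_f + disp[i]``.  Out-of-domain samples are
    background (0).  Label maps must use ``mode="nearest"``.
    """
    is_label = isinstance(image, LabelMap)
    if is_label and mode == "linear":
        raise ImagingError("label maps must be warped with mode='nearest'")
    if mode not in ("linear", "nearest"):
        raise ImagingError(f"unknown interpolation mode {mode!r}")
    # world position sampled for each fixed voxel -> moving-grid index
    fixed_world = (
        np.indices(field.grid_shape, dtype=np.float64)
        * np.asarray(field.spacing).reshape(3, 1, 1, 1)
        + np.asarray(field.origin).reshape(3, 1, 1, 1)
        + field.disp
    )
    moving_idx = (
        fixed_world - np.asarray(image.origin).reshape(3, 1, 1, 1)
    ) / np.asarray(image.spacing).reshape(3, 1, 1, 1)
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(image.data, dtype=np.float64 if mode == "linear" else image.data.dtype),
        moving_idx,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    if is_label:
        return LabelMap(
            out.astype(image.data.dtype), field.spacing, field.origin, dict(image.code_table)
        )
    return Volume(out.astype(np.float32), field.spacing, field.origin)


# ---------------------------------------------------------------------------
# Morphology and distance transforms
#
# Structuring elements are Euclidean balls measured in mm, realised through
# the anisotropy-aware exact Euclidean distance transform, so "erode by 5 mm"
# is the same physical operation at any voxel spacing.


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(np.unique(mask), (0, 1)).all():
            raise ImagingError("mask must be binary")
        mask = mask.astype(bool)
    return mask


def dilate(mask, radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    mask = _as_bool(mask)
    if radius_mm < 0:
        raise ImagingError("radius_mm must be >= 0")
    if radius_mm == 0 or not mask.any() or mask.all():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def erode(mask, radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Erosion by the closed Euclidean ball of ``radius_mm``: a voxel is kept
    iff no background voxel center lies within ``radius_mm`` of it.  Exact
    dual of :func:`dilate`, so opening/closing have their lattice properties."""
    mask = _as_bool(mask)
    if radius_mm < 0:
        raise ImagingError("radius_mm must be >= 0")
    if radius_mm == 0 or not mask.any() or mask.all():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    return dist > radius_mm


def opening(mask, radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    return dilate(erode(mask, radius_mm, spacing), radius_mm, spacing)


def closing(mask, radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    return erode(dilate(mask, radius_mm, spacing), radius_mm, spacing)


def morphology(mask, op: str, radius_mm: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    ops = {"erode": erode, "dilate": dilate, "open": opening, "close": closing}
    if op not in ops:
        raise ImagingError(f"unknown morphology op {op!r}")
    return ops[op](mask, radius_mm, spacing)


#: 6-connectivity structuring element used for components and surfaces.
CONN6 = ndimage.generate_binary_structure(3, 1)


def connected_components(mask) -> tuple[np.ndarray, int]:
    """Label 6-connected components; returns (component labels, count)."""
    return ndimage.label(_as_bool(mask), structure=CONN6)


def largest_component(mask) -> np.ndarray:
    mask = _as_bool(mask)
    if not mask.any():
        return mask.copy()
    comps, n = connected_components(mask)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    return comps == sizes.argmax()


def surface_voxels(mask) -> np.ndarray:
    """Boundary voxels of the mask: mask voxels with >= 1 background 6-neighbor."""
    mask = _as_bool(mask)
    interior = ndimage.binary_erosion(mask, structure=CONN6, border_value=0)
    return mask & ~interior


def surface_distance_map(mask, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Unsigned distance (mm) to the mask's surface voxel set, zero on it."""
    mask = _as_bool(mask)
    if not mask.any():
        raise ImagingError("surface distance of an empty mask is undefined")
    surf = surface_voxels(mask)
    return ndimage.distance_transform_edt(~surf, sampling=spacing)


__all__ = [
    "Volume",
    "LabelMap",
    "BoundingBox",
    "DisplacementField",
    "STRUCTURE_CODES",
    "MAIN_STRUCTURES",
    "LABEL_PRIORITY",
    "AUX_STRUCTURES",
    "ImagingError",
    "GridMismatchError",
    "NonVolumetricError",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "warp",
    "morphology",
    "erode",
    "dilate",
    "opening",
    "closing",
    "connected_components",
    "largest_component",
    "surface_voxels",
    "surface_distance_map",
]
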