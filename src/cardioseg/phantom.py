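"""Synthetic contrast-enhanced cardiac CTA phantoms with ground-truth labels.

The phantom emulates the imaging situation of a contrast CTA study: the four
cardiac chambers and the descending aorta are contrast-filled blood pool
(bright, ~400 HU), the LV myocardium is an intermediate-intensity closed
shell around the LV cavity, lungs are near air density, the spine is bone,
and liver/chest wall are soft tissue.  Geometry is a parametric template
(ellipsoidal chambers, shell myocardium, tubular aorta, flanking lungs)
defined in world millimeters, deformed per subject by a random affine plus a
smooth random warp, so every subject shares topology but differs in shape.
Intensities are per-structure means plus Gaussian noise.

This is deliberately not a biophysical CT simulator: there is no beam
hardening, motion, partial-volume blur beyond grid sampling, or pathology.
It provides exactly what the labeling framework needs — realistic topology
and contrast with exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    ImagingError,
    LabelMap,
    MAIN_STRUCTURES,
    STRUCTURE_CODES,
    Volume,
    erode,
)

#: chamber erosion radius (mm) of the synthetic weak-label degradation
SWL_EROSION_MM = 5.0

_DEFAULT_MEANS = {
    # HU-like scale: air -1000, water 0, contrast blood pool ~400, bone ~700
    "background": 30.0,  # mediastinal / body soft tissue (outside-body air is -1000)
    "LV": 400.0,
    "RV": 400.0,
    "LA": 400.0,
    "RA": 400.0,
    "LVM": 90.0,
    "lung": -800.0,
    "chest_wall": 30.0,
    "liver": 60.0,
    "spine": 700.0,
    "desc_aorta": 400.0,
}

_AIR_HU = -1000.0


@dataclass
class PhantomParams:
    """Study conditions for one phantom cohort.

    The template anatomy lives in a fixed 160 mm field of view; ``shape`` and
    ``spacing`` choose the sampling grid (defaults: 64³ voxels at 2.5 mm).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    intensity_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    noise_sd: float = 15.0
    scale_range: tuple[float, float] = (0.92, 1.08)
    rotation_deg: float = 7.0  # about the z axis
    translation_mm: float = 5.0
    warp_amplitude_mm: float = 3.0
    warp_control_points: int = 5

    def __post_init__(self):
        if self.noise_sd < 0 or self.warp_amplitude_mm < 0 or self.translation_mm < 0:
            raise ImagingError("jitter amplitudes and noise SD must be >= 0")
        m = self.intensity_means
        if not (m["LV"] > m["LVM"] > m["lung"]):
            raise ImagingError(
                "contrast ordering violated: need blood pool > myocardium > lung"
            )

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class PhantomCase:
    """One synthetic subject: image, exact ground truth, and its transform."""

    case_id: str
    volume: Volume
    label: LabelMap
    transform: dict


def _ellipsoid(p, center, radii):
    return (
        ((p[0] - center[0]) / radii[0]) ** 2
        + ((p[1] - center[1]) / radii[1]) ** 2
        + ((p[2] - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _cylinder_z(p, cx, cy, radius):
    return ((p[0] - cx) ** 2 + (p[1] - cy) ** 2) <= radius**2


def _template_labels(p: np.ndarray) -> np.ndarray:
    """Evaluate the anatomical template at world points ``p`` (3, ...).

    Structures are carved in a fixed order so they are pairwise disjoint by
    construction; the LVM is the 6 mm ellipsoidal shell around the LV cavity.
    """
    C = STRUCTURE_CODES
    out = np.zeros(p.shape[1:], dtype=np.int16)
    body = (((p[0] - 80.0) / 76.0) ** 2 + ((p[1] - 80.0) / 72.0) ** 2) <= 1.0
    inner_body = (((p[0] - 80.0) / 64.0) ** 2 + ((p[1] - 80.0) / 60.0) ** 2) <= 1.0

    taken = np.zeros_like(body)

    def paint(mask, code):
        nonlocal taken
        m = mask & ~taken
        out[m] = code
        taken |= m

    lv = _ellipsoid(p, (70, 70, 70), (16, 16, 22))
    paint(lv, C["LV"])
    paint(_ellipsoid(p, (70, 70, 70), (22, 22, 28)), C["LVM"])  # shell: LV carved out
    paint(_ellipsoid(p, (99, 62, 70), (15, 13, 18)), C["RV"])
    paint(_ellipsoid(p, (74, 98, 100), (13, 13, 13)), C["LA"])
    paint(_ellipsoid(p, (102, 90, 96), (12, 12, 14)), C["RA"])
    paint(_cylinder_z(p, 80.0, 124.0, 9.0) & body, C["desc_aorta"])
    paint(_cylinder_z(p, 80.0, 142.0, 7.0) & body, C["spine"])
    paint(_ellipsoid(p, (34, 76, 80), (24, 42, 66)) & inner_body, C["lung"])
    paint(_ellipsoid(p, (126, 76, 80), (24, 42, 66)) & inner_body, C["lung"])
    paint(_ellipsoid(p, (98, 84, 22), (34, 30, 20)) & inner_body, C["liver"])
    paint(body & ~inner_body, C["chest_wall"])
    # remaining body voxels stay code 0 (uncoded soft tissue); outside body is air
    out_of_body = ~body
    out[out_of_body] = 0
    return out, body


def _subject_transform(params: PhantomParams, rng: np.random.Generator) -> dict:
    lo, hi = params.scale_range
    return {
        "scale": rng.uniform(lo, hi, size=3),
        "rot_z_deg": rng.uniform(-params.rotation_deg, params.rotation_deg),
        "translation": rng.uniform(-params.translation_mm, params.translation_mm, size=3),
        "warp_seed": int(rng.integers(0, 2**31 - 1)),
    }


def _smooth_warp(params: PhantomParams, seed: int) -> np.ndarray:
    """Smooth random displacement (mm), shape (3, *grid)."""
    if params.warp_amplitude_mm == 0:
        return np.zeros((3, *params.shape))
    rng = np.random.default_rng(seed)
    nc = params.warp_control_points
    coarse = rng.normal(0.0, params.warp_amplitude_mm, size=(3, nc, nc, nc))
    zoom = [n / nc for n in params.shape]
    return np.stack(
        [ndimage.zoom(coarse[a], zoom, order=3, mode="nearest") for a in range(3)]
    )


def make_phantom(
    params: PhantomParams, subject_seed: int, case_id: str | None = None
) -> PhantomCase:
    """Generate one phantom; bit-deterministic given (params, subject_seed)."""
    if min(params.fov_mm) < 150.0:
        raise ImagingError(
            f"grid too small: field of view {params.fov_mm} mm cannot contain the "
            "heart-plus-thorax template (needs >= 150 mm per axis)"
        )
    rng = np.random.default_rng(subject_seed)
    tf = _subject_transform(params, rng)

    center = np.asarray(params.fov_mm) / 2.0
    theta = np.deg2rad(tf["rot_z_deg"])
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    amat = rot @ np.diag(tf["scale"])
    ainv = np.linalg.inv(amat)

    grid = np.indices(params.shape, dtype=np.float64)
    world = grid * np.asarray(params.spacing).reshape(3, 1, 1, 1)
    # template coordinate of each voxel: invert the subject affine, then add
    # the smooth random warp (both image and labels sample the same points,
    # so geometry stays consistent between them)
    rel = world - (center + np.asarray(tf["translation"])).reshape(3, 1, 1, 1)
    p = np.einsum("ab,b...->a...", ainv, rel) + center.reshape(3, 1, 1, 1)
    # template anatomy is centered in a 160 mm frame regardless of FOV
    p += (80.0 - center).reshape(3, 1, 1, 1)
    p = p + _smooth_warp(params, tf["warp_seed"])

    labels, body = _template_labels(p)

    means = params.intensity_means
    intensity = np.full(params.shape, _AIR_HU)
    intensity[body] = means["background"]
    for name, code in STRUCTURE_CODES.items():
        if code == 0:
            continue
        intensity[labels == code] = means[name]
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=params.shape)

    cid = case_id if case_id is not None else f"phantom_{subject_seed}"
    vol = Volume(intensity.astype(np.float32), params.spacing)
    lab = LabelMap(labels, params.spacing)
    return PhantomCase(cid, vol, lab, tf)


def make_cohort(
    params: PhantomParams, n_atlases: int, n_targets: int, master_seed: int
) -> tuple[list[PhantomCase], list[PhantomCase]]:
    """Deterministic atlas library + unlabeled-target cohort.

    Per-subject seeds are spawned from ``master_seed`` via a SeedSequence, so
    cohorts are stable across runs and different master seeds give different
    subjects.
    """
    if n_atlases < 1 or n_targets < 0:
        raise ImagingError("need n_atlases >= 1 and n_targets >= 0")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_atlases + n_targets)
    seeds = [int(c.generate_state(1)[0]) for c in children]
    atlases = [
        make_phantom(params, seeds[i], case_id=f"atlas_{i:03d}") for i in range(n_atlases)
    ]
    targets = [
        make_phantom(params, seeds[n_atlases + j], case_id=f"target_{j:03d}")
        for j in range(n_targets)
    ]
    return atlases, targets


def make_synthetic_weak_label(label: LabelMap, erosion_mm: float = SWL_EROSION_MM) -> LabelMap:
    """Degrade a label the way the synthetic weak-label control is built.

    Each of the four chambers is replaced by its ``erosion_mm`` Euclidean
    erosion, and the myocardium is expanded to cover the ring between the
    original and the eroded LV cavity (so the shrunken LV sits inside an
    inflated LVM).  Auxiliary codes and the image are untouched.
    """
    C = label.code_table
    for s in MAIN_STRUCTURES:
        if s not in C:
            raise ImagingError(f"label lacks required structure {s}")
    data = label.data.copy()
    orig = {s: label.mask(s) for s in MAIN_STRUCTURES}
    eroded = {}
    for s in ("LV", "RV", "LA", "RA"):
        eroded[s] = erode(orig[s], erosion_mm, label.spacing)
        if orig[s].any() and not eroded[s].any():
            warnings.warn(
                f"{s} vanished entirely under {erosion_mm} mm erosion; kept empty",
                stacklevel=2,
            )
        data[orig[s]] = 0
    lvm_new = orig["LVM"] | (orig["LV"] & ~eroded["LV"])
    data[lvm_new] = C["LVM"]
    for s in ("LV", "RV", "LA", "RA"):
        data[eroded[s]] = C[s]
    return LabelMap(data, label.spacing, label.origin, dict(C))


def corrupt_label(label: LabelMap, severity: float, seed: int = 0) -> LabelMap:
    """Graded label corruption with true Dice non-increasing in severity.

    Each chamber is eroded by ``3·severity`` mm (mirroring the weak-label
    recipe, which erodes chambers but not the myocardium), and every main
    structure loses voxels within 4 mm of its boundary at a rate
    ``0.45·severity``.  The per-voxel random draws depend only on ``seed``,
    so corruptions at increasing severity are nested — the corrupted
    structure at severity s₁ ≥ s₂ is a subset of the one at s₂, which makes
    Dice against ground truth monotone by construction.  Severity 0 is the
    identity.

    The mapping is deliberately bounded below the synthetic weak-label
    degradation (5 mm chamber erosion plus myocardium inflation): graded
    corruption emulates the organic quality spread of computer-generated
    labels, whose worst members are still milder than the deliberate
    negative control.
    """
    if not 0.0 <= severity <= 1.0:
        raise ImagingError(f"severity must be in [0, 1], got {severity}")
    if severity == 0.0:
        return LabelMap(label.data.copy(), label.spacing, label.origin, dict(label.code_table))
    rng = np.random.default_rng(seed)
    u = rng.random(label.shape)  # severity-independent draws -> nested removals
    data = label.data.copy()
    for s in MAIN_STRUCTURES:
        m = label.mask(s)
        if not m.any():
            continue
        kept = m.copy() if s == "LVM" else erode(m, 3.0 * severity, label.spacing)
        near_boundary = m & ~erode(m, 4.0, label.spacing)
        kept &= ~(near_boundary & (u < 0.45 * severity))
        data[m & ~kept] = 0
    return LabelMap(data, label.spacing, label.origin, dict(label.code_table))


__all__ = [
    "PhantomParams",
    "PhantomCase",
    "make_phantom",
    "make_cohort",
    "make_synthetic_weak_label",
    "corrupt_label",
    "SWL_EROSION_MM",
]
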