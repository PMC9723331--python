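"""Multi-atlas segmentation: atlas selection, deformable registration,
label propagation, and consensus fusion.

The computer-label generator segments an unlabeled target by (1) picking the
k most structurally similar atlases from a labeled library, (2) deformably
registering each atlas image to the target, (3) warping each atlas label map
through the recovered transform, and (4) fusing the warped labels by
per-voxel majority vote with a fixed structure-priority tie-break.

Registration is an in-repo demons-style multiresolution registrar behind a
narrow interface (``register_deformable``), so alternative engines can be
plugged in without touching the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .bbox import BBoxConfig, crop, detect_bounding_box, uncrop
from .core import (
    DisplacementField,
    GridMismatchError,
    ImagingError,
    LABEL_PRIORITY,
    LabelMap,
    Volume,
    warp,
)


@dataclass
class Atlas:
    """A labeled reference subject: image plus expert-grade label map."""

    atlas_id: str
    volume: Volume
    label: LabelMap


@dataclass
class AtlasLibrary:
    atlases: list[Atlas]

    def __post_init__(self):
        ids = [a.atlas_id for a in self.atlases]
        if len(set(ids)) != len(ids):
            raise ImagingError("atlas ids must be unique")
        self._bbox_cache: dict[str, object] = {}

    def __len__(self):
        return len(self.atlases)

    def __iter__(self):
        return iter(self.atlases)

    def get(self, atlas_id: str) -> Atlas:
        for a in self.atlases:
            if a.atlas_id == atlas_id:
                return a
        raise KeyError(atlas_id)

    def bbox(self, atlas_id: str, config: BBoxConfig | None = None):
        if atlas_id not in self._bbox_cache:
            self._bbox_cache[atlas_id] = detect_bounding_box(
                self.get(atlas_id).volume, config
            )
        return self._bbox_cache[atlas_id]


@dataclass
class RegistrationConfig:
    """Free parameters of the demons-style deformable registrar."""

    downsample_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (60, 40, 20)
    sigma_fluid_mm: float = 4.0  # Gaussian smoothing of each update field
    sigma_diffusion_mm: float = 2.0  # Gaussian smoothing of the total field
    metric: str = "ssd"  # "ssd" | "lcc"
    step_size: float = 1.0
    tolerance: float = 1e-6  # convergence tolerance on metric change

    def __post_init__(self):
        if self.sigma_fluid_mm < 0 or self.sigma_diffusion_mm < 0:
            raise ImagingError("smoothing sigmas must be >= 0")
        if len(self.downsample_factors) < 1:
            raise ImagingError("need at least one pyramid level")
        if len(self.iterations) != len(self.downsample_factors):
            raise ImagingError("iterations must match pyramid levels")
        if self.metric not in ("ssd", "lcc"):
            raise ImagingError(f"unknown metric {self.metric!r}")


def resample_to(image, reference, mode: str):
    """Resample onto the reference grid by world coordinates (no deformation)."""
    f = DisplacementField.zero(reference.shape, reference.spacing, reference.origin)
    return warp(image, f, mode=mode)


def _robust_normalize(data: np.ndarray) -> np.ndarray:
    """Percentile-based clip + rescale to [0, 1].

    Percentile (rather than fixed-window) normalization makes downstream
    similarity ranking invariant to global affine intensity rescaling.
    """
    lo, hi = np.percentile(data, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(data, dtype=np.float64)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def _selection_image(volume: Volume, box, downsample: int) -> np.ndarray:
    cropped = crop(volume, box)
    norm = _robust_normalize(np.asarray(cropped.data, dtype=np.float64))
    if downsample > 1:
        norm = ndimage.zoom(norm, 1.0 / downsample, order=1)
    return norm


def structural_similarity_score(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local structural similarity (luminance/contrast/structure product)."""
    if a.shape != b.shape:
        b = ndimage.zoom(b, [sa / sb for sa, sb in zip(a.shape, b.shape)], order=1)
        b = b[tuple(slice(0, s) for s in a.shape)]
        if b.shape != a.shape:
            pad = [(0, sa - sb) for sa, sb in zip(a.shape, b.shape)]
            b = np.pad(b, pad, mode="edge")
    win = min(7, *(s - (s + 1) % 2 for s in a.shape))  # largest odd size <= min dim
    return float(structural_similarity(a, b, data_range=1.0, win_size=win))


def select_atlases(
    target: Volume,
    library: AtlasLibrary,
    k: int,
    bbox_config: BBoxConfig | None = None,
    downsample: int = 4,
) -> list[tuple[str, float]]:
    """Rank atlases by structural similarity to the target; return top k.

    Similarity is computed on bounding-box-cropped, robustly normalized,
    ``downsample``-times downsampled images resampled to a common grid (a
    fast selection strategy).  Ties break by ascending atlas id.
    """
    if k > len(library):
        raise ImagingError(f"k={k} exceeds library size {len(library)}")
    tbox = detect_bounding_box(target, bbox_config)
    timg = _selection_image(target, tbox, downsample)
    scored = []
    for atlas in library:
        abox = library.bbox(atlas.atlas_id, bbox_config)
        aimg = _selection_image(atlas.volume, abox, downsample)
        scored.append((atlas.atlas_id, structural_similarity_score(timg, aimg)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


# ---------------------------------------------------------------------------
# Demons-style deformable registration


def _metric_value(fixed, warped, spacing, metric: str) -> float:
    """Similarity (higher is better)."""
    if metric == "ssd":
        return -float(np.mean((fixed - warped) ** 2))
    # local correlation coefficient with Gaussian windows (sigma 3 voxels)
    s = 3.0
    mf = ndimage.gaussian_filter(fixed, s)
    mw = ndimage.gaussian_filter(warped, s)
    cov = ndimage.gaussian_filter(fixed * warped, s) - mf * mw
    vf = ndimage.gaussian_filter(fixed**2, s) - mf**2
    vw = ndimage.gaussian_filter(warped**2, s) - mw**2
    cc = cov / np.sqrt(np.maximum(vf * vw, 1e-10))
    return float(np.mean(cc))


def _downsample_volume(data: np.ndarray, spacing, factor: int):
    if factor == 1:
        return data.copy(), tuple(spacing)
    sm = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    out = ndimage.zoom(sm, 1.0 / factor, order=1)
    new_spacing = tuple(
        s * n / m for s, n, m in zip(spacing, data.shape, out.shape)
    )
    return out, new_spacing


def _warp_level(moving: np.ndarray, disp_mm: np.ndarray, spacing) -> np.ndarray:
    idx = np.indices(moving.shape, dtype=np.float64)
    sp = np.asarray(spacing).reshape(3, 1, 1, 1)
    coords = idx + disp_mm / sp
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")


def register_deformable(
    fixed: Volume, moving: Volume, config: RegistrationConfig | None = None
) -> tuple[DisplacementField, float]:
    """Coarse-to-fine demons registration of ``moving`` into ``fixed``'s grid.

    Per pyramid level, a force field proportional to the intensity difference
    times the warped-image gradient is smoothed by ``sigma_fluid_mm``,
    composed additively into the total field, which is then smoothed by
    ``sigma_diffusion_mm``.  Iteration stops at the level's budget or when the
    metric change drops below tolerance.  The best-seen field (including the
    identity) is returned, so the returned field never degrades the metric
    relative to no registration.
    """
    config = config or RegistrationConfig()
    if not fixed.same_grid(moving):
        moving = resample_to(moving, fixed, mode="linear")
    f_full = _robust_normalize(np.asarray(fixed.data, dtype=np.float64))
    m_full = _robust_normalize(np.asarray(moving.data, dtype=np.float64))
    if f_full.std() < 1e-12 or m_full.std() < 1e-12:
        warnings.warn("degenerate (constant) image; returning zero field", stacklevel=2)
        zero = DisplacementField.zero(fixed.shape, fixed.spacing, fixed.origin)
        return zero, _metric_value(f_full, m_full, fixed.spacing, config.metric)

    disp = None  # (3, *level_shape) in mm
    prev_shape = None
    for factor, n_iter in zip(config.downsample_factors, config.iterations):
        f_lvl, sp_lvl = _downsample_volume(f_full, fixed.spacing, factor)
        m_lvl, _ = _downsample_volume(m_full, fixed.spacing, factor)
        if disp is None:
            disp = np.zeros((3, *f_lvl.shape))
        else:
            zoom = [n / p for n, p in zip(f_lvl.shape, prev_shape)]
            disp = np.stack([ndimage.zoom(disp[a], zoom, order=1) for a in range(3)])
        prev_shape = f_lvl.shape
        sp_arr = np.asarray(sp_lvl)
        sig_fluid = config.sigma_fluid_mm / sp_arr
        sig_diff = config.sigma_diffusion_mm / sp_arr
        alpha2 = (1.0 / float(np.mean(sp_arr))) ** 2

        warped = _warp_level(m_lvl, disp, sp_lvl)
        best_metric = _metric_value(f_lvl, warped, sp_lvl, config.metric)
        best_disp = disp.copy()
        last_metric = best_metric
        for _ in range(n_iter):
            diff = f_lvl - warped
            grad = np.stack(np.gradient(warped, *sp_lvl))
            denom = (grad**2).sum(axis=0) + alpha2 * diff**2
            ratio = np.divide(
                config.step_size * diff, denom,
                out=np.zeros_like(diff), where=denom > 1e-12,
            )
            upd = ratio * grad
            for a in range(3):
                if sig_fluid[a] > 0:
                    upd[a] = ndimage.gaussian_filter(upd[a], sig_fluid[a])
            disp = disp + upd
            for a in range(3):
                if sig_diff[a] > 0:
                    disp[a] = ndimage.gaussian_filter(disp[a], sig_diff[a])
            warped = _warp_level(m_lvl, disp, sp_lvl)
            metric = _metric_value(f_lvl, warped, sp_lvl, config.metric)
            if metric > best_metric:
                best_metric = metric
                best_disp = disp.copy()
            if abs(metric - last_metric) < config.tolerance:
                break
            last_metric = metric
        disp = best_disp

    if prev_shape != fixed.shape:
        zoom = [n / p for n, p in zip(fixed.shape, prev_shape)]
        disp = np.stack([ndimage.zoom(disp[a], zoom, order=1) for a in range(3)])
    field = DisplacementField(disp, fixed.spacing, fixed.origin)
    warped_final = warp(moving, field, mode="linear")
    final_metric = _metric_value(
        f_full,
        _robust_normalize(np.asarray(warped_final.data, dtype=np.float64)),
        fixed.spacing,
        config.metric,
    )
    identity_metric = _metric_value(f_full, m_full, fixed.spacing, config.metric)
    if final_metric < identity_metric:
        field = DisplacementField.zero(fixed.shape, fixed.spacing, fixed.origin)
        final_metric = identity_metric
    return field, final_metric


def propagate_label(atlas: Atlas, field: DisplacementField) -> LabelMap:
    """Warp the atlas's label map into the target grid (nearest neighbor)."""
    return warp(atlas.label, field, mode="nearest")


def _priority_codes(code_table: dict[str, int]) -> list[int]:
    """Codes in tie-break order: main structures by priority, then auxiliary
    codes ascending, then background."""
    ordered = [code_table[s] for s in LABEL_PRIORITY if s in code_table]
    aux = sorted(
        c
        for name, c in code_table.items()
        if c != 0 and c not in ordered
    )
    return ordered + aux + [0]


def fuse_labels(warped: list[LabelMap]) -> LabelMap:
    """Per-voxel majority vote; background votes count; ties break by the
    fixed structure priority (then ascending auxiliary code, then background)."""
    if len(warped) == 0:
        raise ImagingError("need at least one label map to fuse")
    first = warped[0]
    for w in warped[1:]:
        if not first.same_grid(w):
            raise GridMismatchError("fusion inputs must share one grid")
    if len(warped) == 1:
        return LabelMap(
            first.data.copy(), first.spacing, first.origin, dict(first.code_table)
        )
    code_table = dict(first.code_table)
    stack = np.stack([w.data for w in warped])
    codes = _priority_codes(code_table)
    counts = np.stack([(stack == c).sum(axis=0) for c in codes])
    winner = np.argmax(counts, axis=0)  # first max in priority order
    out = np.asarray(codes, dtype=first.data.dtype)[winner]
    return LabelMap(out, first.spacing, first.origin, code_table)


@dataclass
class CLGConfig:
    """Configuration bundle for the full computer-label generator."""

    k: int = 9
    bbox: BBoxConfig = field(default_factory=BBoxConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    selection_downsample: int = 4
    refine: bool = True


def run_clg(
    target: Volume,
    library: AtlasLibrary,
    config: CLGConfig | None = None,
    walker_config=None,
) -> LabelMap:
    """Full computer-label generator for one target volume.

    Bounding box -> atlas selection -> per-atlas deformable registration and
    nearest-neighbor label propagation -> majority fusion -> (optionally)
    multi-pass random-walker corrective refinement and morphological
    post-processing.  Output is a full-grid label map carrying the five main
    structure codes (background outside the box).
    """
    from .corrective import RandomWalkerConfig, postprocess, refine_multipass

    config = config or CLGConfig()
    k = min(config.k, len(library))
    box = detect_bounding_box(target, config.bbox)
    tcrop = crop(target, box)
    ranked = select_atlases(
        target, library, k, config.bbox, config.selection_downsample
    )
    warped = []
    for atlas_id, _score in ranked:
        atlas = library.get(atlas_id)
        moving = resample_to(atlas.volume, tcrop, mode="linear")
        fld, _m = register_deformable(tcrop, moving, config.registration)
        warped.append(warp(atlas.label, fld, mode="nearest"))
    fused = fuse_labels(warped)
    if config.refine:
        wc = walker_config or RandomWalkerConfig()
        refined = refine_multipass(tcrop, fused, wc)
        refined = postprocess(refined)
    else:
        refined = fused
    full = uncrop(refined, box, target.shape)
    return full


__all__ = [
    "Atlas",
    "AtlasLibrary",
    "RegistrationConfig",
    "CLGConfig",
    "resample_to",
    "select_atlases",
    "structural_similarity_score",
    "register_deformable",
    "propagate_label",
    "fuse_labels",
    "run_clg",
]
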