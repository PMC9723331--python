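"""Corrective segmentation: seeded random-walker refinement in multiple passes.

After label fusion, the consensus cardiac labels are refined against the
actual target intensities.  High-confidence seeds are extracted for the
cardiac structures (erosions of the fused labels) and for the surrounding
non-cardiac tissues (lung, chest wall, liver, spine, descending aorta, from
intensity heuristics), and a seeded random walker is run on the
intensity-weighted voxel graph.  The walker solves the combinatorial
Dirichlet problem: for each code, the probability at unseeded voxels is the
harmonic function of the weighted graph Laplacian with boundary values 1 on
that code's seeds and 0 on the others; the argmax assigns the label.

The walker runs in a multiple-pass fashion: one global pass with all codes
carves non-cardiac tissue off the fused heart, then one binary pass per main
structure (in priority order) sharpens that structure's boundary.  Auxiliary
tissue codes are internal scaffolding and are dropped from the final output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .core import (
    AUX_STRUCTURES,
    ImagingError,
    LABEL_PRIORITY,
    LabelMap,
    MAIN_STRUCTURES,
    STRUCTURE_CODES,
    Volume,
    closing,
    dilate,
    erode,
    largest_component,
)


@dataclass
class SeedConfig:
    """Intensity thresholds (HU-like) for non-cardiac seed extraction."""

    cardiac_erosion_mm: float = 3.0
    lung_max: float = -400.0
    bone_min: float = 550.0
    bright_range: tuple[float, float] = (250.0, 550.0)  # descending aorta
    soft_range: tuple[float, float] = (-60.0, 48.0)  # chest wall / mediastinum
    liver_range: tuple[float, float] = (48.0, 140.0)
    heart_margin_mm: float = 8.0  # exclusion zone around the fused heart
    aux_erosion_mm: float = 2.0  # confidence erosion of thresholded masks


@dataclass
class RandomWalkerConfig:
    """Edge weights w_ij = exp(-beta (I_i - I_j)^2) on [0,1]-normalized
    intensity, 6-connectivity."""

    beta: float = 90.0
    tolerance: float = 1e-8
    max_passes: int = 6  # 1 global + one per main structure
    direct_solver_max_unknowns: int = 40000
    #: soft-tissue window (HU-like) mapped to [0,1] before weighting; a
    #: narrow window keeps beta sensitive to the myocardium/soft-tissue
    #: contrast instead of being dominated by the lung-to-bone range
    clip_window: tuple[float, float] = (-100.0, 250.0)
    seeds: SeedConfig = field(default_factory=SeedConfig)

    def __post_init__(self):
        if self.beta < 0:
            raise ImagingError("beta must be >= 0")
        if self.tolerance <= 0:
            raise ImagingError("tolerance must be > 0")


def _normalize(data: np.ndarray, window=(-100.0, 250.0)) -> np.ndarray:
    lo, hi = window
    return (np.clip(np.asarray(data, np.float64), lo, hi) - lo) / (hi - lo)


def extract_seeds(
    volume: Volume, fused: LabelMap, config: SeedConfig | None = None
) -> LabelMap:
    """High-confidence seed voxels per structure.

    Cardiac seeds are erosions of the fused labels; auxiliary seeds come from
    intensity thresholds applied outside a margin around the fused heart.
    Every seed voxel is a strong claim — the walker never re-labels seeds —
    so all masks are eroded before use.
    """
    config = config or SeedConfig()
    C = fused.code_table
    data = np.asarray(volume.data, dtype=np.float64)
    seeds = np.zeros(fused.shape, dtype=np.int16)

    cardiac = np.isin(fused.data, [C[s] for s in MAIN_STRUCTURES if s in C])
    for s in MAIN_STRUCTURES:
        if s not in C:
            continue
        m = erode(fused.mask(s), config.cardiac_erosion_mm, fused.spacing)
        if not m.any():
            warnings.warn(
                f"no seeds for {s} after erosion; structure will keep its fused extent",
                stacklevel=2,
            )
            m = fused.mask(s)  # fall back to the raw fused mask
        seeds[m] = C[s]

    outside = ~dilate(cardiac, config.heart_margin_mm, fused.spacing)
    sp = fused.spacing

    def confident(mask):
        return erode(mask & outside, config.aux_erosion_mm, sp)

    lung = confident(data < config.lung_max)
    if not lung.any():
        warnings.warn("no lung seeds (no sub-threshold voxels)", stacklevel=2)
    spine = confident(data > config.bone_min)
    blo, bhi = config.bright_range
    aorta = confident((data > blo) & (data < bhi))
    if aorta.any():
        aorta = largest_component(aorta)  # the posterior tube
    llo, lhi = config.liver_range
    liver = confident((data > llo) & (data < lhi))
    if liver.any():
        liver = largest_component(liver)
    slo, shi = config.soft_range
    soft = confident((data > slo) & (data < shi)) & ~liver

    for mask, name in (
        (lung, "lung"),
        (soft, "chest_wall"),
        (liver, "liver"),
        (spine, "spine"),
        (aorta, "desc_aorta"),
    ):
        code = C.get(name, STRUCTURE_CODES[name])
        m = mask & (seeds == 0)
        seeds[m] = code

    table = dict(C)
    for name in AUX_STRUCTURES:
        table.setdefault(name, STRUCTURE_CODES[name])
    return LabelMap(seeds, fused.spacing, fused.origin, table)


# ---------------------------------------------------------------------------
# Random walker (graph Laplacian Dirichlet solve)


def _laplacian(norm: np.ndarray, beta: float, domain: np.ndarray):
    """Sparse graph Laplacian over the True voxels of ``domain`` (6-conn)."""
    n = int(domain.sum())
    index = -np.ones(domain.shape, dtype=np.int64)
    index[domain] = np.arange(n)
    rows, cols, weights = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        valid = domain[sl_a] & domain[sl_b]
        d = norm[sl_a][valid] - norm[sl_b][valid]
        w = np.exp(-beta * d**2) + 1e-6
        rows.append(index[sl_a][valid])
        cols.append(index[sl_b][valid])
        weights.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    w_mat = sparse.coo_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    deg = np.asarray(w_mat.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - w_mat
    return lap.tocsr(), index


def random_walker(
    volume: Volume,
    seeds: LabelMap,
    config: RandomWalkerConfig | None = None,
    domain: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int], LabelMap]:
    """Seeded random-walker probabilities and hard labels.

    Returns ``(probs, codes, label)`` where ``probs[c]`` is the probability
    volume of ``codes[c]``; probabilities across codes sum to 1 (to solver
    tolerance) and seeded voxels keep their seed code.  Graph components
    without any seed are assigned background with a warning.
    """
    config = config or RandomWalkerConfig()
    if not volume.same_grid(seeds):
        raise ImagingError("volume and seeds must share one grid")
    if domain is None:
        domain = np.ones(volume.shape, dtype=bool)
    seed_data = np.where(domain, seeds.data, 0)
    codes = sorted(int(c) for c in np.unique(seed_data) if c != 0)
    if len(codes) < 2:
        raise ImagingError("random walker needs >= 2 seeded codes")

    norm = _normalize(volume.data, config.clip_window)
    lap, index = _laplacian(norm, config.beta, domain)
    n = lap.shape[0]
    flat_seed = seed_data[domain]
    seeded = flat_seed > 0
    uns = ~seeded
    n_u = int(uns.sum())

    probs_flat = np.zeros((len(codes), n))
    for ci, c in enumerate(codes):
        probs_flat[ci, flat_seed == c] = 1.0
    if n_u > 0:
        lap_uu = lap[uns][:, uns].tocsc()
        lap_us = lap[uns][:, seeded].tocsr()
        rhs = np.stack(
            [-lap_us @ (flat_seed[seeded] == c).astype(np.float64) for c in codes],
            axis=1,
        )
        # isolated unseeded components have an all-zero row block and a
        # singular subsystem; detect them via graph connectivity
        n_comp, comp = sparse.csgraph.connected_components(lap_uu != 0, directed=False)
        reach = np.zeros(n_u, dtype=bool)
        seeded_neighbors = np.asarray((lap_us != 0).sum(axis=1)).ravel() > 0
        for k in range(n_comp):
            if seeded_neighbors[comp == k].any():
                reach[comp == k] = True
        if not reach.all():
            warnings.warn(
                "graph component(s) with no seeds assigned to background",
                stacklevel=2,
            )
        if reach.any():
            sub = np.where(reach)[0]
            a_mat = lap_uu[sub][:, sub].tocsc()
            b_mat = rhs[sub]
            if len(sub) <= config.direct_solver_max_unknowns:
                lu = splu(a_mat)
                x = np.column_stack([lu.solve(b_mat[:, j]) for j in range(b_mat.shape[1])])
            else:
                m_inv = sparse.diags(1.0 / a_mat.diagonal())
                cols_x = []
                for j in range(b_mat.shape[1]):
                    xj, info = cg(
                        a_mat, b_mat[:, j], rtol=config.tolerance, maxiter=2000, M=m_inv
                    )
                    if info != 0:
                        warnings.warn(f"walker CG did not fully converge (info={info})")
                    cols_x.append(xj)
                x = np.column_stack(cols_x)
            uns_idx = np.where(uns)[0]
            for ci in range(len(codes)):
                probs_flat[ci, uns_idx[sub]] = np.clip(x[:, ci], 0.0, 1.0)

    probs = np.zeros((len(codes), *volume.shape))
    for ci in range(len(codes)):
        probs[ci][domain] = probs_flat[ci]
    arg = np.argmax(probs_flat, axis=0)
    labels_flat = np.asarray(codes, dtype=np.int16)[arg]
    labels_flat[probs_flat.sum(axis=0) < 0.5] = 0  # unreached components
    labels_flat[seeded] = flat_seed[seeded]
    out = np.zeros(volume.shape, dtype=np.int16)
    out[domain] = labels_flat
    label = LabelMap(out, volume.spacing, volume.origin, dict(seeds.code_table))
    return probs, codes, label


# ---------------------------------------------------------------------------
# Multi-pass refinement


def refine_multipass(
    volume: Volume, fused: LabelMap, config: RandomWalkerConfig | None = None
) -> LabelMap:
    """Global walker pass + per-structure binary passes in priority order.

    Pass 1 runs the walker with all cardiac and auxiliary seeds, carving
    non-cardiac tissue off the fused heart.  Each subsequent pass re-solves a
    binary problem (one structure's seeds vs. everything else) restricted to
    that structure's neighborhood and updates only that structure's voxels.
    With ``max_passes = 0`` the fused label is returned with auxiliary codes
    removed.
    """
    config = config or RandomWalkerConfig()
    C = fused.code_table
    main_codes = [C[s] for s in MAIN_STRUCTURES if s in C]

    def strip_aux(data):
        return np.where(np.isin(data, main_codes), data, 0).astype(np.int16)

    if config.max_passes == 0:
        return LabelMap(strip_aux(fused.data), fused.spacing, fused.origin, dict(C))

    seeds = extract_seeds(volume, fused, config.seeds)
    probs, codes, label = random_walker(volume, seeds, config)
    current = label.data.copy()
    global_probs = {c: probs[i] for i, c in enumerate(codes)}

    n_structure_passes = max(0, config.max_passes - 1)
    for s in LABEL_PRIORITY[:n_structure_passes]:
        code = C[s]
        m = current == code
        if not m.any():
            continue
        region = dilate(m, 10.0, volume.spacing)
        idx = np.argwhere(region)
        lo, hi = idx.min(0), idx.max(0) + 1
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        sub_vol = Volume(volume.data[sl], volume.spacing)
        sub_seeds = np.zeros(sub_vol.shape, dtype=np.int16)
        s_seed = erode(m, config.seeds.cardiac_erosion_mm, volume.spacing)
        if not s_seed.any():
            s_seed = m
        # opposing seeds hug the structure: a tight erosion of the current
        # complement keeps the undecided band narrow around the boundary
        other = erode(current != code, 2.0, volume.spacing)
        sub_seeds[s_seed[sl]] = 1
        sub_seeds[other[sl] & (sub_seeds == 0)] = 2
        if not (sub_seeds == 2).any():
            continue
        table = {"fg": 1, "bg": 2}
        p_sub, c_sub, _ = random_walker(
            sub_vol,
            LabelMap(sub_seeds, volume.spacing, code_table=table),
            config,
            domain=region[sl],
        )
        p_s = np.zeros(volume.shape)
        p_s[sl] = p_sub[c_sub.index(1)]
        new_m = (p_s > 0.5) & region
        # don't overwrite earlier-priority (already refined) structures
        earlier = np.isin(
            current, [C[t] for t in LABEL_PRIORITY[: LABEL_PRIORITY.index(s)]]
        )
        gain = new_m & ~m & ~earlier
        lose = m & ~new_m
        current[gain] = code
        if lose.any():
            # voxels leaving the structure take the global pass's runner-up
            stack = np.stack(
                [global_probs[c][lose] for c in codes if c != code]
            )
            alt_codes = np.asarray([c for c in codes if c != code], dtype=np.int16)
            current[lose] = alt_codes[np.argmax(stack, axis=0)]

    return LabelMap(strip_aux(current), fused.spacing, fused.origin, dict(C))


def postprocess(label: LabelMap, closing_mm: float = 2.0) -> LabelMap:
    """Largest-component + morphological closing per main structure.

    Structures are re-assembled in priority order; a later structure cannot
    overwrite an earlier one, so the chambers stay pairwise disjoint.
    """
    C = label.code_table
    out = np.zeros_like(label.data)
    for s in LABEL_PRIORITY:
        if s not in C:
            continue
        m = label.mask(s)
        if not m.any():
            continue
        m = largest_component(m)
        m = closing(m, closing_mm, label.spacing)
        out[m & (out == 0)] = C[s]
    main_codes = [C[s] for s in LABEL_PRIORITY if s in C]
    passthrough = ~np.isin(label.data, main_codes + [0]) & (out == 0)
    out[passthrough] = label.data[passthrough]
    return LabelMap(out, label.spacing, label.origin, dict(C))


__all__ = [
    "SeedConfig",
    "RandomWalkerConfig",
    "extract_seeds",
    "random_walker",
    "refine_multipass",
    "postprocess",
]
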