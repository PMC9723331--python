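"""Segmentation evaluation: Dice, Hausdorff distance, mean surface distance.

Surfaces are boundary voxel sets under 6-connectivity; distances are exact
Euclidean distances between surface voxel centers, in mm, honoring
anisotropic spacing.  The Hausdorff distance is the full maximum (not a
percentile).  Empty masks make HD/MSD undefined; those cases are reported as
NaN and excluded from cohort summaries with a count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    GridMismatchError,
    ImagingError,
    LabelMap,
    MAIN_STRUCTURES,
    surface_voxels,
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|).  Both empty -> 1.0 by convention."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    pts = np.argwhere(surface_voxels(mask)).astype(np.float64)
    return pts * np.asarray(spacing)[None, :]


def _directed_distances(a: np.ndarray, b: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Distances from surface(a) to surface(b) and vice versa, in mm."""
    surf_a = surface_voxels(a)
    surf_b = surface_voxels(b)
    # exact EDT to the other surface, sampled on this surface
    d_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    return d_to_b[surf_a], d_to_a[surf_b]


def _check_pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ImagingError("surface distances are undefined for empty masks")
    return a, b


def hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    a, b = _check_pair(a, b)
    d_ab, d_ba = _directed_distances(a, b, spacing)
    return float(max(d_ab.max(), d_ba.max()))


def mean_surface_distance(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric MSD: the two directed means weighted equally."""
    a, b = _check_pair(a, b)
    d_ab, d_ba = _directed_distances(a, b, spacing)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


@dataclass
class StructureMetrics:
    """Per-case, per-structure Dice / HD (mm) / MSD (mm)."""

    case_id: str
    dice: dict[str, float]
    hd_mm: dict[str, float]
    msd_mm: dict[str, float]


def evaluate_case(
    case_id: str,
    pred: LabelMap,
    truth: LabelMap,
    structures=MAIN_STRUCTURES,
) -> StructureMetrics:
    """All three metrics for each structure of one predicted/reference pair."""
    if not pred.same_grid(truth):
        raise GridMismatchError("prediction and reference are on different grids")
    d, hd, msd = {}, {}, {}
    for s in structures:
        mp, mt = pred.mask(s), truth.mask(s)
        d[s] = dice(mp, mt)
        if mp.any() and mt.any():
            hd[s] = hausdorff(mp, mt, pred.spacing)
            msd[s] = mean_surface_distance(mp, mt, pred.spacing)
        else:
            hd[s] = float("nan")
            msd[s] = float("nan")
    return StructureMetrics(case_id, d, hd, msd)


@dataclass
class CohortSummary:
    """Median / IQR / mean / SD of one metric over a cohort."""

    median: float
    iqr: tuple[float, float]
    mean: float
    sd: float
    n: int
    n_missing: int = 0
    degenerate: bool = False  # n == 1: IQR is not meaningful


def summarize(values) -> CohortSummary:
    """Linear-interpolation (type-7) quantiles; NaNs excluded but counted."""
    values = np.asarray(values, dtype=float)
    missing = int(np.isnan(values).sum())
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ImagingError("cannot summarize an empty value set")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return CohortSummary(
        median=float(med),
        iqr=(float(q1), float(q3)),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n=int(values.size),
        n_missing=missing,
        degenerate=values.size == 1,
    )


def metrics_frame(results: list[StructureMetrics]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s in r.dice:
            rows.append(
                {
                    "case_id": r.case_id,
                    "structure": s,
                    "dice": r.dice[s],
                    "hd_mm": r.hd_mm[s],
                    "msd_mm": r.msd_mm[s],
                }
            )
    return pd.DataFrame(rows)


def write_report(results: list[StructureMetrics], csv_path=None, md_path=None) -> str:
    """Per-structure cohort table (median [IQR], mean±SD) as Markdown.

    Optionally persists the raw per-case rows as CSV and the table as
    Markdown; returns the Markdown text.
    """
    frame = metrics_frame(results)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    lines = [
        "| structure | metric | median [IQR] | mean ± SD | n |",
        "|---|---|---|---|---|",
    ]
    for s in frame["structure"].unique():
        sub = frame[frame["structure"] == s]
        for metric, fmt in (("dice", "{:.3f}"), ("hd_mm", "{:.2f}"), ("msd_mm", "{:.2f}")):
            vals = sub[metric].to_numpy()
            if np.isnan(vals).all():
                continue
            su = summarize(vals)
            lines.append(
                f"| {s} | {metric} | "
                f"{fmt.format(su.median)} [{fmt.format(su.iqr[0])}–{fmt.format(su.iqr[1])}] | "
                f"{fmt.format(su.mean)} ± {fmt.format(su.sd)} | {su.n} |"
            )
    text = "\n".join(lines) + "\n"
    if md_path is not None:
        with io.open(md_path, "w") as fh:
            fh.write(text)
    return text


__all__ = [
    "dice",
    "hausdorff",
    "mean_surface_distance",
    "StructureMetrics",
    "CohortSummary",
    "evaluate_case",
    "summarize",
    "metrics_frame",
    "write_report",
]
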