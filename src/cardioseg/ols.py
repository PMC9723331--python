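"""Reverse-ranking label quality scoring and optimal label selection.

Computer-generated labels come with no ground truth, so their quality is
scored by reversing the registration direction: the target image (moving) is
registered to each of its k most similar atlases (fixed), the computer label
is warped into each atlas space ("reversed target label"), and its Dice
against the atlas's expert reference label is computed.  The per-structure
mean over the k atlases is the reverse-ranking (RR) score; the aggregate is
the unweighted mean over the five main structures.  A cohort ranked by
aggregate RR yields the strong-label (best fraction) or weak-label (worst
fraction) training subsets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bbox import BBoxConfig, crop
from .core import ImagingError, LabelMap, MAIN_STRUCTURES, Volume, warp
from .mas import (
    AtlasLibrary,
    RegistrationConfig,
    register_deformable,
    resample_to,
    select_atlases,
)
from .metrics import dice


@dataclass
class RRScore:
    """Per-structure and aggregate reverse-ranking scores for one case."""

    case_id: str
    per_structure: dict[str, float]
    aggregate: float
    atlas_ids: list[str]

    def as_row(self) -> dict:
        row = {"case_id": self.case_id}
        row.update({f"rr_{s}": self.per_structure[s] for s in MAIN_STRUCTURES})
        row["rr_mean"] = self.aggregate
        row["atlas_ids"] = ";".join(self.atlas_ids)
        return row


def reverse_rank_score(
    target: Volume,
    computer_label: LabelMap,
    library: AtlasLibrary,
    k: int = 9,
    reg_config: RegistrationConfig | None = None,
    bbox_config: BBoxConfig | None = None,
    case_id: str = "",
) -> RRScore:
    """RR score of one computer label against k similarity-selected atlases.

    For each selected atlas the target acts as the moving image and the atlas
    as the fixed image; the computer label is warped (nearest) through the
    recovered field and compared to the atlas reference.  Structures absent
    from the computer label contribute Dice 0 (counted, not skipped), so
    catastrophic failures sink in the ranking.
    """
    if not target.same_grid(computer_label):
        raise ImagingError("computer label must live on the target grid")
    if k > len(library):
        raise ImagingError(f"k={k} exceeds library size {len(library)}")
    ranked = select_atlases(target, library, k, bbox_config)
    per_structure = {s: 0.0 for s in MAIN_STRUCTURES}
    missing = [s for s in MAIN_STRUCTURES if not computer_label.mask(s).any()]
    if missing:
        warnings.warn(
            f"structures absent from computer label: {missing}; scored 0",
            stacklevel=2,
        )
    for atlas_id, _score in ranked:
        atlas = library.get(atlas_id)
        abox = library.bbox(atlas_id, bbox_config)
        acrop = crop(atlas.volume, abox)
        moving = resample_to(target, acrop, mode="linear")
        fld, _m = register_deformable(acrop, moving, reg_config)
        reversed_label = warp(computer_label, fld, mode="nearest")
        ref = crop(atlas.label, abox)
        for s in MAIN_STRUCTURES:
            if s in missing:
                continue
            per_structure[s] += dice(reversed_label.mask(s), ref.mask(s))
    per_structure = {s: v / k for s, v in per_structure.items()}
    aggregate = float(np.mean([per_structure[s] for s in MAIN_STRUCTURES]))
    return RRScore(case_id, per_structure, aggregate, [a for a, _ in ranked])


@dataclass
class SelectionResult:
    """Ranked cohort and the selected best/worst subset."""

    ranked: list[tuple[str, float]]  # (case_id, aggregate), descending
    selected: list[str]
    mode: str
    fraction: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def rank_and_select(
    scores: list[RRScore], fraction: float, mode: str = "best"
) -> SelectionResult:
    """Sort by aggregate RR (descending, ties by ascending case id) and keep
    the best (head) or worst (tail) ``round(fraction * n)`` cases."""
    if not scores:
        raise ImagingError("no scores to rank")
    if not 0.0 < fraction <= 1.0:
        raise ImagingError(f"fraction must be in (0, 1], got {fraction}")
    if mode not in ("best", "worst"):
        raise ImagingError(f"mode must be 'best' or 'worst', got {mode!r}")
    ranked = sorted(
        ((s.case_id, s.aggregate) for s in scores), key=lambda t: (-t[1], t[0])
    )
    n_sel = _round_half_up(fraction * len(ranked))
    ids = [cid for cid, _ in ranked]
    selected = ids[:n_sel] if mode == "best" else ids[len(ids) - n_sel :]
    return SelectionResult(ranked, selected, mode, fraction)


def scores_frame(scores: list[RRScore]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in scores])


__all__ = [
    "RRScore",
    "SelectionResult",
    "reverse_rank_score",
    "rank_and_select",
    "scores_frame",
]
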