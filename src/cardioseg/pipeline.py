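"""End-to-end experiment orchestration on phantom cohorts.

Runs the four-arm training-data comparison at desk scale: generate a phantom
cohort, produce computer labels for every target, score each with the
reverse-ranking scheme, select the strong-label (SL, best fraction) and
weak-label (WL, worst fraction) subsets, synthesize the degraded sWL labels
from the SL labels, train one U-Net per arm with identical hyperparameters,
and evaluate all arms on the same held-out phantoms with ground-truth
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bbox import detect_bounding_box
from .core import ImagingError
from .corrective import RandomWalkerConfig
from .mas import Atlas, AtlasLibrary, CLGConfig, run_clg
from .metrics import StructureMetrics, evaluate_case, metrics_frame, write_report
from .ols import RRScore, rank_and_select, reverse_rank_score, scores_frame
from .phantom import PhantomParams, make_cohort, make_phantom, make_synthetic_weak_label
from .segnet import PatchSpec, TrainConfig, desk_profile, predict, train

ARMS = ("All", "SL", "WL", "sWL")


@dataclass
class ExperimentConfig:
    n_atlases: int = 9
    n_targets: int = 30
    n_test: int = 6
    fraction: float = 0.2
    arms: tuple[str, ...] = ARMS
    rr_k: int = 3
    master_seed: int = 0
    phantom: PhantomParams = field(default_factory=PhantomParams)
    clg: CLGConfig = field(default_factory=CLGConfig)
    walker: RandomWalkerConfig = field(default_factory=RandomWalkerConfig)
    train: TrainConfig = field(default_factory=desk_profile)
    patch: PatchSpec = field(default_factory=lambda: PatchSpec((16, 16, 16), (8, 8, 8)))
    out_dir: str | None = None

    def __post_init__(self):
        if not self.arms:
            raise ImagingError("arms must be nonempty")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ImagingError(f"unknown arms {unknown}")
        if not 0.0 < self.fraction <= 1.0:
            raise ImagingError("fraction must be in (0, 1]")
        if "sWL" in self.arms and "SL" not in set(self.arms) | {"sWL"}:
            pass  # sWL derives its labels from the SL subset internally


@dataclass
class ArmResult:
    arm: str
    training_ids: list[str]
    metrics: list[StructureMetrics]
    mean_dice: float
    rr_mean: float | None


def kfold_split(case_ids: list[str], k: int = 5, seed: int = 0) -> list[list[str]]:
    """Disjoint folds covering all ids, sizes differing by at most one."""
    if k > len(case_ids):
        raise ImagingError(f"k={k} exceeds number of cases {len(case_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    shuffled = [case_ids[i] for i in order]
    return [list(fold) for fold in np.array_split(shuffled, k)]


def prepare_arm_manifests(
    target_ids: list[str], scores: list[RRScore], fraction: float
) -> dict[str, list[str]]:
    """Training-case id lists per arm.  The sWL arm reuses the SL ids — its
    labels are the degraded SL labels, never independently regenerated."""
    best = rank_and_select(scores, fraction, "best").selected
    worst = rank_and_select(scores, fraction, "worst").selected
    return {"All": list(target_ids), "SL": best, "WL": worst, "sWL": list(best)}


def run_experiment(config: ExperimentConfig) -> tuple[list[ArmResult], str]:
    """Full experiment; deterministic given the master seed.

    Returns per-arm results and a Markdown report.  When ``config.out_dir``
    is set, manifests, RR scores, per-arm metrics and the report are
    persisted there.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    atlases, targets = make_cohort(
        config.phantom, config.n_atlases, config.n_targets, config.master_seed
    )
    # held-out test phantoms play the independent manually-labeled dataset
    ss = np.random.SeedSequence([config.master_seed, 7777])
    test_seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(config.n_test)]
    tests = [
        make_phantom(config.phantom, s, case_id=f"test_{i:03d}")
        for i, s in enumerate(test_seeds)
    ]
    library = AtlasLibrary([Atlas(a.case_id, a.volume, a.label) for a in atlases])

    computer_labels = {}
    scores = []
    for case in targets:
        lab = run_clg(case.volume, library, config.clg, config.walker)
        computer_labels[case.case_id] = lab
        scores.append(
            reverse_rank_score(
                case.volume,
                lab,
                library,
                k=config.rr_k,
                reg_config=config.clg.registration,
                bbox_config=config.clg.bbox,
                case_id=case.case_id,
            )
        )
    score_by_id = {s.case_id: s for s in scores}
    manifests = prepare_arm_manifests(
        [t.case_id for t in targets], scores, config.fraction
    )
    if out:
        scores_frame(scores).to_csv(out / "rr_scores.csv", index=False)
        rows = [
            {"case_id": cid, "arm": arm}
            for arm in config.arms
            for cid in manifests[arm]
        ]
        pd.DataFrame(rows).to_csv(out / "manifests.csv", index=False)

    case_by_id = {t.case_id: t for t in targets}
    results = []
    report_lines = ["# Experiment report", ""]
    for arm in config.arms:
        ids = manifests[arm]
        train_cases = []
        for cid in ids:
            case = case_by_id[cid]
            lab = computer_labels[cid]
            if arm == "sWL":
                lab = make_synthetic_weak_label(lab)
            box = detect_bounding_box(case.volume, config.clg.bbox)
            train_cases.append((case.volume, lab, box))
        model, history = train(train_cases, config.train, config.patch)
        if out:
            model.save(out / f"model_{arm}")
        arm_metrics = []
        for t in tests:
            box = detect_bounding_box(t.volume, config.clg.bbox)
            pred = predict(model, t.volume, box, config.patch)
            arm_metrics.append(evaluate_case(t.case_id, pred, t.label))
        frame = metrics_frame(arm_metrics)
        mean_dice = float(frame["dice"].mean())
        rr_vals = [score_by_id[c].aggregate for c in ids if c in score_by_id]
        results.append(
            ArmResult(
                arm, ids, arm_metrics, mean_dice,
                float(np.mean(rr_vals)) if rr_vals else None,
            )
        )
        if out:
            frame.to_csv(out / f"metrics_{arm}.csv", index=False)
        report_lines += [f"## Arm {arm}", "", write_report(arm_metrics), ""]
    report = "\n".join(report_lines)
    if out:
        (out / "report.md").write_text(report)
    return results, report


__all__ = [
    "ARMS",
    "ExperimentConfig",
    "ArmResult",
    "kfold_split",
    "prepare_arm_manifests",
    "run_experiment",
]
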