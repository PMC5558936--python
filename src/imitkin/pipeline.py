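"""End-to-end wiring: simulate -> extract -> screen -> select -> evaluate.

Also owns the on-disk trial format: one delimited text file per trial with
columns ``t, x, y, z`` (seconds and mm, header line) plus a ``manifest.csv``
listing participant, group, condition, trial index and error flag.  The same
reader serves any tracker export matching that layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import NestedCVConfig, evaluate_final_features, nested_loocv
from .io import FeatureKey, FeatureMatrix, slice_matrix, write_feature_table
from .kinematics import (
    SegmentationError,
    Trajectory,
    aggregate,
    exclude_errors,
    extract_kinematics,
)
from .screen import joint_condition_run, screen_conditions
from .synthetic import CONDITION_CODES, SyntheticCohort, TrialRecord, simulate_cohort

__all__ = [
    "RunConfig",
    "write_trial_file",
    "read_trial_file",
    "export_cohort",
    "load_trials",
    "extract_cohort_features",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def write_trial_file(traj: Trajectory, path: str | Path) -> None:
    """Write one trial as delimited text: header ``t,x,y,z``, SI units (s, mm)."""
    arr = np.column_stack([traj.t, traj.x, traj.y, traj.z])
    np.savetxt(path, arr, delimiter=",", header="t,x,y,z", comments="", fmt="%.6f")


def read_trial_file(path: str | Path, rate: float | None = None) -> Trajectory:
    """Read a ``t,x,y,z`` delimited trial file.

    The sampling rate is inferred from the written time stamps and the time
    base rebuilt as exactly uniform (text output quantises the stamps).
    """
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    inferred = rate if rate is not None else round(1.0 / np.median(np.diff(arr[:, 0])))
    t = arr[0, 0] + np.arange(len(arr)) / inferred
    return Trajectory(t, arr[:, 1], arr[:, 2], arr[:, 3], float(inferred))


def export_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write every trial plus the manifest CSV; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tr in cohort.trials:
        name = f"{tr.participant}_{tr.condition}_{tr.trial_index:02d}.csv"
        write_trial_file(tr.trajectory, out / name)
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_trials(trial_dir: str | Path) -> list[TrialRecord]:
    """Load a trial directory written by :func:`export_cohort`."""
    trial_dir = Path(trial_dir)
    manifest = pd.read_csv(trial_dir / "manifest.csv", keep_default_na=False)
    records = []
    for _, row in manifest.iterrows():
        name = f"{row['participant']}_{row['condition']}_{int(row['trial']):02d}.csv"
        traj = read_trial_file(trial_dir / name)
        flag = str(row["error_flag"]) or None
        records.append(
            TrialRecord(
                participant=str(row["participant"]),
                group=str(row["group"]),
                condition=str(row["condition"]),
                trial_index=int(row["trial"]),
                trajectory=traj,
                error_flag=flag,
            )
        )
    return records


def extract_cohort_features(
    trials: list[TrialRecord] | SyntheticCohort,
    cutoff: float = 10.0,
    order: int = 2,
    threshold_fraction: float = 0.1,
    run_length: int = 6,
) -> tuple[FeatureMatrix, dict]:
    """Turn raw trials into the full participants x 320 feature table.

    Flagged error trials and trials whose segmentation fails are excluded
    (reported per group); each retained trial is filtered, segmented and
    reduced to its 20 kinematic parameters; per participant and condition the
    parameter means and SDs are aggregated.  Participants missing any
    condition cell (fewer than 2 usable trials) are dropped with a report —
    the downstream matrix is complete-case.
    """
    if isinstance(trials, SyntheticCohort):
        trials = trials.trials

    kw = dict(cutoff=cutoff, order=order, threshold_fraction=threshold_fraction,
              run_length=run_length)
    extracted: dict[tuple[str, str], list] = {}
    meta: dict[str, str] = {}
    seg_failed: set = set()
    for tr in trials:
        if tr.error_flag is not None:
            continue
        try:
            kv = extract_kinematics(tr.trajectory, trial_id=tr.trial_id, **kw)
        except SegmentationError:
            seg_failed.add(tr.trial_id)
            continue
        extracted.setdefault((tr.participant, tr.condition), []).append(kv)
        meta[tr.participant] = tr.group
    _, exclusion = exclude_errors(list(trials), extra_failed_ids=seg_failed)

    columns = [
        FeatureKey(c, s, p) for c in CONDITION_CODES for s in ("mean", "sd") for p in range(1, 21)
    ]
    rows, labels, participants, dropped = [], [], [], []
    for pid, group in meta.items():
        cells = {}
        complete = True
        for code in CONDITION_CODES:
            kvs = extracted.get((pid, code), [])
            if len(kvs) < 2:
                complete = False
                break
            cells[code] = aggregate(kvs, pid, group, code)
        if not complete:
            dropped.append(pid)
            continue
        row = np.concatenate(
            [np.concatenate([cells[c].mean_vector, cells[c].sd_vector]) for c in CONDITION_CODES]
        )
        rows.append(row)
        labels.append(group)
        participants.append(pid)
    if dropped:
        logger.warning("dropping %d participant(s) with incomplete cells: %s", len(dropped), dropped)
    if not rows:
        raise ValueError("no complete participants after exclusion")
    fm = FeatureMatrix(
        values=np.vstack(rows),
        labels=np.array(labels),
        columns=columns,
        participants=participants,
    )
    report = {
        "exclusion": exclusion,
        "segmentation_failures": len(seg_failed),
        "dropped_participants": dropped,
    }
    return fm, report


@dataclass
class RunConfig:
    """Declarative configuration of one full pipeline run."""

    seed: int = 0
    n_asc: int = 14
    n_ctrl: int = 16
    out_dir: str = "imitkin_run"
    # kinematics
    cutoff: float = 10.0
    order: int = 2
    threshold_fraction: float = 0.1
    run_length: int = 6
    # analysis
    joint_conditions: tuple[str, str] = ("NTF", "NTE")
    selector: str = "combined"
    classifier: str = "svm_linear"
    inner_folds: int = 5
    top_m: int = 9
    export_trials: bool = False


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline on a simulated cohort; write artifact tables.

    Stages: simulate the cohort, extract the 320-column feature table, screen
    the 8 conditions, run the nested evaluation with in-fold selection on the
    joint-condition SD matrix, and evaluate the final top-m occurrence set
    with all five classifiers.  Everything derives from ``config.seed``;
    rerunning with the same config reproduces every artifact bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(config.n_asc, config.n_ctrl, seed=config.seed)
    if config.export_trials:
        export_cohort(cohort, out / "trials")

    fm, report = extract_cohort_features(
        cohort,
        cutoff=config.cutoff,
        order=config.order,
        threshold_fraction=config.threshold_fraction,
        run_length=config.run_length,
    )
    write_feature_table(fm, out / "features.csv")

    screen = screen_conditions(fm)
    screen.to_frame().to_csv(out / "screen_table.csv")

    joint = slice_matrix(fm, list(config.joint_conditions), "sd")
    joint_acc = joint_condition_run(joint)

    cfg = NestedCVConfig(
        selector=config.selector,
        classifier=config.classifier,
        inner_folds=config.inner_folds,
        seed=config.seed,
    )
    nested = nested_loocv(joint, cfg)
    final_set = nested.trace.top(config.top_m)
    final_table = evaluate_final_features(joint, final_set, seed=config.seed)
    final_table.to_csv(out / "final_features_eval.csv")

    occ = pd.DataFrame(
        sorted(nested.trace.occurrences.items()),
        columns=["feature_index", "occurrences"],
    )
    occ.to_csv(out / "selection_occurrences.csv", index=False)

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "exclusion_report": report,
        "screen_best_conditions": screen.best_conditions(),
        "joint_nb_loocv_accuracy_pct": joint_acc,
        "nested_accuracy_pct": 100.0 * nested.accuracy,
        "final_feature_set": final_set,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return out
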