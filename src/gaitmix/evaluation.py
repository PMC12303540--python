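"""End-to-end evaluation of the calibrated cohort against the
reference group means.

For each reference quantity the evaluation simulates the full
calibrated cohort (10 controls, 19 CSVD walkers), runs both extraction
pipelines and averages the resulting group-task means over several
seeded replicate cohorts.  All numbers are produced by the pipeline at
run time; the calibration itself is recomputed from the passed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import calibrated_design
from .pipeline import extract_cohort_features
from .synthetic import simulate_cohort

#: evaluated quantities: id -> (group, task, feature column)
TARGETS: dict[str, tuple[str, str, str]] = {
    "t1": ("control", "normal", "step_regularity"),
    "t2": ("csvd", "normal", "step_regularity"),
    "t3": ("control", "normal", "rms"),
    "t4": ("control", "dual", "step_regularity"),
    "t5": ("control", "normal", "head_to_body_mean"),
    "t6": ("control", "normal", "head_to_ground_mean"),
    "t7": ("csvd", "dual", "head_to_ground_mean"),
    "t8": ("csvd", "dual", "calf_to_vertical_mean"),
}


def evaluate_targets(
    seed: int,
    n_replicates: int = 10,
    n_control: int = 10,
    n_csvd: int = 19,
    tasks: tuple[str, ...] = ("normal", "dual"),
    n_calib: int = 48,
) -> dict[str, dict[str, float | int]]:
    """Recompute every evaluated quantity from scratch.

    Builds the calibrated design, simulates ``n_replicates`` seeded
    cohorts (one repetition per task; the replicates play the role of
    repeated sessions), extracts features, and averages each group-task
    mean over replicates.  Returns ``{id: {"value": ..., "n": ...}}``.
    """
    rng = np.random.default_rng(seed)
    calibration_seed = int(rng.integers(2**31 - 1))
    rep_seeds = [int(s) for s in rng.integers(2**31 - 1, size=n_replicates)]

    design = calibrated_design(
        n_control=n_control,
        n_csvd=n_csvd,
        tasks=tasks,
        repetitions=1,
        seed=0,
        calibration_seed=calibration_seed,
        n_calib=n_calib,
    )

    per_rep: list[pd.DataFrame] = []
    counts: dict[str, int] = {tid: 0 for tid in TARGETS}
    import dataclasses

    for rs in rep_seeds:
        cohort = simulate_cohort(dataclasses.replace(design, seed=rs))
        result = extract_cohort_features(cohort)
        feats = result.features
        means = feats.groupby(["group", "task"], observed=True).mean(numeric_only=True)
        per_rep.append(means)
        for tid, (group, task, col) in TARGETS.items():
            if (group, task) in means.index and col in means.columns:
                counts[tid] += int(
                    feats[(feats["group"] == group) & (feats["task"] == task)][col]
                    .notna()
                    .sum()
                )

    out: dict[str, dict[str, float | int]] = {}
    for tid, (group, task, col) in TARGETS.items():
        vals = [
            float(m.loc[(group, task), col])
            for m in per_rep
            if (group, task) in m.index and col in m.columns
        ]
        out[tid] = {"value": float(np.mean(vals)), "n": counts[tid]}
    return out
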