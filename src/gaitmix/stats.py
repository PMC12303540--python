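"""Group comparison statistics.

Reproduces the statistical surface of a two-group gait study:
per-task, per-parameter Mann-Whitney U comparisons of control versus
CSVD-like walkers, a demographics table (Welch t tests for continuous
variables, chi-square for sex), and headline effect summaries
(relative regularity deficit, head-angle gaps).

Repetitions are averaged within participant before testing, because
the sampling unit is the participant.  Tests are two-sided and no
multiplicity correction gates significance; a Benjamini-Hochberg
q-value column is emitted as supplementary output only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, DesignError, SchemaError

GROUPS = ("control", "csvd")
TASKS = ("normal", "dual", "fast")

#: feature columns eligible for group comparison, in table order
SENSOR_PARAMETERS = (
    "step_frequency",
    "rms",
    "step_variability",
    "step_regularity",
    "step_symmetry",
)
VIDEO_PARAMETERS = (
    "calf_to_vertical_mean",
    "head_to_body_mean",
    "head_to_ground_mean",
    "knee_mean",
    "knee_var",
    "ankle_mean",
    "ankle_var",
    "elbow_mean",
    "elbow_var",
    "upper_arm_trunk_mean",
    "upper_arm_trunk_var",
    "trunk_thigh_mean",
    "trunk_thigh_var",
    "neck_trunk_mean",
    "body_lean_mean",
    "sight_line_mean",
    "heel_height_m",
    "step_length_m",
    "step_speed_mps",
)

KEY_COLUMNS = ("participant", "group", "task", "repetition")


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U, n1*n2 - U)
    p_value: float
    method: str  # "exact" or "normal-approximation"


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``U`` counts pairs ``(x_i, y_j)`` with ``x_i > y_j`` plus half the
    ties; the reported statistic is ``min(U, n1*n2 - U)``.  The p-value
    is exact (full enumeration of the rank distribution) when
    ``min(n1, n2) <= 8`` and there are no ties, otherwise a normal
    approximation with tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # every pooled value identical: the test is degenerate
        return MannWhitneyResult(u=n1 * n2 / 2.0, p_value=1.0, method="normal-approximation")
    ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= 8 and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation"
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    p = float(min(res.pvalue, 1.0))
    return MannWhitneyResult(u=u, p_value=p, method=method)


def _numeric_parameters(table: pd.DataFrame) -> list[str]:
    known = list(SENSOR_PARAMETERS) + list(VIDEO_PARAMETERS)
    return [c for c in known if c in table.columns]


def compare_groups(
    table: pd.DataFrame, parameters: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-task, per-parameter group comparison table.

    ``table`` must carry ``participant``, ``group``, ``task`` and
    feature columns; repetitions (if a ``repetition`` column exists)
    are averaged within participant x task first.  Returns one row per
    (task, parameter) with group means/SDs, the U statistic, the
    two-sided p-value, the method, and a supplementary BH q-value.
    """
    for col in ("participant", "group", "task"):
        if col not in table.columns:
            raise SchemaError(f"missing column '{col}'")
    present = set(table["group"].unique())
    if not set(GROUPS) <= present:
        raise DesignError(f"need both groups {GROUPS}, found {sorted(present)}")
    if parameters is None:
        parameters = _numeric_parameters(table)
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise SchemaError(f"missing parameter columns: {missing}")
    for g in GROUPS:
        if table.loc[table["group"] == g, "participant"].nunique() < 2:
            raise DesignError(f"group '{g}' needs at least 2 participants")

    agg = (
        table.groupby(["participant", "group", "task"], observed=True)[list(parameters)]
        .mean()
        .reset_index()
    )
    tasks = [t for t in TASKS if t in agg["task"].unique()] + [
        t for t in agg["task"].unique() if t not in TASKS
    ]
    rows = []
    for task in tasks:
        sub = agg[agg["task"] == task]
        for param in parameters:
            xc = sub.loc[sub["group"] == "control", param].dropna().to_numpy()
            xd = sub.loc[sub["group"] == "csvd", param].dropna().to_numpy()
            if xc.size < 2 or xd.size < 2:
                raise DesignError(
                    f"task '{task}', parameter '{param}': too few complete participants"
                )
            res = mann_whitney_u(xc, xd)
            rows.append(
                {
                    "task": task,
                    "parameter": param,
                    "control_mean": float(xc.mean()),
                    "control_sd": float(xc.std(ddof=1)),
                    "csvd_mean": float(xd.mean()),
                    "csvd_sd": float(xd.std(ddof=1)),
                    "n_control": int(xc.size),
                    "n_csvd": int(xd.size),
                    "u_statistic": res.u,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value_bh"] = sps.false_discovery_control(out["p_value"], method="bh")
    return out


DEMOGRAPHIC_CONTINUOUS = ("age_years", "height_cm", "weight_kg", "bmi")


def demographics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic summary with between-group tests.

    Continuous variables get a Welch two-sample t test; sex gets a
    chi-square test on the 2x2 contingency table.  One row per
    participant is used (demographics repeat across tasks).
    """
    for col in ("participant", "group"):
        if col not in table.columns:
            raise SchemaError(f"missing column '{col}'")
    per = table.drop_duplicates("participant")
    rows = []
    for var in DEMOGRAPHIC_CONTINUOUS:
        if var not in per.columns:
            continue
        xc = per.loc[per["group"] == "control", var].dropna().to_numpy()
        xd = per.loc[per["group"] == "csvd", var].dropna().to_numpy()
        t = sps.ttest_ind(xc, xd, equal_var=False)
        p = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
        rows.append(
            {
                "variable": var,
                "control_mean": float(xc.mean()),
                "control_sd": float(xc.std(ddof=1)),
                "csvd_mean": float(xd.mean()),
                "csvd_sd": float(xd.std(ddof=1)),
                "p_value": p,
                "test": "welch-t",
            }
        )
    if "sex" in per.columns:
        ct = pd.crosstab(per["group"], per["sex"])
        if ct.shape[1] > 1:
            chi = sps.chi2_contingency(ct)
            p_sex = float(chi.pvalue)
        else:
            p_sex = 1.0
        male_frac = per.assign(m=(per["sex"] == "M")).groupby("group")["m"].mean()
        rows.append(
            {
                "variable": "sex_male_fraction",
                "control_mean": float(male_frac.get("control", np.nan)),
                "control_sd": np.nan,
                "csvd_mean": float(male_frac.get("csvd", np.nan)),
                "csvd_sd": np.nan,
                "p_value": p_sex,
                "test": "chi-square",
            }
        )
    return pd.DataFrame(rows)


def headline_effects(comparison: pd.DataFrame) -> pd.DataFrame:
    """Headline effect summary per task.

    * regularity relative difference = (control - csvd) / control, %
    * head-angle gaps = control mean - csvd mean, degrees
    """
    if "parameter" not in comparison.columns:
        raise SchemaError("comparison table missing 'parameter' column")
    params_present = set(comparison["parameter"])
    if "step_regularity" not in params_present:
        raise DesignError("comparison table has no step_regularity rows")
    if not params_present & {"head_to_body_mean", "head_to_ground_mean"}:
        raise DesignError("comparison table has no head-angle rows")
    rows = []
    for task in comparison["task"].unique():
        sub = comparison[comparison["task"] == task].set_index("parameter")
        reg = sub.loc["step_regularity"]
        row = {
            "task": task,
            "regularity_rel_diff_pct": 100.0
            * (reg["control_mean"] - reg["csvd_mean"])
            / reg["control_mean"],
        }
        for angle in ("head_to_body_mean", "head_to_ground_mean"):
            if angle in sub.index:
                row[f"{angle.removesuffix('_mean')}_gap_deg"] = (
                    sub.loc[angle, "control_mean"] - sub.loc[angle, "csvd_mean"]
                )
        rows.append(row)
    return pd.DataFrame(rows)
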