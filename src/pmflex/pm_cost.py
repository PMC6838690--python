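"""Behavioral strategy metrics: PM cost and PM cost slope.

PM cost is the reaction-time interference from holding a prospective
intention: the ongoing-task RT on a PM-trial probe minus a matched baseline
(mean correct non-PM-trial RT at the same difficulty level and practice bin).
The PM cost slope summarises how cost shifts within a trial — last-window
minus first-window mean cost, per probe, expressed in ms/s — and is the
behavioral index of a strategy shift toward (positive) or away from
(negative) proactive control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmflex.task_design import PROBE_DURATION_S

logger = logging.getLogger(__name__)

RT_FLOOR_S = 0.3            # responses faster than 300 ms are discarded
ACCURACY_EXCLUSION = 0.5    # trials below chance OG accuracy are excluded
MIN_SLOPE_PROBES = 7        # first (1-3) and last (n-3..n-1) windows must not overlap


class SchemaError(ValueError):
    """Input table is missing required columns."""


class BaselineError(ValueError):
    """No usable observations for the baseline table."""


def filter_responses(probes: pd.DataFrame) -> pd.DataFrame:
    """Drop responses faster than 300 ms (strict: exactly 0.300 s is kept).

    Rows without an RT (omissions) are retained; they never enter RT
    analyses but still count toward accuracy.
    """
    if "rt" not in probes.columns:
        raise SchemaError("probes table has no 'rt' column")
    fast = probes["rt"] < RT_FLOOR_S
    n_removed = int(fast.sum())
    if n_removed:
        logger.info("filter_responses: removed %d responses < %.0f ms",
                    n_removed, RT_FLOOR_S * 1000)
    return probes.loc[~fast.fillna(False)].copy()


@dataclass
class BaselineTable:
    """Mean correct non-PM RT by (difficulty level, early/late practice bin).

    A complete session populates 30 cells (15 levels × 2 bins).  Cells with
    no observations are absent from ``table``; lookups fall back to the same
    level's other bin (logged), never across levels.
    """

    table: pd.DataFrame     # index (difficulty_level, time_bin): mean_rt, n_obs
    block_split: dict

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def lookup(self, level: int, time_bin: str) -> float:
        try:
            return float(self.table.loc[(level, time_bin), "mean_rt"])
        except KeyError:
            other = "late" if time_bin == "early" else "early"
            try:
                val = float(self.table.loc[(level, other), "mean_rt"])
            except KeyError:
                return np.nan
            logger.warning("baseline cell (%s, %s) empty; using %s bin",
                           level, time_bin, other)
            return val


def default_block_split(blocks) -> dict:
    """Early/late practice bins: first half vs second half of the blocks.

    With an odd block count the extra block goes to the late bin (a 5-block
    session splits 1–2 early / 3–5 late; a 6-block session 1–3 / 4–6).
    """
    blocks = sorted(set(int(b) for b in blocks))
    n_early = len(blocks) // 2
    return {b: ("early" if i < n_early else "late")
            for i, b in enumerate(blocks)}


def compute_baselines(
    probes: pd.DataFrame,
    block_split: dict | None = None,
    correct_only: bool = True,
) -> BaselineTable:
    """Difficulty- and practice-binned RT baselines from non-PM trials.

    Uses correct ongoing-task responses on non-PM trials only (set
    ``correct_only=False`` for the all-responses control variant).  Expects an
    already RT-filtered table.
    """
    need = {"block", "pm_type", "difficulty_level", "rt", "og_correct"}
    missing = need - set(probes.columns)
    if missing:
        raise SchemaError(f"probes table missing columns: {sorted(missing)}")
    if block_split is None:
        block_split = default_block_split(probes["block"])

    base = probes[(probes["pm_type"] == "non_pm") & probes["rt"].notna()]
    if correct_only:
        base = base[base["og_correct"] == 1]
    if base.empty:
        raise BaselineError("no usable non-PM probes for baselines")
    bins = base["block"].map(block_split)
    table = (
        base.assign(time_bin=bins)
        .groupby(["difficulty_level", "time_bin"])["rt"]
        .agg(mean_rt="mean", n_obs="count")
    )
    return BaselineTable(table=table, block_split=dict(block_split))


def probe_costs(
    pm_probes: pd.DataFrame,
    baselines: BaselineTable,
) -> pd.DataFrame:
    """Per-probe PM cost: RT minus the matched baseline, in seconds.

    Probes whose (level, bin) cell is empty even after the same-level
    fallback get ``cost = NaN`` (flagged, never fatal).
    """
    out = pm_probes.copy()
    bins = out["block"].map(baselines.block_split)
    table = baselines.table["mean_rt"]
    key = pd.MultiIndex.from_arrays([out["difficulty_level"], bins])
    baseline = table.reindex(key).to_numpy()
    empty = np.isnan(baseline)
    if empty.any():
        # same-level other-bin fallback, never across levels
        other = bins.map({"early": "late", "late": "early"})
        alt_key = pd.MultiIndex.from_arrays(
            [out["difficulty_level"][empty], other[empty]])
        alt = table.reindex(alt_key).to_numpy()
        for lev, b in sorted(set(zip(out["difficulty_level"][empty],
                                     bins[empty]))):
            logger.warning("baseline cell (%s, %s) empty; using other bin",
                           lev, b)
        baseline[empty] = alt
    out["time_bin"] = bins
    out["baseline_rt"] = baseline
    out["cost"] = out["rt"] - baseline
    return out


def cost_slope(
    costs,
    n_probes: int,
    probe_duration_s: float = PROBE_DURATION_S,
    min_window_n: int = 1,
) -> float:
    """Within-trial PM cost slope in ms/s.

    ``costs`` are per-probe costs (seconds) ordered by probe for probes
    1..n−1 of a PM trial — the final (target) probe must already be excluded;
    missing entries (incorrect or omitted responses) are NaN.  The slope is
    the mean cost over the last window (probes n−3..n−1) minus the first
    window (probes 1–3), divided by the trial's probe count and by the 2 s
    probe duration.  Trials shorter than 7 probes (overlapping windows) or
    with fewer than ``min_window_n`` usable costs in either window are
    undefined (NaN).
    """
    costs = np.asarray(costs, dtype=float)
    if n_probes < MIN_SLOPE_PROBES:
        return np.nan
    if len(costs) != n_probes - 1:
        raise ValueError(
            f"expected {n_probes - 1} non-target probe costs, got {len(costs)}")
    first = costs[:3]
    last = costs[-3:]
    if np.isfinite(first).sum() < min_window_n or np.isfinite(last).sum() < min_window_n:
        return np.nan
    diff_s = np.nanmean(last) - np.nanmean(first)
    return (diff_s / n_probes) / probe_duration_s * 1000.0


def _trial_slope(g: pd.DataFrame, min_window_n: int) -> float:
    g = g.sort_values("probe")
    n_probes = int(g["probe"].max())
    non_target = g[~g["is_final_probe"]]
    costs = np.full(n_probes - 1, np.nan)
    idx = non_target["probe"].to_numpy(int) - 1
    costs[idx] = non_target["cost"].to_numpy(float)
    return cost_slope(costs, n_probes, min_window_n=min_window_n)


def summarize_trials(
    probes: pd.DataFrame,
    baselines: BaselineTable | dict | None = None,
    correct_only: bool = True,
    min_window_n: int = 1,
    accuracy_threshold: float = ACCURACY_EXCLUSION,
):
    """Per-trial strategy summaries plus cohort-level profiles.

    Parameters
    ----------
    probes : DataFrame
        RT-filtered probe table; multi-participant tables need a
        ``participant`` column (baselines are computed per participant).
    baselines : BaselineTable or mapping participant -> BaselineTable
        Computed if omitted.

    Returns
    -------
    summary : DataFrame
        One row per trial: ongoing-task accuracy, mean cost, cost slope
        (PM trials only), exclusion flag and reason.
    profiles : dict
        ``level_cost`` — per-participant per-level mean PM cost;
        ``condition_slopes`` — mean cost slope by trajectory condition;
        ``cost_level_trend`` — slope/intercept of the pooled linear fit of
        cost on difficulty level (ms of cost per level).
    """
    probes = probes.copy()
    if "participant" not in probes.columns:
        probes["participant"] = 0

    if baselines is None:
        baselines = {
            pid: compute_baselines(g, correct_only=correct_only)
            for pid, g in probes.groupby("participant")
        }
    elif isinstance(baselines, BaselineTable):
        baselines = {pid: baselines for pid in probes["participant"].unique()}

    cost_frames = []
    for pid, g in probes.groupby("participant"):
        pm = g[g["pm_type"] != "non_pm"]
        annotated = probe_costs(pm, baselines[pid])
        # the target-reappearance probe is not an ongoing-task response
        annotated.loc[annotated["is_final_probe"], "cost"] = np.nan
        if correct_only:
            annotated.loc[annotated["og_correct"] != 1, "cost"] = np.nan
        cost_frames.append(annotated)
    pm_costs = pd.concat(cost_frames, ignore_index=True) if cost_frames else probes.iloc[:0]

    # ongoing-task accuracy per trial (final probe of PM trials excluded:
    # the target reappearance is a PM response opportunity, not an OG probe)
    og_mask = ~(probes["is_final_probe"] & (probes["pm_type"] != "non_pm"))
    acc = (
        probes[og_mask]
        .groupby(["participant", "block", "trial"])["og_correct"]
        .mean()
        .rename("og_accuracy")
    )

    meta = (
        probes.groupby(["participant", "block", "trial"])
        .agg(condition=("condition", "first"), pm_type=("pm_type", "first"),
             n_probes=("probe", "max"), is_catch=("is_catch", "first"))
    )
    summary = meta.join(acc)

    pm_groups = pm_costs.groupby(["participant", "block", "trial"])
    mean_cost = pm_groups["cost"].mean().rename("mean_cost")
    slopes = pm_groups.apply(_trial_slope, min_window_n=min_window_n,
                             include_groups=False).rename("cost_slope")
    summary = summary.join(mean_cost).join(slopes)

    hits = probes[probes["is_final_probe"] & (probes["pm_type"] != "non_pm")]
    pm_hit = (hits["response"] == "pm").astype(int)
    pm_hit.index = pd.MultiIndex.from_frame(
        hits[["participant", "block", "trial"]])
    summary = summary.join(pm_hit.rename("pm_hit"))

    summary["excluded"] = summary["og_accuracy"] < accuracy_threshold
    summary["exclusion_reason"] = np.where(
        summary["excluded"], "og_accuracy_below_chance", "")
    summary = summary.reset_index()

    kept = summary[~summary["excluded"]]
    pm_kept = pm_costs.merge(
        kept[["participant", "block", "trial"]],
        on=["participant", "block", "trial"], how="inner")
    pm_kept = pm_kept[~pm_kept["is_final_probe"]]

    level_cost = (
        pm_kept.groupby(["participant", "difficulty_level"])["cost"]
        .mean().rename("mean_cost").reset_index()
    )
    condition_slopes = (
        kept[kept["pm_type"] != "non_pm"]
        .groupby("condition")["cost_slope"].mean().rename("mean_slope")
        .reset_index()
    )
    valid = pm_kept.dropna(subset=["cost"])
    if len(valid) >= 2 and valid["difficulty_level"].nunique() > 1:
        coef = np.polyfit(valid["difficulty_level"], valid["cost"] * 1000.0, 1)
        trend = {"slope_ms_per_level": float(coef[0]),
                 "intercept_ms": float(coef[1])}
    else:
        trend = {"slope_ms_per_level": np.nan, "intercept_ms": np.nan}

    profiles = {"level_cost": level_cost,
                "condition_slopes": condition_slopes,
                "cost_level_trend": trend}
    return summary, profiles
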