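"""Deterministic generators for the dual-task design.

The ongoing (OG) task is a visual search over 10 oriented arrows; difficulty is
controlled by two distractor parameters — the minimum angular distance of
distractors from the horizontal (0°) target, and the maximum variance of
distractor orientations above that minimum.  The factorial combination of the
two parameter sets, excluding pairs whose sum could cross the 90° vertical
plane, defines the ordered difficulty levels.

A session is organised in blocks of 15 trials — the factorial crossing of 3 PM
types (face target, scene target, no target) with 5 within-trial difficulty
trajectories (increase from level 1, increase from 8, fixed at 8, decrease
from 15, decrease from 8).  Five trials per block are short "catch" trials
(< 8 probes).  Each probe lasts 2 s with a 1.9 s response deadline; on PM
trials the target reappears exactly once, on the final probe.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: probe display duration, seconds
PROBE_DURATION_S = 2.0
#: response deadline within a probe, seconds
RESPONSE_DEADLINE_S = 1.9

#: main-task distractor parameter sets, degrees
MIN_DISTANCES = (5, 15, 25, 45, 65, 75)
VARIANCES = (10, 20, 40)
#: pilot study omitted the 75° minimum distance
PILOT_MIN_DISTANCES = (5, 15, 25, 45, 65)

#: within-trial difficulty trajectory conditions -> (start level, step)
CONDITIONS = {
    "inc_easy": (1, +1),
    "inc_mid": (8, +1),
    "fixed": (8, 0),
    "dec_hard": (15, -1),
    "dec_mid": (8, -1),
}
CONDITION_ORDER = ("inc_easy", "inc_mid", "fixed", "dec_hard", "dec_mid")
PM_TYPES = ("face", "scene", "non_pm")

MIN_LEVEL, MAX_LEVEL = 1, 15
CATCH_PROBE_RANGE = (2, 7)      # catch trials contain fewer than 8 probes
NONCATCH_PROBE_RANGE = (8, 15)

#: trial timing outside the probe stream, seconds
CUE_DURATION_S = 4.0        # 3 s target presentation + 1 s fixation
FEEDBACK_DURATION_S = 2.0
REST_DURATION_S = 6.0


class DesignError(ValueError):
    """Raised on invalid design parameters or unsatisfiable constraints."""


@dataclass(frozen=True)
class DifficultySpec:
    """One ordered difficulty condition of the visual search task.

    Parameters
    ----------
    level : int
        Ordinal difficulty, 1 (easiest) .. K (hardest).
    min_distance : float
        Minimum angular distance of distractors from the 0° target, degrees.
    variance : float
        Maximum spread of distractor orientations above ``min_distance``.
    """

    level: int
    min_distance: float
    variance: float


@dataclass
class ArrowArray:
    """One search display: 10 slots of oriented arrows.

    ``orientations[target_slot]`` is exactly 0° when the target is present;
    every distractor orientation lies in [5, 175] ∪ [185, 355].
    """

    orientations: np.ndarray
    target_present: bool
    target_slot: int | None

    N_SLOTS = 10

    def distractor_slots(self) -> np.ndarray:
        slots = np.arange(self.N_SLOTS)
        if self.target_present:
            slots = slots[slots != self.target_slot]
        return slots


@dataclass(frozen=True)
class Trajectory:
    """Per-probe difficulty levels of one trial."""

    condition: str
    levels: tuple[int, ...]


@dataclass
class SessionDesign:
    """Trial- and probe-level tables for one generated session.

    ``trials`` has one row per trial (block, trial, condition, pm_type,
    n_probes, is_catch); ``probes`` one row per 2 s probe with onset, the
    difficulty level from the trial's trajectory, and a final-probe flag (the
    PM target reappears on the final probe of PM trials).
    """

    trials: pd.DataFrame
    probes: pd.DataFrame
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_events(self) -> pd.DataFrame:
        """Probe-level event table (TSV-ready, BIDS-events flavoured)."""
        cols = [
            "block", "trial", "probe", "onset_s", "condition", "pm_type",
            "difficulty_level", "is_catch", "is_final_probe",
        ]
        return self.probes[cols].copy()

    def save(self, path) -> None:
        self.to_events().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# difficulty table

def build_difficulty_table(
    min_distances=MIN_DISTANCES,
    variances=VARIANCES,
    plane_limit: float = 90.0,
) -> list[DifficultySpec]:
    """Cross the distractor parameter sets and order the retained pairs.

    Pairs with ``min_distance + variance > plane_limit`` (distractors could
    cross the vertical plane) are dropped.  Levels are assigned easiest-first:
    descending ``min_distance`` (distractors far from the target pop out),
    then ascending ``variance`` (homogeneous distractors are easier to
    reject).

    Returns the ordered list of :class:`DifficultySpec`; the main-task
    parameter sets yield 15 conditions, the pilot sets yield 14.
    """
    if not len(min_distances) or not len(variances):
        raise DesignError("min_distances and variances must be non-empty")
    if any(m <= 0 for m in min_distances) or any(v <= 0 for v in variances):
        raise DesignError("distractor parameters must be positive")
    pairs = [
        (m, v)
        for m, v in itertools.product(min_distances, variances)
        if m + v <= plane_limit
    ]
    pairs.sort(key=lambda mv: (-mv[0], mv[1]))
    return [
        DifficultySpec(level=i + 1, min_distance=m, variance=v)
        for i, (m, v) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# trajectories

def make_trajectory(condition: str, n_probes: int) -> Trajectory:
    """Difficulty levels for one trial: one ±1 step per probe, clamped.

    Levels start at the condition's start level and shift by one level per
    probe until a difficulty endpoint (1 or 15) is reached, after which they
    stay at the endpoint; the ``fixed`` condition is constant at level 8.
    """
    if condition not in CONDITIONS:
        raise DesignError(f"unknown condition {condition!r}")
    if n_probes < 1:
        raise DesignError("n_probes must be >= 1")
    start, step = CONDITIONS[condition]
    levels = np.clip(start + step * np.arange(n_probes), MIN_LEVEL, MAX_LEVEL)
    return Trajectory(condition=condition, levels=tuple(int(x) for x in levels))


# ---------------------------------------------------------------------------
# arrow arrays

_BANDS = ((5.0, 175.0), (185.0, 355.0))


def _in_allowed_band(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    ok = np.zeros(theta.shape, dtype=bool)
    for lo, hi in _BANDS:
        ok |= (theta >= lo) & (theta <= hi)
    return ok


def circular_distance(a, b) -> np.ndarray:
    """Minimal angular distance in degrees: min(|Δ|, 360 − |Δ|)."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(d, 360.0 - d)


def _draw_orientation(spec: DifficultySpec, rng: np.random.Generator) -> float:
    theta = rng.uniform(spec.min_distance, spec.min_distance + spec.variance)
    if rng.random() < 0.5:  # flip across the horizontal plane
        theta = (360.0 - theta) % 360.0
    if rng.random() < 0.5:  # flip across the vertical plane
        theta = (180.0 - theta) % 360.0
    return theta


def sample_arrow_array(
    spec: DifficultySpec,
    previous: ArrowArray | None = None,
    target_present: bool = True,
    rng_seed=None,
    max_attempts: int = 100,
) -> ArrowArray:
    """Sample one search display under the anti-pop-out constraint.

    Distractor base orientations are uniform on
    ``[min_distance, min_distance + variance]``; each is independently flipped
    across the horizontal plane (θ → 360 − θ) and the vertical plane
    (θ → 180 − θ) with probability 0.5, confining distractors to
    [5, 175] ∪ [185, 355].  No distractor may land within 5° (circular) of the
    orientation shown at the same slot on the previous display; offending
    draws are resampled up to ``max_attempts`` times, after which the slot's
    constraint is relaxed with a logged warning.
    """
    rng = np.random.default_rng(rng_seed)
    n = ArrowArray.N_SLOTS
    orientations = np.full(n, np.nan)
    target_slot = int(rng.integers(n)) if target_present else None

    for slot in range(n):
        if target_present and slot == target_slot:
            orientations[slot] = 0.0
            continue
        prev_theta = None
        if previous is not None:
            prev_theta = previous.orientations[slot]
        for attempt in range(max_attempts):
            theta = _draw_orientation(spec, rng)
            if not _in_allowed_band(theta):
                continue
            if prev_theta is not None and circular_distance(theta, prev_theta) < 5.0:
                continue
            orientations[slot] = theta
            break
        else:
            # relax only this slot's same-slot constraint
            theta = _draw_orientation(spec, rng)
            if not _in_allowed_band(theta):
                raise DesignError(
                    f"could not draw an in-band orientation for spec {spec}"
                )
            logger.warning(
                "anti-pop-out constraint relaxed at slot %d after %d attempts",
                slot, max_attempts,
            )
            orientations[slot] = theta

    return ArrowArray(
        orientations=orientations,
        target_present=target_present,
        target_slot=target_slot,
    )


# ---------------------------------------------------------------------------
# session generation

def _probe_onsets(n_probes: np.ndarray) -> list[np.ndarray]:
    """Cumulative probe onsets across a block: cue, probes, feedback, rest."""
    onsets = []
    t = 0.0
    for n in n_probes:
        t += CUE_DURATION_S
        onsets.append(t + PROBE_DURATION_S * np.arange(n))
        t += PROBE_DURATION_S * n + FEEDBACK_DURATION_S + REST_DURATION_S
    return onsets


def _catch_plan(n_blocks: int, rng: np.random.Generator) -> list[list[tuple]]:
    """Which (pm_type, condition) combos are catch in each block.

    Cycles a shuffled list of the 15 combos, 5 per block, so catch assignments
    are counterbalanced across the session (each combo is catch equally often
    whenever ``3 | n_blocks``).
    """
    combos = list(itertools.product(PM_TYPES, CONDITION_ORDER))
    plan, pool = [], []
    for _ in range(n_blocks):
        if len(pool) < 5:
            fresh = combos.copy()
            rng.shuffle(fresh)
            pool.extend(fresh)
        block_catch = []
        i = 0
        while len(block_catch) < 5:
            if pool[i] not in block_catch:
                block_catch.append(pool.pop(i))
            else:  # same combo twice in one block: defer to a later block
                i += 1
        plan.append(block_catch)
    return plan


def generate_session(n_blocks: int, rng_seed=None) -> SessionDesign:
    """Generate a pseudorandomised main-task session.

    Each block holds the 15 trials of the 3 (PM type) × 5 (trajectory)
    factorial exactly once, in shuffled order; 5 per block are catch trials
    with 2–7 probes, the rest have 8–15.  Probe counts are assigned so each PM
    type receives the same multiset of trial lengths (hence equal probe
    totals) whenever ``n_blocks`` is divisible by 3, and as equal as possible
    otherwise.  Deterministic given ``rng_seed``.
    """
    if n_blocks < 1:
        raise DesignError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng_seed)
    catch_plan = _catch_plan(n_blocks, rng)

    # per-PM-type slot lists: (block, condition, is_catch)
    slots = {pm: [] for pm in PM_TYPES}
    for b, block_catch in enumerate(catch_plan):
        for pm in PM_TYPES:
            for cond in CONDITION_ORDER:
                slots[pm].append((b, cond, (pm, cond) in block_catch))

    n_catch = {pm: sum(s[2] for s in slots[pm]) for pm in PM_TYPES}
    n_noncatch = {pm: len(slots[pm]) - n_catch[pm] for pm in PM_TYPES}

    # shared probe-count multisets across PM types where counts allow
    max_catch = max(n_catch.values())
    max_non = max(n_noncatch.values())
    catch_counts = rng.integers(CATCH_PROBE_RANGE[0], CATCH_PROBE_RANGE[1] + 1,
                                size=max_catch)
    non_counts = rng.integers(NONCATCH_PROBE_RANGE[0], NONCATCH_PROBE_RANGE[1] + 1,
                              size=max_non)

    trial_rows = []
    for pm in PM_TYPES:
        cc = catch_counts[: n_catch[pm]].copy()
        nc = non_counts[: n_noncatch[pm]].copy()
        rng.shuffle(cc)
        rng.shuffle(nc)
        ci = ni = 0
        for (b, cond, is_catch) in slots[pm]:
            if is_catch:
                n_probes = int(cc[ci]); ci += 1
            else:
                n_probes = int(nc[ni]); ni += 1
            trial_rows.append(
                dict(block=b + 1, condition=cond, pm_type=pm,
                     n_probes=n_probes, is_catch=is_catch)
            )

    trials = pd.DataFrame(trial_rows)
    # shuffle trial order within each block
    trials["_order"] = rng.random(len(trials))
    trials = (
        trials.sort_values(["block", "_order"])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    trials["trial"] = trials.groupby("block").cumcount() + 1

    probe_rows = []
    for block, block_trials in trials.groupby("block", sort=True):
        onsets = _probe_onsets(block_trials["n_probes"].to_numpy())
        for (_, tr), tr_onsets in zip(block_trials.iterrows(), onsets):
            traj = make_trajectory(tr["condition"], tr["n_probes"])
            for p, (lev, onset) in enumerate(zip(traj.levels, tr_onsets), start=1):
                probe_rows.append(
                    dict(block=block, trial=tr["trial"], probe=p,
                         onset_s=float(onset), condition=tr["condition"],
                         pm_type=tr["pm_type"], difficulty_level=lev,
                         is_catch=tr["is_catch"],
                         is_final_probe=(p == tr["n_probes"]))
                )
    probes = pd.DataFrame(probe_rows)
    trials = trials[["block", "trial", "condition", "pm_type", "n_probes",
                     "is_catch"]].sort_values(["block", "trial"]).reset_index(drop=True)
    return SessionDesign(trials=trials, probes=probes, seed=rng_seed)


def generate_localizer_design(n_blocks: int, rng_seed=None) -> SessionDesign:
    """Generate the ongoing-task-only localizer.

    Each block is 60 probes split into exactly 8 trials of lengths 2–12, with
    increasing or decreasing difficulty trajectories as in the main task.
    """
    if n_blocks < 1:
        raise DesignError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng_seed)
    dyn_conditions = [c for c in CONDITION_ORDER if c != "fixed"]

    trial_rows = []
    for b in range(1, n_blocks + 1):
        # exact-sum composition of 60 into 8 parts in [2, 12]:
        # start from 4x7 + 4x8 and apply sum-preserving ±1 moves
        lengths = np.array([7, 7, 7, 7, 8, 8, 8, 8])
        for _ in range(200):
            i, j = rng.integers(8, size=2)
            if lengths[i] < 12 and lengths[j] > 2 and i != j:
                lengths[i] += 1
                lengths[j] -= 1
        rng.shuffle(lengths)
        for t, n in enumerate(lengths, start=1):
            cond = dyn_conditions[int(rng.integers(len(dyn_conditions)))]
            trial_rows.append(dict(block=b, trial=t, condition=cond,
                                   pm_type="non_pm", n_probes=int(n),
                                   is_catch=False))
    trials = pd.DataFrame(trial_rows)

    probe_rows = []
    for block, block_trials in trials.groupby("block", sort=True):
        onsets = _probe_onsets(block_trials["n_probes"].to_numpy())
        for (_, tr), tr_onsets in zip(block_trials.iterrows(), onsets):
            traj = make_trajectory(tr["condition"], tr["n_probes"])
            for p, (lev, onset) in enumerate(zip(traj.levels, tr_onsets), start=1):
                probe_rows.append(
                    dict(block=block, trial=tr["trial"], probe=p,
                         onset_s=float(onset), condition=tr["condition"],
                         pm_type="non_pm", difficulty_level=lev,
                         is_catch=False, is_final_probe=(p == tr["n_probes"]))
                )
    return SessionDesign(trials=trials, probes=pd.DataFrame(probe_rows),
                         seed=rng_seed, extra={"localizer": True})
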