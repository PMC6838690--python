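"""Synthetic behavioral and neural data with known ground truth.

The generator operationalises a latent per-probe strategy state θ ∈ [0, 1]
(0 = fully reactive, 1 = fully proactive).  θ drifts linearly within a trial
at a condition-specific rate and expresses itself as an additive reaction-time
cost on PM-trial probes whose magnitude is attenuated as ongoing-task
difficulty rises.  PM hit probability at target onset is a logistic function
of θ on the final probe, floored by a reactive-retrieval success rate.  The
neural generator emits class-templated feature patterns (face / scene /
ongoing task / rest) with additive Gaussian noise and a trial-level evidence
shift coupled to the trial's mean θ, mimicking a 2 s TR acquisition with a
2-sample hemodynamic label lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from pmflex import task_design
from pmflex.task_design import (
    CONDITIONS,
    PROBE_DURATION_S,
    RESPONSE_DEADLINE_S,
    SessionDesign,
)


@dataclass
class SynthParams:
    """Ground-truth parameters of the behavioral generator.

    Defaults emulate the study conditions: baseline reaction time rising and
    accuracy falling across the 15 difficulty levels, a proactive cost around
    0.13 s at the easiest level that nearly vanishes at the hardest, opposing
    strategy drifts on increasing/decreasing trials, a mild expectancy drift
    on fixed trials, and ongoing-task / PM accuracies landing near 84% / 75%.
    """

    rt_base_easy: float = 0.60      # mean correct non-PM RT at level 1, s
    rt_base_hard: float = 1.25      # ... at level 15, s
    acc_easy: float = 0.97          # OG accuracy at level 1
    acc_hard: float = 0.62          # ... at level 15
    cost_amplitude: float = 0.25    # proactive RT cost at full engagement, level 1, s
    cost_difficulty_decay: float = 0.9  # attenuation of expressed cost with level
    theta0: float = 0.55            # strategy state at trial start
    drift_inc: float = -0.04        # Δθ per probe on increasing-difficulty trials
    drift_dec: float = +0.04        # ... on decreasing trials
    drift_fix: float = +0.02        # ... on fixed trials (target expectancy)
    drift_sd: float = 0.08          # per-trial SD of the drift rate
    pm_slope_gain: float = 5.0      # logit gain of hit probability on θ_final − θ0
                                    # (decreasing and fixed trials)
    pm_slope_gain_inc: float | None = None
                                    # gain on increasing trials; None scales the
                                    # main gain by -0.5 (reactive shifts help
                                    # under rising load, more weakly)
    pm_intercept: float = 0.1
    reactive_floor: float = 0.45    # hit probability with no proactive engagement
    rt_noise_sd: float = 0.15       # probe RT noise, s
    n_participants: int = 78
    n_blocks: int = 6
    seed: int = 0

    def __post_init__(self):
        for p in (self.acc_easy, self.acc_hard, self.theta0,
                  self.reactive_floor):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and theta0 must lie in [0, 1]")
        if not self.rt_base_easy < self.rt_base_hard < RESPONSE_DEADLINE_S:
            raise ValueError("need rt_base_easy < rt_base_hard < deadline")

    def asdict(self) -> dict:
        return asdict(self)

    @property
    def gain_inc(self) -> float:
        if self.pm_slope_gain_inc is None:
            return -0.5 * self.pm_slope_gain
        return self.pm_slope_gain_inc


@dataclass
class NeuralSynthParams:
    """Parameters of the neural feature generator."""

    n_features: int = 24
    snr: float = 1.0            # template amplitude relative to unit noise
    coupling: float = 0.5       # trial mean θ -> target-class evidence shift
    tr: float = 2.0             # sampling period, s
    lag_trs: int = 2            # hemodynamic label lag, samples

    def __post_init__(self):
        if self.n_features < 4:
            raise ValueError("n_features must be >= 4")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")

    def asdict(self) -> dict:
        return asdict(self)


def _interp_level(lo: float, hi: float, levels: np.ndarray) -> np.ndarray:
    """Linear interpolation between the level-1 and level-15 anchors."""
    return lo + (hi - lo) * (np.asarray(levels, float) - 1.0) / 14.0


def _decay(levels: np.ndarray, decay: float) -> np.ndarray:
    """Multiplicative attenuation of expressed cost with level, floored at 0."""
    return np.maximum(0.0, 1.0 - decay * (np.asarray(levels, float) - 1.0) / 14.0)


def strategy_trace(condition: str, n_probes: int, params: SynthParams) -> np.ndarray:
    """Latent θ per probe: linear drift by condition, clipped to [0, 1]."""
    drift = {"inc_easy": params.drift_inc, "inc_mid": params.drift_inc,
             "dec_hard": params.drift_dec, "dec_mid": params.drift_dec,
             "fixed": params.drift_fix}[condition]
    t = np.arange(n_probes, dtype=float)
    return np.clip(params.theta0 + drift * t, 0.0, 1.0)


def simulate_participant(
    design: SessionDesign,
    params: SynthParams,
    participant_seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one participant's probe- and trial-level tables.

    Probe RTs are ``rt_base(level) + θ_t · cost_amplitude · decay(level)``
    (the cost term on PM trials only) plus Gaussian noise, floored at 0.3 s;
    raw RTs beyond the 1.9 s deadline are omissions (no RT, incorrect).
    Ongoing-task correctness is Bernoulli in ``acc(level)``.  On the final
    probe of a PM trial the target reappears: a hit (Bernoulli in
    ``reactive_floor + (1 − reactive_floor) · σ(pm_intercept +
    gain · (θ_final − θ0))``, with the gain direction-specific) preempts the
    ongoing-task response.
    """
    rng = np.random.default_rng(participant_seed)
    probes = design.probes.copy()

    drift_map = {"inc_easy": params.drift_inc, "inc_mid": params.drift_inc,
                 "dec_hard": params.drift_dec, "dec_mid": params.drift_dec,
                 "fixed": params.drift_fix}
    # per-trial drift: condition mean plus trial-level jitter (people do not
    # shift strategy identically on every trial of a condition)
    trial_key = probes["block"].astype(int) * 1000 + probes["trial"].astype(int)
    uniq, inv = np.unique(trial_key.to_numpy(), return_inverse=True)
    trial_jitter = rng.normal(0.0, params.drift_sd, len(uniq))
    drift = (probes["condition"].map(drift_map).to_numpy(float)
             + trial_jitter[inv])
    theta = np.clip(
        params.theta0 + drift * (probes["probe"].to_numpy(float) - 1.0),
        0.0, 1.0,
    )
    probes["theta"] = theta

    level = probes["difficulty_level"].to_numpy(float)
    is_pm = (probes["pm_type"] != "non_pm").to_numpy()
    rt_mean = _interp_level(params.rt_base_easy, params.rt_base_hard, level)
    cost = np.where(
        is_pm,
        theta * params.cost_amplitude * _decay(level, params.cost_difficulty_decay),
        0.0,
    )
    raw_rt = rt_mean + cost + rng.normal(0.0, params.rt_noise_sd, len(probes))
    omitted = raw_rt > RESPONSE_DEADLINE_S
    rt = np.maximum(raw_rt, 0.3)
    rt[omitted] = np.nan

    acc = _interp_level(params.acc_easy, params.acc_hard, level)
    og_correct = (rng.random(len(probes)) < acc) & ~omitted

    probes["rt"] = rt
    probes["og_correct"] = og_correct.astype(int)
    probes["response"] = np.where(omitted, "omit", "og")

    # PM target reappears on the final probe of PM trials; a strategy shift
    # helps when it matches the demand trend (proactive on decreasing/fixed
    # trials, reactive on increasing trials)
    final_pm = (probes["is_final_probe"] & is_pm).to_numpy()
    theta_final = theta[final_pm]
    is_inc = probes.loc[final_pm, "condition"].isin(
        ["inc_easy", "inc_mid"]).to_numpy()
    gain = np.where(is_inc, params.gain_inc, params.pm_slope_gain)
    p_hit = params.reactive_floor + (1.0 - params.reactive_floor) / (
        1.0 + np.exp(-(params.pm_intercept
                       + gain * (theta_final - params.theta0)))
    )
    hit = rng.random(final_pm.sum()) < p_hit
    resp = probes["response"].to_numpy(object)
    resp[np.flatnonzero(final_pm)[hit]] = "pm"      # PM response preempts OG
    probes["response"] = resp
    ogc = probes["og_correct"].to_numpy()
    ogc[np.flatnonzero(final_pm)[hit]] = 0
    probes["og_correct"] = ogc

    hit_by_trial = pd.Series(
        hit, index=pd.MultiIndex.from_frame(
            probes.loc[final_pm, ["block", "trial"]]),
    )
    trials = design.trials.copy()
    key = pd.MultiIndex.from_frame(trials[["block", "trial"]])
    trials["pm_hit"] = [
        int(hit_by_trial[k]) if k in hit_by_trial.index else np.nan
        for k in key
    ]
    theta_stats = probes.groupby(["block", "trial"])["theta"].agg(["mean", "last"])
    trials = trials.merge(
        theta_stats.rename(columns={"mean": "theta_mean", "last": "theta_final"}),
        left_on=["block", "trial"], right_index=True,
    )
    return probes, trials


def simulate_cohort(
    params: SynthParams,
    design: SessionDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort on a shared session design.

    Returns (probe table, trial table) with a ``participant`` column.
    Per-participant seeds are derived from ``params.seed`` via
    ``numpy.random.SeedSequence`` spawning, so any participant can be
    regenerated independently.
    """
    if params.n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    ss = np.random.SeedSequence(params.seed)
    design_seed, *subj_seeds = ss.spawn(params.n_participants + 1)
    if design is None:
        design = task_design.generate_session(params.n_blocks, design_seed)

    probe_frames, trial_frames = [], []
    for pid, sseed in enumerate(subj_seeds, start=1):
        probes, trials = simulate_participant(design, params, sseed)
        probes.insert(0, "participant", pid)
        trials.insert(0, "participant", pid)
        probe_frames.append(probes)
        trial_frames.append(trials)
    return (
        pd.concat(probe_frames, ignore_index=True),
        pd.concat(trial_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# neural generator

CLASSES = ("face", "scene", "og", "rest")

#: inter-trial interval in TRs: feedback + rest; first/last sample are guards
ITI_TRS = 4


@dataclass
class NeuralDataset:
    """Time-point × feature matrix with labels and run structure.

    ``labels`` are event-aligned; :meth:`aligned` applies the hemodynamic lag
    by shifting labels (and row metadata) forward ``lag_trs`` samples.  Guard
    samples adjacent to trial boundaries carry the empty label and are
    excluded from training and scoring.
    """

    X: np.ndarray
    labels: np.ndarray          # event-time class labels ('' = guard)
    run: np.ndarray
    trial: np.ndarray           # trial id per sample, -1 outside trials
    is_localizer: np.ndarray
    is_final_probe: np.ndarray
    tr: float = 2.0
    lag_trs: int = 2
    labels_aligned: bool = False

    def aligned(self) -> "NeuralDataset":
        """Shift labels forward by ``lag_trs`` samples relative to the data."""
        if self.labels_aligned:
            return self
        k = self.lag_trs
        n = len(self.labels)
        shift = lambda a, fill: np.concatenate(
            [np.full(k, fill, dtype=a.dtype), a[: n - k]])
        return NeuralDataset(
            X=self.X,
            labels=shift(self.labels, ""),
            run=self.run,                       # run boundaries are physical
            trial=shift(self.trial, -1),
            is_localizer=self.is_localizer,
            is_final_probe=shift(self.is_final_probe, False),
            tr=self.tr, lag_trs=k, labels_aligned=True,
        )


def _templates(n_features: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {c: rng.normal(0.0, 1.0, n_features) for c in CLASSES}


def _block_sequence(block_probes: pd.DataFrame, trial_meta: pd.DataFrame):
    """Per-TR (label, trial, theta_mean, is_final) sequence for one task block.

    Trial ids are globally unique across blocks: ``block * 1000 + trial``.
    """
    seq = []
    for (block, trial), g in block_probes.groupby(["block", "trial"], sort=True):
        meta = trial_meta.loc[(block, trial)]
        pm_type = g["pm_type"].iloc[0]
        label = pm_type if pm_type in ("face", "scene") else "og"
        tm = float(meta["theta_mean"]) if "theta_mean" in meta else 0.5
        gid = int(block) * 1000 + int(trial)
        n = len(g)
        for i in range(n):
            seq.append((label, gid, tm, i == n - 1))
        # ITI: guard, rest, rest, guard
        seq.append(("", -1, 0.5, False))
        for _ in range(ITI_TRS - 2):
            seq.append(("rest", -1, 0.5, False))
        seq.append(("", -1, 0.5, False))
    return seq


def simulate_neural(
    probes: pd.DataFrame,
    trials: pd.DataFrame,
    nparams: NeuralSynthParams,
    seed=None,
    participants=None,
) -> dict[int, NeuralDataset]:
    """Simulate per-participant neural time series from a simulated cohort.

    Each sample is ``snr · template(class) + noise`` with unit Gaussian noise;
    samples of a PM trial's target class additionally receive
    ``coupling · (θ̄ − 0.5)`` along the target template (θ̄ = the trial's mean
    strategy state).  The signal is placed ``lag_trs`` samples after its
    event, so the returned event-aligned labels require the standard lag
    shift before decoding.  Task blocks become runs; an ongoing-task
    localizer run and a face/scene localizer run are appended.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    if participants is None:
        participants = sorted(probes["participant"].unique())
    out = {}
    for pid, sseed in zip(participants, ss.spawn(len(participants))):
        rng = np.random.default_rng(sseed)
        tpl = _templates(nparams.n_features, rng)
        p_probes = probes[probes["participant"] == pid]
        p_trials = trials[trials["participant"] == pid].set_index(["block", "trial"])

        rows = []   # (label, run, trial, theta_mean, is_localizer, is_final)
        for block in sorted(p_probes["block"].unique()):
            seq = _block_sequence(p_probes[p_probes["block"] == block], p_trials)
            rows += [(lab, f"task{block}", tr, tm, False, fin)
                     for (lab, tr, tm, fin) in seq]
        # ongoing-task localizer: 8 pseudo-trials of 6-9 OG probes + ITIs
        for _ in range(8):
            n = int(rng.integers(6, 10))
            rows += [("og", "loc_og", -1, 0.5, True, False)] * n
            rows += [("", "loc_og", -1, 0.5, True, False)]
            rows += [("rest", "loc_og", -1, 0.5, True, False)] * (ITI_TRS - 2)
            rows += [("", "loc_og", -1, 0.5, True, False)]
        # face/scene localizer: alternating mini-blocks of 11 samples
        for i in range(6):
            lab = "face" if i % 2 == 0 else "scene"
            rows += [(lab, "loc_fs", -1, 0.5, True, False)] * 11
            rows += [("", "loc_fs", -1, 0.5, True, False)]
            rows += [("rest", "loc_fs", -1, 0.5, True, False)] * (ITI_TRS - 2)
            rows += [("", "loc_fs", -1, 0.5, True, False)]

        labels = np.array([r[0] for r in rows])
        run = np.array([r[1] for r in rows])
        trial_id = np.array([r[2] for r in rows])
        theta_mean = np.array([r[3] for r in rows])
        is_loc = np.array([r[4] for r in rows])
        is_fin = np.array([r[5] for r in rows])

        n = len(rows)
        X = rng.normal(0.0, 1.0, (n, nparams.n_features))
        lag = nparams.lag_trs
        for t in range(n):
            src = t - lag
            if src < 0 or run[src] != run[t]:
                continue
            lab = labels[src]
            if lab == "":
                continue
            X[t] += nparams.snr * tpl[lab]
            if lab in ("face", "scene") and trial_id[src] >= 0:
                X[t] += nparams.coupling * (theta_mean[src] - 0.5) * tpl[lab]

        out[pid] = NeuralDataset(
            X=X, labels=labels, run=run, trial=trial_id,
            is_localizer=is_loc, is_final_probe=is_fin,
            tr=nparams.tr, lag_trs=lag,
        )
    return out


def simulate_balanced_neural(
    n_per_class: int = 60,
    n_runs: int = 4,
    nparams: NeuralSynthParams | None = None,
    seed=None,
) -> NeuralDataset:
    """Balanced 4-class dataset for decoder calibration.

    Every run holds exactly ``n_per_class / n_runs`` samples of each class
    (``n_per_class`` must be divisible by ``n_runs``), with no label lag and
    no strategy coupling — the setting in which scrambled-label chance is
    exactly 25%.
    """
    if nparams is None:
        nparams = NeuralSynthParams()
    if n_per_class % n_runs:
        raise ValueError("n_per_class must be divisible by n_runs")
    rng = np.random.default_rng(seed)
    tpl = _templates(nparams.n_features, rng)
    per_run = n_per_class // n_runs
    labels, run = [], []
    for r in range(n_runs):
        block = [c for c in CLASSES for _ in range(per_run)]
        rng.shuffle(block)
        labels += block
        run += [f"run{r + 1}"] * len(block)
    labels = np.array(labels)
    run = np.array(run)
    X = rng.normal(0.0, 1.0, (len(labels), nparams.n_features))
    for c in CLASSES:
        X[labels == c] += nparams.snr * tpl[c]
    n = len(labels)
    return NeuralDataset(
        X=X, labels=labels, run=run,
        trial=np.full(n, -1), is_localizer=np.zeros(n, bool),
        is_final_probe=np.zeros(n, bool),
        tr=nparams.tr, lag_trs=0, labels_aligned=True,
    )
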