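"""End-to-end orchestration: design → simulate → cost → trial fits → decode →
inference, reproducible from a config and a master seed.

Stage seeds are derived from the master seed with a counter-based
``SeedSequence`` scheme so any stage can be re-run independently.  All stage
outputs are TSV/JSON, stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pmflex import mvpa, pm_cost, strategy_inference, synthetic_cohort, task_design
from pmflex.synthetic_cohort import NeuralSynthParams, SynthParams
from pmflex.task_design import RESPONSE_DEADLINE_S

logger = logging.getLogger(__name__)

#: fixed stage counters for per-stage seed derivation
_STAGES = ("design", "cohort", "neural", "trialfit", "inference", "decode")


class SchemaReport(list):
    """List of human-readable schema violations; empty means valid."""

    @property
    def ok(self) -> bool:
        return not self


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    seed: int = 0
    synth: SynthParams = field(default_factory=SynthParams)
    neural: NeuralSynthParams = field(default_factory=NeuralSynthParams)
    n_boot: int = 2000
    n_perm: int = 100
    n_neural_participants: int = 0      # 0 disables the decoding stage
    out_dir: str = "pmflex_run"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "synth": self.synth.asdict(),
            "neural": self.neural.asdict(),
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "n_neural_participants": self.n_neural_participants,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = SynthParams(**d["synth"])
        if "neural" in d:
            d["neural"] = NeuralSynthParams(**d["neural"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Counter-based per-stage seed derivation from the master seed."""
    return np.random.SeedSequence(master_seed, spawn_key=(_STAGES.index(stage),))


def validate_events(events: pd.DataFrame) -> SchemaReport:
    """Schema checks on a probe-level event table.

    Verifies required columns, difficulty levels in 1–15, RTs within the
    (0, 1.9] s response window, and per-trial probe numbering; violations are
    reported with row numbers.
    """
    report = SchemaReport()
    required = {"block", "trial", "probe", "condition", "pm_type",
                "difficulty_level"}
    missing = required - set(events.columns)
    if missing:
        report.append(f"missing columns: {sorted(missing)}")
        return report

    bad_level = ~events["difficulty_level"].between(1, 15)
    for i in events.index[bad_level]:
        report.append(
            f"row {i}: difficulty_level {events.at[i, 'difficulty_level']} "
            "outside 1-15")
    if "rt" in events.columns:
        rt = events["rt"]
        bad_rt = rt.notna() & ~((rt > 0) & (rt <= RESPONSE_DEADLINE_S))
        for i in events.index[bad_rt]:
            report.append(
                f"row {i}: rt {events.at[i, 'rt']} outside "
                f"(0, {RESPONSE_DEADLINE_S}] s")
    for (b, t), g in events.groupby(["block", "trial"]):
        probes = np.sort(g["probe"].to_numpy())
        if not np.array_equal(probes, np.arange(1, len(probes) + 1)):
            report.append(f"block {b} trial {t}: probe numbering not 1..n")
    return report


def _stamp(path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        json.dump({"config_hash": config.config_hash, "seed": config.seed,
                   "config": config.to_dict()}, fh, indent=2)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the in-memory report: condition slope means, best-fit
    proportions, bootstrap coefficient tables, and (when the decoding stage
    is enabled) the per-trial PM intention evidence and model comparison.
    Outputs are byte-identical across runs with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash, "seed": config.seed}

    stage = "design"
    try:
        design = task_design.generate_session(
            config.synth.n_blocks, stage_seed(config.seed, "design"))
        design.save(out / "design.tsv")

        stage = "cohort"
        synth = dataclasses.replace(
            config.synth,
            seed=int(stage_seed(config.seed, "cohort").generate_state(1)[0] % 2**31),
        )
        probes, trials = synthetic_cohort.simulate_cohort(synth, design=design)
        probes.to_csv(out / "probes.tsv", sep="\t", index=False)

        stage = "cost"
        filtered = pm_cost.filter_responses(probes)
        summary, profiles = pm_cost.summarize_trials(filtered)
        summary.to_csv(out / "trials.tsv", sep="\t", index=False)
        profiles["level_cost"].to_csv(out / "level_cost.tsv", sep="\t",
                                      index=False)
        report["condition_slopes"] = (
            profiles["condition_slopes"].set_index("condition")["mean_slope"]
            .to_dict())
        report["cost_level_trend"] = profiles["cost_level_trend"]
        report["n_participants"] = int(summary["participant"].nunique())

        stage = "trialfit"
        from pmflex import trial_models
        pm_probe_costs = _pm_probe_costs(filtered)
        fits = trial_models.fit_cohort_trials(pm_probe_costs)
        fits.to_csv(out / "fits.tsv", sep="\t", index=False)
        _, cohort_fit = trial_models.best_fit_proportions(fits)
        cohort_fit.to_csv(out / "best_fit.tsv", sep="\t", index=False)
        report["best_fit"] = cohort_fit.to_dict("records")

        stage = "inference"
        seed = int(stage_seed(config.seed, "inference").generate_state(1)[0]
                   % 2**31)
        try:
            models = strategy_inference.slope_accuracy_model(
                summary, n_iter=config.n_boot, rng_seed=seed)
        except strategy_inference.BootstrapError as e:
            # degenerate at very small cohort sizes; report and continue
            logger.warning("inference skipped: %s", e)
            models = {}
            report["inference_warning"] = str(e)
        if models:
            coef_tables = {k: v.to_frame() for k, v in models.items()}
            pd.concat(coef_tables, names=["model"]).to_csv(
                out / "inference.tsv", sep="\t")
        report["inference"] = {
            k: v.to_frame().to_dict("records") for k, v in models.items()}

        if config.n_neural_participants > 0:
            stage = "decode"
            seed_seq = stage_seed(config.seed, "decode")
            pids = sorted(probes["participant"].unique())
            pids = pids[: config.n_neural_participants]
            datasets = synthetic_cohort.simulate_neural(
                probes, trials, config.neural, seed=seed_seq,
                participants=pids)
            ev_frames = []
            for pid, ds in datasets.items():
                try:
                    result = mvpa.crossvalidate(ds)
                except ValueError as e:
                    # a single-block session has no run rotation to decode
                    logger.warning("decoding skipped for participant %s: %s",
                                   pid, e)
                    report.setdefault("decode_warning", str(e))
                    continue
                # neural trial ids are globally unique: block * 1000 + trial
                p_design = trials[trials["participant"] == pid].assign(
                    trial=lambda d: d["block"] * 1000 + d["trial"]
                )[["trial", "pm_type"]]
                ev = mvpa.pm_intention_evidence(result.evidence, p_design)
                s = ev["trial_summary"].copy()
                s.insert(0, "participant", pid)
                ev_frames.append(s)
            if ev_frames:
                trial_ev = pd.concat(ev_frames, ignore_index=True)
                trial_ev.to_csv(out / "trial_ev.tsv", sep="\t", index=False)
                report["mean_pm_ev"] = float(trial_ev["mean_ev"].mean())
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise

    _stamp(out / "run.json", config)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _pm_probe_costs(filtered_probes: pd.DataFrame) -> pd.DataFrame:
    """Probe-level PM-cost table for the per-trial polynomial fits."""
    frames = []
    probes = filtered_probes.copy()
    if "participant" not in probes.columns:
        probes["participant"] = 0
    for pid, g in probes.groupby("participant"):
        baselines = pm_cost.compute_baselines(g)
        pm = g[g["pm_type"] != "non_pm"]
        annotated = pm_cost.probe_costs(pm, baselines)
        annotated.loc[annotated["is_final_probe"], "cost"] = np.nan
        annotated.loc[annotated["og_correct"] != 1, "cost"] = np.nan
        frames.append(annotated)
    return pd.concat(frames, ignore_index=True)
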