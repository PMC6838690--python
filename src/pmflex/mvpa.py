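"""Simplified decoding of PM intention states from feature time series.

Four one-vs-rest L2-penalised logistic classifiers (face / scene / ongoing
task / rest) are trained on localizer data plus all-but-one task run and
tested on the held-out run, rotating until every run is scored once.  Feature
screening (a one-way ANOVA across the four classes, p < 0.05) is refit inside
each fold.  Each classifier emits a probability-scale evidence value for its
own class — the four values need not sum to one — and the predicted class is
the argmax.  Per-trial PM intention evidence (PM EV) is the mean difference
between evidence for the PM target's category and the nontarget category;
scrambled-label refits give the empirical chance distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from pmflex.synthetic_cohort import CLASSES, NeuralDataset

logger = logging.getLogger(__name__)

DEFAULT_PENALTY = 50.0      # ridge weight on the squared-coefficient term
SCREEN_ALPHA = 0.05


class TrainingError(RuntimeError):
    """A class is absent from the training rows."""


def screen_features(
    X: np.ndarray,
    labels: np.ndarray,
    alpha: float = SCREEN_ALPHA,
) -> np.ndarray:
    """Indices of features whose class means differ (one-way ANOVA p < alpha).

    Features are z-scored across time points first; zero-variance features
    are excluded with a warning.
    """
    sd = X.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("excluding %d zero-variance features", zero_var.sum())
    Z = (X - X.mean(axis=0)) / np.where(zero_var, 1.0, sd)
    groups = [Z[labels == c] for c in CLASSES if (labels == c).any()]
    _, p = stats.f_oneway(*groups)
    keep = (p < alpha) & ~zero_var
    return np.flatnonzero(keep)


@dataclass
class OvrClassifiers:
    """One ridge-logistic model per class plus the fold's preprocessing."""

    models: dict
    feature_idx: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def evidence(self, X: np.ndarray) -> pd.DataFrame:
        """Probability-scale evidence per class (not normalised across
        classes); predicted class is the argmax, ties broken in fixed class
        order (face, scene, og, rest)."""
        Z = (X - self.mean) / self.sd
        Z = Z[:, self.feature_idx]
        ev = pd.DataFrame(
            {c: self.models[c].predict_proba(Z)[:, 1] for c in CLASSES})
        ev["predicted"] = ev[list(CLASSES)].to_numpy().argmax(axis=1)
        ev["predicted"] = [CLASSES[i] for i in ev["predicted"]]
        return ev


def train_ovr_classifiers(
    X: np.ndarray,
    labels: np.ndarray,
    penalty: float = DEFAULT_PENALTY,
    alpha: float = SCREEN_ALPHA,
) -> OvrClassifiers:
    """Train the four one-vs-rest classifiers with in-fold screening.

    ``penalty`` is the weight on the squared-coefficient (ridge) term of the
    logistic loss; scikit-learn's inverse-strength convention maps to
    ``C = 1/penalty``.  ``alpha=None`` disables feature screening (used by
    the leakage regression test, which screens outside the folds).
    """
    present = set(labels)
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise TrainingError(f"classes absent from training data: {missing}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    if alpha is None:
        idx = np.arange(X.shape[1])
    else:
        idx = screen_features(X, labels, alpha=alpha)
    if idx.size == 0:
        logger.info("feature screening kept nothing; using all features")
        idx = np.arange(X.shape[1])
    Zs = Z[:, idx]
    models = {}
    for c in CLASSES:
        clf = LogisticRegression(C=1.0 / penalty, solver="lbfgs",
                                 max_iter=2000)
        clf.fit(Zs, (labels == c).astype(int))
        models[c] = clf
    return OvrClassifiers(models=models, feature_idx=idx, mean=mean, sd=sd)


@dataclass
class DecodingResult:
    """Cross-validated evidence series and summary scores."""

    evidence: pd.DataFrame      # one row per scored test sample
    accuracy: float
    auc: dict                   # per-class one-vs-rest AUC


def _labeled(ds: NeuralDataset) -> np.ndarray:
    return ds.labels != ""


def crossvalidate(
    dataset: NeuralDataset,
    penalty: float = DEFAULT_PENALTY,
    alpha: float = SCREEN_ALPHA,
    max_folds: int | None = None,
) -> DecodingResult:
    """Leave-one-task-run-out decoding with localizer augmentation.

    Localizer rows are always in the training set; final-probe samples (the
    PM target reappearance) are excluded from training but still scored.
    Every labeled task sample is scored exactly once.  ``max_folds`` caps the
    rotation (the remaining runs are then never test runs) — used by the
    scrambled baseline to keep permutation loops affordable.
    """
    ds = dataset.aligned()
    task_runs = sorted(set(ds.run[~ds.is_localizer]))
    if len(task_runs) < 2:
        raise ValueError(
            "need at least two task runs for leave-one-run-out; "
            "split the data into runs")
    test_runs = task_runs if max_folds is None else task_runs[:max_folds]

    labeled = _labeled(ds)
    rows = []
    for run in test_runs:
        is_test = (ds.run == run) & ~ds.is_localizer
        train = labeled & ~is_test & ~ds.is_final_probe
        if max_folds is not None:
            # un-tested runs stay in training
            pass
        clf = train_ovr_classifiers(ds.X[train], ds.labels[train],
                                    penalty=penalty, alpha=alpha)
        score = is_test & labeled
        ev = clf.evidence(ds.X[score])
        ev["label"] = ds.labels[score]
        ev["run"] = run
        ev["trial"] = ds.trial[score]
        ev["is_final_probe"] = ds.is_final_probe[score]
        ev["time_s"] = np.flatnonzero(score) * ds.tr
        rows.append(ev)
    evidence = pd.concat(rows, ignore_index=True)

    accuracy = float((evidence["predicted"] == evidence["label"]).mean())
    auc = {}
    for c in CLASSES:
        truth = (evidence["label"] == c).astype(int)
        if truth.nunique() == 2:
            auc[c] = float(roc_auc_score(truth, evidence[c]))
        else:
            auc[c] = np.nan
    return DecodingResult(evidence=evidence, accuracy=accuracy, auc=auc)


def scrambled_baseline(
    dataset: NeuralDataset,
    n_perm: int = 1000,
    rng_seed=None,
    penalty: float = DEFAULT_PENALTY,
    alpha: float = SCREEN_ALPHA,
    max_folds: int | None = None,
) -> dict:
    """Empirical chance distribution from within-run label permutation.

    Class labels are permuted within each run (preserving per-run class
    counts and the guard/labeled structure), the cross-validation pipeline is
    re-run, and the accuracy recorded.  Returns the accuracy array, its mean,
    and the standard error of the mean.
    """
    rng = np.random.default_rng(rng_seed)
    base = dataset.aligned()
    accs = np.empty(n_perm)
    for i in range(n_perm):
        labels = base.labels.copy()
        for run in np.unique(base.run):
            m = (base.run == run) & (labels != "")
            labels[m] = rng.permutation(labels[m])
        perm = NeuralDataset(
            X=base.X, labels=labels, run=base.run, trial=base.trial,
            is_localizer=base.is_localizer,
            is_final_probe=base.is_final_probe,
            tr=base.tr, lag_trs=base.lag_trs, labels_aligned=True,
        )
        accs[i] = crossvalidate(perm, penalty=penalty, alpha=alpha,
                                max_folds=max_folds).accuracy
    return {
        "accuracies": accs,
        "mean": float(accs.mean()),
        "sem": float(accs.std(ddof=1) / np.sqrt(n_perm)),
    }


def pm_intention_evidence(
    evidence: pd.DataFrame,
    trials: pd.DataFrame,
    tr: float = 2.0,
) -> dict:
    """Per-trial PM intention evidence from a cross-validated evidence table.

    For a PM trial whose target category is face, PM EV at a time point is
    ``evidence(face) − evidence(scene)`` (and vice versa for scene targets);
    the final (target-reappearance) probe is excluded.  Returns the per-trial
    summary (mean EV and within-trial EV slope in EV/s), the EV-by-difficulty
    profile when a ``difficulty_level`` column is present, and the time-point
    EV series.
    """
    ev = evidence[~evidence["is_final_probe"]].copy()
    ev = ev[ev["trial"] >= 0]

    pm_trials = trials[trials["pm_type"].isin(["face", "scene"])]
    target = pm_trials.set_index("trial")["pm_type"]
    ev = ev[ev["trial"].isin(target.index)]
    tgt = ev["trial"].map(target)
    nontgt = tgt.map({"face": "scene", "scene": "face"})
    face = ev["face"].to_numpy()
    scene = ev["scene"].to_numpy()
    ev["pm_ev"] = np.where(tgt == "face", face - scene, scene - face)
    ev["target_class"] = tgt.to_numpy()
    ev["nontarget_class"] = nontgt.to_numpy()

    rows = []
    for trial, g in ev.groupby("trial"):
        t = g["time_s"].to_numpy(float)
        y = g["pm_ev"].to_numpy(float)
        slope = np.nan
        if len(g) >= 2 and np.ptp(t) > 0:
            slope = float(np.polyfit(t - t.min(), y, 1)[0])
        rows.append(dict(trial=trial,
                         pm_target_class=g["target_class"].iloc[0],
                         mean_ev=float(y.mean()),
                         ev_slope=slope,
                         n_samples=len(g)))
    summary = pd.DataFrame(rows)

    by_difficulty = None
    if "difficulty_level" in ev.columns:
        by_difficulty = (ev.groupby("difficulty_level")["pm_ev"]
                         .mean().rename("mean_ev").reset_index())
    return {"trial_summary": summary, "series": ev,
            "by_difficulty": by_difficulty}
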