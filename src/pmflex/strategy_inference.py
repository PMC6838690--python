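"""Participant-level bootstrap inference linking strategy shifts to PM accuracy.

Because single participants contribute few PM trials, inference pools trials
across the cohort: on each bootstrap iteration the full participant count is
resampled with replacement, their trials pooled, and pooled fixed-effect
logistic models of PM hit/miss are fit.  Percentile confidence intervals and
two-sided bootstrap p-values summarise the coefficient distributions.  Model
comparison converts per-iteration AIC scores to Akaike weights (wAIC) and
contrasts behavior-only, neural-only, and combined predictor models with
Wilcoxon signed-rank statistics.

The logistic fits inside bootstrap loops use an in-package Newton (IRLS)
solver for throughput; it reproduces ``statsmodels`` maximum-likelihood
estimates and is verified against them in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pmflex.trial_models import akaike_weights

logger = logging.getLogger(__name__)

MAX_DROP_FRACTION = 0.05    # a run fails if more iterations are dropped

#: trajectory condition -> trial direction
DIRECTION = {"inc_easy": "inc", "inc_mid": "inc",
             "dec_hard": "dec", "dec_mid": "dec", "fixed": "fix"}


class SeparationError(RuntimeError):
    """Quasi-separated logistic fit (diverging coefficients)."""


class BootstrapError(RuntimeError):
    """Too many bootstrap iterations failed."""


# ---------------------------------------------------------------------------
# fast logistic core

def logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    beta_cap: float = 30.0,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood logistic regression via Newton iterations.

    Returns ``(beta, loglik)``.  Raises :class:`SeparationError` when the
    outcome is constant, coefficients diverge beyond ``beta_cap`` (quasi
    separation), or the normal equations are singular.
    """
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise SeparationError("outcome is constant")
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            raise SeparationError("degenerate weights")
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError("singular information matrix") from e
        beta = beta + step
        if np.abs(beta).max() > beta_cap:
            raise SeparationError("coefficients diverged")
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    loglik = float(y @ np.log(mu + eps) + (1 - y) @ np.log(1 - mu + eps))
    return beta, loglik


def logit_aic(X: np.ndarray, y: np.ndarray) -> float:
    beta, ll = logit_irls(X, y)
    return 2 * X.shape[1] - 2 * ll


def mcfadden_r2(X: np.ndarray, y: np.ndarray) -> float:
    _, ll = logit_irls(X, y)
    p = y.mean()
    ll0 = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
    return 1.0 - ll / ll0


# ---------------------------------------------------------------------------
# bootstrap engine

@dataclass
class RegressionResult:
    """Bootstrap summary of one coefficient set.

    ``point`` holds the full-sample estimates, ``distribution`` the
    per-iteration bootstrap estimates; CIs are 2.5/97.5 percentiles and p is
    the two-sided bootstrap tail probability, floored at 1/n_iter.
    """

    names: list
    point: np.ndarray
    distribution: np.ndarray    # n_kept × n_coef
    n_iter: int
    n_dropped: int
    r_squared: float = np.nan

    @property
    def ci(self) -> np.ndarray:
        return np.percentile(self.distribution, [2.5, 97.5], axis=0).T

    @property
    def p_values(self) -> np.ndarray:
        d = self.distribution
        frac_le = (d <= 0).mean(axis=0)
        frac_ge = (d >= 0).mean(axis=0)
        p = 2.0 * np.minimum(frac_le, frac_ge)
        return np.clip(p, 1.0 / max(self.n_iter, 1), 1.0)

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame({
            "coef": self.names,
            "estimate": self.point,
            "boot_mean": self.distribution.mean(axis=0),
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.p_values,
        })


def bootstrap_participants(
    trials: pd.DataFrame,
    stat_fn,
    n_iter: int = 10000,
    rng_seed=None,
    max_drop_fraction: float = MAX_DROP_FRACTION,
):
    """Participant-resampling bootstrap of an arbitrary pooled statistic.

    On each iteration the full participant count is drawn with replacement,
    their trials pooled (a participant drawn twice contributes twice), and
    ``stat_fn(pooled_trials)`` evaluated.  Failing iterations (e.g.
    separation) are dropped and counted; the run fails if more than
    ``max_drop_fraction`` of iterations drop.

    Returns ``(stats_array, n_dropped)``.
    """
    rng = np.random.default_rng(rng_seed)
    pids = trials["participant"].unique()
    groups = {pid: g for pid, g in trials.groupby("participant")}
    out, n_dropped = [], 0
    for _ in range(n_iter):
        draw = rng.choice(pids, size=len(pids), replace=True)
        pooled = pd.concat([groups[pid] for pid in draw], ignore_index=True)
        try:
            out.append(stat_fn(pooled))
        except (SeparationError, np.linalg.LinAlgError, ValueError) as e:
            n_dropped += 1
            logger.debug("bootstrap iteration dropped: %s", e)
    if n_dropped > max_drop_fraction * n_iter:
        raise BootstrapError(
            f"{n_dropped}/{n_iter} bootstrap iterations failed")
    return np.asarray(out), n_dropped


def _prepare_slope_trials(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    if "direction" not in df.columns:
        df["direction"] = df["condition"].map(DIRECTION)
    df = df[df["pm_type"] != "non_pm"]
    df = df.dropna(subset=["cost_slope", "pm_hit"])
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    return df


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Design matrix with intercept for terms over slope / ev / direction.

    ``direction`` is coded dec = 1, inc = 0; interaction terms use ':'.
    """
    cols = [np.ones(len(df))]
    base = {
        "slope": lambda: df["cost_slope"].to_numpy(float),
        "ev": lambda: df["mean_ev"].to_numpy(float),
        "direction": lambda: (df["direction"] == "dec").to_numpy(float),
    }
    for t in terms:
        parts = t.split(":")
        v = base[parts[0]]()
        for p in parts[1:]:
            v = v * base[p]()
        cols.append(v)
    return np.column_stack(cols)


def slope_accuracy_model(
    trials: pd.DataFrame,
    n_iter: int = 2000,
    rng_seed=None,
    max_drop_fraction: float = MAX_DROP_FRACTION,
) -> dict:
    """Pooled logistic models of PM hit on PM cost slope, by trial direction.

    Fits hit ~ slope separately within increasing, decreasing (and, when
    present, fixed) trials plus the slope × direction interaction model on
    the dynamic trials.  All models share each bootstrap iteration's
    participant resample; CIs and p-values are percentile-based.  Returns a
    dict of :class:`RegressionResult` keyed ``'inc'``, ``'dec'``, ``'fix'``
    and ``'interaction'``.
    """
    df = _prepare_slope_trials(trials)

    # per-participant numpy arrays: (slope, hit, direction code)
    dir_code = {"inc": 0.0, "dec": 1.0, "fix": 2.0}
    arrays = {}
    for pid, g in df.groupby("participant"):
        arrays[pid] = (
            g["cost_slope"].to_numpy(float),
            g["pm_hit"].to_numpy(float),
            g["direction"].map(dir_code).to_numpy(float),
        )
    pids = np.array(list(arrays.keys()))

    directions = [d for d in ("inc", "dec", "fix")
                  if (df["direction"] == d).any()]

    def fit_one(name, slope, hit, dcode):
        if name == "interaction":
            m = dcode < 2.0  # dynamic trials only
            is_dec = (dcode[m] == 1.0).astype(float)
            X = np.column_stack([np.ones(m.sum()), slope[m], is_dec,
                                 slope[m] * is_dec])
        else:
            m = dcode == dir_code[name]
            X = np.column_stack([np.ones(m.sum()), slope[m]])
        beta, _ = logit_irls(X, hit[m])
        return beta

    full = tuple(np.concatenate([arrays[p][i] for p in pids])
                 for i in range(3))
    point, model_names = {}, []
    for name in directions + ["interaction"]:
        try:
            point[name] = fit_one(name, *full)
            model_names.append(name)
        except SeparationError as e:
            logger.warning("model %r not estimable on the full sample (%s); "
                           "skipped", name, e)

    rng = np.random.default_rng(rng_seed)
    dists = {name: [] for name in model_names}
    dropped = {name: 0 for name in model_names}
    for _ in range(n_iter):
        draw = rng.choice(pids, size=len(pids), replace=True)
        slope, hit, dcode = (
            np.concatenate([arrays[p][i] for p in draw]) for i in range(3))
        for name in model_names:
            try:
                dists[name].append(fit_one(name, slope, hit, dcode))
            except SeparationError as e:
                dropped[name] += 1
                logger.debug("bootstrap iteration dropped (%s): %s", name, e)
    for name in model_names:
        if dropped[name] > max_drop_fraction * n_iter:
            raise BootstrapError(
                f"{dropped[name]}/{n_iter} iterations failed for {name!r}")

    names_for = {d: ["intercept", "slope"] for d in directions}
    names_for["interaction"] = ["intercept", "slope", "direction",
                                "slope:direction"]
    results = {}
    for name in model_names:
        if name == "interaction":
            m = df["direction"].isin(["inc", "dec"])
            terms = ["slope", "direction", "slope:direction"]
        else:
            m = df["direction"] == name
            terms = ["slope"]
        sub = df[m]
        results[name] = RegressionResult(
            names=names_for[name],
            point=point[name],
            distribution=np.asarray(dists[name]),
            n_iter=n_iter, n_dropped=dropped[name],
            r_squared=mcfadden_r2(_design(sub, terms),
                                  sub["pm_hit"].to_numpy(float)),
        )
    return results


def partial_r2(
    trials: pd.DataFrame,
    control: str,
    focal: str = "cost_slope",
    outcome: str = "pm_hit",
) -> float:
    """Variance in PM accuracy explained by the focal predictor after
    residualising both it and the outcome on a control covariate.

    ``control`` names a column such as mean OG RT, mean OG accuracy, mean PM
    cost, or OG RT slope.  Linear (probability-scale) regressions are used
    for the residualisation.
    """
    df = trials.dropna(subset=[focal, outcome, control])
    c = df[control].to_numpy(float)
    if np.ptp(c) == 0:
        raise ValueError(f"control covariate {control!r} is constant")
    Z = np.column_stack([np.ones(len(df)), c])
    f = df[focal].to_numpy(float)
    y = df[outcome].to_numpy(float)
    rf = f - Z @ np.linalg.lstsq(Z, f, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.ptp(rf) == 0:
        return 0.0
    r = np.corrcoef(rf, ry)[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# behavior + neural model comparison

#: candidate model terms by family
_BEHAVIOR_MODELS = [
    ["slope"], ["direction"], ["slope", "direction"],
    ["slope", "direction", "slope:direction"],
]
_NEURAL_MODELS = [
    ["ev"], ["direction"], ["ev", "direction"],
    ["ev", "direction", "ev:direction"],
]
_FULL_MODEL = ["slope", "ev", "direction", "slope:ev", "slope:direction",
               "ev:direction", "slope:ev:direction"]


@dataclass
class ModelComparison:
    """Per-iteration Akaike weights of the three selected model families."""

    weights: pd.DataFrame       # columns combined / behavior / neural
    median_weights: pd.Series
    wilcoxon: pd.DataFrame
    median_ratios: pd.Series
    n_dropped: int = 0


def compare_predictor_models(
    trials: pd.DataFrame,
    n_iter: int = 1000,
    rng_seed=None,
) -> ModelComparison:
    """Bootstrap wAIC comparison of behavior-only, neural-only, and combined
    logistic models of PM accuracy.

    Per iteration the best (lowest-AIC) behavior-only model, best
    neural-only model, and the full combined model are scored and their AICs
    converted to Akaike weights.  Requires a ``mean_ev`` column (per-trial PM
    intention evidence); without it a behavior-only comparison is impossible
    and a ValueError names the missing metric.
    """
    df = _prepare_slope_trials(trials)
    if "mean_ev" not in df.columns or df["mean_ev"].isna().all():
        raise ValueError("trials lack the neural metric 'mean_ev'")
    df = df.dropna(subset=["mean_ev"])
    df = df[df["direction"].isin(["inc", "dec"])]

    def stat(pooled):
        y = pooled["pm_hit"].to_numpy(float)
        b_aic = min(logit_aic(_design(pooled, m), y) for m in _BEHAVIOR_MODELS)
        n_aic = min(logit_aic(_design(pooled, m), y) for m in _NEURAL_MODELS)
        c_aic = logit_aic(_design(pooled, _FULL_MODEL), y)
        return akaike_weights([c_aic, b_aic, n_aic])

    dist, dropped = bootstrap_participants(df, stat, n_iter=n_iter,
                                           rng_seed=rng_seed)
    weights = pd.DataFrame(dist, columns=["combined", "behavior", "neural"])

    wil_rows = []
    for a, b in itertools.combinations(weights.columns, 2):
        res = stats.wilcoxon(weights[a], weights[b])
        wil_rows.append(dict(model_a=a, model_b=b,
                             statistic=float(res.statistic),
                             p=float(res.pvalue)))
    ratios = pd.Series({
        "combined_vs_behavior": float(
            np.median(weights["combined"] / weights["behavior"])),
        "combined_vs_neural": float(
            np.median(weights["combined"] / weights["neural"])),
    })
    return ModelComparison(
        weights=weights,
        median_weights=weights.median(),
        wilcoxon=pd.DataFrame(wil_rows),
        median_ratios=ratios,
        n_dropped=dropped,
    )
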