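"""Per-trial polynomial model selection for the PM-cost trajectory.

Each dynamic trial's per-probe PM costs are regressed on ongoing-task
difficulty with first-, second-, and third-order polynomials.  Models are
compared with the Gaussian-likelihood AIC, ``n·ln(rss/n) + 2k``, optionally
with the small-sample correction AICc = AIC + 2k(k+1)/(n−k−1), and summarised
as Akaike weights.  A predominantly linear relationship indicates that
strategy shifts within a trial are fluid rather than an all-or-none switch
(which would favour a cubic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ORDERS = (1, 2, 3)


class DegenerateDesignError(ValueError):
    """Constant difficulty predictor: polynomial fit is undefined."""


@dataclass
class ModelFit:
    """One polynomial fit of cost on difficulty.

    ``k`` counts the polynomial coefficients, intercept, and the Gaussian
    error variance (k = order + 2).  ``fitted`` is False when the trial has
    too few points for the order (including the AICc guard n − k − 1 ≤ 0),
    in which case the model is disqualified from comparison.
    """

    order: int
    n: int
    rss: float = np.nan
    k: int = 0
    aic: float = np.nan
    aicc: float = np.nan
    weight: float = np.nan
    fitted: bool = False
    coef: np.ndarray | None = None


def _gaussian_aic(n: int, rss: float, k: int) -> float:
    rss = max(rss, 1e-300)  # guard exact fits
    return n * np.log(rss / n) + 2 * k


def aicc_correction(n: int, k: int) -> float:
    """Small-sample correction term 2k(k+1)/(n−k−1)."""
    return 2.0 * k * (k + 1) / (n - k - 1)


def fit_trial_polynomials(
    levels,
    costs,
    orders=ORDERS,
    min_points_cubic: int = 5,
) -> list[ModelFit]:
    """Least-squares polynomial fits of per-probe cost on difficulty level.

    NaN costs (unusable probes) are dropped.  Orders needing more support
    than available (order 3 below ``min_points_cubic`` points, or any order
    failing the AICc guard) are returned unfitted.  Raises
    :class:`DegenerateDesignError` when difficulty does not vary (fixed
    trials).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(costs, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) and np.ptp(x) == 0:
        raise DegenerateDesignError("difficulty level is constant on this trial")

    fits = []
    for order in orders:
        k = order + 2
        n = len(x)
        fit = ModelFit(order=order, n=n, k=k)
        enough = n >= order + 2 and n - k - 1 > 0
        if order == 3:
            enough = enough and n >= min_points_cubic
        if enough:
            coef = np.polyfit(x, y, order)
            resid = y - np.polyval(coef, x)
            fit.rss = float(resid @ resid)
            fit.aic = _gaussian_aic(n, fit.rss, k)
            fit.aicc = fit.aic + aicc_correction(n, k)
            fit.coef = coef
            fit.fitted = True
        fits.append(fit)

    scores = [f.aicc for f in fits if f.fitted]
    if scores:
        w = akaike_weights(scores)
        it = iter(w)
        for f in fits:
            if f.fitted:
                f.weight = next(it)
    return fits


def akaike_weights(scores) -> np.ndarray:
    """Normalised model weights w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    delta = scores - scores.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def fit_cohort_trials(
    pm_costs: pd.DataFrame,
    criterion: str = "aicc",
) -> pd.DataFrame:
    """Fit per-trial polynomials across a cohort cost table.

    ``pm_costs`` is a probe-level table of PM trials with ``cost`` and
    ``difficulty_level`` columns (final probes already excluded / NaN).
    Fixed-difficulty trials are skipped (constant predictor).  Returns one
    row per (trial, order) with scores and weights under ``criterion``.
    """
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    rows = []
    for (pid, block, trial), g in pm_costs.groupby(
            ["participant", "block", "trial"]):
        g = g[~g["is_final_probe"]]
        try:
            fits = fit_trial_polynomials(g["difficulty_level"], g["cost"])
        except DegenerateDesignError:
            continue
        scores = [getattr(f, criterion) for f in fits if f.fitted]
        if not scores:
            continue
        weights = akaike_weights(scores)
        it = iter(weights)
        for f in fits:
            rows.append(dict(
                participant=pid, block=block, trial=trial, order=f.order,
                n=f.n, rss=f.rss, score=getattr(f, criterion),
                weight=float(next(it)) if f.fitted else np.nan,
                fitted=f.fitted,
            ))
    return pd.DataFrame(rows)


def best_fit_proportions(
    fits: pd.DataFrame,
    ci_level: float = 0.95,
):
    """Per-participant winning-order proportions and mean Akaike weights.

    ``fits`` comes from :func:`fit_cohort_trials`.  Returns
    ``(per_participant, cohort)``: the former holds each participant's
    fraction of trials won by each order and mean weight per order; the
    latter cohort means with t-based confidence intervals.
    """
    fitted = fits[fits["fitted"]]
    idx = fitted.groupby(["participant", "block", "trial"])["score"].idxmin()
    winners = fitted.loc[idx]

    prop = (
        winners.groupby("participant")["order"]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    prop = prop.pivot_table(index="participant", columns="order",
                            values="proportion", fill_value=0.0)
    prop = prop.reindex(columns=list(ORDERS), fill_value=0.0)

    mean_w = (
        fitted.groupby(["participant", "order"])["weight"].mean()
        .unstack("order").reindex(columns=list(ORDERS))
    )

    per_participant = pd.concat(
        {"proportion": prop, "mean_weight": mean_w}, axis=1)

    rows = []
    for kind in ("proportion", "mean_weight"):
        for order in ORDERS:
            vals = per_participant[(kind, order)].dropna().to_numpy()
            m = vals.mean() if len(vals) else np.nan
            if len(vals) > 1:
                half = stats.t.ppf(0.5 + ci_level / 2, len(vals) - 1) * \
                    vals.std(ddof=1) / np.sqrt(len(vals))
            else:
                half = np.nan
            rows.append(dict(metric=kind, order=order, mean=m,
                             ci_low=m - half, ci_high=m + half))
    cohort = pd.DataFrame(rows)
    return per_participant, cohort


def bootstrap_model_selection(
    pm_costs: pd.DataFrame,
    n_iter: int = 1000,
    trials_per_type: int = 50,
    rng_seed=None,
) -> dict:
    """Super-subject bootstrap of polynomial model selection.

    Costs are z-scored within participant, all trials pooled, and on each
    iteration ``trials_per_type`` trials of each of the five trajectory
    conditions are drawn (without replacement when possible, otherwise with
    replacement, logged); orders 1–3 are fit to each pooled sample and the
    lowest-AIC order wins.  Returns per-condition selection fractions, the
    iteration table, and a 1-df chi-square of linear wins against the 1/3
    chance rate.
    """
    rng = np.random.default_rng(rng_seed)
    df = pm_costs[~pm_costs["is_final_probe"]].dropna(subset=["cost"]).copy()
    z = df.groupby("participant")["cost"].transform(
        lambda c: (c - c.mean()) / c.std(ddof=0))
    df["z_cost"] = z

    # pooled per-trial arrays by condition
    by_cond: dict[str, list] = {}
    for (cond, pid, block, trial), g in df.groupby(
            ["condition", "participant", "block", "trial"]):
        if g["difficulty_level"].nunique() < 2:
            continue
        by_cond.setdefault(cond, []).append(
            (g["difficulty_level"].to_numpy(float),
             g["z_cost"].to_numpy(float)))

    records = []
    for it in range(n_iter):
        for cond, pool in by_cond.items():
            replace = len(pool) < trials_per_type
            if replace and it == 0:
                logger.warning(
                    "condition %s has %d trials < %d: sampling with replacement",
                    cond, len(pool), trials_per_type)
            idx = rng.choice(len(pool), size=trials_per_type, replace=replace)
            x = np.concatenate([pool[i][0] for i in idx])
            y = np.concatenate([pool[i][1] for i in idx])
            aics = []
            for order in ORDERS:
                coef = np.polyfit(x, y, order)
                resid = y - np.polyval(coef, x)
                aics.append(_gaussian_aic(len(x), float(resid @ resid),
                                          order + 2))
            records.append(dict(iteration=it, condition=cond,
                                winning_order=ORDERS[int(np.argmin(aics))]))
    iterations = pd.DataFrame(records)
    fractions = (
        iterations.groupby("condition")["winning_order"]
        .value_counts(normalize=True).rename("fraction").reset_index()
    )
    n_linear = int((iterations["winning_order"] == 1).sum())
    n_total = len(iterations)
    chi2, p = stats.chisquare(
        [n_linear, n_total - n_linear],
        [n_total / 3.0, 2.0 * n_total / 3.0],
    )
    return {
        "fractions": fractions,
        "iterations": iterations,
        "chi2": float(chi2),
        "chi2_p": float(p),
        "n_linear": n_linear,
        "n_total": n_total,
    }
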