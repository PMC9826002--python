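"""Model-evaluation metrics and k-fold cross-validation at the cluster level.

Point metrics compare predicted and observed coverage proportions:
average bias (mean of predicted minus observed), RMSE, MAE and the Pearson
correlation.  Interval accuracy is the achieved coverage of equal-tailed 95%
posterior prediction intervals, and APV is the average posterior prediction
variance over grid cells (a precision summary — lower is better).

Cross-validation follows the survey structure: folds are random near-equal
splits of *clusters* (not children); for each fold the indicator datasets
are rebuilt from the training clusters only, the three models are refitted,
and held-out clusters are scored against their empirical proportions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import indicators as ind
from .data_model import ClusterDataset
from .geomodel import FitSettings, PriorSpec, fit, predict_surface

logger = logging.getLogger("vaxmono")

__all__ = [
    "EvalPairs",
    "point_metrics",
    "interval_coverage",
    "apv",
    "kfold_split",
    "crossvalidate",
    "direct_admin_estimates",
]


@dataclass
class EvalPairs:
    """Observed/predicted coverage pairs, optionally with interval limits."""

    observed: np.ndarray
    predicted: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, float)
        self.predicted = np.asarray(self.predicted, float)
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed and predicted must have equal length")
        if (self.lower is None) != (self.upper is None):
            raise ValueError("provide both interval limits or neither")
        if self.lower is not None:
            self.lower = np.asarray(self.lower, float)
            self.upper = np.asarray(self.upper, float)
            if np.any(self.lower > self.upper + 1e-12):
                raise ValueError("interval limits must satisfy lower <= upper")


def point_metrics(e: EvalPairs):
    """(avbias, rmse, mae, correlation) of predicted vs observed coverage."""
    resid = e.predicted - e.observed
    avbias = float(np.mean(resid))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    if len(e.observed) < 2 or np.std(e.observed) == 0 or np.std(e.predicted) == 0:
        warnings.warn("correlation undefined (fewer than 2 pairs or zero variance)")
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(e.observed, e.predicted).statistic)
    return avbias, rmse, mae, corr


def interval_coverage(e: EvalPairs) -> float:
    """Percent of observations inside their (closed) prediction interval."""
    if e.lower is None:
        raise ValueError("interval limits are required for interval_coverage")
    inside = (e.lower <= e.observed) & (e.observed <= e.upper)
    return float(100.0 * np.mean(inside))


def apv(draws: np.ndarray) -> float:
    """Average prediction variance: mean over cells of posterior Var{p(s)}."""
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[1] < 1:
        raise ValueError("expected an (S, L) matrix with at least one cell")
    return float(np.mean(np.var(draws, axis=0)))


def kfold_split(cluster_ids, k: int = 10, seed: int | None = None) -> np.ndarray:
    """Random partition of clusters into k near-equal folds (sizes differ by <= 1)."""
    ids = np.asarray(cluster_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of clusters ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    folds[perm] = np.arange(len(ids)) % k
    return folds


def _empirical_indicator(ds_ind) -> np.ndarray:
    return ds_ind.successes / ds_ind.trials


def _report_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    metric_cols = ["avbias", "rmse", "mae", "correlation", "coverage95"]
    mean_row = {"fold": "mean"}
    for c in metric_cols:
        mean_row[c] = df[c].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def crossvalidate(
    ds: ClusterDataset,
    approach: str,
    spec: PriorSpec,
    settings: FitSettings,
    k: int = 10,
    seed: int | None = None,
    reference: str = "first",
) -> dict[str, pd.DataFrame]:
    """k-fold CV of the three modeled indicators under one approach.

    Returns one report per modeled indicator: rows are folds plus a "mean"
    row, columns are the point metrics and achieved 95% interval coverage.
    Held-out clusters are scored against that indicator's own empirical
    proportion (eg y2/y1 for the first conditional), the quantity the model
    actually targets.  Folds with no valid rows for an indicator are skipped
    with a warning.
    """
    if approach not in ("CP", "RB"):
        raise ValueError(f"approach must be 'CP' or 'RB', got {approach!r}")
    seed = settings.seed if seed is None else seed
    folds = kfold_split(ds.cluster_id, k=k, seed=seed)
    build = ind.build_cp_datasets if approach == "CP" else ind.build_rb_datasets
    labels = [d.indicator for d in build(ds, reference)]
    rows: dict[str, list[dict]] = {lab: [] for lab in labels}
    for fold in range(k):
        train = ds.subset(folds != fold)
        test = ds.subset(folds == fold)
        train_sets = build(train, reference)
        test_sets = build(test, reference)
        for ds_train, ds_test in zip(train_sets, test_sets):
            if len(ds_train) < 3 or len(ds_test) == 0:
                warnings.warn(
                    f"fold {fold}: no usable rows for {ds_train.indicator}; skipped"
                )
                continue
            fr = fit(ds_train, spec, FitSettings(
                seed=seed * 1000 + fold, n_draws=settings.n_draws,
                burn=settings.burn, thin=settings.thin,
                ess_sweeps=settings.ess_sweeps, mh_step=settings.mh_step,
            ))
            draws = predict_surface(fr, ds_test, seed=seed * 1000 + fold + 1)
            pred = draws.mean(axis=0)
            lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
            e = EvalPairs(_empirical_indicator(ds_test), pred, lo, hi)
            avbias, rmse, mae, corr = point_metrics(e)
            rows[ds_train.indicator].append(
                {"fold": fold, "avbias": avbias, "rmse": rmse, "mae": mae,
                 "correlation": corr, "coverage95": interval_coverage(e)}
            )
    return {lab: _report_frame(r) for lab, r in rows.items() if r}


def direct_admin_estimates(ds: ClusterDataset, unit_of_cluster) -> pd.DataFrame:
    """Unweighted direct estimates sum(y)/sum(n) per admin unit and dose.

    ``unit_of_cluster`` maps cluster_id -> unit_id.  Units with zero total
    trials get missing values.  These design-based ratios are the usual
    comparator for the model-based admin aggregates.
    """
    unit = np.array([unit_of_cluster.get(c) for c in ds.cluster_id], dtype=object)
    assigned = np.array([x is not None for x in unit])
    out = []
    for u in pd.unique(unit[assigned]):
        mask = unit == u
        n_tot = ds.n[mask].sum()
        row = {"unit_id": u, "n": n_tot}
        for j, dose in enumerate(("p1", "p2", "p3")):
            row[dose] = ds.y[mask, j].sum() / n_tot if n_tot > 0 else np.nan
        out.append(row)
    return pd.DataFrame(out)
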