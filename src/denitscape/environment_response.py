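"""Environmental responses of denitrifier types and community deltas.

Two complementary analyses:

* MAG-level: relative abundances are standardized to each MAG's maximum
  observed value, a linear model per MAG yields slopes and standard
  errors against NO3- and chlorophyll (proxies for electron acceptor
  and donor supply), and inverse-variance weighting aggregates MAGs
  into a per-denitrifier-type mean response with a 95% CI. Types are
  said to differ when their CIs do not overlap.
* Community-level: random-forest models relate per-Gbp deltas to
  environmental predictors, after a collinearity pre-filter
  (Spearman rho > 0.7 or VIF > 4) and a 100-run stability selection;
  accumulated local effects (ALE) curves display each predictor's
  local effect on the prediction while respecting predictor
  correlation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger("denitscape")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MagResponse:
    """Per-MAG environmental slopes with standard errors."""

    mag_id: str
    denitrifier_type: str
    slopes: dict[str, float]
    ses: dict[str, float]
    max_rel_abundance: float = float("nan")


@dataclass(frozen=True)
class TypeResponse:
    denitrifier_type: str
    predictor: str
    weighted_mean: float
    ci_low: float
    ci_high: float
    n_mags: int


@dataclass
class ALECurve:
    feature: str
    grid: np.ndarray  # K+1 breakpoints
    effects: np.ndarray  # K centered accumulated effects (right bin edges)
    bin_counts: np.ndarray  # K


def standardize_abundance(
    abundance: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Divide each MAG row by its maximum across samples.

    Returns the standardized matrix (values in [0, 1], exactly one 1.0
    per non-degenerate MAG) and the list of all-zero MAGs, which are
    returned as zeros rather than NaN.
    """
    values = abundance.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("relative abundances must be non-negative")
    row_max = values.max(axis=1)
    flagged = [
        str(abundance.index[i]) for i in np.flatnonzero(row_max == 0)
    ]
    safe = np.where(row_max == 0, 1.0, row_max)
    out = pd.DataFrame(
        values / safe[:, None], index=abundance.index, columns=abundance.columns
    )
    return out, flagged


def fit_mag_env_response(
    std_abundance: pd.Series | np.ndarray,
    env: pd.DataFrame,
    mag_id: str = "",
    denitrifier_type: str = "",
    no3_col: str = "no3",
    chl_col: str = "chlorophyll",
) -> MagResponse:
    """OLS response of one MAG's standardized abundance to the gradients.

    Three slopes are reported: NO3- adjusting for chlorophyll and
    chlorophyll adjusting for NO3- (one joint model), and the natural
    log of the chlorophyll:NO3- ratio (a separate model). Zero
    concentrations are offset by half the smallest positive value of
    that variable before the ratio is formed.
    """
    y = np.asarray(std_abundance, dtype=float)
    n = len(y)
    if n < env.shape[1] + 2:
        raise ValueError(
            f"need at least {env.shape[1] + 2} samples for {env.shape[1]} "
            f"predictors, got {n}"
        )
    X = sm.add_constant(env[[no3_col, chl_col]].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design: {no3_col}, {chl_col} collinear")
    joint = sm.OLS(y, X).fit()

    no3 = _offset_zeros(env[no3_col].to_numpy(dtype=float))
    chl = _offset_zeros(env[chl_col].to_numpy(dtype=float))
    log_ratio = np.log(chl / no3)
    ratio_model = sm.OLS(y, sm.add_constant(log_ratio)).fit()

    slopes = {
        no3_col: float(joint.params[1]),
        chl_col: float(joint.params[2]),
        "log_ratio": float(ratio_model.params[1]),
    }
    ses = {
        no3_col: float(joint.bse[1]),
        chl_col: float(joint.bse[2]),
        "log_ratio": float(ratio_model.bse[1]),
    }
    return MagResponse(
        mag_id=mag_id, denitrifier_type=denitrifier_type, slopes=slopes, ses=ses
    )


def _offset_zeros(x: np.ndarray) -> np.ndarray:
    positive = x[x > 0]
    if len(positive) == 0:
        raise ValueError("variable has no positive values; cannot form log ratio")
    return np.where(x <= 0, positive.min() / 2, x)


def weighted_type_response(
    responses: Sequence[MagResponse],
    predictor: str,
    ci_method: str = "t",
) -> list[TypeResponse]:
    """Inverse-variance weighted mean response per denitrifier type.

    Weights are 1/SE^2. With ``ci_method="t"`` (default) the CI is the
    Knapp-Hartung interval — t quantile on k-1 degrees of freedom with
    the weighted-spread variance — which keeps close to nominal
    coverage for the small numbers of MAGs per type typical here;
    ``ci_method="normal"`` gives the plain mean +/- 1.96*sqrt(1/sum(w))
    interval. A single MAG always falls back to the normal interval on
    its own SE.
    """
    if ci_method not in ("t", "normal"):
        raise ValueError("ci_method must be 't' or 'normal'")
    by_type: dict[str, list[MagResponse]] = {}
    for r in responses:
        by_type.setdefault(r.denitrifier_type, []).append(r)
    out = []
    for t, members in by_type.items():
        betas = np.array([m.slopes[predictor] for m in members], float)
        ses = np.array([m.ses[predictor] for m in members], float)
        ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
        if not ok.any():
            raise ValueError(f"type {t!r}: no usable standard errors")
        w = 1.0 / ses[ok] ** 2
        k = int(ok.sum())
        mean = float((w * betas[ok]).sum() / w.sum())
        if ci_method == "t" and k > 1:
            var_kh = float((w * (betas[ok] - mean) ** 2).sum() / ((k - 1) * w.sum()))
            half = stats.t.ppf(0.975, k - 1) * math.sqrt(var_kh)
        else:
            half = Z95 * math.sqrt(1.0 / w.sum())
        out.append(
            TypeResponse(
                denitrifier_type=t,
                predictor=predictor,
                weighted_mean=mean,
                ci_low=mean - half,
                ci_high=mean + half,
                n_mags=int(ok.sum()),
            )
        )
    return out


def types_differ(a: TypeResponse, b: TypeResponse) -> bool:
    """Non-overlapping 95% CIs: the between-type difference criterion."""
    return a.ci_low > b.ci_high or b.ci_low > a.ci_high


# ---------------------------------------------------------------------------
# predictor screening


def _vif(X: np.ndarray, j: int) -> float:
    """Variance inflation factor of column j by auxiliary regression."""
    others = np.delete(X, j, axis=1)
    model = sm.OLS(X[:, j], sm.add_constant(others)).fit()
    r2 = min(model.rsquared, 1 - 1e-12)
    return 1.0 / (1.0 - r2)


def prefilter_collinear(
    env: pd.DataFrame,
    priority: Sequence[str],
    rho_max: float = 0.7,
    vif_max: float = 4.0,
) -> list[str]:
    """Drop collinear predictors before model fitting.

    Within each group of predictors linked by |Spearman rho| > rho_max
    (connected components), only the highest-priority member is kept;
    then predictors are iteratively removed — highest VIF first, lowest
    priority breaking ties — until all VIF <= vif_max. ``priority``
    must list every column, most important first.
    """
    cols = list(env.columns)
    missing = set(cols) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover: {sorted(missing)}")
    rank = {name: i for i, name in enumerate(priority)}

    rho = env.corr(method="spearman").abs().to_numpy()
    # connected components over the |rho| > rho_max graph
    keep = []
    unassigned = set(range(len(cols)))
    while unassigned:
        seed = min(unassigned)
        component = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in list(unassigned - component):
                if rho[i, j] > rho_max:
                    component.add(j)
                    frontier.append(j)
        unassigned -= component
        best = min(component, key=lambda i: rank[cols[i]])
        keep.append(cols[best])
    keep.sort(key=lambda name: rank[name])

    while len(keep) > 1:
        X = env[keep].to_numpy(dtype=float)
        vifs = {name: _vif(X, j) for j, name in enumerate(keep)}
        worst = max(vifs.values())
        if worst <= vif_max:
            break
        offenders = [name for name, v in vifs.items() if v == worst]
        drop = max(offenders, key=lambda name: rank[name])
        logger.info("dropping %s (VIF %.2f > %.2f)", drop, worst, vif_max)
        keep.remove(drop)
    return keep


# ---------------------------------------------------------------------------
# random-forest selection, tuning and ALE


def stability_select(
    X: pd.DataFrame,
    y: Sequence[float],
    n_runs: int = 100,
    retain_at: int = 95,
    seed: int = 0,
    n_trees: int = 100,
) -> list[str]:
    """Decoy-calibrated stability selection of forest predictors.

    Each run appends a shuffled decoy copy of every predictor, fits a
    random forest, computes out-of-bag permutation importance, and
    selects real predictors whose importance exceeds the largest decoy
    importance. Predictors selected in at least ``retain_at`` of
    ``n_runs`` runs are returned (in column order).
    """
    if n_runs < 1 or not 1 <= retain_at <= n_runs:
        raise ValueError("need 1 <= retain_at <= n_runs")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    hits = np.zeros(p, dtype=int)
    for _ in range(n_runs):
        decoys = Xv.copy()
        for j in range(p):
            decoys[:, j] = rng.permutation(decoys[:, j])
        Xaug = np.hstack([Xv, decoys])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(Xaug, y)
        importance = _oob_permutation_importance(forest, Xaug, y, rng)
        threshold = importance[p:].max()
        hits += importance[:p] > threshold
    return [cols[j] for j in range(p) if hits[j] >= retain_at]


def _oob_permutation_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation importance measured on the training predictions.

    Importance of feature j is the increase in mean squared error when
    column j is shuffled (one shuffle per feature)."""
    base = np.mean((forest.predict(X) - y) ** 2)
    importance = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        importance[j] = np.mean((forest.predict(Xp) - y) ** 2) - base
    return importance


@dataclass
class ForestFit:
    params: dict
    oob_rmse: float
    variance_explained: float
    model: RandomForestRegressor
    evaluated: list[tuple[dict, float]] = field(default_factory=list)


def tune_forest(
    X: pd.DataFrame,
    y: Sequence[float],
    grid: Sequence[Mapping[str, object]],
    n_trees: int = 500,
    seed: int = 0,
) -> ForestFit:
    """Grid-search forest hyperparameters by out-of-bag RMSE.

    Grid points are mappings with keys ``mtry`` (features tried per
    split), ``nodesize`` (minimum samples per leaf) and ``sampsize``
    (samples drawn per tree). Points with mtry exceeding the number of
    predictors are skipped with a warning. Returns the best fit plus
    every evaluated (params, oob_rmse) pair.
    """
    if not grid:
        raise ValueError("grid is empty")
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    best: ForestFit | None = None
    evaluated: list[tuple[dict, float]] = []
    for point in grid:
        mtry = int(point["mtry"])
        if mtry > p:
            logger.warning("skipping grid point %s: mtry > %d predictors", point, p)
            continue
        sampsize = int(point.get("sampsize", n))
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mtry,
            min_samples_leaf=int(point.get("nodesize", 5)),
            max_samples=min(sampsize, n) if sampsize < n else None,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse OOB coverage at small n
            forest.fit(Xv, y)
        oob = forest.oob_prediction_
        covered = ~np.isnan(oob)
        rmse = float(np.sqrt(np.mean((oob[covered] - y[covered]) ** 2)))
        evaluated.append((dict(point), rmse))
        if best is None or rmse < best.oob_rmse:
            best = ForestFit(
                params=dict(point),
                oob_rmse=rmse,
                variance_explained=float(1 - rmse**2 / np.var(y)),
                model=forest,
            )
    if best is None:
        raise ValueError("no valid grid point (all mtry > number of predictors)")
    best.evaluated = evaluated
    return best


def accumulated_local_effects(
    predict: Callable[[pd.DataFrame], np.ndarray],
    X: pd.DataFrame,
    feature: str,
    n_bins: int = 20,
) -> ALECurve:
    """First-order accumulated local effects of one numeric feature.

    The feature range is split at quantile breakpoints; within each bin
    the prediction difference between the bin's upper and lower edge is
    averaged with all other features held at their observed values;
    differences accumulate across bins and the curve is centered so the
    count-weighted mean effect is zero. Robust to correlated features
    because only within-bin, data-supported perturbations are used.
    """
    x = X[feature].to_numpy(dtype=float)
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError(f"feature {feature!r} has fewer than 2 distinct values")
    if len(distinct) <= n_bins:
        logger.warning(
            "feature %s: %d distinct values < %d bins; reducing",
            feature, len(distinct), n_bins,
        )
        grid = distinct.astype(float)
    else:
        quantiles = np.linspace(0, 1, n_bins + 1)
        grid = np.unique(np.quantile(x, quantiles))
    K = len(grid) - 1

    bin_idx = np.clip(np.searchsorted(grid, x, side="left") - 1, 0, K - 1)
    local = np.zeros(K)
    counts = np.zeros(K, dtype=int)
    for kbin in range(K):
        mask = bin_idx == kbin
        counts[kbin] = int(mask.sum())
        if counts[kbin] == 0:
            continue
        lo = X.loc[mask].copy()
        hi = X.loc[mask].copy()
        lo[feature] = grid[kbin]
        hi[feature] = grid[kbin + 1]
        local[kbin] = float(np.mean(predict(hi) - predict(lo)))
    cumulative = np.cumsum(local)
    center = float((counts * cumulative).sum() / counts.sum())
    return ALECurve(
        feature=feature,
        grid=grid,
        effects=cumulative - center,
        bin_counts=counts,
    )
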