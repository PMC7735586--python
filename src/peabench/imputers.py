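"""Imputation algorithms for MAR cells of an NPX dataset.

Four methods:

* ``mean``   — per-assay mean of non-MAR values (below-LOD zeros count).
* ``random`` — uniform draw with replacement from the assay's non-MAR values.
* ``rf``     — iterative random-forest imputation (missForest-style) with
  per-assay out-of-bag NRMSE estimates and a stop-on-divergence rule.
* ``gibbs``  — Gibbs sampler with elastic-net conditional means and
  truncated-normal draws (GSimp-style); truncation bounds are exposed
  for left-censored use and default to (-inf, +inf) for MAR cells.

Below-LOD cells are treated as observed data (zero-coded after LOD
subtraction).  Every imputer leaves OBSERVED and BELOW_LOD cells
bit-identical and is deterministic under its seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import DataModelError, NPXDataset

logger = logging.getLogger(__name__)

METHODS = ("mean", "random", "rf", "gibbs")


@dataclass
class RFParams:
    n_trees: int = 100
    max_iter: int = 10
    max_features: str | float = "sqrt"
    min_observed: int = 10


@dataclass
class GibbsParams:
    outer_iters: int = 10
    draws_per_cell: int = 1
    burn_in_fraction: float = 0.5
    lo: float | np.ndarray = -np.inf
    hi: float | np.ndarray = np.inf
    elastic_net_mixing: float = 0.5
    # "cv" for per-assay cross-validated penalty, or a fixed alpha
    regularization_selection: str | float = "cv"
    force_sigma: float | None = None
    min_observed: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in_fraction < 1:
            raise DataModelError("burn_in_fraction must be in [0, 1)")
        if np.any(np.asarray(self.lo) > np.asarray(self.hi)):
            raise DataModelError("truncation bounds must satisfy lo <= hi")


@dataclass
class ImputerSpec:
    method: str = "mean"
    seed: int = 0
    rf: RFParams = field(default_factory=RFParams)
    gibbs: GibbsParams = field(default_factory=GibbsParams)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DataModelError(f"unknown method {self.method!r}; choose from {METHODS}")


@dataclass
class ImputedDataset:
    """Completed matrix plus provenance.

    ``oob_nrmse`` maps assay_id to the out-of-bag NRMSE of the final
    random forest (rf method only); ``trace`` holds one convergence
    statistic per iteration for the iterative methods.
    """

    values: np.ndarray
    method: ImputerSpec
    oob_nrmse: dict[str, float] | None = None
    trace: list[float] = field(default_factory=list)
    converged: bool = True


def _check_columns(ds: NPXDataset, min_observed: int = 1) -> np.ndarray:
    """Non-MAR indicator; reject assays that cannot be imputed."""
    non_mar = ds.non_mar()
    counts = non_mar.sum(axis=0)
    has_mar = (~non_mar).any(axis=0)
    starved = has_mar & (counts < min_observed)
    if starved.any():
        bad = [ds.assay_ids[j] for j in np.where(starved)[0]]
        raise DataModelError(
            f"assay(s) with missing cells but < {min_observed} observed values: {bad}"
        )
    return non_mar


def _finalize(ds: NPXDataset, filled: np.ndarray, spec: ImputerSpec, **kw) -> ImputedDataset:
    non_mar = ds.non_mar()
    out = filled.copy()
    out[non_mar] = ds.values[non_mar]  # non-interference, bit-identical
    if not np.isfinite(out).all():
        raise DataModelError("imputer produced non-finite values")
    return ImputedDataset(values=out, method=spec, **kw)


def impute_mean(ds: NPXDataset, spec: ImputerSpec | None = None) -> ImputedDataset:
    """Fill each MAR cell with its assay's mean over non-MAR values."""
    spec = spec or ImputerSpec(method="mean")
    non_mar = _check_columns(ds)
    vals = ds.values.copy()
    vals[~non_mar] = np.nan
    col_means = np.nanmean(np.where(non_mar, vals, np.nan), axis=0)
    filled = np.where(non_mar, ds.values, np.broadcast_to(col_means, vals.shape))
    return _finalize(ds, filled, spec)


def impute_random(ds: NPXDataset, spec: ImputerSpec | None = None) -> ImputedDataset:
    """Fill each MAR cell with a uniform draw (with replacement) from
    its assay's non-MAR values."""
    spec = spec or ImputerSpec(method="random")
    non_mar = _check_columns(ds)
    rng = np.random.default_rng(spec.seed)
    filled = ds.values.copy()
    for j in range(ds.n_assays):
        mar_rows = np.where(~non_mar[:, j])[0]
        if mar_rows.size == 0:
            continue
        pool = ds.values[non_mar[:, j], j]
        filled[mar_rows, j] = rng.choice(pool, size=mar_rows.size, replace=True)
    return _finalize(ds, filled, spec)


def _mean_init(ds: NPXDataset, non_mar: np.ndarray) -> np.ndarray:
    col_means = np.nanmean(np.where(non_mar, ds.values, np.nan), axis=0)
    return np.where(non_mar, ds.values, np.broadcast_to(col_means, ds.values.shape))


def _column_order(non_mar: np.ndarray) -> list[int]:
    """Columns with missing cells, ascending missingness."""
    miss = (~non_mar).sum(axis=0)
    cols = np.where(miss > 0)[0]
    return list(cols[np.argsort(miss[cols], kind="stable")])


def impute_rf(ds: NPXDataset, spec: ImputerSpec | None = None) -> ImputedDataset:
    """Iterative random-forest imputation.

    Missing cells start at column means; assays are revisited in
    ascending-missingness order, each regressed on all other assays of
    the current completed matrix.  Iteration stops the first time the
    change statistic sum((X_new - X_old)^2) / sum(X_new^2) over imputed
    cells increases, returning the previous iterate, or at ``max_iter``
    with a warning.
    """
    from sklearn.ensemble import RandomForestRegressor

    spec = spec or ImputerSpec(method="rf")
    prm = spec.rf
    if ds.n_assays < 2:
        raise DataModelError("random-forest imputation needs >= 2 assays")
    non_mar = _check_columns(ds, prm.min_observed)
    cols = _column_order(non_mar)
    X = _mean_init(ds, non_mar)
    if not cols:
        return _finalize(ds, X, spec, oob_nrmse={}, trace=[])

    rng = np.random.default_rng(spec.seed)
    mar_cells = ~non_mar
    trace: list[float] = []
    prev_delta = np.inf
    prev_X = X.copy()
    prev_oob: dict[str, float] = {}
    oob: dict[str, float] = {}
    converged = False
    for _ in range(prm.max_iter):
        X_old = X.copy()
        oob = {}
        for j in cols:
            fit_rows = non_mar[:, j]
            pred_rows = ~fit_rows
            others = np.delete(np.arange(ds.n_assays), j)
            y = X[fit_rows, j]
            model = RandomForestRegressor(
                n_estimators=prm.n_trees,
                max_features=prm.max_features,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                model.fit(X[np.ix_(fit_rows, others)], y)
            X[pred_rows, j] = model.predict(X[np.ix_(pred_rows, others)])
            n = y.size
            var1 = y.var(ddof=1)
            if var1 > 0 and n > 1:
                # oob_score_ is R^2 with the n-denominator variance
                oob[ds.assay_ids[j]] = float(
                    np.sqrt(max(0.0, (1.0 - model.oob_score_) * (n - 1) / n))
                )
        num = float(((X - X_old)[mar_cells] ** 2).sum())
        den = float((X[mar_cells] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        trace.append(delta)
        if delta > prev_delta:
            X = prev_X  # diverged: keep previous iterate
            oob = prev_oob
            converged = True
            break
        prev_delta = delta
        prev_X = X.copy()
        prev_oob = dict(oob)
    else:
        logger.warning("rf imputation hit max_iter=%d without divergence", prm.max_iter)
    return _finalize(ds, X, spec, oob_nrmse=oob, trace=trace, converged=converged)


def truncnorm_draw(
    mu: np.ndarray | float,
    sigma: float,
    lo: np.ndarray | float,
    hi: np.ndarray | float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw from N(mu, sigma^2) conditioned on [lo, hi].

    ``sigma == 0`` returns mu clamped to the bounds.
    """
    if sigma < 0:
        raise DataModelError("sigma must be >= 0")
    mu = np.asarray(mu, dtype=float)
    lo_a = np.broadcast_to(np.asarray(lo, dtype=float), mu.shape if mu.shape else (1,))
    hi_a = np.broadcast_to(np.asarray(hi, dtype=float), mu.shape if mu.shape else (1,))
    if np.any(lo_a > hi_a):
        raise DataModelError("truncation bounds must satisfy lo <= hi")
    if sigma == 0:
        return np.clip(mu, lo_a, hi_a).reshape(mu.shape)
    a = (lo_a - mu) / sigma
    b = (hi_a - mu) / sigma
    out = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size or mu.shape or 1, random_state=rng)
    return np.asarray(out, dtype=float)


def _fit_elastic_net(X, y, prm: GibbsParams, seed: int):
    from sklearn.linear_model import ElasticNet, ElasticNetCV

    if prm.regularization_selection == "cv":
        import inspect

        # sklearn >= 1.7 replaced n_alphas with an integer `alphas`
        if "n_alphas" in inspect.signature(ElasticNetCV.__init__).parameters:
            grid = {"n_alphas": 10}
        else:
            grid = {"alphas": 10}
        model = ElasticNetCV(
            l1_ratio=prm.elastic_net_mixing,
            cv=3,
            max_iter=2000,
            random_state=seed,
            **grid,
        )
    else:
        model = ElasticNet(
            alpha=float(prm.regularization_selection),
            l1_ratio=prm.elastic_net_mixing,
            max_iter=2000,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def impute_gibbs_en(ds: NPXDataset, spec: ImputerSpec | None = None) -> ImputedDataset:
    """Gibbs sampler with elastic-net conditional means.

    Each sweep refits an elastic net per missing-value assay on the
    current completed matrix and replaces every MAR cell by a draw from
    a truncated normal centred at the elastic-net prediction, with sd
    equal to the root-mean-square deviation between fitted and observed
    values of that assay, truncated to [lo, hi] (no truncation at
    infinite bounds).  The returned value per cell is the mean of the
    post-burn-in draws.
    """
    spec = spec or ImputerSpec(method="gibbs")
    prm = spec.gibbs
    if ds.n_assays < 2:
        raise DataModelError("gibbs imputation needs >= 2 assays")
    non_mar = _check_columns(ds, prm.min_observed)
    cols = _column_order(non_mar)
    X = _mean_init(ds, non_mar)
    if not cols:
        return _finalize(ds, X, spec, trace=[])

    lo = np.broadcast_to(np.asarray(prm.lo, dtype=float), X.shape)
    hi = np.broadcast_to(np.asarray(prm.hi, dtype=float), X.shape)
    rng = np.random.default_rng(spec.seed)
    n_burn = int(np.ceil(prm.burn_in_fraction * prm.outer_iters))
    acc = np.zeros_like(X)
    n_acc = 0
    trace: list[float] = []
    for sweep in range(prm.outer_iters):
        X_old = X.copy()
        for j in cols:
            fit_rows = non_mar[:, j]
            pred_rows = ~fit_rows
            others = np.delete(np.arange(ds.n_assays), j)
            y = X[fit_rows, j]
            try:
                model = _fit_elastic_net(
                    X[np.ix_(fit_rows, others)], y, prm, int(rng.integers(2**31 - 1))
                )
                fitted = model.predict(X[np.ix_(fit_rows, others)])
                mu = model.predict(X[np.ix_(pred_rows, others)])
            except Exception as exc:  # pragma: no cover - defensive fallback
                logger.warning(
                    "elastic net failed for %s (%s); falling back to column mean",
                    ds.assay_ids[j],
                    exc,
                )
                fitted = np.full(y.shape, y.mean())
                mu = np.full(int(pred_rows.sum()), y.mean())
            sigma = float(np.sqrt(np.mean((y - fitted) ** 2)))
            if prm.force_sigma is not None:
                sigma = prm.force_sigma
            cell_lo = lo[pred_rows, j]
            cell_hi = hi[pred_rows, j]
            for _ in range(prm.draws_per_cell):
                draw = truncnorm_draw(mu, sigma, cell_lo, cell_hi, rng)
            X[pred_rows, j] = draw
        mar = ~non_mar
        trace.append(float(np.mean(np.abs(X[mar] - X_old[mar]))) if mar.any() else 0.0)
        if sweep >= n_burn:
            acc += X
            n_acc += 1
    result = acc / n_acc if n_acc else X
    result = np.where(non_mar, ds.values, result)
    return _finalize(ds, result, spec, trace=trace)


def impute(ds: NPXDataset, spec: ImputerSpec) -> ImputedDataset:
    """Dispatch to the imputer named by ``spec.method``."""
    fn = {
        "mean": impute_mean,
        "random": impute_random,
        "rf": impute_rf,
        "gibbs": impute_gibbs_en,
    }[spec.method]
    return fn(ds, spec)
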