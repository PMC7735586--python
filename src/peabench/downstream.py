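"""Simulation of imputation effects on univariate regression.

For each assay, an outcome Y = beta * x_complete + eps is simulated
repeatedly; the regression coefficient is re-estimated from the
complete data, the non-imputed data (complete-case: rows with missing
x dropped), and the two imputed versions, yielding power, bias and
average absolute difference relative to the complete-data estimate,
plus trend lines of each metric against per-assay imputation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataModelError

DATASETS = ("COMPLETE", "COMPLETE_CASE", "RF", "GIBBS")
SCENARIOS = ("PROTEIN_DEPENDENT", "PROTEIN_INDEPENDENT")


@dataclass
class SimConfig:
    beta: float = 0.01
    noise_sd: float = 1.0
    n_reps: int = 1000
    alpha: float = 0.05
    scenario: str = "PROTEIN_INDEPENDENT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataModelError("alpha must be in (0, 1)")
        if self.n_reps < 1:
            raise DataModelError("n_reps must be >= 1")
        if self.scenario not in SCENARIOS:
            raise DataModelError(f"scenario must be one of {SCENARIOS}")


@dataclass
class SimResult:
    """Per-assay downstream metrics, one entry per dataset."""

    assay_id: str
    scenario: str
    power: dict[str, float]
    bias: dict[str, float]
    avg_abs_diff: dict[str, float]
    est_variance: dict[str, float]


@dataclass
class TrendFit:
    metric: str
    dataset: str
    slope: float
    intercept: float
    crossing: float | None  # accuracy where this line meets COMPLETE_CASE's


def simulate_outcome(
    x_complete: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Y_i = beta * x_i + eps_i with iid Gaussian noise."""
    x = np.asarray(x_complete, dtype=float)
    if not np.isfinite(x).all():
        raise DataModelError("x_complete must be finite")
    return cfg.beta * x + rng.normal(0.0, cfg.noise_sd, size=x.shape)


def fit_univariate(
    x: np.ndarray, y: np.ndarray, scenario: str = "PROTEIN_INDEPENDENT"
) -> tuple[float, float, int]:
    """OLS slope and two-sided p-value, dropping rows with missing x.

    PROTEIN_INDEPENDENT regresses Y on x; PROTEIN_DEPENDENT regresses
    x on Y.  Returns (estimate, p_value, n_used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        raise DataModelError(f"only {n} jointly present pairs (< 3)")
    xs, ys = x[keep], y[keep]
    if scenario == "PROTEIN_INDEPENDENT":
        reg, out = xs, ys
    elif scenario == "PROTEIN_DEPENDENT":
        reg, out = ys, xs
    else:
        raise DataModelError(f"unknown scenario {scenario!r}")
    if reg.var(ddof=0) == 0:
        raise DataModelError("degenerate regressor")
    fit = stats.linregress(reg, out)
    return float(fit.slope), float(fit.pvalue), n


def run_simulation(
    x_complete: np.ndarray,
    x_masked: np.ndarray,
    x_rf: np.ndarray,
    x_gibbs: np.ndarray,
    cfg: SimConfig,
    assay_id: str = "",
) -> SimResult:
    """Repeat outcome simulation + four fits; aggregate per dataset.

    The four vectors must agree everywhere except at originally-masked
    positions (NaN in ``x_masked``).  Bias and average absolute
    difference are taken per-rep against the complete-data estimate of
    the same simulated outcome, then averaged.
    """
    vectors = {
        "COMPLETE": np.asarray(x_complete, dtype=float),
        "COMPLETE_CASE": np.asarray(x_masked, dtype=float),
        "RF": np.asarray(x_rf, dtype=float),
        "GIBBS": np.asarray(x_gibbs, dtype=float),
    }
    n = vectors["COMPLETE"].size
    for name, v in vectors.items():
        if v.size != n:
            raise DataModelError(f"{name} vector length mismatch")
    present = np.isfinite(vectors["COMPLETE_CASE"])
    for name in ("COMPLETE", "RF", "GIBBS"):
        if not np.allclose(vectors[name][present], vectors["COMPLETE_CASE"][present]):
            raise DataModelError(
                f"{name} differs from the masked vector at observed positions"
            )
    rng = np.random.default_rng(cfg.seed)
    ests = {d: np.empty(cfg.n_reps) for d in DATASETS}
    rejects = {d: np.zeros(cfg.n_reps, dtype=bool) for d in DATASETS}
    for r in range(cfg.n_reps):
        y = simulate_outcome(vectors["COMPLETE"], cfg, rng)
        for d in DATASETS:
            est, p, _ = fit_univariate(vectors[d], y, cfg.scenario)
            ests[d][r] = est
            rejects[d][r] = p < cfg.alpha
    ref = ests["COMPLETE"]
    return SimResult(
        assay_id=assay_id,
        scenario=cfg.scenario,
        power={d: float(rejects[d].mean()) for d in DATASETS},
        bias={d: float(np.mean(ests[d] - ref)) for d in DATASETS},
        avg_abs_diff={d: float(np.mean(np.abs(ests[d] - ref))) for d in DATASETS},
        est_variance={d: float(np.var(ests[d], ddof=1)) for d in DATASETS},
    )


def results_frame(results: list[SimResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for d in DATASETS:
            rows.append(
                {
                    "assay_id": r.assay_id,
                    "scenario": r.scenario,
                    "dataset": d,
                    "power": r.power[d],
                    "bias": r.bias[d],
                    "avg_abs_diff": r.avg_abs_diff[d],
                    "est_variance": r.est_variance[d],
                }
            )
    return pd.DataFrame(rows)


def calibrate_noise_sd(
    x_matrix: np.ndarray, beta: float, alpha: float = 0.05, target_power: float = 0.5
) -> float:
    """Pick the outcome noise sd that puts complete-data power near
    ``target_power`` for the median-spread assay (normal approximation
    of the slope test: ncp = beta * sd(x) * sqrt(n) / sigma)."""
    x = np.asarray(x_matrix, dtype=float)
    sd_x = float(np.median(np.nanstd(x, axis=0, ddof=1)))
    n = x.shape[0]
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_p = stats.norm.ppf(target_power)
    ncp = z_a + z_p  # power = Phi(ncp - z_a)
    if ncp <= 0:
        raise DataModelError("target power too low to calibrate")
    return float(abs(beta) * sd_x * np.sqrt(n) / ncp)


def trend_analysis(
    results: list[SimResult],
    accuracies: dict[str, float],
    frac_below_lod: dict[str, float],
    metrics: tuple[str, ...] = ("power", "bias", "avg_abs_diff"),
    lod_threshold: float = 0.25,
) -> list[TrendFit]:
    """Least-squares line of each downstream metric vs. imputation
    accuracy per dataset, over assays under the below-LOD threshold,
    plus the accuracy at which each imputed dataset's line crosses the
    complete-case line (reported only inside [0, 1])."""
    keep = [
        r
        for r in results
        if r.assay_id in accuracies
        and accuracies[r.assay_id] is not None
        and np.isfinite(accuracies[r.assay_id])
        and frac_below_lod.get(r.assay_id, 1.0) < lod_threshold
    ]
    if len(keep) < 5:
        raise DataModelError(
            f"trend analysis needs >= 5 assays below the LOD threshold, got {len(keep)}"
        )
    acc = np.array([accuracies[r.assay_id] for r in keep])
    if np.ptp(acc) <= 1e-12:
        raise DataModelError("degenerate accuracy spread")
    fits: list[TrendFit] = []
    lines: dict[tuple[str, str], tuple[float, float]] = {}
    for metric in metrics:
        for d in DATASETS:
            vals = np.array([getattr(r, metric)[d] for r in keep])
            slope, intercept = np.polyfit(acc, vals, 1)
            lines[(metric, d)] = (float(slope), float(intercept))
        for d in DATASETS:
            slope, intercept = lines[(metric, d)]
            crossing = None
            if d in ("RF", "GIBBS"):
                s_cc, i_cc = lines[(metric, "COMPLETE_CASE")]
                if abs(slope - s_cc) > 1e-12:
                    x_star = (i_cc - intercept) / (slope - s_cc)
                    if 0.0 <= x_star <= 1.0:
                        crossing = float(x_star)
            fits.append(TrendFit(metric, d, slope, intercept, crossing))
    return fits


def trend_frame(fits: list[TrendFit]) -> pd.DataFrame:
    df = pd.DataFrame([f.__dict__ for f in fits])
    for col in ("slope", "intercept", "crossing"):
        df[col] = df[col].astype(float)
    return df
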