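"""Accuracy metrics against ground truth and the benchmark experiments.

Per-assay metrics (Pearson, Spearman, NRMSE, relative variance) are
computed over evaluated MAR cells only; below-LOD cells never enter
accuracy metrics.  Both NRMSE and relative variance use the sample
(n-1) variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataModelError, GroundTruth, NPXDataset
from .imputers import ImputedDataset, ImputerSpec, impute
from .synthetic import SynthBundle, census_below_lod

MIN_EVAL_CELLS = 3


def nrmse(x_true: np.ndarray, x_imp: np.ndarray) -> float:
    """sqrt(mean((x_true - x_imp)^2) / var(x_true)), sample variance."""
    x_true = np.asarray(x_true, dtype=float)
    x_imp = np.asarray(x_imp, dtype=float)
    if x_true.shape != x_imp.shape or x_true.ndim != 1:
        raise DataModelError("nrmse expects two equal-length vectors")
    if x_true.size < 2:
        raise DataModelError("nrmse needs >= 2 values")
    v = x_true.var(ddof=1)
    if v <= 0:
        raise DataModelError("nrmse undefined: zero truth variance")
    return float(np.sqrt(np.mean((x_true - x_imp) ** 2) / v))


def rel_var(x_true: np.ndarray, x_imp: np.ndarray) -> float:
    """var(x_imp) / var(x_true), sample variances."""
    x_true = np.asarray(x_true, dtype=float)
    x_imp = np.asarray(x_imp, dtype=float)
    if x_true.shape != x_imp.shape or x_true.ndim != 1:
        raise DataModelError("rel_var expects two equal-length vectors")
    if x_true.size < 2:
        raise DataModelError("rel_var needs >= 2 values")
    v = x_true.var(ddof=1)
    if v <= 0:
        raise DataModelError("rel_var undefined: zero truth variance")
    if np.ptp(x_imp) == 0:
        # variance of a constant fill is zero by definition; np.var on
        # identical floats can leave rounding dust from the mean
        return 0.0
    return float(x_imp.var(ddof=1) / v)


@dataclass
class ProteinEvalRecord:
    assay_id: str
    pearson: float | None
    spearman: float | None
    nrmse: float | None
    rel_var: float | None
    frac_below_lod: float
    error_ratio: float | None
    n_eval_cells: int


def evaluate(
    imp: ImputedDataset,
    truth: GroundTruth,
    ds: NPXDataset,
    measurement_sd: dict[str, float] | None = None,
) -> list[ProteinEvalRecord]:
    """Score imputed values against truth, per assay, over eval cells.

    Metrics are absent (None) for assays with fewer than 3 eval cells,
    for zero truth variance (NRMSE, relative variance) or zero imputed
    variance (correlations).  ``measurement_sd`` (assay_id -> sd of a
    measurement-error reference) enables the imputation-vs-measurement
    error ratio RMS(imputed - truth) / sd.
    """
    if not truth.eval_mask.any():
        raise DataModelError("truth has an empty eval_mask")
    truth.check_against(ds)
    frac = census_below_lod(ds)
    records: list[ProteinEvalRecord] = []
    for j, aid in enumerate(ds.assay_ids):
        cells = truth.eval_mask[:, j]
        n = int(cells.sum())
        if n == 0:
            continue
        xt = truth.values[cells, j]
        xi = imp.values[cells, j]
        pe = sp = nr = rv = ratio = None
        if n >= MIN_EVAL_CELLS:
            if np.ptp(xt) > 0:
                nr = nrmse(xt, xi)
                rv = rel_var(xt, xi)
                if np.ptp(xi) > 0:
                    with np.errstate(all="ignore"):
                        import warnings as _w

                        with _w.catch_warnings():
                            _w.simplefilter("ignore")
                            pe = float(stats.pearsonr(xt, xi).statistic)
                            sp = float(stats.spearmanr(xt, xi).statistic)
                    if not np.isfinite(pe):
                        pe = None
                    if sp is not None and not np.isfinite(sp):
                        sp = None
            if measurement_sd is not None and aid in measurement_sd:
                sd = measurement_sd[aid]
                if sd > 0:
                    ratio = float(np.sqrt(np.mean((xi - xt) ** 2)) / sd)
        records.append(
            ProteinEvalRecord(
                assay_id=aid,
                pearson=pe,
                spearman=sp,
                nrmse=nr,
                rel_var=rv,
                frac_below_lod=float(frac[j]),
                error_ratio=ratio,
                n_eval_cells=n,
            )
        )
    return records


def records_frame(records: list[ProteinEvalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    for col in ("pearson", "spearman", "nrmse", "rel_var", "error_ratio"):
        if col in df:
            df[col] = df[col].astype(float)
    return df


# ---------------------------------------------------------------------------
# benchmark experiments
# ---------------------------------------------------------------------------


def _subset_columns(bundle: SynthBundle, cols: np.ndarray) -> tuple[NPXDataset, GroundTruth]:
    ds = bundle.observed
    sub = NPXDataset(
        values=ds.values[:, cols].copy(),
        mask=ds.mask[:, cols].copy(),
        assays=[ds.assays[j] for j in cols],
        samples=list(ds.samples),
    )
    gt = GroundTruth(
        values=bundle.truth.values[:, cols].copy(),
        eval_mask=bundle.truth.eval_mask[:, cols].copy(),
    )
    return sub, gt


def panel_subset_experiment(
    bundle: SynthBundle,
    target_panel: str,
    specs: list[ImputerSpec],
) -> pd.DataFrame:
    """Impute the target panel from itself plus one other panel at a
    time, and from all panels, scoring target-panel assays only.

    Returns a long table keyed by (condition, method, assay_id).
    """
    ds = bundle.observed
    panels = ds.panels()
    if target_panel not in panels:
        raise DataModelError(f"target panel {target_panel!r} absent")
    if len(panels) < 2:
        raise DataModelError("panel-subset experiment needs >= 2 panels")
    target_cols = ds.panel_columns(target_panel)
    target_ids = {ds.assay_ids[j] for j in target_cols}
    conditions: list[tuple[str, np.ndarray]] = []
    for p in panels:
        if p == target_panel:
            continue
        cols = np.sort(np.concatenate([target_cols, ds.panel_columns(p)]))
        conditions.append((p, cols))
    conditions.append(("ALL", np.arange(ds.n_assays)))

    rows = []
    for cond, cols in conditions:
        sub, gt = _subset_columns(bundle, cols)
        for spec in specs:
            imp = impute(sub, spec)
            for rec in evaluate(imp, gt, sub):
                if rec.assay_id in target_ids:
                    d = rec.__dict__.copy()
                    d["condition"] = cond
                    d["method"] = spec.method
                    rows.append(d)
    return pd.DataFrame(rows)


def _subset_rows(
    bundle: SynthBundle, rows: np.ndarray
) -> tuple[NPXDataset, GroundTruth]:
    ds = bundle.observed
    sub = NPXDataset(
        values=ds.values[rows].copy(),
        mask=ds.mask[rows].copy(),
        assays=list(ds.assays),
        samples=[ds.samples[i] for i in rows],
    )
    gt = GroundTruth(
        values=bundle.truth.values[rows].copy(),
        eval_mask=bundle.truth.eval_mask[rows].copy(),
    )
    return sub, gt


def sample_size_experiment(
    bundle: SynthBundle,
    chips_to_keep: list[int],
    specs: list[ImputerSpec],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-impute after restricting to subsets of chips, always keeping
    the masked chip.

    ``chips_to_keep`` lists chip counts (each >= 2).  For count k the
    masked chip plus the k-1 lowest-numbered other chips (on the masked
    panel) are retained.  Returns (eval table, paired signed-rank
    comparison table between imputer pairs per level).
    """
    if bundle.config.mar_chip is None:
        raise DataModelError("sample-size experiment needs a masked chip")
    panel, masked_chip = bundle.config.mar_chip
    ds = bundle.observed
    all_chips = ds.chips(panel)
    others = [c for c in all_chips if c != masked_chip]
    rows_out = []
    comparisons = []
    for k in sorted(chips_to_keep):
        if k < 2:
            raise DataModelError("need at least 2 chips per level")
        keep = {masked_chip, *others[: k - 1]}
        rows = np.array(
            [i for i, s in enumerate(ds.samples) if s.chip[panel] in keep]
        )
        sub, gt = _subset_rows(bundle, rows)
        per_method: dict[str, pd.DataFrame] = {}
        for spec in specs:
            imp = impute(sub, spec)
            df = records_frame(evaluate(imp, gt, sub))
            df["n_chips"] = k
            df["method"] = spec.method
            per_method[spec.method] = df
            rows_out.append(df)
        methods = list(per_method)
        for a in range(len(methods)):
            for b in range(a + 1, len(methods)):
                ma, mb = methods[a], methods[b]
                merged = per_method[ma].merge(
                    per_method[mb], on="assay_id", suffixes=("_a", "_b")
                )
                for metric in ("pearson", "rel_var"):
                    x = merged[f"{metric}_a"].astype(float)
                    y = merged[f"{metric}_b"].astype(float)
                    ok = x.notna() & y.notna() & (x != y)
                    p = np.nan
                    if ok.sum() >= 5:
                        p = float(stats.wilcoxon(x[ok], y[ok]).pvalue)
                    comparisons.append(
                        {
                            "n_chips": k,
                            "method_a": ma,
                            "method_b": mb,
                            "metric": metric,
                            "median_a": float(np.nanmedian(x)),
                            "median_b": float(np.nanmedian(y)),
                            "wilcoxon_p": p,
                            "n_pairs": int(ok.sum()),
                        }
                    )
    return pd.concat(rows_out, ignore_index=True), pd.DataFrame(comparisons)
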