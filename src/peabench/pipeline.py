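"""End-to-end benchmark pipeline on synthetic data.

generate -> (normalize) -> LOD subtraction -> QC report -> impute with
every configured method -> per-assay evaluation -> downstream
regression simulation -> summary and manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import DataModelError, GroundTruth, NPXDataset
from .downstream import (
    SimConfig,
    calibrate_noise_sd,
    results_frame,
    run_simulation,
    trend_analysis,
    trend_frame,
)
from .evaluation import evaluate, records_frame
from .imputers import ImputerSpec, GibbsParams, RFParams, impute
from .io import write_npx
from .preprocess import interplate_normalize, subtract_lod
from .qc import apply_mcar_mask, duplicate_concordance, flag_bad_chips, pca_outliers
from .synthetic import SynthConfig, generate

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class QCConfig:
    n_components: int = 2
    threshold_sd: float = 6.0
    chip_deviation_threshold: float = 0.5
    apply_flags: bool = False


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    normalize: bool = False
    normalize_scope: str = "per_assay"
    lod_subtract: bool = True
    qc: QCConfig = field(default_factory=QCConfig)
    imputers: list[ImputerSpec] = field(
        default_factory=lambda: [
            ImputerSpec(method="mean"),
            ImputerSpec(method="random"),
            ImputerSpec(method="rf"),
            ImputerSpec(method="gibbs"),
        ]
    )
    sim: SimConfig | None = field(default_factory=SimConfig)
    sim_scenarios: tuple[str, ...] = ("PROTEIN_DEPENDENT", "PROTEIN_INDEPENDENT")
    auto_noise_sd: bool = True
    seed: int = 0

    def resolve_seeds(self) -> None:
        """Derive per-stage seeds deterministically from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(len(self.imputers) + 2)
        self.synth.seed = int(kids[0].generate_state(1)[0] % 2**31)
        for spec, kid in zip(self.imputers, kids[1:]):
            spec.seed = int(kid.generate_state(1)[0] % 2**31)
        if self.sim is not None:
            self.sim.seed = int(kids[-1].generate_state(1)[0] % 2**31)


def default_benchmark_config(seed: int = 0, scale: str = "ci") -> PipelineConfig:
    """The paper-shaped scenario at a desk-scale size.

    ``scale="ci"``: 800 samples, 5 panels x 12 assays, one masked chip,
    reduced forest/sweep counts so a full run stays in a CI budget.
    ``scale="full"``: the study-sized 802 x 458 layout (slow).
    """
    if scale == "ci":
        synth = SynthConfig(
            n_samples=800,
            panels=[
                ("Immune_Response", 12),
                ("Inflammation", 12),
                ("Cardiovascular_II", 12),
                ("Cardiovascular_III", 12),
                ("Cardiometabolic", 12),
            ],
            n_chips=10,
            n_latent_factors=6,
            # wide signal range: accuracies span ~0.1-0.95 so trend lines
            # against accuracy are well anchored at both ends
            loading_range=(0.05, 1.0),
            n_duplicate_proteins=3,
            n_triplicate_proteins=1,
            mar_chip=("Inflammation", 7),
            extra_mar_rate=0.002,
            seed=seed,
        )
        rf = RFParams(n_trees=60, max_iter=4)
        # fixed penalty + extra sweeps: much faster than per-sweep CV and
        # averages away more draw noise at this problem size
        gibbs = GibbsParams(outer_iters=50, regularization_selection=0.01)
    elif scale == "full":
        synth = SynthConfig(seed=seed)
        rf = RFParams()
        gibbs = GibbsParams()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    cfg = PipelineConfig(
        synth=synth,
        imputers=[
            ImputerSpec(method="mean"),
            ImputerSpec(method="random"),
            ImputerSpec(method="rf", rf=rf),
            ImputerSpec(method="gibbs", gibbs=gibbs),
        ],
        sim=SimConfig(n_reps=200),
        seed=seed,
    )
    cfg.resolve_seeds()
    return cfg


def _write_truth(gt: GroundTruth, ds: NPXDataset, out: Path) -> None:
    tdf = pd.DataFrame(gt.values, index=ds.sample_ids, columns=ds.assay_ids)
    tdf.index.name = "sample_id"
    tdf.to_csv(out / "truth_values.tsv", sep="\t", na_rep="NA", float_format="%.12g")
    mdf = pd.DataFrame(
        gt.eval_mask.astype(int), index=ds.sample_ids, columns=ds.assay_ids
    )
    mdf.index.name = "sample_id"
    mdf.to_csv(out / "truth_eval_mask.tsv", sep="\t")


def complete_matrix(
    ds: NPXDataset, truth: GroundTruth, lod_subtracted: bool = True
) -> np.ndarray:
    """The 'complete dataset' of the downstream simulation: observed
    values where present, zero-coded (censored) truth at MAR cells, so
    it agrees with the observed data at every non-MAR cell."""
    masked = ds.values.copy()
    masked[~ds.non_mar()] = np.nan
    censored = np.maximum(truth.values, 0.0) if lod_subtracted else truth.values
    return np.where(np.isfinite(masked), masked, censored)


def downstream_analysis(
    ds: NPXDataset,
    truth: GroundTruth,
    imputations: dict,
    evals: dict,
    sim_cfg: SimConfig,
    scenarios: tuple[str, ...] = ("PROTEIN_DEPENDENT", "PROTEIN_INDEPENDENT"),
    auto_noise_sd: bool = True,
    lod_subtracted: bool = True,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Per-assay regression simulation plus accuracy trend lines.

    Returns (scenario -> SimResult list, long sim table, trend table).
    Trend lines are fitted twice, against the RF and against the Gibbs
    per-assay accuracies.
    """
    masked = ds.values.copy()
    masked[~ds.non_mar()] = np.nan
    complete = complete_matrix(ds, truth, lod_subtracted)
    x_rf = imputations["rf"].values
    x_gb = imputations["gibbs"].values
    eligible = [j for j in range(ds.n_assays) if truth.eval_mask[:, j].sum() >= 3]
    sim_results: dict[str, list] = {}
    trends = []
    for scenario in scenarios:
        scfg = dataclasses.replace(sim_cfg, scenario=scenario)
        res = []
        for j in eligible:
            scfg_j = dataclasses.replace(scfg, seed=scfg.seed + j)
            if auto_noise_sd:
                # per-assay calibration keeps complete-data power flat
                # (~0.5) across assays, so trend slopes reflect imputation
                # accuracy rather than signal variance
                scfg_j.noise_sd = calibrate_noise_sd(
                    complete[:, j][:, None], scfg.beta, scfg.alpha
                )
            res.append(
                run_simulation(
                    complete[:, j],
                    masked[:, j],
                    x_rf[:, j],
                    x_gb[:, j],
                    scfg_j,
                    assay_id=ds.assay_ids[j],
                )
            )
        sim_results[scenario] = res
        for acc_method, acc_label in (("rf", "RF"), ("gibbs", "GIBBS")):
            acc = {
                r.assay_id: r.pearson
                for r in evals[acc_method]
                if r.pearson is not None
            }
            frac = {r.assay_id: r.frac_below_lod for r in evals[acc_method]}
            try:
                fits = trend_analysis(res, acc, frac)
            except DataModelError as exc:
                logger.warning("trend analysis skipped (%s): %s", scenario, exc)
                continue
            tf = trend_frame(fits)
            tf["scenario"] = scenario
            tf["accuracy_from"] = acc_label
            trends.append(tf)
    sim_df = pd.concat(
        [results_frame(r) for r in sim_results.values()], ignore_index=True
    )
    trend_df = pd.concat(trends, ignore_index=True) if trends else pd.DataFrame()
    return sim_results, sim_df, trend_df


def run_benchmark(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, write all artifacts, return an in-memory report.

    The report dict carries the bundle, per-method imputations and eval
    records, downstream results, and the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %r failed: %s", name, exc)
                return False

        return _T()

    with stage("synth"):
        bundle = generate(cfg.synth)
        ds = bundle.observed
        truth = bundle.truth
        write_npx(ds, out)
    report["bundle"] = bundle

    with stage("preprocess"):
        if cfg.normalize:
            ds = interplate_normalize(ds, scope=cfg.normalize_scope)
        if cfg.lod_subtract:
            lods = np.array([a.lod for a in ds.assays])
            ds = subtract_lod(ds)
            truth = GroundTruth(
                values=truth.values - lods[None, :], eval_mask=truth.eval_mask
            )
        write_npx(ds, out, prefix="prep")
        _write_truth(truth, ds, out)
    report["dataset"] = ds
    report["truth"] = truth

    with stage("qc"):
        outliers = pca_outliers(ds, cfg.qc.n_components, cfg.qc.threshold_sd)
        try:
            conc = duplicate_concordance(ds)
            chip_flags, unscreenable = flag_bad_chips(
                ds, cfg.qc.chip_deviation_threshold
            )
        except DataModelError:
            conc, chip_flags, unscreenable = [], [], []
        qc_rows = (
            [{"kind": "outlier", **f.__dict__} for f in outliers]
            + [{"kind": "chip", **f.__dict__} for f in chip_flags]
            + [{"kind": "concordance", **e.__dict__} for e in conc]
        )
        pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if cfg.qc.apply_flags and (outliers or chip_flags):
            ds, extra_truth, n_masked = apply_mcar_mask(ds, chip_flags, outliers)
            logger.info("QC masked %d additional cells", n_masked)
        report["qc"] = {
            "outliers": outliers,
            "chip_flags": chip_flags,
            "concordance": conc,
            "unscreenable": unscreenable,
        }

    imputations = {}
    evals = {}
    for spec in cfg.imputers:
        with stage(f"impute_{spec.method}"):
            imp = impute(ds, spec)
            imputations[spec.method] = imp
            vdf = pd.DataFrame(imp.values, index=ds.sample_ids, columns=ds.assay_ids)
            vdf.index.name = "sample_id"
            vdf.to_csv(
                out / f"imputed_{spec.method}.tsv", sep="\t", float_format="%.12g"
            )
            if imp.oob_nrmse:
                pd.DataFrame(
                    sorted(imp.oob_nrmse.items()), columns=["assay_id", "oob_nrmse"]
                ).to_csv(out / "oob_nrmse.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        with stage(f"evaluate_{spec.method}"):
            recs = evaluate(imp, truth, ds)
            evals[spec.method] = recs
            records_frame(recs).to_csv(
                out / f"eval_{spec.method}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )
    report["imputations"] = imputations
    report["evals"] = evals

    with stage("summary"):
        rows = []
        for method, recs in evals.items():
            df = records_frame(recs)
            rows.append(
                {
                    "method": method,
                    "n_assays": len(df),
                    "median_pearson": df["pearson"].dropna().median(),
                    "median_spearman": df["spearman"].dropna().median(),
                    "median_nrmse": df["nrmse"].dropna().median(),
                    "median_rel_var": df["rel_var"].dropna().median(),
                }
            )
        summary = pd.DataFrame(rows)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    report["summary"] = summary

    if cfg.sim is not None and {"rf", "gibbs"} <= set(imputations):
        with stage("downstream"):
            sim_results, sim_df, trend_df = downstream_analysis(
                ds,
                truth,
                imputations,
                evals,
                cfg.sim,
                scenarios=cfg.sim_scenarios,
                auto_noise_sd=cfg.auto_noise_sd,
                lod_subtracted=cfg.lod_subtract,
            )
            sim_df.to_csv(out / "sim.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            trend_df.to_csv(out / "trend.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            report["sim"] = sim_results
            report["trend"] = trend_df

    import scipy
    import sklearn

    manifest = {
        "peabench_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "seed": cfg.seed,
        "config": _cfg_to_dict(cfg),
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest"] = manifest
    return report


def _cfg_to_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {
            f.name: _cfg_to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)
        }
    if isinstance(cfg, (list, tuple)):
        return [_cfg_to_dict(v) for v in cfg]
    if isinstance(cfg, np.ndarray):
        return cfg.tolist()
    if isinstance(cfg, (np.floating, np.integer)):
        return cfg.item()
    return cfg
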