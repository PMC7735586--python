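import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peabench.data_model import (
    AssayMeta,
    CellState,
    DataModelError,
    GroundTruth,
    NPXDataset,
    SampleMeta,
)
from peabench.evaluation import (
    evaluate,
    nrmse,
    panel_subset_experiment,
    records_frame,
    rel_var,
    sample_size_experiment,
)
from peabench.imputers import GibbsParams, ImputedDataset, ImputerSpec, impute
from peabench.synthetic import SynthBundle, generate

from .conftest import lod_subtracted, small_config


class TestNRMSE:
    def test_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        assert nrmse(x, x) == 0.0

    def test_two_point_example(self):
        # MSE = 1, sample variance = 2
        assert nrmse(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(
            np.sqrt(0.5), abs=1e-12
        )

    def test_mean_imputation_closed_form(self):
        # filling with the truth's own mean gives exactly sqrt((n-1)/n)
        rng = np.random.default_rng(0)
        for n in (5, 20, 200):
            x = rng.standard_normal(n)
            imp = np.full(n, x.mean())
            assert nrmse(x, imp) == pytest.approx(np.sqrt((n - 1) / n), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataModelError):
            nrmse(np.array([1.0, 1.0]), np.array([1.0, 2.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataModelError):
            nrmse(np.array([1.0, 2.0]), np.array([1.0]))


class TestRelVar:
    def test_constant_imputation_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rel_var(x, np.full(3, 9.0)) == 0.0

    def test_identity_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rel_var(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert rel_var(x, 2 * x) == pytest.approx(4.0, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    shift=st.floats(-50, 50),
    scale=st.floats(0.01, 20),
    seed=st.integers(0, 2**16),
)
def test_metric_invariances(shift, scale, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(10)
    y = x + rng.normal(0, 0.5, 10)
    assert nrmse(x + shift, y + shift) == pytest.approx(nrmse(x, y), rel=1e-9)
    assert rel_var(x + shift, y + shift) == pytest.approx(rel_var(x, y), rel=1e-9)
    assert nrmse(scale * x, scale * y) == pytest.approx(nrmse(x, y), rel=1e-9)
    assert rel_var(scale * x, scale * y) == pytest.approx(rel_var(x, y), rel=1e-9)


def _eval_setup(n=30, p=3, n_eval=10, seed=0):
    rng = np.random.default_rng(seed)
    truth_vals = rng.standard_normal((n, p))
    mask = np.zeros((n, p), dtype=np.int8)
    em = np.zeros((n, p), dtype=bool)
    em[:n_eval, :] = True
    mask[em] = CellState.MAR_MISSING
    values = np.where(em, np.nan, truth_vals)
    ds = NPXDataset(
        values=values,
        mask=mask,
        assays=[AssayMeta(f"A{j}", f"P{j}", "X", 0.0) for j in range(p)],
        samples=[SampleMeta(f"S{i}", {"X": i // 88 + 1}) for i in range(n)],
    )
    return ds, GroundTruth(values=truth_vals, eval_mask=em)


class TestEvaluate:
    def test_perfect_imputation(self):
        ds, gt = _eval_setup()
        imp = ImputedDataset(values=gt.values.copy(), method=ImputerSpec())
        for rec in evaluate(imp, gt, ds):
            assert rec.pearson == pytest.approx(1.0)
            assert rec.nrmse == pytest.approx(0.0, abs=1e-12)
            assert rec.rel_var == pytest.approx(1.0)

    def test_constant_imputation_metrics_absent_correlation(self):
        ds, gt = _eval_setup()
        vals = np.where(gt.eval_mask, 0.0, gt.values)
        imp = ImputedDataset(values=vals, method=ImputerSpec())
        for rec in evaluate(imp, gt, ds):
            assert rec.pearson is None
            assert rec.rel_var == 0.0

    def test_few_cells_absent(self):
        ds, gt = _eval_setup(n_eval=2)
        imp = ImputedDataset(values=gt.values.copy(), method=ImputerSpec())
        for rec in evaluate(imp, gt, ds):
            assert rec.pearson is None and rec.nrmse is None
            assert rec.n_eval_cells == 2

    def test_error_ratio(self):
        ds, gt = _eval_setup(seed=4)
        vals = np.where(gt.eval_mask, gt.values + 0.3, gt.values)
        imp = ImputedDataset(values=vals, method=ImputerSpec())
        recs = evaluate(imp, gt, ds, measurement_sd={"A0": 0.3})
        by_id = {r.assay_id: r for r in recs}
        assert by_id["A0"].error_ratio == pytest.approx(1.0)
        assert by_id["A1"].error_ratio is None

    def test_empty_eval_mask_rejected(self):
        ds, gt = _eval_setup()
        gt.eval_mask[:] = False
        imp = ImputedDataset(values=gt.values.copy(), method=ImputerSpec())
        with pytest.raises(DataModelError):
            evaluate(imp, gt, ds)


FAST_SPECS = [
    ImputerSpec(
        method="gibbs",
        seed=2,
        gibbs=GibbsParams(outer_iters=3, regularization_selection=0.01, force_sigma=0.0),
    )
]


def _three_panel_bundle(seed=0):
    cfg = small_config(
        n_samples=150,
        panels=[("T", 6), ("P", 6), ("Q", 6)],
        n_chips=3,
        n_duplicate_proteins=0,
        mar_chip=("T", 2),
        extra_mar_rate=0.0,
        lod_quantiles=[0.0] * 18,
        seed=seed,
    )
    return generate(cfg)


class TestPanelSubset:
    def test_all_panels_at_least_two_panel(self):
        diffs = []
        for seed in range(10):
            bundle = _three_panel_bundle(seed)
            df = panel_subset_experiment(bundle, "T", FAST_SPECS)
            med = df.groupby("condition").pearson.median()
            two_panel = med.drop("ALL").max()
            diffs.append(med["ALL"] - two_panel)
        assert np.mean(diffs) >= -0.02

    def test_informative_panel_detected(self):
        # target assay correlated only with an assay on panel Q
        rng = np.random.default_rng(6)
        n = 200
        xq = rng.standard_normal(n)
        cols = {
            "T": [xq + rng.normal(0, 0.2, n), rng.standard_normal(n)],
            "P": [rng.standard_normal(n), rng.standard_normal(n)],
            "Q": [xq, rng.standard_normal(n)],
        }
        values = np.column_stack([c for panel in "TPQ" for c in cols[panel]])
        mask = np.zeros((n, 6), dtype=np.int8)
        em = np.zeros((n, 6), dtype=bool)
        em[:40, 0] = True
        mask[em] = CellState.MAR_MISSING
        truth_vals = values.copy()
        values = np.where(em, np.nan, values)
        assays = [
            AssayMeta(f"A{j}", f"PR{j}", panel, 0.0)
            for j, panel in enumerate(["T", "T", "P", "P", "Q", "Q"])
        ]
        ds = NPXDataset(
            values=values,
            mask=mask,
            assays=assays,
            samples=[SampleMeta(f"S{i}", {p: i // 88 + 1 for p in "TPQ"}) for i in range(n)],
        )
        bundle = SynthBundle(
            truth=GroundTruth(values=truth_vals, eval_mask=em),
            observed=ds,
            factor_loadings=np.zeros((6, 1)),
            config=small_config(),
        )
        df = panel_subset_experiment(bundle, "T", FAST_SPECS)
        acc = df[df.assay_id == "A0"].set_index("condition").pearson
        assert acc["Q"] > 0.8 and acc["ALL"] > 0.8
        assert acc["P"] < 0.3

    def test_deterministic(self):
        bundle = _three_panel_bundle(3)
        a = panel_subset_experiment(bundle, "T", FAST_SPECS)
        b = panel_subset_experiment(bundle, "T", FAST_SPECS)
        assert a.equals(b)

    def test_missing_target_rejected(self):
        bundle = _three_panel_bundle(3)
        with pytest.raises(DataModelError):
            panel_subset_experiment(bundle, "NOPE", FAST_SPECS)


@pytest.fixture(scope="module")
def size_results():
    cfg = small_config(
        n_samples=240,
        n_chips=4,
        mar_chip=("P1", 2),
        extra_mar_rate=0.0,
        seed=17,
    )
    bundle = generate(cfg)
    evals, comps = sample_size_experiment(bundle, [2, 3, 4], [FAST_SPECS[0]])
    return bundle, evals, comps


class TestSampleSize:

    def test_accuracy_grows_with_chips(self, size_results):
        _, evals, _ = size_results
        med = evals.groupby("n_chips").pearson.median()
        assert med[4] >= med[2] - 0.10

    def test_masked_chip_always_kept(self, size_results):
        _, evals, _ = size_results
        # every level still evaluates the masked-panel assays
        assert (evals.groupby("n_chips").size() > 0).all()

    def test_full_level_matches_direct_run(self, size_results):
        bundle, evals, _ = size_results
        ds, gt = lod_subtracted(bundle)  # noqa: F841 (scale check only)
        from peabench.evaluation import evaluate as ev

        imp = impute(bundle.observed, FAST_SPECS[0])
        direct = records_frame(ev(imp, bundle.truth, bundle.observed))
        full = evals[evals.n_chips == 4].reset_index(drop=True)
        merged = direct.merge(full, on="assay_id", suffixes=("_d", "_f"))
        np.testing.assert_allclose(
            merged.pearson_d.astype(float), merged.pearson_f.astype(float), atol=1e-12
        )

    def test_too_few_chips_rejected(self, size_results):
        bundle, _, _ = size_results
        with pytest.raises(DataModelError):
            sample_size_experiment(bundle, [1], FAST_SPECS)
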