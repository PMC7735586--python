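import dataclasses

import numpy as np
import pytest

from peabench.data_model import (
    AssayMeta,
    CellState,
    DataModelError,
    NPXDataset,
    SampleMeta,
)
from peabench.io import read_npx, read_bundle_dir, write_npx
from peabench.preprocess import interplate_normalize, subtract_lod
from peabench.synthetic import generate

from .conftest import small_config


def _write_tables(tmp_path, values_rows, assay_rows, sample_rows):
    vp = tmp_path / "values.tsv"
    ap = tmp_path / "assays.tsv"
    sp = tmp_path / "samples.tsv"
    vp.write_text("\n".join("\t".join(r) for r in values_rows) + "\n")
    ap.write_text("\n".join("\t".join(r) for r in assay_rows) + "\n")
    sp.write_text("\n".join("\t".join(r) for r in sample_rows) + "\n")
    return vp, ap, sp


ASSAY_HDR = ["assay_id", "protein_id", "panel", "lod"]


class TestReadNPX:
    def test_na_cell_becomes_mar(self, tmp_path):
        vp, ap, sp = _write_tables(
            tmp_path,
            [["sample_id", "A1", "A2"], ["S1", "1.0", "2.0"],
             ["S2", "NA", "3.0"], ["S3", "4.0", "5.0"]],
            [ASSAY_HDR, ["A1", "P1", "X", "0"], ["A2", "P2", "X", "0"]],
            [["sample_id", "chip_X"], ["S1", "1"], ["S2", "1"], ["S3", "1"]],
        )
        ds = read_npx(vp, ap, sp)
        assert (ds.mask == CellState.MAR_MISSING).sum() == 1
        assert (ds.mask == CellState.OBSERVED).sum() == 5
        assert ds.mask[1, 0] == CellState.MAR_MISSING

    def test_unmatched_assay_meta_rejected(self, tmp_path):
        vp, ap, sp = _write_tables(
            tmp_path,
            [["sample_id", "A1", "A2", "A3", "A4"],
             ["S1", "1", "2", "3", "4"], ["S2", "1", "2", "3", "4"]],
            [ASSAY_HDR, ["A1", "P", "X", "0"], ["A2", "P", "X", "0"],
             ["A3", "P", "X", "0"]],
            [["sample_id", "chip_X"], ["S1", "1"], ["S2", "1"]],
        )
        with pytest.raises(DataModelError, match="A4"):
            read_npx(vp, ap, sp)

    def test_non_numeric_cell_rejected(self, tmp_path):
        vp, ap, sp = _write_tables(
            tmp_path,
            [["sample_id", "A1"], ["S1", "abc"], ["S2", "1.0"]],
            [ASSAY_HDR, ["A1", "P", "X", "0"]],
            [["sample_id", "chip_X"], ["S1", "1"], ["S2", "1"]],
        )
        with pytest.raises(DataModelError, match="non-numeric"):
            read_npx(vp, ap, sp)

    def test_unknown_panel_rejected(self, tmp_path):
        vp, ap, sp = _write_tables(
            tmp_path,
            [["sample_id", "A1"], ["S1", "1.0"], ["S2", "2.0"]],
            [ASSAY_HDR, ["A1", "P", "Y", "0"]],
            [["sample_id", "chip_X"], ["S1", "1"], ["S2", "1"]],
        )
        with pytest.raises(DataModelError, match="Y"):
            read_npx(vp, ap, sp)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, small_bundle):
        ds = small_bundle.observed
        write_npx(ds, tmp_path)
        back = read_bundle_dir(tmp_path)
        np.testing.assert_array_equal(back.mask, ds.mask)
        obs = ds.mask != CellState.MAR_MISSING
        np.testing.assert_allclose(back.values[obs], ds.values[obs], rtol=1e-10)
        assert back.assays == ds.assays or all(
            a.assay_id == b.assay_id
            and a.protein_id == b.protein_id
            and a.panel == b.panel
            and np.isclose(a.lod, b.lod)
            for a, b in zip(back.assays, ds.assays)
        )
        assert [s.chip for s in back.samples] == [s.chip for s in ds.samples]

    def test_flag_file_is_binary(self, tmp_path, tiny_ds):
        paths = write_npx(tiny_ds, tmp_path)
        body = paths["lod_flags"].read_text().splitlines()[1:]
        codes = {c for line in body for c in line.split("\t")[1:]}
        assert codes <= {"0", "1"}

    def test_empty_dataset_refused(self, tmp_path):
        ds = NPXDataset(
            values=np.empty((0, 1)),
            mask=np.empty((0, 1), dtype=np.int8),
            assays=[AssayMeta("A1", "P", "X", 0.0)],
            samples=[],
        )
        with pytest.raises(DataModelError, match="empty"):
            write_npx(ds, tmp_path)


class TestValidation:
    def test_duplicate_assay_ids(self):
        with pytest.raises(DataModelError, match="duplicate assay_id"):
            NPXDataset(
                values=np.zeros((1, 2)),
                mask=np.zeros((1, 2), dtype=np.int8),
                assays=[AssayMeta("A", "P", "X", 0.0), AssayMeta("A", "Q", "X", 0.0)],
                samples=[SampleMeta("S", {"X": 1})],
            )

    def test_chip_capacity_enforced(self):
        n = 89
        with pytest.raises(DataModelError, match="capacity"):
            NPXDataset(
                values=np.zeros((n, 1)),
                mask=np.zeros((n, 1), dtype=np.int8),
                assays=[AssayMeta("A", "P", "X", 0.0)],
                samples=[SampleMeta(f"S{i}", {"X": 1}) for i in range(n)],
            )

    def test_nonfinite_observed_rejected(self):
        with pytest.raises(DataModelError, match="non-finite"):
            NPXDataset(
                values=np.array([[np.inf]]),
                mask=np.zeros((1, 1), dtype=np.int8),
                assays=[AssayMeta("A", "P", "X", 0.0)],
                samples=[SampleMeta("S", {"X": 1})],
            )


class TestSubtractLOD:
    def test_arithmetic(self, tiny_ds):
        out = subtract_lod(tiny_ds)
        # assay A1 has lod 3.0: observed 5.0 -> 2.0, 3.5 -> 0.5; censored -> 0
        assert out.values[0, 0] == 2.0
        assert out.values[1, 0] == 0.5
        assert out.values[2, 0] == 0.0
        assert all(a.lod == 0.0 for a in out.assays)

    def test_idempotent(self, tiny_ds):
        once = subtract_lod(tiny_ds)
        twice = subtract_lod(once)
        np.testing.assert_array_equal(
            np.nan_to_num(once.values), np.nan_to_num(twice.values)
        )

    def test_all_below_lod_column_is_zero(self):
        ds = NPXDataset(
            values=np.full((3, 1), 2.0),
            mask=np.full((3, 1), CellState.BELOW_LOD, dtype=np.int8),
            assays=[AssayMeta("A", "P", "X", 2.0)],
            samples=[SampleMeta(f"S{i}", {"X": 1}) for i in range(3)],
        )
        out = subtract_lod(ds)
        assert (out.values == 0.0).all()

    def test_missing_lod_rejected(self, tiny_ds):
        ds = tiny_ds.copy()
        ds.assays[0] = dataclasses.replace(ds.assays[0], lod=float("nan"))
        with pytest.raises(DataModelError, match="LOD"):
            subtract_lod(ds)

    def test_mask_unchanged(self, tiny_ds):
        out = subtract_lod(tiny_ds)
        np.testing.assert_array_equal(out.mask, tiny_ds.mask)


class TestInterplateNormalize:
    def _two_chip_ds(self):
        values = np.array([[4.0], [6.0], [6.0], [8.0]])
        mask = np.zeros((4, 1), dtype=np.int8)
        assays = [AssayMeta("A", "P", "X", 0.0)]
        samples = [SampleMeta(f"S{i}", {"X": 1 if i < 2 else 2}) for i in range(4)]
        return NPXDataset(values=values, mask=mask, assays=assays, samples=samples)

    def test_chip_medians_aligned(self):
        out = interplate_normalize(self._two_chip_ds())
        # chip medians 5.0 and 7.0, overall 6.0 -> both end at 6.0
        np.testing.assert_allclose(out.values[:, 0], [5.0, 7.0, 5.0, 7.0])

    def test_single_chip_identity(self, tiny_ds):
        ds = tiny_ds.copy()
        for i, s in enumerate(ds.samples):
            ds.samples[i] = SampleMeta(s.sample_id, {p: 1 for p in s.chip})
        out = interplate_normalize(ds)
        obs = ds.mask != CellState.MAR_MISSING
        np.testing.assert_allclose(out.values[obs], ds.values[obs], atol=1e-12)

    def test_postcondition_on_synthetic(self):
        cfg = small_config(n_samples=200, chip_effect_sd=0.8, extra_mar_rate=0.0,
                           mar_chip=None, seed=11)
        ds = generate(cfg).observed
        out = interplate_normalize(ds)
        for panel in out.panels():
            for j in out.panel_columns(panel):
                col = out.values[:, j]
                use = out.mask[:, j] == CellState.OBSERVED
                overall = np.median(col[use])
                for chip in out.chips(panel):
                    rows = out.chip_rows(panel, chip)
                    chip_use = use[rows]
                    if chip_use.any():
                        assert abs(np.median(col[rows][chip_use]) - overall) < 1e-9

    def test_permutation_equivariance(self):
        # a fully masked chip is a normalization error by contract, so use
        # an unmasked bundle here
        ds = generate(small_config(mar_chip=None, seed=23)).observed
        rng = np.random.default_rng(3)
        perm = rng.permutation(ds.n_samples)
        permuted = NPXDataset(
            values=ds.values[perm].copy(),
            mask=ds.mask[perm].copy(),
            assays=list(ds.assays),
            samples=[ds.samples[i] for i in perm],
        )
        a = subtract_lod(interplate_normalize(ds))
        b = subtract_lod(interplate_normalize(permuted))
        np.testing.assert_allclose(
            np.nan_to_num(a.values[perm]), np.nan_to_num(b.values), atol=1e-12
        )

    def test_mask_preserved(self):
        ds = generate(small_config(mar_chip=None, seed=23)).observed
        out = interplate_normalize(ds)
        np.testing.assert_array_equal(out.mask, ds.mask)

    def test_fully_masked_chip_rejected(self, small_bundle):
        with pytest.raises(DataModelError, match="no usable values"):
            interplate_normalize(small_bundle.observed)
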