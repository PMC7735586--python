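"""Delimited-text readers and writers for NPX datasets.

On-disk layout (TSV by default, CSV accepted via ``sep=","``):

* ``values`` table   — first column ``sample_id``, one column per assay;
  MAR cells are empty or the NA sentinel.
* ``assay`` metadata — columns ``assay_id, protein_id, panel, lod``.
* ``sample`` metadata — ``sample_id`` plus one ``chip_<panel>`` column
  per panel (1-based chip indices).
* optional below-LOD flag table — same shape as values, entries in {0,1}.

Numerics are written with 12 significant digits so a write/read round
trip reproduces values to full printed precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import AssayMeta, CellState, DataModelError, NPXDataset, SampleMeta

CHIP_PREFIX = "chip_"
FLOAT_FMT = "%.12g"


def read_npx(
    values_path: str | os.PathLike,
    assay_meta_path: str | os.PathLike,
    sample_meta_path: str | os.PathLike,
    lod_flag_path: str | os.PathLike | None = None,
    sep: str = "\t",
    na_sentinel: str = "NA",
) -> NPXDataset:
    """Read an NPX dataset from delimited-text tables.

    Empty cells and ``na_sentinel`` in the values table become
    MAR_MISSING; cells flagged 1 in ``lod_flag_path`` become BELOW_LOD.
    """
    vals = pd.read_csv(
        values_path, sep=sep, dtype={0: str}, na_values=[na_sentinel], keep_default_na=False
    )
    if vals.shape[1] < 2:
        raise DataModelError("values table needs a sample_id column plus assay columns")
    vals = vals.set_index(vals.columns[0])
    assay_ids = list(vals.columns)

    ameta = pd.read_csv(assay_meta_path, sep=sep, dtype=str, keep_default_na=False)
    required = {"assay_id", "protein_id", "panel", "lod"}
    if not required.issubset(ameta.columns):
        raise DataModelError(
            f"assay metadata missing columns: {sorted(required - set(ameta.columns))}"
        )
    meta_ids = list(ameta["assay_id"])
    unmatched = sorted(set(assay_ids) ^ set(meta_ids))
    if unmatched:
        raise DataModelError(f"assay ids not shared by values and metadata: {unmatched}")
    ameta = ameta.set_index("assay_id").loc[assay_ids]
    assays = [
        AssayMeta(
            assay_id=aid,
            protein_id=row["protein_id"],
            panel=row["panel"],
            lod=float(row["lod"]),
        )
        for aid, row in ameta.iterrows()
    ]

    smeta = pd.read_csv(sample_meta_path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_id" not in smeta.columns:
        raise DataModelError("sample metadata missing 'sample_id' column")
    chip_cols = [c for c in smeta.columns if c.startswith(CHIP_PREFIX)]
    smeta = smeta.set_index("sample_id")
    sample_ids = list(vals.index)
    missing_rows = sorted(set(sample_ids) ^ set(smeta.index))
    if missing_rows:
        raise DataModelError(
            f"sample ids not shared by values and metadata: {missing_rows}"
        )
    smeta = smeta.loc[sample_ids]
    panels = {a.panel for a in assays}
    known = {c[len(CHIP_PREFIX):] for c in chip_cols}
    unknown = sorted(panels - known)
    if unknown:
        raise DataModelError(f"no chip column for panel(s): {unknown}")
    samples = []
    for sid, row in smeta.iterrows():
        chip = {}
        for c in chip_cols:
            panel = c[len(CHIP_PREFIX):]
            if row[c] != "":
                chip[panel] = int(row[c])
        samples.append(SampleMeta(sample_id=sid, chip=chip))

    try:
        values = vals.astype(float).to_numpy()
    except ValueError as exc:
        raise DataModelError(f"non-numeric cell in values table: {exc}") from exc

    mask = np.where(np.isnan(values), CellState.MAR_MISSING, CellState.OBSERVED).astype(
        np.int8
    )
    if lod_flag_path is not None:
        flags = pd.read_csv(lod_flag_path, sep=sep, dtype={0: str})
        flags = flags.set_index(flags.columns[0])
        if list(flags.columns) != assay_ids or list(flags.index) != sample_ids:
            raise DataModelError("below-LOD flag table does not match values table")
        f = flags.to_numpy().astype(int)
        if not np.isin(f, (0, 1)).all():
            raise DataModelError("below-LOD flags must be 0 or 1")
        if (f.astype(bool) & (mask == CellState.MAR_MISSING)).any():
            raise DataModelError("cell flagged below-LOD but missing in values table")
        mask[f.astype(bool)] = CellState.BELOW_LOD
    return NPXDataset(values=values, mask=mask, assays=assays, samples=samples)


def write_npx(
    ds: NPXDataset,
    out_dir: str | os.PathLike,
    sep: str = "\t",
    na_sentinel: str = "NA",
    prefix: str = "npx",
) -> dict[str, Path]:
    """Write a dataset as values / below-LOD flag / metadata tables.

    Returns the written paths keyed by role.  ``read_npx`` on the output
    reproduces ``ds`` exactly for text fields and to printed precision
    for numerics.
    """
    if ds.n_samples == 0 or ds.n_assays == 0:
        raise DataModelError("refusing to write an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": out / f"{prefix}_values.tsv",
        "lod_flags": out / f"{prefix}_below_lod.tsv",
        "assays": out / f"{prefix}_assays.tsv",
        "samples": out / f"{prefix}_samples.tsv",
    }

    vals = ds.values.copy()
    vals[ds.mask == CellState.MAR_MISSING] = np.nan
    vdf = pd.DataFrame(vals, index=ds.sample_ids, columns=ds.assay_ids)
    vdf.index.name = "sample_id"
    vdf.to_csv(paths["values"], sep=sep, na_rep=na_sentinel, float_format=FLOAT_FMT)

    flags = (ds.mask == CellState.BELOW_LOD).astype(int)
    fdf = pd.DataFrame(flags, index=ds.sample_ids, columns=ds.assay_ids)
    fdf.index.name = "sample_id"
    fdf.to_csv(paths["lod_flags"], sep=sep)

    pd.DataFrame(
        {
            "assay_id": ds.assay_ids,
            "protein_id": [a.protein_id for a in ds.assays],
            "panel": [a.panel for a in ds.assays],
            "lod": [a.lod for a in ds.assays],
        }
    ).to_csv(paths["assays"], sep=sep, index=False, float_format=FLOAT_FMT)

    panels = ds.panels()
    sdf = pd.DataFrame({"sample_id": ds.sample_ids})
    for panel in panels:
        sdf[f"{CHIP_PREFIX}{panel}"] = [s.chip.get(panel, "") for s in ds.samples]
    sdf.to_csv(paths["samples"], sep=sep, index=False)
    return paths


def read_bundle_dir(in_dir: str | os.PathLike, prefix: str = "npx", sep: str = "\t") -> NPXDataset:
    """Read a dataset previously written by :func:`write_npx`."""
    d = Path(in_dir)
    return read_npx(
        d / f"{prefix}_values.tsv",
        d / f"{prefix}_assays.tsv",
        d / f"{prefix}_samples.tsv",
        lod_flag_path=d / f"{prefix}_below_lod.tsv",
        sep=sep,
    )
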