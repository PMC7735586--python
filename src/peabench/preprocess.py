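"""Pre-imputation transforms: LOD subtraction and inter-plate normalization."""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import CellState, DataModelError, NPXDataset


def subtract_lod(ds: NPXDataset) -> NPXDataset:
    """Shift each assay by its LOD so censored values are coded 0.

    OBSERVED values become ``value - lod``; BELOW_LOD cells become
    exactly 0; each assay's recorded ``lod`` becomes 0, which makes the
    transform idempotent.
    """
    lods = np.array([a.lod for a in ds.assays], dtype=float)
    if not np.isfinite(lods).all():
        bad = [a.assay_id for a, l in zip(ds.assays, lods) if not np.isfinite(l)]
        raise DataModelError(f"assay(s) without a finite LOD: {bad}")
    out = ds.copy()
    out.values = out.values - lods[None, :]
    out.values[out.mask == CellState.BELOW_LOD] = 0.0
    out.assays = [dataclasses.replace(a, lod=0.0) for a in out.assays]
    return out


def interplate_normalize(
    ds: NPXDataset,
    scope: str = "per_assay",
    include_below_lod: bool = False,
) -> NPXDataset:
    """Align chip medians to the overall median by an additive shift.

    ``scope="per_assay"`` aligns each assay's chip median to that
    assay's overall median (intensity-based inter-plate normalization);
    ``scope="per_chip_global"`` applies one pooled shift per (panel,
    chip).  BELOW_LOD cells are shifted together with observed cells but
    by default do not contribute to medians.
    """
    if scope not in ("per_assay", "per_chip_global"):
        raise ValueError(f"unknown normalization scope: {scope}")
    out = ds.copy()
    if include_below_lod:
        usable = out.non_mar()
    else:
        usable = out.mask == CellState.OBSERVED
    for panel in out.panels():
        cols = out.panel_columns(panel)
        for chip in out.chips(panel):
            rows = out.chip_rows(panel, chip)
            block_use = usable[np.ix_(rows, cols)]
            if not block_use.any():
                raise DataModelError(
                    f"chip {chip} on panel {panel} has no usable values"
                )
        if scope == "per_assay":
            for j in cols:
                col_vals = out.values[:, j]
                overall = np.median(col_vals[usable[:, j]]) if usable[:, j].any() else np.nan
                for chip in out.chips(panel):
                    rows = out.chip_rows(panel, chip)
                    chip_use = usable[rows, j]
                    if not chip_use.any():
                        continue
                    shift = overall - np.median(col_vals[rows][chip_use])
                    out.values[np.ix_(rows, [j])] += shift
        else:
            block = out.values[:, cols]
            overall = np.median(block[usable[:, cols]])
            for chip in out.chips(panel):
                rows = out.chip_rows(panel, chip)
                chip_block = out.values[np.ix_(rows, cols)]
                chip_use = usable[np.ix_(rows, cols)]
                shift = overall - np.median(chip_block[chip_use])
                out.values[np.ix_(rows, cols)] += shift
    # MAR cells may hold stale numbers after shifting; keep them NaN.
    out.values[out.mask == CellState.MAR_MISSING] = np.nan
    return out
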