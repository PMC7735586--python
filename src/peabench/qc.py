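"""Quality-control screens and MCAR mask construction.

Three read-only screens — PCA sample-outlier detection, duplicate-assay
concordance, and malfunctioning-chip flagging via excess duplicate
deviation — plus :func:`apply_mcar_mask`, the single mutating step that
turns failed measurements into missing-at-random cells and moves their
values into a :class:`~peabench.data_model.GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import CellState, DataModelError, GroundTruth, NPXDataset


@dataclass(frozen=True)
class OutlierFlag:
    sample_id: str
    panel: str
    score: float


@dataclass(frozen=True)
class ChipFlag:
    panel: str
    chip: int
    statistic: float


@dataclass(frozen=True)
class ConcordanceEntry:
    protein_id: str
    panel_a: str
    panel_b: str
    pearson: float
    spearman: float
    n_common: int


@dataclass
class QCReport:
    outlier_samples: list[OutlierFlag] = field(default_factory=list)
    chip_flags: list[ChipFlag] = field(default_factory=list)
    duplicate_concordance: list[ConcordanceEntry] = field(default_factory=list)
    unscreenable_panels: list[str] = field(default_factory=list)


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return 1.4826 * mad


def pca_outliers(
    ds: NPXDataset, n_components: int = 2, threshold_sd: float = 6.0
) -> list[OutlierFlag]:
    """Flag samples whose PCA score on any leading component deviates
    more than ``threshold_sd`` robust SDs from the component median.

    Run per panel; MAR cells are median-filled for the decomposition
    only (``ds`` is never mutated).
    """
    from sklearn.decomposition import PCA

    flags: list[OutlierFlag] = []
    for panel in ds.panels():
        cols = ds.panel_columns(panel)
        block = ds.values[:, cols].copy()
        if block.shape[0] < 3:
            raise DataModelError(f"panel {panel} has fewer than 3 samples")
        mar = ds.mask[:, cols] == CellState.MAR_MISSING
        block[mar] = np.nan
        col_med = np.nanmedian(block, axis=0)
        fill = np.where(np.isnan(block), np.broadcast_to(col_med, block.shape), block)
        usable_cols = ((~mar).sum(axis=0) >= 3).sum()
        if usable_cols < n_components:
            raise DataModelError(
                f"panel {panel}: only {usable_cols} assays with >= 3 non-MAR values "
                f"for {n_components} components"
            )
        if np.isnan(fill).any():  # assays fully MAR on this panel
            fill = np.where(np.isnan(fill), 0.0, fill)
        k = min(n_components, min(fill.shape) - 1)
        scores = PCA(n_components=k, random_state=0).fit_transform(fill)
        for comp in range(k):
            s = scores[:, comp]
            sd = _robust_sd(s)
            if sd == 0:
                continue
            dev = np.abs(s - np.median(s)) / sd
            for i in np.where(dev > threshold_sd)[0]:
                flags.append(OutlierFlag(ds.samples[i].sample_id, panel, float(dev[i])))
    # one flag per (sample, panel): keep the largest score
    best: dict[tuple[str, str], OutlierFlag] = {}
    for f in flags:
        key = (f.sample_id, f.panel)
        if key not in best or f.score > best[key].score:
            best[key] = f
    return sorted(best.values(), key=lambda f: (f.panel, f.sample_id))


def duplicate_concordance(ds: NPXDataset) -> list[ConcordanceEntry]:
    """Pearson/Spearman correlation for every unordered panel pair of
    each duplicate protein, over samples observed in both assays."""
    groups = ds.duplicate_groups()
    if not groups:
        raise DataModelError("dataset has no duplicate protein groups")
    entries = []
    obs = ds.mask == CellState.OBSERVED
    for pid, cols in sorted(groups.items()):
        for ia in range(len(cols)):
            for ib in range(ia + 1, len(cols)):
                ja, jb = cols[ia], cols[ib]
                common = obs[:, ja] & obs[:, jb]
                if common.sum() < 3:
                    raise DataModelError(
                        f"duplicate pair {pid} ({ds.assay_ids[ja]}, {ds.assay_ids[jb]}) "
                        f"has {common.sum()} common observed samples (<3)"
                    )
                xa = ds.values[common, ja]
                xb = ds.values[common, jb]
                entries.append(
                    ConcordanceEntry(
                        protein_id=pid,
                        panel_a=ds.assays[ja].panel,
                        panel_b=ds.assays[jb].panel,
                        pearson=float(stats.pearsonr(xa, xb).statistic),
                        spearman=float(stats.spearmanr(xa, xb).statistic),
                        n_common=int(common.sum()),
                    )
                )
    return entries


def flag_bad_chips(
    ds: NPXDataset, deviation_threshold: float = 0.5
) -> tuple[list[ChipFlag], list[str]]:
    """Flag chips whose duplicate-assay disagreement exceeds the other
    chips' by more than ``deviation_threshold`` NPX.

    For each (panel, chip), the statistic is the median absolute
    difference between duplicate-assay pairs (one assay on the panel)
    restricted to the chip's samples, minus the same statistic over all
    other chips.  Panels without duplicate coverage are reported as
    unscreenable, not an error.
    """
    groups = ds.duplicate_groups()
    if not groups:
        raise DataModelError("chip screening requires duplicate protein groups")
    obs = ds.mask == CellState.OBSERVED
    flags: list[ChipFlag] = []
    unscreenable: list[str] = []
    for panel in ds.panels():
        # duplicate pairs with one member on this panel
        pairs = []
        for pid, cols in groups.items():
            for ja in cols:
                if ds.assays[ja].panel != panel:
                    continue
                for jb in cols:
                    if jb != ja and ds.assays[jb].panel != panel:
                        pairs.append((ja, jb))
        if not pairs:
            unscreenable.append(panel)
            continue
        for chip in ds.chips(panel):
            on_chip = np.array([s.chip.get(panel) == chip for s in ds.samples])
            excess = []
            for ja, jb in pairs:
                common = obs[:, ja] & obs[:, jb]
                raw = ds.values[:, ja] - ds.values[:, jb]
                # center on the global pair offset so constant panel shifts
                # (calibration differences) do not affect the screen
                d = np.abs(raw - np.median(raw[common]))
                here = common & on_chip
                there = common & ~on_chip
                if here.sum() < 3 or there.sum() < 3:
                    continue
                excess.append(np.median(d[here]) - np.median(d[there]))
            if not excess:
                continue
            stat = float(np.median(excess))
            if stat > deviation_threshold:
                flags.append(ChipFlag(panel=panel, chip=chip, statistic=stat))
    return flags, unscreenable


def apply_mcar_mask(
    ds: NPXDataset,
    chip_flags: list[ChipFlag] | None = None,
    outliers: list[OutlierFlag] | None = None,
    assay_chip_exclusions: list[tuple[str, int]] | None = None,
) -> tuple[NPXDataset, GroundTruth, int]:
    """Set all flagged measurements to MAR_MISSING, recording the prior
    values in a GroundTruth with eval_mask over the newly masked cells.

    Masks whole chips (that panel's assays x the chip's samples),
    flagged samples (that panel's assays), and listed (assay_id, chip)
    pairs.  Returns the masked dataset, the truth, and the number of
    cells masked.
    """
    out = ds.copy()
    to_mask = np.zeros(ds.values.shape, dtype=bool)
    for f in chip_flags or []:
        cols = out.panel_columns(f.panel)
        rows = out.chip_rows(f.panel, f.chip)
        if rows.size == 0:
            raise DataModelError(f"no samples on chip {f.chip} of panel {f.panel}")
        to_mask[np.ix_(rows, cols)] = True
    sid_to_row = {s.sample_id: i for i, s in enumerate(out.samples)}
    for f in outliers or []:
        if f.sample_id not in sid_to_row:
            raise DataModelError(f"unknown sample {f.sample_id}")
        to_mask[sid_to_row[f.sample_id], out.panel_columns(f.panel)] = True
    aid_to_col = {a.assay_id: j for j, a in enumerate(out.assays)}
    for assay_id, chip in assay_chip_exclusions or []:
        if assay_id not in aid_to_col:
            raise DataModelError(f"unknown assay {assay_id}")
        j = aid_to_col[assay_id]
        rows = out.chip_rows(out.assays[j].panel, chip)
        to_mask[rows, j] = True

    new = to_mask & (out.mask != CellState.MAR_MISSING)
    remaining = (out.mask != CellState.MAR_MISSING) & ~new
    empty_cols = np.where(~remaining.any(axis=0))[0]
    if new.any() and empty_cols.size:
        bad = [out.assay_ids[j] for j in empty_cols]
        raise DataModelError(f"masking would empty assay column(s): {bad}")

    truth_values = np.where(new, out.values, np.nan)
    gt = GroundTruth(values=truth_values, eval_mask=new)
    out.values[new] = np.nan
    out.mask[new] = CellState.MAR_MISSING
    gt.check_against(out)
    return out, gt, int(new.sum())
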