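"""Core data model for NPX-style protein expression datasets.

A dataset is a samples x assays matrix of log2-scale relative expression
(NPX) values together with a per-cell state mask, per-assay metadata
(protein identity, panel membership, limit of detection) and per-sample
metadata (chip assignment per panel).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class CellState(IntEnum):
    """Per-cell observation state."""

    OBSERVED = 0
    MAR_MISSING = 1
    BELOW_LOD = 2


@dataclass(frozen=True)
class AssayMeta:
    """Metadata for one protein assay.

    ``protein_id`` is shared across duplicate assays of the same protein
    on different panels; ``lod`` is the per-assay limit of detection on
    the NPX scale.
    """

    assay_id: str
    protein_id: str
    panel: str
    lod: float


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: its chip index (1-based) per panel."""

    sample_id: str
    chip: dict[str, int] = field(default_factory=dict)


class DataModelError(ValueError):
    """Raised on invalid dataset construction or transform preconditions."""


MAX_CHIP_CAPACITY = 88


@dataclass
class NPXDataset:
    """Samples x assays NPX matrix with a three-state cell mask.

    ``values`` is float64, finite at OBSERVED cells, NaN at MAR_MISSING
    cells.  BELOW_LOD cells carry a finite value: the LOD itself before
    :func:`~peabench.preprocess.subtract_lod`, exactly 0 afterwards.
    """

    values: np.ndarray
    mask: np.ndarray
    assays: list[AssayMeta]
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        n, p = self.values.shape
        if self.mask.shape != (n, p):
            raise DataModelError(
                f"mask shape {self.mask.shape} != values shape {(n, p)}"
            )
        if len(self.assays) != p:
            raise DataModelError(f"{len(self.assays)} assay records for {p} columns")
        if len(self.samples) != n:
            raise DataModelError(f"{len(self.samples)} sample records for {n} rows")
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataModelError(f"duplicate assay_id(s): {dup}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            dup = sorted({i for i in sids if sids.count(i) > 1})
            raise DataModelError(f"duplicate sample_id(s): {dup}")
        bad_states = set(np.unique(self.mask)) - {int(s) for s in CellState}
        if bad_states:
            raise DataModelError(f"unknown mask states: {sorted(bad_states)}")
        obs = self.mask == CellState.OBSERVED
        if not np.isfinite(self.values[obs]).all():
            i, j = np.argwhere(obs & ~np.isfinite(self.values))[0]
            raise DataModelError(
                "non-finite value at OBSERVED cell "
                f"(sample {self.samples[i].sample_id}, assay {self.assays[j].assay_id})"
            )
        for smp in self.samples:
            for panel, chip in smp.chip.items():
                if chip < 1:
                    raise DataModelError(
                        f"chip index must be 1-based, got {chip} for {smp.sample_id}"
                    )
        for panel in self.panels():
            for smp in self.samples:
                if panel not in smp.chip:
                    raise DataModelError(
                        f"sample {smp.sample_id} has no chip for panel {panel}"
                    )
            counts: dict[int, int] = {}
            for smp in self.samples:
                c = smp.chip[panel]
                counts[c] = counts.get(c, 0) + 1
            for c, cnt in counts.items():
                if cnt > MAX_CHIP_CAPACITY:
                    raise DataModelError(
                        f"chip {c} on panel {panel} holds {cnt} samples "
                        f"(capacity {MAX_CHIP_CAPACITY})"
                    )

    # -- accessors -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    @property
    def assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def panels(self) -> list[str]:
        """Panel names in first-appearance order."""
        seen: dict[str, None] = {}
        for a in self.assays:
            seen.setdefault(a.panel, None)
        return list(seen)

    def panel_columns(self, panel: str) -> np.ndarray:
        """Column indices of assays on ``panel``."""
        idx = np.array([j for j, a in enumerate(self.assays) if a.panel == panel])
        if idx.size == 0:
            raise DataModelError(f"unknown panel: {panel}")
        return idx

    def chip_rows(self, panel: str, chip: int) -> np.ndarray:
        """Row indices of samples on ``chip`` (1-based) of ``panel``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if s.chip.get(panel) == chip],
            dtype=int,
        )

    def chips(self, panel: str) -> list[int]:
        return sorted({s.chip[panel] for s in self.samples if panel in s.chip})

    def duplicate_groups(self) -> dict[str, list[int]]:
        """protein_id -> column indices, for proteins with >= 2 assays."""
        groups: dict[str, list[int]] = {}
        for j, a in enumerate(self.assays):
            groups.setdefault(a.protein_id, []).append(j)
        return {pid: cols for pid, cols in groups.items() if len(cols) >= 2}

    def copy(self) -> "NPXDataset":
        return NPXDataset(
            values=self.values.copy(),
            mask=self.mask.copy(),
            assays=list(self.assays),
            samples=copy.deepcopy(self.samples),
        )

    def non_mar(self) -> np.ndarray:
        """Boolean matrix, True where the cell is OBSERVED or BELOW_LOD."""
        return self.mask != CellState.MAR_MISSING


@dataclass
class GroundTruth:
    """Complete matrix paired with the boolean mask of cells to score.

    ``eval_mask`` must be a subset of the paired dataset's MAR_MISSING
    cells; values are finite wherever ``eval_mask`` is True.
    """

    values: np.ndarray
    eval_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.eval_mask = np.asarray(self.eval_mask, dtype=bool)
        if self.values.shape != self.eval_mask.shape:
            raise DataModelError("truth values and eval_mask shapes differ")
        if not np.isfinite(self.values[self.eval_mask]).all():
            raise DataModelError("non-finite truth value at an eval cell")

    def check_against(self, ds: NPXDataset) -> None:
        if self.values.shape != ds.values.shape:
            raise DataModelError("truth shape does not match dataset")
        bad = self.eval_mask & (ds.mask != CellState.MAR_MISSING)
        if bad.any():
            raise DataModelError("eval_mask covers a cell that is not MAR_MISSING")
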