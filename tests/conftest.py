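import numpy as np
import pytest

from peabench.data_model import (
    AssayMeta,
    CellState,
    GroundTruth,
    NPXDataset,
    SampleMeta,
)
from peabench.preprocess import subtract_lod
from peabench.synthetic import SynthConfig, generate


@pytest.fixture
def tiny_ds() -> NPXDataset:
    """4 samples x 3 assays, one MAR cell, one BELOW_LOD cell."""
    values = np.array(
        [
            [5.0, 1.0, 2.0],
            [3.5, 2.0, 2.5],
            [3.0, np.nan, 3.0],
            [4.0, 3.0, 3.5],
        ]
    )
    mask = np.full((4, 3), CellState.OBSERVED, dtype=np.int8)
    mask[2, 1] = CellState.MAR_MISSING
    mask[2, 0] = CellState.BELOW_LOD
    assays = [
        AssayMeta("A1", "P1", "PanelA", 3.0),
        AssayMeta("A2", "P2", "PanelA", 0.0),
        AssayMeta("A3", "P3", "PanelB", 0.5),
    ]
    samples = [
        SampleMeta(f"S{i}", {"PanelA": 1 + i % 2, "PanelB": 1}) for i in range(4)
    ]
    return NPXDataset(values=values, mask=mask, assays=assays, samples=samples)


def small_config(**overrides) -> SynthConfig:
    base = dict(
        n_samples=120,
        panels=[("P1", 8), ("P2", 8)],
        n_chips=3,
        n_latent_factors=4,
        loading_range=(0.3, 1.0),
        unique_noise_sd=0.4,
        n_duplicate_proteins=2,
        n_triplicate_proteins=0,
        mar_chip=("P1", 2),
        extra_mar_rate=0.01,
        seed=7,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(small_config())


def lod_subtracted(bundle):
    """(LOD-subtracted observed dataset, truth on the same scale)."""
    lods = np.array([a.lod for a in bundle.observed.assays])
    ds = subtract_lod(bundle.observed)
    truth = GroundTruth(
        values=bundle.truth.values - lods[None, :], eval_mask=bundle.truth.eval_mask
    )
    return ds, truth
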