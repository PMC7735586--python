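"""Synthetic NPX-like data generator.

Emulates the structure of a multi-panel PEA study: a linear Gaussian
latent-factor model for cross-protein correlation, duplicate assays of
the same protein on different panels, per-assay left-censoring at a
limit of detection, randomized chip assignment per panel, and a
missing-completely-at-random mask (one whole chip plus scattered cells).
Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    AssayMeta,
    CellState,
    DataModelError,
    GroundTruth,
    NPXDataset,
    SampleMeta,
)

DEFAULT_PANELS: list[tuple[str, int]] = [
    ("Immune_Response", 92),
    ("Inflammation", 92),
    ("Cardiovascular_II", 92),
    ("Cardiovascular_III", 92),
    ("Cardiometabolic", 90),
]

# Fractions of assays with zero / <25% / 25-98% censoring (287:108:63 of 458).
CENSUS_BINS = (287 / 458, 108 / 458, 63 / 458)


@dataclass
class SynthConfig:
    """Knobs for :func:`generate`.

    ``duplicate_noise_sd=None`` calibrates per-protein measurement noise
    analytically so duplicate-assay correlation lands at
    ``duplicate_target_r`` in expectation.
    """

    n_samples: int = 802
    panels: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_PANELS))
    n_chips: int = 10
    chip_capacity: int = 88
    n_latent_factors: int = 6
    loading_range: tuple[float, float] = (0.2, 1.0)
    cross_panel_mixing: float = 0.3
    unique_noise_sd: float = 0.4
    n_duplicate_proteins: int = 12
    n_triplicate_proteins: int = 1
    duplicate_noise_sd: float | None = None
    duplicate_target_r: float = 0.884
    census_bins: tuple[float, float, float] = CENSUS_BINS
    lod_quantiles: list[float] | None = None
    mar_chip: tuple[str, int] | None = ("Inflammation", 7)
    extra_mar_rate: float = 0.003
    chip_effect_sd: float = 0.0
    npx_offset: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chips * self.chip_capacity < self.n_samples:
            raise DataModelError(
                f"{self.n_chips} chips x {self.chip_capacity} cannot hold "
                f"{self.n_samples} samples"
            )
        if self.lod_quantiles is not None:
            qs = np.asarray(self.lod_quantiles, dtype=float)
            if qs.size != self.n_assays:
                raise DataModelError("lod_quantiles length must equal total assays")
            if (qs < 0).any() or (qs > 0.98).any():
                raise DataModelError("censoring fractions must lie in [0, 0.98]")
        if not 0 <= self.extra_mar_rate < 1:
            raise DataModelError("extra_mar_rate must be in [0, 1)")
        n_multi = self.n_duplicate_proteins + self.n_triplicate_proteins
        if n_multi and len(self.panels) < 2:
            raise DataModelError("duplicate proteins need at least 2 panels")
        if self.n_triplicate_proteins and len(self.panels) < 3:
            raise DataModelError("triplicate proteins need at least 3 panels")

    @property
    def n_assays(self) -> int:
        return sum(n for _, n in self.panels)


@dataclass
class SynthBundle:
    """Generated truth, the censored/masked observed dataset, and the
    assay x factor loading matrix used to build the truth."""

    truth: GroundTruth
    observed: NPXDataset
    factor_loadings: np.ndarray
    config: SynthConfig

    @property
    def communality(self) -> np.ndarray:
        """Per-assay shared-signal variance, sum over factors of loading^2."""
        return (self.factor_loadings**2).sum(axis=1)


def _plan_assays(cfg: SynthConfig, rng: np.random.Generator):
    """Lay out assay slots per panel and assign protein identities,
    reserving slots for duplicate/triplicate proteins across panels."""
    panel_names = [p for p, _ in cfg.panels]
    slots = {p: n for p, n in cfg.panels}
    multiplicities = [2] * cfg.n_duplicate_proteins + [3] * cfg.n_triplicate_proteins
    assignments: list[tuple[str, list[str]]] = []  # (protein_id, panels)
    cursor = 0
    for m_idx, mult in enumerate(multiplicities):
        chosen = []
        tries = 0
        while len(chosen) < mult:
            p = panel_names[cursor % len(panel_names)]
            cursor += 1
            tries += 1
            if p not in chosen and slots[p] > 0:
                chosen.append(p)
                slots[p] -= 1
            if tries > 10 * len(panel_names):
                raise DataModelError("not enough panel slots for duplicate proteins")
        assignments.append((f"DUP{m_idx:03d}", chosen))
    uniq_idx = 0
    assay_plan: list[tuple[str, str]] = []  # (assay_id later, here (protein, panel))
    for pid, ps in assignments:
        for p in ps:
            assay_plan.append((pid, p))
    for p in panel_names:
        for _ in range(slots[p]):
            assay_plan.append((f"PROT{uniq_idx:04d}", p))
            uniq_idx += 1
    # stable order: group by panel in configured order
    order = {p: i for i, p in enumerate(panel_names)}
    assay_plan.sort(key=lambda t: order[t[1]])
    return assay_plan, panel_names


def _protein_loadings(
    cfg: SynthConfig, panel: str, panel_names: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Draw a loading vector for one protein homed on ``panel``.

    Factors are assigned home panels round-robin; loadings concentrate
    on home factors with a ``cross_panel_mixing`` leak elsewhere, scaled
    so the communality equals s^2 with s drawn from ``loading_range``.
    """
    K = cfg.n_latent_factors
    homes = [panel_names[k % len(panel_names)] for k in range(K)]
    w = np.empty(K)
    for k in range(K):
        if homes[k] == panel:
            w[k] = rng.uniform(0.5, 1.0)
        else:
            w[k] = rng.uniform(0.0, cfg.cross_panel_mixing)
    w *= rng.choice([-1.0, 1.0], size=K)
    s = rng.uniform(*cfg.loading_range)
    norm = np.linalg.norm(w)
    if norm == 0:
        w[rng.integers(K)] = 1.0
        norm = 1.0
    return s * w / norm


def _sample_lod_quantiles(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.lod_quantiles is not None:
        return np.asarray(cfg.lod_quantiles, dtype=float)
    p0, p_low, p_high = cfg.census_bins
    bins = rng.choice(3, size=n, p=[p0, p_low, p_high])
    q = np.zeros(n)
    q[bins == 1] = rng.uniform(0.01, 0.25, size=(bins == 1).sum())
    q[bins == 2] = rng.uniform(0.25, 0.98, size=(bins == 2).sum())
    return q


def _assign_chips(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomize samples to chips (1-based), near-equal sizes <= capacity."""
    n, c = cfg.n_samples, cfg.n_chips
    base, rem = divmod(n, c)
    sizes = [base + 1 if k < rem else base for k in range(c)]
    if max(sizes) > cfg.chip_capacity:
        raise DataModelError("infeasible chip assignment")
    chips = np.concatenate([np.full(sz, k + 1) for k, sz in enumerate(sizes)])
    rng.shuffle(chips)
    return chips


def generate(cfg: SynthConfig) -> SynthBundle:
    """Generate a complete truth matrix, then censor and mask it.

    Truth: x_ij = sum_k lambda_jk f_ik + u_ij (+ offset), with duplicate
    assays of one protein sharing the identical latent signal and unique
    noise, plus independent per-assay measurement noise.  The observed
    dataset censors cells at or below the per-assay LOD (value set to
    the LOD) and hides MAR cells (the configured whole chip plus
    scattered MCAR cells).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    assay_plan, panel_names = _plan_assays(cfg, rng)
    p = len(assay_plan)

    # protein-level latent signals
    F = rng.standard_normal((n, cfg.n_latent_factors))
    protein_load: dict[str, np.ndarray] = {}
    protein_signal: dict[str, np.ndarray] = {}
    home_panel: dict[str, str] = {}
    for pid, panel in assay_plan:
        home_panel.setdefault(pid, panel)
    for pid, panel in home_panel.items():
        lam = _protein_loadings(cfg, panel, panel_names, rng)
        protein_load[pid] = lam
        protein_signal[pid] = F @ lam + rng.normal(0.0, cfg.unique_noise_sd, size=n)

    protein_count: dict[str, int] = {}
    for pid, _ in assay_plan:
        protein_count[pid] = protein_count.get(pid, 0) + 1

    truth = np.empty((n, p))
    loadings = np.empty((p, cfg.n_latent_factors))
    assays: list[AssayMeta] = []
    r = cfg.duplicate_target_r
    for j, (pid, panel) in enumerate(assay_plan):
        sig = protein_signal[pid]
        if protein_count[pid] >= 2:
            if cfg.duplicate_noise_sd is not None:
                sd = cfg.duplicate_noise_sd
            else:
                var_shared = (protein_load[pid] ** 2).sum() + cfg.unique_noise_sd**2
                sd = float(np.sqrt(var_shared * (1.0 - r) / r))
            col = sig + rng.normal(0.0, sd, size=n)
        else:
            col = sig.copy()
        truth[:, j] = col + cfg.npx_offset
        loadings[j] = protein_load[pid]
        assays.append(AssayMeta(assay_id=f"A{j:04d}_{pid}", protein_id=pid, panel=panel, lod=np.nan))

    # per-assay LOD at the configured quantile of the marginal
    qs = _sample_lod_quantiles(cfg, p, rng)
    if cfg.lod_quantiles is None:
        # keep duplicate assays quantifiable so concordance is interpretable
        for j, (pid, _) in enumerate(assay_plan):
            if protein_count[pid] >= 2 and qs[j] > 0.25:
                qs[j] = rng.uniform(0.01, 0.25)
    lods = np.empty(p)
    for j in range(p):
        if qs[j] <= 0:
            lods[j] = truth[:, j].min() - 1.0
        else:
            lods[j] = float(np.quantile(truth[:, j], qs[j]))
    assays = [
        AssayMeta(a.assay_id, a.protein_id, a.panel, float(lods[j]))
        for j, a in enumerate(assays)
    ]

    # chip randomization, independent per panel
    chip_by_panel = {panel: _assign_chips(cfg, rng) for panel in panel_names}
    samples = [
        SampleMeta(
            sample_id=f"S{i:04d}",
            chip={panel: int(chip_by_panel[panel][i]) for panel in panel_names},
        )
        for i in range(n)
    ]

    observed = truth.copy()
    mask = np.full((n, p), CellState.OBSERVED, dtype=np.int8)

    if cfg.chip_effect_sd > 0:
        for panel in panel_names:
            cols = [j for j, a in enumerate(assays) if a.panel == panel]
            for chip in range(1, cfg.n_chips + 1):
                rows = np.where(chip_by_panel[panel] == chip)[0]
                observed[np.ix_(rows, cols)] += rng.normal(0.0, cfg.chip_effect_sd)

    below = truth <= lods[None, :]
    mask[below] = CellState.BELOW_LOD
    observed[below] = np.broadcast_to(lods, (n, p))[below]

    # whole-chip MAR
    mar = np.zeros((n, p), dtype=bool)
    if cfg.mar_chip is not None:
        panel, chip = cfg.mar_chip
        if panel not in panel_names:
            raise DataModelError(f"mar_chip panel {panel!r} not in configured panels")
        cols = [j for j, a in enumerate(assays) if a.panel == panel]
        rows = np.where(chip_by_panel[panel] == chip)[0]
        mar[np.ix_(rows, cols)] = True
    if cfg.extra_mar_rate > 0:
        scatter = rng.random((n, p)) < cfg.extra_mar_rate
        mar |= scatter
    mask[mar] = CellState.MAR_MISSING
    observed[mar] = np.nan

    ds = NPXDataset(values=observed, mask=mask, assays=assays, samples=samples)
    # score only MAR cells whose truth would have been quantifiable
    eval_mask = mar & (truth > lods[None, :])
    gt = GroundTruth(values=truth, eval_mask=eval_mask)
    gt.check_against(ds)
    return SynthBundle(truth=gt, observed=ds, factor_loadings=loadings, config=cfg)


def census_below_lod(ds: NPXDataset) -> np.ndarray:
    """Per-assay fraction of non-MAR cells that are below the LOD."""
    below = (ds.mask == CellState.BELOW_LOD).sum(axis=0)
    non_mar = (ds.mask != CellState.MAR_MISSING).sum(axis=0)
    if (non_mar == 0).any():
        bad = [ds.assay_ids[j] for j in np.where(non_mar == 0)[0]]
        raise DataModelError(f"assay(s) with zero non-MAR cells: {bad}")
    return below / non_mar
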