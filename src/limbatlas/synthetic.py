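"""Synthetic UMI-count atlases with planted ground truth.

Counts are negative-binomially distributed (NB2: variance = mu + mu^2 * phi,
gene-wise phi) around per-gene base means drawn lognormally, modulated by

* population-specific marker fold-changes,
* latent per-cell co-expression factors acting multiplicatively on the
  log-mean of module genes,
* cell-cycle-phase-dependent shifts on (up, down) marker-gene pairs,
* lognormal per-cell library sizes, and
* planted QC-outlier cells (inflated library size or mitochondrial load).

Zero inflation arises only from NB sampling; there is no extra dropout
layer. Every draw is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .cellcycle import PairSet
from .io import CountMatrix, GeneClassMap

__all__ = [
    "PopulationSpec",
    "ModuleSpec",
    "OutlierSpec",
    "SimConfig",
    "SimTruth",
    "simulate_atlas",
    "preset",
    "PRESETS",
]

PHASES = ("G1", "S", "G2M")


@dataclass
class PopulationSpec:
    name: str
    proportion: float
    marker_genes: int = 0
    marker_fold: float = 1.0


@dataclass
class ModuleSpec:
    gene_count: int
    factor_sd: float = 1.0
    loading: float = 0.8
    # optional linkage of the latent factor to one population: cells of that
    # population get their factor shifted by active_shift standard deviations
    active_population: str | None = None
    active_shift: float = 2.0


@dataclass
class OutlierSpec:
    high_umi_frac: float = 0.0
    high_umi_mult: float = 6.0
    high_mito_frac: float = 0.0
    high_mito_level: float = 0.25


@dataclass
class SimConfig:
    """Full parameterization of one simulated atlas."""

    n_cells: int = 500
    n_genes: int = 1000
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [PopulationSpec("pop0", 1.0)]
    )
    modules: list[ModuleSpec] = field(default_factory=list)
    phase_proportions: dict[str, float] = field(
        default_factory=lambda: {"G1": 1.0, "S": 0.0, "G2M": 0.0}
    )
    pair_count: int = 0
    pair_effect: float = 3.0
    # lognormal library sizes, natural-log parameterization
    library_mean_log: float = np.log(2000.0)
    library_sd_log: float = 0.25
    # per-gene NB dispersion phi ~ Gamma(shape, scale)
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.15
    # base relative abundances ~ lognormal(base_mean_log, base_sd_log)
    base_mean_log: float = 0.0
    base_sd_log: float = 1.0
    mito_gene_count: int = 10
    ribo_gene_count: int = 20
    mito_base_share: float = 0.03
    ribo_base_share: float = 0.04
    outliers: OutlierSpec = field(default_factory=OutlierSpec)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(p.proportion for p in self.populations) - 1.0) > 1e-8:
            raise ValueError("population proportions must sum to 1")
        if abs(sum(self.phase_proportions.values()) - 1.0) > 1e-8:
            raise ValueError("phase proportions must sum to 1")
        special = (
            sum(p.marker_genes for p in self.populations)
            + sum(m.gene_count for m in self.modules)
            + 2 * self.pair_count * len(PHASES)
            + self.mito_gene_count
            + self.ribo_gene_count
        )
        if special > self.n_genes:
            raise ValueError(
                f"gene blocks need {special} genes but n_genes={self.n_genes}"
            )


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside a simulated CountMatrix."""

    population_label: np.ndarray  # (n_cells,) str
    phase_label: np.ndarray  # (n_cells,) str
    module_gene_sets: list[list[str]]
    module_factor: np.ndarray  # (n_cells, n_modules)
    outlier_flag: np.ndarray  # (n_cells,) bool
    outlier_kind: np.ndarray  # (n_cells,) str ("", "high_umi", "high_mito")
    pair_sets: list[PairSet]
    marker_gene_sets: dict[str, list[str]]
    gene_classes: GeneClassMap


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray):
    """NB2 draws with variance mu + mu^2 * phi; phi == 0 falls back to Poisson."""
    mu = np.broadcast_to(mu, np.broadcast_shapes(mu.shape, phi.shape))
    counts = np.zeros(mu.shape, dtype=np.int64)
    pois = np.broadcast_to(phi <= 0, counts.shape)
    if np.any(pois):
        counts[pois] = rng.poisson(np.broadcast_to(mu, counts.shape)[pois])
    if np.any(~pois):
        idx = ~pois
        phi_b = np.broadcast_to(phi, counts.shape)[idx]
        mu_b = np.broadcast_to(mu, counts.shape)[idx]
        r = 1.0 / phi_b
        p = r / (r + mu_b)
        counts[idx] = rng.negative_binomial(r, p)
    return counts


def simulate_atlas(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw one UMI-count atlas with planted structure.

    Returns the counts as a :class:`CountMatrix` (genes x cells) plus the
    :class:`SimTruth` record of everything that was planted.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, C = cfg.n_genes, cfg.n_cells

    gene_ids = [f"G{i:05d}" for i in range(G)]

    # --- deterministic gene-block layout (disjoint by construction) ---
    cursor = 0

    def take(n):
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    marker_idx = {p.name: take(p.marker_genes) for p in cfg.populations}
    module_idx = [take(m.gene_count) for m in cfg.modules]
    pair_idx = {ph: (take(cfg.pair_count), take(cfg.pair_count)) for ph in PHASES}
    mito_idx = take(cfg.mito_gene_count)
    ribo_idx = take(cfg.ribo_gene_count)

    classes = {gene_ids[i]: "mitochondrial" for i in mito_idx}
    classes.update({gene_ids[i]: "ribosomal" for i in ribo_idx})
    gene_classes = GeneClassMap(classes)

    # --- per-gene base abundances and dispersions ---
    base = rng.lognormal(cfg.base_mean_log, cfg.base_sd_log, size=G)
    phi = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale, size=G)

    # pair genes share a common base mean within each (hi, lo) pair so that
    # out-of-phase cells rank them 50/50
    for ph in PHASES:
        hi, lo = pair_idx[ph]
        base[lo] = base[hi]

    # pin organelle classes to a target share of total expression
    for idx, share in ((mito_idx, cfg.mito_base_share), (ribo_idx, cfg.ribo_base_share)):
        if len(idx):
            cur = base[idx].sum() / base.sum()
            t = share * (1 - cur) / (cur * (1 - share))
            base[idx] *= t

    # --- per-cell assignments ---
    pop_names = [p.name for p in cfg.populations]
    pop_label = rng.choice(
        pop_names, size=C, p=[p.proportion for p in cfg.populations]
    )
    phase_label = rng.choice(
        PHASES, size=C, p=[cfg.phase_proportions.get(ph, 0.0) for ph in PHASES]
    )
    lib = rng.lognormal(cfg.library_mean_log, cfg.library_sd_log, size=C)

    n_hi_umi = int(round(cfg.outliers.high_umi_frac * C))
    n_hi_mito = int(round(cfg.outliers.high_mito_frac * C))
    out_cells = rng.choice(C, size=n_hi_umi + n_hi_mito, replace=False)
    outlier_kind = np.full(C, "", dtype=object)
    outlier_kind[out_cells[:n_hi_umi]] = "high_umi"
    outlier_kind[out_cells[n_hi_umi:]] = "high_mito"
    # high-UMI outliers sit at high_umi_mult times the expected library size
    # (pinned, not scaled from their own draw, so the planted effect is exact)
    expected_lib = np.exp(cfg.library_mean_log + cfg.library_sd_log**2 / 2)
    lib[outlier_kind == "high_umi"] = cfg.outliers.high_umi_mult * expected_lib

    factors = np.zeros((C, len(cfg.modules)))
    for j, m in enumerate(cfg.modules):
        f = rng.normal(0.0, m.factor_sd, size=C)
        if m.active_population is not None:
            f = f + m.active_shift * m.factor_sd * (
                pop_label == m.active_population
            )
        factors[:, j] = f

    # --- per-cell mean matrix (genes x cells) ---
    mean = np.repeat(base[:, None], C, axis=1)
    for p in cfg.populations:
        cells = pop_label == p.name
        if p.marker_genes and p.marker_fold != 1.0:
            mean[np.ix_(marker_idx[p.name], cells)] *= p.marker_fold
    for j, m in enumerate(cfg.modules):
        mean[module_idx[j]] *= np.exp(m.loading * factors[:, j])[None, :]
    for ph in PHASES:
        hi, lo = pair_idx[ph]
        cells = phase_label == ph
        if len(hi) and cells.any():
            mean[np.ix_(hi, cells)] *= cfg.pair_effect
            mean[np.ix_(lo, cells)] /= cfg.pair_effect
    hi_mito = outlier_kind == "high_mito"
    if hi_mito.any() and len(mito_idx):
        sub = mean[np.ix_(mito_idx, hi_mito)]
        cur = sub.sum(axis=0) / mean[:, hi_mito].sum(axis=0)
        s = cfg.outliers.high_mito_level
        mean[np.ix_(mito_idx, hi_mito)] *= s * (1 - cur) / (cur * (1 - s))

    # normalize per cell to the drawn library size
    mu = mean / mean.sum(axis=0, keepdims=True) * lib[None, :]
    counts = _nb_sample(rng, mu, phi[:, None])

    cm = CountMatrix(
        sp.csr_matrix(counts),
        gene_ids,
        list(gene_ids),
        [f"BC{i:05d}" for i in range(C)],
    )
    pair_sets = [
        PairSet(
            ph,
            [
                (gene_ids[h], gene_ids[l])
                for h, l in zip(pair_idx[ph][0], pair_idx[ph][1])
            ],
        )
        for ph in PHASES
        if cfg.pair_count
    ]
    truth = SimTruth(
        population_label=pop_label,
        phase_label=phase_label,
        module_gene_sets=[[gene_ids[i] for i in idx] for idx in module_idx],
        module_factor=factors,
        outlier_flag=outlier_kind != "",
        outlier_kind=outlier_kind,
        pair_sets=pair_sets,
        marker_gene_sets={
            p.name: [gene_ids[i] for i in marker_idx[p.name]]
            for p in cfg.populations
        },
        gene_classes=gene_classes,
    )
    return cm, truth


def _three_pop_config() -> SimConfig:
    # three discrete populations on top of population-agnostic latent
    # co-expression programs: real atlases always carry continuous
    # within-population variation, and without it the significant-PC space
    # collapses to the two discriminant directions, a degenerate geometry
    # no real sample exhibits
    return SimConfig(
        n_cells=600,
        n_genes=1000,
        populations=[
            PopulationSpec("popA", 0.4, marker_genes=40, marker_fold=4.0),
            PopulationSpec("popB", 0.35, marker_genes=40, marker_fold=4.0),
            PopulationSpec("popC", 0.25, marker_genes=40, marker_fold=4.0),
        ],
        modules=[
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
        ],
        seed=0,
    )


PRESETS = {
    "qc_outliers": lambda: SimConfig(
        n_cells=600,
        n_genes=1000,
        outliers=OutlierSpec(
            high_umi_frac=20 / 600,
            high_umi_mult=6.0,
            high_mito_frac=20 / 600,
            high_mito_level=0.25,
        ),
        seed=0,
    ),
    "three_pops": _three_pop_config,
    # three populations with NO latent programs: any fine-resolution split
    # inside a population is spurious by construction, so DE-based collapse
    # must undo it (continuous module factors would create genuinely
    # differentiated sub-clusters the collapse rule correctly keeps)
    "overclustered": lambda: replace(_three_pop_config(), modules=[]),
    "planted_modules": lambda: SimConfig(
        n_cells=500,
        n_genes=290,
        mito_gene_count=0,
        ribo_gene_count=0,
        modules=[
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
        ],
        seed=0,
    ),
    "cellcycle": lambda: SimConfig(
        n_cells=400,
        n_genes=800,
        phase_proportions={"G1": 0.5, "S": 0.25, "G2M": 0.25},
        pair_count=40,
        pair_effect=3.0,
        seed=0,
    ),
    "two_stage_shared_module": lambda: SimConfig(
        n_cells=400,
        n_genes=600,
        populations=[
            PopulationSpec("shared", 0.5, marker_genes=30, marker_fold=4.0),
            PopulationSpec("private", 0.5, marker_genes=30, marker_fold=4.0),
        ],
        modules=[
            ModuleSpec(
                30, factor_sd=0.5, loading=0.8,
                active_population="shared", active_shift=3.0,
            ),
            ModuleSpec(30, factor_sd=1.0, loading=0.8),
        ],
        seed=0,
    ),
}


def preset(name: str) -> SimConfig:
    """Return the fixture configuration for one named scenario."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name]()


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with the RNG seed replaced."""
    return replace(cfg, seed=seed)
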