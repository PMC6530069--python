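"""Configuration-driven orchestration of the per-stage pipeline and the
cross-stage module-activity comparison.

A stage runs: read counts -> QC filter -> log-normalize -> cell-cycle
scores -> two-tier clustering -> recursive cluster collapse -> per-cluster
marker signatures -> (reference stage only) iterative co-expression module
discovery -> per-cell module activity. Modules discovered on one
designated reference stage — the transcriptionally most complex sample —
are then scored on every stage and averaged per (stage, sub-cluster)
group. Every output table carries the configuration hash and seed, so two
runs with equal hashes are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cellcycle as cc
from . import cluster as cl
from . import coexpression as cx
from . import de as de_mod
from . import qc_norm as qn
from . import synthetic as syn
from .io import CountMatrix, GeneClassMap, read_count_matrix

logger = logging.getLogger(__name__)

__all__ = ["StageInput", "RunConfig", "StageResult", "run_stage", "run_cross_stage"]

# Reference per-stage retained-cell counts (Hamburger-Hamilton stages 25,
# 29 and 31) of the chicken autopod atlas whose workflow this package
# implements; kept as metadata for consistency checks.
ATLAS_STAGE_CELLS = {"HH25": 5982, "HH29": 6823, "HH31": 4823}


@dataclass
class StageInput:
    matrix: str | None = None
    genes: str | None = None
    barcodes: str | None = None
    gene_classes: str | None = None
    preset: str | None = None  # simulate instead of reading from disk
    seed: int | None = None
    resolution_broad: float | None = None
    resolution_fine: float | None = None

    def __post_init__(self):
        if self.preset is None and self.matrix is None:
            raise ValueError("stage needs either triplet paths or a preset")


@dataclass
class RunConfig:
    stages: dict[str, StageInput] = field(default_factory=dict)
    reference_stage: str | None = None
    out_dir: str = "limbatlas_out"
    seed: int = 0
    qc: qn.QCThresholds = field(default_factory=qn.QCThresholds)
    norm_scale_factor: float = 1e4
    hvg_dispersion_cutoff: float = 0.5
    hvg_n_bins: int = 20
    cellcycle_pairs_path: str | None = None
    cellcycle_ortholog_path: str | None = None
    cluster_k: int = 20
    cluster_resolution_broad: float = 0.4
    cluster_resolution_fine: float = 1.4
    cluster_snn_prune: float = cl.DEFAULT_SNN_PRUNE
    cluster_max_components: int = 50
    de: de_mod.DEThresholds = field(default_factory=de_mod.DEThresholds)
    coexpr: cx.CoexprParams = field(default_factory=cx.CoexprParams)

    def config_hash(self) -> str:
        plain = _to_plain(self)
        plain.pop("out_dir", None)  # analysis identity, not output location
        blob = json.dumps(plain, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        stages = {
            name: _build(StageInput, spec)
            for name, spec in d.pop("stages", {}).items()
        }
        qc = _build(qn.QCThresholds, d.pop("qc", {}))
        de = _build(de_mod.DEThresholds, d.pop("de", {}))
        coexpr = _build(cx.CoexprParams, d.pop("coexpr", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(stages=stages, qc=qc, de=de, coexpr=coexpr, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build(cls, spec: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**spec)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


@dataclass
class StageResult:
    stage: str
    cm: CountMatrix  # filtered counts
    qc_table: pd.DataFrame
    nm: qn.NormalizedMatrix
    phase_scores: cc.PhaseScores | None
    hvg: list[str]
    labels: cl.ClusterLabels
    collapsed: np.ndarray
    merge_log: list[dict]
    signatures: dict[int, list[str]]
    de_tables: dict[int, pd.DataFrame]
    module_set: cx.ModuleSet | None
    activity: pd.DataFrame | None


def _load_stage(cfg: RunConfig, name: str):
    si = cfg.stages[name]
    if si.preset is not None:
        sim = syn.preset(si.preset)
        sim = syn.with_seed(sim, si.seed if si.seed is not None else cfg.seed)
        cm, truth = syn.simulate_atlas(sim)
        return cm, truth.gene_classes, truth
    cm = read_count_matrix(si.matrix, si.genes, si.barcodes)
    classes = (
        GeneClassMap.from_tsv(si.gene_classes) if si.gene_classes else GeneClassMap()
    )
    return cm, classes, None


def _write(df: pd.DataFrame, path: str, header_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        df.to_csv(fh, sep="\t")


def run_stage(cfg: RunConfig, stage_name: str, write: bool = True) -> StageResult:
    """Execute the full per-stage pipeline and write its tables."""
    if stage_name not in cfg.stages:
        raise KeyError(f"stage {stage_name!r} not configured")
    si = cfg.stages[stage_name]
    cm_raw, classes, truth = _load_stage(cfg, stage_name)

    qc = qn.compute_qc_metrics(cm_raw, classes)
    kept, qc = qn.filter_cells(qc, cfg.qc)
    keep_mask = qc["keep"].to_numpy()
    cm = cm_raw.subset_cells(keep_mask)

    nm = qn.lognormalize(cm, cfg.norm_scale_factor)

    phase_scores = None
    delta = pd.Series(0.0, index=pd.Index(cm.barcodes, name="barcode"))
    pairsets = None
    if truth is not None and truth.pair_sets:
        pairsets = truth.pair_sets
    elif cfg.cellcycle_pairs_path:
        pairsets = cc.read_pair_tables(cfg.cellcycle_pairs_path)
        if cfg.cellcycle_ortholog_path:
            pairsets, _ = cc.translate_pairs(
                pairsets, cc.read_ortholog_table(cfg.cellcycle_ortholog_path)
            )
    if pairsets is not None:
        phase_scores = cc.score_phases(nm, pairsets)
        delta = pd.Series(
            phase_scores.delta_g2m_s, index=pd.Index(cm.barcodes, name="barcode")
        )
    else:
        logger.info("no cell-cycle pairs for stage %s; delta_g2m_s = 0", stage_name)

    hvg = qn.select_variable_genes(nm, cfg.hvg_dispersion_cutoff, cfg.hvg_n_bins)
    hvg_idx = [i for i, g in enumerate(nm.gene_ids) if g in set(hvg)]
    nm_hvg = nm.subset_genes(hvg_idx)

    cov_cols = {
        "umi_total": cm.cell_totals().astype(float),
        "mito_frac": qc.loc[keep_mask, "mito_frac"].to_numpy(),
    }
    if phase_scores is not None:
        cov_cols["delta_g2m_s"] = delta.to_numpy()
    covars = pd.DataFrame(cov_cols, index=pd.Index(cm.barcodes, name="barcode"))
    covars = covars.loc[:, covars.std() > 0]  # constant nuisances carry no signal
    sm_cluster = qn.regress_and_scale(nm_hvg, covars)

    res_broad = si.resolution_broad or cfg.cluster_resolution_broad
    res_fine = si.resolution_fine or cfg.cluster_resolution_fine
    labels = cl.cluster_two_tier(
        sm_cluster,
        resolution_broad=res_broad,
        resolution_fine=res_fine,
        k=cfg.cluster_k,
        seed=cfg.seed,
        snn_prune=cfg.cluster_snn_prune,
        max_components=cfg.cluster_max_components,
    )

    collapsed, merge_log = de_mod.collapse_clusters(
        cm, sm_cluster, labels.labels_fine, covariate=delta, th=cfg.de
    )

    signatures = {}
    de_tables = {}
    for cid in np.unique(collapsed):
        rest = np.flatnonzero(collapsed != cid)
        focus = np.flatnonzero(collapsed == cid)
        if len(focus) < 3 or len(rest) < 3:
            signatures[int(cid)] = []
            continue
        det = de_mod.nb_de_test(cm, focus, rest, covariate=delta, th=cfg.de)
        signatures[int(cid)] = de_mod.marker_signature(det, cfg.de)
        de_tables[int(cid)] = det

    module_set = None
    activity = None
    if cfg.reference_stage == stage_name:
        module_set = cx.iterative_module_discovery(nm_hvg, cfg.coexpr)
        activity = cx.module_activity(nm, module_set.assignment)

    result = StageResult(
        stage=stage_name,
        cm=cm,
        qc_table=qc,
        nm=nm,
        phase_scores=phase_scores,
        hvg=hvg,
        labels=labels,
        collapsed=collapsed,
        merge_log=merge_log,
        signatures=signatures,
        de_tables=de_tables,
        module_set=module_set,
        activity=activity,
    )
    if write:
        _write_stage(cfg, result)
    return result


def _write_stage(cfg: RunConfig, res: StageResult) -> None:
    out = os.path.join(cfg.out_dir, res.stage)
    os.makedirs(out, exist_ok=True)
    tag = f"# config_hash={cfg.config_hash()} seed={cfg.seed}"
    _write(res.qc_table, os.path.join(out, "qc.tsv"), tag)
    clusters = pd.DataFrame(
        {
            "label_broad": res.labels.labels_broad,
            "label_fine": res.labels.labels_fine,
            "label_collapsed": res.collapsed,
        },
        index=pd.Index(res.cm.barcodes, name="barcode"),
    )
    _write(clusters, os.path.join(out, "clusters.tsv"), tag)
    if res.phase_scores is not None:
        _write(res.phase_scores.to_frame(), os.path.join(out, "phase_scores.tsv"), tag)
    _write(
        pd.DataFrame(res.merge_log, columns=["round", "kept", "merged", "n_de"]),
        os.path.join(out, "merge_log.tsv"),
        tag,
    )
    sig = pd.DataFrame(
        [(c, g) for c, genes in sorted(res.signatures.items()) for g in genes],
        columns=["cluster", "gene"],
    )
    _write(sig, os.path.join(out, "signatures.tsv"), tag)
    names = dict(zip(res.cm.gene_ids, res.cm.gene_names))
    if res.de_tables:
        markers = pd.concat(
            [
                de_mod.de_table_for_export(t, c, names)
                for c, t in sorted(res.de_tables.items())
            ],
            ignore_index=True,
        )
    else:
        markers = de_mod.de_table_for_export(de_mod._empty_de_frame(), 0, names)
    _write(markers, os.path.join(out, "markers.tsv"), tag)
    with open(os.path.join(out, "hvg.txt"), "w") as fh:
        fh.write(tag + "\n")
        for g in res.hvg:
            fh.write(g + "\n")
    if res.module_set is not None:
        ms = res.module_set
        mod_table = pd.DataFrame(
            {
                "nodeName": ms.assignment.index,
                "module": ms.assignment.to_numpy(),
                "membership": [
                    ms.membership.loc[g, m] if m != cx.UNASSIGNED else np.nan
                    for g, m in ms.assignment.items()
                ],
            }
        )
        _write(mod_table.set_index("nodeName"), os.path.join(out, "modules.tsv"), tag)
        _write(ms.eigengenes, os.path.join(out, "eigengenes.tsv"), tag)
        _write(res.activity, os.path.join(out, "activity.tsv"), tag)


def run_cross_stage(
    cfg: RunConfig, results: dict[str, StageResult] | None = None, write: bool = True
):
    """Score the reference stage's modules on every stage.

    Returns (module x (stage, sub-cluster) mean-activity table, row order,
    column order, per-stage per-module gene-coverage fractions).
    """
    if cfg.reference_stage is None:
        raise ValueError("reference_stage must be set")
    if results is None:
        results = {s: run_stage(cfg, s, write=write) for s in cfg.stages}
    ref = results[cfg.reference_stage]
    if ref.module_set is None:
        raise ValueError("reference stage has no ModuleSet")
    ms = ref.module_set

    frames, coverage = [], {}
    for stage, res in results.items():
        present = set(res.nm.gene_ids)
        cov = {}
        keep_modules = []
        for m in ms.module_labels:
            genes = ms.genes_of(m)
            frac = sum(g in present for g in genes) / max(len(genes), 1)
            cov[m] = frac
            if frac > 0:
                keep_modules.append(m)
            else:
                logger.warning("module %s absent from stage %s; excluded", m, stage)
        coverage[stage] = cov
        assign = ms.assignment[ms.assignment.isin(keep_modules)]
        act = cx.module_activity(res.nm, assign)
        act.index = pd.MultiIndex.from_arrays(
            [[stage] * len(act), res.collapsed], names=["stage", "sub_cluster"]
        )
        frames.append(act)
    allact = pd.concat(frames)
    groups = list(allact.index)
    allact = allact.reset_index(drop=True)
    mat, row_order, col_order = cx.activity_by_group(allact, groups)
    if write:
        os.makedirs(cfg.out_dir, exist_ok=True)
        tag = f"# config_hash={cfg.config_hash()} seed={cfg.seed}"
        flat = mat.copy()
        flat.columns = [f"{s}:{c}" for s, c in flat.columns]
        _write(flat, os.path.join(cfg.out_dir, "cross_stage_activity.tsv"), tag)
    return mat, row_order, col_order, coverage
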