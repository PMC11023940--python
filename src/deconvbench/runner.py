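"""Configuration-driven benchmark execution.

A run walks the full grid: QC -> stratified split -> reference build ->
each simulation scenario -> each preprocessing spec -> each solver ->
evaluation (+ consensus and cross-method agreement), writing every
artifact as TSV under the output directory together with a manifest
(config echo, per-stage wall/CPU time and peak RSS, file inventory with
checksums). A rerun with the same config and seed reproduces the numeric
artifacts byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .datasets import BulkMatrix, ProportionMatrix, SingleCellDataset
from .metrics import agreement_analysis, build_metrics_report, plot_agreement_heatmap
from .preprocess import PreprocessSpec, preprocess_pair
from .pseudobulk import SimulationConfig, simulate
from .reference import ReferenceBundle, build_reference, split_train_test
from .solvers import SolverSpec, _max_rss_bytes, consensus, run_methods
from .synth import SynthConfig, generate_sc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a benchmark run needs; loadable from a YAML file."""

    outdir: str = "deconvbench_out"
    seed: int = 0
    synthdata: dict | None = None
    input: dict | None = None          # expression/annotation paths
    split_fraction: float = 0.5
    qc: bool = True
    markers: bool = True
    simulations: list = field(default_factory=lambda: [{}])
    preprocessing: list = field(default_factory=lambda: [{}])
    solvers: list = field(default_factory=lambda: ["nnls"])
    consensus_members: list = field(default_factory=lambda: ["dwls", "rlr", "nnls"])
    scopes: tuple = ("overall",)

    def __post_init__(self) -> None:
        if not self.solvers:
            raise ValueError("at least one solver is required")
        if self.synthdata is None and self.input is None:
            raise ValueError("config needs either a 'synthdata' or an 'input' section")
        if self.input is not None:
            for key in ("expression", "annotation"):
                p = self.input.get(key)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"input.{key}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    inventory: dict = field(default_factory=dict)   # path -> sha256

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"config": self.config, "stages": self.stages,
                 "inventory": self.inventory},
                fh, sort_keys=False)

    def validate_inventory(self, root: str | Path) -> None:
        """Fail if any inventoried artifact is missing or altered."""
        root = Path(root)
        for rel, digest in self.inventory.items():
            p = root / rel
            if not p.exists():
                raise FileNotFoundError(f"inventoried artifact missing: {rel}")
            if _sha256(p) != digest:
                raise ValueError(f"inventoried artifact changed: {rel}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageTimer:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0, self.c0 = time.perf_counter(), time.process_time()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.stages.append({
            "stage": self.name,
            "wall_time_s": round(time.perf_counter() - self.t0, 6),
            "cpu_time_s": round(time.process_time() - self.c0, 6),
            "max_rss_bytes": _max_rss_bytes(),
            "failed": exc_type is not None,
        })
        return False


def _load_source(cfg: RunConfig) -> SingleCellDataset:
    if cfg.synthdata is not None:
        synth_cfg = SynthConfig(**{**cfg.synthdata, "seed":
                                   cfg.synthdata.get("seed", cfg.seed)})
        return generate_sc(synth_cfg)
    ds = dio.read_expression(cfg.input["expression"],
                             fmt=cfg.input.get("fmt"),
                             annotation=cfg.input["annotation"])
    return ds


def _write(df: pd.DataFrame, outdir: Path, rel: str, manifest: RunManifest,
           index_label: str = "gene") -> None:
    path = outdir / rel
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
    manifest.inventory[rel] = _sha256(path)


def run_benchmark(cfg: RunConfig) -> RunManifest:
    """Execute the full benchmark grid described by ``cfg``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(cfg))
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3 + len(cfg.simulations))
    seeds = [int(s % (2 ** 31)) for s in seeds]
    try:
        with _StageTimer(manifest, "load_or_generate"):
            ds = _load_source(cfg)
        if cfg.qc:
            with _StageTimer(manifest, "qc"):
                ds = dio.qc_filter(ds)
        with _StageTimer(manifest, "split"):
            train, test = split_train_test(ds, fraction=cfg.split_fraction,
                                           seed=seeds[0])
        with _StageTimer(manifest, "reference"):
            ref = build_reference(train, with_markers=cfg.markers)
            _write(ref.C1, outdir, "reference/C1.tsv", manifest)
            _write(ref.ref_var, outdir, "reference/refVar.tsv", manifest)
            c2_rows = [(ct, g) for ct, genes in ref.C2.items() for g in genes]
            _write(pd.DataFrame(c2_rows, columns=["cell_type", "gene"])
                   .set_index("cell_type"),
                   outdir, "reference/C2.tsv", manifest, index_label="cell_type")

        all_metrics = []
        for si, sim_kwargs in enumerate(cfg.simulations):
            sim_cfg = SimulationConfig(**{**sim_kwargs, "seed":
                                          sim_kwargs.get("seed", seeds[3 + si])})
            with _StageTimer(manifest, f"simulate[{si}]"):
                exp = simulate(test, sim_cfg)
            _write(exp.bulk.to_frame(), outdir, f"sim_{si}/pseudobulk.tsv", manifest)
            _write(exp.truth.to_frame(), outdir, f"sim_{si}/truth.tsv", manifest,
                   index_label="sample")
            for pi, prep_kwargs in enumerate(cfg.preprocessing):
                spec = PreprocessSpec(**prep_kwargs)
                with _StageTimer(manifest, f"preprocess[{si}][{pi}]"):
                    bulk_p, c1_p = preprocess_pair(exp.bulk, ref, spec)
                with _StageTimer(manifest, f"solve[{si}][{pi}]"):
                    results = run_methods(c1_p, bulk_p,
                                          [_solver_spec(s) for s in cfg.solvers],
                                          record_to=manifest.stages)
                for name, props in results.items():
                    _write(props.to_frame(), outdir,
                           f"sim_{si}/prep_{pi}/props_{name}.tsv", manifest,
                           index_label="sample")
                with _StageTimer(manifest, f"evaluate[{si}][{pi}]"):
                    report = build_metrics_report(results, exp.truth,
                                                  scopes=tuple(cfg.scopes))
                    report.insert(0, "prep", spec.label)
                    report.insert(0, "sim", si)
                    all_metrics.append(report)
                if len(results) >= 2:
                    members = [m for m in cfg.consensus_members if m in results]
                    if len(members) >= 2:
                        with _StageTimer(manifest, f"consensus[{si}][{pi}]"):
                            cons = consensus(results, members=tuple(members))
                        _write(cons.mean_props.to_frame(), outdir,
                               f"sim_{si}/prep_{pi}/consensus.tsv", manifest,
                               index_label="sample")
                        _write(cons.per_cell_type_sd, outdir,
                               f"sim_{si}/prep_{pi}/consensus_sd.tsv", manifest,
                               index_label="sample")
                    corr, order = agreement_analysis(results)
                    _write(corr.loc[order, order], outdir,
                           f"sim_{si}/prep_{pi}/agreement.tsv", manifest,
                           index_label="method")
        if all_metrics:
            _write(pd.concat(all_metrics, ignore_index=True).set_index("sim"),
                   outdir, "metrics.tsv", manifest, index_label="sim")
    finally:
        manifest.to_yaml(outdir / "manifest.yaml")
    return manifest


def _solver_spec(entry) -> SolverSpec:
    if isinstance(entry, str):
        return SolverSpec(entry)
    if isinstance(entry, dict):
        entry = dict(entry)
        return SolverSpec(entry.pop("name"), hyperparameters=entry)
    return entry


def _config_echo(cfg: RunConfig) -> dict:
    echo = {}
    for k, v in vars(cfg).items():
        if isinstance(v, tuple):
            v = list(v)
        echo[k] = v
    return echo


def deconvolve_real(
    bulk_path: str | Path,
    sc_path: str | Path,
    annotation_path: str | Path,
    cfg: RunConfig,
    truth_path: str | Path | None = None,
) -> RunManifest:
    """Deconvolve user-supplied bulk samples against a single-cell reference.

    The reference is built from the *full* single-cell input (no split).
    With a ground-truth table the metric report is written; without one
    the cross-method agreement analysis is produced instead, plus the
    consensus with its per-cell-type SD.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(cfg))
    try:
        with _StageTimer(manifest, "load"):
            sc = dio.read_expression(sc_path, annotation=annotation_path)
            bulk = dio.read_expression(bulk_path)
        if cfg.qc:
            with _StageTimer(manifest, "qc"):
                sc = dio.qc_filter(sc)
        with _StageTimer(manifest, "reference"):
            ref = build_reference(sc, with_markers=cfg.markers)
        with _StageTimer(manifest, "harmonize"):
            bulk_h, _ = dio.harmonize_genes(bulk, ref.gene_ids)
            c1 = ref.C1.loc[bulk_h.gene_ids]
            ref = ReferenceBundle(C0=ref.C0, C1=c1, C2=ref.C2,
                                  ref_var=ref.ref_var.loc[bulk_h.gene_ids])
        prep_kwargs = cfg.preprocessing[0] if cfg.preprocessing else {}
        spec = PreprocessSpec(**prep_kwargs)
        with _StageTimer(manifest, "preprocess"):
            bulk_p, c1_p = preprocess_pair(bulk_h, ref, spec)
        with _StageTimer(manifest, "solve"):
            results = run_methods(c1_p, bulk_p,
                                  [_solver_spec(s) for s in cfg.solvers],
                                  record_to=manifest.stages)
        for name, props in results.items():
            _write(props.to_frame(), outdir, f"props_{name}.tsv", manifest,
                   index_label="sample")
        members = [m for m in cfg.consensus_members if m in results]
        if len(members) >= 2:
            with _StageTimer(manifest, "consensus"):
                cons = consensus(results, members=tuple(members))
            _write(cons.mean_props.to_frame(), outdir, "consensus.tsv",
                   manifest, index_label="sample")
            _write(cons.per_cell_type_sd, outdir, "consensus_sd.tsv",
                   manifest, index_label="sample")
        if truth_path is not None:
            with _StageTimer(manifest, "evaluate"):
                truth = dio.read_proportions(truth_path)
                report = build_metrics_report(results, truth,
                                              scopes=tuple(cfg.scopes))
            _write(report.set_index("method"), outdir, "metrics.tsv",
                   manifest, index_label="method")
        elif len(results) >= 2:
            with _StageTimer(manifest, "agreement"):
                corr, order = agreement_analysis(results)
            _write(corr.loc[order, order], outdir, "agreement.tsv",
                   manifest, index_label="method")
            try:
                plot_agreement_heatmap(corr, order, outdir / "agreement.png")
            except Exception as exc:  # plotting is best-effort
                logger.warning("heatmap not written: %s", exc)
    finally:
        manifest.to_yaml(outdir / "manifest.yaml")
    return manifest
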