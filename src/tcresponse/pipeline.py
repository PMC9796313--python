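"""End-to-end orchestration of the analysis stages with a YAML config.

Stages: (simulate | load counts) -> low-count filter -> TMM + log-CPM
(+ RPKM) -> precision weights -> weighted fits + moderation -> the two
sequential contrasts -> kinetic classification -> per-class summaries,
and, when the respective inputs are configured, GO over-representation
with term clustering, BGC summaries and spatial-grid association. A run
manifest records package version, parameters, seed and input checksums.
Each stage writes to ``<name>.partial.tsv`` and renames on completion,
so an aborted run leaves its partial outputs identifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tcresponse import __version__, de, enrichment, io, kinetics, normalize, spatial
from tcresponse.bgc import read_membership, summarize_bgc
from tcresponse.simulate import SimulationConfig, simulate_counts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for a full run."""

    out_dir: str = "results"
    counts: str | None = None
    design: str | None = None
    lengths: str | None = None
    obo: str | None = None
    annotation: str | None = None
    bgc_membership: str | None = None
    grid: str | None = None
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides; used when counts is None
    min_cpm: float = 1.0
    min_samples: int = 2
    lfc_min: float = 1.0
    p_max: float = 0.01
    min_term_size: int = 3
    cut_distance: float = 2.0
    enrich_alpha: float = 0.05
    rpkm: bool = False
    rpkm_effective: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lfc_min", "p_max", "min_term_size", "cut_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_stage(table: pd.DataFrame, out_dir: Path, name: str, index: bool = True) -> Path:
    partial = out_dir / f"{name}.partial.tsv"
    final = out_dir / f"{name}.tsv"
    table.to_csv(partial, sep="\t", index=index)
    partial.rename(final)
    return final


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the in-memory result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "package_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "seed": config.seed,
        "inputs": {},
    }
    for name in ("counts", "design", "lengths", "obo", "annotation",
                 "bgc_membership", "grid"):
        path = getattr(config, name)
        if path:
            if not Path(path).exists():
                raise PipelineError(name, FileNotFoundError(path))
            manifest["inputs"][name] = _checksum(path)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    # ---- input -----------------------------------------------------------
    if config.counts:
        exp = stage("load_counts", lambda: io.read_counts(
            config.counts, config.design, config.lengths))
    else:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
        manifest["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(sim_cfg).items()
        }
        exp, truth = stage("simulate", lambda: simulate_counts(sim_cfg))
        bundle["truth"] = truth
        _write_stage(truth.table, out_dir, "planted_truth")
        io.write_experiment(exp, out_dir / "counts.tsv", out_dir / "design.tsv")
    if config.rpkm and exp.gene_lengths is None:
        raise PipelineError("rpkm", ValueError(
            "RPKM requested but no gene lengths provided"))
    bundle["experiment"] = exp

    # ---- normalization ---------------------------------------------------
    filtered = stage("filter", lambda: normalize.filter_low_counts(
        exp, config.min_cpm, config.min_samples))
    norm = stage("normalize", lambda: normalize.normalize_experiment(
        filtered, use_effective_for_rpkm=config.rpkm_effective))
    bundle["filtered"] = filtered
    bundle["normalization"] = norm
    _write_stage(pd.DataFrame({
        "lib_size": norm.lib_sizes, "tmm": norm.tmm,
        "effective_lib_size": norm.effective_lib_sizes,
    }), out_dir, "factors")
    _write_stage(norm.log_cpm, out_dir, "log_cpm")
    if config.rpkm and norm.rpkm is not None:
        _write_stage(norm.rpkm, out_dir, "rpkm")

    # ---- differential expression ----------------------------------------
    X = de.design_matrix(filtered.design)
    weights = stage("voom", lambda: normalize.voom_weights(
        norm.log_cpm, X, lib_sizes=norm.effective_lib_sizes))
    fits = stage("fit", lambda: de.fit_models(norm.log_cpm, weights.weights, X))
    mfit = stage("moderate", lambda: de.moderate(fits))
    tables = stage("contrasts", lambda: de.test_contrasts(mfit))
    bundle["weights"] = weights
    bundle["moderated_fit"] = mfit
    bundle["contrasts"] = tables
    for cname, tab in tables.items():
        _write_stage(tab, out_dir, f"de_{cname.replace('-', '_vs_')}")

    # ---- kinetic classification -----------------------------------------
    calls = stage("classify", lambda: kinetics.classify_genes(
        tables, lfc_min=config.lfc_min, p_max=config.p_max))
    bundle["classification"] = calls
    _write_stage(calls, out_dir, "kinetic_classes")
    _write_stage(kinetics.summarize_classes(calls), out_dir,
                 "kinetic_class_summary", index=False)
    io.write_gene_sets(kinetics.class_gene_sets(calls),
                       out_dir / "kinetic_classes.gmt", "kinetic class")

    # ---- GO enrichment ---------------------------------------------------
    if config.obo and config.annotation:
        graph = stage("read_obo", lambda: io.read_obo(config.obo))
        raw_annot = stage("read_annotation", lambda: io.read_annotation(
            config.annotation))
        annot = enrichment.propagate_annotations(
            {g: set(t) for g, t in raw_annot.items()}, graph)
        universe = [g for g in calls.index if annot.get(g)]
        enr_tables = []
        for label, genes in kinetics.class_gene_sets(calls).items():
            members = sorted(set(genes) & set(universe))
            if not members:
                continue
            tab = stage(f"enrich_{label}", lambda g=members: enrichment.enrich(
                g, universe, annot, graph, min_term_size=config.min_term_size))
            tab = enrichment.add_term_clusters(
                tab, graph, alpha=config.enrich_alpha,
                cut_distance=config.cut_distance)
            tab.insert(0, "gene_set", label)
            enr_tables.append(tab)
        if enr_tables:
            enr = pd.concat(enr_tables, ignore_index=True)
            bundle["enrichment"] = enr
            _write_stage(enr, out_dir, "go_enrichment", index=False)

    # ---- BGC summary -----------------------------------------------------
    if config.bgc_membership:
        membership = stage("read_membership", lambda: read_membership(
            config.bgc_membership))
        summary = stage("bgc_summary", lambda: summarize_bgc(calls, membership))
        bundle["bgc_summary"] = summary
        _write_stage(summary, out_dir, "bgc_summary", index=False)

    # ---- spatial grid ----------------------------------------------------
    if config.grid:
        grid = stage("read_grid", lambda: io.read_grid(config.grid))
        assoc_rows = []
        for analyte in grid.analytes:
            if analyte == spatial.ABSORBANCE:
                continue
            a = stage(f"spearman_{analyte}", lambda an=analyte: spatial.spearman(
                grid, an, n_perm=999, seed=config.seed))
            assoc_rows.append({
                "analyte": a.analyte, "n": a.n, "rho": a.rho, "p": a.p,
                "perm_p": a.perm_p,
            })
            _write_stage(spatial.grid_matrix(grid, analyte), out_dir,
                         f"grid_{analyte}")
        assoc = pd.DataFrame(assoc_rows)
        bundle["spatial"] = assoc
        _write_stage(assoc, out_dir, "spatial_association", index=False)
        _write_stage(spatial.correlation_matrix(grid), out_dir,
                     "spatial_correlation_matrix")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
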