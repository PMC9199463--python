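"""Pipeline configuration, orchestration, CLI and run manifest.

Each tissue runs normalize -> HVG -> PCA -> SNN/Louvain clustering ->
dual-marker gating -> Wilcoxon marker discovery -> pre-ranked GSEA; the
per-tissue marker sets then feed a cross-tissue Venn partition, and an
optional spatial stage clusters spots and reports marker co-localization.
All tables land in a run directory together with a JSON manifest (config,
seed, per-stage row counts) and a log; the whole run is deterministic given
the seed.

A tissue where no cluster passes the enrichment gate is flagged and its
marker/GSEA stages are skipped; the remaining tissues proceed and the run
is marked partial.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from . import cluster as _cluster
from . import gate as _gate
from . import gsea as _gsea
from . import io as _io
from . import markers as _markers
from . import preprocess as _pre
from . import simdata as _sim
from . import spatial as _spatial
from .gate import GateParams

logger = logging.getLogger("perimark")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "run_tissue", "cli"]

DEFAULT_N_PCS = {"kidney": 45, "bladder": 30}
DEFAULT_N_PCS_FALLBACK = 35


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the study defaults.

    ``n_pcs`` maps tissue -> PC count (45 kidney, 30 bladder, 35 otherwise);
    marker thresholds are (adjusted p, pct1, pct2, pct3) = (0.05, 0.80,
    0.05, 0.10), all compared strictly.
    """

    tissues: dict[str, str] = field(default_factory=dict)  # tissue -> bundle dir
    simulate: dict | None = None                           # SimConfig fields
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: dict[str, int] = field(default_factory=dict)
    n_pcs_default: int = DEFAULT_N_PCS_FALLBACK
    k: int = 20
    prune: float = 1 / 15
    resolution: float = 0.5
    gate: dict = field(default_factory=dict)               # GateParams fields
    alpha: float = 0.05
    pct1_min: float = 0.80
    pct2_max: float = 0.05
    pct3_max: float = 0.10
    gmt: str | None = None
    n_perm: int = 1000
    q_threshold: float = 0.05
    spatial_grid: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        for name, lo, hi in (
            ("alpha", 0, 1), ("pct1_min", 0, 1), ("pct2_max", 0, 1),
            ("pct3_max", 0, 1), ("q_threshold", 0, 1), ("prune", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                errors.append(f"{name}={v} outside ({lo}, {hi})")
        if self.resolution <= 0:
            errors.append(f"resolution={self.resolution} must be positive")
        for name in ("n_hvg", "k", "n_perm", "n_pcs_default"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.scale_factor <= 0:
            errors.append("scale_factor must be positive")
        if self.seed is None:
            errors.append("seed is required")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def pcs_for(self, tissue: str) -> int:
        if tissue in self.n_pcs:
            return self.n_pcs[tissue]
        return DEFAULT_N_PCS.get(tissue, self.n_pcs_default)

    def gate_params(self) -> GateParams:
        return GateParams(**self.gate) if self.gate else GateParams()

    def sim_config(self) -> _sim.SimConfig | None:
        if self.simulate is None:
            return None
        data = dict(self.simulate)
        for key in ("canonical_pair", "libsize_lognormal"):
            if key in data:
                data[key] = tuple(data[key])
        return _sim.SimConfig(**data)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a JSON or YAML config; inject defaults, reject unknown keys.

    All type/range violations are reported at once.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    if "spatial_grid" in data and data["spatial_grid"] is not None:
        data["spatial_grid"] = tuple(data["spatial_grid"])
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Per-tissue stages
# ---------------------------------------------------------------------------

def run_tissue(
    counts: _io.CountMatrix,
    config: PipelineConfig,
    gene_sets: _io.GeneSetCollection | None,
    seed: int,
) -> dict:
    """normalize -> HVG -> PCA -> cluster -> gate -> markers -> GSEA for one
    tissue. Returns a dict of stage results; ``marker_table``/``gsea`` are
    None when gating finds no enriched cluster."""
    tissue = counts.tissue
    norm = _pre.log_normalize(counts, config.scale_factor)
    hvgs = _pre.select_hvg_vst(counts, config.n_hvg)
    n_pcs = min(config.pcs_for(tissue), len(hvgs) - 1, counts.n_cells - 1)
    emb = _pre.scale_and_pca(norm, hvgs, n_pcs)
    neighbors = _cluster.knn(emb, min(config.k, counts.n_cells - 1))
    graph = _cluster.snn_jaccard(neighbors, config.prune)
    labels = _cluster.louvain(graph, config.resolution, seed)
    logger.info("%s: %d cells, %d clusters", tissue, counts.n_cells, labels.n_clusters)

    gate_result = _gate.run_gate(counts, labels, config.gate_params())
    logger.info(
        "%s: enriched clusters %s, %d stringent pericytes",
        tissue, sorted(gate_result.enriched_cluster_ids),
        int(gate_result.stringent_mask.sum()),
    )
    out = {
        "labels": labels,
        "gate": gate_result,
        "marker_table": None,
        "selected": set(),
        "gsea": None,
    }
    if not gate_result.enriched_cluster_ids or gate_result.stringent_mask.sum() < 3:
        logger.warning("%s: gating failed; marker/GSEA stages skipped", tissue)
        return out

    table = _markers.de_table(
        norm, counts, gate_result.stringent_mask, labels,
        gate_result.enriched_cluster_ids,
    )
    table = _markers.select_markers(
        table, config.alpha, config.pct1_min, config.pct2_max, config.pct3_max
    )
    out["marker_table"] = table
    out["selected"] = set(table.loc[table["selected"], "gene"])
    logger.info("%s: %d markers selected", tissue, len(out["selected"]))

    if gene_sets is not None and len(gene_sets):
        ranked = _gsea.rank_by_log2fc(table)
        out["gsea"] = _gsea.preranked_gsea(
            ranked, gene_sets, config.n_perm, seed=seed,
            q_threshold=config.q_threshold,
        )
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all tissues (from bundles or simulation) plus the cross-tissue
    Venn and optional spatial stage; write tables, manifest and log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "stages": {},
        "partial": False,
    }
    try:
        sim_cfg = config.sim_config()
        datasets: dict[str, _io.CountMatrix] = {}
        truth = None
        if sim_cfg is not None:
            sim = _sim.simulate_multi_tissue(sim_cfg, config.seed)
            for tissue, (counts, t) in sim.items():
                datasets[tissue] = counts
                truth = t
        for tissue, bundle in config.tissues.items():
            datasets[tissue] = _io.read_mtx_bundle(bundle, tissue=tissue)
        if not datasets:
            raise ValueError("config specifies no tissues and no simulation")

        if config.gmt:
            gene_sets = _io.read_gmt(config.gmt)
        elif truth is not None:
            gene_sets = _sim.toy_gene_sets(truth, seed=config.seed)
        else:
            gene_sets = None

        marker_sets: dict[str, set[str]] = {}
        summaries = []
        for tissue in sorted(datasets):
            try:
                result = run_tissue(
                    datasets[tissue], config, gene_sets,
                    _sim.tissue_seed(config.seed, tissue),
                )
            except Exception as exc:
                raise RuntimeError(f"tissue {tissue}: stage failed: {exc}") from exc
            summaries.append(result["gate"].summary)
            stage_info = {
                "n_cells": datasets[tissue].n_cells,
                "n_clusters": result["labels"].n_clusters,
                "enriched_clusters": sorted(result["gate"].enriched_cluster_ids),
                "n_stringent": int(result["gate"].stringent_mask.sum()),
                "n_selected_markers": len(result["selected"]),
            }
            manifest["stages"][tissue] = stage_info
            if result["marker_table"] is not None:
                _io.write_marker_table(
                    result["marker_table"], out_dir / f"markers_{tissue}.tsv"
                )
                marker_sets[tissue] = result["selected"]
            else:
                manifest["partial"] = True
            if result["gsea"] is not None:
                _io.write_gsea_table(result["gsea"], out_dir / f"gsea_{tissue}.tsv")

        _io.write_gate_summary(
            _gate.combine_summaries(summaries), out_dir / "gate_summary.tsv"
        )
        if len(marker_sets) >= 2:
            venn = _markers.cross_tissue_venn(marker_sets)
            _io.write_venn_table(
                _markers.venn_to_frame(venn), out_dir / "venn_markers.tsv"
            )
            manifest["stages"]["venn"] = {
                "n_patterns": len(venn),
                "union_size": sum(len(g) for g in venn.values()),
            }

        if sim_cfg is not None and config.spatial_grid is not None:
            spots, spot_truth = _sim.simulate_spatial_section(
                sim_cfg, config.spatial_grid, _sim.tissue_seed(config.seed, "spatial")
            )
            spot_result = run_spatial(spots, config)
            spot_result["venn"].to_frame().pipe(
                _io.write_venn_table, out_dir / "spatial_venn.tsv"
            )
            manifest["stages"]["spatial"] = {
                "n_spots": spots.n_spots,
                "n_clusters": spot_result["labels"].n_clusters,
                "n_pericyte_spots": len(spot_result["pericyte_spots"]),
            }

        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return out_dir
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_spatial(spots: _spatial.SpotTable, config: PipelineConfig) -> dict:
    """Spot clustering, pericyte-spot designation and marker co-localization
    for one section. Marker analogues follow the human-symbol convention."""
    labels = _spatial.cluster_spots(
        spots, n_hvg=config.n_hvg, n_pcs=min(10, config.n_pcs_default),
        k=config.k, prune=config.prune, resolution=config.resolution,
        seed=config.seed, scale_factor=config.scale_factor,
    )
    gp = config.gate_params()
    upper = _markers.map_orthologs([gp.marker_a, gp.marker_b])
    spot_params = GateParams(
        marker_a=upper[gp.marker_a], marker_b=upper[gp.marker_b],
        min_dual_fraction=gp.min_dual_fraction,
        fold_over_global=gp.fold_over_global,
    )
    pericyte_spots = _spatial.designate_pericyte_spots(spots, labels, spot_params)
    set_a = _spatial.spot_sets(spots, "HIGD1B")
    set_b = _spatial.spot_sets(spots, "NOTCH3")
    venn = _spatial.venn_colocalize(set_a, set_b, pericyte_spots)
    return {
        "labels": labels,
        "pericyte_spots": pericyte_spots,
        "set_a": set_a,
        "set_b": set_b,
        "venn": venn,
    }


def _config_to_jsonable(config: PipelineConfig) -> dict:
    data = dataclasses.asdict(config)
    if data.get("spatial_grid") is not None:
        data["spatial_grid"] = list(data["spatial_grid"])
    return data


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Cross-tissue pericyte marker discovery."""
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")


@cli.command()
@click.option("--out", type=click.Path(), required=True, help="output directory")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-tissues", type=int, default=4, show_default=True)
@click.option("--n-cells", type=int, default=600, show_default=True)
def simulate(out: str, seed: int, n_tissues: int, n_cells: int) -> None:
    """Simulate multi-tissue count bundles with ground truth."""
    cfg = _sim.SimConfig(n_tissues=n_tissues, n_cells=n_cells, seed=seed)
    out_path = Path(out)
    out_path.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out_path / "sim_config.json")
    for tissue, (counts, truth) in _sim.simulate_multi_tissue(cfg, seed).items():
        _io.write_mtx_bundle(counts, out_path / tissue)
        _sim.write_ground_truth(truth, counts, out_path / f"truth_{tissue}")
    click.echo(f"wrote {n_tissues} tissue bundles to {out_path}")


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def run_all(config_path: str, out: str) -> None:
    """Run the full pipeline from a JSON/YAML config."""
    config = validate_config(config_path)
    run_dir = run_pipeline(config, out)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    if manifest["partial"]:
        click.echo("run completed PARTIALLY (a tissue failed gating); see run.log")
        raise SystemExit(3)
    click.echo(f"run complete: {run_dir}")


@cli.command("spatial")
@click.option("--spots", "csv_path", type=click.Path(exists=True), required=True,
              help="spot CSV (barcode,row,col)")
@click.option("--bundle", type=click.Path(exists=True), required=True,
              help="matching MTX count bundle directory")
@click.option("--out", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
def spatial_cmd(csv_path: str, bundle: str, out: str, seed: int) -> None:
    """Cluster spots and report marker co-localization."""
    spots = _spatial.SpotTable.read(csv_path, bundle)
    config = PipelineConfig(seed=seed)
    result = run_spatial(spots, config)
    out_path = Path(out)
    out_path.mkdir(parents=True, exist_ok=True)
    _io.write_venn_table(result["venn"].to_frame(), out_path / "spatial_venn.tsv")
    click.echo(
        f"{spots.n_spots} spots, {result['labels'].n_clusters} clusters, "
        f"{len(result['pericyte_spots'])} pericyte spots"
    )


if __name__ == "__main__":
    cli()
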