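"""End-to-end orchestration: merge -> fold-changes -> stats -> clustering -> enrichment.

A run is driven by a :class:`PipelineConfig` (loadable from YAML/JSON) and
writes a bundle of tidy TSV result tables plus a manifest with a config
hash, the seed and a checksum per output, so reruns are verifiable
bit-for-bit.  The single global seed is fanned out to per-stage child seeds
with ``numpy.random.SeedSequence``, keeping each stage reproducible on its
own regardless of stage ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlate, cycle_stats, enrich, ingest, patterns
from .containers import LAYERS, MultiOmicDataset
from .synthetic_data import SimulationConfig, as_multiomic, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one place.

    Defaults are the published analysis settings: one-sample t-test FDR
    < 0.05, 1.5-fold change in >= 2 of 3 layers, ten k-means clusters, a
    tau of 1 Z-unit for mode calls, enrichment FDR < 0.02.
    """

    # input: either a synthetic simulation or a directory of tables
    synthetic: SimulationConfig | None = None
    paths: dict[str, str] = field(default_factory=dict)

    alpha: float = 0.05
    fold: float = 1.5
    min_layers: int = 2
    min_reps: int = 2
    k: int = 10
    tau: float = 1.0
    enrichment_fdr: float = 0.02
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("fold", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SimulationConfig(**syn) if isinstance(syn, dict) else SimulationConfig()
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence(base).spawn(stage + 1)[stage].generate_state(1)[0] % (2**31))


def _load_real(config: PipelineConfig) -> tuple[MultiOmicDataset, pd.DataFrame | None]:
    paths = {k: Path(v) for k, v in config.paths.items()}
    required = ["mRNA", "translation", "protein", "sample_sheet", "idmap"]
    missing = [k for k in required if k not in paths or not paths[k].exists()]
    if missing:
        raise FileNotFoundError(f"missing input paths: {missing}")
    sheet = ingest.read_sample_sheet(paths["sample_sheet"])
    by_layer = {
        layer: {c: s for c, s in sheet.items() if s.layer == layer} for layer in LAYERS
    }
    layers = {
        layer: ingest.read_expression_table(paths[layer], layer, by_layer[layer])
        for layer in LAYERS
    }
    idmap = ingest.read_id_map(paths["idmap"])
    ds = ingest.merge_multiomic(layers["mRNA"], layers["translation"], layers["protein"], idmap)
    annotations = None
    if "annotations" in paths and paths["annotations"].exists():
        term_sets = enrich.read_gmt(paths["annotations"])
        annotations = pd.DataFrame(
            [(g, t) for t, genes in term_sets.items() for g in genes],
            columns=["gene", "term"],
        )
    return ds, annotations


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage and write the result bundle to ``outdir``.

    Outputs: merged dataset summary, fold-change/test tables, raw and
    disattenuated correlation matrices, cluster assignments with regulatory
    modes, enrichment tables, and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    # -- input ---------------------------------------------------------------
    _stage("input")
    if config.synthetic is not None:
        sim_cfg = dataclasses.replace(config.synthetic, seed=_stage_seed(config.seed, 0))
        sd, truth = simulate(sim_cfg)
        ds = as_multiomic(sd)
        annotations = sd.annotations
        truth.params.to_csv(outdir / "synthetic_truth.tsv", sep="\t")
        written["synthetic_truth"] = outdir / "synthetic_truth.tsv"
    else:
        ds, annotations = _load_real(config)

    summary = ingest.summarize_dataset(ds)
    written["dataset_summary"] = outdir / "dataset_summary.json"
    written["dataset_summary"].write_text(json.dumps(summary, indent=2))

    # -- fold changes + tests ------------------------------------------------
    _stage("cycle_stats")
    fcm = cycle_stats.fold_changes(ds, min_reps=config.min_reps)
    fcm = cycle_stats.zscore_columns(fcm)
    results = cycle_stats.one_sample_test(fcm, alpha=config.alpha)
    sig_genes = cycle_stats.significant_union_filter(results, alpha=config.alpha)
    fc_genes = cycle_stats.fc_threshold_filter(fcm, fold=config.fold, min_layers=config.min_layers)

    tidy = fcm.mean_fc.stack(["layer", "transition"], future_stack=True).rename("mean_fc").reset_index()
    tidy.columns = ["gene", "layer", "transition", "mean_fc"]
    mean_z = fcm.mean_z.stack(["layer", "transition"], future_stack=True).rename("mean_z").reset_index()
    tidy["mean_z"] = mean_z["mean_z"]
    written["fold_changes"] = outdir / "fold_changes.tsv"
    tidy.to_csv(written["fold_changes"], sep="\t", index=False, float_format="%.6g")
    written["test_results"] = outdir / "test_results.tsv"
    results.to_csv(written["test_results"], sep="\t", index=False, float_format="%.6g")

    # -- correlation structure -----------------------------------------------
    _stage("correlate")
    cm_abs = correlate.correlation_matrix(ds)
    cm_fc = correlate.correlation_matrix(fcm, use_z=True)
    written["correlation_abundance"] = outdir / "correlation_abundance.tsv"
    cm_abs.r.to_csv(written["correlation_abundance"], sep="\t", float_format="%.6g")
    written["correlation_foldchange"] = outdir / "correlation_foldchange.tsv"
    cm_fc.r.to_csv(written["correlation_foldchange"], sep="\t", float_format="%.6g")

    corrected = _disattenuated_layer_correlations(ds)
    written["correlation_corrected"] = outdir / "correlation_corrected.tsv"
    corrected.to_csv(written["correlation_corrected"], sep="\t", float_format="%.6g")

    # -- clustering + modes ----------------------------------------------------
    _stage("patterns")
    profiles = fcm.profiles(use_z=True).loc[lambda p: p.index.isin(sig_genes)]
    k = min(config.k, max(1, len(profiles)))
    cr = patterns.kmeans_profiles(
        profiles, k=k, seed=_stage_seed(config.seed, 1), restarts=config.kmeans_restarts
    )
    modes = patterns.classify_modes(
        fcm.profiles(use_z=True), patterns.ModeThresholds(tau=config.tau)
    )
    assign = pd.DataFrame({"cluster": cr.assignments, "mode": modes.reindex(cr.assignments.index)})
    assign.index.name = "gene"
    written["clusters"] = outdir / "clusters.tsv"
    assign.to_csv(written["clusters"], sep="\t")
    written["cluster_centroids"] = outdir / "cluster_centroids.tsv"
    cr.centroids.to_csv(written["cluster_centroids"], sep="\t", float_format="%.6g")
    written["fc_filter_genes"] = outdir / "fc_filter_genes.txt"
    written["fc_filter_genes"].write_text("\n".join(fc_genes) + "\n")

    # -- enrichment ------------------------------------------------------------
    _stage("enrich")
    if annotations is not None and len(annotations):
        term_sets = {t: set(g["gene"]) for t, g in annotations.groupby("term")}
        fisher = enrich.fisher_enrichment(
            pd.Index(sig_genes), ds.gene_index, term_sets, fdr=config.enrichment_fdr
        )
        written["fisher_enrichment"] = outdir / "fisher_enrichment.tsv"
        fisher.to_csv(written["fisher_enrichment"], sep="\t", index=False, float_format="%.6g")

        scores = enrich.stability_score(ds)
        oned = enrich.enrichment_1d(scores, term_sets, fdr=config.enrichment_fdr)
        written["stability_enrichment"] = outdir / "stability_enrichment.tsv"
        oned.to_csv(written["stability_enrichment"], sep="\t", index=False, float_format="%.6g")

    # -- manifest ---------------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_jsonable(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {
            name: {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for name, p in sorted(written.items())
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = mpath
    return written


def _disattenuated_layer_correlations(ds: MultiOmicDataset) -> pd.DataFrame:
    """Observed and reliability-corrected between-layer Spearman per phase."""
    rows = []
    from .containers import PHASES

    for phase in PHASES:
        rel = {
            layer: correlate.reliability(ds.layers[layer], phase).r_xx for layer in LAYERS
        }
        for la, lb in (("mRNA", "translation"), ("mRNA", "protein"), ("translation", "protein")):
            pairs = []
            for s in ds.layers[la].samples:
                if s.phase == phase:
                    other = [
                        t.label
                        for t in ds.layers[lb].samples
                        if t.phase == phase and t.replicate == s.replicate
                    ]
                    if other:
                        pairs.append(
                            correlate.spearman(
                                ds.layers[la].values[s.label], ds.layers[lb].values[other[0]]
                            )
                        )
            r_xy = float(np.nanmean(pairs))
            rows.append(
                {
                    "phase": phase,
                    "layer_x": la,
                    "layer_y": lb,
                    "r_observed": r_xy,
                    "r_xx": rel[la],
                    "r_yy": rel[lb],
                    "r_corrected": correlate.disattenuate(r_xy, rel[la], rel[lb]),
                }
            )
    return pd.DataFrame(rows)
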