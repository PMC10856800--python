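"""One-command orchestration of the full workflow plus a PCA utility.

``run_pipeline`` chains QC → preprocessing → (automatic power selection) →
signed adjacency → TOM → clustering → module detection with the kME filter
→ color assignment → eigenmetabolites → module–trait statistics → module
significance → GS/MM scatter → eigenmetabolite network → hub graph →
annotation suggestions, writing every table (TSV), figure and a manifest
into one run directory.  The analysis path contains no stochastic step, so
reruns with the same config produce byte-identical tables.
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

from . import plotting
from .hubs import (DEFAULT_EDGE_THRESHOLD, export_graph, hub_ranking,
                   module_subgraph, suggest_annotations, tom_summary)
from .io import (FeatureTable, PreprocessConfig, TraitTable, preprocess,
                 read_feature_table, read_trait_table, sample_dendrogram)
from .modules import (GREY, DetectionConfig, assign_colors, cluster_features,
                      eigenmetabolites, enforce_min_kme, initial_labels, kme,
                      merge_close_modules)
from .network import (DEFAULT_POWERS, NetworkConfig, adjacency,
                      correlation_matrix, pick_soft_threshold,
                      topological_overlap)
from .traits import (eigengene_network, gs_mm_scatter, metabolite_significance,
                     module_significance, module_trait_matrix)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    features_path: str = ""
    traits_path: str = ""
    output_dir: str = "metabonet_run"
    orientation: str = "features_in_rows"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    auto_power: bool = False
    candidate_powers: tuple = DEFAULT_POWERS
    target_fit: float = 0.90
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    trait_names: tuple = ()          # empty = all traits in the table
    hub_module: str = "auto"          # "auto" = module with largest MS
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    sample_cut_height: float | None = None
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fit <= 1.0:
            raise ValueError("target_fit must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidate_powers"] = list(self.candidate_powers)
        d["trait_names"] = list(self.trait_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig(**d["network"])
        if "detection" in d and isinstance(d["detection"], dict):
            d["detection"] = DetectionConfig(**d["detection"])
        if "candidate_powers" in d:
            d["candidate_powers"] = tuple(d["candidate_powers"])
        if "trait_names" in d:
            d["trait_names"] = tuple(d["trait_names"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the analysis parameters (paths excluded)."""
        d = self.to_dict()
        for key in ("features_path", "traits_path", "output_dir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    output_dir: Path
    manifest: list[dict]
    assignment: "object" = None
    me: "object" = None
    module_trait: "object" = None
    chosen_power: float | None = None
    complete: bool = False

    def files(self) -> list[str]:
        return [entry["file"] for entry in self.manifest]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def run_pipeline(config: PipelineConfig,
                 table: FeatureTable | None = None,
                 traits: TraitTable | None = None) -> ResultsBundle:
    """Execute every workflow stage and write a manifest of the outputs.

    Inputs may be passed in memory or read from the configured paths.  Any
    stage failure aborts with the stage name in the message; outputs written
    before the failure stay on disk with the manifest marked incomplete.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    digest = config.digest()
    bundle = ResultsBundle(out, manifest)

    def record(path: Path, role: str, step: str) -> None:
        manifest.append({"file": path.name, "role": role, "step": step,
                         "config_digest": digest})

    def save_manifest(complete: bool) -> None:
        payload = {"complete": complete, "config_digest": digest,
                   "files": manifest}
        (out / "manifest.json").write_text(json.dumps(payload, indent=2))

    stage = "load"
    try:
        if table is None:
            table = read_feature_table(config.features_path, config.orientation)
        if traits is None:
            traits = read_trait_table(config.traits_path)

        stage = "qc"
        tree = sample_dendrogram(table, config.sample_cut_height)
        pd.Series(tree.outliers, dtype=str, name="outlier").to_csv(
            out / "outliers.tsv", sep="\t", index=False)
        record(out / "outliers.tsv", "flagged outlier samples", stage)
        if config.make_plots:
            for p in plotting.plot_sample_tree(tree, out / "sample_tree.png"):
                record(Path(p), "sample dendrogram", stage)
        if tree.outliers:
            keep = [s for s in table.sample_ids if s not in tree.outliers]
            table = FeatureTable(table.abundance.loc[keep], table.meta)
            traits = TraitTable(traits.traits.loc[keep])

        stage = "preprocess"
        table = preprocess(table, config.preprocess)
        sd = table.abundance.std(axis=0, ddof=1)
        table = table.subset_features(sd.index[sd > 0])

        stage = "pick_power"
        net_cfg = config.network
        if config.auto_power:
            power, fit_table, reached = pick_soft_threshold(
                table, config.candidate_powers, config.target_fit,
                net_cfg.network_type, net_cfg.correlation_method)
            net_cfg = NetworkConfig(power, net_cfg.network_type,
                                    net_cfg.correlation_method)
            _write_tsv(fit_table, out / "scale_free_fit.tsv", "row")
            record(out / "scale_free_fit.tsv", "scale-free fit table", stage)
            if config.make_plots:
                for p in plotting.plot_scale_free_fit(
                        fit_table, config.target_fit, power,
                        out / "scale_free_fit.png"):
                    record(Path(p), "scale-free fit plot", stage)
        bundle.chosen_power = net_cfg.power

        stage = "adjacency"
        cor = correlation_matrix(table, net_cfg.correlation_method)
        adj = adjacency(cor, net_cfg)

        stage = "tom"
        tom = topological_overlap(adj)

        stage = "cluster"
        feature_tree = cluster_features(tom)

        stage = "modules"
        labels = initial_labels(feature_tree, tom, config.detection)
        labels = enforce_min_kme(table, labels, config.detection)
        if config.detection.merge_modules and len(labels.module_names) >= 2:
            labels = merge_close_modules(table, labels, config.detection)
            labels = enforce_min_kme(table, labels, config.detection)
        labels = assign_colors(labels)
        bundle.assignment = labels

        stage = "eigenmetabolites"
        has_modules = bool(labels.module_names)
        me = mm = None
        if has_modules:
            me = eigenmetabolites(table, labels)
            mm = kme(table, me, labels)
            bundle.me = me
            _write_tsv(me.values, out / "eigenmetabolites.tsv", "sample_id")
            record(out / "eigenmetabolites.tsv", "module eigenmetabolites", stage)
        assign_df = pd.DataFrame({"module": labels.labels})
        if mm is not None:
            assign_df["own_kme"] = mm.own_module_kme().reindex(assign_df.index)
        _write_tsv(assign_df, out / "modules.tsv", "feature_id")
        record(out / "modules.tsv", "module assignment", stage)
        if config.make_plots:
            for p in plotting.plot_feature_dendrogram(
                    feature_tree, labels, table.feature_ids,
                    out / "feature_dendrogram.png"):
                record(Path(p), "feature dendrogram + colors", stage)

        trait_names = list(config.trait_names) or traits.trait_names
        traits_used = TraitTable(traits.traits[trait_names])

        stage = "module_trait"
        ms_all = {}
        hub_module = None
        if has_modules:
            mts = module_trait_matrix(me, traits_used)
            bundle.module_trait = mts
            _write_tsv(mts.correlation, out / "module_trait_cor.tsv", "module")
            _write_tsv(mts.p_value, out / "module_trait_p.tsv", "module")
            record(out / "module_trait_cor.tsv", "module-trait correlations", stage)
            record(out / "module_trait_p.tsv", "module-trait p-values", stage)
            if config.make_plots:
                for p in plotting.plot_module_trait_heatmap(
                        mts, out / "module_trait_heatmap.png"):
                    record(Path(p), "module-trait heatmap", stage)

            stage = "module_significance"
            for t in trait_names:
                gs = metabolite_significance(table, traits_used.vector(t), t)
                ms_all[t] = module_significance(gs, labels)
            ms_df = pd.DataFrame(ms_all)
            _write_tsv(ms_df, out / "module_significance.tsv", "module")
            record(out / "module_significance.tsv", "module significance", stage)
            if config.make_plots and trait_names:
                for p in plotting.plot_module_significance(
                        ms_df[trait_names[0]], out / "module_significance.png"):
                    record(Path(p), "module significance bars", stage)

            stage = "hub_selection"
            if config.hub_module == "auto":
                hub_module = ms_df.max(axis=1).idxmax()
            else:
                hub_module = config.hub_module
                if hub_module not in labels.module_names:
                    raise ValueError(f"unknown module color {hub_module!r}")

            stage = "gs_mm_scatter"
            primary_trait = (ms_df.loc[hub_module].idxmax()
                             if trait_names else None)
            if primary_trait is not None and len(labels.members(hub_module)) >= 3:
                gs = metabolite_significance(
                    table, traits_used.vector(primary_trait), primary_trait)
                data, r, p_val = gs_mm_scatter(gs, mm, labels, hub_module)
                _write_tsv(data, out / "gs_mm_scatter.tsv", "feature_id")
                record(out / "gs_mm_scatter.tsv", "GS vs kME scatter data", stage)
                if config.make_plots:
                    for p in plotting.plot_gs_mm_scatter(
                            data, hub_module, r, p_val,
                            out / "gs_mm_scatter.png"):
                        record(Path(p), "GS vs kME scatter", stage)

            stage = "eigengene_network"
            if len(labels.module_names) + len(trait_names) >= 3:
                enet = eigengene_network(me, traits_used, trait_names)
                _write_tsv(enet.correlation, out / "eigengene_network.tsv", "name")
                record(out / "eigengene_network.tsv", "eigenmetabolite network", stage)
                if config.make_plots:
                    for p in plotting.plot_eigengene_network(
                            enet, out / "eigengene_network.png"):
                        record(Path(p), "eigenmetabolite network plot", stage)

            stage = "hub_graph"
            graph = module_subgraph(tom, labels, hub_module,
                                    config.edge_threshold, table.meta)
            summary = tom_summary(tom, labels, hub_module)
            (out / "tom_summary.json").write_text(json.dumps(
                {"module": hub_module, **summary}, indent=2))
            record(out / "tom_summary.json", "module TOM summary", stage)
            hub_table = hub_ranking(graph, tom)
            hub_table.to_csv(out / "hub_table.tsv", sep="\t", index=False)
            record(out / "hub_table.tsv", "hub ranking", stage)
            export_graph(graph, out / "module_graph.graphml", "graphml")
            record(out / "module_graph.graphml", "module graph (GraphML)", stage)
            export_graph(graph, out / "module_graph_edges.tsv", "edge_tsv")
            record(out / "module_graph_edges.tsv", "module graph edges", stage)
            if config.make_plots:
                hub_id = hub_table.loc[hub_table["is_hub"], "feature_id"].iloc[0]
                for p in plotting.plot_module_graph(
                        graph, out / "module_graph.png", hub=hub_id):
                    record(Path(p), "module graph plot", stage)

            stage = "annotations"
            suggestions = suggest_annotations(graph, k=5)
            rows = [{"unknown": u, "candidate_neighbor": nbr, "tom": w,
                     "rank": i + 1}
                    for u, lst in suggestions.items()
                    for i, (nbr, w) in enumerate(lst)]
            pd.DataFrame(rows, columns=["unknown", "candidate_neighbor",
                                        "tom", "rank"]).to_csv(
                out / "annotation_suggestions.tsv", sep="\t", index=False)
            record(out / "annotation_suggestions.tsv",
                   "annotation suggestions", stage)
        else:
            logger.warning("no modules detected; downstream stages skipped")

        stage = "manifest"
        bundle.complete = True
        save_manifest(True)
        record_df = pd.DataFrame(manifest)
        logger.info("pipeline complete: %d outputs in %s", len(record_df), out)
        return bundle
    except Exception as exc:
        save_manifest(False)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def pca_overview(table: FeatureTable, scale: bool = True
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the sample × feature matrix for a quick overview plot.

    Features are centered and, by default, scaled to unit variance (the
    common metabolomics convention).  Returns (scores, variance-explained
    percentages), percentages non-increasing and summing to ≤ 100.
    """
    X = table.values()
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    pct = 100.0 * var / var.sum()
    n_pc = min(X.shape) - 1 if min(X.shape) > 1 else 1
    scores = pd.DataFrame(
        U[:, :n_pc] * s[:n_pc],
        index=table.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_pc)])
    return scores, pct[:n_pc]
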