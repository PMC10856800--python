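"""Figure helpers for the standard workflow plots.

All functions take an explicit output path, write PNG (and SVG alongside
when ``svg=True``), and close the figure; nothing is shown interactively.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.cluster.hierarchy import dendrogram

from .io import SampleTree
from .modules import Eigenmetabolites, ModuleAssignment, GREY
from .traits import EigengeneNetwork, ModuleTraitStats


def _save(fig, path, svg: bool = False) -> list[str]:
    paths = [str(path)]
    fig.savefig(path, dpi=150, bbox_inches="tight")
    if svg:
        alt = str(path).rsplit(".", 1)[0] + ".svg"
        fig.savefig(alt, bbox_inches="tight")
        paths.append(alt)
    plt.close(fig)
    return paths


def plot_sample_tree(tree: SampleTree, path, svg: bool = False) -> list[str]:
    """Sample dendrogram with the outlier cut line, if any."""
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(tree.linkage_matrix, labels=tree.sample_ids, ax=ax,
               leaf_rotation=90)
    if tree.cut_height is not None:
        ax.axhline(tree.cut_height, color="red", ls="--", lw=1)
    ax.set_ylabel("height")
    ax.set_title("Sample clustering" +
                 (f" — outliers: {', '.join(tree.outliers)}" if tree.outliers
                  else " — no outliers"))
    return _save(fig, path, svg)


def plot_feature_dendrogram(tree: np.ndarray, labels: ModuleAssignment,
                            feature_ids: list[str], path,
                            svg: bool = False) -> list[str]:
    """Feature dendrogram with a module color band underneath."""
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(10, 5), sharex=True,
        gridspec_kw={"height_ratios": [5, 1], "hspace": 0.02})
    dd = dendrogram(tree, no_labels=True, ax=ax1, color_threshold=0,
                    above_threshold_color="black")
    order = dd["leaves"]
    colors = [labels.labels.get(feature_ids[i], GREY) for i in order]
    for i, c in enumerate(colors):
        ax2.bar(i * 10 + 5, 1, width=10, color=c if c != GREY else "lightgrey")
    ax2.set_yticks([])
    ax2.set_xticks([])
    ax1.set_ylabel("1 - TOM")
    ax1.set_title("Feature clustering and module colors")
    return _save(fig, path, svg)


def plot_module_trait_heatmap(stats: ModuleTraitStats, path,
                              svg: bool = False) -> list[str]:
    """Annotated module × trait heatmap: correlation with p-value per cell."""
    R, P = stats.correlation, stats.p_value
    annot = R.copy().astype(object)
    for m in R.index:
        for t in R.columns:
            annot.at[m, t] = f"{R.at[m, t]:.2f}\n({P.at[m, t]:.1e})"
    fig, ax = plt.subplots(figsize=(1.6 * len(R.columns) + 3,
                                    0.6 * len(R.index) + 2))
    sns.heatmap(R, annot=annot, fmt="", cmap="RdBu_r", center=0, vmin=-1,
                vmax=1, ax=ax, cbar_kws={"label": "correlation"})
    ax.set_title("Module–trait relationships")
    return _save(fig, path, svg)


def plot_module_significance(ms: pd.Series, path, svg: bool = False) -> list[str]:
    """Bar chart of module significance (mean |GS|) per module."""
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(ms), 4))
    bar_colors = [m if m != GREY else "lightgrey" for m in ms.index]
    ax.bar(ms.index, ms.values, color=bar_colors, edgecolor="black")
    ax.set_ylabel("module significance (mean |GS|)")
    ax.tick_params(axis="x", rotation=45)
    return _save(fig, path, svg)


def plot_eigengene_network(net: EigengeneNetwork, path,
                           svg: bool = False) -> list[str]:
    """Dendrogram plus heatmap of the ME (+trait) correlation structure."""
    names = list(net.correlation.index)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 9),
                                   gridspec_kw={"height_ratios": [1, 2]})
    dd = dendrogram(net.linkage_matrix, labels=names, ax=ax1, leaf_rotation=90)
    ax1.set_ylabel("1 - cor")
    order = [names[i] for i in dd["leaves"]]
    sns.heatmap(net.correlation.loc[order, order], cmap="RdBu_r", center=0,
                vmin=-1, vmax=1, ax=ax2, square=True)
    fig.suptitle("Eigenmetabolite network")
    return _save(fig, path, svg)


def plot_gs_mm_scatter(data: pd.DataFrame, module: str, r: float, p: float,
                       path, svg: bool = False) -> list[str]:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(data["kme"], data["gs"],
               color=module if module != GREY else "lightgrey",
               edgecolor="black", alpha=0.8)
    ax.set_xlabel(f"module membership (kME, {module})")
    ax.set_ylabel("metabolite significance |GS|")
    ax.set_title(f"{module}: cor = {r:.2f}, p = {p:.2g}")
    return _save(fig, path, svg)


def plot_module_abundance_heatmap(standardized: pd.DataFrame, module: str,
                                  path, svg: bool = False) -> list[str]:
    """Heatmap of a module's z-scored abundances (features × samples)."""
    fig, ax = plt.subplots(figsize=(8, 5))
    sns.heatmap(standardized.T, cmap="RdBu_r", center=0, ax=ax,
                cbar_kws={"label": "z-score"})
    ax.set_title(f"Standardized abundances — {module} module")
    ax.set_xlabel("sample")
    return _save(fig, path, svg)


def plot_module_graph(graph, path, hub: str | None = None,
                      svg: bool = False) -> list[str]:
    """Node-and-edge drawing of a TOM-thresholded module graph."""
    import networkx as nx

    fig, ax = plt.subplots(figsize=(7, 7))
    pos = nx.spring_layout(graph, seed=0, weight="weight")
    weights = [3 * d["weight"] / max(1e-9, max(
        (d2["weight"] for _, _, d2 in graph.edges(data=True)), default=1.0))
        for _, _, d in graph.edges(data=True)]
    node_colors = ["red" if n == hub else "steelblue" for n in graph.nodes]
    nx.draw_networkx(graph, pos=pos, ax=ax, node_size=120, width=weights,
                     node_color=node_colors, font_size=6)
    ax.set_axis_off()
    return _save(fig, path, svg)


def plot_scale_free_fit(fit_table: pd.DataFrame, target: float, chosen: float,
                        path, svg: bool = False) -> list[str]:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(fit_table["power"], fit_table["fit_index"], "o-")
    ax1.axhline(target, color="red", ls="--", lw=1)
    ax1.axvline(chosen, color="green", ls=":", lw=1)
    ax1.set_xlabel("soft threshold (power)")
    ax1.set_ylabel("scale-free fit index")
    ax2.plot(fit_table["power"], fit_table["mean_k"], "o-")
    ax2.set_xlabel("soft threshold (power)")
    ax2.set_ylabel("mean connectivity")
    return _save(fig, path, svg)


def plot_pca_scores(scores: pd.DataFrame, variance_pct: np.ndarray, path,
                    groups: pd.Series | None = None,
                    svg: bool = False) -> list[str]:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    if groups is not None:
        for level in sorted(groups.unique()):
            sel = groups == level
            ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"],
                       label=str(level), edgecolor="black")
        ax.legend(title=groups.name)
    else:
        ax.scatter(scores["PC1"], scores["PC2"], edgecolor="black")
    ax.set_xlabel(f"PC1 ({variance_pct[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({variance_pct[1]:.2f}%)")
    ax.set_title("PCA score plot")
    return _save(fig, path, svg)
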