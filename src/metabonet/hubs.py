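"""TOM-thresholded module graphs, hub ranking and annotation propagation.

Edges are drawn strictly above the TOM threshold (0.13 by default); the hub
metabolite of a module is the member with the largest weighted degree over
those edges, with deterministic tie-breaking.  Unknown features inherit
candidate annotations from their strongest identified neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .modules import ModuleAssignment, GREY
from .network import TOMMatrix

DEFAULT_EDGE_THRESHOLD = 0.13


def module_subgraph(tom: TOMMatrix, labels: ModuleAssignment, module: str,
                    threshold: float = DEFAULT_EDGE_THRESHOLD,
                    meta: pd.DataFrame | None = None) -> nx.Graph:
    """Graph over a module's members with edges where TOM > threshold.

    Isolated nodes are retained.  Node attributes carry the feature
    metadata (mz, rt, annotation) when ``meta`` is given, plus module and
    strength (sum of incident edge weights).
    """
    if module == GREY:
        raise ValueError("grey holds unassigned features; no module graph")
    if module not in labels.module_names:
        raise ValueError(f"unknown module {module!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    members = labels.members(module)
    T = tom.values.loc[members, members].to_numpy(dtype=float)
    G = nx.Graph()
    for fid in members:
        attrs = {"module": module}
        if meta is not None and fid in meta.index:
            row = meta.loc[fid]
            attrs.update(
                feature_id=fid,
                mz=float(row.get("mz", np.nan)),
                rt=float(row.get("rt", np.nan)),
                annotation=str(row.get("annotation", "") or ""),
            )
        G.add_node(fid, **attrs)
    n = len(members)
    for i in range(n):
        for j in range(i + 1, n):
            if T[i, j] > threshold:
                G.add_edge(members[i], members[j], weight=float(T[i, j]))
    for fid in G.nodes:
        G.nodes[fid]["strength"] = float(
            sum(d["weight"] for _, _, d in G.edges(fid, data=True)))
    return G


def tom_summary(tom: TOMMatrix, labels: ModuleAssignment,
                module: str) -> dict[str, float]:
    """min/max/mean/sd of off-diagonal pairwise TOM within a module."""
    members = labels.members(module)
    if len(members) < 2:
        raise ValueError(f"module {module!r} needs >= 2 members for a summary")
    T = tom.values.loc[members, members].to_numpy(dtype=float)
    upper = T[np.triu_indices_from(T, k=1)]
    return {"min": float(upper.min()), "max": float(upper.max()),
            "mean": float(upper.mean()), "sd": float(upper.std(ddof=0)),
            "n_pairs": int(upper.size)}


def hub_ranking(graph: nx.Graph, tom: TOMMatrix | None = None) -> pd.DataFrame:
    """Rank module members by weighted degree over supra-threshold edges.

    Ties break by maximum single incident edge weight (descending), then by
    feature ID (ascending), so the ranking is a deterministic total order.
    The top-ranked member is flagged as the hub.  When ``tom`` is given, raw
    intramodular connectivity (sum of TOM to all other members, regardless
    of the threshold) is reported as a secondary column.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("hub_ranking requires a non-empty graph")
    rows = []
    for fid in graph.nodes:
        weights = [d["weight"] for _, _, d in graph.edges(fid, data=True)]
        rows.append({
            "feature_id": fid,
            "weighted_degree": float(sum(weights)),
            "degree": len(weights),
            "max_edge": float(max(weights)) if weights else 0.0,
        })
    table = pd.DataFrame(rows)
    if tom is not None:
        ids = list(graph.nodes)
        sub = tom.values.loc[ids, ids].to_numpy(dtype=float)
        table["intramodular_connectivity"] = sub.sum(axis=1) - np.diag(sub)
    table = table.sort_values(
        ["weighted_degree", "max_edge", "feature_id"],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["is_hub"] = table["rank"] == 1
    return table


def suggest_annotations(graph: nx.Graph, k: int = 5) -> dict[str, list[tuple[str, float]]]:
    """Candidate annotations for unknown features from identified neighbours.

    For each node whose ``annotation`` attribute is empty, the annotated
    neighbours are listed by descending edge TOM, truncated to ``k``.
    Unknowns with no annotated neighbour get an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    suggestions: dict[str, list[tuple[str, float]]] = {}
    for fid, attrs in graph.nodes(data=True):
        if str(attrs.get("annotation", "") or "").strip():
            continue
        candidates = []
        for nbr in graph.neighbors(fid):
            ann = str(graph.nodes[nbr].get("annotation", "") or "").strip()
            if ann:
                candidates.append((nbr, float(graph.edges[fid, nbr]["weight"])))
        candidates.sort(key=lambda item: (-item[1], item[0]))
        suggestions[fid] = candidates[:k]
    return suggestions


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write a module graph as GraphML or an edge TSV (source, target, tom).

    GraphML keeps node attributes (feature_id, mz, rt, annotation, module,
    strength) and edge weights; both formats round-trip via
    :func:`read_graph`.
    """
    if format == "graphml":
        G = graph.copy()
        for _, attrs in G.nodes(data=True):
            for key, value in list(attrs.items()):
                if isinstance(value, float) and np.isnan(value):
                    del attrs[key]
        nx.write_graphml(G, path)
    elif format == "edge_tsv":
        rows = [{"source": u, "target": v, "tom": f"{d['weight']:.15g}"}
                for u, v, d in graph.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "tom"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graph(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        G = nx.Graph()
        for _, row in df.iterrows():
            G.add_edge(str(row["source"]), str(row["target"]),
                       weight=float(row["tom"]))
        return G
    raise ValueError(f"unknown export format {format!r}")
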