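"""Bait-anchored coexpression networks from ranked logit-score tables.

Inputs are per-bait ranked lists of coexpressed genes with a logit score
(LS), a monotonic transform of the mutual rank of two genes' coexpression;
larger LS means stronger coexpression. Three builders are provided: top-k
per bait, a minimum-LS threshold, and their union restricted to
coexpressors with a minimum degree. All graphs are undirected, deduplicated
across directions (the stored LS is the maximum over contributing
directions), and every edge touches at least one bait.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CoexprList",
    "NetworkStats",
    "load_coexpression",
    "top_k_network",
    "threshold_network",
    "combined_min_degree_network",
    "annotate_nodes",
    "network_stats",
    "export_graph",
    "read_graph",
]

LIST_CAP = 100


@dataclasses.dataclass(frozen=True)
class CoexprList:
    """One bait's ranked coexpressors: (gene, LS) sorted by descending LS."""

    bait: str
    entries: tuple  # of (gene, ls)

    def __post_init__(self):
        genes = [g for g, _ in self.entries]
        if self.bait in genes:
            raise ValueError(f"bait {self.bait!r} appears in its own list")
        if len(genes) != len(set(genes)):
            raise ValueError(f"duplicate genes in list for bait {self.bait!r}")
        ls = [s for _, s in self.entries]
        if any(a < b for a, b in zip(ls, ls[1:])):
            raise ValueError("entries must be sorted by descending LS")

    @classmethod
    def build(cls, bait: str, pairs: Sequence[tuple],
              cap: int = LIST_CAP) -> "CoexprList":
        """Sort, drop self-hits, resolve duplicates by max LS, cap length."""
        best: dict = {}
        for gene, ls in pairs:
            if gene == bait:
                continue
            if gene in best:
                warnings.warn(f"duplicate entry ({bait}, {gene}); keeping max LS")
                best[gene] = max(best[gene], float(ls))
            else:
                best[gene] = float(ls)
        ordered = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:cap]
        return cls(bait, tuple(ordered))

    def top(self, k: int) -> tuple:
        """Top-k entries; ties at rank k broken by accession order."""
        return self.entries[:k]

    def at_least(self, ls_min: float) -> tuple:
        return tuple((g, s) for g, s in self.entries if s >= ls_min)


def load_coexpression(path, cap: int = LIST_CAP) -> dict:
    """Read a long-format TSV (bait, gene, LS) into per-bait ranked lists."""
    df = pd.read_csv(path, sep="\t", dtype={"bait": str, "gene": str})
    for col in ("bait", "gene", "LS"):
        if col not in df.columns:
            raise ValueError(f"coexpression table lacks column {col!r}")
    ls_numeric = pd.to_numeric(df["LS"], errors="coerce")
    bad = ls_numeric.isna() & df["LS"].notna()
    if bad.any():
        raise ValueError(f"non-numeric LS at data row {int(bad.idxmax()) + 1}")
    df["LS"] = ls_numeric
    lists = {}
    for bait, sub in df.groupby("bait", sort=True):
        lists[bait] = CoexprList.build(bait, list(zip(sub["gene"], sub["LS"])),
                                       cap=cap)
    return lists


def _merge_edge(edges: dict, u: str, v: str, ls: float) -> None:
    key = (u, v) if u <= v else (v, u)
    if key in edges:
        edges[key] = max(edges[key], ls)
    else:
        edges[key] = ls


def _graph_from_edges(edges: Mapping[tuple, float], rules: Mapping[tuple, str],
                      baits: Sequence[str]) -> nx.Graph:
    g = nx.Graph()
    bait_set = set(baits)
    for (u, v), ls in edges.items():
        g.add_edge(u, v, ls=float(ls), rule=rules[(u, v)])
    for node in g.nodes:
        g.nodes[node]["is_bait"] = node in bait_set
        g.nodes[node]["bait_class"] = "none"
    return g


def top_k_network(lists: Mapping[str, CoexprList], k: int = 20,
                  baits: Sequence[str] | None = None) -> nx.Graph:
    """Each bait linked to its k strongest coexpressors (deduplicated)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    baits = list(baits) if baits is not None else sorted(lists)
    edges: dict = {}
    for bait in baits:
        for gene, ls in lists[bait].top(k):
            _merge_edge(edges, bait, gene, ls)
    return _graph_from_edges(edges, {e: "topk" for e in edges}, baits)


def threshold_network(lists: Mapping[str, CoexprList], ls_min: float,
                      baits: Sequence[str] | None = None) -> nx.Graph:
    """Each bait linked to coexpressors with LS >= ``ls_min`` (inclusive)."""
    baits = list(baits) if baits is not None else sorted(lists)
    edges: dict = {}
    for bait in baits:
        for gene, ls in lists[bait].at_least(ls_min):
            _merge_edge(edges, bait, gene, ls)
    return _graph_from_edges(edges, {e: "threshold" for e in edges}, baits)


def combined_min_degree_network(lists: Mapping[str, CoexprList], k: int = 20,
                                ls_min: float = 6.0, min_degree: int = 2,
                                baits: Sequence[str] | None = None) -> nx.Graph:
    """Union of top-k and threshold edges, pruned to well-connected coexpressors.

    Non-bait nodes whose degree in the combined graph is below
    ``min_degree`` are removed in a single pass (degrees measured before any
    removal), together with their edges; baits survive only if they keep at
    least one edge.
    """
    baits = list(baits) if baits is not None else sorted(lists)
    topk = top_k_network(lists, k=k, baits=baits)
    thr = threshold_network(lists, ls_min=ls_min, baits=baits)
    edges: dict = {}
    rules: dict = {}
    for g, rule in ((topk, "topk"), (thr, "threshold")):
        for u, v, data in g.edges(data=True):
            key = (u, v) if u <= v else (v, u)
            if key in edges:
                edges[key] = max(edges[key], data["ls"])
                if rules[key] != rule:
                    rules[key] = "both"
            else:
                edges[key] = data["ls"]
                rules[key] = rule
    combined = _graph_from_edges(edges, rules, baits)
    bait_set = set(baits)
    degree = dict(combined.degree())
    drop = [n for n in combined.nodes
            if n not in bait_set and degree[n] < min_degree]
    combined.remove_nodes_from(drop)
    combined.remove_nodes_from(
        [n for n in bait_set if n in combined and combined.degree(n) == 0])
    return combined


def annotate_nodes(net: nx.Graph, annotations: pd.DataFrame | None = None,
                   clp_baits: Sequence[str] = (),
                   trapped_baits: Sequence[str] = ()) -> nx.Graph:
    """Attach bait class and subcellular location attributes in place."""
    clp, trapped = set(clp_baits), set(trapped_baits)
    for node in net.nodes:
        if node in clp:
            net.nodes[node]["bait_class"] = "CLP"
            net.nodes[node]["is_bait"] = True
        elif node in trapped:
            net.nodes[node]["bait_class"] = "trapped"
            net.nodes[node]["is_bait"] = True
        if annotations is not None and node in annotations.index:
            net.nodes[node]["location"] = annotations.loc[node, "location"]
    return net


@dataclasses.dataclass(frozen=True)
class NetworkStats:
    """Node/edge counts and bait-attached connectivity of a coexpression graph.

    Bait-bait edges count under both bait classes, so
    ``connectivity * n_nodes == edges_clp + edges_trapped``.
    """

    n_nodes: int
    n_edges: int
    edges_per_gene: float
    frac_plastid: float
    edges_clp: int
    edges_trapped: int
    n_bait_bait_edges: int
    connectivity: float


def network_stats(net: nx.Graph, annotations: pd.DataFrame | None = None,
                  clp_baits: Sequence[str] = (),
                  trapped_baits: Sequence[str] = ()) -> NetworkStats:
    """Count edges attached to each bait class and overall connectivity."""
    clp, trapped = set(clp_baits), set(trapped_baits)
    n_nodes, n_edges = net.number_of_nodes(), net.number_of_edges()
    edges_clp = edges_trapped = bait_bait = 0
    baits = clp | trapped
    for u, v in net.edges:
        if u in clp or v in clp:
            edges_clp += 1
        if u in trapped or v in trapped:
            edges_trapped += 1
        if u in baits and v in baits:
            bait_bait += 1
    if annotations is not None:
        loc = [annotations.loc[n, "location"] for n in net.nodes
               if n in annotations.index]
        frac_plastid = (sum(x == "plastid" for x in loc) / len(loc)
                        if loc else np.nan)
    else:
        frac_plastid = np.nan
    return NetworkStats(
        n_nodes=n_nodes, n_edges=n_edges,
        edges_per_gene=n_edges / n_nodes if n_nodes else np.nan,
        frac_plastid=frac_plastid,
        edges_clp=edges_clp, edges_trapped=edges_trapped,
        n_bait_bait_edges=bait_bait,
        connectivity=((edges_clp + edges_trapped) / n_nodes
                      if n_nodes else np.nan))


def export_graph(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write GraphML, a tab-separated edge list, or SIF."""
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "edge_tsv":
        rows = [{"source": u, "target": v, "ls": d.get("ls"),
                 "rule": d.get("rule")} for u, v, d in net.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "ls", "rule"]).to_csv(
            path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in net.edges(data=True):
                fh.write(f"{u}\t{d.get('rule', 'coexpr')}\t{v}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Read back a graph written by :func:`export_graph` (graphml/edge_tsv)."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], ls=row["ls"],
                       rule=row["rule"])
        return g
    raise ValueError(f"unknown import format {fmt!r}")
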