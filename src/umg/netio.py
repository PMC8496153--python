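"""Reading, filtering and combining weighted protein-protein interaction networks.

A cohort-specific network is produced by (1) an edge-quality filter — a
confidence threshold for STRING-style scores or a top-fraction cut for
HumanNet-style log-likelihood scores — (2) restriction to the largest
connected component, (3) removal of genes unexpressed in the tumor cohort
(FPKM > 15 in > 20% of samples retained), and (4) a second largest-component
restriction so the propagation operator stays irreducible.

Gene identifiers are opaque, case-sensitive strings; no symbol aliasing is
performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "WeightedNetwork",
    "read_edge_list",
    "read_expression",
    "write_edge_list",
    "filter_by_confidence",
    "filter_top_fraction",
    "largest_connected_component",
    "filter_by_expression",
    "composite_union",
]

DIALECTS = ("string_style", "humannet_style", "generic_tsv")


@dataclass
class WeightedNetwork:
    """An undirected, weighted gene network with no self-loops or isolated nodes.

    Wraps a :class:`networkx.Graph`; edge weights live in the ``weight``
    attribute and are strictly positive in the score units of the source
    network (STRING confidence, HumanNet log-likelihood, ...).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    source_tag: str = ""

    @classmethod
    def from_edges(cls, edges, source_tag: str = "") -> "WeightedNetwork":
        """Build from an iterable of ``(u, v, weight)`` triples.

        Self-loops are dropped, duplicate edges collapse to the maximum
        weight, and non-positive weights raise.
        """
        g = nx.Graph()
        for u, v, w in edges:
            if u == v:
                continue
            w = float(w)
            if not math.isfinite(w) or w <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive weight {w!r}")
            if g.has_edge(u, v):
                if w > g[u][v]["weight"]:
                    g[u][v]["weight"] = w
            else:
                g.add_edge(u, v, weight=w)
        return cls(graph=g, source_tag=source_tag)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        """Iterate ``(u, v, weight)`` triples (stored orientation)."""
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["weight"]

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def has_node(self, node: str) -> bool:
        return node in self.graph

    def weights(self) -> list[float]:
        return [d["weight"] for _, _, d in self.graph.edges(data=True)]

    def _replace(self, graph: nx.Graph) -> "WeightedNetwork":
        graph.remove_nodes_from([n for n in graph.nodes if graph.degree(n) == 0])
        return WeightedNetwork(graph=graph, source_tag=self.source_tag)


def read_edge_list(path, dialect: str = "generic_tsv", source_tag: str | None = None) -> WeightedNetwork:
    """Read a 3-column (node, node, score) edge list into a :class:`WeightedNetwork`.

    ``string_style`` splits on any whitespace (STRING protein-links files),
    the other dialects on tabs. A header line is detected by a non-numeric
    third field and skipped. Duplicate edges keep the maximum weight and
    self-loops are removed; a malformed row raises naming its line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sep = None if dialect == "string_style" else "\t"
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(sep) if sep else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            u, v, raw = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                w = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}: line {lineno}: non-numeric score {raw!r}") from None
            if not u or not v:
                raise ValueError(f"{path}: line {lineno}: empty node identifier")
            edges.append((u, v, w))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return WeightedNetwork.from_edges(edges, source_tag=source_tag or str(path))


def write_edge_list(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample FPKM matrix (TSV, first column = gene)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in expression matrix: {dupes[:5]}")
    if (expr.values < 0).any():
        raise ValueError("expression matrix contains negative FPKM values")
    return expr


def filter_by_confidence(net: WeightedNetwork, threshold: float, scale_hint: float | None = None) -> WeightedNetwork:
    """Keep edges with confidence >= ``threshold`` (boundary inclusive).

    STRING distributes combined scores on a 0-1000 integer scale; pass
    ``scale_hint=1000`` so a threshold of 0.7 means combined_score >= 700.
    """
    eff = threshold * scale_hint if scale_hint else threshold
    ws = net.weights()
    if ws and not (min(ws) <= eff <= max(ws)):
        warnings.warn(
            f"confidence threshold {eff:g} lies outside the observed score range "
            f"[{min(ws):g}, {max(ws):g}]",
            stacklevel=2,
        )
    g = nx.Graph()
    g.add_weighted_edges_from((u, v, w) for u, v, w in net.edges() if w >= eff)
    return net._replace(g)


def filter_top_fraction(net: WeightedNetwork, fraction: float) -> WeightedNetwork:
    """Keep the ``ceil(fraction * |E|)`` highest-weight edges, ties at the cutoff included."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("cannot take top fraction of an empty network")
    k = math.ceil(fraction * m)
    cutoff = sorted(net.weights(), reverse=True)[k - 1]
    g = nx.Graph()
    g.add_weighted_edges_from((u, v, w) for u, v, w in net.edges() if w >= cutoff)
    return net._replace(g)


def largest_connected_component(net: WeightedNetwork) -> WeightedNetwork:
    """Induced subgraph on the largest component.

    Size ties break toward the component holding the lexicographically
    smallest node, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    return net._replace(net.graph.subgraph(comps[0]).copy())


def filter_by_expression(
    net: WeightedNetwork,
    expr: pd.DataFrame,
    fpkm_threshold: float = 15.0,
    sample_fraction: float = 0.2,
) -> WeightedNetwork:
    """Drop genes not expressed in the cohort, then re-take the largest component.

    A gene is retained iff FPKM > ``fpkm_threshold`` in strictly more than
    ``sample_fraction`` of samples. Genes absent from ``expr`` are removed.
    The result is the largest connected component of what survives; a fully
    disconnected result raises.
    """
    if expr.shape[1] == 0:
        raise ValueError("expression matrix has zero samples")
    frac = (expr > fpkm_threshold).mean(axis=1)
    expressed = set(frac.index[frac > sample_fraction])
    keep = [n for n in net.graph.nodes if n in expressed]
    sub = net._replace(net.graph.subgraph(keep).copy())
    if sub.number_of_nodes() == 0:
        raise ValueError("expression filter removed the entire network")
    return largest_connected_component(sub)


def composite_union(nets: list[WeightedNetwork]) -> WeightedNetwork:
    """Union of networks with per-source min-max weight rescaling to [0, 1].

    An edge present in several sources keeps the maximum rescaled weight.
    The composite is used for adjacency/degree queries (positionality), where
    weights are immaterial; rescaling only keeps them comparable.
    """
    if len(nets) < 2:
        raise ValueError("composite_union needs at least two networks")
    g = nx.Graph()
    for net in nets:
        ws = net.weights()
        lo, hi = (min(ws), max(ws)) if ws else (0.0, 1.0)
        span = hi - lo
        for u, v, w in net.edges():
            r = 1.0 if span == 0 else (w - lo) / span
            r = max(r, 1e-9)  # keep weights strictly positive after rescaling
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], r)
            else:
                g.add_edge(u, v, weight=r)
    tag = "+".join(n.source_tag or "?" for n in nets)
    return WeightedNetwork(graph=g, source_tag=tag)
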