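"""Shared test helpers: random networks and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from umg.netio import WeightedNetwork


def random_connected_network(rng: np.random.Generator, n: int) -> WeightedNetwork:
    """Random connected weighted graph on n nodes: spanning tree + extra edges."""
    nodes = [f"N{i:03d}" for i in range(n)]
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((nodes[j], nodes[i], float(rng.uniform(0.1, 1.0))))
    extra = int(rng.integers(0, max(1, n)))
    for _ in range(extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.append((nodes[int(a)], nodes[int(b)], float(rng.uniform(0.1, 1.0))))
    return WeightedNetwork.from_edges(edges, source_tag="random")


def brute_force_ranks(scores: dict[str, float]) -> dict[str, float]:
    """Tie-averaged descending ranks computed by explicit sorting, no pandas."""
    ordered = sorted(scores.items(), key=lambda kv: -kv[1])
    ranks: dict[str, float] = {}
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j][1] == ordered[i][1]:
            j += 1
        avg = (i + 1 + j) / 2  # mean of positions i+1 .. j
        for k in range(i, j):
            ranks[ordered[k][0]] = avg
        i = j
    return ranks


def brute_force_select(ris: dict[str, float], rfs: dict[str, float], beta: float, T: int) -> set[str]:
    """Direct application of the selection rule, gene by gene."""
    n = len(ris)
    return {g for g in ris if (ris[g] - rfs[g]) >= beta * n and rfs[g] <= T}


def brute_force_rank_p(ref: list[float], other: list[float]) -> float:
    """Exact one-sided permutation p-value that ref ranks are stochastically smaller."""
    combined = list(ref) + list(other)
    obs = sum(ref)
    hits = sum(1 for c in itertools.combinations(combined, len(ref)) if sum(c) <= obs + 1e-9)
    return hits / math.comb(len(combined), len(ref))
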