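"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import defaultdict, deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from diffconet.io import ExpressionDataset, PhenotypeTable


@pytest.fixture
def small_dataset() -> tuple[ExpressionDataset, PhenotypeTable]:
    """3 genes x 6 samples, 3 response / 3 nonresponse."""
    samples = [f"s{i}" for i in range(1, 7)]
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 3.0, 4.0, 5.0],
            [5.0, 5.1, 4.9, 5.0, 5.2, 4.8],
            [2.0, 2.5, 2.2, 7.0, 7.5, 7.2],
        ],
        index=["gA", "gB", "gC"],
        columns=samples,
    )
    dataset = ExpressionDataset(values=values, dataset_id="toy")
    phenotype = PhenotypeTable(
        labels=pd.Series(
            ["response"] * 3 + ["nonresponse"] * 3, index=samples, name="condition"
        )
    )
    return dataset, phenotype


def exhaustive_betweenness(graph: nx.Graph) -> dict:
    """Betweenness by brute-force enumeration of all shortest paths.

    For every unordered node pair (s, t), enumerate ALL shortest s-t paths
    by BFS layering and credit each intermediate node with the fraction of
    paths passing through it.  Independent of the Brandes accumulation used
    by the implementation; only feasible for tiny graphs.
    """
    result = {v: 0.0 for v in graph.nodes}
    nodes = list(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                result[v] += 1.0 / len(paths)
    return result


def _all_shortest_paths(graph: nx.Graph, s, t) -> list[list]:
    # BFS distances from s, then recursive backtrack from t
    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for w in graph.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    if t not in dist:
        return []
    paths: list[list] = []

    def backtrack(v, acc):
        if v == s:
            paths.append([s, *reversed(acc)])
            return
        for u in graph.neighbors(v):
            if dist.get(u, -1) == dist[v] - 1:
                backtrack(u, acc + [v])

    backtrack(t, [])
    return paths


@pytest.fixture
def betweenness_oracle():
    return exhaustive_betweenness


def grid_search_cox_beta(
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    lo: float = -5.0,
    hi: float = 5.0,
) -> float:
    """1-D maximum of the hand-written Breslow/exact partial likelihood.

    Written independently of the package fitter: for untied event times the
    partial log likelihood is sum over events of beta*x_i - log(sum of
    exp(beta*x_j) over the risk set).  Golden-section-free: dense grid then
    local refinement.
    """

    def loglik(beta: float) -> float:
        order = np.argsort(times)
        ll = 0.0
        for pos, i in enumerate(order):
            if not events[i]:
                continue
            risk = order[pos:]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll

    grid = np.linspace(lo, hi, 2001)
    best = grid[int(np.argmax([loglik(b) for b in grid]))]
    fine = np.linspace(best - 0.01, best + 0.01, 2001)
    return float(fine[int(np.argmax([loglik(b) for b in fine]))])


@pytest.fixture
def cox_grid_oracle():
    return grid_search_cox_beta
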