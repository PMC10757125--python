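"""Condition-specific co-expression networks, centralities and hub modules.

PONO (response-state network) is the union of PO and NO edges; OPON
(nonresponse-state network) the union of OP and ON edges.  Hubs are genes
ranking highly on both degree (local connectivity) and betweenness
centrality (global shortest-path load); the module is the induced subgraph
on the selected hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from diffconet.diffcoexpr import condition_correlations
from diffconet.io import ExpressionDataset, PhenotypeTable, ValidationError

logger = logging.getLogger(__name__)

NETWORK_CLASSES = {"PONO": ("PO", "NO"), "OPON": ("OP", "ON")}


def assemble_networks(edges: pd.DataFrame) -> dict[str, nx.Graph]:
    """Build the PONO and OPON graphs from classified pair records.

    Duplicate pairs collapse to a single edge (logged); isolated genes are
    excluded by construction (nodes exist only through their edges).
    """
    networks: dict[str, nx.Graph] = {}
    for network_id, classes in NETWORK_CLASSES.items():
        graph = nx.Graph(network_id=network_id)
        sub = edges[edges["pair_class"].isin(classes)]
        n_dup = 0
        for row in sub.itertuples(index=False):
            a, b = sorted((row.gene_a, row.gene_b))
            if a == b:
                raise ValidationError(f"self-loop on gene {a!r}")
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(
                a,
                b,
                pair_class=row.pair_class,
                r_response=float(row.r_response),
                r_nonresponse=float(row.r_nonresponse),
            )
        if n_dup:
            logger.info("%s: collapsed %d duplicate pairs", network_id, n_dup)
        logger.info(
            "%s: %d genes, %d edges", network_id,
            graph.number_of_nodes(), graph.number_of_edges(),
        )
        networks[network_id] = graph
    return networks


def compute_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree and (unnormalized) betweenness per node.

    Betweenness counts, for each unordered pair (s, t), the fraction of
    unweighted shortest s-t paths through the node (Brandes accumulation);
    pairs in different components contribute nothing.
    """
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "betweenness"]).rename_axis("gene")
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    frame = pd.DataFrame(
        {
            "degree": [graph.degree(v) for v in graph.nodes],
            "betweenness": [betweenness[v] for v in graph.nodes],
        },
        index=pd.Index(list(graph.nodes), name="gene"),
    )
    return frame.sort_index()


@dataclass
class HubModule:
    """Hub genes of one network and the induced subgraph on them."""

    network_id: str
    hubs: list[str]  # ordered by rank
    subgraph: nx.Graph
    k_degree: int
    k_betweenness: int
    module_size: int
    used_fallback_union: bool = False


def _top_k(metrics: pd.DataFrame, column: str, k: int) -> list[str]:
    other = "betweenness" if column == "degree" else "degree"
    order = sorted(
        metrics.index,
        key=lambda g: (-metrics.at[g, column], -metrics.at[g, other], g),
    )
    return order[:k]


def rank_hubs(
    metrics: pd.DataFrame,
    graph: nx.Graph,
    k_degree: int = 10,
    k_betweenness: int = 10,
    module_size: int = 5,
) -> HubModule:
    """Select the hub module: top-K degree ∩ top-K betweenness, rank-summed.

    Candidates in both top-K lists are ordered by the sum of their two rank
    positions, truncated to ``module_size``; ties break by higher degree
    then lexicographic gene id, so the selection is deterministic and
    invariant to node input order.  An empty intersection falls back to the
    union (logged).
    """
    if metrics.empty:
        raise ValidationError("cannot rank hubs of an empty network")
    by_degree = _top_k(metrics, "degree", k_degree)
    by_betweenness = _top_k(metrics, "betweenness", k_betweenness)
    candidates = set(by_degree) & set(by_betweenness)
    fallback = False
    if not candidates:
        logger.warning("empty degree/betweenness intersection; using union")
        candidates = set(by_degree) | set(by_betweenness)
        fallback = True
    # global rank positions (not restricted to the top-K window)
    rank_deg = {g: i for i, g in enumerate(_top_k(metrics, "degree", len(metrics)))}
    rank_bet = {
        g: i for i, g in enumerate(_top_k(metrics, "betweenness", len(metrics)))
    }
    ordered = sorted(
        candidates,
        key=lambda g: (
            rank_deg[g] + rank_bet[g],
            -metrics.at[g, "degree"],
            g,
        ),
    )
    hubs = ordered[:module_size]
    module = nx.Graph(graph.subgraph(hubs))
    module.graph["network_id"] = graph.graph.get("network_id", "")
    return HubModule(
        network_id=graph.graph.get("network_id", ""),
        hubs=hubs,
        subgraph=module,
        k_degree=k_degree,
        k_betweenness=k_betweenness,
        module_size=module_size,
        used_fallback_union=fallback,
    )


def annotate_graph(graph: nx.Graph, metrics: pd.DataFrame, module: HubModule) -> None:
    """Attach degree/betweenness/is_hub node attributes in place (for export)."""
    hubs = set(module.hubs)
    for gene in graph.nodes:
        graph.nodes[gene]["degree"] = int(metrics.at[gene, "degree"])
        graph.nodes[gene]["betweenness"] = float(metrics.at[gene, "betweenness"])
        graph.nodes[gene]["is_hub"] = gene in hubs


def module_correlation_matrix(
    datasets: ExpressionDataset | Sequence[ExpressionDataset],
    phenotypes: PhenotypeTable | Sequence[PhenotypeTable],
    hub_genes: Sequence[str],
    combine: str = "per_dataset_z",
) -> pd.DataFrame:
    """Paired triangular correlation matrix over the hub genes.

    Lower triangle: response-state correlations; upper triangle:
    nonresponse-state correlations; unit diagonal.  Matches the usual
    split-triangle module plot.
    """
    if isinstance(datasets, ExpressionDataset):
        datasets = [datasets]
        phenotypes = [phenotypes]  # type: ignore[list-item]
    for ds in datasets:
        missing = [g for g in hub_genes if g not in ds.values.index]
        if missing:
            raise ValidationError(
                f"hub gene {missing[0]!r} missing from dataset {ds.dataset_id}"
            )
    hub_genes = list(hub_genes)
    table = condition_correlations(datasets, phenotypes, hub_genes, combine=combine)
    k = len(hub_genes)
    pos = {g: i for i, g in enumerate(sorted(hub_genes))}
    mat = np.eye(k)
    for row in table.itertuples(index=False):
        i, j = pos[row.gene_a], pos[row.gene_b]
        lo, hi = max(i, j), min(i, j)
        mat[lo, hi] = row.r_response  # lower triangle
        mat[hi, lo] = row.r_nonresponse  # upper triangle
    ordered = sorted(hub_genes)
    return pd.DataFrame(mat, index=ordered, columns=ordered)
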