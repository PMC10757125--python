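"""Transcription-factor overlay: which TFs regulate the network genes.

A curated TF->target table is intersected with each network's gene set;
TFs are ranked by in-network target coverage (optionally by hypergeometric
enrichment against the table's own gene background, which penalizes
promiscuous regulators), and co-regulated gene sets are the intersection
of several TFs' in-network targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from diffconet.io import TFEdgeTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TFSummary:
    """Per-TF in-network target sets for one network."""

    network_id: str
    targets_in_network: dict[str, set[str]]  # TF -> genes (original casing)

    @property
    def coverage(self) -> dict[str, int]:
        return {tf: len(genes) for tf, genes in self.targets_in_network.items()}


def map_tf_targets(graph: nx.Graph, tf_table: TFEdgeTable) -> TFSummary:
    """In-network target set per TF; TFs without any target are omitted.

    Symbol matching is exact but case-insensitive.  A TF that is itself a
    network gene and targets itself counts as its own target (logged).
    """
    if tf_table.edges.empty:
        raise ValidationError("empty TF table")
    nodes_by_upper = {str(g).upper(): g for g in graph.nodes}
    targets: dict[str, set[str]] = {}
    for row in tf_table.edges.itertuples(index=False):
        gene = nodes_by_upper.get(str(row.target).upper())
        if gene is None:
            continue
        tf = str(row.tf)
        targets.setdefault(tf, set()).add(gene)
        if str(row.tf).upper() == str(row.target).upper():
            logger.info("TF %s targets itself within the network", tf)
    return TFSummary(
        network_id=graph.graph.get("network_id", ""), targets_in_network=targets
    )


def top_regulators(summary: TFSummary, k: int = 10) -> list[tuple[str, int]]:
    """Top-k TFs by in-network coverage, ties broken lexicographically."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not summary.targets_in_network:
        raise ValidationError("TF summary is empty")
    ranked = sorted(summary.coverage.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def enrichment_ranked_regulators(
    summary: TFSummary, tf_table: TFEdgeTable, network_genes: set[str], k: int = 10
) -> list[tuple[str, int, float]]:
    """TFs ranked by hypergeometric enrichment of in-network targets.

    Background: all genes appearing as targets in the TF table.  Returns
    (tf, coverage, p) sorted by p then coverage; raw-count ranking can be
    dominated by promiscuous TFs, which this variant corrects for.
    """
    background = set(tf_table.edges["target"].str.upper())
    n_bg = len(background)
    n_net = len({g.upper() for g in network_genes} & background)
    rows = []
    for tf, genes in summary.targets_in_network.items():
        n_tf = int((tf_table.edges["tf"] == tf).sum())
        kk = len(genes)
        p = float(stats.hypergeom.sf(kk - 1, n_bg, n_tf, n_net))
        rows.append((tf, kk, p))
    rows.sort(key=lambda r: (r[2], -r[1], r[0]))
    return rows[:k]


def coregulated_genes(summary: TFSummary, tf_set: list[str] | set[str]) -> set[str]:
    """Genes regulated by every TF in ``tf_set`` within the network."""
    result: set[str] | None = None
    for tf in tf_set:
        if tf not in summary.targets_in_network:
            raise ValidationError(f"TF {tf!r} absent from the network summary")
        genes = summary.targets_in_network[tf]
        result = set(genes) if result is None else (result & genes)
    if result is None:
        raise ValueError("tf_set must not be empty")
    return result


def summary_table(summary: TFSummary) -> pd.DataFrame:
    """Flat TSV-friendly table: tf, coverage, semicolon-joined targets."""
    rows = [
        {"tf": tf, "coverage": len(genes), "targets": ";".join(sorted(genes))}
        for tf, genes in sorted(summary.targets_in_network.items())
    ]
    return pd.DataFrame(rows, columns=["tf", "coverage", "targets"])
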