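"""Readers and writers for every external format the pipeline touches.

Formats: expression TSV (genes x samples, log2 scale), phenotype TSV,
TF-target TSV (HTRIdb-style exports), GMT gene sets, survival TSV, and
SIF/GraphML network export.  All parsers validate strictly: malformed
numerics are rejected with row/column coordinates rather than coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE = "response"
NONRESPONSE = "nonresponse"
CONDITIONS = (RESPONSE, NONRESPONSE)

#: accepted spellings (case-insensitive) for the two condition labels
_LABEL_ALIASES = {
    "response": RESPONSE,
    "responder": RESPONSE,
    "responded": RESPONSE,
    "nonresponse": NONRESPONSE,
    "non-response": NONRESPONSE,
    "nonresponder": NONRESPONSE,
    "non-responder": NONRESPONSE,
    "unresponded": NONRESPONSE,
}


class FormatError(ValueError):
    """Structural problem in an input file (header, columns, duplicates)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries its coordinates."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Log2 expression values for genes x samples.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns; all entries must be finite and identifiers unique.
    """

    values: pd.DataFrame
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Sample -> condition label in {response, nonresponse}, plus covariates."""

    labels: pd.Series  # index: sample_id, values in CONDITIONS
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            dup = self.labels.index[self.labels.index.duplicated()][0]
            raise ValidationError(f"duplicate sample {dup!r} in phenotype table")
        bad = set(self.labels.unique()) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"unknown condition labels {sorted(bad)}; allowed: {list(CONDITIONS)}"
            )

    def samples(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {condition!r}; allowed: {list(CONDITIONS)}"
            )
        return list(self.labels.index[self.labels == condition])

    def check_covers(self, dataset: ExpressionDataset) -> None:
        missing = set(dataset.sample_ids) - set(self.labels.index)
        if missing:
            raise ValidationError(
                f"samples without phenotype label: {sorted(missing)[:5]}"
            )


@dataclass
class TFEdgeTable:
    """De-duplicated (tf, target) interaction records."""

    edges: pd.DataFrame  # columns: tf, target
    provenance: str = ""

    def __post_init__(self) -> None:
        if list(self.edges.columns) != ["tf", "target"]:
            self.edges = self.edges.rename(
                columns=dict(zip(self.edges.columns, ["tf", "target"]))
            )
        if (self.edges["tf"].str.len() == 0).any() or (
            self.edges["target"].str.len() == 0
        ).any():
            raise ValidationError("empty TF or target symbol")
        if self.edges.duplicated().any():
            raise ValidationError("duplicate (tf, target) pairs after load")

    def targets_of(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT content)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1=event, 0=censored)."""

    data: pd.DataFrame  # index sample_id, columns: time, event

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample {dup!r} in survival table")
        if (self.data["time"] < 0).any():
            bad = self.data.index[self.data["time"] < 0][0]
            raise ValidationError(f"negative time for sample {bad!r}")
        if not self.data["event"].isin([0, 1]).all():
            bad = self.data.index[~self.data["event"].isin([0, 1])][0]
            raise ValidationError(f"event not in {{0,1}} for sample {bad!r}")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    dataset_id: str = "dataset",
    duplicate_policy: Literal["highest_mean", "mean", "error"] = "highest_mean",
) -> ExpressionDataset:
    """Read a tab-separated genes x samples matrix (first column = gene).

    Duplicate gene rows are collapsed by ``duplicate_policy``; the default
    keeps the row with the highest mean expression (common microarray
    practice for multi-probe genes) and logs the event.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise FormatError(f"{path}: missing or malformed header row")
        sample_ids = header.split("\t")[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
            raise FormatError(f"{path}: duplicate sample id {dup!r} in header")
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(sample_ids) + 1}"
                )
            values = []
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    values.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                        f"column {col} (sample {sample_ids[col - 2]!r})"
                    ) from None
            genes.append(fields[0])
            rows.append(values)
    frame = pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)
    if frame.index.has_duplicates:
        frame = _collapse_duplicates(frame, duplicate_policy, path)
    return ExpressionDataset(values=frame, dataset_id=dataset_id)


def _collapse_duplicates(
    frame: pd.DataFrame, policy: str, path: Path
) -> pd.DataFrame:
    dups = sorted(set(frame.index[frame.index.duplicated()]))
    if policy == "error":
        raise FormatError(f"{path}: duplicate gene rows {dups[:5]}")
    if policy == "highest_mean":
        order = frame.mean(axis=1).to_numpy()
        frame = frame.iloc[np.argsort(-order, kind="stable")]
        frame = frame[~frame.index.duplicated(keep="first")]
    elif policy == "mean":
        frame = frame.groupby(level=0, sort=False).mean()
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown duplicate policy {policy!r}")
    logger.info("collapsed %d duplicate gene rows (%s)", len(dups), policy)
    return frame


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------


def read_phenotype_table(
    path: str | Path, drop_unknown: bool = False
) -> PhenotypeTable:
    """Read a TSV with columns sample_id, condition.

    Labels are normalized case-insensitively to {response, nonresponse}.
    Any other label (e.g. "stable") is rejected by default — samples that
    neither responded nor failed therapy are excluded from the design, and
    dropping them must be an explicit choice (``drop_unknown=True``).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(frame.columns))}"
        )
    normalized = frame["condition"].str.strip().str.lower().map(_LABEL_ALIASES)
    unknown = frame.loc[normalized.isna(), "condition"]
    if len(unknown):
        if drop_unknown:
            logger.info("dropping %d samples with unknown labels", len(unknown))
            frame = frame.loc[normalized.notna()]
            normalized = normalized.dropna()
        else:
            raise ValidationError(
                f"{path}: unknown condition label {unknown.iloc[0]!r}; "
                f"allowed labels: {list(CONDITIONS)} (use drop_unknown to discard)"
            )
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated sample {dup!r}")
    labels = pd.Series(
        normalized.to_numpy(), index=frame["sample_id"].to_numpy(), name="condition"
    )
    return PhenotypeTable(labels=labels)


def write_phenotype_table(phenotype: PhenotypeTable, path: str | Path) -> None:
    out = phenotype.labels.rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TF-target interactions
# ---------------------------------------------------------------------------


def read_tf_interactions(
    path: str | Path,
    tf_column: str | int = "tf",
    target_column: str | int = "target",
    provenance: str = "",
) -> TFEdgeTable:
    """Read a TSV of TF->target interactions (HTRIdb-style exports).

    Columns may be named or given as 0-based indices to accommodate the
    varied export layouts of curated interaction databases.  Duplicate
    (tf, target) rows are dropped and the count logged.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty:
        raise FormatError(f"{path}: no interaction rows")

    def _col(spec: str | int) -> pd.Series:
        if isinstance(spec, int):
            if spec >= frame.shape[1]:
                raise FormatError(f"{path}: no column index {spec}")
            return frame.iloc[:, spec]
        if spec not in frame.columns:
            raise FormatError(f"{path}: missing column {spec!r}")
        return frame[spec]

    edges = pd.DataFrame(
        {"tf": _col(tf_column).str.strip(), "target": _col(target_column).str.strip()}
    )
    n_before = len(edges)
    edges = edges.drop_duplicates(ignore_index=True)
    if n_before - len(edges):
        logger.info("dropped %d duplicate TF-target rows", n_before - len(edges))
    return TFEdgeTable(edges=edges, provenance=provenance or str(path))


def write_tf_interactions(table: TFEdgeTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"{path}: set {name!r} at line {lineno} has no members")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def read_survival_table(path: str | Path) -> SurvivalTable:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(frame.columns))}"
        )
    frame = frame.set_index("sample_id")
    return SurvivalTable(data=frame[["time", "event"]])


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.data.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_network(
    graph: nx.Graph, path: str | Path, format: Literal["sif", "graphml"] = "sif"
) -> None:
    """Export a classified co-expression network.

    SIF lines read ``geneA <class> geneB`` with the PO/NO/OP/ON class as the
    interaction token (so downstream viewers can style the four classes);
    GraphML carries edge attributes r_response/r_nonresponse/class and any
    node attributes (degree, betweenness, is_hub) present on the graph.
    """
    path = Path(path)
    if graph.number_of_edges() == 0:
        logger.warning("writing empty network to %s", path)
    if format == "sif":
        lines = []
        for a, b, data in graph.edges(data=True):
            a, b = sorted((a, b))
            lines.append(f"{a}\t{data.get('pair_class', 'co')}\t{b}")
        path.write_text("".join(line + "\n" for line in sorted(lines)))
    elif format == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
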