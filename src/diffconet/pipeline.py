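"""End-to-end orchestration: inputs -> DEGs -> edges -> networks -> prognosis.

Stages communicate through typed artifacts on disk (TSV/JSON/SIF/GraphML)
so each can be rerun or cross-checked standalone.  A run manifest records
parameters, input hashes, per-stage timing and artifact names; a rerun
with the same config and inputs is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from diffconet import diffcoexpr, diffexpr, enrichment, io, network
from diffconet import prognosis as prognosis_mod
from diffconet import regulators as regulators_mod
from diffconet import synthetic_data

logger = logging.getLogger(__name__)


def _package_version() -> str:
    import diffconet

    return diffconet.__version__


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run."""

    expression: list[str] = field(default_factory=list)
    phenotype: list[str] = field(default_factory=list)
    tf_table: str | None = None
    gene_sets: str | None = None
    survival_expression: str | None = None
    survival: str | None = None
    outdir: str = "diffconet_out"
    # differential expression
    adj_p: float = 0.05
    fc: float = 1.5
    down_rule: str = "reciprocal"
    moderation: bool = True
    intersect_mode: str = "any_direction"
    # differential co-expression
    tau: float = 0.7
    ratio_min: float = 1.0
    combine: str = "per_dataset_z"
    # hub module selection
    k_degree: int = 10
    k_betweenness: int = 10
    module_size: int = 5
    # regulators
    top_k_tfs: int = 10
    # prognosis
    split: str = "median"
    ties: str = "efron"
    pi_method: str = "split"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.expression) != len(self.phenotype):
            raise ValueError("need one phenotype table per expression matrix")
        if not self.expression:
            raise ValueError("at least one expression matrix is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "version": _package_version(),
            "parameters": dataclasses.asdict(config),
            "inputs": {},
            "stages": [],
        }
        for path in [
            *config.expression, *config.phenotype,
            *(p for p in (config.tf_table, config.gene_sets,
                          config.survival_expression, config.survival) if p),
        ]:
            self.data["inputs"][str(path)] = _sha256(path)

    def stage(self, name: str, started: float, **counts) -> None:
        self.data["stages"].append(
            {"name": name, "seconds": round(time.perf_counter() - started, 3),
             **counts}
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all artifacts under ``config.outdir``.

    Returns a summary dict mirroring the analysis funnel: per-dataset DEG
    counts, mutual DEG universe, per-class edge counts, network and module
    sizes, top regulators, enrichment hits and prognostic statistics.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    summary: dict = {}

    # stage 1: load inputs ---------------------------------------------------
    t0 = time.perf_counter()
    datasets = [
        io.read_expression_matrix(p, dataset_id=Path(p).stem)
        for p in config.expression
    ]
    phenotypes = [io.read_phenotype_table(p) for p in config.phenotype]
    for ds, ph in zip(datasets, phenotypes):
        ph.check_covers(ds)
    manifest.stage("load_inputs", t0, n_datasets=len(datasets))

    # stage 2: differential expression ---------------------------------------
    t0 = time.perf_counter()
    deg_sets = []
    summary["degs"] = {}
    for ds, ph in zip(datasets, phenotypes):
        records, degs = diffexpr.differential_expression(
            ds, ph,
            moderation=config.moderation,
            adj_p_max=config.adj_p,
            fc_cutoff=config.fc,
            down_rule=config.down_rule,  # type: ignore[arg-type]
        )
        records.to_csv(outdir / f"degs_{ds.dataset_id}.tsv", sep="\t")
        deg_sets.append(degs)
        summary["degs"][ds.dataset_id] = {"up": len(degs.up), "down": len(degs.down)}
    manifest.stage("differential_expression", t0,
                   **{k: v["up"] + v["down"] for k, v in summary["degs"].items()})

    # stage 3: DEG universe --------------------------------------------------
    t0 = time.perf_counter()
    if len(deg_sets) >= 2:
        universe = diffexpr.intersect_degs(
            deg_sets[0], deg_sets[1], mode=config.intersect_mode  # type: ignore[arg-type]
        )
    else:
        universe = sorted(deg_sets[0].genes)
    (outdir / "deg_universe.txt").write_text("".join(g + "\n" for g in universe))
    summary["mutual_degs"] = len(universe)
    manifest.stage("deg_universe", t0, n_genes=len(universe))

    # stage 4: differential co-expression ------------------------------------
    t0 = time.perf_counter()
    thresholds = diffcoexpr.CoexThresholds(
        tau=config.tau, ratio_min=config.ratio_min
    )
    corr = diffcoexpr.condition_correlations(
        datasets, phenotypes, universe, combine=config.combine  # type: ignore[arg-type]
    )
    edges = diffcoexpr.build_differential_edges(corr, thresholds)
    edges.to_csv(outdir / "differential_edges.tsv", sep="\t", index=False)
    class_counts = edges["pair_class"].value_counts().to_dict()
    summary["edge_classes"] = {
        c: int(class_counts.get(c, 0)) for c in diffcoexpr.PAIR_CLASSES
    }
    manifest.stage("differential_coexpression", t0, n_pairs=len(corr),
                   n_edges=len(edges))

    # stage 5: networks, centralities, hub modules ---------------------------
    t0 = time.perf_counter()
    networks = network.assemble_networks(edges)
    modules: dict[str, network.HubModule] = {}
    summary["networks"] = {}
    for net_id, graph in networks.items():
        entry = {
            "n_genes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "hubs": [],
        }
        if graph.number_of_nodes():
            metrics = network.compute_centralities(graph)
            module = network.rank_hubs(
                metrics, graph,
                k_degree=config.k_degree,
                k_betweenness=config.k_betweenness,
                module_size=config.module_size,
            )
            modules[net_id] = module
            network.annotate_graph(graph, metrics, module)
            metrics.assign(is_hub=metrics.index.isin(module.hubs)).to_csv(
                outdir / f"metrics_{net_id}.tsv", sep="\t"
            )
            matrix = network.module_correlation_matrix(
                datasets, phenotypes, module.hubs, combine=config.combine
            )
            matrix.to_csv(outdir / f"module_correlations_{net_id}.tsv", sep="\t")
            entry["hubs"] = module.hubs
        io.write_network(graph, outdir / f"network_{net_id}.sif", format="sif")
        io.write_network(graph, outdir / f"network_{net_id}.graphml", format="graphml")
        summary["networks"][net_id] = entry
    manifest.stage("networks_and_modules", t0,
                   **{k: v["n_edges"] for k, v in summary["networks"].items()})

    # stage 6: transcription-factor overlay ----------------------------------
    t0 = time.perf_counter()
    summary["regulators"] = {}
    if config.tf_table:
        tf_table = io.read_tf_interactions(config.tf_table)
        for net_id, graph in networks.items():
            if graph.number_of_nodes() == 0:
                continue
            tf_summary = regulators_mod.map_tf_targets(graph, tf_table)
            if not tf_summary.targets_in_network:
                continue
            regulators_mod.summary_table(tf_summary).to_csv(
                outdir / f"tf_summary_{net_id}.tsv", sep="\t", index=False
            )
            summary["regulators"][net_id] = [
                list(t) for t in
                regulators_mod.top_regulators(tf_summary, k=config.top_k_tfs)
            ]
    manifest.stage("tf_overlay", t0)

    # stage 7: over-representation -------------------------------------------
    t0 = time.perf_counter()
    summary["enrichment"] = {}
    if config.gene_sets:
        collection = io.read_gene_sets(config.gene_sets)
        gene_universe = sorted(set().union(*(ds.gene_ids for ds in datasets)))
        for net_id, graph in networks.items():
            if graph.number_of_nodes() == 0:
                continue
            result = enrichment.hypergeometric_ora(
                set(graph.nodes), collection, gene_universe
            )
            result.to_csv(outdir / f"enrichment_{net_id}.tsv", sep="\t", index=False)
            summary["enrichment"][net_id] = int((result["adjusted_p"] < 0.05).sum())
    manifest.stage("enrichment", t0)

    # stage 8: prognostic evaluation -----------------------------------------
    t0 = time.perf_counter()
    summary["prognosis"] = {}
    if config.survival and config.survival_expression:
        surv_expr = io.read_expression_matrix(
            config.survival_expression, dataset_id="survival_cohort"
        )
        survival = io.read_survival_table(config.survival)
        for net_id, module in modules.items():
            result = prognosis_mod.evaluate_network_prognosis(
                surv_expr, module.hubs, survival,
                split_method=config.split,  # type: ignore[arg-type]
                ties=config.ties,  # type: ignore[arg-type]
                pi_method=config.pi_method,  # type: ignore[arg-type]
            )
            (outdir / f"prognosis_{net_id}.json").write_text(
                json.dumps(result.summary(), indent=2) + "\n"
            )
            result.km_low.as_frame().to_csv(
                outdir / f"km_{net_id}_low.tsv", sep="\t", index=False
            )
            result.km_high.as_frame().to_csv(
                outdir / f"km_{net_id}_high.tsv", sep="\t", index=False
            )
            summary["prognosis"][net_id] = result.summary()
    manifest.stage("prognostic_evaluation", t0)

    config.to_yaml(outdir / "config.yaml")
    manifest.write(outdir / "manifest.json")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def demo(outdir: str | Path = "diffconet_demo", seed: int = 7) -> dict:
    """Generate the cohort-scale synthetic fixture and run the full pipeline.

    Writes the fixture to ``outdir``/inputs in the standard text formats,
    runs every stage, and returns (and prints) a summary of the analysis
    funnel: DEG counts, mutual DEGs, per-class edges, network and module
    sizes, top TFs and the per-network prognostic statistics.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    bundle = synthetic_data.cohort_fixture(seed=seed)
    io.write_expression_matrix(bundle.expr_a, inputs / "cohortA_expression.tsv")
    io.write_expression_matrix(bundle.expr_b, inputs / "cohortB_expression.tsv")
    io.write_phenotype_table(bundle.pheno_a, inputs / "cohortA_phenotype.tsv")
    io.write_phenotype_table(bundle.pheno_b, inputs / "cohortB_phenotype.tsv")
    io.write_tf_interactions(bundle.tf_table, inputs / "tf_interactions.tsv")
    io.write_expression_matrix(bundle.survival_expr, inputs / "survival_expression.tsv")
    io.write_survival_table(bundle.survival, inputs / "survival.tsv")
    config = PipelineConfig(
        expression=[str(inputs / "cohortA_expression.tsv"),
                    str(inputs / "cohortB_expression.tsv")],
        phenotype=[str(inputs / "cohortA_phenotype.tsv"),
                   str(inputs / "cohortB_phenotype.tsv")],
        tf_table=str(inputs / "tf_interactions.tsv"),
        survival_expression=str(inputs / "survival_expression.tsv"),
        survival=str(inputs / "survival.tsv"),
        outdir=str(outdir / "results"),
        seed=seed,
    )
    summary = run_pipeline(config)
    logger.info("demo summary: %s", json.dumps(summary, indent=2))
    return summary
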