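"""Synthetic expression, TF, gene-set and survival data with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: two patient cohorts split into response/nonresponse, mean-shift
differentially expressed genes, gene blocks whose within-block correlation
is present in one condition and absent or sign-flipped in the other
(compound-symmetry multivariate normal, so the target pairwise correlation
holds by construction), and survival times driven by a known linear
predictor of module-gene expression under an exponential
proportional-hazards model.

Every generated object carries a :class:`SimulationTruth` so recovery of
the planted structure (DEGs, pair classes, hubs, hazard ratios) can be
scored exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from diffconet.diffcoexpr import NONE_CLASS, CoexThresholds, classify_pair
from diffconet.io import (
    CONDITIONS,
    NONRESPONSE,
    RESPONSE,
    ExpressionDataset,
    PhenotypeTable,
    SurvivalTable,
    TFEdgeTable,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid simulation configuration detected before sampling."""


@dataclass
class BlockSpec:
    """A planted correlation block.

    ``rho_on`` is the pairwise correlation among the ``size`` member genes
    in the ``on_condition``; ``rho_off`` the correlation in the other
    condition.  Negative correlations are bounded by compound-symmetry
    validity (rho >= -1/(m-1)): the on-condition value is validated
    strictly, while the off-condition value is clamped into the feasible
    range (with a 5% margin) since it only encodes "absent or opposite"
    co-expression.
    """

    size: int
    rho_on: float
    rho_off: float
    on_condition: str = RESPONSE

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ConfigurationError("block needs at least 2 genes")
        if self.on_condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.on_condition!r}")
        if not -1.0 < self.rho_on <= 1.0 or not -1.0 < self.rho_off < 1.0:
            raise ConfigurationError("block correlations must lie in (-1, 1]")
        lower = -1.0 / (self.size - 1)
        if self.rho_on < lower:
            raise ConfigurationError(
                f"rho_on={self.rho_on} infeasible for a compound-symmetry block "
                f"of {self.size} genes (needs rho >= {lower:.3f})"
            )

    @property
    def rho_off_effective(self) -> float:
        lower = -0.95 / (self.size - 1)
        if self.rho_off < lower:
            logger.info(
                "clamping off-condition correlation %.3g -> %.4g for a "
                "%d-gene block", self.rho_off, lower, self.size,
            )
            return lower
        return self.rho_off

    def population_correlations(self) -> tuple[float, float]:
        """(rho in response, rho in nonresponse) for member pairs."""
        if self.on_condition == RESPONSE:
            return self.rho_on, self.rho_off_effective
        return self.rho_off_effective, self.rho_on

    def expected_class(self, thresholds: CoexThresholds | None = None) -> str:
        r_resp, r_non = self.population_correlations()
        return classify_pair(r_resp, r_non, thresholds)


@dataclass
class DEGSpec:
    """Planted mean-shift differential expression."""

    n_up: int = 0
    n_down: int = 0
    delta: float = 1.0  # log2 shift added in the response condition

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if self.n_up < 0 or self.n_down < 0:
            raise ConfigurationError("DEG counts must be >= 0")


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic expression dataset.

    Defaults model a small log2-scale microarray cohort: baseline
    intensity 7.0, residual noise SD 0.5 (typical for RMA-normalized
    arrays), no batch shift.  ``blocks_from_degs`` places block member
    genes among the planted up-regulated DEGs so that planted pairs
    survive the DEG-universe filter of the full pipeline.
    """

    n_genes: int = 500
    samples_per_condition: tuple[int, int] = (20, 20)  # (response, nonresponse)
    deg_spec: DEGSpec = field(default_factory=DEGSpec)
    blocks: list[BlockSpec] = field(default_factory=list)
    noise_sd: float = 0.5
    baseline: float = 7.0
    batch_shift_sd: float = 0.0
    blocks_from_degs: bool = False
    #: require every planted block to map to a PO/NO/OP/ON class; disable
    #: for null-control experiments that plant the SAME correlation in both
    #: conditions on purpose
    enforce_classifiable: bool = True
    dataset_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if min(self.samples_per_condition) < 0:
            raise ConfigurationError("sample counts must be >= 0")
        n_block_genes = sum(b.size for b in self.blocks)
        n_deg = self.deg_spec.n_up + self.deg_spec.n_down
        needed = n_deg + (0 if self.blocks_from_degs else n_block_genes)
        if self.blocks_from_degs and n_block_genes > self.deg_spec.n_up:
            raise ConfigurationError(
                "blocks_from_degs requires n_up >= total block size"
            )
        if needed > self.n_genes:
            raise ConfigurationError("more planted genes than n_genes")


@dataclass
class SimulationTruth:
    """Ground truth for everything the generator planted."""

    deg_up: list[str] = field(default_factory=list)
    deg_down: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str, str]] = field(default_factory=list)  # a, b, class
    hubs: dict[str, list[str]] = field(default_factory=dict)  # network_id -> genes
    betas: dict[str, float] = field(default_factory=dict)
    censor_target: float = 0.0

    @property
    def deg_genes(self) -> set[str]:
        return set(self.deg_up) | set(self.deg_down)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_block(
    rng: np.random.Generator, size: int, n: int, rho: float
) -> np.ndarray:
    """Draw n samples of a `size`-gene compound-symmetry block (unit SD)."""
    if n == 0:
        return np.empty((size, 0))
    if rho >= 0:
        # exact factor construction; handles rho = 1 (degenerate) cleanly
        shared = rng.standard_normal(n)
        idio = rng.standard_normal((size, n))
        return math.sqrt(rho) * shared[None, :] + math.sqrt(1.0 - rho) * idio
    cov = np.full((size, size), rho)
    np.fill_diagonal(cov, 1.0)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-10:
        raise ConfigurationError(
            f"block correlation matrix not positive semi-definite (rho={rho})"
        )
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return root @ rng.standard_normal((size, n))


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, PhenotypeTable, SimulationTruth]:
    """Sample one expression dataset with planted DEGs and correlation blocks.

    Per condition, block members are drawn from a compound-symmetry
    multivariate normal (rho_on in the block's on-condition, rho_off
    otherwise); all other genes are independent N(baseline, noise_sd^2);
    up/down DEGs receive a +/-delta mean shift in the response condition.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    truth = SimulationTruth()
    spec = config.deg_spec
    truth.deg_up = genes[: spec.n_up]
    truth.deg_down = genes[spec.n_up : spec.n_up + spec.n_down]

    # allocate block member genes
    pool = truth.deg_up if config.blocks_from_degs else genes[spec.n_up + spec.n_down :]
    cursor = 0
    block_members: list[list[str]] = []
    for block in config.blocks:
        members = list(pool[cursor : cursor + block.size])
        cursor += block.size
        block_members.append(members)
        cls = block.expected_class()
        if cls == NONE_CLASS and config.enforce_classifiable:
            raise ConfigurationError(
                f"planted block (rho_on={block.rho_on}, rho_off={block.rho_off}, "
                f"on={block.on_condition}) would not be classified as "
                "differentially co-expressed"
            )
        for i in range(block.size):
            for j in range(i + 1, block.size):
                a, b = sorted((members[i], members[j]))
                truth.pairs.append((a, b, cls))
        if block.size >= 3:
            network = "PONO" if block.on_condition == RESPONSE else "OPON"
            truth.hubs.setdefault(network, []).extend(members)

    n_resp, n_non = config.samples_per_condition
    sample_ids = [f"{config.dataset_id}_R{i + 1}" for i in range(n_resp)] + [
        f"{config.dataset_id}_N{i + 1}" for i in range(n_non)
    ]
    labels = [RESPONSE] * n_resp + [NONRESPONSE] * n_non

    matrix = np.empty((config.n_genes, n_resp + n_non))
    index = {g: i for i, g in enumerate(genes)}
    for condition, sl in ((RESPONSE, slice(0, n_resp)), (NONRESPONSE, slice(n_resp, None))):
        n_cond = n_resp if condition == RESPONSE else n_non
        z = rng.standard_normal((config.n_genes, n_cond))
        for block, members in zip(config.blocks, block_members):
            rho = block.rho_on if condition == block.on_condition else block.rho_off_effective
            rows = [index[g] for g in members]
            z[rows, :] = _sample_block(rng, block.size, n_cond, rho)
        matrix[:, sl] = config.baseline + config.noise_sd * z

    up_rows = [index[g] for g in truth.deg_up]
    down_rows = [index[g] for g in truth.deg_down]
    matrix[up_rows, :n_resp] += spec.delta
    matrix[down_rows, :n_resp] -= spec.delta

    if config.batch_shift_sd > 0:
        matrix += config.batch_shift_sd * rng.standard_normal(config.n_genes)[:, None]

    dataset = ExpressionDataset(
        values=pd.DataFrame(matrix, index=genes, columns=sample_ids),
        dataset_id=config.dataset_id,
    )
    phenotype = PhenotypeTable(
        labels=pd.Series(labels, index=sample_ids, name="condition")
    )
    return dataset, phenotype, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _linear_predictor(
    expression: ExpressionDataset, betas: dict[str, float]
) -> np.ndarray:
    pi = np.zeros(expression.n_samples)
    for gene, beta in betas.items():
        if beta == 0:
            continue
        x = expression.values.loc[gene].to_numpy(float)
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        pi += beta * z
    return pi


def generate_survival(
    expression: ExpressionDataset,
    betas: dict[str, float],
    baseline_rate: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential proportional-hazards survival driven by module expression.

    Event times ~ Exp(baseline_rate * exp(sum_g beta_g * z_g)) with each
    gene z-scored across samples; censoring times are independent
    Exp(censor_rate) (censor_rate = 0 disables censoring); the recorded
    time is the minimum and the event indicator marks true events.
    """
    if baseline_rate <= 0:
        raise ConfigurationError("baseline_rate must be positive")
    if censor_rate < 0:
        raise ConfigurationError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    pi = _linear_predictor(expression, betas)
    rates = baseline_rate * np.exp(pi)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / censor_rate, size=event_times.shape)
    else:
        censor_times = np.full_like(event_times, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    frame = pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(expression.sample_ids, name="sample_id"),
    )
    return SurvivalTable(data=frame)


def calibrate_censor_rate(
    expression: ExpressionDataset,
    betas: dict[str, float],
    baseline_rate: float,
    target_fraction: float,
) -> float:
    """Censoring rate giving the target expected censoring fraction.

    With event rate lambda_i and independent Exp(c) censoring the sample is
    censored with probability c / (c + lambda_i); the mean over samples is
    solved for c by root bracketing.
    """
    if not 0 < target_fraction < 1:
        raise ConfigurationError("target_fraction must lie in (0, 1)")
    rates = baseline_rate * np.exp(_linear_predictor(expression, betas))

    def frac(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target_fraction

    return float(brentq(frac, 1e-12, 1e6))


# ---------------------------------------------------------------------------
# TF fixture
# ---------------------------------------------------------------------------


def generate_tf_table(
    truth: SimulationTruth,
    all_genes: list[str],
    n_decoy_tfs: int = 5,
    targets_per_tf: int = 5,
    master_coverage: float = 1.0,
    seed: int = 0,
) -> TFEdgeTable:
    """TF->target fixture: master TFs blanket the planted modules, decoys don't.

    One master TF per planted hub module targets ``master_coverage`` of its
    genes; decoy TFs target random genes outside every module.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    module_genes: set[str] = set()
    for network, hubs in sorted(truth.hubs.items()):
        n_cover = max(1, int(round(master_coverage * len(hubs))))
        for target in hubs[:n_cover]:
            rows.append((f"MASTER_{network}", target))
        module_genes.update(hubs)
    decoy_pool = [g for g in all_genes if g not in module_genes]
    for d in range(n_decoy_tfs):
        picks = rng.choice(len(decoy_pool), size=min(targets_per_tf, len(decoy_pool)),
                           replace=False)
        for p in sorted(picks):
            rows.append((f"DECOY{d + 1}", decoy_pool[p]))
    edges = pd.DataFrame(rows, columns=["tf", "target"]).drop_duplicates(
        ignore_index=True
    )
    return TFEdgeTable(edges=edges, provenance="synthetic")


# ---------------------------------------------------------------------------
# cohort-scale fixture
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Everything the full pipeline consumes, with shared planted truth."""

    expr_a: ExpressionDataset
    pheno_a: PhenotypeTable
    expr_b: ExpressionDataset
    pheno_b: PhenotypeTable
    tf_table: TFEdgeTable
    survival_expr: ExpressionDataset
    survival: SurvivalTable
    truth: SimulationTruth


#: design values for the cohort-scale fixture: two microarray-sized cohorts
#: (53 samples split 9/44 and 26 split 13/13), ~2000 genes with 100 shared
#: mean-shift DEGs, one 5-gene block per network plus one negative pair each
FIXTURE_N_GENES = 2000
FIXTURE_DEGS = DEGSpec(n_up=60, n_down=40, delta=1.0)
FIXTURE_BLOCKS = [
    BlockSpec(size=5, rho_on=0.85, rho_off=-0.3, on_condition=RESPONSE),
    BlockSpec(size=5, rho_on=0.85, rho_off=-0.3, on_condition=NONRESPONSE),
    BlockSpec(size=2, rho_on=-0.85, rho_off=0.3, on_condition=RESPONSE),
    BlockSpec(size=2, rho_on=-0.85, rho_off=0.3, on_condition=NONRESPONSE),
]
#: per-gene Cox coefficients sized so the designed high-vs-low hazard ratio
#: of the response-network module is ~4 and the nonresponse module's ~3.7:
#: HR ~ exp(1.596 * sd(PI)), sd(PI) = b * sqrt(m + m(m-1) rho)
FIXTURE_BETA_PONO = 0.185
FIXTURE_BETA_OPON = 0.173


def cohort_fixture(seed: int = 0) -> FixtureBundle:
    """Generate the full two-cohort fixture plus TF table and survival cohort.

    Cohort A has 53 samples (9 response / 44 nonresponse), cohort B 26
    (13/13) with a per-gene batch shift; both carry the same planted DEGs
    and correlation blocks so the cross-dataset DEG intersection and pooled
    correlations recover them.  A separate 200-sample cohort (both planted
    blocks active) drives the prognostic evaluation, with ~30% censoring.
    """
    base = SimulationConfig(
        n_genes=FIXTURE_N_GENES,
        deg_spec=FIXTURE_DEGS,
        blocks=list(FIXTURE_BLOCKS),
        blocks_from_degs=True,
        noise_sd=0.5,
    )
    expr_a, pheno_a, truth = generate_expression(
        replace(base, samples_per_condition=(9, 44), dataset_id="cohortA", seed=seed)
    )
    expr_b, pheno_b, _ = generate_expression(
        replace(
            base,
            samples_per_condition=(13, 13),
            dataset_id="cohortB",
            batch_shift_sd=0.2,
            seed=seed + 1,
        )
    )

    # survival cohort: both modules "on" so their designed correlation (and
    # hence the designed sd of the prognostic index) holds for all samples
    surv_blocks = [
        BlockSpec(size=5, rho_on=0.85, rho_off=-0.3, on_condition=RESPONSE),
        BlockSpec(size=5, rho_on=0.85, rho_off=-0.3, on_condition=RESPONSE),
    ]
    surv_config = SimulationConfig(
        n_genes=FIXTURE_N_GENES,
        samples_per_condition=(200, 0),
        deg_spec=FIXTURE_DEGS,
        blocks=surv_blocks,
        blocks_from_degs=True,
        noise_sd=0.5,
        dataset_id="survcohort",
        seed=seed + 2,
    )
    survival_expr, _, _ = generate_expression(surv_config)

    betas = {g: FIXTURE_BETA_PONO for g in truth.hubs.get("PONO", [])}
    betas.update({g: FIXTURE_BETA_OPON for g in truth.hubs.get("OPON", [])})
    truth.betas = betas
    truth.censor_target = 0.3
    censor_rate = calibrate_censor_rate(
        survival_expr, betas, baseline_rate=0.1, target_fraction=0.3
    )
    survival = generate_survival(
        survival_expr, betas, baseline_rate=0.1, censor_rate=censor_rate,
        seed=seed + 3,
    )
    tf_table = generate_tf_table(
        truth, all_genes=expr_a.gene_ids, n_decoy_tfs=5, targets_per_tf=5,
        seed=seed + 4,
    )
    return FixtureBundle(
        expr_a=expr_a,
        pheno_a=pheno_a,
        expr_b=expr_b,
        pheno_b=pheno_b,
        tf_table=tf_table,
        survival_expr=survival_expr,
        survival=survival,
        truth=truth,
    )
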