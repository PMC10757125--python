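"""Pairwise Pearson correlations per condition and PO/NO/OP/ON classification.

For every unordered pair of genes in the analysis universe the Pearson
correlation is computed separately within the response-labelled and the
nonresponse-labelled samples.  A pair is differentially co-expressed when
(i) it is significantly correlated (|r| >= tau, default 0.7) in exactly one
condition and not in the other, and (ii) the relative-change ratio
|(r_response - r_nonresponse) / r_response| reaches 1.  The four classes:

    PO  positive in response, none in nonresponse
    NO  negative in response, none in nonresponse
    OP  none in response, positive in nonresponse
    ON  none in response, negative in nonresponse

Because the ratio's denominator is always the response-state correlation,
the ratio criterion is strictly stronger than the threshold pattern for
PO/NO pairs (it additionally requires the nonresponse correlation to be
<= 0), while for OP/ON pairs the near-zero denominator makes it pass
whenever the correlations actually differ (guarded PASS).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from diffconet.io import (
    NONRESPONSE,
    RESPONSE,
    ExpressionDataset,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`differential_ratio` when the denominator is
#: (numerically) zero but the two correlations genuinely differ
PASS = math.inf

PAIR_CLASSES = ("PO", "NO", "OP", "ON")
NONE_CLASS = "NONE"


@dataclass
class CoexThresholds:
    """Classification thresholds.

    ``tau`` is the significance threshold on |r| (default 0.7, a widely
    used cutoff for calling a gene pair co-expressed); "no correlation"
    means |r| < ``tau_low`` which defaults to the same tau.  ``ratio_min``
    is the minimum relative-change ratio and ``epsilon`` guards the
    zero denominator.
    """

    tau: float = 0.7
    ratio_min: float = 1.0
    epsilon: float = 1e-12
    tau_low: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.ratio_min <= 0:
            raise ValueError("ratio_min must be positive")
        if self.tau_low is None:
            self.tau_low = self.tau


class ConstantVectorError(ValueError):
    """Correlation requested against a constant vector (undefined)."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation, clamped to [-1, 1] against round-off.

    Raises :class:`ConstantVectorError` for a constant input — an undefined
    correlation is never silently reported as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0 or sy == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r = float(xd @ yd) / math.sqrt(sx * sy)
    return max(-1.0, min(1.0, r))


def _zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    sd = sd.replace(0.0, np.nan)  # constant genes stay NaN -> NONE downstream
    return matrix.sub(mean, axis=0).div(sd, axis=0)


def _condition_matrix(
    datasets: Sequence[ExpressionDataset],
    phenotypes: Sequence[PhenotypeTable],
    gene_universe: Sequence[str],
    condition: str,
    combine: str,
) -> np.ndarray:
    blocks = []
    for ds, ph in zip(datasets, phenotypes):
        ph.check_covers(ds)
        samples = [s for s in ds.sample_ids if ph.labels[s] == condition]
        if not samples:
            continue
        sub = ds.values.loc[list(gene_universe), samples]
        if combine == "per_dataset_z":
            sub = _zscore_columns(sub)
        blocks.append(sub.to_numpy())
    if not blocks:
        raise ValidationError(f"no samples for condition {condition!r}")
    return np.hstack(blocks)


def condition_correlations(
    datasets: ExpressionDataset | Sequence[ExpressionDataset],
    phenotypes: PhenotypeTable | Sequence[PhenotypeTable],
    gene_universe: Sequence[str],
    combine: Literal["per_dataset_z", "concat"] = "per_dataset_z",
) -> pd.DataFrame:
    """Per-pair correlations in both conditions over ``gene_universe``.

    With several datasets, ``per_dataset_z`` (default) z-scores each gene
    within each dataset before pooling samples, suppressing batch-offset
    driven spurious correlation; ``concat`` pools raw values.  Returns one
    row per unordered pair (gene_a < gene_b) with columns r_response and
    r_nonresponse; pairs involving a constant gene get NaN correlations
    (classified NONE downstream) and are logged.
    """
    if isinstance(datasets, ExpressionDataset):
        datasets = [datasets]
        phenotypes = [phenotypes]  # type: ignore[list-item]
    gene_universe = sorted(dict.fromkeys(gene_universe))
    for ds in datasets:
        missing = set(gene_universe) - set(ds.gene_ids)
        if missing:
            raise ValidationError(
                f"universe genes missing from {ds.dataset_id}: {sorted(missing)[:5]}"
            )
    corr = {}
    for condition in (RESPONSE, NONRESPONSE):
        mat = _condition_matrix(datasets, phenotypes, gene_universe, condition, combine)
        if mat.shape[1] < 4:
            raise ValidationError(
                f"condition {condition!r} has {mat.shape[1]} samples; need >= 4"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(mat)
        corr[condition] = np.clip(r, -1.0, 1.0)
    pairs = list(itertools.combinations(range(len(gene_universe)), 2))
    ii = np.array([p[0] for p in pairs], dtype=int)
    jj = np.array([p[1] for p in pairs], dtype=int)
    table = pd.DataFrame(
        {
            "gene_a": np.asarray(gene_universe, object)[ii],
            "gene_b": np.asarray(gene_universe, object)[jj],
            "r_response": corr[RESPONSE][ii, jj],
            "r_nonresponse": corr[NONRESPONSE][ii, jj],
        }
    )
    n_nan = int(table[["r_response", "r_nonresponse"]].isna().any(axis=1).sum())
    if n_nan:
        logger.warning(
            "%d pairs involve a constant gene; their class will be NONE", n_nan
        )
    return table


def differential_ratio(
    r_resp: float, r_non: float, epsilon: float = 1e-12
) -> float:
    """Relative change |(r_response - r_nonresponse) / r_response|.

    When the denominator is numerically zero the ratio is the :data:`PASS`
    sentinel if the correlations actually differ, else 0.
    """
    if abs(r_resp) < epsilon:
        return PASS if abs(r_resp - r_non) > epsilon else 0.0
    return abs((r_resp - r_non) / r_resp)


def classify_pair(
    r_resp: float, r_non: float, thresholds: CoexThresholds | None = None
) -> str:
    """Assign PO/NO/OP/ON or NONE to one pair of condition correlations.

    A class is assigned only when BOTH the four-condition threshold
    pattern and the differential-ratio criterion (ratio >= ratio_min, or
    the guarded PASS) hold.
    """
    thr = thresholds or CoexThresholds()
    if not (np.isfinite(r_resp) and np.isfinite(r_non)):
        return NONE_CLASS
    tau, low = thr.tau, thr.tau_low
    if r_resp >= tau and abs(r_non) < low:
        pattern = "PO"
    elif r_resp <= -tau and abs(r_non) < low:
        pattern = "NO"
    elif abs(r_resp) < low and r_non >= tau:
        pattern = "OP"
    elif abs(r_resp) < low and r_non <= -tau:
        pattern = "ON"
    else:
        return NONE_CLASS
    ratio = differential_ratio(r_resp, r_non, thr.epsilon)
    if ratio >= thr.ratio_min:
        return pattern
    return NONE_CLASS


def build_differential_edges(
    table: pd.DataFrame, thresholds: CoexThresholds | None = None
) -> pd.DataFrame:
    """Classify a correlation table and keep the non-NONE records.

    Returns rows gene_a, gene_b, r_response, r_nonresponse, ratio,
    pair_class with gene_a < gene_b; per-class counts are logged.
    """
    thr = thresholds or CoexThresholds()
    out = table.copy()
    # canonical orientation: gene_a < gene_b lexicographically
    flip = out["gene_a"] > out["gene_b"]
    if flip.any():
        a = out.loc[flip, "gene_b"].to_numpy()
        out.loc[flip, "gene_b"] = out.loc[flip, "gene_a"].to_numpy()
        out.loc[flip, "gene_a"] = a
    out["ratio"] = [
        differential_ratio(r1, r2, thr.epsilon)
        if np.isfinite(r1) and np.isfinite(r2)
        else np.nan
        for r1, r2 in zip(out["r_response"], out["r_nonresponse"])
    ]
    out["pair_class"] = [
        classify_pair(r1, r2, thr)
        for r1, r2 in zip(out["r_response"], out["r_nonresponse"])
    ]
    edges = out[out["pair_class"] != NONE_CLASS].reset_index(drop=True)
    counts = edges["pair_class"].value_counts().to_dict()
    logger.info(
        "classified %d/%d pairs as differential: %s",
        len(edges),
        len(table),
        {c: counts.get(c, 0) for c in PAIR_CLASSES},
    )
    return edges
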