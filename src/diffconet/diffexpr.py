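"""Two-group differential expression with empirical-Bayes variance moderation.

The workhorse is a moderated two-sample t-statistic: per-gene pooled
variances are shrunk toward a common prior estimated from the marginal
distribution of the sample variances (method-of-moments on log s^2,
empirical-Bayes style), which stabilizes inference in small cohorts such
as a 9-vs-44 responder split.  Significance is controlled with the
Benjamini-Hochberg step-up FDR and genes are called up/down by a fold
change cutoff (default 1.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from diffconet.io import (
    NONRESPONSE,
    RESPONSE,
    ExpressionDataset,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: sentinel for a fully pooled prior (every gene gets the prior variance)
INFINITE_PRIOR_DF = np.inf

#: variance floor used when a gene is constant in both groups but the means
#: differ and moderation is off; keeps the t finite while flagging the event
EPSILON_VARIANCE = 1e-12


@dataclass
class ModerationParams:
    """Empirical-Bayes prior for the gene-wise variances.

    ``prior_df`` (d0) counts the pseudo-observations behind the prior
    variance ``prior_var`` (s0^2); d0 = 0 reduces to the ordinary t and
    d0 = inf pools every gene to s0^2.
    """

    prior_df: float
    prior_var: float
    residual_df: float

    def posterior_var(self, sample_var: np.ndarray) -> np.ndarray:
        if np.isinf(self.prior_df):
            return np.full_like(np.asarray(sample_var, float), self.prior_var)
        d0, dg = self.prior_df, self.residual_df
        return (d0 * self.prior_var + dg * sample_var) / (d0 + dg)


@dataclass
class DEGSet:
    """Up/down gene calls for one dataset at stated thresholds."""

    dataset_id: str
    up: list[str]
    down: list[str]
    adj_p_max: float = 0.05
    fc_cutoff: float = 1.5
    down_rule: str = "reciprocal"

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValidationError("a gene cannot be both up- and down-regulated")

    @property
    def genes(self) -> set[str]:
        return set(self.up) | set(self.down)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(sample_var: np.ndarray, residual_df: float) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) from the spread of log variances.

    Writing z_g = log s_g^2, E z_g = log s0^2 + [psi(d_g/2) - log(d_g/2)]
    - [psi(d0/2) - log(d0/2)] and Var z_g = psi'(d_g/2) + psi'(d0/2) under
    the scaled-F marginal model, so d0 follows from a trigamma inversion of
    the excess spread and s0^2 from the mean.  Genes with zero variance are
    excluded from the fit (they carry no spread information).
    """
    sv = np.asarray(sample_var, float)
    sv = sv[sv > 0]
    if sv.size < 2:
        return ModerationParams(0.0, float(np.mean(sample_var)), residual_df)
    dg = residual_df
    z = np.log(sv)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, dg / 2.0))
    if excess <= 0:
        # no detectable gene-to-gene variance heterogeneity: pool fully
        prior_var = float(np.exp(np.mean(e)))
        return ModerationParams(INFINITE_PRIOR_DF, prior_var, residual_df)
    d0 = 2.0 * _trigamma_inverse(excess)
    prior_var = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return ModerationParams(d0, prior_var, residual_df)


def moderated_t_test(
    dataset: ExpressionDataset,
    phenotype: PhenotypeTable,
    moderation: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample (moderated) t between response and nonresponse.

    Returns a DataFrame indexed by gene with columns mean_response,
    mean_nonresponse, log2_fc (response minus nonresponse), t_statistic,
    p_value.  With ``moderation`` the pooled variances are shrunk toward
    the empirical-Bayes prior and the t degrees of freedom grow by d0.
    """
    phenotype.check_covers(dataset)
    resp = [s for s in dataset.sample_ids if phenotype.labels[s] == RESPONSE]
    non = [s for s in dataset.sample_ids if phenotype.labels[s] == NONRESPONSE]
    n1, n2 = len(resp), len(non)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need >=2 samples per condition, got {n1} response / {n2} nonresponse"
        )
    x1 = dataset.values[resp].to_numpy()
    x2 = dataset.values[non].to_numpy()
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    delta = m1 - m2
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (ss1 + ss2) / df_resid

    if moderation:
        params = estimate_moderation(s2, df_resid)
        s2_post = params.posterior_var(s2)
        df_total = (
            np.inf if np.isinf(params.prior_df) else params.prior_df + df_resid
        )
        logger.info(
            "moderation: d0=%.3g, s0^2=%.4g", params.prior_df, params.prior_var
        )
    else:
        s2_post = s2.copy()
        df_total = df_resid

    zero_var = s2_post <= 0
    if zero_var.any():
        n_guard = int((zero_var & (delta != 0)).sum())
        if n_guard:
            logger.warning(
                "%d genes with zero variance but nonzero mean difference; "
                "applying epsilon-variance guard",
                n_guard,
            )
        s2_post = np.where(zero_var, EPSILON_VARIANCE, s2_post)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = delta / se
    # constant gene with no mean difference: t = 0, p = 1 by convention
    t = np.where(zero_var & (delta == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "mean_response": m1,
            "mean_nonresponse": m2,
            "log2_fc": delta,
            "t_statistic": t,
            "p_value": p,
        },
        index=dataset.values.index.rename("gene"),
    )


def bh_adjust(p_values: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    records: pd.DataFrame,
    dataset_id: str = "dataset",
    adj_p_max: float = 0.05,
    fc_cutoff: float = 1.5,
    down_rule: Literal["reciprocal", "half"] = "reciprocal",
) -> DEGSet:
    """Call up/down regulated genes from a moderated-t table.

    Up: adjusted p < ``adj_p_max`` and fold change >= ``fc_cutoff``.
    Down: adjusted p < ``adj_p_max`` and fold change at or below the down
    threshold, which is 1/``fc_cutoff`` under ``down_rule='reciprocal'``
    (symmetric on the log scale) or the literal 0.5 under
    ``down_rule='half'`` — reported fold-change conventions differ between
    the two, so both are supported explicitly.
    """
    records = records.copy()
    if "adjusted_p" not in records.columns:
        records["adjusted_p"] = bh_adjust(records["p_value"].to_numpy())
    up_log2 = np.log2(fc_cutoff)
    if down_rule == "reciprocal":
        down_log2 = -np.log2(fc_cutoff)
        down_mask = records["log2_fc"] <= down_log2
    elif down_rule == "half":
        down_mask = records["log2_fc"] < np.log2(0.5)
    else:
        raise ValueError(f"unknown down_rule {down_rule!r}")
    sig = records["adjusted_p"] < adj_p_max
    up = sorted(records.index[sig & (records["log2_fc"] >= up_log2)])
    down = sorted(records.index[sig & down_mask])
    logger.info(
        "%s: %d up, %d down at adj_p<%g, fc>=%g (%s down rule)",
        dataset_id, len(up), len(down), adj_p_max, fc_cutoff, down_rule,
    )
    return DEGSet(
        dataset_id=dataset_id,
        up=up,
        down=down,
        adj_p_max=adj_p_max,
        fc_cutoff=fc_cutoff,
        down_rule=down_rule,
    )


def differential_expression(
    dataset: ExpressionDataset,
    phenotype: PhenotypeTable,
    moderation: bool = True,
    adj_p_max: float = 0.05,
    fc_cutoff: float = 1.5,
    down_rule: Literal["reciprocal", "half"] = "reciprocal",
) -> tuple[pd.DataFrame, DEGSet]:
    """Full per-dataset DEG analysis: moderated t -> BH -> threshold calls."""
    records = moderated_t_test(dataset, phenotype, moderation=moderation)
    records["adjusted_p"] = bh_adjust(records["p_value"].to_numpy())
    records["direction"] = "none"
    degs = call_degs(
        records,
        dataset_id=dataset.dataset_id,
        adj_p_max=adj_p_max,
        fc_cutoff=fc_cutoff,
        down_rule=down_rule,
    )
    records.loc[records.index.isin(degs.up), "direction"] = "up"
    records.loc[records.index.isin(degs.down), "direction"] = "down"
    return records, degs


def intersect_degs(
    set_a: DEGSet,
    set_b: DEGSet,
    mode: Literal["any_direction", "same_direction"] = "any_direction",
) -> list[str]:
    """Mutual DEGs between two datasets.

    ``any_direction`` intersects the full DEG lists; ``same_direction``
    additionally requires the regulation direction to agree.
    """
    if mode == "any_direction":
        mutual = set_a.genes & set_b.genes
    elif mode == "same_direction":
        mutual = (set(set_a.up) & set(set_b.up)) | (set(set_a.down) & set(set_b.down))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sorted(mutual)


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Optional cross-sample quantile normalization (off by default upstream).

    Each sample's values are replaced by the mean expression profile at the
    matching ranks; ties get the average of the tied reference values.
    """
    values = dataset.values
    ranked = values.rank(method="average", axis=0)
    mean_profile = np.sort(values.to_numpy(), axis=0).mean(axis=1)
    # interpolate at average ranks so ties are handled smoothly
    positions = np.arange(1, values.shape[0] + 1, dtype=float)
    out = values.copy()
    for col in values.columns:
        out[col] = np.interp(ranked[col].to_numpy(), positions, mean_profile)
    return ExpressionDataset(values=out, dataset_id=dataset.dataset_id)
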