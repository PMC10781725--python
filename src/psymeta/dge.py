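"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene, logFC is the case-minus-control mean difference on the log2 scale
and the residual variance is shrunk toward a prior estimated from the
across-gene variance distribution (method of moments on log variances, the
standard scaled-inverse-chi-square hierarchical model). Two-sided p-values
come from the t distribution with residual-plus-prior degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocessing import ExpressionStudy

logger = logging.getLogger("psymeta")


@dataclass
class DGETable:
    """One study's differential-expression summary.

    ``table`` has columns gene, logFC, p and optionally t; ``reporting`` is
    'full' or 'partial', and partial tables carry the truncation threshold
    their rows were filtered at (every reported p <= threshold).
    """

    study_id: str
    table: pd.DataFrame
    reporting: str = "full"
    threshold: float | None = None

    def __post_init__(self) -> None:
        t = self.table
        if t["gene"].duplicated().any():
            raise ValueError(f"{self.study_id}: duplicate gene symbols in DGE table")
        p = t["p"].to_numpy(float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError(f"{self.study_id}: p-values outside [0, 1]")
        if self.reporting == "partial":
            if self.threshold is None:
                raise ValueError(f"{self.study_id}: partial table requires a truncation threshold")
            if np.any(p > self.threshold + 1e-12):
                raise ValueError(f"{self.study_id}: partial table contains p above its threshold")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"])


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting value for all y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df d0, prior_var s0^2) to gene variances.

    Models s2 ~ s0^2 * F(df, d0) via the moments of log s2. Returns
    (d0, s0sq); d0 may be ``inf`` when the observed log-variance spread is no
    larger than expected under a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("all genes have zero within-group variance; prior unestimable")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(evar))
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


def moderated_t_dge(study: ExpressionStudy, prior_df: float | None = None) -> DGETable:
    """Moderated-t differential expression for one normalized study.

    ``prior_df`` overrides the estimated prior degrees of freedom; passing 0
    recovers the ordinary pooled-variance two-sample t-test exactly.
    """
    case = study.values[study.case_columns].to_numpy(float)
    ctrl = study.values[study.control_columns].to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"{study.study_id}: need >= 2 samples per group, got {n1}/{n2}")

    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    n_genes = len(logfc)
    if prior_df is None:
        if n_genes == 1:
            logger.warning("%s: single gene; falling back to ordinary t", study.study_id)
            d0, s0sq = 0.0, 1.0
        else:
            d0, s0sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0sq = estimate_variance_prior(s2, df_resid)[1] if d0 > 0 else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(df_resid + d0)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {"gene": study.values.index.to_numpy(), "logFC": logfc, "p": p, "t": t}
    )
    return DGETable(study_id=study.study_id, table=table, reporting="full")


def truncate_table(table: DGETable, threshold: float) -> DGETable:
    """Keep only rows with p <= threshold; mark the table partial."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"truncation threshold must lie in (0, 1]; got {threshold}")
    kept = table.table[table.table["p"] <= threshold].reset_index(drop=True)
    return replace(table, table=kept, reporting="partial", threshold=float(threshold))


def blank_logfc(table: DGETable) -> DGETable:
    """Return a copy with the logFC column (and t) marked unavailable."""
    out = table.table.copy()
    out["logFC"] = np.nan
    if "t" in out.columns:
        out = out.drop(columns=["t"])
    return replace(table, table=out)
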