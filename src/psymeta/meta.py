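"""Two-level adaptively weighted Fisher (AW-Fisher) meta-analysis.

Within each database, study p-values are combined per gene by searching all
nonzero binary study-inclusion weight vectors w, scoring each by the upper
chi-square tail of the weighted Fisher statistic T(w) = sum_k w_k (-2 ln p_k)
at 2*sum(w) degrees of freedom, and taking the minimum candidate p. Because
that minimum is itself optimized, its null distribution is assessed by a
shared, seeded Monte-Carlo table of min-candidate-p values under independent
Uniform(0,1) study p-values. Partial (truncated) tables first receive mean
imputation for their unreported genes: a gene missing from a table truncated
at threshold t is known to have p in (t, 1], whose mean is (t+1)/2.

The two database-level AW p-values are then combined the same way; common
DEGs are the genes significant cross-database with both databases selected
(weight (1,1)) and direction-concordant (C or S) in each database. Gene-level
log-fold-changes are pooled within a database by inverse-p weighting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import ConcordanceRecord
from .dge import DGETable

logger = logging.getLogger("psymeta")

P_FLOOR = 1e-300


@dataclass
class AWFisherResult:
    gene: str
    p_combined: float
    weights: tuple[int, ...]
    observed_min_candidate_p: float
    n_imputed: int = 0


@dataclass
class MetaGeneResult:
    """Per-gene cross-database meta-analysis summary."""

    gene: str
    p_a: float
    p_b: float
    weights_a: tuple[int, ...]
    weights_b: tuple[int, ...]
    p_cross: float
    weights_cross: tuple[int, int]
    status_a: str
    status_b: str
    logfc_a: float
    logfc_b: float
    is_common_deg: bool
    direction: str  # up | down | mixed | na


def impute_missing_pvalues(
    tables: list[DGETable], method: str = "censored_mean"
) -> list[DGETable]:
    """Complete partial tables over the union gene universe.

    ``censored_mean`` (default): a gene absent from a table truncated at
    threshold t receives p = (t+1)/2, the mean of the censored interval
    (t, 1]. ``grand_mean``: the mean of the table's observed p-values
    (the alternative reading of "mean imputation"). Imputed rows are flagged
    in an ``imputed`` column; full tables are untouched.
    """
    universe: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.table["gene"]:
            if g not in seen:
                seen.add(g)
                universe.append(g)

    out: list[DGETable] = []
    for t in tables:
        if t.reporting != "partial":
            tbl = t.table.copy()
            tbl["imputed"] = False
            out.append(replace(t, table=tbl))
            continue
        if t.threshold is None:
            raise ValueError(f"{t.study_id}: partial table without truncation threshold")
        if method == "censored_mean":
            p_imp = (t.threshold + 1.0) / 2.0
        elif method == "grand_mean":
            p_imp = float(t.table["p"].mean())
        else:
            raise ValueError(f"unknown imputation method {method!r}")
        present = set(t.table["gene"])
        missing = [g for g in universe if g not in present]
        tbl = t.table.copy()
        tbl["imputed"] = False
        if missing:
            add = pd.DataFrame(
                {
                    "gene": missing,
                    "logFC": np.nan,
                    "p": p_imp,
                    "imputed": True,
                }
            )
            tbl = pd.concat([tbl, add], ignore_index=True)
        out.append(DGETable(study_id=t.study_id, table=tbl, reporting="full", threshold=None))
    return out


def _weight_matrix(k: int) -> np.ndarray:
    """All 2^k - 1 nonzero binary weight vectors, most-inclusive-first order.

    Sorted by (descending number of ones, then lexicographic), so that with
    ``argmin`` on candidate p-values ties resolve to the most inclusive
    weight vector, then the lexicographically smallest.
    """
    if k < 1:
        raise ValueError("need at least one study")
    if k > 20:
        raise ValueError("weight enumeration bounded at 20 studies")
    rows = [w for w in itertools.product((0, 1), repeat=k) if any(w)]
    rows.sort(key=lambda w: (-sum(w), w))
    return np.array(rows, dtype=np.int8)


def fisher_stat(pvals: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted Fisher statistic T(w) and its chi-square candidate p-value."""
    pvals = np.clip(np.asarray(pvals, dtype=float), P_FLOOR, 1.0)
    w = np.asarray(w)
    if len(pvals) != len(w):
        raise ValueError("pvals and w must have equal length")
    if not w.any():
        raise ValueError("weight vector must have at least one nonzero entry")
    t_stat = float(np.sum(w * (-2.0 * np.log(pvals))))
    df = 2.0 * int(w.sum())
    return t_stat, float(stats.chi2.sf(t_stat, df))


def _min_candidate_p(pmat: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row min candidate p over all weight vectors; returns (min_p, argmin row)."""
    logp = -2.0 * np.log(np.clip(pmat, P_FLOOR, 1.0))  # (G, K)
    t_all = logp @ weights.T.astype(float)  # (G, W)
    dfs = 2.0 * weights.sum(axis=1).astype(float)  # (W,)
    cand = stats.chi2.sf(t_all, dfs[None, :])
    best = np.argmin(cand, axis=1)  # first minimum = most inclusive by row order
    return cand[np.arange(len(cand)), best], best


def build_null_table(k: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of min-candidate-p for K studies."""
    weights = _weight_matrix(k)
    null_p = rng.uniform(size=(B, k))
    min_p, _ = _min_candidate_p(null_p, weights)
    return np.sort(min_p)


def aw_fisher(
    pmat: np.ndarray,
    genes: list[str] | None = None,
    B: int = 10_000,
    rng: np.random.Generator | None = None,
    null_table: np.ndarray | None = None,
    n_imputed: np.ndarray | None = None,
) -> list[AWFisherResult]:
    """AW-Fisher combination for a genes x studies p-value matrix.

    The combined p-value is the null probability that the minimum candidate
    p is <= the observed one, estimated from the shared Monte-Carlo table as
    (1 + #{null <= observed}) / (B + 1), hence floored at 1/(B+1).
    """
    pmat = np.atleast_2d(np.asarray(pmat, dtype=float))
    n_genes, k = pmat.shape
    if k == 0:
        raise ValueError("no studies to combine")
    weights = _weight_matrix(k)
    obs_min_p, best = _min_candidate_p(pmat, weights)
    if null_table is None:
        if rng is None:
            raise ValueError("aw_fisher needs an rng (or a prebuilt null_table)")
        null_table = build_null_table(k, B, rng)
    n_null = len(null_table)
    counts = np.searchsorted(null_table, obs_min_p, side="right")
    p_comb = (counts + 1.0) / (n_null + 1.0)
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    n_imp = n_imputed if n_imputed is not None else np.zeros(n_genes, dtype=int)
    return [
        AWFisherResult(
            gene=g,
            p_combined=float(pc),
            weights=tuple(int(x) for x in weights[b]),
            observed_min_candidate_p=float(om),
            n_imputed=int(ni),
        )
        for g, pc, b, om, ni in zip(genes, p_comb, best, obs_min_p, n_imp)
    ]


def meta_analyze_database(
    tables: list[DGETable],
    B: int = 10_000,
    rng: np.random.Generator | None = None,
    imputation: str = "censored_mean",
) -> list[AWFisherResult]:
    """Impute partial tables, assemble the p matrix, and run AW-Fisher."""
    completed = impute_missing_pvalues(tables, method=imputation)
    universe: list[str] = []
    seen: set[str] = set()
    for t in completed:
        for g in t.table["gene"]:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    pmat = np.ones((len(universe), len(completed)))
    imputed = np.zeros((len(universe), len(completed)), dtype=bool)
    index = {g: i for i, g in enumerate(universe)}
    for j, t in enumerate(completed):
        rows = t.table["gene"].map(index).to_numpy()
        pmat[rows, j] = t.table["p"].to_numpy(float)
        if "imputed" in t.table.columns:
            imputed[rows, j] = t.table["imputed"].to_numpy(bool)
    return aw_fisher(pmat, genes=universe, B=B, rng=rng, n_imputed=imputed.sum(axis=1))


def combine_databases(
    meta_a: list[AWFisherResult],
    meta_b: list[AWFisherResult],
    B: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[list[AWFisherResult], list[str]]:
    """AW-Fisher on the per-gene pair of database-level p-values.

    Genes missing from either database are dropped and returned in the log.
    """
    a = {r.gene: r for r in meta_a}
    b = {r.gene: r for r in meta_b}
    shared = [g for g in a if g in b]
    dropped = sorted((set(a) | set(b)) - set(shared))
    if not shared:
        raise ValueError("no genes shared between the two databases")
    if dropped:
        logger.info("combine_databases: dropped %d genes absent from one database", len(dropped))
    pmat = np.array([[a[g].p_combined, b[g].p_combined] for g in shared])
    return aw_fisher(pmat, genes=shared, B=B, rng=rng), dropped


def combine_logfc(tables: list[DGETable]) -> pd.Series:
    """Inverse-p-weighted pooled logFC per gene over studies reporting a logFC.

    pooled = sum_s logFC_gs / p_gs / sum_s 1 / p_gs, with p floored at 1e-300;
    genes with no reported logFC anywhere get NaN.
    """
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for t in tables:
        for gene, logfc, p in t.table[["gene", "logFC", "p"]].itertuples(index=False):
            if not np.isfinite(logfc):
                continue
            w = 1.0 / max(float(p), P_FLOOR)
            num[gene] = num.get(gene, 0.0) + w * float(logfc)
            den[gene] = den.get(gene, 0.0) + w
    genes = sorted(set(g for t in tables for g in t.table["gene"]))
    return pd.Series(
        {g: (num[g] / den[g]) if g in den else np.nan for g in genes}, name="pooled_logFC"
    )


def select_common_degs(
    cross: list[AWFisherResult],
    results_a: list[AWFisherResult],
    results_b: list[AWFisherResult],
    concordance_a: list[ConcordanceRecord],
    concordance_b: list[ConcordanceRecord],
    logfc_a: pd.Series,
    logfc_b: pd.Series,
    alpha: float = 0.05,
) -> list[MetaGeneResult]:
    """Flag common DEGs: cross p < alpha with weight (1,1) and C/S in both databases.

    Every cross-database gene is retained with its evidence; the flag marks
    those meeting both criteria. Direction is 'up'/'down' when both pooled
    logFCs share that sign, 'mixed' when they disagree, 'na' when either is
    unavailable.
    """
    amap = {r.gene: r for r in results_a}
    bmap = {r.gene: r for r in results_b}
    ca = {r.gene: r.status for r in concordance_a}
    cb = {r.gene: r.status for r in concordance_b}
    out: list[MetaGeneResult] = []
    for r in cross:
        g = r.gene
        sa, sb = ca.get(g, "D"), cb.get(g, "D")
        la = float(logfc_a.get(g, np.nan))
        lb = float(logfc_b.get(g, np.nan))
        common = (
            r.p_combined < alpha
            and tuple(r.weights) == (1, 1)
            and sa in ("C", "S")
            and sb in ("C", "S")
        )
        if np.isfinite(la) and np.isfinite(lb) and la != 0 and lb != 0:
            if la > 0 and lb > 0:
                direction = "up"
            elif la < 0 and lb < 0:
                direction = "down"
            else:
                direction = "mixed"
        else:
            direction = "na"
        out.append(
            MetaGeneResult(
                gene=g,
                p_a=amap[g].p_combined,
                p_b=bmap[g].p_combined,
                weights_a=amap[g].weights,
                weights_b=bmap[g].weights,
                p_cross=r.p_combined,
                weights_cross=(int(r.weights[0]), int(r.weights[1])),
                status_a=sa,
                status_b=sb,
                logfc_a=la,
                logfc_b=lb,
                is_common_deg=bool(common),
                direction=direction,
            )
        )
    return out


def meta_results_frame(results: list[MetaGeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "p_a": [r.p_a for r in results],
            "p_b": [r.p_b for r in results],
            "weights_a": ["".join(map(str, r.weights_a)) for r in results],
            "weights_b": ["".join(map(str, r.weights_b)) for r in results],
            "p_cross": [r.p_cross for r in results],
            "weights_cross": ["".join(map(str, r.weights_cross)) for r in results],
            "status_a": [r.status_a for r in results],
            "status_b": [r.status_b for r in results],
            "logfc_a": [r.logfc_a for r in results],
            "logfc_b": [r.logfc_b for r in results],
            "is_common_deg": [r.is_common_deg for r in results],
            "direction": [r.direction for r in results],
        }
    )
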