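"""Over-representation analysis of a DEG list against gene-set collections.

Hypergeometric upper-tail test of the overlap between the DEG list and each
pathway, restricted to a stated background universe (here, the genes shared
across studies). Pathways with at most 5 members inside the background are
excluded; reported rows require overlap >= 3, enrichment ratio >= 1 and
p < 0.05 (raw; a Benjamini-Hochberg column is added for information only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GeneSetCollection, normalize_symbol


@dataclass
class EnrichmentRow:
    pathway: str
    k: int  # DEGs found in the pathway
    m: int  # pathway size within background
    n: int  # DEG list size
    N: int  # background size
    enrichment_ratio: float  # (k/n) / (m/N)
    p: float  # hypergeometric upper tail P(X >= k)
    members: list[str]

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p)) if self.p > 0 else np.inf


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, m successes, n draws)."""
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def enrich(
    deg_genes: set[str],
    background: set[str],
    sets: GeneSetCollection,
    min_overlap: int = 3,
    min_enrichment: float = 1.0,
    p_cutoff: float = 0.05,
    min_pathway_size: int = 6,
) -> list[EnrichmentRow]:
    """Test every pathway and return the filtered rows sorted by p ascending.

    ``deg_genes`` must be a subset of ``background``; pathway membership is
    intersected with the background before sizing or testing.
    """
    deg = {normalize_symbol(g) for g in deg_genes}
    bg = {normalize_symbol(g) for g in background}
    if not bg:
        raise ValueError("background gene universe is empty")
    offenders = sorted(deg - bg)
    if offenders:
        raise ValueError(f"DEG genes outside the background universe: {offenders[:10]}")
    N, n = len(bg), len(deg)
    rows: list[EnrichmentRow] = []
    for name, members in sets:
        in_bg = [g for g in members if g in bg]
        m = len(in_bg)
        if m < min_pathway_size:
            continue
        found = sorted(set(in_bg) & deg)
        k = len(found)
        if k == 0:
            continue
        ratio = (k / n) / (m / N)
        p = hypergeom_upper_tail(k, N, m, n)
        if k >= min_overlap and ratio >= min_enrichment and p < p_cutoff:
            rows.append(
                EnrichmentRow(pathway=name, k=k, m=m, n=n, N=N, enrichment_ratio=ratio, p=p, members=found)
            )
    rows.sort(key=lambda r: (r.p, r.pathway))
    return rows


def report_enrichment(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate rows with -log10(p), 'k/m' formatting and a BH-FDR column."""
    df = pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "genes_found": [f"{r.k}/{r.m}" for r in rows],
            "k": [r.k for r in rows],
            "m": [r.m for r in rows],
            "enrichment_ratio": [r.enrichment_ratio for r in rows],
            "p": [r.p for r in rows],
            "neg_log10_p": [r.neg_log10_p for r in rows],
            "members": [",".join(r.members) for r in rows],
        }
    )
    if len(df):
        p = df["p"].to_numpy(float)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        bh = np.empty_like(p)
        bh[order] = np.clip(adj, 0, 1)
        df["p_bh"] = bh
    else:
        df["p_bh"] = []
    return df
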