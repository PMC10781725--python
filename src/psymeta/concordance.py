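"""Cross-study direction-concordance classification (C / S / D).

Within one database, each gene is classified from the signs of its reported
log-fold-changes: C (concordant) if every study reporting an effect size
agrees in direction; S (conditionally concordant) if the studies significant
at the p cutoff agree (marginal signals are treated as noise); D otherwise.
Zero log-fold-changes carry no direction and are ignored, as are studies
reporting a p-value but no effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import DGETable


@dataclass
class ConcordanceRecord:
    gene: str
    database: str
    status: str  # C | S | D
    n_studies_with_effect_size: int
    n_studies_significant: int
    vacuous: bool = False  # effect size available in <= 1 study


def classify_concordance(
    tables: list[DGETable],
    p_cutoff: float = 0.05,
    database: str = "",
    min_significant: int = 1,
) -> list[ConcordanceRecord]:
    """Classify every gene appearing in any table into C / S / D.

    ``min_significant`` is the number of significant direction-bearing
    studies required for the conditional rule (default 1). Genes with an
    effect size in at most one study are vacuously concordant and flagged.
    """
    if len(tables) < 2:
        raise ValueError("concordance assessment needs >= 2 studies")
    if not 0.0 < p_cutoff < 1.0:
        raise ValueError(f"p_cutoff must lie in (0, 1); got {p_cutoff}")

    per_gene: dict[str, list[tuple[float, float]]] = {}
    for t in tables:
        for gene, logfc, p in t.table[["gene", "logFC", "p"]].itertuples(index=False):
            per_gene.setdefault(gene, []).append((logfc, p))

    records: list[ConcordanceRecord] = []
    for gene in sorted(per_gene):
        entries = per_gene[gene]
        # a zero or missing logFC contributes no direction
        signs = [np.sign(lfc) for lfc, _ in entries if np.isfinite(lfc) and lfc != 0]
        sig_signs = [
            np.sign(lfc)
            for lfc, p in entries
            if np.isfinite(lfc) and lfc != 0 and p < p_cutoff
        ]
        n_eff = len(signs)
        n_sig = len(sig_signs)
        if n_eff <= 1:
            status, vacuous = "C", True
        elif len(set(signs)) == 1:
            status, vacuous = "C", False
        elif n_sig >= min_significant and len(set(sig_signs)) == 1:
            status, vacuous = "S", False
        else:
            status, vacuous = "D", False
        records.append(
            ConcordanceRecord(
                gene=gene,
                database=database,
                status=status,
                n_studies_with_effect_size=n_eff,
                n_studies_significant=n_sig,
                vacuous=vacuous,
            )
        )
    return records


def summarize_concordance(records: list[ConcordanceRecord]) -> pd.DataFrame:
    """Counts and one-decimal percentages per status, summing to the gene total."""
    if not records:
        raise ValueError("no concordance records to summarize")
    counts = {"C": 0, "S": 0, "D": 0}
    for r in records:
        counts[r.status] += 1
    total = len(records)
    return pd.DataFrame(
        {
            "status": list(counts),
            "n_genes": list(counts.values()),
            "percent": [round(100.0 * c / total, 1) for c in counts.values()],
        }
    )


def concordance_frame(records: list[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "database": [r.database for r in records],
            "status": [r.status for r in records],
            "n_studies_with_effect_size": [r.n_studies_with_effect_size for r in records],
            "n_studies_significant": [r.n_studies_significant for r in records],
            "vacuous": [r.vacuous for r in records],
        }
    )
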