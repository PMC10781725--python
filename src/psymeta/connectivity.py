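"""Reversal-signature connectivity scoring against a perturbagen library.

The disease query is the pair of up/down common-DEG sets (genes dysregulated
in the same direction in both databases, by the sign of the pooled
log-fold-change). Each perturbagen's score is the Pearson correlation
between its log-FC vector, restricted to query genes present in the library,
and the signed membership vector (+1 up, -1 down); a Spearman option ranks
both vectors first. Strongly negative scores mark reversal candidates; the
default discordance cutoff is -0.321, inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import normalize_symbol
from .meta import MetaGeneResult

logger = logging.getLogger("psymeta")


@dataclass
class PerturbagenLibrary:
    """Perturbagen x gene log-FC matrix; ids unique, entries finite."""

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate perturbagen ids in library")
        if len(self.values) and not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("perturbagen library contains non-finite entries")
        self.values.columns = self.values.columns.map(normalize_symbol)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ConnectivityRow:
    perturbagen: str
    score: float
    n_matched: int
    discordant: bool


def build_query(meta: list[MetaGeneResult]) -> tuple[set[str], set[str]]:
    """Up/down gene sets from the flagged common DEGs.

    Up = positive pooled logFC in both databases, down = negative in both;
    mixed-direction common DEGs are excluded and logged.
    """
    common = [r for r in meta if r.is_common_deg]
    if not common:
        raise ValueError("no common DEGs to build a query from")
    up = {r.gene for r in common if r.direction == "up"}
    down = {r.gene for r in common if r.direction == "down"}
    mixed = [r.gene for r in common if r.direction not in ("up", "down")]
    if mixed:
        logger.info("build_query: excluded %d mixed/na-direction common DEGs", len(mixed))
    return up, down


def connectivity_scores(
    up: set[str],
    down: set[str],
    lib: PerturbagenLibrary,
    min_matched: int = 10,
    method: str = "pearson",
    cutoff: float = -0.321,
) -> list[ConnectivityRow]:
    """Score every perturbagen against the signed query; sorted ascending.

    Perturbagens matching fewer than ``min_matched`` query genes, or with a
    zero-variance log-FC vector over the matched genes, are skipped with a
    warning. ``discordant`` flags scores <= cutoff (inclusive).
    """
    up = {normalize_symbol(g) for g in up}
    down = {normalize_symbol(g) for g in down}
    overlap_genes = [g for g in lib.values.columns if g in up or g in down]
    direction = np.array([1.0 if g in up else -1.0 for g in overlap_genes])
    rows: list[ConnectivityRow] = []
    for pert_id in lib.values.index:
        vec = lib.values.loc[pert_id, overlap_genes].to_numpy(float)
        n_matched = len(vec)
        if n_matched < min_matched:
            logger.warning("%s: only %d query genes matched (< %d); skipped", pert_id, n_matched, min_matched)
            continue
        if np.std(vec) == 0 or np.std(direction) == 0:
            logger.warning("%s: zero-variance vector; score undefined, skipped", pert_id)
            continue
        if method == "pearson":
            score = float(stats.pearsonr(vec, direction).statistic)
        elif method == "spearman":
            score = float(stats.spearmanr(vec, direction).statistic)
        else:
            raise ValueError(f"unknown scoring method {method!r}")
        rows.append(
            ConnectivityRow(
                perturbagen=str(pert_id),
                score=score,
                n_matched=n_matched,
                discordant=bool(score <= cutoff),
            )
        )
    rows.sort(key=lambda r: (r.score, r.perturbagen))
    return rows


def select_discordant(rows: list[ConnectivityRow], cutoff: float = -0.321) -> list[ConnectivityRow]:
    """Reversal candidates: rows with score <= cutoff, flag refreshed."""
    return [
        ConnectivityRow(r.perturbagen, r.score, r.n_matched, True)
        for r in rows
        if r.score <= cutoff
    ]


def connectivity_frame(rows: list[ConnectivityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "perturbagen": [r.perturbagen for r in rows],
            "score": [r.score for r in rows],
            "n_matched": [r.n_matched for r in rows],
            "discordant": [r.discordant for r in rows],
        }
    )
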