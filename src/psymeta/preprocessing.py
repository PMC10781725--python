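"""Per-study expression preprocessing for case/control intensity matrices.

The fixed order is: log2 decision -> log2 transform -> low-expression filter
-> quantile normalization -> duplicate resolution. The log2 decision uses
the pooled-matrix quantile rule (fire when the 99th percentile exceeds 100,
or the range exceeds 50 with a positive first quartile); the low-expression
filter drops genes negative in strictly more than half of the samples on the
raw scale, except genes on an externally supplied keep-list (genes already
present in the other database's summary tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import normalize_symbol

logger = logging.getLogger("psymeta")


@dataclass
class ExpressionStudy:
    """One study's genes x samples matrix with two-level group labels.

    ``values`` is indexed by gene symbol with sample ids as columns;
    ``groups`` maps each sample id to 'case' or 'control'. ``transform``
    tracks the processing state (raw | log2 | normalized).
    """

    study_id: str
    values: pd.DataFrame
    groups: pd.Series
    transform: str = "raw"
    raw_values: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError(f"{self.study_id}: duplicate sample ids")
        if set(self.groups.index) != set(self.values.columns):
            raise ValueError(f"{self.study_id}: group labels do not match sample ids")
        levels = set(self.groups.unique())
        if levels != {"case", "control"}:
            raise ValueError(f"{self.study_id}: group labels must be exactly case/control, got {levels}")
        self.values.index = self.values.index.map(normalize_symbol)

    @property
    def case_columns(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    @property
    def control_columns(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "control"]


def needs_log2(study: ExpressionStudy) -> bool:
    """Decide whether a raw intensity matrix should be log2-transformed.

    True iff the pooled 99th percentile exceeds 100, or the pooled range
    exceeds 50 with a strictly positive pooled first quartile.
    """
    x = study.values.to_numpy(float).ravel()
    if x.size == 0:
        raise ValueError(f"{study.study_id}: empty matrix")
    q99 = np.quantile(x, 0.99)
    q1 = np.quantile(x, 0.25)
    rng = x.max() - x.min()
    return bool(q99 > 100 or (rng > 50 and q1 > 0))


def log2_transform(study: ExpressionStudy) -> ExpressionStudy:
    """log2(x + offset); clean positive matrices get offset 0.

    When the matrix contains values <= 0 the offset shifts the minimum to 1
    (offset = 1 - min), so no entry maps to -inf or NaN; background-dominated
    rows are still removed later by the raw-scale negativity filter.
    """
    x = study.values.to_numpy(float)
    offset = 1.0 - x.min() if (x <= 0).any() else 0.0
    out = pd.DataFrame(np.log2(x + offset), index=study.values.index, columns=study.values.columns)
    return replace(study, values=out, transform="log2",
                   raw_values=study.raw_values if study.raw_values is not None else study.values)


def filter_low_expression(
    study: ExpressionStudy, keep_genes: set[str] | None = None
) -> tuple[ExpressionStudy, list[str]]:
    """Drop genes with raw-scale negative values in strictly more than half the samples.

    The negativity test always uses the pre-transformation matrix. Genes in
    ``keep_genes`` are retained regardless (they are needed downstream for
    cross-database matching). Returns the filtered study and the dropped list.
    """
    keep = {normalize_symbol(g) for g in (keep_genes or set())}
    raw = study.raw_values if study.raw_values is not None else study.values
    n_samples = raw.shape[1]
    n_negative = (raw.to_numpy(float) < 0).sum(axis=1)
    drop_mask = n_negative > n_samples / 2
    dropped = [g for g, d in zip(raw.index, drop_mask) if d and g not in keep]
    filtered = study.values.drop(index=[g for g in dropped if g in study.values.index])
    return replace(study, values=filtered), dropped


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample onto the common distribution of across-sample mean quantiles.

    After normalization every column's sorted vector equals the mean of the
    per-sample sorted vectors; rank ties within a sample receive the average
    of the corresponding reference values.
    """
    x = study.values.to_numpy(float)
    if x.shape[1] < 2:
        logger.warning("%s: single-sample matrix; quantile normalization is a no-op", study.study_id)
        return replace(study, transform="normalized")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values over tied input values
        s = pd.Series(col)
        if s.duplicated().any():
            ranked = pd.Series(ranked).groupby(col).transform("mean").to_numpy()
        out[:, j] = ranked
    values = pd.DataFrame(out, index=study.values.index, columns=study.values.columns)
    return replace(study, values=values, transform="normalized")


def resolve_duplicates(study: ExpressionStudy) -> ExpressionStudy:
    """For each duplicated gene symbol keep the row with the greatest across-sample variance.

    Exact variance ties are broken by first occurrence, deterministically.
    """
    values = study.values
    if not values.index.duplicated().any():
        return study
    variances = values.var(axis=1, ddof=1).to_numpy()
    keep_rows: list[int] = []
    best_for_gene: dict[str, int] = {}
    for i, g in enumerate(values.index):
        if g not in best_for_gene:
            best_for_gene[g] = i
            keep_rows.append(i)
        elif variances[i] > variances[best_for_gene[g]]:
            keep_rows.remove(best_for_gene[g])
            best_for_gene[g] = i
            keep_rows.append(i)
    keep_rows.sort()
    out = values.iloc[keep_rows]
    raw = study.raw_values.iloc[keep_rows] if study.raw_values is not None and len(study.raw_values) == len(values) else study.raw_values
    return replace(study, values=out, raw_values=raw)


def preprocess_study(
    study: ExpressionStudy, keep_genes: set[str] | None = None
) -> tuple[ExpressionStudy, list[str]]:
    """Run the full fixed-order preprocessing pipeline on a raw study."""
    dropped: list[str] = []
    if study.transform == "raw":
        if needs_log2(study):
            study = log2_transform(study)
        study, dropped = filter_low_expression(study, keep_genes)
        study = quantile_normalize(study)
        study = resolve_duplicates(study)
    elif study.transform == "log2":
        study, dropped = filter_low_expression(study, keep_genes)
        study = quantile_normalize(study)
        study = resolve_duplicates(study)
    return study, dropped
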