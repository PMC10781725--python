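"""Readers, writers, run configuration and seed management.

All on-disk tables are tab-separated UTF-8 with ``#``-prefixed metadata
header lines (``# key=value``), so outputs are greppable and diff-able and
every file records the configuration hash and RNG seed that produced it.
Floating-point columns are serialized at fixed precision so repeated runs
with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("psymeta")

FLOAT_FORMAT = "%.10g"

_GENE_ALIASES = {"gene", "symbol", "gene_symbol", "genesymbol", "gene.symbol"}
_LOGFC_ALIASES = {"logfc", "log_fc", "lfc", "log2fc", "log2foldchange", "logfoldchange"}
_P_ALIASES = {"p", "pvalue", "p_value", "pval", "p.value"}


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when file contents violate a domain constraint (e.g. p outside [0,1])."""


@dataclass
class PipelineConfig:
    """Run-level configuration: thresholds, paths and the master seed.

    Parameters mirror the analysis defaults: per-stage significance at 0.05,
    conditional-concordance p cutoff 0.05, over-representation filters
    (overlap >= 3, enrichment ratio >= 1, p < 0.05, pathway size >= 6 within
    the background) and the connectivity reversal cutoff of -0.321.
    """

    studies_a: list[str] = field(default_factory=list)
    studies_b: list[str] = field(default_factory=list)
    alpha_meta: float = 0.05
    concordance_p_cutoff: float = 0.05
    min_overlap: int = 3
    min_enrichment: float = 1.0
    enrichment_p_cutoff: float = 0.05
    min_pathway_size: int = 6
    connectivity_cutoff: float = -0.321
    rng_seed: int = 0
    monte_carlo_B: int = 10_000

    def __post_init__(self) -> None:
        for name in ("alpha_meta", "concordance_p_cutoff", "enrichment_p_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1); got {v}")
        if self.monte_carlo_B < 100:
            raise ValidationError(
                f"monte_carlo_B must be >= 100 for a usable null table; got {self.monte_carlo_B}"
            )
        self.rng_seed = int(self.rng_seed)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with optional descriptions.

    Set names are unique, member lists de-duplicated preserving order, and
    no set is empty.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def normalize_symbol(symbol: str) -> str:
    """Canonical gene identifier: upper-cased, whitespace-trimmed symbol."""
    return str(symbol).strip().upper()


def spawn_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic child RNG for (seed, *keys).

    Each (purpose, study, ...) key tuple gets an independent stream, so adding
    studies or stages never shifts the random numbers of earlier ones.
    """
    digest = hashlib.sha256(repr(tuple(keys)).encode()).digest()
    spawn_key = tuple(int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed), spawn_key=spawn_key)))


def _match_column(columns: Sequence[str], aliases: set[str]) -> str | None:
    for c in columns:
        if str(c).strip().lower() in aliases:
            return c
    return None


def read_dge_table(
    path: str | Path,
    study_id: str | None = None,
    reporting: str = "full",
    threshold: float | None = None,
):
    """Read a per-study differential-expression summary table.

    The file is tab-separated with a header naming gene / logFC / p columns
    (common aliases accepted, case-insensitive); the logFC column may be
    absent, in which case every record carries a missing effect size.
    Truncated ("partial") tables should declare their reporting threshold;
    if ``reporting='partial'`` and no threshold is given, the maximum
    reported p-value is used as a fallback and logged.
    """
    from .dge import DGETable  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    gene_col = _match_column(df.columns, _GENE_ALIASES)
    p_col = _match_column(df.columns, _P_ALIASES)
    if gene_col is None or p_col is None:
        raise FormatError(
            f"{path}: need gene and p columns; found {list(df.columns)}"
        )
    logfc_col = _match_column(df.columns, _LOGFC_ALIASES)

    genes = df[gene_col].map(normalize_symbol)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise FormatError(
            f"{path}: duplicate gene symbols ({sorted(set(dup))[:5]}...); "
            "resolve duplicates upstream (preprocessing.resolve_duplicates)"
        )
    p = pd.to_numeric(df[p_col], errors="coerce")
    bad = df.index[(p < 0) | (p > 1) | p.isna()]
    if len(bad):
        row = int(bad[0])
        raise ValidationError(
            f"{path}: p-value outside [0, 1] at row {row} (gene {genes.iloc[row]!r}, p={df[p_col].iloc[row]!r})"
        )

    out = pd.DataFrame({"gene": genes.to_numpy(), "p": p.to_numpy(float)})
    if logfc_col is not None:
        out["logFC"] = pd.to_numeric(df[logfc_col], errors="coerce").to_numpy(float)
    else:
        out["logFC"] = np.nan
    out = out[["gene", "logFC", "p"]]

    if reporting == "partial" and threshold is None:
        threshold = float(out["p"].max())
        logger.warning("%s: partial table without declared threshold; using max reported p = %g", path, threshold)
    return DGETable(
        study_id=study_id or path.stem,
        table=out,
        reporting=reporting,
        threshold=threshold,
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``name TAB description TAB gene...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = normalize_symbol(g)
                if g and g not in seen:
                    seen.add(g)
                    members.append(g)
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        logger.warning("%s: empty GMT file", path)
        return GeneSetCollection(sets={}, descriptions={})
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a results table with ``# key=value`` metadata header lines.

    Column order is taken from the frame as given; floats use a fixed format
    so identical runs produce byte-identical files.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a table written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_results(results, path: str | Path, config: PipelineConfig | None = None) -> None:
    """Write any stage's result rows (a DataFrame or list of dataclass rows).

    The header records the config hash and seed so every artifact is
    traceable to the run that produced it.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = list(results)
        df = pd.DataFrame([asdict(r) if hasattr(r, "__dataclass_fields__") else r for r in rows])
    meta: dict[str, object] = {}
    if config is not None:
        meta["config_hash"] = config.config_hash()
        meta["seed"] = config.rng_seed
    write_table(df, path, meta=meta)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
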