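"""Synthetic two-database multi-study expression data with planted DEGs.

Emulates the structure the meta-analysis assumes: two "databases" of
case/control studies sharing a gene universe, a planted set of genes
differentially expressed in BOTH databases with a common direction, extra
database-private DEGs, per-study baseline offsets (between-study
heterogeneity), studies that report only their significant genes (truncated
tables), and studies that report p-values without log-fold-changes.
Expression is Gaussian on the log2 scale, matching the normalized-intensity
inputs the pipeline consumes. Seeding is stream-split: every (database,
study, purpose) gets its own child stream, so adding studies never shifts
earlier studies' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PerturbagenLibrary
from .dge import DGETable, moderated_t_dge, truncate_table, blank_logfc
from .io_core import spawn_rng
from .preprocessing import ExpressionStudy


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic scenario.

    Defaults give two databases of 3 studies each over 5,000 genes with 200
    shared planted DEGs of mean |logFC| 1.0 (log2 units) against unit residual
    noise at 20 samples per arm, one truncated study per database reporting
    only p <= 0.05, and no logFC-free studies unless asked for.
    """

    n_genes: int = 5_000
    n_studies_a: int = 3
    n_studies_b: int = 3
    samples_per_arm: int = 20
    n_shared_deg: int = 200
    n_private_deg_a: int = 50
    n_private_deg_b: int = 50
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_study_sd: float = 0.5
    partial_fraction: float = 1.0 / 3.0
    partial_threshold: float = 0.05
    logfc_missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_deg + max(self.n_private_deg_a, self.n_private_deg_b) > self.n_genes:
            raise ValueError("planted DEGs exceed the gene universe")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        for name in ("partial_fraction", "logfc_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.samples_per_arm < 3:
            raise ValueError("need >= 3 samples per arm for downstream variance estimation")


@dataclass
class GroundTruth:
    """Per-gene planted truth: mutually exclusive flags and true signs.

    Shared DEGs carry the same sign in both databases; private DEGs have a
    sign only in their own database (0 elsewhere); null genes have sign 0.
    """

    genes: list[str]
    shared_deg: np.ndarray  # bool
    private_deg_a: np.ndarray  # bool
    private_deg_b: np.ndarray  # bool
    sign_a: np.ndarray  # -1/0/+1
    sign_b: np.ndarray

    def __post_init__(self) -> None:
        overlap = (
            self.shared_deg.astype(int) + self.private_deg_a.astype(int) + self.private_deg_b.astype(int)
        )
        if (overlap > 1).any():
            raise ValueError("planted flags must be mutually exclusive")
        if (self.sign_a[self.shared_deg] != self.sign_b[self.shared_deg]).any():
            raise ValueError("shared DEGs must share their true sign across databases")

    @property
    def shared_genes(self) -> list[str]:
        return [g for g, f in zip(self.genes, self.shared_deg) if f]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Assign shared / private / null roles and true signs, deterministically."""
    rng = spawn_rng(cfg.seed, "truth")
    genes = _gene_names(cfg.n_genes)
    order = rng.permutation(cfg.n_genes)
    n_s, n_a, n_b = cfg.n_shared_deg, cfg.n_private_deg_a, cfg.n_private_deg_b
    shared = np.zeros(cfg.n_genes, dtype=bool)
    priv_a = np.zeros(cfg.n_genes, dtype=bool)
    priv_b = np.zeros(cfg.n_genes, dtype=bool)
    shared[order[:n_s]] = True
    priv_a[order[n_s : n_s + n_a]] = True
    priv_b[order[n_s + n_a : n_s + n_a + n_b]] = True
    sign_shared = rng.choice([-1, 1], size=cfg.n_genes)
    sign_a = np.where(shared | priv_a, sign_shared, 0)
    sign_b = np.where(shared, sign_shared, 0)
    sign_b = np.where(priv_b, rng.choice([-1, 1], size=cfg.n_genes), sign_b)
    return GroundTruth(
        genes=genes,
        shared_deg=shared,
        private_deg_a=priv_a,
        private_deg_b=priv_b,
        sign_a=sign_a,
        sign_b=sign_b,
    )


def generate_expression_study(
    cfg: SimulationConfig,
    database: str,
    study_index: int,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """One genes x samples case/control matrix with planted shifts.

    Null genes are Normal(baseline, noise_sd) in both arms; planted DEGs are
    shifted by sign * effect_size in cases. Each study draws its own gene
    baseline offsets once, creating between-study mean heterogeneity.
    """
    if database not in ("A", "B"):
        raise ValueError("database must be 'A' or 'B'")
    n_studies = cfg.n_studies_a if database == "A" else cfg.n_studies_b
    if not 0 <= study_index < n_studies:
        raise ValueError(f"study_index {study_index} out of range for database {database}")
    if truth is None:
        truth = make_ground_truth(cfg)
    rng = spawn_rng(cfg.seed, "expr", database, study_index)
    n, m = cfg.n_genes, cfg.samples_per_arm
    baseline = cfg.baseline_mean + rng.normal(0.0, cfg.baseline_study_sd, size=n)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, 2 * m))
    x = baseline[:, None] + noise
    sign = truth.sign_a if database == "A" else truth.sign_b
    x[:, :m] += (sign * cfg.effect_size)[:, None]  # cases first
    samples = [f"{database}{study_index}_case{i}" for i in range(m)] + [
        f"{database}{study_index}_ctrl{i}" for i in range(m)
    ]
    groups = pd.Series(["case"] * m + ["control"] * m, index=samples)
    study = ExpressionStudy(
        study_id=f"{database}{study_index}",
        values=pd.DataFrame(x, index=truth.genes, columns=samples),
        groups=groups,
        transform="normalized",
    )
    return study, truth


def generate_dge_tables(
    cfg: SimulationConfig,
) -> tuple[dict[str, list[DGETable]], GroundTruth]:
    """Per-database DGE tables via the real DGE stage, with reporting quirks.

    The first ceil(partial_fraction * n_studies) studies of each database are
    truncated at ``partial_threshold``; the next ceil(logfc_missing_fraction *
    n_studies) emit p-values only. Deterministic given the config seed.
    """
    truth = make_ground_truth(cfg)
    tables: dict[str, list[DGETable]] = {"A": [], "B": []}
    for database, n_studies in (("A", cfg.n_studies_a), ("B", cfg.n_studies_b)):
        n_partial = int(np.ceil(cfg.partial_fraction * n_studies))
        n_nolfc = int(np.ceil(cfg.logfc_missing_fraction * n_studies))
        for idx in range(n_studies):
            study, _ = generate_expression_study(cfg, database, idx, truth)
            table = moderated_t_dge(study)
            if idx < n_partial:
                table = truncate_table(table, cfg.partial_threshold)
            elif idx < n_partial + n_nolfc:
                table = blank_logfc(table)
            tables[database].append(table)
    return tables, truth


def generate_gene_sets(
    truth: GroundTruth,
    n_random_sets: int = 20,
    set_size: int = 25,
    seed: int = 0,
    include_planted_set: bool = True,
):
    """Gene-set fixture: random sets from the universe plus one set enriched
    in the planted shared DEGs (for positive-control enrichment tests)."""
    from .io_core import GeneSetCollection

    rng = spawn_rng(seed, "gene_sets")
    genes = np.array(truth.genes)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    if include_planted_set:
        shared = truth.shared_genes
        take = min(set_size, len(shared))
        members = list(rng.choice(shared, size=take, replace=False))
        pad = set_size - take
        if pad > 0:
            members += list(rng.choice(genes, size=pad, replace=False))
        sets["PLANTED_PATHWAY"] = sorted(set(members))
        descriptions["PLANTED_PATHWAY"] = "enriched in planted shared DEGs"
    for i in range(n_random_sets):
        name = f"RANDOM_SET_{i:03d}"
        sets[name] = sorted(set(rng.choice(genes, size=set_size, replace=False)))
        descriptions[name] = "uniform random members"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def generate_perturbagen_library(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_perturbagens: int = 100,
    include_reverser: bool = True,
    reverser_noise_sd: float = 0.05,
) -> PerturbagenLibrary:
    """Random perturbagen log-FC vectors over the gene universe.

    When ``include_reverser`` is set, the first perturbagen ("REVERSER") is
    the negated true shared-DEG signature plus small noise — a planted
    reversal candidate the connectivity stage must rank first.
    """
    rng = spawn_rng(cfg.seed, "perturbagens")
    genes = list(truth.genes)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    if include_reverser:
        signature = truth.sign_a * cfg.effect_size * truth.shared_deg
        rows.append(-signature + rng.normal(0.0, reverser_noise_sd, size=len(genes)))
        ids.append("REVERSER")
    for i in range(n_perturbagens - int(include_reverser)):
        rows.append(rng.normal(0.0, cfg.effect_size, size=len(genes)))
        ids.append(f"PERT_{i:04d}")
    values = (
        pd.DataFrame(np.array(rows), index=ids, columns=genes)
        if rows
        else pd.DataFrame(np.empty((0, len(genes))), index=pd.Index([], dtype=object), columns=genes)
    )
    return PerturbagenLibrary(values=values)
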