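import numpy as np
import pandas as pd
import pytest

from psymeta import ExpressionStudy, SimulationConfig, generate_dge_tables


def make_study(values, study_id="S1", n_case=None):
    """Wrap a genes x samples array into an ExpressionStudy (first half cases)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    n_case = n_case if n_case is not None else n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (n_samples - n_case), index=samples
    )
    genes = [f"G{i}" for i in range(n_genes)]
    return ExpressionStudy(
        study_id=study_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
        transform="normalized",
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A small two-database scenario with planted shared/private DEGs."""
    cfg = SimulationConfig(
        n_genes=600,
        n_shared_deg=40,
        n_private_deg_a=15,
        n_private_deg_b=15,
        samples_per_arm=10,
        effect_size=1.5,
        seed=7,
    )
    tables, truth = generate_dge_tables(cfg)
    return cfg, tables, truth
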