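import warnings

import numpy as np
import pandas as pd
import pytest

from truthbench.io import ExpressionMatrix, SampleSheet
from truthbench.simulate import SimulationConfig, simulate_panel

SIX_GROUPS = ["M8", "F7", "D5", "D6", "T1", "T2"]


def make_group_matrix(
    rng,
    n_genes=300,
    groups=SIX_GROUPS,
    replicates=3,
    group_sd=0.5,
    noise_sd=0.2,
    lab="lab01",
):
    """Log2 matrix with per-gene group means ~ N(0, group_sd) and replicate
    noise; returns (ExpressionMatrix, SampleSheet)."""
    gm = rng.normal(0.0, group_sd, (n_genes, len(groups)))
    cols, names, rows = [], [], []
    for gi, stype in enumerate(groups):
        for r in range(1, replicates + 1):
            cols.append(gm[:, gi] + rng.normal(0.0, noise_sd, n_genes))
            name = f"{lab}_{stype}_r{r}"
            names.append(name)
            rows.append(
                {"library_id": name, "lab_id": lab, "sample_type": stype, "replicate": r}
            )
    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.array(cols).T, index=[f"g{i:04d}" for i in range(n_genes)], columns=names
        ),
        "log2fpkm",
    )
    return matrix, SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_panel():
    """A 2-lab, 400-gene simulated panel shared by read-only tests."""
    cfg = SimulationConfig(n_genes=400, n_labs=2, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        counts, fpkm, sheet, truth = simulate_panel(cfg)
    return cfg, counts, fpkm, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
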