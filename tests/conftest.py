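import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import uvkinet as uk

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_design(replicates: int = 3, control_week8: bool = True) -> uk.SampleDesign:
    rows = []
    weeks_ctrl = (1, 8) if control_week8 else (1,)
    for w in weeks_ctrl:
        for r in range(1, replicates + 1):
            rows.append((f"ctrl_w{w}_r{r}", "control", w, r))
    for w in (1, 2, 4, 6, 8):
        for r in range(1, replicates + 1):
            rows.append((f"uv_w{w}_r{r}", "uv", w, r))
    return uk.SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "group", "week", "replicate"])
    )


def make_matrix(gene_values: dict[str, dict], design=None) -> uk.ExpressionMatrix:
    """Build a matrix from {gene: {(group, week): [replicate values]}};
    missing cells default to 100 with a tiny fixed jitter."""
    design = design or make_design()
    data = {}
    for gene, cells in gene_values.items():
        row = {}
        for _, s in design.table.iterrows():
            key = (s["group"], s["week"])
            vals = cells.get(key, [99.0, 100.0, 101.0])
            row[s["sample_id"]] = vals[s["replicate"] - 1]
        data[gene] = row
    df = pd.DataFrame(data).T
    return uk.ExpressionMatrix(df[design.sample_ids], design)


@pytest.fixture(scope="session")
def design3():
    return make_design()


@pytest.fixture(scope="session")
def planted_instance():
    """One default synthetic study (seed 7, no drift genes) taken through
    the DEG cascade and the down-gene co-expression network; shared by the
    recovery tests."""
    spec = uk.SyntheticSpec(n_drift=0, rng_seed=7)
    matrix, design, truth = uk.generate(spec)
    deg = uk.run_deg_pipeline(matrix)
    network = uk.correlation_network(deg.profiles("down"))
    return spec, matrix, truth, deg, network


@pytest.fixture(scope="session")
def zero_noise_network():
    """Noiseless planted module: within-module correlations are exactly 1."""
    spec = uk.SyntheticSpec(n_background=100, n_module_true_neighbors=20,
                            n_drift=0, module_noise_sd_log2=0.0, rng_seed=3)
    matrix, design, truth = uk.generate(spec)
    deg = uk.run_deg_pipeline(matrix)
    network = uk.correlation_network(deg.profiles("down"))
    return spec, truth, network
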