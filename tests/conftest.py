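import numpy as np
import pandas as pd
import pytest

from stagespec import (ExpressionMatrix, SampleMetadata, SyntheticConfig,
                       generate_timecourse)


@pytest.fixture
def tiny_expr():
    """5 genes x 4 samples, two time points x two groups, distinct values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(6, 1, size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=["C_1h_r1", "C_6h_r1", "KA_1h_r1", "KA_6h_r1"],
    )
    return ExpressionMatrix(values=values, scale="log2")


@pytest.fixture
def tiny_meta():
    table = pd.DataFrame(
        {
            "sample_id": ["C_1h_r1", "C_6h_r1", "KA_1h_r1", "KA_6h_r1"],
            "group": ["control", "control", "case", "case"],
            "time_h": [1.0, 6.0, 1.0, 6.0],
            "replicate": [1, 1, 1, 1],
        }
    ).set_index("sample_id")
    return SampleMetadata(table=table)


@pytest.fixture(scope="session")
def recovery_bundle():
    """The default planted-recovery study: 2000 genes, 10 up + 10 down per
    stage, log2 FC 3, noise sd 0.3, 3 replicates, fixed seed."""
    cfg = SyntheticConfig(
        n_genes=2000,
        n_specific_per_stage=10,
        specific_log2_fc=3.0,
        noise_log2_sd=0.3,
        replicates=3,
        seed=42,
    )
    return generate_timecourse(cfg)


def make_meta(time_points, replicates, groups=("control", "case")):
    rows = []
    for grp, tag in zip(groups, ("C", "KA")):
        for t in time_points:
            for r in range(1, replicates + 1):
                rows.append({"sample_id": f"{tag}_{t:g}h_r{r}", "group": grp,
                             "time_h": float(t), "replicate": r})
    return SampleMetadata(table=pd.DataFrame(rows).set_index("sample_id"))
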