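import numpy as np
import pandas as pd
import pytest

from respmr.response import ExpressionMatrix
from respmr.simulate import (SimulationConfig, simulate_expression_study,
                             simulate_reference_panel)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=120, n_snps=360, n_response_genes=40, n_diff_response_genes=15,
        n_panel=300, n_eqtl_samples=200, n_cases=200, n_controls=200,
        eqtl_effect_sd=0.4, mediation_effect=0.3, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_reference_panel(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_panel):
    return simulate_expression_study(small_config, small_panel)


def toy_expression(values_by_sample, groups=None, detection_p=None):
    """Build an ExpressionMatrix from {(ind, cond, rep): vector-per-gene}."""
    cols, data, meta = [], [], []
    groups = groups or {}
    for (ind, cond, rep), vec in values_by_sample.items():
        name = f"{ind}_{cond}_r{rep}"
        cols.append(name)
        data.append(np.asarray(vec, dtype=float))
        meta.append((name, ind, rep, cond, groups.get(ind, "nDM")))
    genes = [f"g{i}" for i in range(len(data[0]))]
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    samples = pd.DataFrame(meta, columns=["sample", "individual", "replicate",
                                          "condition", "group"]).set_index("sample")
    det = None
    if detection_p is not None:
        det = pd.DataFrame(detection_p, index=genes, columns=cols)
    return ExpressionMatrix(values=values, samples=samples, detection_p=det)
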