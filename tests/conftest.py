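import numpy as np
import pandas as pd
import pytest

from promtarget import (
    SimulationConfig,
    generate_array_design,
    generate_chip_signal,
    generate_expression,
    sample_truth,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=0, n_seq_ids=60)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One shared synthetic dataset: design, annotation, truth, signal, expression."""
    design, annotation = generate_array_design(small_config)
    truth = sample_truth(design, annotation, small_config)
    signal = generate_chip_signal(design, truth, small_config)
    matrix = generate_expression(annotation, truth, small_config)
    return {
        "config": small_config,
        "design": design,
        "annotation": annotation,
        "truth": truth,
        "signal": signal,
        "matrix": matrix,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_expression_matrix(wt_rows, ko_rows, probe_sets, genes):
    """Small ExpressionMatrix from per-probe-set WT and KO value lists."""
    from promtarget import ExpressionMatrix

    wt = np.atleast_2d(np.asarray(wt_rows, float))
    ko = np.atleast_2d(np.asarray(ko_rows, float))
    samples = [f"WT{i+1}" for i in range(wt.shape[1])] + [
        f"KO{i+1}" for i in range(ko.shape[1])
    ]
    values = pd.DataFrame(
        np.hstack([wt, ko]), index=pd.Index(probe_sets, name="probe_set"),
        columns=samples,
    )
    groups = pd.Series(
        ["WT"] * wt.shape[1] + ["KO"] * ko.shape[1], index=samples
    )
    probe_map = pd.Series(dict(zip(probe_sets, genes)))
    return ExpressionMatrix(values, groups, probe_map)
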