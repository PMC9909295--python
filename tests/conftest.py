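from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from toleromics import (
    CountMatrix,
    SimulationSpec,
    Stimulus,
    classify_sequence,
    compute_rpm,
    filter_genes,
    generate_counts,
)
from toleromics.design import Condition, Timepoint

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def toy_count_matrix(values: np.ndarray, experiment_id: str = "exp1") -> CountMatrix:
    """Wrap a genes x 18 array into a CountMatrix over the full design."""
    conds = [
        Condition(a1, a2, t)
        for a1 in Stimulus
        for a2 in Stimulus
        for t in Timepoint
    ]
    if values.shape[1] != len(conds):
        raise ValueError("need one column per condition (18)")
    libs = [f"{experiment_id}_{c.label}" for c in conds]
    counts = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(values.shape[0])],
        columns=libs,
    )
    return CountMatrix(
        counts=counts,
        conditions=dict(zip(libs, conds)),
        experiment_id=experiment_id,
    )


@pytest.fixture(scope="session")
def default_simulation():
    """One default-condition simulated study, shared across the session."""
    spec = SimulationSpec(seed=20240521)
    cm1, cm2, truth = generate_counts(spec)
    return spec, cm1, cm2, truth


@pytest.fixture(scope="session")
def classified_simulation(default_simulation):
    """Both experiments classified for the homologous LPS sequence."""
    _, cm1, cm2, truth = default_simulation
    keep = filter_genes([cm1, cm2])
    rpm1, rpm2 = compute_rpm(cm1), compute_rpm(cm2)
    tab1 = classify_sequence(rpm1, Stimulus.L, Stimulus.L, genes=keep)
    tab2 = classify_sequence(rpm2, Stimulus.L, Stimulus.L, genes=keep)
    return rpm1, rpm2, tab1, tab2, truth
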