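import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mlcnet.cohort import CohortTable, VariableMeta
from mlcnet.network import MultiLevelNetwork
from mlcnet.simulate import default_study_spec, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped synthetic cohort (60 subjects, 47 variables), seed 1."""
    cohort, truth = generate_cohort(default_study_spec(1))
    return cohort, truth


@pytest.fixture
def tiny_cohort():
    """Handmade 6-subject, 4-variable cohort with one missing cell."""
    data = pd.DataFrame(
        {
            "FEV1": [95.0, 88.0, 70.0, 64.0, 55.0, 102.0],
            "Eos": [120.0, 300.0, 450.0, np.nan, 600.0, 100.0],
            "CD34": [1.2, 1.9, 1.4, 2.4, 2.0, 1.1],
            "CRP": [0.4, 1.2, 5.0, 7.5, 3.3, 0.2],
        },
        index=pd.Index([f"S{i}" for i in range(1, 7)], name="subject_id"),
    )
    groups = pd.Series(
        ["control", "control", "copd", "copd", "copd", "control"],
        index=data.index, name="group",
    )
    meta = [
        VariableMeta("FEV1", "lung_function", "continuous", "% ref"),
        VariableMeta("Eos", "blood", "count", "cells/uL"),
        VariableMeta("CD34", "bone_marrow", "continuous", "%"),
        VariableMeta("CRP", "blood", "continuous", "mg/dl"),
    ]
    return CohortTable(data, groups, meta)


def make_network(edges, nodes=None, levels=None, p_threshold=0.01):
    """Assemble a MultiLevelNetwork directly from an edge list (test helper)."""
    g = nx.Graph(p_threshold=p_threshold)
    nodes = list(nodes) if nodes is not None else sorted(
        {n for e in edges for n in e[:2]}
    )
    levels = levels or {}
    for n in nodes:
        g.add_node(n, level=levels.get(n, "blood"))
    for e in edges:
        a, b = e[0], e[1]
        rho = e[2] if len(e) > 2 else 0.8
        g.add_edge(a, b, rho=rho, weight=abs(rho), p=0.001, n=30,
                   sign="pos" if rho >= 0 else "neg")
    return MultiLevelNetwork(graph=g, p_threshold=p_threshold)
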