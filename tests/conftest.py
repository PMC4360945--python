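import numpy as np
import pandas as pd
import pytest

from screenfunnel import CriterionSpec, MolecularGraph, Pose, ScoreTable


@pytest.fixture
def ethanol_graph():
    # heavy atoms only: C-C-O
    return MolecularGraph(("C", "C", "O"), ((0, 1, 1), (1, 2, 1)))


@pytest.fixture
def ethanol_pose(ethanol_graph):
    coords = np.array([[0.0, 0.0, 0.0], [1.54, 0.0, 0.0], [2.31, 1.2, 0.0]])
    return Pose(ethanol_graph, coords)


@pytest.fixture
def hexagon_pose():
    g = MolecularGraph(
        ("C",) * 6,
        ((0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (0, 5, 1)),
    )
    r = 1.4
    coords = r * np.array(
        [[np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0.0] for k in range(6)]
    )
    return Pose(g, coords)


def make_table(data: dict[str, dict[str, float]], directions: dict[str, str]) -> ScoreTable:
    """data: criterion -> {compound: value}."""
    specs = tuple(CriterionSpec(name, directions[name]) for name in data)
    df = pd.DataFrame(data, dtype=float)
    df.index.name = "id"
    return ScoreTable(df, specs)


@pytest.fixture
def lower_table():
    return make_table(
        {"glide": {"A": -9.1, "B": -7.2, "C": -8.5}},
        {"glide": "lower_better"},
    )
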