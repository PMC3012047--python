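import pandas as pd
import pytest
from hypothesis import settings

from netcondense import (InteractionType, MeasurementTable, TypedEdge,
                         TypedNetwork)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def edge(src: str, tgt: str, kind: str, eid: str) -> TypedEdge:
    return TypedEdge(src, tgt, InteractionType(kind), eid)


def table_of(rows: dict[str, tuple[float, float]]) -> MeasurementTable:
    frame = pd.DataFrame(
        {"m_e1": {k: v[0] for k, v in rows.items()},
         "m_e2": {k: v[1] for k, v in rows.items()}})
    frame.index.name = "id"
    return MeasurementTable(frame)


@pytest.fixture
def toy_network() -> TypedNetwork:
    """Five nodes, one edge of each type plus a duplicate and a self-loop."""
    edges = [
        edge("A", "B", "interaction", "e1"),
        edge("B", "C", "stimulation", "e2"),
        edge("C", "D", "inhibition", "e3"),
        edge("A", "B", "interaction", "e4"),  # duplicate, distinct id
        edge("E", "E", "stimulation", "e5"),  # self-loop
    ]
    return TypedNetwork(nodes={"A", "B", "C", "D", "E"}, edges=edges)


@pytest.fixture
def toy_table() -> MeasurementTable:
    return table_of({"A": (1.0, 2.0), "B": (3.0, 5.0), "C": (2.0, 1.0),
                     "D": (1.0, 3.0), "E": (4.0, 4.5)})
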