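import numpy as np
import pytest

from neuroadaptive.task_space import TaskPoint, TaskProbabilityTable, TaskSpace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_table():
    return TaskProbabilityTable(
        rows={
            "alpha": (0.1, 0.9, 0.3, 0.6),
            "bravo": (0.5, 0.5, 0.2, 0.8),
            "charlie": (0.9, 0.1, 0.7, 0.4),
            "delta": (0.3, 0.3, 0.5, 0.5),
        },
        component_names=("comp05", "comp06", "comp08", "comp09"),
    )


@pytest.fixture(scope="session")
def square_space():
    """Four tasks at the corners of the unit square."""
    return TaskSpace(
        name="square",
        dim=2,
        candidates=(
            TaskPoint("a", (0.0, 0.0)),
            TaskPoint("b", (1.0, 0.0)),
            TaskPoint("c", (0.0, 1.0)),
            TaskPoint("d", (1.0, 1.0)),
        ),
        bounds=((0.0, 1.0), (0.0, 1.0)),
        grid_resolution=5,
    )


@pytest.fixture(scope="session")
def exp1_bundle():
    from neuroadaptive.fixtures import fixture_bundle

    return fixture_bundle("exp1_like")
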