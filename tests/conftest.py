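import numpy as np
import pytest

from cosmarker import ExpressionMatrix, SimConfig, simulate_dataset


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples, K=2, hand-checkable numbers."""
    return ExpressionMatrix(
        features=["gA", "gB", "gC"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [2.0, 4.0, 6.0, 6.0],
                [1.0, 1.0, 0.0, 0.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
        subtype_of={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


@pytest.fixture
def tiny_csv(tmp_path, tiny_matrix):
    m = tiny_matrix
    path = tmp_path / "expr.csv"
    lines = ["feature," + ",".join(m.samples)]
    for i, f in enumerate(m.features):
        lines.append(f + "," + ",".join(str(v) for v in m.values[i]))
    path.write_text("\n".join(lines) + "\n")
    labels = tmp_path / "labels.csv"
    labels.write_text("".join(f"{s},{m.subtype_of[s]}\n" for s in m.samples))
    return path, labels


@pytest.fixture(scope="session")
def default_sim():
    """One standard-setting simulated dataset shared across tests."""
    return simulate_dataset(SimConfig(n_features=4000, seed=123))


@pytest.fixture(scope="session")
def pure_null_sim():
    return simulate_dataset(SimConfig(n_features=4000, mg_fraction=0.0, seed=321))
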