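import numpy as np
import pytest

from orthopath.io_formats import ExpressionStudy, TargetMap
from orthopath.pathway_graph import PathwayGraph


@pytest.fixture
def small_study() -> ExpressionStudy:
    """3 genes x 4 samples, 2 disease / 2 control, log2 scale."""
    return ExpressionStudy(
        study_id="s1",
        features=["gA", "gB", "gC"],
        samples=["d1", "d2", "c1", "c2"],
        values=np.array(
            [
                [8.0, 9.0, 6.0, 7.0],
                [5.0, 5.5, 5.2, 5.1],
                [10.0, 10.0, 10.0, 10.0],
            ]
        ),
        groups={"d1": "disease", "d2": "disease", "c1": "control", "c2": "control"},
        data_type="mrna",
    )


@pytest.fixture
def chain_pathway() -> PathwayGraph:
    g = PathwayGraph(pathway_id="pw1", name="chain")
    g.add_edge("A", "B", "activation")
    g.add_edge("B", "C", "activation")
    return g


@pytest.fixture
def simple_targets() -> TargetMap:
    tm = TargetMap()
    tm.add("hsa-miR-1", "A")
    tm.add("hsa-miR-1", "B")
    tm.add("hsa-miR-2", "ZZZ")  # no target on the chain pathway
    return tm


@pytest.fixture
def random_study_factory():
    return random_study


def random_study(
    rng: np.random.Generator,
    n_features: int = 50,
    n_per_group: int = 5,
    delta: float = 0.0,
    data_type: str = "mrna",
    study_id: str = "rnd",
) -> ExpressionStudy:
    """Gaussian two-group study; first feature carries effect ``delta``."""
    base = rng.normal(8, 2, size=n_features)
    shift = np.zeros(n_features)
    shift[0] = delta
    disease = rng.normal((base + shift)[:, None], 1.0, size=(n_features, n_per_group))
    control = rng.normal(base[:, None], 1.0, size=(n_features, n_per_group))
    samples = [f"d{i}" for i in range(n_per_group)] + [
        f"c{i}" for i in range(n_per_group)
    ]
    return ExpressionStudy(
        study_id=study_id,
        features=[f"f{i}" for i in range(n_features)],
        samples=samples,
        values=np.hstack([disease, control]),
        groups={s: ("disease" if s.startswith("d") else "control") for s in samples},
        data_type=data_type,
    )
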