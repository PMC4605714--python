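import numpy as np
import pytest

from collage.datamodel import (
    ConstraintMatrix,
    FusionGraph,
    ObjectType,
    RelationMatrix,
)
from collage.synthetic import SyntheticSpec

# The published gene-prioritization fusion graph: 10 object types (1 = genes)
# and 13 relation edges, plus a protein-interaction constraint loop on genes.
STUDY_EDGES = [
    (1, 2), (1, 4), (1, 5), (1, 6), (1, 7), (1, 8), (1, 9), (1, 10),
    (2, 3), (2, 4), (5, 4), (6, 4), (6, 5),
]


def make_study_graph(with_constraint: bool = True) -> FusionGraph:
    """The study topology with placeholder 2x2 matrices (topology-only)."""
    types = {
        str(t): ObjectType(name=str(t), ids=(f"{t}a", f"{t}b"))
        for t in range(1, 11)
    }
    relations = [
        RelationMatrix(source=str(i), target=str(j), label=f"R_{i}_{j}",
                       values=np.zeros((2, 2)))
        for i, j in STUDY_EDGES
    ]
    constraints = []
    if with_constraint:
        constraints.append(
            ConstraintMatrix(type="1", values=np.zeros((2, 2))))
    return FusionGraph(types=types, relations=relations,
                       constraints=constraints, target="1")


@pytest.fixture
def study_graph() -> FusionGraph:
    return make_study_graph()


def planted3_spec(seed: int) -> SyntheticSpec:
    """Three relations sharing planted recipes across three object types."""
    return SyntheticSpec(
        n_per_type={"a": 60, "b": 40, "c": 30},
        true_ranks={"a": 4, "b": 3, "c": 3},
        topology=[("a", "b"), ("a", "c"), ("b", "c")],
        target="a",
        seed=seed,
    )


def random_wellposed_instance(rng: np.random.Generator):
    """A small random fusion graph whose penalized loss is bounded on the
    solver's trajectory: every constrained type also carries relation data,
    and constraint magnitudes are mild relative to the data."""
    sizes = {"a": int(rng.integers(4, 10)), "b": int(rng.integers(4, 10)),
             "c": int(rng.integers(4, 10))}
    ids = {n: tuple(f"{n}{k}" for k in range(sizes[n])) for n in sizes}
    extra = [("a", "c"), ("b", "c"), ("b", "a")]
    chosen = [("a", "b")] + [extra[j] for j in
                             rng.choice(3, size=int(rng.integers(0, 3)),
                                        replace=False)]
    relations = []
    for s, t in chosen:
        values = rng.standard_normal((sizes[s], sizes[t]))
        if rng.random() < 0.3:
            mask = (rng.random(values.shape) >= 0.2).astype(float)
        else:
            mask = np.ones_like(values)
        relations.append(RelationMatrix(source=s, target=t, label=f"{s}{t}",
                                        values=values, mask=mask))
    constraints = []
    if rng.random() < 0.5:
        theta = rng.standard_normal((sizes["a"],) * 2)
        constraints.append(
            ConstraintMatrix(type="a", values=0.025 * (theta + theta.T)))
    graph = FusionGraph(
        types={n: ObjectType(n, ids[n]) for n in sizes},
        relations=relations, constraints=constraints, target="a")
    ranks = {n: max(2, sizes[n] // 3) for n in sizes}
    return graph, ranks
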