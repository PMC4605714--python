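import numpy as np
import pytest

from collage.datamodel import (
    ConstraintMatrix,
    FusionGraph,
    ObjectType,
    RelationMatrix,
)
from collage.factorization import (
    FactorModel,
    FitSettings,
    RankSchedule,
    compute_ranks,
    fit,
    init_factors,
    objective,
    rank_scan,
    reconstruction_error,
    save_model,
    load_model,
    update_backbones,
    update_recipes,
)
from collage.synthetic import generate
from conftest import make_study_graph, planted3_spec


def tiny_graph(values, source_n, target_n, constraints=()):
    types = {"a": ObjectType("a", tuple(f"a{i}" for i in range(source_n))),
             "b": ObjectType("b", tuple(f"b{j}" for j in range(target_n)))}
    rel = RelationMatrix(source="a", target="b", label="r",
                         values=np.asarray(values, dtype=float))
    return FusionGraph(types=types, relations=[rel],
                       constraints=list(constraints), target="a")


# ---------------------------------------------------------------------------
# rank schedule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,k,min_rank,expected", [
    (100, 0.1, 5, 10),
    (20, 0.1, 5, 5),       # floored at the minimum rank
    (12870, 0.1, 5, 1287),  # the gene-type rank used in the study
])
def test_compute_ranks(n, k, min_rank, expected):
    types = {"x": ObjectType("x", tuple(f"x{i}" for i in range(n)))}
    graph = FusionGraph(types=types, target="x")
    ranks = compute_ranks(graph, k, min_rank=min_rank)
    assert ranks.ranks["x"] == expected


def test_compute_ranks_caps_at_object_count():
    types = {"x": ObjectType("x", ("x0", "x1", "x2"))}
    graph = FusionGraph(types=types, target="x")
    with pytest.warns(UserWarning, match="capped"):
        ranks = compute_ranks(graph, 0.5, min_rank=5)
    assert ranks.ranks["x"] == 3


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def test_objective_hand_computed_cases():
    g = tiny_graph([[2.0]], 1, 1)
    model = FactorModel(G={"a": np.array([[1.0]]), "b": np.array([[1.0]])},
                        S={"r": np.array([[1.0]])})
    assert objective(g, model) == pytest.approx(1.0)  # (2-1)^2

    model.S["r"] = np.array([[2.0]])
    assert objective(g, model) == pytest.approx(0.0)  # exact reconstruction

    con = ConstraintMatrix(type="a", values=np.array([[0.5]]))
    g2 = FusionGraph(types={"a": ObjectType("a", ("a0",))},
                     constraints=[con], target="a")
    m2 = FactorModel(G={"a": np.array([[1.0]])}, S={})
    assert objective(g2, m2) == pytest.approx(0.5)  # tr(G^T Theta G)


def test_objective_honors_mask():
    rel = RelationMatrix(source="a", target="b", label="r",
                         values=np.array([[2.0, 7.0]]),
                         mask=np.array([[1.0, 0.0]]))
    g = FusionGraph(types={"a": ObjectType("a", ("a0",)),
                           "b": ObjectType("b", ("b0", "b1"))},
                    relations=[rel], target="a")
    model = FactorModel(G={"a": np.array([[1.0]]),
                           "b": np.array([[1.0], [1.0]])},
                        S={"r": np.array([[1.0]])})
    # only the observed cell contributes: (2-1)^2, the 7 is invisible
    assert objective(g, model) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_deterministic_and_strictly_positive():
    graph, _ = generate(planted3_spec(0))
    ranks = RankSchedule(k=0.1, min_rank=3, ranks={"a": 4, "b": 3, "c": 3})
    m1 = init_factors(graph, ranks, seed=7)
    m2 = init_factors(graph, ranks, seed=7)
    m3 = init_factors(graph, ranks, seed=8)
    for t in m1.G:
        np.testing.assert_array_equal(m1.G[t], m2.G[t])
        assert np.all(m1.G[t] > 0)
    assert any(not np.array_equal(m1.G[t], m3.G[t]) for t in m1.G)


# ---------------------------------------------------------------------------
# backbone update (exact least squares)
# ---------------------------------------------------------------------------

def test_backbone_identity_recipes_give_data():
    R = np.arange(6, dtype=float).reshape(2, 3)
    g = tiny_graph(R, 2, 3)
    model = FactorModel(G={"a": np.eye(2), "b": np.eye(3)}, S={})
    update_backbones(g, model)
    np.testing.assert_allclose(model.S["r"], R)


def test_backbone_matches_generic_least_squares():
    rng = np.random.default_rng(5)
    R = rng.standard_normal((6, 5))
    g = tiny_graph(R, 6, 5)
    Gi = np.linalg.qr(rng.standard_normal((6, 3)))[0]  # orthonormal columns
    Gj = np.linalg.qr(rng.standard_normal((5, 2)))[0]
    model = FactorModel(G={"a": Gi, "b": Gj}, S={})
    update_backbones(g, model)
    np.testing.assert_allclose(model.S["r"], Gi.T @ R @ Gj, atol=1e-10)
    # independent oracle: vectorized least squares for S in R ~ Gi S Gj^T
    A = np.kron(Gj, Gi)
    s, *_ = np.linalg.lstsq(A, R.ravel(order="F"), rcond=None)
    np.testing.assert_allclose(model.S["r"].ravel(order="F"), s, atol=1e-10)


def test_backbone_recovers_planted_backbone_exactly():
    rng = np.random.default_rng(6)
    Gi = np.abs(rng.standard_normal((8, 3)))
    Gj = np.abs(rng.standard_normal((7, 2)))
    S_true = rng.standard_normal((3, 2))
    g = tiny_graph(Gi @ S_true @ Gj.T, 8, 7)
    model = FactorModel(G={"a": Gi, "b": Gj}, S={})
    update_backbones(g, model)
    np.testing.assert_allclose(model.S["r"], S_true, atol=1e-8)


# ---------------------------------------------------------------------------
# recipe update (multiplicative)
# ---------------------------------------------------------------------------

def test_recipe_update_fixed_point_at_perfect_fit():
    rng = np.random.default_rng(1)
    Gi = np.abs(rng.standard_normal((6, 2)))
    Gj = np.abs(rng.standard_normal((5, 2)))
    S = rng.standard_normal((2, 2))
    g = tiny_graph(Gi @ S @ Gj.T, 6, 5)
    model = FactorModel(G={"a": Gi.copy(), "b": Gj.copy()}, S={"r": S.copy()})
    before = objective(g, model)
    update_recipes(g, model)
    assert objective(g, model) <= before + 1e-9


def test_recipe_update_keeps_zeros_and_nonnegativity():
    rng = np.random.default_rng(2)
    g = tiny_graph(rng.standard_normal((5, 4)), 5, 4)
    model = FactorModel(G={"a": np.abs(rng.standard_normal((5, 2))),
                           "b": np.abs(rng.standard_normal((4, 2)))}, S={})
    model.G["a"][2, 1] = 0.0
    update_backbones(g, model)
    update_recipes(g, model)
    assert model.G["a"][2, 1] == 0.0
    for G in model.G.values():
        assert np.all(G >= 0)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def test_fit_zero_iterations_returns_initialized_model():
    graph, _ = generate(planted3_spec(1))
    ranks = RankSchedule(k=0.1, min_rank=3, ranks={"a": 4, "b": 3, "c": 3})
    settings = FitSettings(n_runs=1, max_iter=0, seed=3)
    model = fit(graph, ranks, settings)
    ref = init_factors(graph, ranks, seed=3)
    for t in model.G:
        np.testing.assert_array_equal(model.G[t], ref.G[t])


def test_fit_best_objective_is_argmin_over_runs():
    graph, _ = generate(planted3_spec(2))
    ranks = RankSchedule(k=0.1, min_rank=3, ranks={"a": 4, "b": 3, "c": 3})
    runs = fit(graph, ranks, FitSettings(n_runs=5, max_iter=30, tol=1e-9,
                                         seed=0,
                                         run_combination="per_run_scores"))
    best = fit(graph, ranks, FitSettings(n_runs=5, max_iter=30, tol=1e-9,
                                         seed=0))
    finals = [m.objective_trace[-1] for m in runs]
    assert best.objective_trace[-1] == pytest.approx(min(finals))


def test_fit_single_relation_full_rank_reaches_zero():
    """With c_i = n_i the factorization is unconstrained in capacity, so a
    single fully observed relation must be reconstructed to numerical zero."""
    rng = np.random.default_rng(9)
    R = np.abs(rng.standard_normal((8, 6)))
    g = tiny_graph(R, 8, 6)
    ranks = RankSchedule(k=0.9, min_rank=1, ranks={"a": 8, "b": 6})
    model = fit(g, ranks, FitSettings(n_runs=2, max_iter=500, tol=1e-14,
                                      seed=0))
    assert reconstruction_error(g, model) < 1e-6 * np.linalg.norm(R)


def test_shared_recipe_is_one_object_across_relations():
    graph, _ = generate(planted3_spec(3))
    ranks = RankSchedule(k=0.1, min_rank=3, ranks={"a": 4, "b": 3, "c": 3})
    model = init_factors(graph, ranks, seed=0)
    # relations a-b and a-c share the recipe of type "a" by identity
    assert model.G["a"] is model.G[graph.relations[0].source]
    before = model.G["a"]
    model.G["a"][0, 0] = 123.0
    assert before[0, 0] == 123.0  # mutation is visible through every view


def test_objective_trace_nonincreasing_on_planted_fit():
    graph, _ = generate(planted3_spec(4))
    ranks = RankSchedule(k=0.1, min_rank=3, ranks={"a": 4, "b": 3, "c": 3})
    model = fit(graph, ranks, FitSettings(n_runs=2, max_iter=100, tol=1e-12,
                                          seed=1))
    trace = np.array(model.objective_trace)
    assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)


# ---------------------------------------------------------------------------
# rank scan
# ---------------------------------------------------------------------------

def test_rank_scan_errors_nonnegative_and_capacity_monotone():
    graph, _ = generate(planted3_spec(5))
    settings = FitSettings(n_runs=2, max_iter=200, tol=1e-8, seed=0)
    table, _ = rank_scan(graph, [0.05, 0.1, 0.2], settings, min_rank=2)
    assert len(table) == 3
    assert (table["total_error"] >= 0).all()
    # planted fraction is ~0.1; half that rank fits the data worse
    errs = dict(zip(table["k"], table["total_error"]))
    assert errs[0.2] < errs[0.05]


def test_rank_scan_single_point_has_no_kink():
    graph, _ = generate(planted3_spec(6))
    table, kink = rank_scan(graph, [0.1],
                            FitSettings(n_runs=1, max_iter=20, tol=1e-6,
                                        seed=0), min_rank=2)
    assert len(table) == 1 and kink is None


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def test_model_checkpoint_roundtrip(tmp_path):
    graph, _ = generate(planted3_spec(7))
    ranks = RankSchedule(k=0.1, min_rank=3, ranks={"a": 4, "b": 3, "c": 3})
    model = fit(graph, ranks, FitSettings(n_runs=1, max_iter=20, tol=1e-6,
                                          seed=4))
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    for t in model.G:
        np.testing.assert_allclose(back.G[t], model.G[t], atol=1e-12)
    for lab in model.S:
        np.testing.assert_allclose(back.S[lab], model.S[lab], atol=1e-12)
    assert back.seed == model.seed
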