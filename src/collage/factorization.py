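"""Collective penalized matrix tri-factorization with shared recipe matrices.

Every relation matrix R_ij in the fusion graph is decomposed as
R_ij ~= G_i S_ij G_j^T, where the nonnegative *recipe* matrix G_i
(n_i x c_i) is shared by all relations touching object type i and the
unconstrained *backbone* matrix S_ij (c_i x c_j) is specific to one
relation.  The fitted model minimizes

    sum_ij || M_ij o (R_ij - G_i S_ij G_j^T) ||_F^2
        + sum_i sum_l tr(G_i^T Theta_i^(l) G_i)

over G_i >= 0 and unconstrained S_ij, where M_ij is the observation mask
and Theta_i^(l) are the constraint matrices (must-link negative,
cannot-link positive).

The solver alternates an exact least-squares solve for every backbone
matrix (pseudo-inverse, with unobserved cells imputed by the current
reconstruction) with a multiplicative update of each recipe matrix,
G <- G o sqrt(N / (D + eps)), built from the positive/negative parts of
the objective gradient.  Multiplicative updates preserve nonnegativity
exactly and never revive an entry that has reached zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import json

import numpy as np

from .datamodel import FusionGraph, GraphConfigError, RelationMatrix

__all__ = [
    "RankSchedule",
    "FitSettings",
    "FactorModel",
    "FitError",
    "compute_ranks",
    "objective",
    "reconstruction_error",
    "init_factors",
    "update_backbones",
    "update_recipes",
    "fit",
    "rank_scan",
    "save_model",
    "load_model",
]


class FitError(RuntimeError):
    """Raised when every restart of the solver diverges."""


@dataclass(frozen=True)
class RankSchedule:
    """Per-type latent dimensionality c_i derived from a single fraction k.

    c_i = max(round(k * n_i), min_rank), capped at n_i; ``ranks`` may carry
    explicit per-type overrides.
    """

    k: float
    min_rank: int
    ranks: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))


def compute_ranks(graph: FusionGraph, k: float, min_rank: int = 5,
                  overrides: Mapping[str, int] | None = None) -> RankSchedule:
    """Derive the factorization rank of every object type from fraction k.

    Rounding is round-half-to-even; ranks below ``min_rank`` are floored and
    ranks above n_i are capped (with a warning).
    """
    if not 0 < k < 1:
        raise ValueError(f"k must lie in (0, 1), got {k}")
    if min_rank < 1:
        raise ValueError(f"min_rank must be >= 1, got {min_rank}")
    ranks: dict[str, int] = {}
    for name, typ in graph.types.items():
        if overrides and name in overrides:
            c = int(overrides[name])
        else:
            c = max(int(np.round(k * typ.n)), min_rank)
        if c > typ.n:
            warnings.warn(
                f"type {name!r}: rank {c} exceeds object count {typ.n}; capped")
            c = typ.n
        ranks[name] = c
    return RankSchedule(k=k, min_rank=min_rank, ranks=ranks)


@dataclass
class FitSettings:
    """Solver settings.

    ``tol`` applies to the change of the total reconstruction error between
    consecutive iterations (sum over relations of masked Frobenius norms);
    ``tol_mode`` selects absolute (default) or relative change.  Restart r
    uses random seed ``seed + r``.
    """

    n_runs: int = 20
    max_iter: int = 200
    tol: float = 0.01
    tol_mode: str = "absolute"
    run_combination: str = "best_objective"
    seed: int = 0
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.tol_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown tol_mode {self.tol_mode!r}")
        if self.run_combination not in ("best_objective", "per_run_scores"):
            raise ValueError(
                f"unknown run_combination {self.run_combination!r}")


@dataclass
class FactorModel:
    """A fitted latent model: recipe matrices G, backbone matrices S."""

    G: dict[str, np.ndarray]
    S: dict[str, np.ndarray]
    ids: dict[str, tuple[str, ...]] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    seed: int = 0

    def copy(self) -> "FactorModel":
        return FactorModel(G={k: v.copy() for k, v in self.G.items()},
                           S={k: v.copy() for k, v in self.S.items()},
                           ids=dict(self.ids),
                           objective_trace=list(self.objective_trace),
                           seed=self.seed)


def _check_shapes(graph: FusionGraph, model: FactorModel) -> None:
    for name, typ in graph.types.items():
        G = model.G.get(name)
        if G is None or G.shape[0] != typ.n:
            raise GraphConfigError(
                f"model G[{name!r}] missing or row count != {typ.n}")
    for rel in graph.relations:
        S = model.S.get(rel.label)
        if S is None:
            raise GraphConfigError(f"model S[{rel.label!r}] missing")
        ci = model.G[rel.source].shape[1]
        cj = model.G[rel.target].shape[1]
        if S.shape != (ci, cj):
            raise GraphConfigError(
                f"model S[{rel.label!r}]: shape {S.shape} != ({ci}, {cj})")


def _filled(rel: RelationMatrix, model: FactorModel) -> np.ndarray:
    """R with unobserved cells imputed by the current reconstruction."""
    if rel.fully_observed:
        return rel.values
    if rel.label in model.S:
        recon = model.G[rel.source] @ model.S[rel.label] @ model.G[rel.target].T
    else:
        recon = np.zeros_like(rel.values)
    return np.where(rel.mask != 0, rel.values, recon)


def reconstruction_error(graph: FusionGraph, model: FactorModel) -> float:
    """Total reconstruction error: sum over relations of the Frobenius norm
    of the masked residual (the stopping and rank-scan statistic)."""
    total = 0.0
    for rel in graph.relations:
        recon = model.G[rel.source] @ model.S[rel.label] @ model.G[rel.target].T
        total += float(np.linalg.norm(rel.mask * (rel.values - recon)))
    return total


def objective(graph: FusionGraph, model: FactorModel) -> float:
    """Penalized objective: squared masked reconstruction error plus the
    constraint trace penalty (which may be negative)."""
    _check_shapes(graph, model)
    total = 0.0
    for rel in graph.relations:
        recon = model.G[rel.source] @ model.S[rel.label] @ model.G[rel.target].T
        total += float(np.sum((rel.mask * (rel.values - recon)) ** 2))
    for con in graph.constraints:
        G = model.G[con.type]
        total += float(np.trace(G.T @ con.values @ G))
    return total


def init_factors(graph: FusionGraph, ranks: RankSchedule, seed: int) -> FactorModel:
    """Random nonnegative initialization of all recipe matrices.

    Each G_i is uniform on (0, 1) scaled by the mean absolute observed value
    of the data touching type i (so factors start on the data's scale), and
    the backbones are then set by their exact least-squares solve.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    model = FactorModel(G={}, S={},
                        ids={n: t.ids for n, t in graph.types.items()},
                        seed=seed)
    for name in sorted(graph.types):
        typ = graph.types[name]
        c = ranks.ranks[name]
        vals, weight = 0.0, 0.0
        for rel in graph.relations_touching(name):
            vals += float(np.sum(np.abs(rel.values) * rel.mask))
            weight += float(np.sum(rel.mask))
        scale = vals / weight if weight > 0 and vals > 0 else 1.0
        model.G[name] = rng.uniform(size=(typ.n, c)) * scale
    update_backbones(graph, model)
    return model


def update_backbones(graph: FusionGraph, model: FactorModel) -> FactorModel:
    """Exact least-squares update of every backbone matrix with G fixed:
    S <- (G_i^T G_i)^+ G_i^T R G_j (G_j^T G_j)^+, on the imputed matrix."""
    for rel in graph.relations:
        Gi, Gj = model.G[rel.source], model.G[rel.target]
        Rf = _filled(rel, model)
        left = np.linalg.pinv(Gi.T @ Gi) @ Gi.T
        right = Gj @ np.linalg.pinv(Gj.T @ Gj)
        model.S[rel.label] = left @ Rf @ right
    return model


def _pos(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _neg(x: np.ndarray) -> np.ndarray:
    return np.maximum(-x, 0.0)


def update_recipes(graph: FusionGraph, model: FactorModel,
                   epsilon: float = 1e-12) -> FactorModel:
    """Multiplicative update of every recipe matrix with S fixed.

    For each type i, G_i <- G_i o sqrt(N_i / (D_i + eps)) where N_i collects
    the gradient's decrease terms ([R G_j S^T]^+, G_i [S G_j^T G_j S^T]^-,
    [Theta_i]^- G_i over all touching relations/constraints) and D_i the
    complementary parts.  The mixed-sign c x c kernel S G_j^T G_j S^T is
    split into positive/negative parts *before* multiplying by the
    nonnegative G_i — the splitting under which the standard semi-NMF
    auxiliary-function argument guarantees a non-increasing objective.
    Types are updated sequentially in sorted order so each step is a
    single-factor descent with all other factors fixed.
    """
    fills = {rel.label: _filled(rel, model) for rel in graph.relations}
    for name in sorted(model.G):
        G = model.G[name]
        N = np.zeros_like(G)
        D = np.zeros_like(G)
        touched = False
        for rel in graph.relations:
            S = model.S[rel.label]
            Rf = fills[rel.label]
            if rel.source == name:
                Gj = model.G[rel.target]
                P = Rf @ Gj @ S.T
                K = S @ (Gj.T @ Gj) @ S.T
                N += _pos(P) + G @ _neg(K)
                D += _neg(P) + G @ _pos(K)
                touched = True
            if rel.target == name:
                Gi = model.G[rel.source]
                P = Rf.T @ Gi @ S
                K = S.T @ (Gi.T @ Gi) @ S
                N += _pos(P) + G @ _neg(K)
                D += _neg(P) + G @ _pos(K)
                touched = True
        for con in graph.constraints_for(name):
            N += _neg(con.values) @ G
            D += _pos(con.values) @ G
            touched = True
        if touched:
            model.G[name] = G * np.sqrt(N / (D + epsilon))
    return model


def _run_once(graph: FusionGraph, ranks: RankSchedule, settings: FitSettings,
              seed: int) -> FactorModel:
    model = init_factors(graph, ranks, seed)
    model.objective_trace.append(objective(graph, model))
    err_prev = reconstruction_error(graph, model)
    for _ in range(settings.max_iter):
        update_backbones(graph, model)
        update_recipes(graph, model, settings.epsilon)
        obj = objective(graph, model)
        if not np.isfinite(obj):
            raise FitError(f"run with seed {seed}: non-finite objective")
        model.objective_trace.append(obj)
        err = reconstruction_error(graph, model)
        delta = abs(err - err_prev)
        if settings.tol_mode == "relative":
            delta = delta / max(err_prev, np.finfo(float).tiny)
        if delta < settings.tol:
            break
        err_prev = err
    return model


def fit(graph: FusionGraph, ranks: RankSchedule,
        settings: FitSettings | None = None):
    """Run the collective factorization with random restarts.

    Returns the restart with the lowest final objective, or the list of all
    restart models when ``settings.run_combination == "per_run_scores"``.
    Restarts that produce non-finite factors are discarded; if every restart
    diverges a :class:`FitError` is raised with the diagnostics.
    """
    settings = settings or FitSettings()
    models: list[FactorModel] = []
    failures: list[str] = []
    for r in range(settings.n_runs):
        try:
            models.append(_run_once(graph, ranks, settings, settings.seed + r))
        except FitError as exc:
            failures.append(str(exc))
    if not models:
        raise FitError("all restarts diverged: " + "; ".join(failures))
    if settings.run_combination == "per_run_scores":
        return models
    return min(models, key=lambda m: m.objective_trace[-1])


def rank_scan(graph: FusionGraph, k_values, settings: FitSettings | None = None,
              min_rank: int = 5):
    """Fit the model on a grid of rank fractions k and report errors.

    Returns ``(table, suggested_k)`` where the table (pandas DataFrame) has
    one row per k with the total reconstruction error averaged over restarts
    plus per-relation errors, and ``suggested_k`` is the k with the maximum
    positive second difference of error vs k (the automated "kink") — a
    suggestion only, None when the grid has fewer than three points.
    """
    import pandas as pd

    settings = settings or FitSettings()
    settings = dataclasses.replace(settings, run_combination="per_run_scores")
    rows = []
    for k in k_values:
        ranks = compute_ranks(graph, k, min_rank=min_rank)
        models = fit(graph, ranks, settings)
        per_rel = {rel.label: 0.0 for rel in graph.relations}
        total = 0.0
        for model in models:
            total += reconstruction_error(graph, model)
            for rel in graph.relations:
                recon = (model.G[rel.source] @ model.S[rel.label]
                         @ model.G[rel.target].T)
                per_rel[rel.label] += float(
                    np.linalg.norm(rel.mask * (rel.values - recon)))
        row = {"k": float(k),
               "total_error": total / len(models)}
        row.update({f"error_{lab}": v / len(models) for lab, v in per_rel.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    suggested = None
    if len(table) >= 3:
        err = table["total_error"].to_numpy()
        second = err[:-2] - 2 * err[1:-1] + err[2:]
        if np.any(second > 0):
            suggested = float(table["k"].to_numpy()[1:-1][int(np.argmax(second))])
    return table, suggested


# ---------------------------------------------------------------------------
# model checkpointing
# ---------------------------------------------------------------------------

def save_model(model: FactorModel, out_dir: str | Path,
               settings: FitSettings | None = None) -> Path:
    """Write one dense delimited file per latent matrix plus a manifest."""
    from .io import write_dense

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, G in model.G.items():
        ids = model.ids.get(name, tuple(str(i) for i in range(G.shape[0])))
        comps = [f"c{j}" for j in range(G.shape[1])]
        write_dense(out_dir / f"G_{name}.tsv", G, None, ids, comps)
    for label, S in model.S.items():
        rows = [f"r{i}" for i in range(S.shape[0])]
        cols = [f"c{j}" for j in range(S.shape[1])]
        write_dense(out_dir / f"S_{label}.tsv", S, None, rows, cols)
    manifest = {
        "seed": model.seed,
        "objective_trace": model.objective_trace,
        "types": sorted(model.G),
        "relations": sorted(model.S),
        "settings": dataclasses.asdict(settings) if settings else None,
    }
    path = out_dir / "model.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def load_model(model_dir: str | Path) -> FactorModel:
    from .io import read_dense

    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "model.json").read_text())
    G, S, ids = {}, {}, {}
    for name in manifest["types"]:
        values, _, row_ids, _ = read_dense(model_dir / f"G_{name}.tsv")
        G[name] = values
        ids[name] = row_ids
    for label in manifest["relations"]:
        values, _, _, _ = read_dense(model_dir / f"S_{label}.tsv")
        S[label] = values
    return FactorModel(G=G, S=S, ids=ids,
                       objective_trace=list(manifest["objective_trace"]),
                       seed=int(manifest["seed"]))
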