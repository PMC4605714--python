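"""Synthetic fusion graphs with planted shared latent block structure.

The generator emulates the statistical structure the factorization
assumes: every object type carries a planted nonnegative recipe matrix in
which each object has one dominant latent component, every relation is a
product R = G_i S_ij G_j^T of the shared planted recipes plus additive
Gaussian noise, and an optional constraint matrix encodes must-links
within a designated *module* (one latent component of the target type)
whose members serve as ground-truth positives in recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    ConstraintMatrix,
    FusionGraph,
    ObjectType,
    RelationMatrix,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "seed_split",
           "default_spec"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic fusion graph.

    ``module`` designates the latent component of the target type whose
    members are the planted positives.  ``noise_sd`` is the standard
    deviation of additive Gaussian noise; relations declared nonnegative
    are clipped at zero after adding noise.  Deterministic given ``seed``.
    """

    n_per_type: dict[str, int]
    true_ranks: dict[str, int]
    topology: list[tuple[str, str]]
    target: str
    noise_sd: float = 0.0
    missing_frac: float = 0.0
    module: int = 0
    constraint: bool = False
    clip_nonnegative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for src, tgt in self.topology:
            for name in (src, tgt):
                if name not in self.n_per_type:
                    raise ValueError(f"topology references undeclared type {name!r}")
        if self.target not in self.n_per_type:
            raise ValueError(f"target {self.target!r} not declared")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, c in self.true_ranks.items():
            if not 1 <= c <= self.n_per_type[name]:
                raise ValueError(f"rank for {name!r} out of range")


@dataclass
class GroundTruth:
    """Planted factors and module membership behind a synthetic graph."""

    G: dict[str, np.ndarray]
    S: dict[str, np.ndarray]
    assignments: dict[str, np.ndarray]
    module_members: tuple[str, ...]
    ids: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _planted_recipe(rng: np.random.Generator, n: int, c: int):
    """Nonnegative block recipe: one dominant component per object.

    The first c objects seed one component each so none is empty; dominant
    weights are U(0.8, 1.2) against a U(0, 0.1) background.
    """
    assign = np.concatenate([np.arange(c), rng.integers(0, c, size=n - c)])
    G = rng.uniform(0.0, 0.1, size=(n, c))
    G[np.arange(n), assign] = rng.uniform(0.8, 1.2, size=n)
    return G, assign


def generate(spec: SyntheticSpec) -> tuple[FusionGraph, GroundTruth]:
    """Build a fusion graph with planted structure; returns graph + truth."""
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.n_per_type)
    ids = {name: tuple(f"{name}{i:04d}" for i in range(spec.n_per_type[name]))
           for name in names}
    G, assignments = {}, {}
    for name in names:
        G[name], assignments[name] = _planted_recipe(
            rng, spec.n_per_type[name], spec.true_ranks[name])

    relations, S = [], {}
    for src, tgt in spec.topology:
        label = f"{src}-{tgt}"
        if label in S:  # parallel edge: disambiguate
            k = 2
            while f"{label}.{k}" in S:
                k += 1
            label = f"{label}.{k}"
        Sm = rng.uniform(0.0, 1.0, size=(spec.true_ranks[src],
                                         spec.true_ranks[tgt]))
        S[label] = Sm
        values = G[src] @ Sm @ G[tgt].T
        if spec.noise_sd > 0:
            values = values + spec.noise_sd * rng.standard_normal(values.shape)
            if spec.clip_nonnegative:
                values = np.clip(values, 0.0, None)
        if spec.missing_frac > 0:
            mask = (rng.random(values.shape) >= spec.missing_frac).astype(float)
        else:
            mask = np.ones_like(values)
        relations.append(RelationMatrix(source=src, target=tgt, label=label,
                                        values=values, mask=mask,
                                        row_ids=ids[src], col_ids=ids[tgt]))

    constraints = []
    member_flags = assignments[spec.target] == spec.module
    if spec.constraint:
        theta = -1.0 * np.outer(member_flags, member_flags)
        np.fill_diagonal(theta, 0.0)
        constraints.append(ConstraintMatrix(type=spec.target, values=theta))

    graph = FusionGraph(
        types={name: ObjectType(name=name, ids=ids[name]) for name in names},
        relations=relations, constraints=constraints, target=spec.target)
    truth = GroundTruth(
        G=G, S=S, assignments=assignments,
        module_members=tuple(np.array(ids[spec.target])[member_flags]),
        ids=ids)
    return graph, truth


def seed_split(truth: GroundTruth, n_seeds: int, seed: int | None = None,
               target: str | None = None):
    """Split the planted module into (seeds, positives) plus negatives.

    Seeds are sampled uniformly from the module; the remaining members are
    positives; every off-module target object is a negative.  The three
    sets are disjoint by construction.
    """
    members = list(truth.module_members)
    if n_seeds >= len(members):
        raise ValueError(
            f"module has {len(members)} members; cannot hold out "
            f"{n_seeds} seeds")
    if target is None:
        target = next(t for t, ids in truth.ids.items()
                      if set(members) <= set(ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(members), size=n_seeds, replace=False)
    seeds = [members[i] for i in sorted(chosen)]
    positives = [m for m in members if m not in set(seeds)]
    negatives = [obj for obj in truth.ids[target] if obj not in set(members)]
    return seeds, positives, negatives


def default_spec(seed: int = 0, noise_sd: float = 0.0,
                 missing_frac: float = 0.0, constraint: bool = False) -> SyntheticSpec:
    """A miniature 5-type, 6-edge fusion graph echoing a gene-centred design.

    A "gene" hub connects to terms, pathways and articles; articles map to
    terms and pathways to compounds, giving multi-step chains at desk scale.
    """
    return SyntheticSpec(
        n_per_type={"gene": 60, "term": 30, "article": 25,
                    "pathway": 20, "compound": 12},
        true_ranks={"gene": 5, "term": 4, "article": 3,
                    "pathway": 3, "compound": 3},
        topology=[("gene", "term"), ("gene", "pathway"), ("gene", "article"),
                  ("article", "term"), ("pathway", "compound"),
                  ("term", "compound")],
        target="gene",
        noise_sd=noise_sd,
        missing_frac=missing_frac,
        constraint=constraint,
        seed=seed,
    )
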