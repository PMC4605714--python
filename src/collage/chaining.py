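"""Latent matrix chaining: profiling target objects in any reachable latent space.

A *chain* is a directed simple path of relation edges rooted at the target
object type (the empty chain counts).  Multiplying the target's recipe
matrix by the backbone matrices along the path yields a *profile matrix*
placing every target object in the latent space of the path's terminal
type.  Constraint loops never participate in chaining.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .datamodel import FusionGraph
from .factorization import FactorModel

__all__ = [
    "Chain",
    "ProfileMatrix",
    "enumerate_chains",
    "chain_profile",
    "build_profiles",
    "chain_membership_counts",
]


@dataclass(frozen=True)
class Chain:
    """A directed simple path of relation-edge labels rooted at ``root``."""

    edges: tuple[str, ...]
    root: str
    terminal: str

    def __len__(self) -> int:
        return len(self.edges)

    def describe(self) -> str:
        parts = [f"G_{self.root}"] + [f"S_{label}" for label in self.edges]
        return " · ".join(parts)


@dataclass
class ProfileMatrix:
    """The matrix product a chain induces: target objects x terminal components."""

    chain: Chain
    values: np.ndarray
    ids: tuple[str, ...] = ()


def enumerate_chains(graph: FusionGraph, target: str | None = None) -> list[Chain]:
    """Enumerate the empty chain plus every directed simple path from target.

    Edges are traversed only in their stored direction; parallel edges yield
    distinct chains; no node is visited twice (which guarantees termination
    on cyclic graphs).  The result is ordered lexicographically by
    edge-label sequence, empty chain first.
    """
    target = target if target is not None else graph.target
    if target not in graph.types:
        raise KeyError(f"unknown target type {target!r}")
    outgoing: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for rel in graph.relations:
        outgoing[rel.source].append((rel.label, rel.target))

    chains: list[Chain] = []

    def visit(node: str, seen: frozenset[str], labels: tuple[str, ...]) -> None:
        chains.append(Chain(edges=labels, root=target, terminal=node))
        for label, nxt in sorted(outgoing[node]):
            if nxt not in seen:
                visit(nxt, seen | {nxt}, labels + (label,))

    visit(target, frozenset({target}), ())
    chains.sort(key=lambda c: c.edges)
    return chains


def chain_profile(model: FactorModel, chain: Chain) -> ProfileMatrix:
    """Materialize the profile matrix of one chain.

    The empty chain returns G_root itself; otherwise the ordered product
    G_root · S_e1 · S_e2 · ... .
    """
    if chain.root not in model.G:
        raise KeyError(f"model has no recipe matrix for type {chain.root!r}")
    values = model.G[chain.root]
    for label in chain.edges:
        if label not in model.S:
            raise KeyError(f"model has no backbone matrix for edge {label!r}")
        S = model.S[label]
        if values.shape[1] != S.shape[0]:
            raise ValueError(
                f"chain {chain.describe()}: cannot multiply "
                f"{values.shape} by S_{label} {S.shape}"
            )
        values = values @ S
    return ProfileMatrix(chain=chain, values=values,
                         ids=tuple(model.ids.get(chain.root, ())))


def build_profiles(graph: FusionGraph, model: FactorModel,
                   target: str | None = None) -> list[ProfileMatrix]:
    """Enumerate all chains and materialize every profile matrix."""
    return [chain_profile(model, chain)
            for chain in enumerate_chains(graph, target)]


def chain_membership_counts(chains: list[Chain]) -> dict[str, int]:
    """For each relation edge, the number of chains that contain it."""
    counts: dict[str, int] = {}
    for chain in chains:
        for label in chain.edges:
            counts[label] = counts.get(label, 0) + 1
    return counts
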