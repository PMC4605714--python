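"""Typed multi-relational data model.

A fusion graph is a directed multigraph whose nodes are *object types*
(genes, ontology terms, pathways, articles, ...) and whose edges carry
dyadic data matrices relating two types.  Relation edges carry an
``n_source x n_target`` real matrix; loops carry square symmetric
constraint matrices used only for regularization (negative entries are
must-link, positive entries cannot-link) and are never factorized.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GraphConfigError",
    "MatrixLoadError",
    "ObjectType",
    "RelationMatrix",
    "ConstraintMatrix",
    "FusionGraph",
    "normalize_rows",
    "symmetrize",
]


class GraphConfigError(ValueError):
    """Raised when a fusion-graph configuration is inconsistent."""


class MatrixLoadError(ValueError):
    """Raised when a matrix file does not match its declared object type."""


@dataclass(frozen=True)
class ObjectType:
    """A node of the fusion graph: a named, ordered universe of objects."""

    name: str
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if len(self.ids) < 1:
            raise GraphConfigError(f"object type {self.name!r} has no objects")
        if len(set(self.ids)) != len(self.ids):
            raise GraphConfigError(
                f"object type {self.name!r} has duplicate identifiers"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, object_id: str) -> int:
        try:
            return self.ids.index(object_id)
        except ValueError:
            raise KeyError(
                f"unknown object id {object_id!r} for type {self.name!r}"
            ) from None


@dataclass
class RelationMatrix:
    """A relation R between objects of ``source`` (rows) and ``target`` (cols).

    ``mask`` is a binary observation indicator of the same shape; masked-out
    (0) cells are ignored by every downstream computation that honors masks.
    ``missing_policy`` records how absent cells of a sparse input were
    interpreted ("zero": observed zeros, "unobserved": mask 0).
    """

    source: str
    target: str
    label: str
    values: np.ndarray
    mask: np.ndarray | None = None
    row_ids: tuple[str, ...] | None = None
    col_ids: tuple[str, ...] | None = None
    missing_policy: str = "zero"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixLoadError(
                f"relation {self.label!r}: expected a 2-d matrix, "
                f"got ndim={self.values.ndim}"
            )
        if self.mask is None:
            self.mask = np.ones_like(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=float)
            if self.mask.shape != self.values.shape:
                raise MatrixLoadError(
                    f"relation {self.label!r}: mask shape {self.mask.shape} "
                    f"!= values shape {self.values.shape}"
                )
        if self.row_ids is not None:
            self.row_ids = tuple(str(i) for i in self.row_ids)
        if self.col_ids is not None:
            self.col_ids = tuple(str(i) for i in self.col_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def fully_observed(self) -> bool:
        return bool(np.all(self.mask == 1))


@dataclass
class ConstraintMatrix:
    """A symmetric square penalty matrix on a single object type.

    Negative entries encode must-link (similar latent profiles rewarded),
    positive entries cannot-link.  Constraint matrices regularize the
    factorization and are never factorized themselves.
    """

    type: str
    values: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise MatrixLoadError(
                f"constraint on {self.type!r}: matrix must be square, "
                f"got shape {self.values.shape}"
            )


def symmetrize(values: np.ndarray, *, label: str = "constraint",
               atol: float = 1e-8) -> np.ndarray:
    """Average a square matrix with its transpose, warning on asymmetry.

    The trace penalty tr(G^T Theta G) only depends on the symmetric part of
    Theta, so symmetrizing at load loses nothing.
    """
    values = np.asarray(values, dtype=float)
    sym = 0.5 * (values + values.T)
    if not np.allclose(values, values.T, atol=atol):
        warnings.warn(
            f"{label}: matrix is asymmetric; symmetrized by averaging "
            "with its transpose",
            stacklevel=2,
        )
    return sym


def normalize_rows(relation: RelationMatrix) -> RelationMatrix:
    """Scale every row profile to unit Euclidean (Frobenius) norm.

    Row norms are computed over observed cells only.  All-zero (or fully
    unobserved) rows are returned unchanged; the mask is untouched.  The
    operation is idempotent.
    """
    observed = relation.values * relation.mask
    norms = np.linalg.norm(observed, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return dataclasses.replace(relation, values=relation.values / safe,
                               mask=relation.mask.copy())


@dataclass
class FusionGraph:
    """The full data-fusion system: typed nodes plus relation/constraint edges.

    Multi-edges between the same type pair are allowed and distinguished by
    ``label``.  ``target`` names the object type whose objects are profiled
    and prioritized.
    """

    types: Mapping[str, ObjectType]
    relations: Sequence[RelationMatrix] = field(default_factory=list)
    constraints: Sequence[ConstraintMatrix] = field(default_factory=list)
    target: str = ""

    def __post_init__(self) -> None:
        self.types = dict(self.types)
        self.relations = list(self.relations)
        self.constraints = list(self.constraints)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.target and self.target not in self.types:
            raise GraphConfigError(f"target type {self.target!r} not declared")
        labels = [r.label for r in self.relations]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise GraphConfigError(f"duplicate relation labels: {dup}")
        for rel in self.relations:
            for axis, name in (("row", rel.source), ("column", rel.target)):
                if name not in self.types:
                    raise GraphConfigError(
                        f"relation {rel.label!r} references undeclared "
                        f"type {name!r} on its {axis} axis"
                    )
            ns, nt = self.types[rel.source].n, self.types[rel.target].n
            if rel.shape != (ns, nt):
                raise GraphConfigError(
                    f"relation {rel.label!r}: shape {rel.shape} contradicts "
                    f"declared counts ({ns}, {nt}) for "
                    f"({rel.source!r}, {rel.target!r})"
                )
            if rel.row_ids is not None and rel.row_ids != self.types[rel.source].ids:
                raise GraphConfigError(
                    f"relation {rel.label!r}: row identifiers do not match "
                    f"type {rel.source!r}"
                )
            if rel.col_ids is not None and rel.col_ids != self.types[rel.target].ids:
                raise GraphConfigError(
                    f"relation {rel.label!r}: column identifiers do not match "
                    f"type {rel.target!r}"
                )
        for con in self.constraints:
            if con.type not in self.types:
                raise GraphConfigError(
                    f"constraint references undeclared type {con.type!r}"
                )
            n = self.types[con.type].n
            if con.values.shape != (n, n):
                raise GraphConfigError(
                    f"constraint on {con.type!r}: shape {con.values.shape} "
                    f"contradicts declared count {n}"
                )

    # -- convenience accessors ----------------------------------------------
    def n(self, type_name: str) -> int:
        return self.types[type_name].n

    def relation(self, label: str) -> RelationMatrix:
        for rel in self.relations:
            if rel.label == label:
                return rel
        raise KeyError(f"no relation labelled {label!r}")

    def relations_touching(self, type_name: str) -> Iterator[RelationMatrix]:
        for rel in self.relations:
            if type_name in (rel.source, rel.target):
                yield rel

    def constraints_for(self, type_name: str) -> Iterator[ConstraintMatrix]:
        for con in self.constraints:
            if con.type == type_name:
                yield con
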