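"""Readers and writers for relation matrices and fusion-graph configurations.

Dense matrices are tab-delimited text: first row = column ids, first column
= row ids, ``NA`` = missing (mask 0).  Sparse matrices are MatrixMarket
coordinate files accompanied by two plain-text identifier sidecars
(``<stem>.rows.txt`` / ``<stem>.cols.txt``, one id per line).  Graph
configurations are YAML documents with sections ``types``, ``relations``,
``constraints`` and ``target``; the exact field names are documented in the
README.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .datamodel import (
    ConstraintMatrix,
    FusionGraph,
    GraphConfigError,
    MatrixLoadError,
    ObjectType,
    RelationMatrix,
    normalize_rows,
    symmetrize,
)

__all__ = [
    "read_relation",
    "write_relation",
    "read_dense",
    "write_dense",
    "read_sparse",
    "write_sparse",
    "reindex_relation",
    "load_graph",
    "write_graph",
]


# ---------------------------------------------------------------------------
# dense delimited format
# ---------------------------------------------------------------------------

def read_dense(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple, tuple]:
    """Read a tab-delimited matrix; returns (values, mask, row_ids, col_ids)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                            keep_default_na=False, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixLoadError(f"{path}: cannot read dense matrix: {exc}") from exc
    values = np.empty(frame.shape, dtype=float)
    mask = np.ones(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            if cell is np.nan or (isinstance(cell, float) and np.isnan(cell)):
                values[i, j] = 0.0
                mask[i, j] = 0.0
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise MatrixLoadError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{frame.index[i]!r}, column {col!r}"
                ) from None
    return values, mask, tuple(map(str, frame.index)), tuple(map(str, frame.columns))


def write_dense(path: str | Path, values: np.ndarray, mask: np.ndarray | None,
                row_ids, col_ids) -> None:
    values = np.asarray(values, dtype=float)
    out = values.astype(object)
    if mask is not None:
        out = np.where(np.asarray(mask) == 0, np.nan, values).astype(object)
    frame = pd.DataFrame(out, index=list(row_ids), columns=list(col_ids))
    frame.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# sparse coordinate format (MatrixMarket + id sidecars)
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def read_sparse(path: str | Path, missing: str = "zero"):
    """Read a MatrixMarket coordinate file plus its id sidecars.

    ``missing`` decides how absent coordinates are treated: ``"zero"`` makes
    them observed zeros (mask 1), ``"unobserved"`` masks them out (mask 0).
    """
    path = Path(path)
    if missing not in ("zero", "unobserved"):
        raise ValueError(f"missing policy must be 'zero' or 'unobserved', got {missing!r}")
    rows_file, cols_file = _sidecar_paths(path)
    for f in (rows_file, cols_file):
        if not f.exists():
            raise MatrixLoadError(f"{path}: identifier sidecar {f} not found")
    row_ids = tuple(rows_file.read_text().split())
    col_ids = tuple(cols_file.read_text().split())
    coo = scipy.io.mmread(str(path)).tocoo()
    if coo.shape != (len(row_ids), len(col_ids)):
        raise MatrixLoadError(
            f"{path}: matrix shape {coo.shape} does not match sidecar "
            f"identifier counts ({len(row_ids)}, {len(col_ids)})"
        )
    values = np.zeros(coo.shape, dtype=float)
    values[coo.row, coo.col] = coo.data
    if missing == "unobserved":
        mask = np.zeros(coo.shape, dtype=float)
        mask[coo.row, coo.col] = 1.0
    else:
        mask = np.ones(coo.shape, dtype=float)
    return values, mask, row_ids, col_ids


def write_sparse(path: str | Path, values: np.ndarray, mask: np.ndarray | None,
                 row_ids, col_ids) -> None:
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if mask is not None and not np.all(np.asarray(mask) == 1):
        # store only observed cells; absent coordinates read back as unobserved
        m = np.asarray(mask) != 0
        coo = scipy.sparse.coo_matrix(
            (values[m], np.nonzero(m)), shape=values.shape)
    else:
        coo = scipy.sparse.coo_matrix(values)
    scipy.io.mmwrite(str(path), coo)
    rows_file, cols_file = _sidecar_paths(path)
    rows_file.write_text("\n".join(map(str, row_ids)) + "\n")
    cols_file.write_text("\n".join(map(str, col_ids)) + "\n")


# ---------------------------------------------------------------------------
# RelationMatrix-level API
# ---------------------------------------------------------------------------

def read_relation(path: str | Path, format: str, source: str, target: str,
                  label: str | None = None, missing: str = "zero") -> RelationMatrix:
    """Load one relation matrix from disk.

    ``format`` is ``"dense-delimited"`` or ``"sparse-coordinate"``.  The
    chosen sparse missingness policy is recorded on the returned object.
    """
    path = Path(path)
    if not path.exists():
        raise MatrixLoadError(f"relation file not found: {path}")
    if format in ("dense-delimited", "dense"):
        values, mask, row_ids, col_ids = read_dense(path)
        policy = "zero"
    elif format in ("sparse-coordinate", "sparse"):
        values, mask, row_ids, col_ids = read_sparse(path, missing=missing)
        policy = missing
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return RelationMatrix(source=source, target=target,
                          label=label or path.stem, values=values, mask=mask,
                          row_ids=row_ids, col_ids=col_ids,
                          missing_policy=policy)


def write_relation(path: str | Path, relation: RelationMatrix,
                   format: str = "dense-delimited") -> None:
    row_ids = relation.row_ids or [str(i) for i in range(relation.shape[0])]
    col_ids = relation.col_ids or [str(j) for j in range(relation.shape[1])]
    if format in ("dense-delimited", "dense"):
        write_dense(path, relation.values, relation.mask, row_ids, col_ids)
    elif format in ("sparse-coordinate", "sparse"):
        write_sparse(path, relation.values, relation.mask, row_ids, col_ids)
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def reindex_relation(relation: RelationMatrix, row_ids, col_ids) -> RelationMatrix:
    """Re-order a relation's rows/columns to the declared identifier order.

    The file's identifiers must be a permutation of the declared ones;
    anything else is a load error naming the offending axis.
    """
    row_ids = tuple(map(str, row_ids))
    col_ids = tuple(map(str, col_ids))
    rel = relation
    for axis, have, want in (("row", rel.row_ids, row_ids),
                             ("column", rel.col_ids, col_ids)):
        if have is None:
            continue
        if sorted(have) != sorted(want):
            missing = sorted(set(want) - set(have))[:5]
            extra = sorted(set(have) - set(want))[:5]
            raise MatrixLoadError(
                f"relation {rel.label!r}: {axis} identifiers do not match the "
                f"declared type (missing {missing}, unexpected {extra})"
            )
    values, mask = rel.values, rel.mask
    if rel.row_ids is not None and rel.row_ids != row_ids:
        order = [rel.row_ids.index(i) for i in row_ids]
        values, mask = values[order, :], mask[order, :]
    if rel.col_ids is not None and rel.col_ids != col_ids:
        order = [rel.col_ids.index(j) for j in col_ids]
        values, mask = values[:, order], mask[:, order]
    return dataclasses.replace(rel, values=values, mask=mask,
                               row_ids=row_ids, col_ids=col_ids)


# ---------------------------------------------------------------------------
# graph configuration
# ---------------------------------------------------------------------------

def _read_ids(entry: dict, base: Path) -> tuple[str, ...]:
    if "ids" in entry:
        return tuple(map(str, entry["ids"]))
    if "ids_file" in entry:
        return tuple((base / entry["ids_file"]).read_text().split())
    raise GraphConfigError(
        f"type {entry.get('name')!r}: provide either 'ids' or 'ids_file'")


def load_graph(config: str | Path) -> FusionGraph:
    """Load and validate a full fusion graph from a YAML configuration.

    Relation entries accept ``label, source, target, path, format,
    normalize, missing``; constraint entries ``type, path, scale, index``.
    Relative paths are resolved against the configuration file's directory.
    Row normalization is applied where requested, after re-indexing to the
    declared identifier order.
    """
    config = Path(config)
    doc = yaml.safe_load(config.read_text())
    if not isinstance(doc, dict):
        raise GraphConfigError(f"{config}: configuration must be a mapping")
    base = config.parent

    types: dict[str, ObjectType] = {}
    for entry in doc.get("types", []):
        name = str(entry["name"])
        if name in types:
            raise GraphConfigError(f"duplicate type declaration {name!r}")
        types[name] = ObjectType(name=name, ids=_read_ids(entry, base))

    relations = []
    for entry in doc.get("relations", []) or []:
        source, target = str(entry["source"]), str(entry["target"])
        for name in (source, target):
            if name not in types:
                raise GraphConfigError(
                    f"relation {entry.get('label')!r} references undeclared "
                    f"type {name!r}"
                )
        rel = read_relation(base / entry["path"],
                            entry.get("format", "dense-delimited"),
                            source, target,
                            label=entry.get("label"),
                            missing=entry.get("missing", "zero"))
        rel = reindex_relation(rel, types[source].ids, types[target].ids)
        if entry.get("normalize", False):
            rel = normalize_rows(rel)
        relations.append(rel)

    constraints = []
    for idx, entry in enumerate(doc.get("constraints", []) or []):
        tname = str(entry["type"])
        if tname not in types:
            raise GraphConfigError(
                f"constraint references undeclared type {tname!r}")
        values, mask, row_ids, col_ids = read_dense(base / entry["path"])
        if row_ids != types[tname].ids or col_ids != types[tname].ids:
            con_rel = RelationMatrix(source=tname, target=tname,
                                     label=f"constraint-{idx}", values=values,
                                     mask=mask, row_ids=row_ids, col_ids=col_ids)
            con_rel = reindex_relation(con_rel, types[tname].ids, types[tname].ids)
            values = con_rel.values
        values = symmetrize(values, label=f"constraint on {tname!r}")
        values = values * float(entry.get("scale", 1.0))
        constraints.append(ConstraintMatrix(type=tname, values=values,
                                            index=int(entry.get("index", idx))))

    target = doc.get("target", "")
    return FusionGraph(types=types, relations=relations,
                       constraints=constraints, target=str(target))


def write_graph(graph: FusionGraph, out_dir: str | Path,
                format: str = "dense-delimited") -> Path:
    """Write a fusion graph (matrices + YAML config) into a directory.

    Returns the path of the written configuration file; ``load_graph`` on it
    round-trips the graph.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if format in ("dense-delimited", "dense") else ".mtx"
    doc: dict = {"target": graph.target, "types": [], "relations": [],
                 "constraints": []}
    for name, typ in graph.types.items():
        ids_file = f"ids_{name}.txt"
        (out_dir / ids_file).write_text("\n".join(typ.ids) + "\n")
        doc["types"].append({"name": name, "ids_file": ids_file})
    for rel in graph.relations:
        fname = f"R_{rel.label}{ext}"
        rel_out = dataclasses.replace(
            rel, row_ids=graph.types[rel.source].ids,
            col_ids=graph.types[rel.target].ids)
        write_relation(out_dir / fname, rel_out, format=format)
        entry = {"label": rel.label, "source": rel.source,
                 "target": rel.target, "path": fname, "format": format}
        if format in ("sparse-coordinate", "sparse"):
            entry["missing"] = "unobserved" if not rel.fully_observed else "zero"
        doc["relations"].append(entry)
    for con in graph.constraints:
        fname = f"Theta_{con.type}_{con.index}.tsv"
        ids = graph.types[con.type].ids
        write_dense(out_dir / fname, con.values, None, ids, ids)
        doc["constraints"].append({"type": con.type, "path": fname,
                                   "index": con.index})
    config_path = out_dir / "graph.yaml"
    config_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return config_path
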