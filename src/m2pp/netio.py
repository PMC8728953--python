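"""Domain containers and delimited-text I/O for heterogeneous networks.

The analysis operates on three entity sets — drug-targeted proteins
("targets"), diseases and drugs — joined by three binary association layers
(target–disease, target–drug, disease–drug) and per-type similarity layers.
All matrices in one run share a single canonical index space per entity kind,
fixed by an :class:`EntityRegistry`.

File formats are deliberately plain: two-column TSV edge lists for binary
associations, TSV matrices with an id header row/column for similarities,
and ``disease<TAB>category`` lines for disease category annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
DIAGONAL_TOL = 1e-8
RANGE_TOL = 1e-12

__all__ = [
    "EntityRegistry",
    "AssociationMatrix",
    "SimilarityMatrix",
    "CategoryAnnotation",
    "HeterogeneousNetwork",
    "read_id_list",
    "read_edge_list",
    "write_edge_list",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_categories",
    "network_summary",
    "write_scores",
]


class NetworkFormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered registry of unique entity identifiers of one kind.

    The registry fixes the 0-based index every matrix over this entity set
    uses; ``index`` is the exact inverse of ``ids``.  Identifiers are opaque
    strings (gene symbols, MeSH ids, DrugBank accessions — the method never
    interprets them).
    """

    kind: str
    ids: tuple[str, ...]
    index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in {"target", "disease", "drug"}:
            raise ValueError(f"unknown entity kind {self.kind!r}")
        if not self.ids:
            raise ValueError("registry must contain at least one id")
        if any(not i for i in self.ids):
            raise ValueError("empty identifier in registry")
        index = {eid: k for k, eid in enumerate(self.ids)}
        if len(index) != len(self.ids):
            raise ValueError("duplicate identifiers in registry")
        object.__setattr__(self, "index", index)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, eid: str) -> bool:
        return eid in self.index


def read_id_list(path: str | Path, kind: str) -> EntityRegistry:
    """Read one identifier per line (``#`` comments skipped) into a registry.

    Entity ordering is the order of first appearance in the file.
    """
    ids: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line not in seen:
            seen.add(line)
            ids.append(line)
    return EntityRegistry(kind=kind, ids=tuple(ids))


def _as_binary(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("association matrix entries must be exactly 0 or 1")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary adjacency matrix of one bipartite association layer."""

    rows: EntityRegistry
    cols: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_binary(self.values)
        if arr.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"matrix shape {arr.shape} does not match registries "
                f"({len(self.rows)}, {len(self.cols)})"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n_edges(self) -> int:
        return int(self.values.sum())

    @property
    def size(self) -> int:
        return self.values.size

    @property
    def sparsity(self) -> float:
        """Edge count over matrix size (unrounded)."""
        return self.n_edges / self.size


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    entities: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        n = len(self.entities)
        if arr.shape != (n, n):
            raise ValueError(f"matrix shape {arr.shape} does not match registry ({n})")
        if arr.min() < -RANGE_TOL or arr.max() > 1 + RANGE_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        if np.abs(arr - arr.T).max() > SYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric beyond {SYMMETRY_TOL}")
        if np.abs(np.diagonal(arr) - 1.0).max() > DIAGONAL_TOL:
            raise ValueError("similarity matrix diagonal must equal 1")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.entities)


@dataclass(frozen=True)
class CategoryAnnotation:
    """Disease id → set of category codes (a disease may carry several)."""

    diseases: EntityRegistry
    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for did in self.mapping:
            if did not in self.diseases:
                raise ValueError(f"annotated disease {did!r} not in registry")

    def codes(self) -> tuple[str, ...]:
        return tuple(sorted({c for cs in self.mapping.values() for c in cs}))

    def diseases_in(self, code: str) -> list[str]:
        return [d for d in self.diseases.ids if code in self.mapping.get(d, ())]


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """The three entity registries plus the three binary association layers."""

    targets: EntityRegistry
    diseases: EntityRegistry
    drugs: EntityRegistry
    tda: AssociationMatrix  # target–disease associations
    tdi: AssociationMatrix  # target–drug interactions
    dda: AssociationMatrix  # disease–drug associations

    def __post_init__(self) -> None:
        pairs = {
            "tda": (self.tda, self.targets, self.diseases),
            "tdi": (self.tdi, self.targets, self.drugs),
            "dda": (self.dda, self.diseases, self.drugs),
        }
        for name, (mat, rows, cols) in pairs.items():
            if mat.rows is not rows and mat.rows.ids != rows.ids:
                raise ValueError(f"{name} row registry mismatch")
            if mat.cols is not cols and mat.cols.ids != cols.ids:
                raise ValueError(f"{name} column registry mismatch")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)


def read_edge_list(
    path: str | Path, rows: EntityRegistry, cols: EntityRegistry
) -> AssociationMatrix:
    """Read a two-column TSV edge list into a binary association matrix.

    Each non-comment line is ``row_id<TAB>col_id``.  Duplicate pairs collapse
    to a single 1 (a warning reports the count); unlisted pairs are 0.
    """
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise NetworkFormatError(
                    f"{path}: malformed line {lineno}: expected "
                    f"'row_id<TAB>col_id', got {line!r}"
                )
            rid, cid = parts[0], parts[1]
            if rid not in rows:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: unknown {rows.kind} id {rid!r}"
                )
            if cid not in cols:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: unknown {cols.kind} id {cid!r}"
                )
            i, j = rows.index[rid], cols.index[cid]
            if values[i, j]:
                n_dup += 1
            values[i, j] = 1
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edges", path, n_dup)
    return AssociationMatrix(rows=rows, cols=cols, values=values)


def write_edge_list(path: str | Path, matrix: AssociationMatrix) -> None:
    """Write an association matrix as a two-column TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {matrix.rows.kind}_id\t{matrix.cols.kind}_id\n")
        for i, j in zip(*np.nonzero(matrix.values)):
            fh.write(f"{matrix.rows.ids[i]}\t{matrix.cols.ids[j]}\n")


def read_similarity_matrix(
    path: str | Path, entities: EntityRegistry
) -> SimilarityMatrix:
    """Read a TSV similarity matrix (id header row and column).

    Rows/columns are re-permuted to registry order before validation, so the
    file's own ordering is irrelevant.  Asymmetry beyond 1e-8, entries outside
    [0, 1] and off-unit diagonals are rejected.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    missing = [e for e in entities.ids if e not in frame.index]
    if missing:
        raise NetworkFormatError(f"{path}: missing entities {missing[:5]}")
    unknown = [e for e in frame.index if e not in entities]
    if unknown:
        raise NetworkFormatError(f"{path}: unknown entities {unknown[:5]}")
    frame = frame.loc[list(entities.ids), list(entities.ids)]
    return SimilarityMatrix(entities=entities, values=frame.to_numpy(dtype=float))


def write_similarity_matrix(path: str | Path, matrix: SimilarityMatrix) -> None:
    """Write a similarity matrix as TSV with id header row/column.

    Values are written with 17 significant digits so a read round-trips
    exactly.
    """
    frame = pd.DataFrame(
        matrix.values, index=matrix.entities.ids, columns=matrix.entities.ids
    )
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_categories(path: str | Path, diseases: EntityRegistry) -> CategoryAnnotation:
    """Read ``disease_id<TAB>category_code`` lines (one category per line)."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise NetworkFormatError(
                    f"{path}: malformed line {lineno}: {line!r}"
                )
            did, code = parts[0], parts[1]
            if did not in diseases:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: unknown disease id {did!r}"
                )
            mapping.setdefault(did, set()).add(code)
    return CategoryAnnotation(
        diseases=diseases,
        mapping={d: frozenset(c) for d, c in mapping.items()},
    )


def network_summary(net: HeterogeneousNetwork) -> pd.DataFrame:
    """Characteristics of the six network layers.

    For the three association layers: size (|rows|·|cols|), edge count and
    sparsity = edges / size rounded to 3 decimals.  The three similarity
    layers are complete weighted graphs, so the edge count is n·n and the
    sparsity 1.
    """
    nT, nD, nM = net.n_targets, net.n_diseases, net.n_drugs
    rows = []
    for name, mat in [
        ("target-disease association", net.tda),
        ("target-drug interaction", net.tdi),
        ("disease-drug association", net.dda),
    ]:
        rows.append(
            {
                "network": name,
                "size": mat.size,
                "n_edges": mat.n_edges,
                "weight_range": "0 or 1",
                "sparsity": round(mat.sparsity, 3),
            }
        )
    for name, n in [
        ("disease-disease similarity", nD),
        ("target-target similarity", nT),
        ("drug-drug similarity", nM),
    ]:
        rows.append(
            {
                "network": name,
                "size": n * n,
                "n_edges": n * n,
                "weight_range": "[0,1]",
                "sparsity": 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("network")


def write_scores(
    path: str | Path,
    scored_pairs: Iterable[tuple[str, str, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Write scored target–disease pairs ranked by descending score.

    Ties are broken deterministically by (target id, disease id).  Returns the
    ranked frame that was written.
    """
    if isinstance(scored_pairs, pd.DataFrame):
        frame = scored_pairs[["target_id", "disease_id", "score"]].copy()
    else:
        frame = pd.DataFrame(
            list(scored_pairs), columns=["target_id", "disease_id", "score"]
        )
    frame = frame.sort_values(
        by=["score", "target_id", "disease_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return frame
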