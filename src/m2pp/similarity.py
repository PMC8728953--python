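"""Similarity-layer construction: GIP kernels and entropy-based fusion.

Two similarity sources exist per entity type: a *semantic* matrix supplied as
input (ontology / sequence based, computed upstream) and a *topological*
matrix derived here from the binary association profiles via the Gaussian
interaction-profile (GIP) kernel,

    S[i, j] = exp(-k * ||p_i - p_j||^2),    k = k' / mean_k ||p_k||^2,

where p_i is entity i's binary association profile and the bandwidth scale
k' defaults to 1.  The two sources are merged per entity by an entropy rule:
Shannon row entropy measures how diffuse each entity's similarity profile is,
and for every row (and every cross-block row) the matrix with the lower
entropy — the less "random" one — is selected, block-assembled into one
symmetric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import AssociationMatrix, EntityRegistry, SimilarityMatrix

__all__ = [
    "GipParams",
    "EntropyPartition",
    "gip_kernel",
    "gip_similarity",
    "average_semantic",
    "row_entropy",
    "entropy_partition",
    "entropy_fuse",
]


@dataclass(frozen=True)
class GipParams:
    """Bandwidth scale k' of the GIP kernel; the effective bandwidth is
    derived from the profile matrix at every call (never cached across
    masked/unmasked variants of the association matrix)."""

    bandwidth_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.bandwidth_scale > 0:
            raise ValueError("bandwidth_scale must be positive")


@dataclass(frozen=True)
class EntropyPartition:
    """Index sets of the two-level entropy partition.

    ``set_a``/``set_b`` split all entities by full-row entropy comparison
    (semantic wins ties); ``set_a_a``/``set_a_b`` split ``set_a`` again by the
    entropies of the rectangular cross blocks against ``set_b``.
    """

    set_a: np.ndarray
    set_b: np.ndarray
    set_a_a: np.ndarray
    set_a_b: np.ndarray

    def __post_init__(self) -> None:
        a, b = set(self.set_a.tolist()), set(self.set_b.tolist())
        aa, ab = set(self.set_a_a.tolist()), set(self.set_a_b.tolist())
        if a & b or (aa | ab) != a or aa & ab:
            raise ValueError("invalid entropy partition")


def gip_kernel(profiles: np.ndarray, bandwidth_scale: float = 1.0) -> np.ndarray:
    """GIP kernel over the *rows* of ``profiles``.

    Raises if every profile is zero (the mean squared norm, hence the
    bandwidth, would be undefined).
    """
    X = np.asarray(profiles, dtype=float)
    sq_norms = (X * X).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError("undefined bandwidth: all profiles are zero")
    k = bandwidth_scale / mean_sq
    # exact-symmetric squared distances via the Gram matrix
    gram = X @ X.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    d2 = np.maximum((d2 + d2.T) / 2.0, 0.0)
    np.fill_diagonal(d2, 0.0)
    S = np.exp(-k * d2)
    np.fill_diagonal(S, 1.0)
    return S


def gip_similarity(
    profiles: AssociationMatrix,
    axis: str = "columns",
    params: GipParams | None = None,
) -> SimilarityMatrix:
    """Topological similarity of one entity set from its association profiles.

    ``axis="columns"`` treats each column as an entity profile (disease or
    drug profiles of a target-row matrix); ``axis="rows"`` the converse.
    """
    params = params or GipParams()
    if axis == "columns":
        entities, mat = profiles.cols, profiles.values.T
    elif axis == "rows":
        entities, mat = profiles.rows, profiles.values
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    return SimilarityMatrix(
        entities=entities, values=gip_kernel(mat, params.bandwidth_scale)
    )


def _check_same_registry(s1: SimilarityMatrix, s2: SimilarityMatrix) -> EntityRegistry:
    if s1.entities is not s2.entities and s1.entities.ids != s2.entities.ids:
        raise ValueError("similarity matrices cover different entity registries")
    return s1.entities


def average_semantic(s1: SimilarityMatrix, s2: SimilarityMatrix) -> SimilarityMatrix:
    """Entrywise mean of two similarity matrices over the same registry.

    This is how the two disease semantic similarities (and the target
    sequence + functional similarities) are combined into one semantic layer.
    """
    entities = _check_same_registry(s1, s2)
    return SimilarityMatrix(entities=entities, values=(s1.values + s2.values) / 2.0)


def row_entropy(W: np.ndarray) -> np.ndarray:
    """Shannon entropy of each row of a nonnegative matrix (natural log).

    Rows are normalised to probability vectors; 0·log 0 contributes 0 and a
    row summing to zero gets entropy 0.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.size and W.min() < 0:
        raise ValueError("row_entropy requires nonnegative entries")
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    sums = W.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sums > 0, W / np.where(sums > 0, sums, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=1)


def entropy_partition(
    s_sem: SimilarityMatrix, s_top: SimilarityMatrix
) -> EntropyPartition:
    """Two-level partition of the registry by row-entropy comparison.

    Level 1 compares full-matrix row entropies (ties → semantic set A).
    Level 2 re-compares the entropies of the rectangular cross blocks
    ``S[A, B]``; when B is empty those rows have entropy 0 on both sides and
    the tie rule puts all of A into A_a.
    """
    _check_same_registry(s_sem, s_top)
    e_sem = row_entropy(s_sem.values)
    e_top = row_entropy(s_top.values)
    in_a = e_sem <= e_top
    set_a = np.flatnonzero(in_a)
    set_b = np.flatnonzero(~in_a)
    e_sem_ab = row_entropy(s_sem.values[np.ix_(set_a, set_b)])
    e_top_ab = row_entropy(s_top.values[np.ix_(set_a, set_b)])
    in_aa = e_sem_ab <= e_top_ab
    return EntropyPartition(
        set_a=set_a,
        set_b=set_b,
        set_a_a=set_a[in_aa],
        set_a_b=set_a[~in_aa],
    )


def entropy_fuse(
    s_sem: SimilarityMatrix, s_top: SimilarityMatrix
) -> SimilarityMatrix:
    """Fuse a semantic and a topological similarity matrix by entropy.

    With partition (A, B, A_a, A_b): the A×A block comes from the semantic
    matrix, B×B from the topological one; within the A×B cross block, rows in
    A_a come from the semantic matrix and rows in A_b from the topological
    one; the B×A block is the transpose of A×B, which guarantees symmetry.
    Every entry of the result therefore equals the corresponding entry of one
    of the two inputs, and the output is returned in registry order.
    """
    entities = _check_same_registry(s_sem, s_top)
    part = entropy_partition(s_sem, s_top)
    A, B = part.set_a, part.set_b
    F = np.empty_like(s_sem.values)
    F[np.ix_(A, A)] = s_sem.values[np.ix_(A, A)]
    F[np.ix_(B, B)] = s_top.values[np.ix_(B, B)]
    F[np.ix_(part.set_a_a, B)] = s_sem.values[np.ix_(part.set_a_a, B)]
    F[np.ix_(part.set_a_b, B)] = s_top.values[np.ix_(part.set_a_b, B)]
    F[np.ix_(B, A)] = F[np.ix_(A, B)].T
    return SimilarityMatrix(entities=entities, values=F)
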