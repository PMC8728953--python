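"""Literal-definition reference implementations (validation oracles).

Every function here follows the printed set/summation definitions with plain
Python loops, with no shared code with the production implementations in
:mod:`m2pp.similarity` and :mod:`m2pp.features`.  They are deliberately slow
and exist so the vectorised implementations can be held to the definitions
on small random instances.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "row_entropy_ref",
    "entropy_fuse_ref",
    "features_ref",
    "auroc_ref",
    "aupr_ref",
]


def row_entropy_ref(W: np.ndarray) -> list[float]:
    """Per-row Shannon entropy by direct summation (natural log)."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    out = []
    for row in W:
        total = float(sum(row))
        e = 0.0
        if total > 0:
            for w in row:
                p = w / total
                if p > 0:
                    e -= p * math.log(p)
        out.append(e)
    return out


def entropy_fuse_ref(S_sem: np.ndarray, S_top: np.ndarray) -> np.ndarray:
    """Entropy-based fusion by explicit set construction and block assembly."""
    S_sem = np.asarray(S_sem, dtype=float)
    S_top = np.asarray(S_top, dtype=float)
    n = S_sem.shape[0]
    e_sem = row_entropy_ref(S_sem)
    e_top = row_entropy_ref(S_top)
    A = [i for i in range(n) if e_sem[i] <= e_top[i]]
    B = [i for i in range(n) if e_top[i] < e_sem[i]]
    e_sem_ab = row_entropy_ref(S_sem[np.ix_(A, B)]) if A else []
    e_top_ab = row_entropy_ref(S_top[np.ix_(A, B)]) if A else []
    A_a = [A[k] for k in range(len(A)) if e_sem_ab[k] <= e_top_ab[k]]
    A_b = [A[k] for k in range(len(A)) if e_top_ab[k] < e_sem_ab[k]]
    F = np.zeros_like(S_sem)
    for i in A:
        for j in A:
            F[i, j] = S_sem[i, j]
    for i in B:
        for j in B:
            F[i, j] = S_top[i, j]
    for i in A:
        src = S_sem if i in A_a else S_top
        for j in B:
            F[i, j] = src[i, j]
            F[j, i] = src[i, j]
    return F


def features_ref(
    i: int,
    j: int,
    TDA: np.ndarray,
    TDI: np.ndarray,
    DDA: np.ndarray,
    TTS: np.ndarray,
    DDS: np.ndarray,
    MMS_T: np.ndarray,
    MMS_D: np.ndarray,
    exclude_self: bool = False,
) -> list[float]:
    """All nine features for pair (i, j) by exhaustive loops over the sets.

    With ``exclude_self`` the query target/disease are barred from every
    neighborhood and intermediate path position.
    """
    nT, nD = TDA.shape
    nM = TDI.shape[1]
    ex = exclude_self

    P = [y for y in range(nD) if TDA[i, y] == 0 and not (ex and y == j)]
    fea1 = sum(DDS[y, j] for y in P) / len(P) if P else 0.0
    Q = [x for x in range(nT) if TDA[x, j] == 0 and not (ex and x == i)]
    fea2 = sum(TTS[i, x] for x in Q) / len(Q) if Q else 0.0

    a = max((x for x in range(nT) if x != i), key=lambda x: (TTS[i, x], -x))
    b = max((y for y in range(nD) if y != j), key=lambda y: (DDS[y, j], -y))
    fea3 = (
        TTS[i, a] * TDA[a, j]
        + TDA[i, b] * DDS[b, j]
        + TTS[i, a] * TDA[a, b] * DDS[b, j]
    )

    K = [z for z in range(nM) if TDI[i, z] == 1 and DDA[j, z] == 1]
    fea4 = 0.0
    for k in K:
        h_num = sum(TDI[i, x] * MMS_T[x, k] for x in range(nM))
        h_den = len([x for x in range(nM) if TDI[i, x] == 1 and MMS_T[x, k] != 0])
        l_num = sum(DDA[j, y] * MMS_D[y, k] for y in range(nM))
        l_den = len([y for y in range(nM) if DDA[j, y] == 1 and MMS_D[y, k] != 0])
        H = h_num / h_den
        L = l_num / l_den if l_den else 0.0
        fea4 = max(fea4, L / H)

    xs5 = [x for x in range(nT) if not (ex and x == i)]
    num5 = sum(TTS[i, x] * TDA[x, j] for x in xs5)
    den5 = len([x for x in xs5 if TTS[i, x] != 0 and TDA[x, j] == 1])
    fea5 = num5 / den5 if den5 else 0.0
    ys6 = [y for y in range(nD) if not (ex and y == j)]
    num6 = sum(TDA[i, y] * DDS[y, j] for y in ys6)
    den6 = len([y for y in ys6 if TDA[i, y] == 1 and DDS[y, j] != 0])
    fea6 = num6 / den6 if den6 else 0.0

    num7 = den7 = 0.0
    for x in range(nT):
        for s in range(nT):
            if ex and (x == i or s == i):
                continue
            num7 += TTS[i, x] * TTS[x, s] * TDA[s, j]
            if TTS[i, x] != 0 and TTS[x, s] != 0 and TDA[s, j] == 1:
                den7 += 1
    fea7 = num7 / den7 if den7 else 0.0

    num8 = den8 = 0.0
    for x in range(nT):
        for y in range(nD):
            if ex and (x == i or y == j):
                continue
            num8 += TTS[i, x] * TDA[x, y] * DDS[y, j]
            if TTS[i, x] != 0 and TDA[x, y] == 1 and DDS[y, j] != 0:
                den8 += 1
    fea8 = num8 / den8 if den8 else 0.0

    num9 = den9 = 0.0
    for y in range(nD):
        for t in range(nD):
            if ex and (y == j or t == j):
                continue
            num9 += TDA[i, y] * DDS[y, t] * DDS[t, j]
            if TDA[i, y] == 1 and DDS[y, t] != 0 and DDS[t, j] != 0:
                den9 += 1
    fea9 = num9 / den9 if den9 else 0.0

    return [float(v) for v in (fea1, fea2, fea3, fea4, fea5, fea6, fea7, fea8, fea9)]


def auroc_ref(labels, scores) -> float:
    """AUROC as the probability of correct ranking over all +/- pairs
    (ties count one half)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def aupr_ref(labels, scores) -> float:
    """Area under the precision–recall curve by an explicit threshold sweep
    over the distinct scores (rectangular step interpolation)."""
    labels = list(labels)
    scores = list(scores)
    n_pos = sum(labels)
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for y, s in zip(labels, scores) if s >= thr and y == 1)
        fp = sum(1 for y, s in zip(labels, scores) if s >= thr and y == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
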