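"""The nine-dimensional feature vector for a target–disease pair.

Three information channels feed the feature vector of a pair (t_i, d_j):

* neighborhood similarity (fea1–fea3): average similarity between the query
  entities and their not-yet-associated neighborhoods, plus a nearest-
  neighbor path score;
* drug-inferred information (fea4): the best ratio of disease–drug to
  target–drug average path weight over drugs co-associated with both query
  entities;
* path information (fea5–fea9): average edge-weight products over all
  length-2 and length-3 meta-paths of fixed patterns (e.g.
  target–target–disease), where each average divides the weighted path sum
  by the number of admissible paths.

Empty sets and 0/0 averages evaluate to 0 ("no evidence"), keeping every
feature finite and nonnegative; fea1/fea2 are means of [0, 1] similarities
and fea3 is bounded by 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .netio import HeterogeneousNetwork, SimilarityMatrix

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "fea_neighborhood",
    "fea_nearest_path",
    "fea_drug_inferred",
    "fea_path2",
    "fea_path3",
    "pair_features",
    "feature_matrices",
    "build_feature_table",
]

FEATURE_NAMES: tuple[str, ...] = tuple(f"fea{k}" for k in range(1, 10))


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the 0/0 (and x/0) convention → 0."""
    out = np.zeros(np.broadcast(num, den).shape)
    np.divide(num, den, out=out, where=den != 0)
    return out


def fea_neighborhood(
    i: int,
    j: int,
    TDA: np.ndarray,
    DDS: np.ndarray,
    TTS: np.ndarray,
    exclude_self: bool = False,
) -> tuple[float, float]:
    """fea1/fea2: average similarity to the unassociated neighborhoods.

    fea1 averages DDS[y, j] over diseases y without a known association to
    target i; fea2 averages TTS[i, x] over targets x without a known
    association to disease j.  With ``exclude_self`` the query entities
    themselves (y=j, x=i) are dropped from the neighborhoods.
    """
    P = TDA[i, :] == 0
    Q = TDA[:, j] == 0
    if exclude_self:
        P = P.copy()
        Q = Q.copy()
        P[j] = False
        Q[i] = False
    fea1 = float(DDS[P, j].mean()) if P.any() else 0.0
    fea2 = float(TTS[i, Q].mean()) if Q.any() else 0.0
    return fea1, fea2


def fea_nearest_path(
    i: int, j: int, TDA: np.ndarray, DDS: np.ndarray, TTS: np.ndarray
) -> float:
    """fea3: path weights through the nearest target / disease neighbor.

    a is the target most similar to i (excluding i itself), b the disease
    most similar to j (excluding j); the score sums the t_i–t_a–d_j,
    t_i–d_b–d_j and t_i–t_a–d_b–d_j path weights.  Argmax ties break to the
    smallest index.
    """
    nT, nD = TDA.shape
    if nT < 2 or nD < 2:
        raise ValueError("fea3 requires at least two targets and two diseases")
    trow = TTS[i, :].copy()
    trow[i] = -np.inf
    a = int(np.argmax(trow))
    dcol = DDS[:, j].copy()
    dcol[j] = -np.inf
    b = int(np.argmax(dcol))
    return float(
        TTS[i, a] * TDA[a, j]
        + TDA[i, b] * DDS[b, j]
        + TTS[i, a] * TDA[a, b] * DDS[b, j]
    )


def _drug_path_weights(assoc: np.ndarray, MMS: np.ndarray) -> np.ndarray:
    """Average entity–drug path weight matrix: (assoc @ MMS) over the count of
    associated drugs with a nonzero similarity to the endpoint drug."""
    num = assoc.astype(float) @ MMS
    den = assoc.astype(float) @ (MMS != 0)
    return _safe_div(num, den)


def fea_drug_inferred(
    i: int,
    j: int,
    TDI: np.ndarray,
    DDA: np.ndarray,
    MMS_T: np.ndarray,
    MMS_D: np.ndarray,
) -> float:
    """fea4: best disease-path/target-path weight ratio over co-associated
    drugs (drugs linked to both the target and the disease); 0 when none."""
    K = np.flatnonzero((TDI[i, :] == 1) & (DDA[j, :] == 1))
    if K.size == 0:
        return 0.0
    H = _drug_path_weights(TDI[i : i + 1, :], MMS_T)[0]
    L = _drug_path_weights(DDA[j : j + 1, :], MMS_D)[0]
    return float(np.max(L[K] / H[K]))


def fea_path2(
    i: int,
    j: int,
    TDA: np.ndarray,
    DDS: np.ndarray,
    TTS: np.ndarray,
    exclude_self: bool = False,
) -> tuple[float, float]:
    """fea5/fea6: average weight of length-2 paths.

    fea5 follows target–target–disease (TTS edge then TDA edge), fea6
    target–disease–disease (TDA then DDS); each divides the weighted path
    sum by the number of admissible paths.
    """
    tts_row = TTS[i, :].astype(float)
    tda_row = TDA[i, :].astype(float)
    dds_col = DDS[:, j].astype(float)
    if exclude_self:
        tts_row = tts_row.copy()
        tts_row[i] = 0.0
        dds_col = dds_col.copy()
        dds_col[j] = 0.0
    num5 = float(tts_row @ TDA[:, j])
    den5 = int(np.count_nonzero((tts_row != 0) & (TDA[:, j] == 1)))
    num6 = float(tda_row @ dds_col)
    den6 = int(np.count_nonzero((tda_row == 1) & (dds_col != 0)))
    return (num5 / den5 if den5 else 0.0, num6 / den6 if den6 else 0.0)


def fea_path3(
    i: int,
    j: int,
    TDA: np.ndarray,
    DDS: np.ndarray,
    TTS: np.ndarray,
    exclude_self: bool = False,
) -> tuple[float, float, float]:
    """fea7/fea8/fea9: average weight of length-3 paths.

    Patterns: target–target–target–disease, target–target–disease–disease,
    target–disease–disease–disease.  Counts run over the admissible
    intermediate pairs.  With ``exclude_self`` the query entities are barred
    from every intermediate position (paths may not revisit i or j).
    """
    TTSf = TTS.astype(float)
    DDSf = DDS.astype(float)
    TDAf = TDA.astype(float)
    tts_row = TTSf[i, :]      # first hop of fea7/fea8 (position x)
    dds_col = DDSf[:, j]      # last hop of fea8/fea9 (positions y / t)
    tda_row = TDAf[i, :]      # first hop of fea9 (position y)
    tda_col = TDAf[:, j]      # last hop of fea7 (position s)
    if exclude_self:
        # bar the query entities from every intermediate position: each
        # position is gated by exactly one of the four outer vectors
        tts_row = tts_row.copy(); tts_row[i] = 0.0
        dds_col = dds_col.copy(); dds_col[j] = 0.0
        tda_row = tda_row.copy(); tda_row[j] = 0.0
        tda_col = tda_col.copy(); tda_col[i] = 0.0
    tts_row_nz = (tts_row != 0).astype(float)
    dds_col_nz = (dds_col != 0).astype(float)
    tts_nz = (TTSf != 0).astype(float)
    dds_nz = (DDSf != 0).astype(float)

    num7 = float(tts_row @ TTSf @ tda_col)
    den7 = float(tts_row_nz @ tts_nz @ tda_col)
    num8 = float(tts_row @ TDAf @ dds_col)
    den8 = float(tts_row_nz @ TDAf @ dds_col_nz)
    num9 = float(tda_row @ DDSf @ dds_col)
    den9 = float(tda_row @ dds_nz @ dds_col_nz)
    return (
        num7 / den7 if den7 else 0.0,
        num8 / den8 if den8 else 0.0,
        num9 / den9 if den9 else 0.0,
    )


def pair_features(
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
) -> np.ndarray:
    """The full 9-vector for one pair, composing the five feature operations."""
    f1, f2 = fea_neighborhood(i, j, TDA, DDS, TTS, exclude_self)
    f3 = fea_nearest_path(i, j, TDA, DDS, TTS)
    f4 = fea_drug_inferred(i, j, TDI, DDA, MMS_T, MMS_D)
    f5, f6 = fea_path2(i, j, TDA, DDS, TTS, exclude_self)
    f7, f8, f9 = fea_path3(i, j, TDA, DDS, TTS, exclude_self)
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9])


def feature_matrices(
    TDA: np.ndarray,
    TDI: np.ndarray,
    DDA: np.ndarray,
    TTS: np.ndarray,
    DDS: np.ndarray,
    MMS_T: np.ndarray,
    MMS_D: np.ndarray,
    exclude_self: bool = False,
) -> np.ndarray:
    """All nine features for every (target, disease) pair at once.

    Returns an array of shape (nT, nD, 9).  This vectorised path is
    algebraically identical to composing the per-pair operations (the test
    suite holds it to the literal set definitions); use it whenever a whole
    score matrix is needed, e.g. inside cross-validation.

    With ``exclude_self`` the query entities are removed from every
    neighborhood/intermediate position via inclusion–exclusion on the matrix
    products (both similarity matrices have unit diagonals, which the
    correction terms rely on).
    """
    TDAf = np.asarray(TDA, dtype=float)
    TDIf = np.asarray(TDI, dtype=float)
    DDAf = np.asarray(DDA, dtype=float)
    TTSf = np.asarray(TTS, dtype=float)
    DDSf = np.asarray(DDS, dtype=float)
    nT, nD = TDAf.shape
    if nT < 2 or nD < 2:
        raise ValueError("feature_matrices requires nT >= 2 and nD >= 2")
    out = np.empty((nT, nD, 9))

    comp = 1.0 - TDAf  # indicator of unassociated pairs
    if exclude_self:
        out[:, :, 0] = _safe_div(
            comp @ DDSf - comp, comp.sum(axis=1, keepdims=True) - comp
        )
        out[:, :, 1] = _safe_div(
            TTSf @ comp - comp, comp.sum(axis=0, keepdims=True) - comp
        )
    else:
        out[:, :, 0] = _safe_div(comp @ DDSf, comp.sum(axis=1, keepdims=True))
        out[:, :, 1] = _safe_div(TTSf @ comp, comp.sum(axis=0, keepdims=True))

    # fea3: nearest neighbors a (per target) and b (per disease)
    tts_off = TTSf.copy()
    np.fill_diagonal(tts_off, -np.inf)
    a = np.argmax(tts_off, axis=1)
    dds_off = DDSf.copy()
    np.fill_diagonal(dds_off, -np.inf)
    b = np.argmax(dds_off, axis=0)
    ta = TTSf[np.arange(nT), a]          # TTS[i, a_i]
    db = DDSf[b, np.arange(nD)]          # DDS[b_j, j]
    out[:, :, 2] = (
        ta[:, None] * TDAf[a, :]
        + TDAf[:, b] * db[None, :]
        + ta[:, None] * TDAf[np.ix_(a, b)] * db[None, :]
    )

    # fea4: co-associated drug ratio, one masked max per target row
    H = _drug_path_weights(TDIf, np.asarray(MMS_T, dtype=float))
    L = _drug_path_weights(DDAf, np.asarray(MMS_D, dtype=float))
    fea4 = np.zeros((nT, nD))
    dda_mask = DDAf == 1
    for i in range(nT):
        k = np.flatnonzero(TDIf[i, :] == 1)
        if k.size == 0:
            continue
        ratio = L[:, k] / H[i, k][None, :]
        masked = np.where(dda_mask[:, k], ratio, -np.inf)
        best = masked.max(axis=1)
        fea4[i, :] = np.where(np.isfinite(best), best, 0.0)
    out[:, :, 3] = fea4

    tts_nz = (TTSf != 0).astype(float)
    dds_nz = (DDSf != 0).astype(float)
    SA, ZA = TTSf @ TDAf, tts_nz @ TDAf
    AD, AZ = TDAf @ DDSf, TDAf @ dds_nz
    if not exclude_self:
        out[:, :, 4] = _safe_div(SA, ZA)
        out[:, :, 5] = _safe_div(AD, AZ)
        out[:, :, 6] = _safe_div(TTSf @ SA, tts_nz @ ZA)
        out[:, :, 7] = _safe_div(SA @ DDSf, ZA @ dds_nz)
        out[:, :, 8] = _safe_div(AD @ DDSf, AZ @ dds_nz)
    else:
        # inclusion–exclusion removes the x=i / s=i / y=j / t=j path terms
        out[:, :, 4] = _safe_div(SA - TDAf, ZA - TDAf)
        out[:, :, 5] = _safe_div(AD - TDAf, AZ - TDAf)
        dS2 = np.einsum("ij,ji->i", TTSf, TTSf)      # diag of TTS²
        dZ2 = np.einsum("ij,ji->i", tts_nz, tts_nz)
        out[:, :, 6] = _safe_div(
            TTSf @ SA - SA - dS2[:, None] * TDAf + TDAf,
            tts_nz @ ZA - ZA - dZ2[:, None] * TDAf + TDAf,
        )
        out[:, :, 7] = _safe_div(
            SA @ DDSf - AD - SA + TDAf,
            ZA @ dds_nz - AZ - ZA + TDAf,
        )
        dD2 = np.einsum("ij,ji->i", DDSf, DDSf)      # diag of DDS²
        dW2 = np.einsum("ij,ji->i", dds_nz, dds_nz)
        out[:, :, 8] = _safe_div(
            AD @ DDSf - dD2[None, :] * TDAf - AD + TDAf,
            AZ @ dds_nz - dW2[None, :] * TDAf - AZ + TDAf,
        )
    return out


@dataclass(frozen=True)
class FeatureTable:
    """Per-pair feature vectors with labels and provenance.

    ``frame`` columns: target_index, disease_index, target_id, disease_id,
    fea1…fea9, label (1 known association, 0 sampled negative, -1 unlabeled).
    ``mask`` records which associations were zeroed in TDA before the
    features were computed.
    """

    frame: pd.DataFrame
    mask: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        pairs = list(zip(self.frame["target_index"], self.frame["disease_index"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (target, disease) pair in feature table")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()


def build_feature_table(
    pairs: Sequence[tuple[int, int]],
    net: HeterogeneousNetwork,
    TTS: SimilarityMatrix,
    DDS: SimilarityMatrix,
    MMS_T: SimilarityMatrix,
    MMS_D: SimilarityMatrix,
    mask: Iterable[tuple[int, int]] = (),
    labels: Sequence[int] | None = None,
    exclude_self: bool = False,
) -> FeatureTable:
    """Feature table for the given pairs, computed on a masked copy of TDA.

    ``mask`` lists (target, disease) associations zeroed in TDA before any
    feature computation — used to hide held-out test associations from the
    TDA-dependent features.  ``labels`` defaults to the (masked) TDA entry of
    each pair.
    """
    tda = net.tda.values.copy()
    mask = frozenset((int(i), int(j)) for i, j in mask)
    for i, j in mask:
        tda[i, j] = 0
    nT, nD = tda.shape
    for i, j in pairs:
        if not (0 <= i < nT and 0 <= j < nD):
            raise IndexError(f"pair ({i}, {j}) out of range for {tda.shape}")
    fm = feature_matrices(
        tda, net.tdi.values, net.dda.values,
        TTS.values, DDS.values, MMS_T.values, MMS_D.values,
        exclude_self=exclude_self,
    )
    idx = np.array([(i, j) for i, j in pairs], dtype=int).reshape(-1, 2)
    rows = fm[idx[:, 0], idx[:, 1], :]
    if labels is None:
        labels = [int(tda[i, j]) for i, j in pairs]
    frame = pd.DataFrame(
        {
            "target_index": [int(i) for i, _ in pairs],
            "disease_index": [int(j) for _, j in pairs],
            "target_id": [net.targets.ids[i] for i, _ in pairs],
            "disease_id": [net.diseases.ids[j] for _, j in pairs],
        }
    )
    for k, name in enumerate(FEATURE_NAMES):
        frame[name] = rows[:, k] if len(pairs) else np.zeros(0)
    frame["label"] = list(labels)
    return FeatureTable(frame=frame, mask=mask)
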