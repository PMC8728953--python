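"""Random-forest pair scoring and the evaluation protocols.

The model is a regression forest on the nine pair features with 0/1
association labels as the regression target (ntree = 500, mtry = number of
features / 3, following the R randomForest defaults for this design); a
pair's score is the ensemble mean, read as the confidence that the pair is
associated.

Evaluation follows the imbalanced link-prediction design: the known
associations are the positives, an equal number of unconfirmed pairs is
sampled as negatives, both are stratified into five folds, and each fold's
test set additionally contains *all* remaining unconfirmed ("unlabeled")
pairs counted as negatives in AUROC/AUPR — so AUPR is measured against the
full ~n_T·n_D candidate universe, not the balanced sample.  Five-fold CV is
repeated five times with fresh negative samples, and mean ± SD over the
repeat means is reported.

Feature ablation is summarised by the influence coefficient: the logistic
sigmoid of the summed paired AUROC (resp. AUPR) differences between the
full model and a one-feature-removed model under the same fold settings,
averaged over the two metrics.  0.5 means the feature has no effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import FEATURE_NAMES, FeatureTable, feature_matrices
from .netio import CategoryAnnotation, HeterogeneousNetwork, SimilarityMatrix
from .similarity import entropy_fuse, gip_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "ForestParams",
    "CVConfig",
    "CVResult",
    "PairScorer",
    "sample_negatives",
    "train_forest",
    "auroc",
    "aupr",
    "run_cv",
    "run_cv_subsets",
    "ablation_study",
    "influence_coefficients",
    "category_eval",
    "CategoryResult",
    "rank_targets_for_disease",
    "rank_whole_network",
]


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyperparameters (ntree, mtry, seed).

    ``n_vars_per_split=None`` resolves to floor(n_features / 3) at fit time,
    i.e. 3 for the full nine-feature model.
    """

    n_trees: int = 500
    n_vars_per_split: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")

    def mtry(self, n_features: int) -> int:
        m = self.n_vars_per_split or max(1, n_features // 3)
        if m > n_features:
            raise ValueError("n_vars_per_split exceeds feature count")
        return m


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings.

    ``mask_test_positives`` zeroes each fold's held-out associations in TDA
    before computing that fold's features, so TDA-dependent features cannot
    leak test labels; switching it off reproduces the literal formulas on
    the unmasked matrix.  ``shuffle_labels`` permutes the 0/1 labels across
    the sampled positive+negative pool per repeat (null calibration).
    ``recompute_similarity`` re-derives the GIP topological layers and the
    entropy fusion from the masked TDA inside every fold (strict mode)
    instead of using the once-precomputed matrices.  ``exclude_self`` bars
    the query entities from the features' neighborhoods and path positions,
    removing the self-evidence terms through which an unmasked training
    positive can read its own label out of TDA.
    """

    n_folds: int = 5
    n_repeats: int = 5
    negative_ratio: float = 1.0
    seed: int = 0
    mask_test_positives: bool = True
    shuffle_labels: bool = False
    recompute_similarity: bool = False
    exclude_self: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1 or self.negative_ratio <= 0:
            raise ValueError("invalid CV configuration")


@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics of a repeated stratified CV run.

    ``fold_auroc``/``fold_aupr`` have shape (n_repeats, n_folds).  The
    overall mean is the mean of the per-repeat means; the SD is the sample
    SD over the per-repeat means (0 for a single repeat).
    """

    fold_auroc: np.ndarray
    fold_aupr: np.ndarray

    @property
    def repeat_auroc(self) -> np.ndarray:
        return self.fold_auroc.mean(axis=1)

    @property
    def repeat_aupr(self) -> np.ndarray:
        return self.fold_aupr.mean(axis=1)

    @property
    def auroc_mean(self) -> float:
        return float(self.repeat_auroc.mean())

    @property
    def aupr_mean(self) -> float:
        return float(self.repeat_aupr.mean())

    @property
    def auroc_sd(self) -> float:
        r = self.repeat_auroc
        return float(np.std(r, ddof=1)) if r.size > 1 else 0.0

    @property
    def aupr_sd(self) -> float:
        r = self.repeat_aupr
        return float(np.std(r, ddof=1)) if r.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "fold_auroc": self.fold_auroc.tolist(),
            "fold_aupr": self.fold_aupr.tolist(),
            "auroc_mean": self.auroc_mean,
            "auroc_sd": self.auroc_sd,
            "aupr_mean": self.aupr_mean,
            "aupr_sd": self.aupr_sd,
        }


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (probability of correct ranking, ties ½)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined for single-class labels")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision–recall curve (step interpolation)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPR undefined for single-class labels")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def sample_negatives(
    net: HeterogeneousNetwork,
    n: int,
    seed: int,
    exclude_diseases: Sequence[int] = (),
) -> np.ndarray:
    """Uniform sample without replacement of n unconfirmed (TDA = 0) pairs.

    ``exclude_diseases`` removes whole disease columns from the candidate
    pool (leave-disease-out / leave-category-out protocols).  Returns an
    (n, 2) array of (target, disease) indices, deterministic given the seed.
    """
    eligible = net.tda.values == 0
    if len(exclude_diseases):
        eligible = eligible.copy()
        eligible[:, np.asarray(exclude_diseases, dtype=int)] = False
    flat = np.flatnonzero(eligible.ravel())
    if n > flat.size:
        raise ValueError(f"requested {n} negatives but only {flat.size} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    return np.column_stack(np.unravel_index(chosen, net.tda.values.shape))


def _resolve_subset(feature_subset) -> list[int]:
    """Normalise a feature subset (1-based ints or fea-names) to 0-based cols."""
    if feature_subset is None:
        return list(range(9))
    cols = []
    for f in feature_subset:
        if isinstance(f, str):
            cols.append(FEATURE_NAMES.index(f))
        else:
            if not 1 <= int(f) <= 9:
                raise ValueError(f"feature index {f} outside 1..9")
            cols.append(int(f) - 1)
    if len(set(cols)) != len(cols) or not cols:
        raise ValueError("feature subset must be a nonempty set of distinct features")
    return sorted(cols)


def _fit_forest(
    X: np.ndarray, y: np.ndarray, params: ForestParams
) -> RandomForestRegressor:
    model = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=params.mtry(X.shape[1]),
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


@dataclass(frozen=True)
class PairScorer:
    """A fitted forest plus the feature columns it consumes."""

    model: RandomForestRegressor
    columns: tuple[str, ...]

    def score(self, features: FeatureTable | pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, FeatureTable):
            X = features.frame[list(self.columns)].to_numpy()
        elif isinstance(features, pd.DataFrame):
            X = features[list(self.columns)].to_numpy()
        else:
            X = np.asarray(features, dtype=float)
        return self.model.predict(X)


def train_forest(
    table: FeatureTable,
    params: ForestParams = ForestParams(),
    feature_subset=None,
) -> PairScorer:
    """Fit the regression forest on a labeled feature table.

    Labels must be 0/1 (regression targets); scores are the tree-ensemble
    mean, hence lie in [0, 1].  A single-class table trains with a warning.
    """
    y = table.y
    if not np.isin(y, (0, 1)).all():
        raise ValueError("train_forest requires 0/1 labels only")
    if len(np.unique(y)) < 2:
        logger.warning("training table contains a single class")
    cols = tuple(FEATURE_NAMES[c] for c in _resolve_subset(feature_subset))
    X = table.frame[list(cols)].to_numpy()
    return PairScorer(model=_fit_forest(X, y.astype(float), params), columns=cols)


def _fold_slices(n: int, n_folds: int) -> list[np.ndarray]:
    """Partition range(n) into folds whose sizes differ by at most one."""
    idx = np.arange(n)
    return [idx[f::n_folds] for f in range(n_folds)]


def _feature_matrix_for_fold(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    masked_tda: np.ndarray,
    cfg: CVConfig,
    tts_s: SimilarityMatrix | None,
    dds_s: SimilarityMatrix | None,
) -> np.ndarray:
    if cfg.recompute_similarity:
        if tts_s is None or dds_s is None:
            raise ValueError(
                "recompute_similarity requires the semantic matrices tts_s/dds_s"
            )
        from .netio import AssociationMatrix

        masked = AssociationMatrix(net.targets, net.diseases, masked_tda)
        tts = entropy_fuse(tts_s, gip_similarity(masked, axis="rows"))
        dds = entropy_fuse(dds_s, gip_similarity(masked, axis="columns"))
    return feature_matrices(
        masked_tda,
        net.tdi.values,
        net.dda.values,
        tts.values,
        dds.values,
        mms_t.values,
        mms_d.values,
        exclude_self=cfg.exclude_self,
    ).reshape(-1, 9)


def run_cv_subsets(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    cfg: CVConfig = CVConfig(),
    params: ForestParams = ForestParams(),
    subsets: Mapping[str, Sequence] | None = None,
    tts_s: SimilarityMatrix | None = None,
    dds_s: SimilarityMatrix | None = None,
) -> dict[str, CVResult]:
    """Repeated stratified CV evaluating several feature subsets at once.

    The (expensive) per-fold featurisation is shared across subsets, and all
    subsets see identical folds and negative samples — exactly the "same
    fold settings" the influence coefficient requires.
    """
    subsets = dict(subsets) if subsets else {"full": None}
    subset_cols = {name: _resolve_subset(s) for name, s in subsets.items()}
    tda = net.tda.values
    nT, nD = tda.shape
    positives = np.argwhere(tda == 1)
    n_pos = len(positives)
    if n_pos < cfg.n_folds:
        raise ValueError("fewer positives than folds")
    n_neg = int(round(cfg.negative_ratio * n_pos))

    results = {
        name: (
            np.zeros((cfg.n_repeats, cfg.n_folds)),
            np.zeros((cfg.n_repeats, cfg.n_folds)),
        )
        for name in subsets
    }
    for r in range(cfg.n_repeats):
        seed_r = cfg.seed + r
        rng = np.random.default_rng(seed_r)
        negatives = sample_negatives(net, n_neg, seed_r)
        sampled = np.vstack([positives, negatives])
        labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        if cfg.shuffle_labels:
            labels = rng.permutation(labels)

        pos_idx = rng.permutation(np.flatnonzero(labels == 1))
        neg_idx = rng.permutation(np.flatnonzero(labels == 0))
        pos_folds = _fold_slices(len(pos_idx), cfg.n_folds)
        neg_folds = _fold_slices(len(neg_idx), cfg.n_folds)

        unlabeled = tda == 0
        unlabeled = unlabeled.copy()
        unlabeled[negatives[:, 0], negatives[:, 1]] = False
        unl_flat = np.flatnonzero(unlabeled.ravel())

        sampled_flat = sampled[:, 0] * nD + sampled[:, 1]
        for f in range(cfg.n_folds):
            test_rows = np.concatenate(
                [pos_idx[pos_folds[f]], neg_idx[neg_folds[f]]]
            )
            train_rows = np.setdiff1d(np.arange(len(sampled)), test_rows)

            masked_tda = tda
            if cfg.mask_test_positives:
                test_pos_pairs = sampled[test_rows][labels[test_rows] == 1]
                masked_tda = tda.copy()
                masked_tda[test_pos_pairs[:, 0], test_pos_pairs[:, 1]] = 0
            fm = _feature_matrix_for_fold(
                net, tts, dds, mms_t, mms_d, masked_tda, cfg, tts_s, dds_s
            )

            X_train = fm[sampled_flat[train_rows]]
            y_train = labels[train_rows]
            test_flat = np.concatenate([sampled_flat[test_rows], unl_flat])
            y_test = np.concatenate(
                [labels[test_rows], np.zeros(unl_flat.size)]
            )
            X_test = fm[test_flat]
            for name, cols in subset_cols.items():
                model = _fit_forest(X_train[:, cols], y_train, params)
                scores = model.predict(X_test[:, cols])
                results[name][0][r, f] = auroc(y_test, scores)
                results[name][1][r, f] = aupr(y_test, scores)
    return {
        name: CVResult(fold_auroc=a, fold_aupr=p)
        for name, (a, p) in results.items()
    }


def run_cv(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    cfg: CVConfig = CVConfig(),
    params: ForestParams = ForestParams(),
    feature_subset=None,
    tts_s: SimilarityMatrix | None = None,
    dds_s: SimilarityMatrix | None = None,
) -> CVResult:
    """Repeated stratified five-fold CV with the unlabeled test pool.

    Per repeat a fresh negative sample (seed = base seed + repeat index) is
    drawn, positives and negatives are split into folds as evenly as
    possible, and each fold is tested on its held-out samples plus all
    unlabeled pairs (counted as negatives).
    """
    return run_cv_subsets(
        net, tts, dds, mms_t, mms_d, cfg, params,
        subsets={"run": feature_subset},
        tts_s=tts_s, dds_s=dds_s,
    )["run"]


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def influence_coefficients(
    full: CVResult,
    ablated: Mapping[str, CVResult],
    level: str = "fold",
) -> pd.DataFrame:
    """Influence coefficient of each ablated feature.

    DifferenceAUROC = sigmoid(sum of paired AUROC differences between the
    full model and the ablated model) under the same fold settings; same
    for AUPR; the influence coefficient is the mean of the two.  ``level``
    selects whether the paired sum runs over the fold-level values
    (default, n_repeats·n_folds terms) or the per-repeat means.
    """
    rows = {}
    for name, res in ablated.items():
        if res.fold_auroc.shape != full.fold_auroc.shape:
            raise ValueError(f"fold structure mismatch for {name!r}")
        if level == "fold":
            d_roc = _sigmoid(float((full.fold_auroc - res.fold_auroc).sum()))
            d_pr = _sigmoid(float((full.fold_aupr - res.fold_aupr).sum()))
        elif level == "repeat":
            d_roc = _sigmoid(float((full.repeat_auroc - res.repeat_auroc).sum()))
            d_pr = _sigmoid(float((full.repeat_aupr - res.repeat_aupr).sum()))
        else:
            raise ValueError("level must be 'fold' or 'repeat'")
        rows[name] = {
            "difference_auroc": d_roc,
            "difference_aupr": d_pr,
            "influence": (d_roc + d_pr) / 2.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def ablation_study(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    cfg: CVConfig = CVConfig(),
    params: ForestParams = ForestParams(),
) -> tuple[CVResult, dict[str, CVResult], pd.DataFrame]:
    """Full model vs every one-feature-removed model under shared folds.

    Returns (full-model CVResult, per-feature ablated CVResults, influence
    coefficient table).
    """
    subsets: dict[str, Sequence | None] = {"full": None}
    for k, name in enumerate(FEATURE_NAMES):
        subsets[name] = [f for f in FEATURE_NAMES if f != name]
    results = run_cv_subsets(
        net, tts, dds, mms_t, mms_d, cfg, params, subsets=subsets
    )
    full = results.pop("full")
    report = influence_coefficients(full, results)
    return full, results, report


@dataclass(frozen=True)
class CategoryResult:
    """Leave-category-out evaluation summary."""

    code: str
    repeat_auroc: np.ndarray
    repeat_aupr: np.ndarray
    n_diseases: int
    n_skipped: int

    @property
    def auroc_mean(self) -> float:
        return float(self.repeat_auroc.mean())

    @property
    def aupr_mean(self) -> float:
        return float(self.repeat_aupr.mean())

    @property
    def auroc_sd(self) -> float:
        r = self.repeat_auroc
        return float(np.std(r, ddof=1)) if r.size > 1 else 0.0

    @property
    def aupr_sd(self) -> float:
        r = self.repeat_aupr
        return float(np.std(r, ddof=1)) if r.size > 1 else 0.0


def category_eval(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    categories: CategoryAnnotation,
    code: str,
    cfg: CVConfig = CVConfig(),
    params: ForestParams = ForestParams(),
) -> CategoryResult:
    """Leave-category-out evaluation of one disease category.

    The model trains on associations (and equally many sampled unconfirmed
    pairs) of all diseases *outside* the category; every category disease
    with at least one known association is then scored against all targets
    and its AUROC/AUPR computed; the category score is the mean over those
    diseases, repeated ``cfg.n_repeats`` times with fresh negatives.
    """
    cat_ids = categories.diseases_in(code)
    if not cat_ids:
        raise ValueError(f"category {code!r} has no diseases")
    cat_j = np.array([net.diseases.index[d] for d in cat_ids], dtype=int)
    tda = net.tda.values
    nT, nD = tda.shape
    deg = tda[:, cat_j].sum(axis=0)
    evaluable = cat_j[(deg > 0) & (deg < nT)]
    n_skipped = len(cat_j) - len(evaluable)
    if n_skipped:
        logger.info(
            "category %s: skipping %d diseases without a defined AUROC",
            code, n_skipped,
        )
    if evaluable.size == 0:
        raise ValueError(f"category {code!r} has no evaluable disease")

    out_mask = np.ones(nD, dtype=bool)
    out_mask[cat_j] = False
    positives = np.argwhere(tda[:, out_mask] == 1)
    if len(positives) == 0:
        raise ValueError("no training positives outside the category")
    out_cols = np.flatnonzero(out_mask)
    positives = np.column_stack([positives[:, 0], out_cols[positives[:, 1]]])

    masked_tda = tda
    if cfg.mask_test_positives:
        masked_tda = tda.copy()
        masked_tda[:, cat_j] = 0
    fm = _feature_matrix_for_fold(
        net, tts, dds, mms_t, mms_d, masked_tda, cfg, None, None
    )
    pos_flat = positives[:, 0] * nD + positives[:, 1]

    rep_auroc = np.zeros(cfg.n_repeats)
    rep_aupr = np.zeros(cfg.n_repeats)
    for r in range(cfg.n_repeats):
        seed_r = cfg.seed + r
        negatives = sample_negatives(
            net, len(positives), seed_r, exclude_diseases=cat_j
        )
        neg_flat = negatives[:, 0] * nD + negatives[:, 1]
        X = fm[np.concatenate([pos_flat, neg_flat])]
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        model = _fit_forest(X, y, params)
        per_d_auroc, per_d_aupr = [], []
        for j in evaluable:
            scores = model.predict(fm[np.arange(nT) * nD + j])
            labels = tda[:, j]
            per_d_auroc.append(auroc(labels, scores))
            per_d_aupr.append(aupr(labels, scores))
        rep_auroc[r] = np.mean(per_d_auroc)
        rep_aupr[r] = np.mean(per_d_aupr)
    return CategoryResult(
        code=code,
        repeat_auroc=rep_auroc,
        repeat_aupr=rep_aupr,
        n_diseases=len(evaluable),
        n_skipped=n_skipped,
    )


def rank_targets_for_disease(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    disease_id: str,
    cfg: CVConfig = CVConfig(),
    params: ForestParams = ForestParams(),
) -> pd.DataFrame:
    """Leave-disease-out ranking of candidate targets for one disease.

    The investigated disease is excluded from training (its associations are
    neither positives nor negative candidates); all targets are scored for
    it over ``cfg.n_repeats`` repeats with fresh negatives, scores averaged,
    and the unconfirmed targets returned ranked by descending mean score
    (ties broken by target id).
    """
    if disease_id not in net.diseases:
        raise KeyError(f"unknown disease id {disease_id!r}")
    j = net.diseases.index[disease_id]
    tda = net.tda.values
    nT, nD = tda.shape
    keep = np.ones(nD, dtype=bool)
    keep[j] = False
    positives = np.argwhere(tda[:, keep] == 1)
    cols = np.flatnonzero(keep)
    positives = np.column_stack([positives[:, 0], cols[positives[:, 1]]])

    masked_tda = tda
    if cfg.mask_test_positives:
        masked_tda = tda.copy()
        masked_tda[:, j] = 0
    fm = _feature_matrix_for_fold(
        net, tts, dds, mms_t, mms_d, masked_tda, cfg, None, None
    )
    pos_flat = positives[:, 0] * nD + positives[:, 1]
    col_flat = np.arange(nT) * nD + j

    scores = np.zeros(nT)
    for r in range(cfg.n_repeats):
        negatives = sample_negatives(
            net, len(positives), cfg.seed + r, exclude_diseases=[j]
        )
        neg_flat = negatives[:, 0] * nD + negatives[:, 1]
        X = fm[np.concatenate([pos_flat, neg_flat])]
        y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
        model = _fit_forest(X, y, params)
        scores += model.predict(fm[col_flat])
    scores /= cfg.n_repeats

    unconfirmed = np.flatnonzero(tda[:, j] == 0)
    frame = pd.DataFrame(
        {
            "target_id": [net.targets.ids[i] for i in unconfirmed],
            "disease_id": disease_id,
            "score": scores[unconfirmed],
        }
    )
    frame = frame.sort_values(
        by=["score", "target_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def rank_whole_network(
    net: HeterogeneousNetwork,
    tts: SimilarityMatrix,
    dds: SimilarityMatrix,
    mms_t: SimilarityMatrix,
    mms_d: SimilarityMatrix,
    cfg: CVConfig = CVConfig(),
    params: ForestParams = ForestParams(),
) -> pd.DataFrame:
    """Score and rank every unconfirmed pair of the whole network.

    Trains once on all known associations plus an equal-size sampled
    negative set, scores all TDA = 0 pairs and ranks them descending
    (ties by target then disease id).
    """
    tda = net.tda.values
    nT, nD = tda.shape
    positives = np.argwhere(tda == 1)
    negatives = sample_negatives(
        net, int(round(cfg.negative_ratio * len(positives))), cfg.seed
    )
    fm = _feature_matrix_for_fold(
        net, tts, dds, mms_t, mms_d, tda, cfg, None, None
    )
    pairs = np.vstack([positives, negatives])
    X = fm[pairs[:, 0] * nD + pairs[:, 1]]
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    model = _fit_forest(X, y, params)

    unconfirmed = np.argwhere(tda == 0)
    scores = model.predict(fm[unconfirmed[:, 0] * nD + unconfirmed[:, 1]])
    frame = pd.DataFrame(
        {
            "target_id": [net.targets.ids[i] for i in unconfirmed[:, 0]],
            "disease_id": [net.diseases.ids[j] for j in unconfirmed[:, 1]],
            "score": scores,
        }
    )
    frame = frame.sort_values(
        by=["score", "target_id", "disease_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
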