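"""Three-class random forest and its evaluation protocol.

The model is a bootstrap-aggregated forest of decision trees over the
encoded feature matrix; a variant's class probability is the fraction of
trees voting for that class, so the three scores sum to one exactly.
Evaluation follows the repeated cross-validation protocol: stratified
10-fold cross-validation, re-randomized (including per-gene training-variant
selection when pools are supplied) and repeated 40 times, reporting
per-class precision/recall, pairwise-average multiclass AUC and per-tree
out-of-bag permutation importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._seeds import sk_seed, spawn_rng
from .catalogue import FeatureCatalogue
from .errors import ContractError, ValidationError
from .features import (
    CLASSES,
    DEFAULT_PER_GENE,
    OBSERVED_SHARE,
    FeatureMatrix,
    LabeledPool,
    apply_imputation,
    encode,
    fit_imputation,
    sample_pools,
)

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500


# ---------------------------------------------------------------------------
# metrics


def precision(tp: int, fp: int) -> float | None:
    """Positive predictive value TP/(TP+FP); None when undefined."""
    if tp < 0 or fp < 0:
        raise ValidationError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float | None:
    """Sensitivity TP/(TP+FN); None when undefined."""
    if tp < 0 or fn < 0:
        raise ValidationError("counts must be non-negative")
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Counts[i, j] = rows with true class i called as class j."""
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted, strict=True):
        counts[index[t], index[p]] += 1
    return counts


def class_precision_recall(
    counts: np.ndarray, classes: Sequence[str]
) -> dict[str, dict[str, float | None]]:
    out = {}
    for i, c in enumerate(classes):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum() - tp)
        fn = int(counts[i, :].sum() - tp)
        out[c] = {"precision": precision(tp, fp), "recall": recall(tp, fn)}
    return out


def _pairwise_auc(scores_i: np.ndarray, scores_j: np.ndarray) -> float:
    """P(score of a class-i row > score of a class-j row), ties counted half.

    Computed from the rank-sum of the class-i rows among the combined sample,
    using the same score column for both groups.
    """
    n_i, n_j = len(scores_i), len(scores_j)
    ranks = rankdata(np.concatenate([scores_i, scores_j]))
    s_i = ranks[:n_i].sum()
    return (s_i - n_i * (n_i + 1) / 2) / (n_i * n_j)


def multiclass_auc(
    scores: np.ndarray, labels: Sequence[str], classes: Sequence[str] | None = None
) -> float:
    """Pairwise-average multiclass AUC (Hand-Till M).

    For each unordered class pair (i, j) the separability A(i, j) is the
    average of A(i|j) — how well class-i scores rank class-i rows above
    class-j rows — and A(j|i); the statistic is the mean over all pairs.
    For two classes this reduces to the standard rank-sum AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = [c for c in CLASSES if c in labels]
        if not classes:
            classes = sorted(set(labels))
    if scores.shape != (len(labels), len(classes)):
        raise ContractError(
            f"score matrix shape {scores.shape} does not match "
            f"{len(labels)} rows x {len(classes)} classes"
        )
    masks = {c: labels == c for c in classes}
    for c in classes:
        if not masks[c].any():
            raise ValidationError(f"class {c!r} has no rows")
    pair_aucs = []
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            ca, cb = classes[a], classes[b]
            a_given_b = _pairwise_auc(scores[masks[ca], a], scores[masks[cb], a])
            b_given_a = _pairwise_auc(scores[masks[cb], b], scores[masks[ca], b])
            pair_aucs.append((a_given_b + b_given_a) / 2)
    return float(np.mean(pair_aucs))


# ---------------------------------------------------------------------------
# model


class ForestModel:
    """Trained random forest with vote-fraction class probabilities."""

    def __init__(
        self,
        forest: RandomForestClassifier,
        classes: tuple[str, ...],
        columns: list[str],
        catalogue_digest: str | None,
        encoding: dict,
        imputation: dict[str, float] | None,
        seed: int,
        train_values: np.ndarray,
        train_labels: np.ndarray,
    ):
        self.forest = forest
        self.classes = classes
        self.columns = columns
        self.catalogue_digest = catalogue_digest
        self.encoding = encoding
        self.imputation = imputation
        self.seed = seed
        self._train_values = train_values
        self._train_labels = train_labels

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    def _check(self, matrix: FeatureMatrix) -> np.ndarray:
        if matrix.columns != self.columns:
            missing = [c for c in self.columns if c not in matrix.columns]
            extra = [c for c in matrix.columns if c not in self.columns]
            raise ContractError(
                f"feature columns do not match the model: missing={missing}, "
                f"extra={extra}"
            )
        if (
            self.catalogue_digest is not None
            and matrix.catalogue_digest is not None
            and matrix.catalogue_digest != self.catalogue_digest
        ):
            raise ContractError("catalogue hash differs from the model's")
        if np.isnan(matrix.values).any():
            raise ValidationError("matrix contains missing values; impute first")
        return matrix.values

    def predict_proba(self, matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
        """Per-row class probabilities as tree-vote fractions (rows sum to 1)."""
        X = self._check(matrix) if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        votes = np.zeros((X.shape[0], len(self.classes)))
        rows = np.arange(X.shape[0])
        for est in self.forest.estimators_:
            # per-tree hard vote from the leaf class counts
            pred = est.tree_.predict(X32).reshape(X32.shape[0], -1).argmax(axis=1)
            votes[rows, pred] += 1.0
        return votes / self.n_trees

    def predict(self, matrix: FeatureMatrix | np.ndarray) -> list[str]:
        proba = self.predict_proba(matrix)
        return [self.classes[i] for i in proba.argmax(axis=1)]

    def save(self, path) -> None:
        joblib.dump(
            {
                "forest": self.forest,
                "classes": self.classes,
                "columns": self.columns,
                "catalogue_digest": self.catalogue_digest,
                "encoding": self.encoding,
                "imputation": self.imputation,
                "seed": self.seed,
                "train_values": self._train_values,
                "train_labels": self._train_labels,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ForestModel":
        blob = joblib.load(path)
        return cls(
            forest=blob["forest"],
            classes=tuple(blob["classes"]),
            columns=list(blob["columns"]),
            catalogue_digest=blob["catalogue_digest"],
            encoding=blob["encoding"],
            imputation=blob["imputation"],
            seed=blob["seed"],
            train_values=blob["train_values"],
            train_labels=blob["train_labels"],
        )


def train(
    matrix: FeatureMatrix,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> ForestModel:
    """Fit the forest on an imputed, labelled matrix.

    ``max_features`` is the per-split candidate-feature count (default
    sqrt(p)).  Deterministic given ``seed``.
    """
    if matrix.labels is None:
        raise ValidationError("training requires class labels")
    if matrix.has_missing():
        raise ValidationError("matrix contains missing values; impute first")
    present = [c for c in CLASSES if c in matrix.labels]
    if not present:
        present = sorted(set(matrix.labels))
    if len(present) < 2:
        raise ValidationError(
            f"training requires >=2 classes, found only {present}"
        )
    class_index = {c: i for i, c in enumerate(present)}
    y = np.asarray([class_index[l] for l in matrix.labels])
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=seed % (2**31),
        n_jobs=1,
    )
    forest.fit(matrix.values, y)
    return ForestModel(
        forest=forest,
        classes=tuple(present),
        columns=list(matrix.columns),
        catalogue_digest=matrix.catalogue_digest,
        encoding=matrix.encoding,
        imputation=dict(matrix.imputation) if matrix.imputation else None,
        seed=seed,
        train_values=matrix.values.copy(),
        train_labels=y,
    )


# ---------------------------------------------------------------------------
# permutation importance


def permutation_importance(model: ForestModel, seed: int = 0) -> pd.DataFrame:
    """Normalized OOB mean decrease in accuracy per feature.

    For every tree, prediction error is measured on its out-of-bag rows
    before and after permuting one feature column; the per-tree differences
    (permuted minus raw error) are averaged over trees and divided by their
    standard deviation.  A zero standard deviation with a nonzero mean
    reports the unnormalized mean; a constant feature reports 0.
    """
    X = np.ascontiguousarray(model._train_values, dtype=np.float32)
    y = model._train_labels
    n = X.shape[0]
    rng = spawn_rng(seed, 97)

    def tree_predict(est, data):
        # low-level tree predict: skips per-call input validation
        leaf_values = est.tree_.predict(data)
        return leaf_values.reshape(data.shape[0], -1).argmax(axis=1)

    diffs: list[np.ndarray] = []  # per usable tree: per-feature error increase
    skipped = 0
    all_inbag = model.forest.estimators_samples_
    for t, est in enumerate(model.forest.estimators_):
        inbag = all_inbag[t]
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        if not oob_mask.any():
            skipped += 1
            continue
        X_oob = np.ascontiguousarray(X[oob_mask])
        y_oob = y[oob_mask]
        err_raw = float(np.mean(tree_predict(est, X_oob) != y_oob))
        row = np.empty(X.shape[1])
        X_perm = X_oob.copy()
        for j in range(X.shape[1]):
            original = X_perm[:, j].copy()
            X_perm[:, j] = original[rng.permutation(len(original))]
            err_perm = float(np.mean(tree_predict(est, X_perm) != y_oob))
            row[j] = err_perm - err_raw
            X_perm[:, j] = original
        diffs.append(row)
    if skipped:
        logger.warning("permutation importance: %d trees had no OOB rows", skipped)
    if not diffs:
        raise ValidationError("no tree had out-of-bag rows")
    D = np.vstack(diffs)
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1) if D.shape[0] > 1 else np.zeros(D.shape[1])
    importance = np.where(sd > 0, np.divide(mean, sd, out=np.zeros_like(mean), where=sd > 0), mean)
    importance = np.where((sd == 0) & (mean == 0), 0.0, importance)
    out = pd.DataFrame(
        {
            "feature": model.columns,
            "mean_decrease_accuracy": mean,
            "sd": sd,
            "importance": importance,
        }
    )
    return out.sort_values("importance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class RepeatResult:
    """Metrics of one cross-validation repeat."""

    repeat: int
    fold_confusions: list[np.ndarray]
    auc: float
    pooled: dict[str, dict[str, float | None]]  # from summed confusion
    fold_averaged: dict[str, dict[str, float | None]]

    @property
    def confusion(self) -> np.ndarray:
        return np.sum(self.fold_confusions, axis=0)


@dataclass
class EvaluationReport:
    """Aggregate of all repeats of the cross-validation protocol."""

    classes: tuple[str, ...]
    folds: int
    repeats: list[RepeatResult] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.repeats]))

    def metric_values(self, cls: str, metric: str, pooled: bool = True) -> list[float]:
        out = []
        for r in self.repeats:
            source = r.pooled if pooled else r.fold_averaged
            v = source[cls][metric]
            if v is not None:
                out.append(v)
        return out

    def summary(self) -> pd.DataFrame:
        """Per-class min/mean/max of precision and recall over repeats."""
        rows = []
        for cls in self.classes:
            for metric in ("precision", "recall"):
                vals = self.metric_values(cls, metric)
                rows.append(
                    {
                        "class": cls,
                        "metric": metric,
                        "min": float(np.min(vals)) if vals else np.nan,
                        "mean": float(np.mean(vals)) if vals else np.nan,
                        "max": float(np.max(vals)) if vals else np.nan,
                    }
                )
        aucs = [r.auc for r in self.repeats]
        rows.append(
            {
                "class": "all",
                "metric": "multiclass_auc",
                "min": float(np.min(aucs)),
                "mean": float(np.mean(aucs)),
                "max": float(np.max(aucs)),
            }
        )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False, float_format="%.6f")


def _one_repeat(
    matrix: FeatureMatrix,
    repeat: int,
    folds: int,
    rng: np.random.Generator,
    n_trees: int,
    max_features,
    classes: tuple[str, ...],
    imputation_scope: str,
    weighting: str,
) -> RepeatResult:
    labels = np.asarray(matrix.labels)
    for c in classes:
        if (labels == c).sum() < folds:
            raise ValidationError(
                f"class {c!r} has fewer rows than the {folds} folds"
            )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=sk_seed(rng))
    oof_scores = np.zeros((matrix.n_rows, len(classes)))
    fold_confusions = []
    fold_metrics = []
    global_fills = (
        fit_imputation(matrix, weighting=weighting)
        if imputation_scope == "global" and matrix.has_missing()
        else None
    )
    for train_idx, test_idx in splitter.split(matrix.values, labels):
        m_train = matrix.subset(train_idx)
        m_test = matrix.subset(test_idx)
        if matrix.has_missing():
            fills = (
                global_fills
                if global_fills is not None
                else fit_imputation(m_train, weighting=weighting)
            )
            m_train = apply_imputation(m_train, fills)
            m_test = apply_imputation(m_test, fills)
        model = train(
            m_train, n_trees=n_trees, seed=sk_seed(rng), max_features=max_features
        )
        proba = model.predict_proba(m_test)
        # align the model's class order to the report's
        aligned = np.zeros((len(test_idx), len(classes)))
        for k, c in enumerate(model.classes):
            aligned[:, classes.index(c)] = proba[:, k]
        oof_scores[test_idx] = aligned
        predicted = [classes[i] for i in aligned.argmax(axis=1)]
        counts = confusion_matrix(labels[test_idx], predicted, classes)
        fold_confusions.append(counts)
        fold_metrics.append(class_precision_recall(counts, classes))
    total = np.sum(fold_confusions, axis=0)
    pooled = class_precision_recall(total, classes)
    fold_averaged = {}
    for c in classes:
        fold_averaged[c] = {}
        for metric in ("precision", "recall"):
            vals = [fm[c][metric] for fm in fold_metrics if fm[c][metric] is not None]
            fold_averaged[c][metric] = float(np.mean(vals)) if vals else None
    auc = multiclass_auc(oof_scores, labels, classes=list(classes))
    return RepeatResult(
        repeat=repeat,
        fold_confusions=fold_confusions,
        auc=auc,
        pooled=pooled,
        fold_averaged=fold_averaged,
    )


def cross_validate(
    data: FeatureMatrix | Mapping[str, LabeledPool],
    folds: int = 10,
    repeats: int = 40,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_features: str | int | float = "sqrt",
    catalogue: FeatureCatalogue | None = None,
    per_gene: Mapping[str, int] = DEFAULT_PER_GENE,
    imputation_scope: str = "fold",
    weighting: str = OBSERVED_SHARE,
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation.

    ``data`` is either a labelled :class:`FeatureMatrix` (missing values are
    imputed inside each training fold by default, to avoid leakage) or a
    mapping of class label -> :class:`LabeledPool`, in which case the
    per-gene training-variant selection is re-drawn at every repeat before
    encoding, matching the repeat-randomization of the training protocol.
    Every row is scored exactly once per repeat; per-repeat multiclass AUC is
    computed on the pooled out-of-fold scores.
    """
    from_pools = not isinstance(data, FeatureMatrix)
    if from_pools and catalogue is None:
        raise ValidationError("cross-validating pools requires a feature catalogue")
    if not from_pools and data.labels is None:
        raise ValidationError("cross-validation requires class labels")
    if from_pools:
        classes = tuple(c for c in CLASSES if c in data)
    else:
        classes = tuple(c for c in CLASSES if c in data.labels)
        if not classes:
            classes = tuple(sorted(set(data.labels)))
    if len(classes) < 2:
        raise ValidationError("cross-validation requires >=2 classes")
    report = EvaluationReport(classes=classes, folds=folds)
    for r in range(repeats):
        rng = spawn_rng(seed, 11, r)
        if from_pools:
            records, labels = sample_pools(data, per_gene, rng)
            matrix = encode(records, catalogue, labels=labels)
        else:
            matrix = data
        report.repeats.append(
            _one_repeat(
                matrix,
                r,
                folds,
                rng,
                n_trees,
                max_features,
                classes,
                imputation_scope,
                weighting,
            )
        )
    return report
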