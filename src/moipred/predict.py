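"""Scoring annotated variants and validation bookkeeping.

A trained forest turns each variant's longest-transcript annotation record
into three class probabilities — benign, dominant, recessive — that sum to
one; the class call is the argmax and any non-benign call is pathogenic.
Accuracy bookkeeping for labelled validation sets (pathogenicity and
inheritance accuracy as k/n and percent) and a rank-sum comparison of score
distributions are provided alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .annotate import AnnotationRecord, Variant
from .catalogue import FeatureCatalogue
from .classifier import ForestModel
from .errors import ContractError, ValidationError
from .features import CLASSES, apply_imputation, encode

logger = logging.getLogger(__name__)

#: argmax tie-break order: prefer the more actionable call
TIE_ORDER = ("dominant", "recessive", "benign")

ARGMAX_RULE = "argmax"
SUM_RULE = "pathogenic-sum"

_SCORE_TOL = 1e-9


@dataclass(frozen=True)
class PredictionRecord:
    """Three-score output for one variant."""

    variant: Variant
    gene: str
    transcript_id: str
    benign_score: float
    dominant_score: float
    recessive_score: float
    class_call: str
    pathogenicity_call: str

    def __post_init__(self):
        total = self.benign_score + self.dominant_score + self.recessive_score
        if abs(total - 1.0) > _SCORE_TOL:
            raise ContractError(
                f"{self.variant}: class scores sum to {total!r}, not 1"
            )
        if self.class_call not in CLASSES:
            raise ContractError(f"unknown class call {self.class_call!r}")

    def scores(self) -> dict[str, float]:
        return {
            "benign": self.benign_score,
            "dominant": self.dominant_score,
            "recessive": self.recessive_score,
        }


def _call_class(scores: Mapping[str, float]) -> str:
    best = max(scores.values())
    tied = [c for c in TIE_ORDER if math.isclose(scores[c], best, abs_tol=0.0)]
    if len(tied) > 1:
        logger.info("tied class scores %s; calling %s", dict(scores), tied[0])
    return tied[0]


def _call_pathogenicity(scores: Mapping[str, float], class_call: str, rule: str) -> str:
    if rule == ARGMAX_RULE:
        return "benign" if class_call == "benign" else "pathogenic"
    if rule == SUM_RULE:
        return (
            "pathogenic"
            if scores["dominant"] + scores["recessive"] > 0.5
            else "benign"
        )
    raise ValidationError(f"unknown pathogenicity rule {rule!r}")


def score_variants(
    model: ForestModel,
    records: Sequence[AnnotationRecord],
    catalogue: FeatureCatalogue,
    pathogenicity_rule: str = ARGMAX_RULE,
) -> list[PredictionRecord]:
    """Score annotation records: one prediction per variant.

    When several transcript records exist for a variant, the
    longest-isoform record is used.  Records are encoded with the model's
    catalogue and missing values filled from the model's stored
    training-time imputation vector (no refitting at prediction time).
    """
    by_variant: dict[tuple, AnnotationRecord] = {}
    for rec in records:
        key = rec.variant.key()
        current = by_variant.get(key)
        if current is None or (rec.is_longest_isoform and not current.is_longest_isoform):
            by_variant[key] = rec
    chosen = list(by_variant.values())
    if not chosen:
        return []
    matrix = encode(chosen, catalogue)
    if matrix.has_missing():
        if not model.imputation:
            raise ContractError(
                "records contain missing values but the model stores no "
                "imputation vector"
            )
        matrix = apply_imputation(matrix, model.imputation)
    proba = model.predict_proba(matrix)
    predictions = []
    for rec, row in zip(chosen, proba):
        scores = {c: 0.0 for c in CLASSES}
        for k, c in enumerate(model.classes):
            scores[c] = float(row[k])
        class_call = _call_class(scores)
        predictions.append(
            PredictionRecord(
                variant=rec.variant,
                gene=rec.gene,
                transcript_id=rec.transcript_id,
                benign_score=scores["benign"],
                dominant_score=scores["dominant"],
                recessive_score=scores["recessive"],
                class_call=class_call,
                pathogenicity_call=_call_pathogenicity(
                    scores, class_call, pathogenicity_rule
                ),
            )
        )
    predictions.sort(key=lambda p: p.variant.key())
    return predictions


# ---------------------------------------------------------------------------
# evaluation bookkeeping


@dataclass(frozen=True)
class AccuracyTable:
    """Pathogenicity and inheritance accuracy over a labelled set."""

    pathogenicity_correct: int
    pathogenicity_total: int
    inheritance_correct: int
    inheritance_total: int

    @property
    def pathogenicity_percent(self) -> float | None:
        if self.pathogenicity_total == 0:
            return None
        return 100.0 * self.pathogenicity_correct / self.pathogenicity_total

    @property
    def inheritance_percent(self) -> float | None:
        if self.inheritance_total == 0:
            return None
        return 100.0 * self.inheritance_correct / self.inheritance_total

    def to_frame(self) -> pd.DataFrame:
        def fmt(k, n, pct):
            return {
                "correct": k,
                "total": n,
                "fraction": f"{k}/{n}",
                "percent": round(pct, 1) if pct is not None else None,
            }

        return pd.DataFrame(
            [
                {"measure": "pathogenicity"}
                | fmt(
                    self.pathogenicity_correct,
                    self.pathogenicity_total,
                    self.pathogenicity_percent,
                ),
                {"measure": "inheritance"}
                | fmt(
                    self.inheritance_correct,
                    self.inheritance_total,
                    self.inheritance_percent,
                ),
            ]
        )


def evaluate_calls(
    predictions: Sequence[PredictionRecord], truth: Mapping[tuple, str]
) -> AccuracyTable:
    """Score predictions against per-variant truth labels.

    Pathogenicity accuracy counts correct pathogenic/benign calls over all
    variants (a dominant call on a recessive-truth variant is still
    correctly pathogenic); inheritance accuracy counts exact class matches
    over the dominant/recessive-truth variants only.
    """
    path_correct = path_total = inh_correct = inh_total = 0
    for pred in predictions:
        key = pred.variant.key()
        if key not in truth:
            raise ValidationError(f"no truth label for {pred.variant}")
        label = truth[key]
        if label not in CLASSES:
            raise ValidationError(f"unknown truth label {label!r} for {pred.variant}")
        truth_path = "benign" if label == "benign" else "pathogenic"
        path_total += 1
        if pred.pathogenicity_call == truth_path:
            path_correct += 1
        if label in ("dominant", "recessive"):
            inh_total += 1
            if pred.class_call == label:
                inh_correct += 1
    return AccuracyTable(path_correct, path_total, inh_correct, inh_total)


def compare_score_distributions(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two score samples.

    Returns (statistic, p-value).  Raises on an empty group; a fully tied
    comparison (every value identical across both groups) is degenerate and
    raises as well.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both score groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        raise ValidationError("all scores tied across both groups; test degenerate")
    stat, p = ranksums(a, b)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# output

PREDICTION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "benign_score",
    "dominant_score",
    "recessive_score",
    "class_call",
    "pathogenicity_call",
]


def predictions_to_frame(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append(
            {
                "chrom": p.variant.chrom,
                "pos": p.variant.pos,
                "ref": p.variant.ref,
                "alt": p.variant.alt,
                "gene": p.gene,
                "transcript": p.transcript_id,
                "benign_score": p.benign_score,
                "dominant_score": p.dominant_score,
                "recessive_score": p.recessive_score,
                "class_call": p.class_call,
                "pathogenicity_call": p.pathogenicity_call,
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_predictions(predictions: Sequence[PredictionRecord], path) -> None:
    predictions_to_frame(predictions).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
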