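"""Training-pool assembly and the numeric feature matrix.

Training pools are class-labelled annotation records grouped by gene.  To
limit over-representation of heavily mutated genes, a per-gene sampler draws
a fixed number of variants per gene (one for benign and recessive, two for
the dominant class by default), keeping only longest-transcript records.
Descriptive (boolean/categorical) features are encoded to -1/+1 columns,
numeric features pass through, and missing values are imputed with a
weighted average over the three classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalogue as cat
from .annotate import AnnotationRecord
from .errors import ContractError, ValidationError

CLASSES = ("benign", "dominant", "recessive")

#: per-gene sampling rule of the default (haploinsufficient-dominant) model
DEFAULT_PER_GENE = {"benign": 1, "dominant": 2, "recessive": 1}
#: per-gene sampling rule of the 'all dominant' model variant
ALL_DOMINANT_PER_GENE = {"benign": 1, "dominant": 1, "recessive": 1}


@dataclass
class LabeledPool:
    """All candidate training records of one class, grouped by gene."""

    label: str
    records: list[AnnotationRecord]

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValidationError(f"unknown class label {self.label!r}")
        for rec in self.records:
            if not rec.gene:
                raise ValidationError("pool record without a gene symbol")

    def by_gene(self) -> dict[str, list[AnnotationRecord]]:
        grouped: dict[str, list[AnnotationRecord]] = {}
        for rec in self.records:
            grouped.setdefault(rec.gene, []).append(rec)
        return grouped

    def __len__(self) -> int:
        return len(self.records)


def sample_training_pool(
    pool: LabeledPool, per_gene: int, rng: np.random.Generator | int
) -> list[AnnotationRecord]:
    """Draw up to ``per_gene`` longest-transcript records per gene, uniformly.

    The selected count is sum over genes of min(per_gene, n_gene); genes with
    fewer candidates contribute everything they have.  Selection order is
    deterministic given the generator state.
    """
    if per_gene < 1:
        raise ValidationError(f"per_gene must be >= 1, got {per_gene}")
    if not pool.records:
        raise ValidationError(f"pool {pool.label!r} is empty")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    selected: list[AnnotationRecord] = []
    grouped = pool.by_gene()
    for gene in sorted(grouped):
        candidates = [r for r in grouped[gene] if r.is_longest_isoform]
        if not candidates:  # fall back when no longest-transcript record exists
            candidates = grouped[gene]
        candidates = sorted(candidates, key=lambda r: r.row_id())
        k = min(per_gene, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False)
        selected.extend(candidates[i] for i in sorted(idx))
    return selected


def sample_pools(
    pools: Mapping[str, LabeledPool],
    per_gene: Mapping[str, int],
    rng: np.random.Generator | int,
) -> tuple[list[AnnotationRecord], list[str]]:
    """Sample every class pool; returns (records, labels) in class order."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    records: list[AnnotationRecord] = []
    labels: list[str] = []
    for label in CLASSES:
        if label not in pools:
            continue
        chosen = sample_training_pool(pools[label], per_gene[label], rng)
        records.extend(chosen)
        labels.extend([label] * len(chosen))
    return records, labels


# ---------------------------------------------------------------------------
# FeatureMatrix


@dataclass
class FeatureMatrix:
    """Numeric matrix over an encoded feature catalogue.

    ``values`` has one column per encoded feature (NaN marks missing until
    imputation); ``encoding`` records the level -> -1/+1 map of each encoded
    descriptive column; ``imputation`` holds the per-column fill value once
    fitted.
    """

    row_ids: list[tuple]
    columns: list[str]
    values: np.ndarray
    labels: list[str] | None = None
    encoding: dict[str, dict[str, float]] = field(default_factory=dict)
    imputation: dict[str, float] | None = None
    catalogue_digest: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ContractError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.columns)} columns"
            )
        if self.labels is not None and len(self.labels) != len(self.row_ids):
            raise ContractError("label count does not match row count")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            row_ids=list(self.row_ids),
            columns=list(self.columns),
            values=self.values.copy(),
            labels=list(self.labels) if self.labels is not None else None,
            encoding={k: dict(v) for k, v in self.encoding.items()},
            imputation=dict(self.imputation) if self.imputation else None,
            catalogue_digest=self.catalogue_digest,
        )

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            row_ids=[self.row_ids[i] for i in indices],
            columns=list(self.columns),
            values=self.values[indices],
            labels=[self.labels[i] for i in indices] if self.labels else None,
            encoding={k: dict(v) for k, v in self.encoding.items()},
            imputation=dict(self.imputation) if self.imputation else None,
            catalogue_digest=self.catalogue_digest,
        )


def _encoded_columns(catalogue: cat.FeatureCatalogue) -> tuple[list[str], dict]:
    """Expand the catalogue into matrix columns with their encoding maps."""
    columns: list[str] = []
    encoding: dict[str, dict[str, float]] = {}
    for feat in catalogue:
        if feat.kind == cat.NUMERIC:
            columns.append(feat.name)
        elif feat.kind == cat.BOOLEAN:
            columns.append(feat.name)
            encoding[feat.name] = {"true": 1.0, "false": -1.0}
        elif len(feat.levels) == 2:
            # two-level categorical: a single -1/+1 column, first level = +1
            columns.append(feat.name)
            encoding[feat.name] = {feat.levels[0]: 1.0, feat.levels[1]: -1.0}
        else:
            for level in feat.levels:
                col = f"{feat.name}={level}"
                columns.append(col)
                encoding[col] = {level: 1.0, "__other__": -1.0}
    return columns, encoding


def encode(
    records: Sequence[AnnotationRecord], catalogue: cat.FeatureCatalogue,
    labels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Encode annotation records into a numeric matrix with missing markers.

    Booleans map to -1/+1, two-level categoricals to a single -1/+1 column,
    wider categoricals to one -1/+1 indicator column per level; numerics pass
    through unchanged; missing values stay NaN for :func:`impute`.
    """
    columns, encoding = _encoded_columns(catalogue)
    values = np.full((len(records), len(columns)), np.nan)
    col_of = {c: j for j, c in enumerate(columns)}
    for i, rec in enumerate(records):
        for feat in catalogue:
            raw = rec.features.get(feat.name)
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            if feat.kind == cat.NUMERIC:
                values[i, col_of[feat.name]] = float(raw)
            elif feat.kind == cat.BOOLEAN:
                values[i, col_of[feat.name]] = 1.0 if raw else -1.0
            elif len(feat.levels) == 2:
                if str(raw) not in feat.levels:
                    raise ContractError(
                        f"feature {feat.name!r}: unknown level {raw!r}"
                    )
                values[i, col_of[feat.name]] = encoding[feat.name][str(raw)]
            else:
                if str(raw) not in feat.levels:
                    raise ContractError(
                        f"feature {feat.name!r}: unknown level {raw!r}"
                    )
                for level in feat.levels:
                    col = f"{feat.name}={level}"
                    values[i, col_of[col]] = 1.0 if str(raw) == level else -1.0
    return FeatureMatrix(
        row_ids=[rec.row_id() for rec in records],
        columns=columns,
        values=values,
        labels=list(labels) if labels is not None else None,
        encoding=encoding,
        catalogue_digest=catalogue.digest(),
    )


OBSERVED_SHARE = "observed-share"
EQUAL_CLASS = "equal-class"


def fit_imputation(
    matrix: FeatureMatrix, weighting: str = OBSERVED_SHARE
) -> dict[str, float]:
    """Per-column fill values as weighted averages over the three classes.

    With ``observed-share`` weighting, each class's mean is weighted by its
    share of the rows where the feature is observed — equivalently the pooled
    mean over observed rows.  ``equal-class`` weights the class means
    uniformly instead.  A feature observed in no row is an error.
    """
    if matrix.labels is None:
        raise ValidationError("imputation fitting requires class labels")
    labels = np.asarray(matrix.labels)
    fills: dict[str, float] = {}
    dead: list[str] = []
    for j, col in enumerate(matrix.columns):
        column = matrix.values[:, j]
        observed = ~np.isnan(column)
        if not observed.any():
            dead.append(col)
            continue
        if weighting == OBSERVED_SHARE:
            fills[col] = float(column[observed].mean())
        elif weighting == EQUAL_CLASS:
            class_means = [
                column[observed & (labels == c)].mean()
                for c in CLASSES
                if (observed & (labels == c)).any()
            ]
            fills[col] = float(np.mean(class_means))
        else:
            raise ValidationError(f"unknown imputation weighting {weighting!r}")
    if dead:
        raise ValidationError(
            f"features with no observed values cannot be imputed: {dead}"
        )
    return fills


def apply_imputation(matrix: FeatureMatrix, fills: Mapping[str, float]) -> FeatureMatrix:
    """Fill missing entries from ``fills`` without touching observed values."""
    out = matrix.copy()
    for j, col in enumerate(out.columns):
        mask = np.isnan(out.values[:, j])
        if mask.any():
            if col not in fills:
                raise ContractError(f"no imputation fill recorded for column {col!r}")
            out.values[mask, j] = fills[col]
    out.imputation = dict(fills)
    return out


def impute(
    matrix: FeatureMatrix, weighting: str = OBSERVED_SHARE
) -> FeatureMatrix:
    """Fit fills on the labelled matrix and apply them; records the fills."""
    fills = fit_imputation(matrix, weighting=weighting)
    return apply_imputation(matrix, fills)


# ---------------------------------------------------------------------------
# serialization


def write_matrix(matrix: FeatureMatrix, path, sidecar_path=None) -> None:
    """Write the matrix as TSV plus a JSON sidecar with encoding state."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.columns)
    df.insert(0, "row_id", ["|".join(str(p) for p in rid) for rid in matrix.row_ids])
    if matrix.labels is not None:
        df.insert(1, "label", matrix.labels)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "columns": matrix.columns,
                "encoding": matrix.encoding,
                "imputation": matrix.imputation,
                "catalogue_digest": matrix.catalogue_digest,
            },
            indent=1,
        )
    )


def read_matrix(path, sidecar_path=None) -> FeatureMatrix:
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
    labels = df["label"].tolist() if "label" in df.columns else None
    row_ids = [tuple(r.split("|")) for r in df["row_id"]]
    values = df[meta["columns"]].to_numpy(dtype=float)
    return FeatureMatrix(
        row_ids=row_ids,
        columns=meta["columns"],
        values=values,
        labels=labels,
        encoding=meta["encoding"],
        imputation=meta["imputation"],
        catalogue_digest=meta["catalogue_digest"],
    )
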