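"""Mixed-type tabular preprocessing for screening data.

Turns a raw table of numeric, categorical and yes/no columns (missing values
allowed) into a complete, encoded, scaled design matrix with an explicit
group structure mapping each original variable to its block of encoded
columns.  All statistics — imputation means/modes, category vocabularies and
scaler parameters — are fitted on training rows only and then applied to any
rows, so cross-validation and holdout evaluation never leak information from
held-out data.

Pipeline order is fixed: impute, then encode, then scale numeric columns.
One-hot blocks are never rescaled column-wise (a z-score on sparse indicator
columns would destroy their {0,1} semantics); min-max scaling would leave
them unchanged anyway.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("gsoelm.preprocessing")

MISSING_MARKERS = {"", "NA", "NaN", "nan", None}

SCALER_KINDS = ("minmax", "zscore", "robust", "unitnorm")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() in MISSING_MARKERS


def is_missing(values: pd.Series) -> np.ndarray:
    """Boolean mask of missing cells (NaN, None, empty string or 'NA')."""
    return values.map(_is_missing).to_numpy(dtype=bool)


# ---------------------------------------------------------------------------
# Schema declaration (what each raw column is)
# ---------------------------------------------------------------------------

@dataclass
class ColumnSpec:
    """Role declaration for one raw column.

    role is one of ``numeric``, ``categorical``, ``boolean``, ``label``.
    ``vocabulary`` optionally pins the category list (and one-hot column
    order) for a categorical column; otherwise it is fitted from the
    training rows as the sorted set of observed values.  ``bounds``
    optionally pins (min, max) for a numeric column, e.g. a 0-10 item score
    whose extremes need not occur in a small sample.
    """

    name: str
    role: str
    vocabulary: list[str] | None = None
    bounds: tuple[float, float] | None = None
    true_value: str = "Yes"
    false_value: str = "No"

    def __post_init__(self) -> None:
        if self.role not in ("numeric", "categorical", "boolean", "label"):
            raise ValueError(f"unknown role {self.role!r} for column {self.name!r}")


@dataclass
class RawSchema:
    """Ordered column declarations for a raw table, exactly one label."""

    columns: list[ColumnSpec]

    def __post_init__(self) -> None:
        labels = [c for c in self.columns if c.role == "label"]
        if len(labels) != 1:
            raise ValueError("schema must declare exactly one label column")
        features = [c for c in self.columns if c.role in ("numeric", "categorical")]
        booleans = [c for c in self.columns if c.role == "boolean"]
        if not features and not booleans:
            raise ValueError("schema must declare at least one feature column")

    @property
    def label(self) -> ColumnSpec:
        return next(c for c in self.columns if c.role == "label")

    @property
    def feature_columns(self) -> list[ColumnSpec]:
        return [c for c in self.columns if c.role != "label"]

    @classmethod
    def from_yaml_dict(cls, data: dict) -> "RawSchema":
        cols = []
        for entry in data["columns"]:
            entry = dict(entry)
            if "bounds" in entry and entry["bounds"] is not None:
                entry["bounds"] = tuple(entry["bounds"])
            cols.append(ColumnSpec(**entry))
        return cls(cols)


# ---------------------------------------------------------------------------
# Imputation (fitted on training rows only)
# ---------------------------------------------------------------------------

def impute_numeric_mean(column: pd.Series, train_mask: np.ndarray) -> pd.Series:
    """Replace missing entries with the mean of non-missing *training* entries."""
    missing = is_missing(column)
    numeric = pd.to_numeric(column.where(~missing), errors="coerce")
    train_vals = numeric[np.asarray(train_mask, dtype=bool) & ~missing]
    if len(train_vals) == 0:
        raise ValueError(f"column {column.name!r}: all training values missing, cannot impute mean")
    return numeric.fillna(float(train_vals.mean()))


def impute_categorical_mode(column: pd.Series, train_mask: np.ndarray) -> pd.Series:
    """Replace missing entries with the modal training category.

    Ties are broken by the lexicographically smallest category so the result
    is deterministic.
    """
    missing = is_missing(column)
    train_vals = column[np.asarray(train_mask, dtype=bool) & ~missing]
    if len(train_vals) == 0:
        raise ValueError(f"column {column.name!r}: all training values missing, cannot impute mode")
    counts = train_vals.value_counts()
    top = counts.max()
    mode = sorted(counts[counts == top].index)[0]
    out = column.copy()
    out[missing] = mode
    return out


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def one_hot_encode(value: str, vocabulary: Sequence[str], strict: bool = True) -> np.ndarray:
    """Indicator vector of ``value`` within an ordered vocabulary.

    With ``strict`` (the default) an unseen category raises; otherwise it
    yields an all-zero row.
    """
    vec = np.zeros(len(vocabulary), dtype=float)
    try:
        vec[list(vocabulary).index(value)] = 1.0
    except ValueError:
        if strict:
            raise ValueError(f"unseen category {value!r}; vocabulary is {list(vocabulary)}") from None
    return vec


def encode_boolean(value: str, pair: tuple[str, str] = ("Yes", "No")) -> int:
    """Map a declared yes/no pair to 1/0; anything else is an error."""
    true_value, false_value = pair
    if value == true_value:
        return 1
    if value == false_value:
        return 0
    raise ValueError(f"boolean value {value!r} not in declared pair {pair}")


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerSpec:
    """Fitted per-column scaling statistics.

    Each numeric column is transformed as ``(x - shift) / scale``:
    min-max uses (min, max-min), z-score (mean, population sd), robust
    (median, IQR).  ``unitnorm`` stores no column statistics; instead the
    full encoded feature row is divided by its Euclidean norm after the
    (identity) column step.
    """

    kind: str
    shift: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    fitted_on_train: bool = True

    @property
    def row_normalize(self) -> bool:
        return self.kind == "unitnorm"

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        if self.kind == "unitnorm":
            return np.asarray(values, dtype=float)
        return (np.asarray(values, dtype=float) - self.shift[name]) / self.scale[name]


def fit_scaler(
    kind: str,
    numeric: pd.DataFrame,
    train_mask: np.ndarray,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> ScalerSpec:
    """Fit scaling statistics on training rows of complete numeric columns.

    ``bounds`` lets a column declare known (min, max) used instead of the
    observed training extremes under min-max scaling.
    """
    if kind not in SCALER_KINDS:
        raise ValueError(f"unknown scaler kind {kind!r}; expected one of {SCALER_KINDS}")
    spec = ScalerSpec(kind=kind)
    if kind == "unitnorm":
        return spec
    bounds = bounds or {}
    mask = np.asarray(train_mask, dtype=bool)
    for name in numeric.columns:
        col = numeric[name].to_numpy(dtype=float)[mask]
        if kind == "minmax":
            lo, hi = bounds.get(name, (col.min(), col.max()))
            if hi <= lo:
                raise ValueError(f"column {name!r} is constant; min-max scaling undefined")
            spec.shift[name], spec.scale[name] = float(lo), float(hi - lo)
        elif kind == "zscore":
            mu = col.mean()
            sigma = col.std(ddof=0)  # population sd
            if sigma <= 0:
                raise ValueError(f"column {name!r} is constant; z-score scaling undefined")
            spec.shift[name], spec.scale[name] = float(mu), float(sigma)
        elif kind == "robust":
            med = np.median(col)
            q1, q3 = np.percentile(col, [25, 75])
            iqr = q3 - q1
            if iqr <= 0:
                raise ValueError(f"column {name!r} has zero IQR; robust scaling undefined")
            spec.shift[name], spec.scale[name] = float(med), float(iqr)
    return spec


def apply_scaler(spec: ScalerSpec, numeric: pd.DataFrame) -> pd.DataFrame:
    """Apply fitted column statistics to (any) rows; no clipping."""
    out = {}
    for name in numeric.columns:
        out[name] = spec.transform_column(name, numeric[name].to_numpy(dtype=float))
    return pd.DataFrame(out, index=numeric.index)


# ---------------------------------------------------------------------------
# Fitted feature schema and design matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureSchema:
    """Everything fitted on training rows, enough to encode new data exactly.

    ``groups`` maps each original variable to the indices of its encoded
    columns: one index for a numeric or boolean column, K_j indices for a
    categorical with K_j vocabulary entries.  Total encoded width is
    M' = M_num + sum_j K_j (+ booleans).
    """

    raw: RawSchema
    scaler: ScalerSpec
    numeric_means: dict[str, float]
    categorical_modes: dict[str, str]
    vocabularies: dict[str, list[str]]
    encoded_columns: list[str]
    groups: dict[str, list[int]]
    strict: bool = True

    @property
    def n_features(self) -> int:
        return len(self.encoded_columns)

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def transform(self, raw: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
        """Encode rows with the fitted statistics; returns (X, y or None)."""
        n = len(raw)
        blocks: list[np.ndarray] = []
        numeric_cols: dict[str, pd.Series] = {}
        for spec in self.raw.feature_columns:
            if spec.name not in raw.columns:
                raise ValueError(f"input table is missing column {spec.name!r}")
            col = raw[spec.name]
            if spec.role == "numeric":
                missing = is_missing(col)
                vals = pd.to_numeric(col.where(~missing), errors="coerce")
                numeric_cols[spec.name] = vals.fillna(self.numeric_means[spec.name])
            elif spec.role == "categorical":
                filled = col.copy()
                filled[is_missing(col)] = self.categorical_modes[spec.name]
                vocab = self.vocabularies[spec.name]
                block = np.vstack([
                    one_hot_encode(v, vocab, strict=self.strict) for v in filled
                ])
                blocks.append((spec.name, block))
            else:  # boolean feature
                filled = col.copy()
                filled[is_missing(col)] = self.categorical_modes[spec.name]
                vec = np.array([
                    encode_boolean(v, (spec.true_value, spec.false_value)) for v in filled
                ], dtype=float)
                blocks.append((spec.name, vec[:, None]))

        scaled = apply_scaler(self.scaler, pd.DataFrame(numeric_cols, index=raw.index)) \
            if numeric_cols else pd.DataFrame(index=raw.index)

        parts = []
        for spec in self.raw.feature_columns:
            if spec.role == "numeric":
                parts.append(scaled[spec.name].to_numpy()[:, None])
            else:
                name, block = next(b for b in blocks if b[0] == spec.name)
                parts.append(block)
        X = np.hstack(parts) if parts else np.empty((n, 0))

        if self.scaler.row_normalize:
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            norms[norms == 0] = 1.0  # all-zero rows left untouched
            X = X / norms

        y = None
        label = self.raw.label
        if label.name in raw.columns:
            y = np.array([
                encode_boolean(v, (label.true_value, label.false_value))
                for v in raw[label.name]
            ])
        return X, y

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "raw": {
                "columns": [
                    {
                        "name": c.name, "role": c.role, "vocabulary": c.vocabulary,
                        "bounds": list(c.bounds) if c.bounds else None,
                        "true_value": c.true_value, "false_value": c.false_value,
                    }
                    for c in self.raw.columns
                ]
            },
            "scaler": {
                "kind": self.scaler.kind, "shift": self.scaler.shift,
                "scale": self.scaler.scale, "fitted_on_train": self.scaler.fitted_on_train,
            },
            "numeric_means": self.numeric_means,
            "categorical_modes": self.categorical_modes,
            "vocabularies": self.vocabularies,
            "encoded_columns": self.encoded_columns,
            "groups": self.groups,
            "strict": self.strict,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureSchema":
        raw = RawSchema.from_yaml_dict(data["raw"])
        s = data["scaler"]
        scaler = ScalerSpec(kind=s["kind"], shift=dict(s["shift"]), scale=dict(s["scale"]),
                            fitted_on_train=s["fitted_on_train"])
        return cls(
            raw=raw, scaler=scaler,
            numeric_means=dict(data["numeric_means"]),
            categorical_modes=dict(data["categorical_modes"]),
            vocabularies={k: list(v) for k, v in data["vocabularies"].items()},
            encoded_columns=list(data["encoded_columns"]),
            groups={k: list(v) for k, v in data["groups"].items()},
            strict=data.get("strict", True),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DesignMatrix:
    """Complete encoded design matrix with labels and its fitted schema."""

    X: np.ndarray
    y: np.ndarray | None
    schema: FeatureSchema

    @property
    def columns(self) -> list[str]:
        return self.schema.encoded_columns

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        if self.y is not None:
            df["Class"] = self.y
        return df


def build_design_matrix(
    raw: pd.DataFrame,
    schema: RawSchema,
    scaler: str = "minmax",
    train_mask: np.ndarray | None = None,
    strict: bool = True,
) -> tuple[DesignMatrix, FeatureSchema]:
    """Fit preprocessing on training rows and encode the whole table.

    Order: impute (mean / mode) -> encode (one-hot / indicator) -> scale
    numeric columns.  ``train_mask`` selects the rows whose statistics are
    used; all rows are transformed.  Deterministic for fixed input.
    """
    if train_mask is None:
        train_mask = np.ones(len(raw), dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ValueError("train_mask selects no rows")

    numeric_means: dict[str, float] = {}
    categorical_modes: dict[str, str] = {}
    vocabularies: dict[str, list[str]] = {}
    numeric_imputed: dict[str, pd.Series] = {}
    bounds: dict[str, tuple[float, float]] = {}

    for spec in schema.feature_columns:
        col = raw[spec.name]
        if spec.role == "numeric":
            imputed = impute_numeric_mean(col, train_mask)
            missing = is_missing(col)
            train_vals = pd.to_numeric(col.where(~missing), errors="coerce")[train_mask & ~missing]
            numeric_means[spec.name] = float(train_vals.mean())
            numeric_imputed[spec.name] = imputed
            if spec.bounds is not None:
                bounds[spec.name] = spec.bounds
        else:
            imputed = impute_categorical_mode(col, train_mask)
            missing = is_missing(col)
            train_vals = col[train_mask & ~missing]
            counts = train_vals.value_counts()
            categorical_modes[spec.name] = sorted(counts[counts == counts.max()].index)[0]
            if spec.role == "categorical":
                if spec.vocabulary is not None:
                    vocabularies[spec.name] = list(spec.vocabulary)
                else:
                    vocabularies[spec.name] = sorted(set(imputed[train_mask]))

    numeric_frame = pd.DataFrame(numeric_imputed, index=raw.index)
    scaler_spec = fit_scaler(scaler, numeric_frame, train_mask, bounds=bounds) \
        if len(numeric_frame.columns) else ScalerSpec(kind=scaler)

    encoded_columns: list[str] = []
    groups: dict[str, list[int]] = {}
    for spec in schema.feature_columns:
        start = len(encoded_columns)
        if spec.role == "numeric":
            encoded_columns.append(spec.name)
        elif spec.role == "categorical":
            encoded_columns.extend(f"{spec.name}={v}" for v in vocabularies[spec.name])
        else:
            encoded_columns.append(spec.name)
        groups[spec.name] = list(range(start, len(encoded_columns)))

    fitted = FeatureSchema(
        raw=schema, scaler=scaler_spec, numeric_means=numeric_means,
        categorical_modes=categorical_modes, vocabularies=vocabularies,
        encoded_columns=encoded_columns, groups=groups, strict=strict,
    )
    X, y = fitted.transform(raw)
    return DesignMatrix(X=X, y=y, schema=fitted), fitted


# ---------------------------------------------------------------------------
# SMOTE-style minority oversampling
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolating minority-class nearest neighbours.

    Applied to the *training* design matrix only, after the train/test
    split.  Synthetic rows are x_i + u (x_nn - x_i) with u ~ U(0,1) and a
    neighbour drawn among the k nearest minority points.  With a schema,
    interpolated one-hot blocks are snapped back to a valid pattern by
    argmax within each group and single binary columns are rounded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class input; cannot oversample")
    minority = classes[np.argmin(counts)]
    n_minority, n_majority = counts.min(), counts.max()
    n_needed = int(n_majority - n_minority)
    if n_needed == 0:
        return X.copy(), y.copy()
    if n_minority < 2:
        raise ValueError("minority class has fewer than 2 members; cannot interpolate")
    if n_minority <= k_neighbors:
        logger.warning("minority count %d <= k_neighbors %d; reducing k to %d",
                       n_minority, k_neighbors, n_minority - 1)
        k_neighbors = n_minority - 1

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # column 0 is the point itself

    synth = np.empty((n_needed, X.shape[1]))
    for s in range(n_needed):
        i = rng.integers(n_minority)
        j = idx[i][1 + rng.integers(k_neighbors)]
        u = rng.random()
        synth[s] = X_min[i] + u * (X_min[j] - X_min[i])

    if schema is not None:
        for name, cols in schema.groups.items():
            if len(cols) > 1:  # one-hot block: snap to argmax pattern
                block = synth[:, cols]
                hot = np.argmax(block, axis=1)
                block[:] = 0.0
                block[np.arange(len(block)), hot] = 1.0
                synth[:, cols] = block
            else:
                spec = next(c for c in schema.raw.feature_columns if c.name == name)
                if spec.role == "boolean":
                    synth[:, cols[0]] = np.round(synth[:, cols[0]])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out
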