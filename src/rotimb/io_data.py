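"""Loading, encoding, and validating two-class tabular datasets.

The package targets screening-style data: a large "normal" (majority,
negative) class and a small "abnormal" (minority, positive) class, e.g. a
mammography cohort with 10,923 healthy and 260 cancerous patients.
Internally the abnormal class is always coded 1 and the normal class 0,
and "positive" always means abnormal.

Nominal attributes are carried as integer category codes (stored as floats
so that NaN can mark missing entries) together with their domains, until
:func:`encode_features` one-hot encodes them.  Learning operations require
a fully numeric, finite feature matrix; :func:`require_numeric` enforces
that contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.io import arff as _scipy_arff

ABNORMAL = 1
NORMAL = 0

Convention = Literal["abnormal_over_total", "abnormal_over_normal"]


class DataError(ValueError):
    """Raised when a dataset violates the two-class tabular contract."""


@dataclass
class LabeledDataset:
    """An N x n feature matrix with binary abnormal/normal labels.

    Parameters
    ----------
    features:
        ``(N, n)`` float matrix.  For nominal columns the entries are
        category codes into ``nominal_domains``; NaN marks missing values.
    labels:
        length-N integer vector over ``{ABNORMAL, NORMAL}`` = {1, 0}.
    feature_names:
        length-n column names, in original file order.
    nominal_domains:
        map from column index to the ordered tuple of category levels for
        columns that still require one-hot encoding.  Empty for fully
        numeric data.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    nominal_domains: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.features.shape[0],):
            raise DataError("labels must be a length-N vector")
        bad = set(np.unique(self.labels)) - {ABNORMAL, NORMAL}
        if bad:
            raise DataError(f"labels must be 0 (normal) or 1 (abnormal), got {sorted(bad)}")
        self.feature_names = tuple(self.feature_names)
        if len(self.feature_names) != self.features.shape[1]:
            raise DataError("feature_names length must match the number of columns")

    @property
    def n_examples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_abnormal(self) -> int:
        return int(np.sum(self.labels == ABNORMAL))

    @property
    def n_normal(self) -> int:
        return int(np.sum(self.labels == NORMAL))

    @property
    def needs_encoding(self) -> bool:
        """True when nominal columns or missing values remain."""
        return bool(self.nominal_domains) or bool(np.isnan(self.features).any())

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.features)


@dataclass(frozen=True)
class ClassSplit:
    """Per-class views of a dataset: X_a (abnormal rows) and X_n (normal rows)."""

    X_a: np.ndarray
    X_n: np.ndarray
    abnormal_indices: np.ndarray
    normal_indices: np.ndarray

    @property
    def n_abnormal(self) -> int:
        return self.X_a.shape[0]

    @property
    def n_normal(self) -> int:
        return self.X_n.shape[0]


def require_numeric(ds: LabeledDataset, context: str = "this operation") -> None:
    """Raise unless the dataset is fully numeric and finite."""
    if ds.nominal_domains:
        raise DataError(
            f"{context} requires numeric features; call encode_features() first "
            f"(nominal columns: {sorted(ds.nominal_domains)})"
        )
    if not np.isfinite(ds.features).all():
        raise DataError(f"{context} requires finite features; impute missing values first")


def _binary_labels(raw: pd.Series, positive_label: object) -> np.ndarray:
    values = raw.astype(str).str.strip()
    if values.isna().any() or (values == "").any():
        raise DataError("missing values in the label column")
    observed = sorted(values.unique())
    if len(observed) < 2:
        raise DataError(f"not binary: found {len(observed)} label value(s) {observed}")
    if len(observed) > 2:
        raise DataError(f"not binary: found {len(observed)} label values {observed}")
    pos = str(positive_label).strip()
    if pos not in observed:
        raise DataError(f"positive label {pos!r} not among observed labels {observed}")
    return np.where(values.to_numpy() == pos, ABNORMAL, NORMAL)


def _column_to_numeric_or_codes(
    col: pd.Series,
) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Return (values, domain): floats for numeric columns, codes + domain otherwise."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float), None
    text = col.astype("string").str.strip()
    text = text.where(text.notna() & (text != "") & (text != "?"))
    coerced = pd.to_numeric(text, errors="coerce")
    if coerced.notna().equals(text.notna()):
        return coerced.to_numpy(dtype=float), None
    domain = tuple(sorted(text.dropna().unique()))
    code_map = {level: float(i) for i, level in enumerate(domain)}
    codes = np.array(
        [code_map[v] if isinstance(v, str) else np.nan for v in text], dtype=float
    )
    return codes, domain


def load_csv(path: str | Path, label_column: str, positive_label: object) -> LabeledDataset:
    """Read an RFC-4180 CSV with a header row into a :class:`LabeledDataset`.

    ``positive_label`` names the abnormal class; the other observed label
    value becomes the normal class.  Non-numeric columns are recorded as
    nominal (sorted unique non-missing values as the domain); ``?`` and
    empty cells are treated as missing.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, skipinitialspace=True, na_values=["?"])
    except pd.errors.EmptyDataError:
        raise DataError("no data rows") from None
    except pd.errors.ParserError as exc:
        raise DataError(f"unparseable CSV: {exc}") from exc
    if df.shape[0] == 0:
        raise DataError("no data rows")
    if label_column not in df.columns:
        raise DataError(f"missing label column {label_column!r}; have {list(df.columns)}")
    labels = _binary_labels(df[label_column], positive_label)
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise DataError("no feature columns")
    columns, domains = [], {}
    for j, name in enumerate(feature_cols):
        values, domain = _column_to_numeric_or_codes(df[name])
        columns.append(values)
        if domain is not None:
            domains[j] = domain
    return LabeledDataset(
        features=np.column_stack(columns),
        labels=labels,
        feature_names=tuple(feature_cols),
        nominal_domains=domains,
    )


def load_arff(
    path: str | Path,
    positive_label: object,
    label_attribute: str | None = None,
) -> LabeledDataset:
    """Read a Weka-dialect ARFF file (``?`` missing marker).

    ``label_attribute`` defaults to the last declared attribute.  Nominal
    attribute domains come from the ``@attribute`` declarations; the
    resulting dataset is flagged as requiring encoding when nominal
    predictors are present.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    try:
        data, meta = _scipy_arff.loadarff(str(path))
    except Exception as exc:  # scipy raises several parse-error types
        raise DataError(f"unparseable ARFF: {exc}") from exc
    names = list(meta.names())
    if data.shape[0] == 0:
        raise DataError("no data rows")
    label_name = label_attribute if label_attribute is not None else names[-1]
    if label_name not in names:
        raise DataError(f"missing label attribute {label_name!r}")

    def _decode(series: np.ndarray) -> pd.Series:
        out = pd.Series([v.decode() if isinstance(v, bytes) else v for v in series])
        return out.where(out != "?")

    labels = _binary_labels(_decode(data[label_name]).astype(str), positive_label)
    columns, domains, feature_names = [], {}, []
    j = 0
    for name in names:
        if name == label_name:
            continue
        kind, declared = meta[name]
        if kind == "numeric":
            columns.append(np.asarray(data[name], dtype=float))
        else:
            domain = tuple(declared)
            code_map = {level: float(i) for i, level in enumerate(domain)}
            decoded = _decode(data[name])
            columns.append(
                np.array(
                    [code_map[v] if isinstance(v, str) else np.nan for v in decoded],
                    dtype=float,
                )
            )
            domains[j] = domain
        feature_names.append(name)
        j += 1
    return LabeledDataset(
        features=np.column_stack(columns),
        labels=labels,
        feature_names=tuple(feature_names),
        nominal_domains=domains,
    )


def encode_features(ds: LabeledDataset) -> LabeledDataset:
    """One-hot encode nominal columns and impute missing values.

    Missing numeric entries are replaced by the class-independent column
    mean; missing nominal entries by the column mode (smallest code on a
    tie).  Nominal columns expand in place into one indicator column per
    level, named ``<column>=<level>``, so the output column order is
    deterministic.  Idempotent on already-numeric, complete data.
    """
    if not ds.needs_encoding:
        return ds
    columns: list[np.ndarray] = []
    names: list[str] = []
    for j, name in enumerate(ds.feature_names):
        col = ds.features[:, j]
        missing = np.isnan(col)
        if j in ds.nominal_domains:
            domain = ds.nominal_domains[j]
            if len(domain) == 0 or missing.all():
                raise DataError(f"degenerate feature {name!r}: no observed values")
            if missing.any():
                observed = col[~missing].astype(int)
                counts = np.bincount(observed, minlength=len(domain))
                col = col.copy()
                col[missing] = float(np.argmax(counts))  # mode; smallest code on tie
            for level_code, level in enumerate(domain):
                columns.append((col == float(level_code)).astype(float))
                names.append(f"{name}={level}")
        else:
            if missing.all():
                raise DataError(f"degenerate feature {name!r}: all values missing")
            if missing.any():
                col = col.copy()
                col[missing] = col[~missing].mean()
            columns.append(col.astype(float))
            names.append(name)
    return LabeledDataset(
        features=np.column_stack(columns),
        labels=ds.labels.copy(),
        feature_names=tuple(names),
        nominal_domains={},
    )


def class_split(ds: LabeledDataset) -> ClassSplit:
    """Split into the abnormal set X_a (N_a x n) and normal set X_n (N_n x n).

    Row order within each class follows the parent dataset.  Raises when a
    class is empty, since every training operation needs both classes.
    """
    abnormal_idx = np.flatnonzero(ds.labels == ABNORMAL)
    normal_idx = np.flatnonzero(ds.labels == NORMAL)
    if abnormal_idx.size == 0:
        raise DataError("abnormal class is empty")
    if normal_idx.size == 0:
        raise DataError("normal class is empty")
    return ClassSplit(
        X_a=ds.features[abnormal_idx],
        X_n=ds.features[normal_idx],
        abnormal_indices=abnormal_idx,
        normal_indices=normal_idx,
    )


def imbalance_degree(
    n_abnormal: int,
    n_normal: int,
    convention: Convention = "abnormal_over_total",
) -> float:
    """Quantify class skew.

    ``abnormal_over_total`` (default) returns N_a / (N_a + N_n), matching
    how published benchmark tables print the degree; ``abnormal_over_normal``
    returns the verbal minority/majority ratio N_a / N_n.
    """
    if n_abnormal < 1 or n_normal < 1:
        raise DataError("both class counts must be at least 1")
    if convention == "abnormal_over_total":
        return n_abnormal / (n_abnormal + n_normal)
    if convention == "abnormal_over_normal":
        return n_abnormal / n_normal
    raise ValueError(f"unknown convention {convention!r}")
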