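"""Reading, writing and preprocessing of labelled omics matrices.

The central container is :class:`FeatureMatrix`, a samples × features table
with a categorical label per sample and an explicit missing-value mask.
Matrices arrive as delimiter-separated text (GEO series-matrix style exports
keep features in rows, one header line of identifiers, one designated label
row/column).  Features carrying any missing value are removed outright before
selection; in the expression and methylation series this package targets such
features are a tiny fraction of the total, so removal is preferred over
imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing (compared case-insensitively).
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


class ParseError(ValueError):
    """Raised when a cell cannot be interpreted as a number."""


@dataclass(frozen=True)
class FeatureMatrix:
    """A labelled samples × features matrix with a missing-value mask.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_features)
        Measurements; entries flagged in ``missing_mask`` hold NaN.
    labels : ndarray of str, shape (n_samples,)
        Class label per sample.
    feature_ids, sample_ids : ndarray of str
        Unique identifiers along each axis.
    missing_mask : ndarray of bool, same shape as ``values``
        True where the source file contained a missing token.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        feature_ids = np.asarray(self.feature_ids, dtype=object)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        mask = self.missing_mask
        if mask is None:
            mask = np.isnan(values)
        mask = np.asarray(mask, dtype=bool)

        n_samples, n_features = values.shape
        if n_samples < 2:
            raise ValidationError("need at least 2 samples")
        if n_features < 1:
            raise ValidationError("need at least 1 feature")
        if labels.shape != (n_samples,):
            raise ValidationError("labels length must equal n_samples")
        if feature_ids.shape != (n_features,):
            raise ValidationError("feature_ids length must equal n_features")
        if sample_ids.shape != (n_samples,):
            raise ValidationError("sample_ids length must equal n_samples")
        if mask.shape != values.shape:
            raise ValidationError("missing_mask shape must match values")
        _check_unique(feature_ids, "feature id")
        _check_unique(sample_ids, "sample id")

        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "missing_mask", mask)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels.astype(str))


def _check_unique(ids: np.ndarray, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


def _parse_cell(token: str, row: int, col: int) -> tuple[float, bool]:
    """Return (value, is_missing) for one cell; raise ParseError otherwise."""
    stripped = token.strip()
    if stripped.lower() in MISSING_TOKENS:
        return np.nan, True
    try:
        return float(stripped), False
    except ValueError:
        raise ParseError(
            f"non-numeric cell {token!r} at data row {row}, column {col}"
        ) from None


def read_matrix(
    path: str | Path,
    orientation: str = "samples_in_columns",
    label_source: str = "label",
    delimiter: str = "\t",
) -> FeatureMatrix:
    """Read a labelled matrix from delimiter-separated text.

    Parameters
    ----------
    path : str or Path
        Text file with one header line of identifiers.
    orientation : {"samples_in_columns", "samples_in_rows"}
        Series-matrix exports keep features in rows (samples in columns),
        which is the default; the matrix is normalised to samples-in-rows.
    label_source : str
        Name of the row (samples-in-columns) or column (samples-in-rows)
        holding the class labels.
    delimiter : str
        Field separator; ``"\\t"`` for TSV, ``","`` for CSV.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "samples_in_columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        raw = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    lines = [ln for ln in raw.splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header line and at least one data line")
    header = lines[0].split(delimiter)
    col_ids = [h.strip() for h in header[1:]]
    row_ids: list[str] = []
    label_row: list[str] | None = None
    data_rows: list[list[str]] = []
    raw_rows: list[list[str]] = []
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split(delimiter)
        rid = parts[0].strip()
        cells = [c for c in parts[1:]]
        if len(cells) != len(col_ids):
            raise ParseError(
                f"{path}: line {i + 1} has {len(cells)} cells, expected {len(col_ids)}"
            )
        if rid == label_source:
            label_row = [c.strip() for c in cells]
            continue
        row_ids.append(rid)
        raw_rows.append(cells)

    if orientation == "samples_in_columns":
        if label_row is None:
            raise ValidationError(
                f"label row {label_source!r} not found in {path}"
            )
        labels = np.asarray(label_row, dtype=object)
        sample_ids = np.asarray(col_ids, dtype=object)
        feature_ids = np.asarray(row_ids, dtype=object)
        values = np.empty((len(sample_ids), len(feature_ids)))
        mask = np.zeros_like(values, dtype=bool)
        for j, cells in enumerate(raw_rows):
            for i, tok in enumerate(cells):
                values[i, j], mask[i, j] = _parse_cell(tok, j, i)
    else:
        if label_source not in col_ids:
            raise ValidationError(
                f"label column {label_source!r} not found in {path}"
            )
        lab_idx = col_ids.index(label_source)
        feature_ids = np.asarray(
            [c for k, c in enumerate(col_ids) if k != lab_idx], dtype=object
        )
        sample_ids = np.asarray(row_ids, dtype=object)
        labels = np.asarray(
            [cells[lab_idx].strip() for cells in raw_rows], dtype=object
        )
        values = np.empty((len(sample_ids), len(feature_ids)))
        mask = np.zeros_like(values, dtype=bool)
        for i, cells in enumerate(raw_rows):
            k = 0
            for j, tok in enumerate(cells):
                if j == lab_idx:
                    continue
                values[i, k], mask[i, k] = _parse_cell(tok, i, k)
                k += 1

    return FeatureMatrix(
        values=values,
        labels=labels,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        missing_mask=mask,
    )


def write_matrix(
    m: FeatureMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix as samples-in-columns text with a label row.

    Missing entries are written as ``NA``.  The layout round-trips through
    :func:`read_matrix` with default orientation.
    """
    path = Path(path)
    df = pd.DataFrame(
        np.where(m.missing_mask, np.nan, m.values).T,
        index=m.feature_ids,
        columns=m.sample_ids,
    )
    with path.open("w") as fh:
        fh.write("id" + delimiter + delimiter.join(map(str, m.sample_ids)) + "\n")
        fh.write("label" + delimiter + delimiter.join(map(str, m.labels)) + "\n")
        for fid, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(fid) + delimiter + delimiter.join(cells) + "\n")


def drop_missing_features(m: FeatureMatrix) -> FeatureMatrix:
    """Remove every feature that is missing in at least one sample.

    A feature with even a single missing entry is dropped from all samples;
    surviving features keep their relative order and values untouched.
    Idempotent.
    """
    affected = m.missing_mask.any(axis=0)
    if affected.all():
        raise ValidationError("no features remain after missing-value removal")
    n_dropped = int(affected.sum())
    if n_dropped:
        logger.info(
            "dropping %d/%d features with missing values (%.4f%%)",
            n_dropped,
            m.n_features,
            100.0 * n_dropped / m.n_features,
        )
    keep = ~affected
    return replace(
        m,
        values=m.values[:, keep],
        feature_ids=m.feature_ids[keep],
        missing_mask=m.missing_mask[:, keep],
    )


def write_feature_list(
    mask: Sequence[bool] | np.ndarray,
    feature_ids: Sequence[str] | np.ndarray,
    path: str | Path,
) -> None:
    """Write the identifiers of selected features, one per line, in order."""
    mask = np.asarray(mask, dtype=bool)
    feature_ids = np.asarray(feature_ids, dtype=object)
    if mask.shape != feature_ids.shape:
        raise ValidationError(
            f"mask length {mask.size} != feature_ids length {feature_ids.size}"
        )
    Path(path).write_text(
        "".join(str(fid) + "\n" for fid in feature_ids[mask])
    )


def read_feature_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line feature list."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def mask_from_feature_list(
    selected: Sequence[str], feature_ids: Sequence[str] | np.ndarray
) -> np.ndarray:
    """Boolean inclusion mask over ``feature_ids`` for the named features."""
    ids = list(feature_ids)
    index = {fid: i for i, fid in enumerate(ids)}
    mask = np.zeros(len(ids), dtype=bool)
    for fid in selected:
        if fid not in index:
            raise ValidationError(f"unknown feature id {fid!r}")
        mask[index[fid]] = True
    return mask
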