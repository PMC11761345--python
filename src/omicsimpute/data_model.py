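"""Samples x features table with a missing-cell mask, CSV I/O and pre-filtering.

The central container is :class:`OmicsMatrix`: a rectangular numeric table
(rows are samples, columns are features/analytes) where missing cells are
carried as NaN. An optional feature -> group map records which measurement
platform or analyte class each feature belongs to; downstream steps treat
groups independently.

CSV layout: first row feature names, optional second row group labels,
first column sample identifiers, remaining cells numbers / empty / NA.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateOutputError,
    FormatError,
    IdentifierError,
    ParseError,
)

#: markers accepted as a missing cell on read (compared case-insensitively,
#: after stripping whitespace); missing cells are written back as "".
MISSING_MARKERS = frozenset({"", "na", "nan"})


def _parse_cell(text: str, row_label: str, col_label: str) -> float:
    s = text.strip()
    if s.lower() in MISSING_MARKERS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(
            f"cell at sample {row_label!r}, feature {col_label!r} is not "
            f"numeric or a missing marker: {text!r}"
        ) from None


@dataclass
class OmicsMatrix:
    """A samples x features numeric table with NaN-coded missing cells.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature-id columns; dtype float,
        NaN marks a missing measurement.
    groups
        Optional mapping feature id -> group label. When present it must
        assign exactly one label to every feature.
    """

    values: pd.DataFrame
    groups: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise IdentifierError(f"duplicate sample identifiers: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise IdentifierError(f"duplicate feature identifiers: {dupes}")
        if self.groups is not None:
            self.groups = {str(k): str(v) for k, v in self.groups.items()}
            missing = set(map(str, self.values.columns)) - set(self.groups)
            extra = set(self.groups) - set(map(str, self.values.columns))
            if missing or extra:
                raise IdentifierError(
                    f"group map must cover every feature exactly once; "
                    f"uncovered={sorted(missing)}, unknown={sorted(extra)}"
                )

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean table, True where the value is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.mask.to_numpy().sum())

    @property
    def n_observed(self) -> int:
        return self.values.size - self.n_missing

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), None if self.groups is None else dict(self.groups))

    def group_columns(self) -> dict[str, list[str]]:
        """Feature ids per group label; a single pseudo-group when no groups."""
        if self.groups is None:
            return {"__all__": self.feature_ids}
        out: dict[str, list[str]] = {}
        for f in self.feature_ids:
            out.setdefault(self.groups[f], []).append(f)
        return out

    def subset(self, samples: Sequence[str] | None = None,
               features: Sequence[str] | None = None) -> "OmicsMatrix":
        vals = self.values
        if samples is not None:
            vals = vals.loc[list(samples)]
        if features is not None:
            vals = vals[list(features)]
        groups = None
        if self.groups is not None:
            groups = {f: self.groups[f] for f in map(str, vals.columns)}
        return OmicsMatrix(vals.copy(), groups)

    def __eq__(self, other: object) -> bool:  # value equality incl. NaN pattern
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        if self.groups != other.groups:
            return False
        if self.sample_ids != other.sample_ids or self.feature_ids != other.feature_ids:
            return False
        a, b = self.to_numpy(), other.to_numpy()
        return bool(np.array_equal(a, b, equal_nan=True))


@dataclass(frozen=True)
class FilterSpec:
    """Missingness-percentage thresholds for pre-filtering.

    A feature (then, on the reduced table, a sample) is removed when its
    percent-missing is >= the corresponding threshold. ``None`` disables
    that axis.
    """

    feature_pct: float | None = None
    sample_pct: float | None = None

    def __post_init__(self) -> None:
        for name, pct in (("feature_pct", self.feature_pct), ("sample_pct", self.sample_pct)):
            if pct is not None and not (0.0 <= pct <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {pct}")


def read_dataset(path: str | Path, has_group_row: bool = False) -> OmicsMatrix:
    """Read a CSV feature table into an :class:`OmicsMatrix`.

    First row: feature names. Optional second row (``has_group_row``): a
    group label per feature. First column: sample identifiers. Cells must
    parse as a number or a missing marker (empty / NA / NaN, any case).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: need at least one feature column")
    feature_ids = [h.strip() for h in header[1:]]
    width = len(header)
    body = rows[1:]
    groups = None
    if has_group_row:
        if not body:
            raise FormatError(f"{path}: group row requested but file has only a header")
        group_row = body[0]
        if len(group_row) != width:
            raise FormatError(
                f"{path}: group row has {len(group_row)} fields, expected {width}"
            )
        groups = dict(zip(feature_ids, (g.strip() for g in group_row[1:])))
        body = body[1:]
    if not body:
        raise FormatError(f"{path}: no data rows")

    sample_ids: list[str] = []
    data: list[list[float]] = []
    for r, row in enumerate(body, start=2 + int(has_group_row)):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {r} has {len(row)} fields, expected {width}"
            )
        sid = row[0].strip()
        sample_ids.append(sid)
        data.append([_parse_cell(cell, sid, feature_ids[j]) for j, cell in enumerate(row[1:])])

    frame = pd.DataFrame(data, index=sample_ids, columns=feature_ids, dtype=float)
    return OmicsMatrix(frame, groups)


def write_dataset(m: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` as CSV (missing cells as empty fields).

    Round-trips through :func:`read_dataset` (pass ``has_group_row=True``
    when the matrix carries groups).
    """
    if m.n_samples == 0 or m.n_features == 0:
        raise DegenerateOutputError("refusing to write a matrix with an empty dimension")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *m.feature_ids])
        if m.groups is not None:
            writer.writerow(["group", *(m.groups[f] for f in m.feature_ids)])
        arr = m.to_numpy()
        for i, sid in enumerate(m.sample_ids):
            writer.writerow([sid] + ["" if math.isnan(v) else repr(float(v)) for v in arr[i]])


def _pct_missing(mask: np.ndarray, axis: int) -> np.ndarray:
    return 100.0 * mask.mean(axis=axis)


def filter_by_missingness(m: OmicsMatrix, spec: FilterSpec) -> OmicsMatrix:
    """Drop features, then samples, whose percent-missing is >= the threshold.

    Features are evaluated first; sample percentages are recomputed on the
    feature-filtered table. Raises :class:`DegenerateOutputError` when a
    threshold removes an entire axis.
    """
    vals = m.values
    if spec.feature_pct is not None:
        keep = _pct_missing(vals.isna().to_numpy(), axis=0) < spec.feature_pct
        vals = vals.loc[:, keep]
        if vals.shape[1] == 0:
            raise DegenerateOutputError(
                f"feature filter at {spec.feature_pct}% removed every feature"
            )
    if spec.sample_pct is not None:
        keep = _pct_missing(vals.isna().to_numpy(), axis=1) < spec.sample_pct
        vals = vals.loc[keep]
        if vals.shape[0] == 0:
            raise DegenerateOutputError(
                f"sample filter at {spec.sample_pct}% removed every sample"
            )
    groups = None
    if m.groups is not None:
        groups = {str(f): m.groups[str(f)] for f in vals.columns}
    return OmicsMatrix(vals.copy(), groups)
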