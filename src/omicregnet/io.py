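"""Data containers, TSV readers/writers, standardization, and survival filtering.

Omics matrices are stored feature-by-sample on disk (the usual distribution
orientation) and exposed as pandas DataFrames. Regression stages transpose to
samples x features themselves.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

OMICS_KINDS = ("mRNA", "miRNA", "methylation")

#: Patients surviving fewer than this many days are excluded (postoperative
#: deaths etc.); the boundary value itself is kept.
MIN_SURVIVAL_DAYS = 30


class LoadError(ValueError):
    """Malformed input file (bad header, non-numeric cell, duplicate ID)."""


@dataclass
class OmicsMatrix:
    """A feature-by-sample numeric matrix of one omics kind.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples. No missing values.
    omics_kind : str
        One of ``"mRNA"``, ``"miRNA"``, ``"methylation"``.
    standardized : bool
        True once each feature has zero mean and unit (sample) SD.
    """

    values: pd.DataFrame
    omics_kind: str
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.omics_kind not in OMICS_KINDS:
            raise ValueError(
                f"omics_kind must be one of {OMICS_KINDS}, got {self.omics_kind!r}"
            )
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise LoadError(f"missing values in features {bad[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_by_features(self) -> pd.DataFrame:
        """Analysis orientation (samples x features)."""
        return self.values.T

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        return replace(self, values=self.values.loc[list(feature_ids), :])


@dataclass
class SurvivalTable:
    """Per-sample right-censored survival: time in days, event 1=death 0=censored."""

    data: pd.DataFrame  # index: sample_id; columns: time, event

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        if not {"time", "event"} <= set(self.data.columns):
            raise LoadError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise LoadError("survival times must be strictly positive")
        if not self.data["event"].isin([0, 1]).all():
            raise LoadError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=bool)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])

    def to_structured(self) -> np.ndarray:
        """Structured array (event, time) as used by scikit-survival."""
        return np.array(
            list(zip(self.event, self.time)),
            dtype=[("event", "?"), ("time", "<f8")],
        )


def _check_unique(index: Iterable, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise LoadError(f"duplicate {what} ID(s): {dups[:5]}")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_omics_matrix(path: str | Path, omics_kind: str) -> OmicsMatrix:
    """Read a TSV with a header row of sample IDs and first column of feature IDs.

    Duplicate feature or sample IDs, non-numeric cells, and empty files are
    rejected with a :class:`LoadError` naming the offender. Features with any
    missing value are dropped (count reported in the error-free path via the
    returned matrix's shape; silent imputation is never performed).
    """
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(fh, sep="\t", index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise LoadError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise LoadError(f"{path}: no data rows")
    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        # locate a specific offending cell for the message
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
        raise LoadError(
            f"{path}: non-numeric value in column {col!r}"
            + (f", row {bad_rows[0]!r}" if bad_rows else "")
        )
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    if len(df) < n_before:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d feature(s) with missing values", n_before - len(df)
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(values=df.astype(float), omics_kind=omics_kind)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id")


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a TSV of (sample_id, time_days, event)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    cols = list(df.columns)
    if len(cols) < 3:
        raise LoadError(f"{path}: expected columns sample_id, time_days, event")
    df = df.rename(columns={cols[0]: "sample_id", cols[1]: "time", cols[2]: "event"})
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SurvivalTable(df[["time", "event"]].astype(float).assign(
        event=lambda d: d["event"].astype(int)
    ))


def write_survival(s: SurvivalTable, path: str | Path) -> None:
    out = s.data.copy()
    out.insert(0, "sample_id", out.index)
    out.rename(columns={"time": "time_days"}).to_csv(
        path, sep="\t", index=False
    )


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Scale every feature to zero mean and unit sample SD (ddof=1).

    Raises ``ValueError`` listing zero-variance features; the caller decides
    whether to drop them first.
    """
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() < 1e-12)
    if zero.size:
        names = [m.feature_ids[i] for i in zero[:10]]
        raise ValueError(f"zero-variance feature(s): {names}")
    out = pd.DataFrame(
        (vals - mu) / sd, index=m.values.index, columns=m.values.columns
    )
    return OmicsMatrix(values=out, omics_kind=m.omics_kind, standardized=True)


def drop_zero_variance(m: OmicsMatrix) -> OmicsMatrix:
    """Remove constant features (helper so standardize preconditions hold)."""
    sd = m.values.std(axis=1, ddof=1)
    keep = sd[sd >= 1e-12].index
    return m.subset_features(list(keep))


def filter_survival(s: SurvivalTable, min_days: float = MIN_SURVIVAL_DAYS) -> SurvivalTable:
    """Drop samples with survival time below ``min_days`` (boundary kept)."""
    keep = s.data["time"] >= min_days
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(f"all {len(s.data)} samples below {min_days} days; nothing to analyze")
    if n_removed:
        import logging

        logging.getLogger(__name__).info(
            "removed %d sample(s) with survival < %g days", n_removed, min_days
        )
    return SurvivalTable(s.data.loc[keep])


def align_samples(*tables: OmicsMatrix | SurvivalTable) -> list[str]:
    """Sorted intersection of sample IDs across all tables.

    Raises ``ValueError`` with per-table sizes when the intersection is empty.
    """
    if not tables:
        raise ValueError("no tables given")
    sets = [set(t.sample_ids) for t in tables]
    common = set.intersection(*sets)
    if not common:
        sizes = [len(s) for s in sets]
        raise ValueError(f"empty sample intersection (per-table sizes: {sizes})")
    return sorted(common)


def apply_alignment(
    alignment: Sequence[str], *tables: OmicsMatrix | SurvivalTable
) -> tuple:
    """Subset every table to the aligned samples, in the alignment's order."""
    return tuple(t.subset_samples(list(alignment)) for t in tables)
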