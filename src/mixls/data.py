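"""Longitudinal data container and CSV ingestion.

Intensive longitudinal data (e.g. ecological momentary assessment) arrive as
occasion-level rows keyed by a subject identifier, sorted so each subject's
rows are contiguous.  Variables are classified automatically as level-1
(time-varying) or level-2 (time-invariant) by a constancy-within-subject
check.  Missing values are flagged with a user-declared non-zero numeric code
and handled by listwise deletion over the variables a model actually uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, MissingCodeError, SortOrderError

__all__ = [
    "LongitudinalData",
    "read_longitudinal_csv",
    "decompose_within_between",
    "aggregate_to_subject_level",
]


@dataclass
class LongitudinalData:
    """Occasion-level dataset with a subject-level (level-2) grouping.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per measurement occasion.  Must be sorted so each subject's
        rows are contiguous.
    id_col : str
        Name of the subject-identifier column.
    """

    frame: pd.DataFrame
    id_col: str
    level1_names: list = field(default_factory=list)
    level2_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.id_col not in self.frame.columns:
            raise DataError(f"ID column {self.id_col!r} not in data")
        ids = np.asarray(self.frame[self.id_col])
        if len(ids) == 0:
            raise DataError("empty dataset")
        _check_contiguous(ids)
        self.frame = self.frame.reset_index(drop=True)
        # row index where each subject starts (for segment reductions)
        change = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
        self._starts = change
        self.subject_ids = ids[change]
        self.occasions_per_subject = np.diff(np.r_[change, len(ids)])
        if not self.level1_names and not self.level2_names:
            self._classify()
        if self.n_subjects < 2:
            raise DataError("need at least 2 subjects")

    # -- registry ---------------------------------------------------------
    def _classify(self):
        self.level1_names, self.level2_names = [], []
        for name in self.frame.columns:
            if name == self.id_col:
                continue
            if self.is_time_invariant(name):
                self.level2_names.append(name)
            else:
                self.level1_names.append(name)

    def is_time_invariant(self, var):
        """True if `var` is constant within every subject."""
        x = np.asarray(self.frame[var], dtype=float)
        dev = x - np.repeat(self.subject_means(var), self.occasions_per_subject)
        return bool(np.all(np.abs(dev) <= 1e-12 * (1.0 + np.abs(x))))

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self):
        return len(self.subject_ids)

    @property
    def n_obs(self):
        return len(self.frame)

    @property
    def row_starts(self):
        """Start index of each subject's row block (for np.add.reduceat)."""
        return self._starts

    def column(self, name):
        if name not in self.frame.columns:
            raise DataError(f"unknown variable {name!r}")
        return np.asarray(self.frame[name], dtype=float)

    def design(self, names, intercept=True):
        """Column-stacked design matrix, implied leading intercept."""
        cols = [np.ones(self.n_obs)] if intercept else []
        cols += [self.column(n) for n in names]
        return np.column_stack(cols) if cols else np.empty((self.n_obs, 0))

    def subject_means(self, var):
        x = self.column(var) if isinstance(var, str) else np.asarray(var, float)
        sums = np.add.reduceat(x, self._starts)
        return sums / self.occasions_per_subject

    def subject_table(self, names=()):
        """Subject-level DataFrame (one row per subject)."""
        out = pd.DataFrame({self.id_col: self.subject_ids})
        for name in names:
            out[name] = aggregate_to_subject_level(self, name)
        return out


def _check_contiguous(ids):
    seen = set()
    prev = None
    for k, v in enumerate(ids):
        if v != prev:
            if v in seen:
                raise SortOrderError(
                    f"ID {v!r} reappears at row {k} after other IDs intervened; "
                    "sort the file by the subject identifier"
                )
            seen.add(v)
            prev = v


def read_longitudinal_csv(path, id_column=None, missing_code=None,
                          used_variables=None):
    """Read a longitudinal CSV into a :class:`LongitudinalData`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row, sorted by the subject identifier.
    id_column : str, optional
        Defaults to the first column.
    missing_code : float, optional
        Non-zero numeric code marking missing cells.  Rows where any *used*
        variable equals the code are dropped (listwise deletion).
    used_variables : sequence of str, optional
        Variables the requested models touch; deletion and validation are
        restricted to these.  Defaults to all columns.

    Returns
    -------
    data : LongitudinalData
    report : dict
        ``rows_dropped``, ``subjects_dropped`` counts.
    """
    frame = pd.read_csv(path)
    if frame.columns.size == 0 or frame.shape[0] == 0:
        raise DataError("file has no data rows")
    if id_column is None:
        id_column = frame.columns[0]
    if id_column not in frame.columns:
        raise DataError(f"ID column {id_column!r} not found")
    used = list(used_variables) if used_variables is not None else [
        c for c in frame.columns if c != id_column]
    for name in used:
        if name not in frame.columns:
            raise DataError(f"used variable {name!r} not found in file")
        col = pd.to_numeric(frame[name], errors="coerce")
        bad = col.isna() & frame[name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataError(
                f"non-numeric value {frame[name][row]!r} in column {name!r}, "
                f"data row {row + 1}")
        if col.isna().any():
            row = int(np.flatnonzero(col.isna())[0])
            raise DataError(
                f"blank cell in column {name!r}, data row {row + 1}; "
                "blanks are not valid missing-value markers")
        frame[name] = col.astype(float)

    n_subj_before = frame[id_column].nunique()
    dropped = 0
    if missing_code is not None:
        if missing_code == 0:
            raise MissingCodeError(
                "missing-value code must be a non-zero real number")
        mask = np.zeros(len(frame), dtype=bool)
        for name in used:
            mask |= np.asarray(frame[name] == float(missing_code))
        dropped = int(mask.sum())
        frame = frame.loc[~mask].reset_index(drop=True)
        if len(frame) == 0:
            raise DataError("all rows dropped by listwise deletion")

    keep = [id_column] + [c for c in frame.columns if c in used]
    data = LongitudinalData(frame[keep], id_col=id_column)
    report = {
        "rows_dropped": dropped,
        "subjects_dropped": int(n_subj_before - data.n_subjects),
    }
    return data, report


def decompose_within_between(data, var, suffix_bs="_BS", suffix_ws="_WS"):
    """Disaggregate a time-varying covariate into BS and WS components.

    Adds ``var_BS`` (subject mean, a level-2 variable) and ``var_WS``
    (occasion deviation from the subject mean, level-1).  Their sum
    reconstructs ``var`` exactly and each subject's WS component averages
    to zero.
    """
    if var in data.level2_names:
        raise DataError(
            f"{var!r} is time-invariant; within/between decomposition "
            "applies to level-1 variables only")
    if var not in data.level1_names:
        raise DataError(f"unknown level-1 variable {var!r}")
    means = data.subject_means(var)
    bs = np.repeat(means, data.occasions_per_subject)
    frame = data.frame.copy()
    frame[var + suffix_bs] = bs
    frame[var + suffix_ws] = data.column(var) - bs
    out = LongitudinalData(
        frame, data.id_col,
        level1_names=data.level1_names + [var + suffix_ws],
        level2_names=data.level2_names + [var + suffix_bs],
    )
    return out


def aggregate_to_subject_level(data, var):
    """One value per subject: the constant for level-2 variables, the
    subject mean for level-1 variables (with a transformation notice)."""
    if var not in data.frame.columns:
        raise DataError(f"unknown variable {var!r}")
    if var in data.level1_names:
        warnings.warn(
            f"time-varying variable {var!r} aggregated to its subject-level "
            "mean for subject-level use", UserWarning, stacklevel=2)
        return data.subject_means(var)
    # level-2: constant within subject, take the first row's value
    return data.column(var)[data.row_starts]
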