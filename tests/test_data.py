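"""Data container, CSV ingestion and within/between decomposition."""

import io

import numpy as np
import pandas as pd
import pytest

from mixls import (LongitudinalData, aggregate_to_subject_level,
                   decompose_within_between, read_longitudinal_csv)
from mixls.errors import DataError, MissingCodeError, SortOrderError


def _frame():
    return pd.DataFrame({
        "id": [1, 1, 1, 2, 2, 3, 3, 3, 3],
        "y": [1.0, 2.0, 3.0, 4.0, 6.0, 1.0, 1.0, 1.0, 5.0],
        "sex": [0, 0, 0, 1, 1, 0, 0, 0, 0],
        "mood": [2.0, 4.0, 6.0, 1.0, 3.0, 0.0, 2.0, 2.0, 4.0],
    })


def test_container_basics():
    d = LongitudinalData(_frame(), "id")
    assert d.n_subjects == 3
    assert d.n_obs == 9
    assert list(d.subject_ids) == [1, 2, 3]
    assert list(d.occasions_per_subject) == [3, 2, 4]
    assert list(d.row_starts) == [0, 3, 5]
    np.testing.assert_allclose(d.subject_means("y"), [2.0, 5.0, 2.0])


def test_level_classification():
    d = LongitudinalData(_frame(), "id")
    assert "sex" in d.level2_names
    assert "y" in d.level1_names and "mood" in d.level1_names


def test_design_matrix_has_implied_intercept():
    d = LongitudinalData(_frame(), "id")
    X = d.design(["sex"])
    assert X.shape == (9, 2)
    np.testing.assert_allclose(X[:, 0], 1.0)
    with pytest.raises(DataError):
        d.design(["nope"])


def test_unsorted_ids_rejected():
    f = _frame()
    f.loc[8, "id"] = 1      # subject 1 reappears after 2 and 3
    with pytest.raises(SortOrderError):
        LongitudinalData(f, "id")


def test_empty_and_single_subject_rejected():
    with pytest.raises(DataError):
        LongitudinalData(pd.DataFrame({"id": []}), "id")
    with pytest.raises(DataError):
        LongitudinalData(pd.DataFrame({"id": [1, 1], "y": [0.0, 1.0]}), "id")
    with pytest.raises(DataError):
        LongitudinalData(_frame(), "subject")  # no such column


def test_read_csv_with_missing_code():
    f = _frame()
    f.loc[1, "y"] = -999.0
    buf = io.StringIO(f.to_csv(index=False))
    data, report = read_longitudinal_csv(buf, missing_code=-999)
    assert report["rows_dropped"] == 1
    assert report["subjects_dropped"] == 0
    assert data.n_obs == 8


def test_read_csv_zero_missing_code_rejected():
    buf = io.StringIO(_frame().to_csv(index=False))
    with pytest.raises(MissingCodeError):
        read_longitudinal_csv(buf, missing_code=0)


def test_read_csv_rejects_non_numeric_and_blank_cells():
    f = _frame().astype(object)
    f.loc[2, "mood"] = "high"
    with pytest.raises(DataError, match="non-numeric"):
        read_longitudinal_csv(io.StringIO(f.to_csv(index=False)))
    f2 = _frame()
    f2.loc[2, "mood"] = np.nan
    with pytest.raises(DataError, match="blank"):
        read_longitudinal_csv(io.StringIO(f2.to_csv(index=False)))


def test_read_csv_restricts_deletion_to_used_variables():
    f = _frame()
    f.loc[0, "mood"] = -999.0   # missing in an unused column
    buf = io.StringIO(f.to_csv(index=False))
    data, report = read_longitudinal_csv(buf, missing_code=-999,
                                         used_variables=["y", "sex"])
    assert report["rows_dropped"] == 0
    assert data.n_obs == 9
    with pytest.raises(DataError, match="not found"):
        read_longitudinal_csv(io.StringIO(_frame().to_csv(index=False)),
                              used_variables=["ghost"])


def test_decompose_within_between():
    d = LongitudinalData(_frame(), "id")
    out = decompose_within_between(d, "mood")
    bs = out.column("mood_BS")
    ws = out.column("mood_WS")
    np.testing.assert_allclose(bs + ws, d.column("mood"))
    np.testing.assert_allclose(out.subject_means("mood_WS"), 0.0, atol=1e-12)
    assert "mood_BS" in out.level2_names
    assert "mood_WS" in out.level1_names
    with pytest.raises(DataError):
        decompose_within_between(d, "sex")       # time-invariant
    with pytest.raises(DataError):
        decompose_within_between(d, "missing")


def test_aggregate_to_subject_level():
    d = LongitudinalData(_frame(), "id")
    np.testing.assert_allclose(aggregate_to_subject_level(d, "sex"),
                               [0, 1, 0])
    with pytest.warns(UserWarning, match="aggregated"):
        m = aggregate_to_subject_level(d, "mood")
    np.testing.assert_allclose(m, d.subject_means("mood"))
    with pytest.raises(DataError):
        aggregate_to_subject_level(d, "ghost")
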