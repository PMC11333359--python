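import numpy as np
import pandas as pd
import pytest

from faersig.preprocess import CASE_COLUMNS, AnalysisDataset


def make_cases(rows):
    """rows: iterable of (primaryid, caseid) or dicts with case fields."""
    records = []
    for row in rows:
        if isinstance(row, dict):
            rec = {
                "primaryid": row["primaryid"],
                "caseid": row.get("caseid", row["primaryid"]),
                "sex": row.get("sex", "missing"),
                "age_years": row.get("age_years", np.nan),
                "reporter_type": row.get("reporter_type", "other_missing"),
                "reporter_country": row.get("reporter_country"),
                "quarter": row.get("quarter", "2014Q3"),
            }
        else:
            pid, caseid = row
            rec = {
                "primaryid": pid, "caseid": caseid, "sex": "missing",
                "age_years": np.nan, "reporter_type": "other_missing",
                "reporter_country": None, "quarter": "2014Q3",
            }
        records.append(rec)
    return pd.DataFrame(records, columns=CASE_COLUMNS)


def make_dataset(case_rows, event_rows, exposure):
    """Assemble an AnalysisDataset from terse fixtures.

    event_rows: iterable of (primaryid, pt); exposure: {label: ids}.
    """
    cases = make_cases(case_rows)
    events = pd.DataFrame(event_rows, columns=["primaryid", "pt"])
    ds = AnalysisDataset(
        cases=cases,
        events=events,
        exposure={k: frozenset(v) for k, v in exposure.items()},
    )
    ds.validate()
    return ds


@pytest.fixture
def mention_dataset():
    """Exposed reports carry events {X, X, Y}; other reports carry {X, Z}."""
    return make_dataset(
        case_rows=[(1, 1), (2, 2), (3, 3), (4, 4)],
        event_rows=[(1, "X"), (1, "X"), (2, "Y"), (3, "X"), (4, "Z")],
        exposure={"drug": {1, 2}},
    )
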