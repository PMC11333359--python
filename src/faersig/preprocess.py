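"""Deduplication and analysis-dataset assembly.

Two dedup rules are applied to the pooled, cross-quarter case list:

1. a primaryid appearing on more than one raw row is an error — every row
   bearing it is excluded;
2. among rows sharing a caseid, only the row with the largest primaryid
   (the latest case version) survives.

The exposed set for a drug query is the set of surviving reports where a
matching drug is the primary suspect (role code PS).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from faersig.faers_io import DrugEntry, EventEntry, ReportCase

logger = logging.getLogger(__name__)

CASE_COLUMNS = [
    "primaryid", "caseid", "sex", "age_years",
    "reporter_type", "reporter_country", "quarter",
]
DRUG_COLUMNS = ["primaryid", "drugname", "prod_ai", "role_cod"]
EVENT_COLUMNS = ["primaryid", "pt"]


def _to_frame(records, columns: list[str]) -> pd.DataFrame:
    """Normalize a DataFrame or a sequence of dataclass records."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in columns if c not in records.columns]
        if missing:
            raise ValueError(f"input frame lacks columns {missing}")
        return records[columns].copy()
    rows = list(records)
    if rows and not dataclasses.is_dataclass(rows[0]):
        raise TypeError(f"expected dataclass records, got {type(rows[0])}")
    return pd.DataFrame(
        [[getattr(r, c) for c in columns] for r in rows], columns=columns
    )


@dataclass(frozen=True)
class DrugQuery:
    """A drug of interest: generic plus brand names, matched as substrings."""

    label: str
    generic_names: Sequence[str] = ()
    brand_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"query {self.label!r} has no usable names")

    @property
    def names(self) -> list[str]:
        return [
            n.strip() for n in (*self.generic_names, *self.brand_names) if n.strip()
        ]


@dataclass
class DedupLog:
    n_input: int = 0
    n_primaryid_collision: int = 0
    n_caseid_superseded: int = 0
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


@dataclass
class AnalysisDataset:
    """Deduplicated background plus per-drug exposed report sets.

    ``cases`` and ``events`` are frames with the :data:`CASE_COLUMNS` /
    :data:`EVENT_COLUMNS` schemas; ``exposure`` maps a drug label to the
    set of primaryids where that drug is the primary suspect.
    """

    cases: pd.DataFrame
    events: pd.DataFrame
    exposure: dict[str, frozenset[int]] = field(default_factory=dict)
    dedup_log: DedupLog | None = None

    def validate(self) -> None:
        ids = set(self.cases["primaryid"])
        if len(ids) != len(self.cases):
            raise ValueError("cases contain duplicate primaryids")
        if not set(self.events["primaryid"]).issubset(ids):
            raise ValueError("events reference unknown primaryids")
        for label, exposed in self.exposure.items():
            if not set(exposed).issubset(ids):
                raise ValueError(f"exposure[{label!r}] references unknown primaryids")


def deduplicate(cases) -> tuple[pd.DataFrame, DedupLog]:
    """Apply the two dedup rules; returns (surviving cases, log).

    Accepts a case frame or a sequence of :class:`~faersig.faers_io.ReportCase`.
    Output is sorted by primaryid, so it is invariant to input row order,
    and the operation is idempotent.
    """
    df = _to_frame(cases, CASE_COLUMNS)
    log = DedupLog(n_input=len(df))
    colliding = df["primaryid"].duplicated(keep=False)
    log.n_primaryid_collision = int(colliding.sum())
    df = df.loc[~colliding]
    if len(df):
        latest = df.groupby("caseid")["primaryid"].transform("max")
        keep = df["primaryid"] == latest
        log.n_caseid_superseded = int((~keep).sum())
        df = df.loc[keep]
    df = df.sort_values("primaryid", kind="mergesort").reset_index(drop=True)
    log.n_output = len(df)
    return df, log


def match_drug(entries, query: DrugQuery) -> frozenset[int]:
    """Primaryids whose report lists a primary-suspect drug matching the query.

    A drug entry matches when its role code is PS and either the verbatim
    drug name or the active-ingredient field contains any query name as a
    case-insensitive substring (after trimming).
    """
    names = query.names  # raises for an all-blank query
    df = _to_frame(entries, DRUG_COLUMNS)
    ps = df.loc[df["role_cod"] == "PS"]
    if ps.empty:
        return frozenset()
    pattern = re.compile("|".join(re.escape(n.lower()) for n in names))
    hit = pd.Series(False, index=ps.index)
    for column in ("drugname", "prod_ai"):
        # match distinct values once, then broadcast — name columns are
        # highly repetitive in real quarters
        values = ps[column].dropna().unique()
        matched = [
            v for v in values if pattern.search(str(v).strip().lower()) is not None
        ]
        if matched:
            hit |= ps[column].isin(matched)
    return frozenset(int(i) for i in ps.loc[hit, "primaryid"].unique())


def build_dataset(
    cases,
    drug_entries,
    event_entries,
    queries: Iterable[DrugQuery] = (),
) -> AnalysisDataset:
    """Deduplicate, restrict drug/event rows to survivors, compute exposure."""
    deduped, log = deduplicate(cases)
    survivors = deduped["primaryid"]
    drugs = _to_frame(drug_entries, DRUG_COLUMNS)
    drugs = drugs.loc[drugs["primaryid"].isin(survivors)]
    events = _to_frame(event_entries, EVENT_COLUMNS)
    events = events.loc[events["primaryid"].isin(survivors)].reset_index(drop=True)
    exposure = {q.label: match_drug(drugs, q) for q in queries}
    ds = AnalysisDataset(cases=deduped, events=events, exposure=exposure, dedup_log=log)
    ds.validate()
    return ds
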