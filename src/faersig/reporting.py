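"""Result surfaces: demographics, top-N signal tables, method comparison,
cross-drug intersections and the clustered log-ROR matrix."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from faersig.preprocess import AnalysisDataset
from faersig.signal_stats import (
    ContingencyTable,
    SignalResult,
    compute_signal,
    result_sort_key,
)

OVERALL = "Overall"

SEX_LEVELS = ["female", "male", "missing"]
AGE_LEVELS = ["<18", "18-64.9", "65-85", ">85", "missing"]
REPORTER_LEVELS = ["consumer", "health_professional", "other_missing"]


def pct(numerator: float, denominator: float, digits: int = 2) -> float:
    """Percentage rounded half-up to ``digits`` decimals (printed-table style)."""
    if denominator == 0:
        return float("nan")
    if float(numerator).is_integer():
        numerator = int(numerator)
    if float(denominator).is_integer():
        denominator = int(denominator)
    raw = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(raw.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


def age_bin(age_years: float | None) -> str:
    """Printed age bins: <18, [18, 65), [65, 85], >85, missing."""
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "missing"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64.9"
    if age_years <= 85:
        return "65-85"
    return ">85"


@dataclass
class DemographicsSummary:
    """Per-drug and overall counts/percentages for the demographic blocks.

    The Overall column follows the summed convention: a report that is
    primary-suspect-exposed to two queried drugs contributes to both drug
    columns and twice to Overall, so Overall equals the row-wise sum of
    the drug columns.  ``overall_distinct`` carries the distinct-report
    count alongside.
    """

    drugs: list[str]
    report_counts: dict[str, int]
    overall_summed: int
    overall_distinct: int
    report_shares: dict[str, float]
    table: pd.DataFrame  # columns: block, level, drug, count, percent

    def count(self, block: str, level: str, drug: str) -> int:
        return int(self._cell(block, level, drug)["count"])

    def percent(self, block: str, level: str, drug: str) -> float:
        return float(self._cell(block, level, drug)["percent"])

    def _cell(self, block: str, level: str, drug: str) -> pd.Series:
        m = self.table[
            (self.table["block"] == block)
            & (self.table["level"] == level)
            & (self.table["drug"] == drug)
        ]
        if len(m) != 1:
            raise KeyError(f"no unique cell ({block}, {level}, {drug})")
        return m.iloc[0]


def _block_counts(sub: pd.DataFrame, column: str, levels: Sequence[str]) -> pd.Series:
    counts = sub[column].value_counts()
    return pd.Series({lvl: int(counts.get(lvl, 0)) for lvl in levels})


def demographics(dataset: AnalysisDataset, top_countries: int = 4) -> DemographicsSummary:
    """Summarize sex, age bins, reporter type and reporter country per
    exposed drug, with the summed Overall column."""
    drugs = list(dataset.exposure)
    cases = dataset.cases
    subsets = {
        label: cases[cases["primaryid"].isin(ids)]
        for label, ids in dataset.exposure.items()
    }
    report_counts = {label: len(sub) for label, sub in subsets.items()}
    overall_summed = sum(report_counts.values())
    all_ids: set[int] = set()
    for ids in dataset.exposure.values():
        all_ids |= set(ids)
    overall_distinct = len(all_ids)
    report_shares = {
        label: pct(n, overall_summed) for label, n in report_counts.items()
    }

    def prepared(sub: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=sub.index)
        out["sex"] = sub["sex"]
        out["age"] = sub["age_years"].map(age_bin)
        out["reporter_type"] = sub["reporter_type"].astype(object)
        out["country"] = sub["reporter_country"].astype(object).fillna("__missing__")
        return out

    prep = {label: prepared(sub) for label, sub in subsets.items()}

    # country levels: top-k by summed overall count, remainder + missing pooled
    pooled_country = pd.concat(
        [p["country"] for p in prep.values()], ignore_index=True
    ) if prep else pd.Series(dtype=object)
    country_counts = pooled_country[pooled_country != "__missing__"].value_counts()
    top = list(country_counts.index[:top_countries])
    country_levels = top + ["Other/Missing"]

    rows = []
    blocks = [
        ("sex", "sex", SEX_LEVELS),
        ("age", "age", AGE_LEVELS),
        ("reporter_type", "reporter_type", REPORTER_LEVELS),
    ]
    for block, column, levels in blocks:
        per_drug = {
            label: _block_counts(prep[label], column, levels) for label in drugs
        }
        for level in levels:
            overall_count = sum(int(per_drug[label][level]) for label in drugs)
            for label in drugs:
                rows.append(
                    {
                        "block": block, "level": level, "drug": label,
                        "count": int(per_drug[label][level]),
                        "percent": pct(per_drug[label][level], report_counts[label]),
                    }
                )
            rows.append(
                {
                    "block": block, "level": level, "drug": OVERALL,
                    "count": overall_count,
                    "percent": pct(overall_count, overall_summed),
                }
            )
    for level in country_levels:
        overall_count = 0
        level_rows = []
        for label in drugs:
            col = prep[label]["country"]
            if level == "Other/Missing":
                n = int((~col.isin(top)).sum())
            else:
                n = int((col == level).sum())
            overall_count += n
            level_rows.append(
                {
                    "block": "country", "level": level, "drug": label,
                    "count": n, "percent": pct(n, report_counts[label]),
                }
            )
        rows.extend(level_rows)
        rows.append(
            {
                "block": "country", "level": level, "drug": OVERALL,
                "count": overall_count,
                "percent": pct(overall_count, overall_summed),
            }
        )
    table = pd.DataFrame(rows, columns=["block", "level", "drug", "count", "percent"])
    return DemographicsSummary(
        drugs=drugs,
        report_counts=report_counts,
        overall_summed=overall_summed,
        overall_distinct=overall_distinct,
        report_shares=report_shares,
        table=table,
    )


def _fmt(x: float, digits: int = 2) -> str:
    return "" if math.isnan(x) else f"{x:.{digits}f}"


def top_signals(
    results: Iterable[SignalResult], n: int = 20, sort_key=None
) -> pd.DataFrame:
    """Rank signals by intensity (default: ROR descending, ties by a then PT).

    Expects positive signals; emits one row per PT with the frequency
    (the a cell), every estimate/bound, and printed-style composite
    columns.  ``n`` larger than the result count returns everything.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = sorted(results, key=sort_key or result_sort_key)[:n]
    rows = []
    for r in ranked:
        rows.append(
            {
                "pt": r.pt,
                "frequency": r.table.a,
                "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
                "prr": r.prr, "chi2": r.chi2,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "ic": r.ic, "ic025": r.ic025,
                "ror_ci": f"{_fmt(r.ror)} ({_fmt(r.ror_low)}-{_fmt(r.ror_high)})",
                "prr_chi2": f"{_fmt(r.prr)} ({_fmt(r.chi2)})",
                "ebgm_ebgm05": f"{_fmt(r.ebgm)} ({_fmt(r.ebgm05)})",
                "ic_ic025": f"{_fmt(r.ic)} ({_fmt(r.ic025)})",
            }
        )
    columns = [
        "pt", "frequency", "ror", "ror_low", "ror_high", "prr", "chi2",
        "ebgm", "ebgm05", "ic", "ic025",
        "ror_ci", "prr_chi2", "ebgm_ebgm05", "ic_ic025",
    ]
    return pd.DataFrame(rows, columns=columns)


def pool_results(
    per_drug: Mapping[str, Sequence[SignalResult]], label: str = "pooled"
) -> list[SignalResult]:
    """Combine per-drug screens over a shared background into one screen.

    Assumes the per-drug results were computed against the same event
    universe with disjoint exposed sets (the usual multi-drug screen of
    one dataset): the pooled exposure is their union, so the pooled
    frequency of a PT is the sum of the per-drug a cells.
    """
    totals = {}  # drug -> (exposed mentions, universe size)
    pt_margin: dict[str, int] = {}
    a_sums: dict[str, int] = {}
    universe = None
    for drug, results in per_drug.items():
        for r in results:
            t = r.table
            n = t.a + t.b + t.c + t.d
            if universe is None:
                universe = n
            elif n != universe:
                raise ValueError("per-drug results come from different universes")
            totals[drug] = t.a + t.b
            margin = t.a + t.c
            if r.pt in pt_margin and pt_margin[r.pt] != margin:
                raise ValueError(f"inconsistent event margin for PT {r.pt!r}")
            pt_margin[r.pt] = margin
            a_sums[r.pt] = a_sums.get(r.pt, 0) + t.a
    if universe is None:
        return []
    exposed_total = sum(totals.values())
    pooled = []
    for pt, a in a_sums.items():
        b = exposed_total - a
        c = pt_margin[pt] - a
        d = universe - a - b - c
        pooled.append(compute_signal(label, pt, ContingencyTable(a, b, c, d)))
    pooled.sort(key=result_sort_key)
    return pooled


def method_comparison(results: Iterable[SignalResult]) -> dict[str, int]:
    """Counts of PTs meeting each criterion, at least one, and all four."""
    counts = {
        "n_pts": 0, "ror": 0, "prr": 0, "bcpnn": 0, "mgps": 0,
        "any": 0, "all_four": 0,
    }
    for r in results:
        counts["n_pts"] += 1
        flags = (r.flag_ror, r.flag_prr, r.flag_bcpnn, r.flag_mgps)
        for name, f in zip(("ror", "prr", "bcpnn", "mgps"), flags):
            counts[name] += f
        counts["any"] += any(flags)
        counts["all_four"] += all(flags)
    return counts


def intersect_signals(
    labelled_sets: Mapping[str, set | frozenset]
) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region counts for 2-4 labelled signal sets.

    Keys are sorted label tuples; the region for a tuple counts elements
    in exactly those sets and no others, so region counts partition the
    union.
    """
    labels = sorted(labelled_sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("intersect_signals takes 2-4 labelled sets")
    sets = {k: set(v) for k, v in labelled_sets.items()}
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[l] for l in labels if l not in combo))
            regions[combo] = len(inside - outside)
    return regions


@dataclass
class SignalMatrix:
    """Clustered log(ROR+1) matrix: PTs x drugs."""

    pts: list[str]  # row labels in clustered order
    drugs: list[str]
    values: np.ndarray  # shape (len(pts), len(drugs))
    row_order: list[int]  # permutation applied to the lexicographic row set

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pts, columns=self.drugs)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for rank, (pt, row) in enumerate(zip(self.pts, self.values)):
            for drug, value in zip(self.drugs, row):
                rows.append(
                    {"pt": pt, "drug": drug, "value": float(value), "row_rank": rank}
                )
        return pd.DataFrame(rows, columns=["pt", "drug", "value", "row_rank"])


def heatmap_matrix(
    per_drug_results: Mapping[str, Sequence[SignalResult]],
    n: int = 20,
    log_base: float = math.e,
) -> SignalMatrix:
    """Log-transformed ROR matrix over the union of per-drug top-N PT sets.

    A cell holds log(ROR+1) when the PT is a positive signal for that
    drug and 0 otherwise (including undefined RORs), so every value is
    finite and nonnegative.  Rows are ordered by hierarchical clustering
    (Euclidean distance, average linkage) on the lexicographically sorted
    row set, which makes the ordering invariant to input permutation.
    """
    drugs = list(per_drug_results)
    top_pts: set[str] = set()
    ror_of: dict[str, dict[str, float]] = {d: {} for d in drugs}
    for drug, results in per_drug_results.items():
        positives = [r for r in results if r.positive]
        for r in positives:
            ror_of[drug][r.pt] = r.ror
        ranked = sorted(positives, key=result_sort_key)[:n]
        top_pts |= {r.pt for r in ranked}
    pts = sorted(top_pts)
    scale = math.log(log_base)
    values = np.zeros((len(pts), len(drugs)))
    for i, pt in enumerate(pts):
        for j, drug in enumerate(drugs):
            r = ror_of[drug].get(pt)
            if r is not None and not math.isnan(r):
                values[i, j] = math.log(r + 1.0) / scale
    if len(pts) > 2:
        order = list(leaves_list(linkage(values, method="average", metric="euclidean")))
    else:
        order = list(range(len(pts)))
    return SignalMatrix(
        pts=[pts[i] for i in order],
        drugs=drugs,
        values=values[order],
        row_order=order,
    )
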