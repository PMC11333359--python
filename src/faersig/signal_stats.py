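"""2x2 contingency tables and the four disproportionality statistics.

For a (drug, event) pair the table is

    a  = target drug & target event        b = target drug & other events
    c  = other drugs & target event        d = other drugs & other events

and the statistics are the reporting odds ratio (Woolf interval), the
proportional reporting ratio with an uncorrected Pearson chi-square, the
closed-form BCPNN information component, and a simplified EBGM
(observed/expected with a log-normal lower bound — not the full
gamma-Poisson mixture fit).  Undefined estimates are NaN with their flag
False; no continuity correction is applied anywhere.

A pair is a positive signal when all four criteria hold simultaneously:
ROR lower bound > 1 with a >= 3; PRR >= 2 with chi2 >= 4 and a >= 3;
IC025 > 0; EBGM05 >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from faersig.preprocess import AnalysisDataset

NAN = float("nan")
_Z = 1.96
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.n == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """All four estimators and positivity flags for one (drug, PT) pair."""

    drug_label: str
    pt: str
    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_mgps: bool

    @property
    def positive(self) -> bool:
        return self.flag_ror and self.flag_prr and self.flag_bcpnn and self.flag_mgps

    @property
    def a(self) -> int:
        return self.table.a


def _se_log(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def ror(t: ContingencyTable) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with its 95% Woolf interval.

    Any zero cell leaves the estimate and interval undefined (NaN) with
    the flag False; otherwise the flag requires lower bound > 1 and a >= 3.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return NAN, NAN, NAN, False
    estimate = (t.a * t.d) / (t.b * t.c)
    half = _Z * _se_log(t)
    low = math.exp(math.log(estimate) - half)
    high = math.exp(math.log(estimate) + half)
    return estimate, low, high, (low > 1.0 and t.a >= 3)


def prr(t: ContingencyTable) -> tuple[float, float, bool]:
    """Proportional reporting ratio and uncorrected Pearson chi-square.

    PRR is undefined when the drug has no reports (a+b = 0) or the event
    never occurs in the background (c = 0).  chi-square is 0 for tables
    with a zero margin (observed equals expected).
    """
    n = t.n
    margins = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if margins == 0:
        chi2 = 0.0
    else:
        chi2 = (t.a * t.d - t.b * t.c) ** 2 * n / margins
    if t.c == 0 or t.a + t.b == 0:
        return NAN, chi2, False
    estimate = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    return estimate, chi2, (estimate >= 2.0 and chi2 >= 4.0 and t.a >= 3)


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float, bool]:
    """Closed-form BCPNN information component and its IC025 bound.

    Shrinkage keeps every quantity finite for any table with positive
    total, including zero cells.  The flag is IC025 > 0.
    """
    n = t.n
    m_drug = t.a + t.b + 1.0
    m_event = t.a + t.c + 1.0
    gamma = (n + 2.0) ** 2 / (m_drug * m_event)
    ic = math.log2((t.a + 1.0) * (n + 2.0) ** 2 / ((n + gamma) * m_drug * m_event))
    vic = (1.0 / _LN2) ** 2 * (
        (n - t.a + gamma - 1.0) / ((t.a + 1.0) * (1.0 + n + gamma))
        + (n - (m_drug - 1.0) + 1.0) / (m_drug * (n + 3.0))
        + (n - (m_event - 1.0) + 1.0) / (m_event * (n + 3.0))
    )
    ic025 = ic - 2.0 * math.sqrt(vic)
    return ic, ic025, ic025 > 0.0


def ebgm(t: ContingencyTable) -> tuple[float, float, bool]:
    """Simplified EBGM: observed/expected with a log-normal lower bound.

    The point estimate needs a > 0; the EBGM05 bound additionally needs
    every cell positive.  The flag is EBGM05 >= 2 (with a > 0).
    """
    if t.a == 0:
        return NAN, NAN, False
    estimate = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    if min(t.b, t.c, t.d) == 0:
        return estimate, NAN, False
    low = math.exp(math.log(estimate) - _Z * _se_log(t))
    return estimate, low, low >= 2.0


def compute_signal(drug_label: str, pt: str, t: ContingencyTable) -> SignalResult:
    """Evaluate all four statistics on one table."""
    ror_est, ror_low, ror_high, f_ror = ror(t)
    prr_est, chi2, f_prr = prr(t)
    ic, ic025, f_ic = bcpnn_ic(t)
    ebgm_est, ebgm05, f_ebgm = ebgm(t)
    return SignalResult(
        drug_label=drug_label, pt=pt, table=t,
        ror=ror_est, ror_low=ror_low, ror_high=ror_high,
        prr=prr_est, chi2=chi2,
        ic=ic, ic025=ic025,
        ebgm=ebgm_est, ebgm05=ebgm05,
        flag_ror=f_ror, flag_prr=f_prr, flag_bcpnn=f_ic, flag_mgps=f_ebgm,
    )


def make_contingency(
    dataset: AnalysisDataset,
    drug_label: str,
    pt: str,
    unit: str = "mentions",
) -> ContingencyTable:
    """Count the 2x2 table for one (drug, PT) pair.

    ``unit="mentions"`` (default): each (report, PT) event row is one
    observation, so the four cells sum to the total number of event rows.
    ``unit="reports"``: each report is one observation and a report counts
    for the event if it mentions the PT at least once.
    """
    if drug_label not in dataset.exposure:
        raise KeyError(f"unknown drug label {drug_label!r}")
    exposed = dataset.exposure[drug_label]
    ev = dataset.events
    is_exposed = ev["primaryid"].isin(exposed)
    is_target = ev["pt"] == pt
    if unit == "mentions":
        a = int((is_exposed & is_target).sum())
        b = int(is_exposed.sum()) - a
        c = int(is_target.sum()) - a
        d = len(ev) - a - b - c
    elif unit == "reports":
        with_pt = set(ev.loc[is_target, "primaryid"])
        ids = dataset.cases["primaryid"]
        a = int(ids.isin(exposed & frozenset(with_pt)).sum())
        b = len(exposed) - a
        c = len(with_pt) - a
        d = len(ids) - a - b - c
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    return ContingencyTable(a, b, c, d)


def result_sort_key(r: SignalResult) -> tuple:
    """Default reporting order: ROR descending (undefined last), then a
    descending, then PT lexicographic."""
    defined = not math.isnan(r.ror)
    return (0 if defined else 1, -(r.ror if defined else 0.0), -r.a, r.pt)


def screen(
    dataset: AnalysisDataset, drug_label: str, unit: str = "mentions"
) -> list[SignalResult]:
    """One SignalResult per distinct PT occurring in the drug's exposed set."""
    if drug_label not in dataset.exposure:
        raise KeyError(f"unknown drug label {drug_label!r}")
    exposed = dataset.exposure[drug_label]
    ev = dataset.events
    is_exposed = ev["primaryid"].isin(exposed)
    n_events = len(ev)
    pt_totals = ev["pt"].value_counts()
    a_counts = ev.loc[is_exposed, "pt"].value_counts()
    n_exposed_mentions = int(is_exposed.sum())
    results = []
    # value_counts on a categorical column lists zero-count categories too
    a_counts = a_counts[a_counts > 0]
    if unit == "mentions":
        for pt_name, a in a_counts.items():
            a = int(a)
            b = n_exposed_mentions - a
            c = int(pt_totals[pt_name]) - a
            d = n_events - a - b - c
            results.append(
                compute_signal(drug_label, str(pt_name), ContingencyTable(a, b, c, d))
            )
    elif unit == "reports":
        for pt_name in a_counts.index:
            t = make_contingency(dataset, drug_label, str(pt_name), unit="reports")
            results.append(compute_signal(drug_label, str(pt_name), t))
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    results.sort(key=result_sort_key)
    return results


def results_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Flatten SignalResults into the screening output table."""
    rows = [
        {
            "drug": r.drug_label, "pt": r.pt,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
            "prr": r.prr, "chi2": r.chi2,
            "ic": r.ic, "ic025": r.ic025,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            "flag_ror": r.flag_ror, "flag_prr": r.flag_prr,
            "flag_bcpnn": r.flag_bcpnn, "flag_mgps": r.flag_mgps,
            "positive": r.positive,
        }
        for r in results
    ]
    columns = [
        "drug", "pt", "a", "b", "c", "d", "ror", "ror_low", "ror_high",
        "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05",
        "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "positive",
    ]
    return pd.DataFrame(rows, columns=columns)
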