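"""PT -> SOC mapping and aggregation of positive signals by organ class.

The licensed dictionary itself is not shipped; a two-column TSV
(``pt``, ``soc``) supplied by the user stands in for it.  Joining is done
on trimmed, casefolded PTs while the emitted table preserves the map's
original SOC spelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from faersig.signal_stats import SignalResult

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"


def _norm(pt: str) -> str:
    return pt.strip().casefold()


@dataclass
class PtSocMap:
    """Case-insensitive map from preferred term to its primary SOC."""

    entries: Mapping[str, str]
    version_label: str = ""

    def soc_for(self, pt: str) -> str | None:
        return self.entries.get(_norm(pt))

    def __len__(self) -> int:
        return len(self.entries)


def load_pt_soc_map(path: str | Path, version_label: str = "") -> PtSocMap:
    """Load the mapping TSV; a PT mapped to two different SOCs is fatal."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pt", "soc"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: mapping file must have columns {sorted(required)}")
    entries: dict[str, str] = {}
    for pt, soc in zip(df["pt"], df["soc"]):
        key = _norm(str(pt))
        soc = str(soc).strip()
        if key in entries and entries[key] != soc:
            raise ValueError(
                f"{path}: PT {pt!r} maps to both {entries[key]!r} and {soc!r}"
            )
        entries[key] = soc
    return PtSocMap(entries=entries, version_label=version_label)


def aggregate_soc(
    results: Iterable[SignalResult], pt_soc: PtSocMap
) -> pd.DataFrame:
    """Aggregate positive-signal event counts by SOC, per drug.

    Each positive result contributes its ``a`` cell (event occurrences,
    not distinct PTs) to its SOC's frequency; percentages are taken
    against the drug's own total.  PTs absent from the map are pooled
    under ``UNMAPPED`` and logged.

    Returns a frame with columns drug, soc, frequency, percent, sorted by
    drug then frequency descending then SOC.
    """
    rows = []
    for r in results:
        if not r.positive:
            continue
        soc = pt_soc.soc_for(r.pt)
        if soc is None:
            logger.warning("PT %r has no SOC mapping", r.pt)
            soc = UNMAPPED
        rows.append({"drug": r.drug_label, "soc": soc, "frequency": r.table.a})
    if not rows:
        return pd.DataFrame(columns=["drug", "soc", "frequency", "percent"])
    df = (
        pd.DataFrame(rows)
        .groupby(["drug", "soc"], as_index=False)["frequency"]
        .sum()
    )
    totals = df.groupby("drug")["frequency"].transform("sum")
    df["percent"] = 100.0 * df["frequency"] / totals
    return df.sort_values(
        ["drug", "frequency", "soc"], ascending=[True, False, True]
    ).reset_index(drop=True)
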