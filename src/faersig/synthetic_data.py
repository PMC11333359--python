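"""FAERS-format simulator with known ground truth.

Each synthetic report draws one primary-suspect drug from the configured
background shares and ``1 + Poisson`` preferred terms from the event-rate
vector; for planted (drug, PT) pairs the event's rate is multiplied by the
pair's rate multiplier (within-drug rates renormalize, which is what makes
the implied odds ratio exactly computable).  Two FAERS pathologies are
injected on top: case re-submissions (same caseid, larger primaryid,
identical content) and erroneous primaryid collisions (same primaryid,
different caseid) — deduplication must drop the former's old version and
both of the latter.

Generation is a pure function of the seed; quarters consume independent
child streams so adding quarters never perturbs earlier ones.  String
columns are emitted as pandas categoricals backed by integer codes, which
keeps six-figure report counts cheap to simulate and screen.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from faersig.faers_io import OCCUPATION_TO_REPORTER_TYPE, ROLE_CODES, write_delimited
from faersig.preprocess import CASE_COLUMNS

_DUP_PID_OFFSET = 10**9
_ERR_CASEID_OFFSET = 5 * 10**8


@dataclass(frozen=True)
class DrugSpec:
    label: str
    names: Sequence[str]
    background_share: float


@dataclass(frozen=True)
class EventSpec:
    pt: str
    background_rate: float


@dataclass(frozen=True)
class PlantedPair:
    drug_label: str
    pt: str
    rate_multiplier: float  # lambda > 0


@dataclass
class SyntheticConfig:
    n_reports: int
    drugs: Sequence[DrugSpec]
    events: Sequence[EventSpec]
    planted: Sequence[PlantedPair] = ()
    extra_events_mean: float = 1.0  # PTs per report = 1 + Poisson(mean)
    duplicate_case_rate: float = 0.0
    same_primaryid_error_rate: float = 0.0
    comedication_rate: float = 0.2
    sex_probs: tuple[float, float, float] = (0.55, 0.35, 0.10)  # F, M, missing
    age_mean: float = 55.0
    age_sd: float = 18.0
    age_missing_rate: float = 0.3
    occupation_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.6, "MD": 0.15, "PH": 0.05, "OT": 0.05, "": 0.15}
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.8, "JP": 0.1, "CA": 0.03, "": 0.07}
    )
    n_quarters: int = 1
    start_quarter: str = "2014Q3"
    build_raw_tables: bool = True  # skip the file-dialect DEMO view for speed
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.drugs or not self.events:
            raise ValueError("at least one drug and one event are required")
        if any(d.background_share <= 0 for d in self.drugs):
            raise ValueError("drug background shares must be positive")
        if any(not d.names for d in self.drugs):
            raise ValueError("every drug needs at least one name")
        if any(e.background_rate <= 0 for e in self.events):
            raise ValueError("event background rates must be positive")
        labels = {d.label for d in self.drugs}
        if len(labels) != len(self.drugs):
            raise ValueError("drug labels must be unique")
        pts = {e.pt for e in self.events}
        if len(pts) != len(self.events):
            raise ValueError("event PTs must be unique")
        for p in self.planted:
            if p.rate_multiplier <= 0:
                raise ValueError("rate multipliers must be positive")
            if p.drug_label not in labels or p.pt not in pts:
                raise ValueError(f"planted pair ({p.drug_label}, {p.pt}) is unknown")
        for prob in (
            self.duplicate_case_rate,
            self.same_primaryid_error_rate,
            self.comedication_rate,
            self.age_missing_rate,
            *self.sex_probs,
            *self.occupation_probs.values(),
            *self.country_probs.values(),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_quarters <= 0:
            raise ValueError("n_quarters must be positive")


@dataclass
class SyntheticDataset:
    """In-memory synthetic quarters, both raw-coded and parsed views.

    ``demo`` uses FAERS codes (sex F/M/'', age + age_cod, occp_cod) and is
    what :func:`write_quarters` serializes; it is empty when the config
    disables ``build_raw_tables``.  ``cases`` is the parsed view matching
    the :mod:`faersig.preprocess` schema, alongside the ``drugs`` and
    ``events`` frames.
    """

    demo: pd.DataFrame
    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    quarters: list[str]


@dataclass
class SyntheticTruth:
    """What was planted, what was generated, and what must survive dedup."""

    planted: list[PlantedPair]
    mention_counts: pd.DataFrame  # drug, pt, count — over surviving reports
    exposed_reports: dict[str, int]  # drug label -> surviving PS report count
    expected_mentions: pd.DataFrame  # drug, pt, expected count
    n_reports: int
    n_duplicate_cases: int
    n_primaryid_errors: int
    seed: int

    @property
    def n_surviving(self) -> int:
        return self.n_reports - self.n_primaryid_errors

    def count(self, drug_label: str, pt: str) -> int:
        m = self.mention_counts
        hit = m[(m["drug"] == drug_label) & (m["pt"] == pt)]
        return int(hit["count"].iloc[0]) if len(hit) else 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "n_reports": self.n_reports,
            "n_duplicate_cases": self.n_duplicate_cases,
            "n_primaryid_errors": self.n_primaryid_errors,
            "planted": [dataclasses.asdict(p) for p in self.planted],
            "exposed_reports": self.exposed_reports,
            "mention_counts": self.mention_counts.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _quarter_labels(start: str, n: int) -> list[str]:
    year, q = int(start[:4]), int(start[5])
    labels = []
    for _ in range(n):
        labels.append(f"{year}Q{q}")
        q += 1
        if q == 5:
            q, year = 1, year + 1
    return labels


def _event_weights(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """(normalized drug shares, per-drug normalized event-rate rows)."""
    shares = np.array([d.background_share for d in config.drugs], dtype=float)
    shares /= shares.sum()
    base = np.array([e.background_rate for e in config.events], dtype=float)
    pt_index = {e.pt: i for i, e in enumerate(config.events)}
    drug_index = {d.label: i for i, d in enumerate(config.drugs)}
    rates = np.tile(base, (len(config.drugs), 1))
    for p in config.planted:
        rates[drug_index[p.drug_label], pt_index[p.pt]] *= p.rate_multiplier
    rates /= rates.sum(axis=1, keepdims=True)
    return shares, rates


def expected_ror(config: SyntheticConfig, drug_label: str, pt: str) -> float:
    """Population (mention-level) odds ratio implied by the generative model."""
    labels = [d.label for d in config.drugs]
    pts = [e.pt for e in config.events]
    if drug_label not in labels:
        raise KeyError(f"unknown drug label {drug_label!r}")
    if pt not in pts:
        raise KeyError(f"unknown PT {pt!r}")
    shares, rates = _event_weights(config)
    g = labels.index(drug_label)
    e = pts.index(pt)
    p_a = shares[g] * rates[g, e]
    p_b = shares[g] - p_a
    p_c = float(np.dot(np.delete(shares, g), np.delete(rates[:, e], g)))
    p_d = (1.0 - shares[g]) - p_c
    return (p_a * p_d) / (p_b * p_c)


def _probs(mapping: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    codes = list(mapping)
    p = np.array([mapping[c] for c in codes], dtype=float)
    return codes, p / p.sum()


def generate(config: SyntheticConfig) -> tuple[SyntheticDataset, SyntheticTruth]:
    """Simulate the configured quarters; returns the dataset and its truth."""
    config.validate()
    shares, rates = _event_weights(config)
    labels = [d.label for d in config.drugs]
    pts = [e.pt for e in config.events]
    quarters = _quarter_labels(config.start_quarter, config.n_quarters)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_quarters)

    # unique global name list; per drug: offset of its verbatim names
    name_list: list[str] = []
    name_of: dict[str, int] = {}
    drug_name_idx: list[np.ndarray] = []
    for spec in config.drugs:
        idx = []
        for n in spec.names:
            if n not in name_of:
                name_of[n] = len(name_list)
                name_list.append(n)
            idx.append(name_of[n])
        drug_name_idx.append(np.array(idx))

    occ_codes, occ_p = _probs(config.occupation_probs)
    cty_codes, cty_p = _probs(config.country_probs)
    reporter_types = ["consumer", "health_professional", "other_missing"]
    occ_to_type = np.array(
        [
            reporter_types.index(
                OCCUPATION_TO_REPORTER_TYPE.get(c.upper(), "other_missing")
            )
            for c in occ_codes
        ],
        dtype=np.int8,
    )
    cty_missing = np.array([c == "" for c in cty_codes])

    per_q = [config.n_reports // config.n_quarters] * config.n_quarters
    for i in range(config.n_reports % config.n_quarters):
        per_q[i] += 1

    demo_parts, case_parts, drug_parts, event_parts = [], [], [], []
    count_matrix = np.zeros((len(labels), len(pts)), dtype=np.int64)
    exposed = dict.fromkeys(labels, 0)
    n_dup_total = n_err_total = 0

    for qi, (qlabel, n_q, ss) in enumerate(zip(quarters, per_q, streams)):
        if n_q == 0:
            continue
        rng = np.random.default_rng(ss)
        pid = 10**7 * (qi + 1) + np.arange(n_q, dtype=np.int64)

        drug_idx = rng.choice(len(labels), size=n_q, p=shares)
        k = 1 + rng.poisson(config.extra_events_mean, size=n_q)

        sex_idx = rng.choice(3, size=n_q, p=np.asarray(config.sex_probs))
        age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n_q)), 0, 120)
        age_missing = rng.random(n_q) < config.age_missing_rate
        occ_idx = rng.choice(len(occ_codes), size=n_q, p=occ_p)
        cty_idx = rng.choice(len(cty_codes), size=n_q, p=cty_p)

        err_mask = rng.random(n_q) < config.same_primaryid_error_rate

        # reaction mentions, grouped per drug so planted rates apply
        ev_pid_parts, ev_idx_parts = [], []
        for g in range(len(labels)):
            mask = drug_idx == g
            m_g = int(k[mask].sum())
            if m_g == 0:
                continue
            draws = rng.choice(len(pts), size=m_g, p=rates[g])
            ev_pid_parts.append(np.repeat(pid[mask], k[mask]))
            ev_idx_parts.append(draws)
            keep = np.repeat(~err_mask[mask], k[mask])
            count_matrix[g] += np.bincount(draws[keep], minlength=len(pts))
            exposed[labels[g]] += int((mask & ~err_mask).sum())
        ev_pid = np.concatenate(ev_pid_parts)
        ev_idx = np.concatenate(ev_idx_parts)

        # primary-suspect row per report (verbatim name chosen uniformly)
        name_idx = np.empty(n_q, dtype=np.int64)
        ai_idx = np.empty(n_q, dtype=np.int64)
        for g in range(len(labels)):
            mask = drug_idx == g
            choices = drug_name_idx[g]
            name_idx[mask] = choices[rng.integers(len(choices), size=int(mask.sum()))]
            ai_idx[mask] = choices[0]
        drug_pid = [pid]
        drug_name = [name_idx]
        drug_ai = [ai_idx]
        drug_role = [np.zeros(n_q, dtype=np.int8)]  # PS

        comed_mask = rng.random(n_q) < config.comedication_rate
        n_comed = int(comed_mask.sum())
        if n_comed:
            comed_drug = rng.integers(len(labels), size=n_comed)
            comed_name = np.array(
                [drug_name_idx[g][0] for g in comed_drug], dtype=np.int64
            )
            drug_pid.append(pid[comed_mask])
            drug_name.append(comed_name)
            drug_ai.append(comed_name.copy())
            # roles SS/C/I = codes 1..3
            drug_role.append(rng.integers(1, 4, size=n_comed).astype(np.int8))

        # case re-submissions: same caseid, primaryid shifted by a fixed
        # offset (hence strictly larger and globally unique), same content
        dup_mask = (~err_mask) & (rng.random(n_q) < config.duplicate_case_rate)
        n_dup = int(dup_mask.sum())
        n_err = int(err_mask.sum())
        n_dup_total += n_dup
        n_err_total += n_err

        cat_pid = np.concatenate(drug_pid)
        cat_name = np.concatenate(drug_name)
        cat_ai = np.concatenate(drug_ai)
        cat_role = np.concatenate(drug_role)
        if n_dup:
            sel = np.isin(cat_pid, pid[dup_mask])
            cat_pid = np.concatenate([cat_pid, cat_pid[sel] + _DUP_PID_OFFSET])
            cat_name = np.concatenate([cat_name, cat_name[sel]])
            cat_ai = np.concatenate([cat_ai, cat_ai[sel]])
            cat_role = np.concatenate([cat_role, cat_role[sel]])
            ev_sel = np.isin(ev_pid, pid[dup_mask])
            ev_pid = np.concatenate([ev_pid, ev_pid[ev_sel] + _DUP_PID_OFFSET])
            ev_idx = np.concatenate([ev_idx, ev_idx[ev_sel]])

        # demo row selector: originals, re-submissions, error clones
        sel_rows = np.concatenate(
            [np.arange(n_q), np.flatnonzero(dup_mask), np.flatnonzero(err_mask)]
        )
        q_pid = np.concatenate(
            [pid, pid[dup_mask] + _DUP_PID_OFFSET, pid[err_mask]]
        )
        q_caseid = np.concatenate(
            [pid, pid[dup_mask], pid[err_mask] + _ERR_CASEID_OFFSET]
        )
        q_sex = sex_idx[sel_rows]
        q_age = age[sel_rows]
        q_age_missing = age_missing[sel_rows]
        q_occ = occ_idx[sel_rows]
        q_cty = cty_idx[sel_rows]

        if config.build_raw_tables:
            age_str = np.where(q_age_missing, "", q_age.astype(np.int64).astype(str))
            demo_parts.append(
                pd.DataFrame(
                    {
                        "primaryid": q_pid,
                        "caseid": q_caseid,
                        "age": age_str,
                        "age_cod": np.where(q_age_missing, "", "YR"),
                        "sex": np.array(["F", "M", ""], dtype=object)[q_sex],
                        "occp_cod": np.array(occ_codes, dtype=object)[q_occ],
                        "reporter_country": np.array(cty_codes, dtype=object)[q_cty],
                        "quarter": qlabel,
                    }
                )
            )

        case_parts.append(
            pd.DataFrame(
                {
                    "primaryid": q_pid,
                    "caseid": q_caseid,
                    "sex": pd.Categorical.from_codes(
                        q_sex, ["female", "male", "missing"]
                    ),
                    "age_years": np.where(q_age_missing, np.nan, q_age),
                    "reporter_type": pd.Categorical.from_codes(
                        occ_to_type[q_occ], reporter_types
                    ),
                    "reporter_country": pd.Categorical.from_codes(
                        np.where(cty_missing[q_cty], -1, q_cty),
                        [c if c else "(missing)" for c in cty_codes],
                    ),
                    "quarter": qlabel,
                }
            )
        )
        drug_parts.append(
            pd.DataFrame(
                {
                    "primaryid": cat_pid,
                    "drugname": pd.Categorical.from_codes(cat_name, name_list),
                    "prod_ai": pd.Categorical.from_codes(cat_ai, name_list),
                    "role_cod": pd.Categorical.from_codes(
                        cat_role, list(ROLE_CODES)
                    ),
                    "quarter": qlabel,
                }
            )
        )
        event_parts.append(
            pd.DataFrame(
                {
                    "primaryid": ev_pid,
                    "pt": pd.Categorical.from_codes(ev_idx, pts),
                    "quarter": qlabel,
                }
            )
        )

    demo = (
        pd.concat(demo_parts, ignore_index=True)
        if demo_parts
        else pd.DataFrame(
            columns=[
                "primaryid", "caseid", "age", "age_cod", "sex",
                "occp_cod", "reporter_country", "quarter",
            ]
        )
    )
    cases = pd.concat(case_parts, ignore_index=True)[CASE_COLUMNS]
    drugs = pd.concat(drug_parts, ignore_index=True)
    events = pd.concat(event_parts, ignore_index=True)

    n_mentions = config.n_reports * (1.0 + config.extra_events_mean)
    expected = pd.DataFrame(
        [
            {
                "drug": labels[g],
                "pt": pts[e],
                "expected": n_mentions * shares[g] * rates[g, e],
            }
            for g in range(len(labels))
            for e in range(len(pts))
        ]
    )
    counts = pd.DataFrame(
        [
            {"drug": labels[g], "pt": pts[e], "count": int(count_matrix[g, e])}
            for g in range(len(labels))
            for e in range(len(pts))
        ]
    )
    truth = SyntheticTruth(
        planted=list(config.planted),
        mention_counts=counts,
        exposed_reports=exposed,
        expected_mentions=expected,
        n_reports=config.n_reports,
        n_duplicate_cases=n_dup_total,
        n_primaryid_errors=n_err_total,
        seed=config.seed,
    )
    return SyntheticDataset(demo, cases, drugs, events, quarters), truth


def _quarter_suffix(quarter: str) -> str:
    return f"{quarter[2:4]}Q{quarter[5]}"


def write_quarters(
    dataset: SyntheticDataset, outdir: str | Path, delimiter: str = "$"
) -> list[Path]:
    """Serialize each quarter as DEMOyyQq.txt / DRUGyyQq.txt / REACyyQq.txt."""
    if dataset.demo.empty and not dataset.cases.empty:
        raise ValueError(
            "raw DEMO view was not built (config.build_raw_tables=False)"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for quarter in dataset.quarters:
        suffix = _quarter_suffix(quarter)
        demo = dataset.demo[dataset.demo["quarter"] == quarter]
        drugs = dataset.drugs[dataset.drugs["quarter"] == quarter]
        events = dataset.events[dataset.events["quarter"] == quarter]
        written.append(
            write_delimited(
                demo.drop(columns="quarter"), outdir / f"DEMO{suffix}.txt", delimiter
            )
        )
        written.append(
            write_delimited(
                drugs.drop(columns="quarter"), outdir / f"DRUG{suffix}.txt", delimiter
            )
        )
        written.append(
            write_delimited(
                events.drop(columns="quarter"), outdir / f"REAC{suffix}.txt", delimiter
            )
        )
    return written
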