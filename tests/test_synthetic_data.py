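import math

import numpy as np
import pytest
from scipy import stats as sps

from faersig import build_dataset, deduplicate
from faersig.cli import load_quarters
from faersig.preprocess import DrugQuery
from faersig.synthetic_data import (
    DrugSpec,
    EventSpec,
    PlantedPair,
    SyntheticConfig,
    _event_weights,
    expected_ror,
    generate,
    write_quarters,
)


def base_config(**overrides) -> SyntheticConfig:
    params = dict(
        n_reports=1000,
        drugs=[
            DrugSpec("target", ["targetol", "Brandex"], 0.25),
            DrugSpec("background", ["placebomix"], 0.75),
        ],
        events=[EventSpec(f"event {i}", 1.0) for i in range(10)]
        + [EventSpec("planted event", 0.5)],
        planted=[PlantedPair("target", "planted event", 5.0)],
        seed=11,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


class TestConfigValidation:
    def test_unknown_planted_pair(self):
        cfg = base_config(planted=[PlantedPair("ghost", "event 0", 2.0)])
        with pytest.raises(ValueError, match="ghost"):
            cfg.validate()

    def test_nonpositive_multiplier(self):
        cfg = base_config(planted=[PlantedPair("target", "event 0", 0.0)])
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_probability(self):
        with pytest.raises(ValueError):
            base_config(duplicate_case_rate=1.5).validate()

    def test_invalid_config_writes_nothing(self, tmp_path):
        cfg = base_config(n_reports=-5)
        with pytest.raises(ValueError):
            generate(cfg)
        assert list(tmp_path.iterdir()) == []


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = base_config(duplicate_case_rate=0.1, same_primaryid_error_rate=0.02)
        for run in ("one", "two"):
            ds, _ = generate(cfg)
            write_quarters(ds, tmp_path / run)
        for f1 in sorted((tmp_path / "one").iterdir()):
            f2 = tmp_path / "two" / f1.name
            assert f1.read_bytes() == f2.read_bytes()

    def test_different_seed_differs(self):
        _, t1 = generate(base_config(seed=1))
        _, t2 = generate(base_config(seed=2))
        assert not t1.mention_counts.equals(t2.mention_counts)

    def test_earlier_quarters_stable_when_adding_more(self):
        ds1, _ = generate(base_config(n_quarters=2, n_reports=400))
        ds2, _ = generate(base_config(n_quarters=4, n_reports=800))
        q = ds1.quarters[0]
        a = ds1.events[ds1.events["quarter"] == q].reset_index(drop=True)
        b = ds2.events[ds2.events["quarter"] == q].reset_index(drop=True)
        assert a.equals(b)


class TestDedupInjection:
    def test_duplicate_rate_row_counts(self):
        cfg = base_config(n_reports=1000, duplicate_case_rate=0.1, seed=3)
        ds, truth = generate(cfg)
        assert len(ds.cases) == 1000 + truth.n_duplicate_cases
        assert 60 <= truth.n_duplicate_cases <= 140  # ~Binomial(1000, .1)
        deduped, _ = deduplicate(ds.cases)
        assert len(deduped) == 1000

    def test_dedup_recovery_exact(self):
        cfg = base_config(
            n_reports=2000, duplicate_case_rate=0.05,
            same_primaryid_error_rate=0.02, seed=9,
        )
        ds, truth = generate(cfg)
        deduped, log = deduplicate(ds.cases)
        assert len(deduped) == cfg.n_reports - truth.n_primaryid_errors
        assert log.n_primaryid_collision == 2 * truth.n_primaryid_errors
        assert log.n_caseid_superseded == truth.n_duplicate_cases

    def test_resubmitted_case_keeps_its_content(self):
        cfg = base_config(n_reports=500, duplicate_case_rate=0.2, seed=5)
        ds, truth = generate(cfg)
        q = DrugQuery("target", ["targetol"], ["Brandex"])
        ads = build_dataset(ds.cases, ds.drugs, ds.events, [q])
        # every surviving report still has drug and event rows
        assert set(ads.events["primaryid"]).issubset(set(ads.cases["primaryid"]))
        assert len(ads.exposure["target"]) == truth.exposed_reports["target"]


class TestTruth:
    def test_planted_exposure_count_recovered(self):
        ds, truth = generate(base_config(seed=21))
        q = DrugQuery("target", ["targetol"], ["Brandex"])
        ads = build_dataset(ds.cases, ds.drugs, ds.events, [q])
        assert len(ads.exposure["target"]) == truth.exposed_reports["target"]

    def test_mention_counts_match_pipeline(self):
        from faersig.signal_stats import make_contingency

        ds, truth = generate(base_config(seed=22))
        q = DrugQuery("target", ["targetol"], ["Brandex"])
        ads = build_dataset(ds.cases, ds.drugs, ds.events, [q])
        t = make_contingency(ads, "target", "planted event")
        assert t.a == truth.count("target", "planted event")

    def test_truth_json_round_trip(self, tmp_path):
        import json

        _, truth = generate(base_config())
        path = truth.to_json(tmp_path / "truth.json")
        payload = json.loads(path.read_text())
        assert payload["n_reports"] == 1000
        assert payload["planted"][0]["rate_multiplier"] == 5.0


class TestExpectedRor:
    def test_lambda_one_gives_unity(self):
        cfg = base_config(planted=[])
        assert expected_ror(cfg, "target", "event 0") == pytest.approx(1.0)

    def test_rare_event_limit(self):
        events = [EventSpec(f"e{i}", 1.0) for i in range(500)] + [
            EventSpec("rare", 0.001)
        ]
        cfg = base_config(events=events, planted=[PlantedPair("target", "rare", 10.0)])
        assert expected_ror(cfg, "target", "rare") == pytest.approx(10.0, rel=1e-6)

    def test_unknown_pair_is_error(self):
        with pytest.raises(KeyError):
            expected_ror(base_config(), "target", "no such pt")

    def test_matches_brute_force_cell_probabilities(self):
        # independent enumeration of P(drug=g, pt=e) from first principles
        cfg = base_config(
            drugs=[
                DrugSpec("a", ["a1"], 0.2),
                DrugSpec("b", ["b1"], 0.3),
                DrugSpec("c", ["c1"], 0.5),
            ],
            events=[EventSpec("p", 0.3), EventSpec("q", 0.5), EventSpec("r", 0.2)],
            planted=[
                PlantedPair("a", "p", 4.0),
                PlantedPair("b", "q", 0.5),
            ],
        )
        shares = {"a": 0.2, "b": 0.3, "c": 0.5}
        rates = {"p": 0.3, "q": 0.5, "r": 0.2}
        lam = {("a", "p"): 4.0, ("b", "q"): 0.5}
        joint = {}
        for g, s in shares.items():
            norm = sum(rates[e] * lam.get((g, e), 1.0) for e in rates)
            for e, w in rates.items():
                joint[(g, e)] = s * w * lam.get((g, e), 1.0) / norm
        for g in shares:
            for e in rates:
                p_a = joint[(g, e)]
                p_b = sum(joint[(g, e2)] for e2 in rates if e2 != e)
                p_c = sum(joint[(g2, e)] for g2 in shares if g2 != g)
                p_d = 1.0 - p_a - p_b - p_c
                oracle = (p_a * p_d) / (p_b * p_c)
                assert expected_ror(cfg, g, e) == pytest.approx(oracle, rel=1e-12)


class TestDistribution:
    def test_null_counts_consistent_with_independence(self):
        # lambda = 1 everywhere: per-drug PT counts are multinomial draws
        # from the background rates — chi-square GOF should not reject
        cfg = base_config(
            n_reports=25_000, extra_events_mean=1.0, planted=[], seed=13,
            build_raw_tables=False,
        )
        ds, truth = generate(cfg)  # ~50,000 mentions
        _, rates = _event_weights(cfg)
        counts = truth.mention_counts.pivot(
            index="drug", columns="pt", values="count"
        )
        pts = [e.pt for e in cfg.events]
        for g, spec in enumerate(cfg.drugs):
            observed = counts.loc[spec.label, pts].to_numpy(dtype=float)
            expected = rates[g] * observed.sum()
            p = sps.chisquare(observed, expected).pvalue
            assert p > 0.001

    def test_planted_pair_enriched(self):
        cfg = base_config(n_reports=20_000, seed=17, build_raw_tables=False)
        _, truth = generate(cfg)
        exp = truth.expected_mentions
        planted_expected = float(
            exp[(exp["drug"] == "target") & (exp["pt"] == "planted event")][
                "expected"
            ].iloc[0]
        )
        observed = truth.count("target", "planted event")
        assert observed == pytest.approx(planted_expected, rel=0.2)


class TestFileRoundTrip:
    def test_written_quarter_reads_back(self, tmp_path):
        cfg = base_config(n_reports=300, duplicate_case_rate=0.1,
                          same_primaryid_error_rate=0.02, seed=8)
        ds, truth = generate(cfg)
        write_quarters(ds, tmp_path)
        cases, drug_entries, event_entries = load_quarters(
            tmp_path, ds.quarters
        )
        assert len(cases) == len(ds.cases)
        assert len(drug_entries) == len(ds.drugs)
        assert len(event_entries) == len(ds.events)
        # parsed demographics survive the FAERS dialect round trip
        by_pid = {c.primaryid: c for c in cases}
        for row in ds.cases.head(50).itertuples():
            c = by_pid[row.primaryid]
            assert c.sex == row.sex
            assert c.reporter_type == row.reporter_type
            if isinstance(row.age_years, float) and math.isnan(row.age_years):
                assert c.age_years is None
            else:
                assert c.age_years == row.age_years

    def test_pipeline_from_files_matches_in_memory(self, tmp_path):
        cfg = base_config(n_reports=400, seed=4)
        ds, truth = generate(cfg)
        write_quarters(ds, tmp_path)
        cases, drug_entries, event_entries = load_quarters(tmp_path, ds.quarters)
        q = DrugQuery("target", ["targetol"], ["Brandex"])
        from_files = build_dataset(cases, drug_entries, event_entries, [q])
        in_memory = build_dataset(ds.cases, ds.drugs, ds.events, [q])
        assert len(from_files.cases) == len(in_memory.cases)
        assert from_files.exposure == in_memory.exposure

    def test_raw_tables_disabled_refuses_to_write(self, tmp_path):
        ds, _ = generate(base_config(build_raw_tables=False))
        with pytest.raises(ValueError):
            write_quarters(ds, tmp_path)
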