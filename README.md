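# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event report data.

The package implements the standard pharmacovigilance screening pipeline:

1. **Ingest** — parse quarterly `$`-delimited ASCII tables (DEMO / DRUG /
   REAC), with name-based column lookup, a fixed codebook for sex, age
   units and reporter occupation, and Latin-1 decoding.
2. **Preprocess** — global cross-quarter deduplication (same caseid → keep
   the largest primaryid; a repeated primaryid is treated as an error and
   all bearers are dropped), then per-drug exposed sets restricted to
   primary-suspect (`role_cod = PS`) mentions matched by case-insensitive
   substring against generic and brand names.
3. **Screen** — per (drug, preferred term) 2×2 contingency tables and four
   statistics with their positivity criteria:
   - ROR with 95% Woolf interval (flag: lower bound > 1 and a ≥ 3),
   - PRR with uncorrected Pearson χ² (flag: PRR ≥ 2, χ² ≥ 4, a ≥ 3),
   - closed-form BCPNN information component (flag: IC025 > 0),
   - simplified EBGM = observed/expected with a log-normal lower bound
     (flag: EBGM05 ≥ 2).
   A pair is a *positive signal* when all four flags hold.
4. **Aggregate & report** — PT→SOC rollups from a user-supplied mapping
   TSV, demographics summaries, top-N signal tables (per drug and pooled),
   per-method positive counts, Venn-region intersections across drugs, and
   a hierarchically clustered log(ROR+1) matrix.
5. **Simulate** — a FAERS-format generator with planted drug–event
   disproportionality of known strength, injected duplicate cases and
   primaryid collisions, and an analytic `expected_ror` for parameter
   recovery testing.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-table
arithmetic identities, oracle suites against scipy/statsmodels and an
independent transcription of the IC closed form, identity/limit behaviour,
a 100-replicate synthetic ROR-recovery experiment, a null-data specificity
bound, and a hand-traced dedup fixture. The full suite runs in well under
a minute on one CPU.

## CLI

```bash
faersig simulate -o data/ --seed 7 --n-reports 5000   # synthetic quarters + truth.json
faersig ingest  -c config.yaml -o dataset/            # parse + dedup + exposure
faersig screen  -c config.yaml -o signals.tsv         # four statistics per (drug, PT)
faersig report  -c config.yaml -o report/ [--png]     # all reporting surfaces
faersig stats   tables.csv                            # statistics for raw a,b,c,d rows
```

A pipeline config is a small YAML file:

```yaml
data_dir: data/
quarters: ["2014Q3", "2014Q4"]
unit: mentions            # or: reports
top_n: 20
pt_soc_map: pt_soc.tsv    # two columns: pt, soc
queries:
  - label: suvorexant
    generic_names: [suvorexant]
    brand_names: [Belsomra]
```

Notes on conventions: counting defaults to the event-mention level (every
report–PT row is one observation; the `unit` option switches to
report-level counting); no continuity correction is applied anywhere, so
zero cells yield undefined estimates with flags set to false; the pooled
"Overall" column of the demographics summary is the sum of the per-drug
columns (a report exposed to two queried drugs counts twice), with the
distinct-report count carried alongside.
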