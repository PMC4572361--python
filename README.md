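# fmct — find my compound's targets

`fmct` proposes protein targets for a query compound by chemical
similarity: compounds that look alike tend to bind alike, so the targets
annotated to a query's nearest neighbors in a curated bioactivity table are
good target hypotheses. This is ligand-based *target fishing* as used in
drug repurposing and off-target/polypharmacology triage. The package is
aimed at computational chemists who have a BindingDB-style affinity dump
(or use the BindingDB web services) and want reproducible, scriptable
target prediction without a workflow GUI.

## What it computes

Given a reference table of curated rows (compound SMILES, protein target,
UniProt accession, Kᵢ or IC₅₀ in nM) and a query structure, `fmct` scans
every record and keeps those with

    similarity(query, record) ≥ t        (default t = 0.7)
    affinity ≤ c                          (default c = 10 µM)

then merges hits with identical UniProt accessions into one target
hypothesis ranked by its best supporting similarity. Four similarity
variants are provided:

- **path** — Tanimoto coefficient `c/(a+b−c)` over the default RDKit
  topological path (Daylight-style) fingerprint; the fast default.
- **avg5** — the unweighted mean of *k* (default 5) fingerprint metrics
  chosen from the catalog of (fingerprint family × {Tanimoto, Dice,
  Cosine}) by a Pearson correlation filter that retains the metrics least
  correlated with each other over a compound-pair panel.
- **mcs** — maximum-common-substructure similarity on a 0–1 scale
  (fragment-tolerant matching, atoms+bonds Tanimoto normalization; see
  `docs/methods.md` for the calibration).
- **path+mcs** — the fast fingerprint scan re-ranked by MCS similarity.

Supporting machinery: a TSV curation pipeline with the standard filters
(keep Kᵢ/IC₅₀ rows, drop `<`/`>` range qualifiers, drop structures that
fail sanitization), per-target leader clustering at Tanimoto 0.8 to build a
representative-only *reduced* reference table for high-throughput scans, a
thin XML client for the BindingDB `getLigandsByUniprot` /
`getTargetByCompound` REST endpoints, and a seeded synthetic-fixture
generator so the whole stack is testable offline.

## Worked example

Build a small synthetic reference table (4 targets × 3 scaffold series × 5
compounds, plus 5 qualifier rows and 5 invalid rows), then ask for targets:

```sh
fmct synth --out demo/
fmct build-table --tsv demo/reference.tsv --out demo/table.json --fast
# 70 raw rows -> 65 measured -> 60 records; written to demo/table.json
```

Scoring two classic antihistamine-related structures:

```sh
fmct sim 'Clc1ccc(cc1)C(OCCN1CCCCC1)c1ccccc1' 'CN(C)CCOC(c1ccccc1)c1ccccc1'
# 0.7035
```

That is cloperastine versus diphenhydramine: a path-fingerprint Tanimoto of
0.70 means the cough suppressant is well inside the similarity
neighborhood of the antihistamine it was derived from, so a scan of
cloperastine against a table containing diphenhydramine (annotated to the
histamine H1 receptor at 15 nM) reports H1 as a target hypothesis with
best similarity 0.70 — the textbook neighbor-transfer hit.

Predicting targets for a planted query against the synthetic table:

```sh
python - <<'PY'
import json
from fmct import QueryConfig, fmct_single, load_table
table = load_table("demo/table.json")
query = json.load(open("demo/manifest.json"))["queries"][0]
report = fmct_single(query["smiles"], table, QueryConfig())
for hit in report.target_hits:
    print(hit.uniprot_primary, hit.target_name, round(hit.best_similarity, 3),
          len(hit.supporting_hits))
PY
# P10000 Synthetic target 1 0.875 5
```

The query was generated as a decoration of target 1's first scaffold
series, and the engine recovers exactly that target, supported by all five
series members. Reducing the table keeps one representative (the most
potent compound) per cluster:

```sh
fmct reduce-table --table demo/table.json --out demo/reduced.json
# 60 -> 12 records (12 clusters)
```

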