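# Methods

## The prediction model

`fmct` implements similarity-based target transfer. The underlying
assumption is the similar-property principle: if a query compound *q* is
chemically similar to a reference compound *r* with a measured affinity
for protein *P*, then *P* is a plausible target for *q*. No statistics are
attached to a hit — there is no background model or E-value, deliberately:
the method reports raw similarity evidence (the supporting compound, its
similarity to the query, and its measured affinity) and leaves significance
judgement to the user or to downstream tools. Hits supported only by low
similarity scores deserve proportionally low confidence.

A scan therefore consists of: compute `s(q, r)` for every reference record,
keep records with `s ≥ t` and affinity `≤ c`, group by UniProt accession
(one protein may appear in many rows), and rank proteins by their best
supporting similarity. Records lacking an accession are grouped under their
target name and flagged rather than dropped, since such rows still carry
evidence.

### Parameters

| parameter | default | meaning |
|---|---|---|
| similarity threshold *t* | 0.7 | inclusive lower bound on `s(q, r)`; inclusive so that *t* = 1.0 returns exact matches. There is no canonical value; 0.7 sits where path-fingerprint hits are usually judged credible, and informative hits in practice span roughly 0.6–1.0. Lowering *t* expands candidates rapidly. |
| affinity cutoff *c* | 10 000 nM (10 µM) | a measurement stronger than *c* counts as binding evidence. Applied per measurement row, so a compound survives if any of its rows for a target passes. |
| top-N (batch mode) | 3 | targets reported per compound in the compact batch table; raise it to avoid missing hits below rank 3. |

## Similarity variants

**Path-fingerprint Tanimoto (`path`).** The default RDKit topological path
fingerprint with stock parameters (2048 bits, paths up to 7 bonds),
compared with the Tanimoto coefficient `c/(a+b−c)`. Fast and the best
single metric in practice.

**Averaged selection (`avg5`).** The metric catalog crosses every
fingerprint family the toolkit provides with the three bit-vector
comparison formulas (Tanimoto, Dice `2c/(a+b)`, Cosine `c/√(ab)`). The
named family roster holds 14 entries spanning two toolkits' conventions;
this build generates 9 of them (path, Morgan, feature-Morgan, atom-pair,
topological-torsion, MACCS, Avalon, layered, pattern) and registers the
remaining CDK-only families as unavailable, so the enumeration is 3 × 9 =
27 metrics here and 3 × N in general. Because many of these metrics are
strongly redundant, a Pearson correlation filter selects the *k* (default
5) metrics least correlated with each other over a panel of compound
pairs; the prediction-time score is their unweighted mean. A frozen
selection can be loaded from JSON, or re-derived from any pair panel.

*Correlation filter algorithm.* The selection minimizes the maximum
pairwise |r| of the retained set. For tractable catalogs (subset count ≤
5·10⁵, which covers 42-choose-5) the optimum is found by exhaustive
enumeration with deterministic tie-breaks: ties on the max fall to the
smaller sorted pairwise-|r| spectrum, then to earlier catalog indices.
Larger catalogs fall back to greedy pairwise elimination (repeatedly drop,
from the most-correlated surviving pair, the member with the larger mean
|r| to the other survivors; ties drop the later catalog index). Greedy is a
good but not exact heuristic — on random correlated profiles it misses the
exhaustive optimum in roughly a third of cases, which is why the exact
search is the default. Zero-variance metric columns get correlation 0 with
a warning. All-zero fingerprints are scored by convention: both empty → 1,
exactly one empty → 0 (the raw formulas are 0/0 there).

**Maximum common substructure (`mcs`).** Heavy-atom MCS via RDKit FMCS,
element-matched atoms, order-matched bonds, ring bonds matching ring bonds
only. Two matching modes:

- *connected* — the single connected MCS, straight from FMCS;
- *fragment* (default) — greedy fragment-tolerant matching: find the
  connected MCS, delete the matched atoms from both molecules, repeat
  until no shared fragment of the minimum size remains; residual isolated
  atoms are paired by element. This scores highly a pair of molecules that
  share all their pieces wired differently, which a connected MCS
  undervalues.

Normalizations, selectable per call (all equal 1 exactly on
substructure-identical inputs):

| id | formula |
|---|---|
| `atom_bond_tanimoto` (default) | `(n+m) / (n_a+m_a + n_b+m_b − n−m)` over matched atoms *n* and bonds *m* |
| `tanimoto` | `n / (n_a + n_b − n)` |
| `min` | `n / min(n_a, n_b)` |

*Calibration.* The exact scoring convention of graph-mining MCS tools is
not standardized, so the default was fixed by calibration on the
documented cloperastine / LTA4H-inhibitor pair — two compounds with the
same parts joined differently, whose reference MCS similarity is 0.92
against a path-fingerprint similarity of only 0.41. Achieved values per
option on that pair (this toolkit):

| mode + normalization | value |
|---|---|
| connected + tanimoto | 0.438 |
| connected + min | 0.609 |
| fragment + tanimoto | 0.957 |
| fragment + min | 1.000 |
| fragment + atom_bond_tanimoto | **0.918** |

Fragment matching with the atoms+bonds Tanimoto reproduces the reference
value most closely and is the shipped default; `scripts/acceptance.py`
prints all five for audit. The per-pair MCS timeout defaults to 60 s;
hitting it returns the best match so far with a `timed_out` flag, never an
error. The `path+mcs` variant scans with the path fingerprint and re-ranks
the surviving hits by MCS (hit set preserved; order by MCS similarity,
then fingerprint similarity, then monomer id).

One structure note: the LTA4H inhibitor used in calibration and examples
is transcribed as 1-[2-(4-benzylphenoxy)ethyl]piperidine, the piperidine
member of the benzylphenoxy-alkylamine inhibitor series, consistent with
its described micromolar potency and with the ether-plus-piperidine
rearrangement relationship to cloperastine.

## Reference-table curation

The TSV reader maps logical fields to header names through a dialect
mapping (shipped default follows the current public BindingDB dump
headers) because dump headers drift across releases. A physical row with
both a Kᵢ and an IC₅₀ yields two records — each measurement is independent
evidence. Curation then applies, in order: (1) keep rows whose affinity
field parses as a plain positive number — any `<` or `>` anywhere in the
field marks a range/bound and drops the row; a bare `=` prefix is
stripped; scientific notation accepted; zero, negative and non-finite
values rejected; (2) drop rows whose SMILES fails RDKit parsing and
sanitization or whose fingerprint generation fails, counted separately.
Stage counts and drop reasons are logged and stored in `build_meta`; when
the input is a real BindingDB snapshot these counts are audit output, not
asserted values, since they depend on the snapshot version. Canonical
SMILES is stored next to the verbatim input; exact-structure comparisons
use the canonical form. Molecular descriptors are not computed — only
fingerprints feed the prediction workflows. Tables persist as versioned
JSON with hex-encoded fingerprints; loading a truncated or
version-mismatched file is an explicit format error, never a silent
partial load.

## Reduced reference table

For many-query workloads, each target's compounds are clustered on
path-fingerprint Tanimoto and only representatives are kept. "Threshold
0.8" is read as *similarity* ≥ 0.8 — the standard clustering practice —
with a `distance_mode` flag restoring the literal Tanimoto-distance
reading (similarity ≥ 0.2, far looser). Clustering is leader-style
(sphere exclusion): records visited in (affinity asc, monomer id asc)
order join the first cluster whose leader they match, else found a new
cluster — O(n·k), deterministic, and the most potent compound of a tight
series always leads. An exact complete-linkage option exists for small
groups and serves as a cross-check; the two agree whenever clusters are
internally tight (every within pair above threshold) and can legitimately
differ otherwise, since leader clustering only constrains members to their
leader. Representatives per cluster: `highest_affinity` (lowest nM, ties
by monomer id; default) or a seeded `random` draw; both are exposed
because either convention is defensible. The reduction trades recall for
speed by construction: a query similar to a cluster's representative loses
nothing, while a query similar only to a cluster's periphery is found in
the full table but missed in the reduced one. The test suite demonstrates
both regimes on planted queries.

## Web-service client

A thin client for the BindingDB REST endpoints (ligands by UniProt
accession; targets by compound SMILES with a server-side similarity
cutoff). Responses are XML; element names are mapped through a dialect
like the TSV reader since the wire schema is versioned outside this
package. Parsed rows run through the same record validation as the TSV
path — one schema, two sources. The HTTP layer is an injectable transport
(stdlib urllib by default, 30 s timeout, 2 retries with exponential
backoff) so the entire module is tested against canned XML; nothing in the
test suite touches the network. The client canonicalizes the query SMILES
for the URL and otherwise never alters it.

## Synthetic fixtures: what they do and do not show

The generator plants scaffold series: a large (~30 heavy atoms) drug-like
core plus variants carrying one small substituent (F, Cl, Br, methyl,
hydroxy, amino, methoxy) on an aromatic carbon. Variants are ranked by
path-fingerprint similarity to the core, which keeps every member within
0.8 of the core, while distinct cores sit below ~0.4 of each other —
so each (target, series) slot is one planned cluster at the 0.8 threshold.
The core always receives the lowest affinity of its series, making it the
deterministic cluster leader and `highest_affinity` representative.
Affinities are log-uniform over the spec range (default 1–10⁴ nM);
qualifier rows carry `>`-prefixed values; invalid rows use fixed
unparsable SMILES. Planted queries come in two kinds: *inside* (a held-out
decoration, near the core) and *between* (a double decoration near one
member but below threshold to the core), found by deterministic search.
Generation is a pure function of the spec; the default spec (4 targets × 3
series × 5 compounds + 5 + 5 bad rows, seed 7) yields 70 raw rows, 60
curated records, 12 clusters and a 12-record reduced table.

What passing tests on these fixtures shows: the pipeline's counting,
filtering, clustering, ranking and merging logic is exact, and the
full-vs-reduced recall trade-off behaves as designed. What it does not
show: performance on real bioactivity data — real chemistry has no planted
separations, activity cliffs break the similar-property assumption, and
real tables are four orders of magnitude larger. Claims about real-data
recall require a real snapshot.

## Numerical and determinism choices

- Hit ordering is fully specified (similarity desc, affinity asc, monomer
  id asc; targets by best similarity desc, then accession) so reports are
  byte-reproducible.
- All randomness (fixture generation, random representative selection) is
  seeded; fixture TSVs are byte-identical across runs for a fixed spec.
- Degenerate inputs: empty fingerprints use the both-zero → 1 convention;
  single-heavy-atom molecules are handled in MCS by element pairing (FMCS
  itself needs at least one bond); an empty scan result is a report with
  an advisory message, not an error.
- MCS fragment iteration stops at fragments below `min_fragment_atoms`
  (default 1, i.e. everything counts); raising it approximates miners that
  ignore trivial fragments.

## Known limitations

- No statistical significance for hits; ranks and raw similarities only.
- The 14-family fingerprint roster is only partially realizable on one
  toolkit; the catalog reports what is actually available (9 here).
- Fragment-MCS is a greedy iterated-FMCS construction: it does not
  guarantee the globally maximal common *subgraph set*, only a good
  deterministic lower bound.
- The affinity model is a scalar nM value per row; units other than nM,
  mixed qualifiers (`~`, `≥`) and multi-chain UniProt annotations beyond
  the primary accession are out of scope.
- Leader clustering depends on visit order (by design, for determinism);
  it is not invariant to relabeling affinities.
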