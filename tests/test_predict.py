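"""Target-prediction engine: scanning, merging, re-ranking, batch reports."""

import random

import pytest

from fmct.errors import InputError, StructureError
from fmct.examples import CLOPERASTINE, DIPHENHYDRAMINE, LTA4H_INHIBITOR
from fmct.mcs import mcs_similarity
from fmct.predict import (
    QueryConfig,
    Variant,
    fmct_batch,
    fmct_single,
    mcs_rerank,
    merge_by_uniprot,
    scan,
)
from fmct.reference_table import (
    AffinityType,
    RawRow,
    ReferenceTable,
    sanitize_and_fingerprint,
)
from fmct.similarity import rdkit_path_similarity


def mini_table(entries) -> ReferenceTable:
    """entries: (smiles, monomer_id, target_name, uniprot, affinity_nM)"""
    rows = [
        RawRow(
            smiles=smiles,
            monomer_id=mid,
            target_name=target,
            uniprot_ids=(uniprot,) if uniprot else (),
            affinity_type=AffinityType.KI,
            affinity_text=str(affinity),
        )
        for smiles, mid, target, uniprot, affinity in entries
    ]
    records, _ = sanitize_and_fingerprint(rows, ["path"])
    return ReferenceTable(records=records, build_meta={})


def brute_force_scan(query, table, config):
    """Independent oracle: plain loop + filter + sort."""
    hits = []
    for rec in table.records:
        sim = rdkit_path_similarity(query, rec.smiles)
        if sim >= config.similarity_threshold and rec.affinity_nM <= config.affinity_cutoff_nM:
            hits.append((rec, sim))
    hits.sort(key=lambda pair: (-pair[1], pair[0].affinity_nM, pair[0].monomer_id))
    return hits


@pytest.fixture(scope="module")
def h1_table():
    return mini_table([
        (DIPHENHYDRAMINE, "M001", "Histamine H1 receptor", "P35367", 15.0),
        (LTA4H_INHIBITOR, "M002", "Leukotriene A4 hydrolase", "P09960", 1800.0),
        ("CCO", "M003", "Unrelated enzyme", "P00001", 5.0),
    ])


class TestScan:
    def test_exact_match_is_sole_top_hit(self, h1_table):
        config = QueryConfig(similarity_threshold=0.99)
        hits = scan(DIPHENHYDRAMINE, h1_table, config)
        assert len(hits) == 1
        assert hits[0].similarity == 1.0
        assert hits[0].record.monomer_id == "M001"

    def test_threshold_one_without_exact_match_is_empty(self, h1_table):
        assert scan("c1ccncc1", h1_table, QueryConfig(similarity_threshold=1.0)) == []

    def test_unparsable_query_raises(self, h1_table):
        with pytest.raises(StructureError):
            scan("C1CC", h1_table, QueryConfig())

    def test_matches_brute_force_oracle_on_fixture(self, ref_table, manifest):
        rng = random.Random(11)
        queries = [q["smiles"] for q in manifest["queries"]]
        for _ in range(10):
            config = QueryConfig(
                similarity_threshold=rng.choice([0.3, 0.5, 0.7, 0.85]),
                affinity_cutoff_nM=rng.choice([100.0, 1000.0, 10000.0]),
            )
            query = rng.choice(queries)
            got = scan(query, ref_table, config)
            expected = brute_force_scan(query, ref_table, config)
            assert [h.record.monomer_id for h in got] == [
                r.monomer_id for r, _ in expected
            ]
            assert [h.similarity for h in got] == pytest.approx(
                [s for _, s in expected]
            )

    def test_threshold_monotonicity(self, ref_table, manifest):
        query = manifest["queries"][0]["smiles"]
        lo = {h.record.monomer_id for h in scan(query, ref_table, QueryConfig(similarity_threshold=0.4))}
        hi = {h.record.monomer_id for h in scan(query, ref_table, QueryConfig(similarity_threshold=0.8))}
        assert hi <= lo

    def test_cutoff_monotonicity(self, ref_table, manifest):
        query = manifest["queries"][0]["smiles"]
        loose = {h.record.monomer_id for h in scan(query, ref_table, QueryConfig(similarity_threshold=0.4, affinity_cutoff_nM=10000))}
        tight = {h.record.monomer_id for h in scan(query, ref_table, QueryConfig(similarity_threshold=0.4, affinity_cutoff_nM=100))}
        assert tight <= loose


class TestMerge:
    def test_grouping_by_accession(self, h1_table):
        config = QueryConfig(similarity_threshold=0.0)
        hits = scan(DIPHENHYDRAMINE, h1_table, config)
        targets = merge_by_uniprot(hits)
        assert len(targets) == 3
        assert sum(len(t.supporting_hits) for t in targets) == len(hits)

    def test_repeated_accession_merges(self):
        table = mini_table([
            (DIPHENHYDRAMINE, "M1", "Histamine H1 receptor", "P35367", 15.0),
            ("CN(C)CCOC(c1ccc(C)cc1)c1ccccc1", "M2", "Histamine H1 receptor", "P35367", 40.0),
            ("CN(C)CCOC(c1ccc(F)cc1)c1ccccc1", "M3", "Histamine H1 receptor", "P35367", 80.0),
            (CLOPERASTINE, "M4", "5-HT1A receptor", "P08908", 90.0),
        ])
        hits = scan(DIPHENHYDRAMINE, table, QueryConfig(similarity_threshold=0.5))
        targets = merge_by_uniprot(hits)
        by_acc = {t.uniprot_primary: t for t in targets}
        assert len(by_acc["P35367"].supporting_hits) == 3
        assert by_acc["P35367"].best_similarity == max(
            h.similarity for h in by_acc["P35367"].supporting_hits
        )

    def test_missing_accession_grouped_by_name_flagged(self):
        table = mini_table([("CCO", "M1", "Orphan target", "", 5.0)])
        hits = scan("CCO", table, QueryConfig())
        targets = merge_by_uniprot(hits)
        assert targets[0].no_accession and targets[0].target_name == "Orphan target"

    def test_empty_input(self):
        assert merge_by_uniprot([]) == []


class TestRerank:
    def test_set_invariant_and_populated(self, h1_table):
        hits = scan(CLOPERASTINE, h1_table, QueryConfig(similarity_threshold=0.3))
        reranked = mcs_rerank(hits, CLOPERASTINE)
        assert {h.record.monomer_id for h in reranked} == {
            h.record.monomer_id for h in hits
        }
        assert all(h.mcs_similarity is not None for h in reranked)

    def test_order_flips_when_mcs_disagrees_with_fingerprint(self, h1_table):
        """Cloperastine is closer to diphenhydramine by path fingerprint but
        closer to the LTA4H inhibitor by fragment-level MCS."""
        hits = scan(CLOPERASTINE, h1_table, QueryConfig(similarity_threshold=0.3))
        assert [h.record.monomer_id for h in hits][:2] == ["M001", "M002"]
        reranked = mcs_rerank(hits, CLOPERASTINE)
        assert [h.record.monomer_id for h in reranked][:2] == ["M002", "M001"]

    def test_single_hit_unchanged(self, h1_table):
        hits = scan(DIPHENHYDRAMINE, h1_table, QueryConfig(similarity_threshold=0.99))
        reranked = mcs_rerank(hits, DIPHENHYDRAMINE)
        assert len(reranked) == 1 and reranked[0].mcs_similarity == 1.0


class TestSingleReport:
    def test_neighbor_transfers_target(self, h1_table):
        """A query similar to a known H1 binder should surface the H1
        receptor, supported by that binder."""
        report = fmct_single(CLOPERASTINE, h1_table, QueryConfig(similarity_threshold=0.7))
        assert report.target_hits
        top = report.target_hits[0]
        assert top.uniprot_primary == "P35367"
        assert top.supporting_hits[0].record.monomer_id == "M001"
        assert top.best_similarity == pytest.approx(
            rdkit_path_similarity(CLOPERASTINE, DIPHENHYDRAMINE)
        )

    def test_no_neighbor_gives_empty_report_with_advice(self, h1_table):
        report = fmct_single("C1CCOC1", h1_table, QueryConfig(similarity_threshold=0.9))
        assert report.target_hits == []
        assert "threshold" in report.message

    def test_planted_query_recovers_target_rank_one(self, ref_table, manifest):
        for q in manifest["queries"]:
            if q["kind"] != "inside":
                continue
            report = fmct_single(q["smiles"], ref_table, QueryConfig())
            assert report.target_hits[0].uniprot_primary == q["uniprot"]

    def test_similarity_range_consistent(self, ref_table, manifest):
        report = fmct_single(
            manifest["queries"][0]["smiles"], ref_table, QueryConfig(similarity_threshold=0.3)
        )
        hi, lo = report.similarity_range
        sims = [t.best_similarity for t in report.target_hits]
        assert hi == max(sims) and lo == min(sims)
        assert sims == sorted(sims, reverse=True)

    def test_path_then_mcs_variant_ranks_by_mcs(self, h1_table):
        report = fmct_single(
            CLOPERASTINE, h1_table,
            QueryConfig(similarity_variant=Variant.PATH_THEN_MCS, similarity_threshold=0.3),
        )
        assert report.target_hits[0].uniprot_primary == "P09960"
        expected = mcs_similarity(CLOPERASTINE, LTA4H_INHIBITOR).similarity
        assert report.target_hits[0].best_similarity == pytest.approx(expected)

    def test_pure_mcs_variant(self, h1_table):
        report = fmct_single(
            CLOPERASTINE, h1_table,
            QueryConfig(similarity_variant=Variant.PURE_MCS, similarity_threshold=0.85),
        )
        assert [t.uniprot_primary for t in report.target_hits] == ["P09960"]


class TestBatch:
    def test_rows_match_truncated_single_reports(self, ref_table, manifest):
        config = QueryConfig(top_n_per_compound=3)
        queries = [(f"q{i}", q["smiles"]) for i, q in enumerate(manifest["queries"][:3])]
        rows = fmct_batch(queries, ref_table, config)
        assert len(rows) == 3
        for (qid, smiles), row in zip(queries, rows):
            single = fmct_single(smiles, ref_table, config)
            assert [t["uniprot"] for t in row["targets"]] == [
                t.uniprot_primary for t in single.target_hits[:3]
            ]

    def test_fewer_hits_than_top_n(self, h1_table):
        rows = fmct_batch(
            [("q", DIPHENHYDRAMINE)], h1_table,
            QueryConfig(similarity_threshold=0.99, top_n_per_compound=3),
        )
        assert len(rows[0]["targets"]) == 1

    def test_top_n_override(self, ref_table, manifest):
        config = QueryConfig(similarity_threshold=0.2, top_n_per_compound=10)
        rows = fmct_batch(
            [("q", manifest["queries"][0]["smiles"])], ref_table, config
        )
        assert len(rows[0]["targets"]) <= 10

    def test_unparsable_row_reported_not_fatal(self, h1_table):
        rows = fmct_batch([("bad", "C1CC"), ("ok", "CCO")], h1_table, QueryConfig())
        assert rows[0]["error"] and not rows[1]["error"]

    def test_all_unparsable_is_input_error(self, h1_table):
        with pytest.raises(InputError):
            fmct_batch([("a", "C1CC"), ("b", "XZY")], h1_table, QueryConfig())
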