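"""The target-prediction engine.

Scan a query compound against every record of a reference table with a
chosen similarity variant, keep records that pass both the similarity
threshold and the affinity cutoff, merge hits that point at the same
protein (same UniProt accession), and report targets ranked by their best
supporting similarity. Four variants:

- ``PATH_TANIMOTO``: Tanimoto over the default path fingerprint (fast).
- ``AVG5``: mean of the k correlation-selected fingerprint metrics.
- ``PURE_MCS``: maximum-common-substructure similarity, no prefilter.
- ``PATH_THEN_MCS``: fingerprint scan, then hits re-ranked by MCS.

Threshold comparison is inclusive (>=) so a threshold of 1.0 returns exact
matches. The affinity cutoff applies per measurement row: a compound stays
if any of its rows for a target passes. Tie-breaks are fully specified so
reports are byte-reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from rdkit import Chem

from .errors import InputError, StructureError
from .fingerprints import DEFAULT_FAMILY, fingerprint_mol, mol_from_smiles
from .mcs import McsOptions, mcs_similarity
from .reference_table import BindingRecord, ReferenceTable
from .similarity import (
    Formula,
    MetricSelection,
    averaged_similarity,
    bit_similarity,
)

log = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "QueryConfig",
    "CompoundHit",
    "TargetHit",
    "PredictionReport",
    "scan",
    "merge_by_uniprot",
    "mcs_rerank",
    "fmct_single",
    "fmct_batch",
    "read_queries",
    "write_report_csv",
    "write_batch_csv",
]


class Variant(str, Enum):
    PATH_TANIMOTO = "path"
    AVG5 = "avg5"
    PURE_MCS = "mcs"
    PATH_THEN_MCS = "path+mcs"


@dataclass(frozen=True)
class QueryConfig:
    """Knobs of one prediction run.

    ``affinity_cutoff_nM`` defaults to 10000 nM (10 uM), the conventional
    potency bound for calling a measurement evidence of binding.
    """

    similarity_variant: Variant = Variant.PATH_TANIMOTO
    similarity_threshold: float = 0.7
    affinity_cutoff_nM: float = 10_000.0
    top_n_per_compound: int = 3
    selection: MetricSelection | None = None   # required for AVG5
    mcs_options: McsOptions = field(default_factory=McsOptions)

    def __post_init__(self):
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.affinity_cutoff_nM <= 0:
            raise ValueError("affinity_cutoff_nM must be positive")


@dataclass
class CompoundHit:
    record: BindingRecord
    similarity: float
    mcs_similarity: float | None = None
    mcs_timed_out: bool = False

    @property
    def effective_similarity(self) -> float:
        """Ranking score: the MCS value once a re-rank populated it."""
        return self.similarity if self.mcs_similarity is None else self.mcs_similarity


@dataclass
class TargetHit:
    uniprot_primary: str
    target_name: str
    best_similarity: float
    supporting_hits: list[CompoundHit]
    no_accession: bool = False  # grouped by name because the accession is missing


@dataclass
class PredictionReport:
    query_smiles: str
    query_canonical: str
    config: QueryConfig
    target_hits: list[TargetHit]
    message: str = ""

    @property
    def similarity_range(self) -> tuple[float, float] | None:
        """(max, min) best-similarity over reported targets, as printed in
        per-method report headers."""
        if not self.target_hits:
            return None
        sims = [t.best_similarity for t in self.target_hits]
        return (max(sims), min(sims))


def _record_similarity(query_mol, query_smiles: str, record: BindingRecord,
                       config: QueryConfig, cache: dict) -> float:
    variant = config.similarity_variant
    if variant in (Variant.PATH_TANIMOTO, Variant.PATH_THEN_MCS):
        if "query_fp" not in cache:
            cache["query_fp"] = fingerprint_mol(query_mol, DEFAULT_FAMILY)
        rec_fp = record.fingerprints.get(DEFAULT_FAMILY)
        if rec_fp is None:
            rec_fp = fingerprint_mol(mol_from_smiles(record.smiles), DEFAULT_FAMILY)
        return bit_similarity(cache["query_fp"], rec_fp, Formula.TANIMOTO)
    if variant is Variant.AVG5:
        if config.selection is None:
            raise ValueError("AVG5 variant requires a MetricSelection in config")
        return averaged_similarity(query_smiles, record.smiles, config.selection)
    # PURE_MCS
    return mcs_similarity(query_smiles, record.smiles, config.mcs_options).similarity


def scan(query_smiles: str, table: ReferenceTable, config: QueryConfig) -> list[CompoundHit]:
    """All records with similarity >= threshold and affinity <= cutoff,
    sorted by (similarity desc, affinity asc, monomer_id asc)."""
    query_mol = mol_from_smiles(query_smiles)
    cache: dict = {}
    hits: list[CompoundHit] = []
    for record in table.records:
        if record.affinity_nM > config.affinity_cutoff_nM:
            continue
        sim = _record_similarity(query_mol, query_smiles, record, config, cache)
        if sim >= config.similarity_threshold:
            hits.append(CompoundHit(record=record, similarity=sim))
    hits.sort(key=lambda h: (-h.similarity, h.record.affinity_nM, h.record.monomer_id))
    return hits


def merge_by_uniprot(hits: list[CompoundHit]) -> list[TargetHit]:
    """One TargetHit per distinct accession; accession-less records are
    grouped under their target name and flagged."""
    groups: dict[tuple[str, str], list[CompoundHit]] = {}
    order: list[tuple[str, str]] = []
    for hit in hits:
        rec = hit.record
        if rec.uniprot_primary:
            key = ("uniprot", rec.uniprot_primary)
        else:
            key = ("name", rec.target_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(hit)
    out: list[TargetHit] = []
    for kind, ident in order:
        supporters = sorted(
            groups[(kind, ident)],
            key=lambda h: (-h.effective_similarity, h.record.affinity_nM, h.record.monomer_id),
        )
        out.append(
            TargetHit(
                uniprot_primary=ident if kind == "uniprot" else "",
                target_name=supporters[0].record.target_name,
                best_similarity=supporters[0].effective_similarity,
                supporting_hits=supporters,
                no_accession=(kind == "name"),
            )
        )
    return out


def mcs_rerank(
    hits: list[CompoundHit], query_smiles: str, opts: McsOptions | None = None
) -> list[CompoundHit]:
    """Populate MCS similarity for every hit and re-sort by it.

    The hit *set* is unchanged; order becomes (MCS similarity desc,
    fingerprint similarity desc, monomer_id asc). A per-hit MCS timeout is
    not an error: the hit keeps its best-so-far value and a flag.
    """
    opts = opts or McsOptions()
    reranked = []
    for hit in hits:
        res = mcs_similarity(query_smiles, hit.record.smiles, opts)
        reranked.append(
            replace(hit, mcs_similarity=res.similarity, mcs_timed_out=res.timed_out)
        )
    reranked.sort(
        key=lambda h: (-h.mcs_similarity, -h.similarity, h.record.monomer_id)
    )
    return reranked


def fmct_single(query_smiles: str, table: ReferenceTable, config: QueryConfig) -> PredictionReport:
    """Full prediction for one query: scan, optional MCS re-rank, merge."""
    canonical = Chem.MolToSmiles(mol_from_smiles(query_smiles))
    hits = scan(query_smiles, table, config)
    if config.similarity_variant is Variant.PATH_THEN_MCS:
        hits = mcs_rerank(hits, query_smiles, config.mcs_options)
    targets = merge_by_uniprot(hits)
    targets.sort(key=lambda t: (-t.best_similarity, t.uniprot_primary, t.target_name))
    message = ""
    if not targets:
        message = (
            "no reference compound passed the similarity threshold "
            f"{config.similarity_threshold:g} with affinity <= "
            f"{config.affinity_cutoff_nM:g} nM; consider lowering the threshold"
        )
    return PredictionReport(
        query_smiles=query_smiles,
        query_canonical=canonical,
        config=config,
        target_hits=targets,
        message=message,
    )


def read_queries(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, SMILES) queries from a .smi/.txt (SMILES [id]) or .sdf file."""
    path = Path(path)
    queries: list[tuple[str, str]] = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                queries.append((f"sdf-{i}", ""))  # unparsable placeholder
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf-{i}"
            queries.append((name or f"sdf-{i}", Chem.MolToSmiles(mol)))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"q{i}"
            queries.append((name, smiles))
    return queries


def fmct_batch(
    queries: list[tuple[str, str]], table: ReferenceTable, config: QueryConfig
) -> list[dict]:
    """Compact batch report: one row per query with its top-N targets.

    Each row: ``{"query_id", "query_smiles", "error", "targets": [...]}``
    where targets holds up to ``config.top_n_per_compound`` dicts of
    (target_name, uniprot, best_similarity). Unparsable queries produce a
    row with an error note; if *every* query is unparsable, that is an
    :class:`InputError`.
    """
    rows: list[dict] = []
    n_ok = 0
    for qid, smiles in queries:
        try:
            report = fmct_single(smiles, table, config)
        except StructureError as exc:
            rows.append({"query_id": qid, "query_smiles": smiles,
                         "error": str(exc), "targets": []})
            continue
        n_ok += 1
        rows.append(
            {
                "query_id": qid,
                "query_smiles": smiles,
                "error": "",
                "targets": [
                    {
                        "target_name": t.target_name,
                        "uniprot": t.uniprot_primary,
                        "best_similarity": t.best_similarity,
                    }
                    for t in report.target_hits[: config.top_n_per_compound]
                ],
            }
        )
    if queries and n_ok == 0:
        raise InputError("none of the batch queries could be parsed")
    return rows


# --- CSV output -----------------------------------------------------------

SINGLE_COLUMNS = [
    "target_name", "uniprot", "best_similarity", "monomer_id",
    "smiles", "affinity_type", "affinity_nM",
]


def write_report_csv(report: PredictionReport, path: str | Path) -> None:
    """One supporting compound per row, grouped by target rank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SINGLE_COLUMNS)
        for target in report.target_hits:
            for hit in target.supporting_hits:
                writer.writerow([
                    target.target_name,
                    target.uniprot_primary,
                    f"{target.best_similarity:.4f}",
                    hit.record.monomer_id,
                    hit.record.smiles,
                    hit.record.affinity_type.value,
                    f"{hit.record.affinity_nM:g}",
                ])


def write_batch_csv(rows: list[dict], path: str | Path, top_n: int) -> None:
    """One query per row; empty cells where fewer than top_n targets exist."""
    header = ["query_id", "query_smiles", "error"]
    for i in range(1, top_n + 1):
        header += [f"target{i}_name", f"target{i}_uniprot", f"target{i}_similarity"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in rows:
            cells = [row["query_id"], row["query_smiles"], row["error"]]
            for i in range(top_n):
                if i < len(row["targets"]):
                    t = row["targets"][i]
                    cells += [t["target_name"], t["uniprot"], f"{t['best_similarity']:.4f}"]
                else:
                    cells += ["", "", ""]
            writer.writerow(cells)
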