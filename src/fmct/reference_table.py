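"""Build, persist and reload the curated bioactivity reference table.

The input is a BindingDB-style full-download TSV: one compound-target
affinity measurement per row, with SMILES, target name, UniProt accession,
and Ki / IC50 columns in nanomolar. Curation applies the published filters:

1. keep only rows carrying a Ki or IC50 measurement;
2. drop rows whose affinity is a range/bound (any '<' or '>' qualifier);
3. drop rows whose SMILES fails RDKit parsing + sanitization, or whose
   fingerprint generation fails.

Surviving rows become :class:`BindingRecord` objects carrying the parsed
affinity in nM, the canonical SMILES and one bit fingerprint per requested
family. Stage counts are logged and recorded in ``build_meta`` so a build
against a real BindingDB snapshot can be audited.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path

import pandas as pd
import rdkit
from rdkit import Chem

from .errors import ConfigurationError, FormatError
from .fingerprints import (
    DEFAULT_FAMILY,
    FAMILY_REGISTRY,
    BitFingerprint,
    available_families,
    fingerprint_mol,
)

log = logging.getLogger(__name__)

__all__ = [
    "AffinityType",
    "RawRow",
    "BindingRecord",
    "ReferenceTable",
    "DEFAULT_DIALECT",
    "load_bindingdb_tsv",
    "filter_measurements",
    "sanitize_and_fingerprint",
    "build_reference_table",
    "save_table",
    "load_table",
    "parse_affinity",
]

TABLE_FORMAT_VERSION = "fmct-table/1"

#: logical field -> header name for the current public BindingDB dump.
#: Override any entry via a user dialect mapping.
DEFAULT_DIALECT: dict[str, str] = {
    "smiles": "Ligand SMILES",
    "monomer_id": "BindingDB MonomerID",
    "target_name": "Target Name",
    "uniprot": "UniProt (SwissProt) Primary ID of Target Chain",
    "ki": "Ki (nM)",
    "ic50": "IC50 (nM)",
}


class AffinityType(str, Enum):
    KI = "Ki"
    IC50 = "IC50"
    NONE = "none"


@dataclass(frozen=True)
class RawRow:
    """One measurement as read from the TSV, before any curation.

    ``affinity_text`` is preserved verbatim so qualifier detection and
    numeric parsing happen downstream, where they are counted.
    """

    smiles: str
    monomer_id: str
    target_name: str
    uniprot_ids: tuple[str, ...]
    affinity_type: AffinityType
    affinity_text: str

    @property
    def uniprot_primary(self) -> str:
        return self.uniprot_ids[0] if self.uniprot_ids else ""


@dataclass(frozen=True)
class BindingRecord:
    """A curated measurement: canonical structure + parsed affinity + fingerprints."""

    smiles: str                      # canonical form
    input_smiles: str
    monomer_id: str
    target_name: str
    uniprot_primary: str
    affinity_type: AffinityType
    affinity_nM: float
    fingerprints: dict[str, BitFingerprint] = field(default_factory=dict, repr=False)


@dataclass
class ReferenceTable:
    records: list[BindingRecord]
    build_meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


_QUALIFIER_RE = re.compile(r"[<>]")
_NUMBER_RE = re.compile(r"^=?\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*$")


def parse_affinity(text: str) -> float | None:
    """Parse an affinity field into a positive finite nM value.

    Returns None for anything else: blanks, range qualifiers ('<'/'>'
    anywhere in the field), non-numeric text, zero/negative values. A bare
    '=' prefix is accepted (some dump variants print '=5000').
    """
    if text is None:
        return None
    text = text.strip()
    if not text or _QUALIFIER_RE.search(text):
        return None
    m = _NUMBER_RE.match(text)
    if not m:
        return None
    value = float(m.group(1))
    if value <= 0 or not math.isfinite(value):
        return None
    return value


def _resolve_dialect(dialect: dict[str, str] | None) -> dict[str, str]:
    resolved = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(
                f"unknown dialect field(s) {sorted(unknown)}; "
                f"valid fields: {sorted(DEFAULT_DIALECT)}"
            )
        resolved.update(dialect)
    return resolved


def load_bindingdb_tsv(
    path: str | Path, dialect: dict[str, str] | None = None
) -> list[RawRow]:
    """Read a BindingDB-style TSV into raw rows.

    A physical line with both Ki and IC50 populated yields one row per
    measurement (each measurement is independent evidence). Lines with
    neither yield a single row with affinity type ``NONE`` so that the
    measurement filter, not the reader, counts them out. Malformed lines
    are counted and logged, never fatal.
    """
    dialect = _resolve_dialect(dialect)
    path = Path(path)
    bad_lines: list[str] = []
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        on_bad_lines=lambda line: bad_lines.append("\t".join(line)),  # type: ignore[arg-type]
        engine="python",
    )
    required = {k: dialect[k] for k in ("smiles", "target_name")}
    missing = [col for col in required.values() if col not in df.columns]
    # affinity columns: at least one of ki/ic50 must exist
    if not any(dialect[k] in df.columns for k in ("ki", "ic50")):
        missing.append(f"{dialect['ki']} (or {dialect['ic50']})")
    if missing:
        raise ConfigurationError(
            f"required column(s) missing from {path.name}: {missing}; "
            "adjust the dialect mapping if the header names differ"
        )
    if bad_lines:
        log.warning("%d malformed line(s) skipped in %s", len(bad_lines), path)

    def cell(row, key) -> str:
        col = dialect[key]
        return str(row[col]).strip() if col in df.columns else ""

    rows: list[RawRow] = []
    for _, r in df.iterrows():
        uniprot = tuple(u.strip() for u in cell(r, "uniprot").split(",") if u.strip())
        common = dict(
            smiles=cell(r, "smiles"),
            monomer_id=cell(r, "monomer_id"),
            target_name=cell(r, "target_name"),
            uniprot_ids=uniprot,
        )
        ki_text = cell(r, "ki")
        ic50_text = cell(r, "ic50")
        emitted = False
        if ki_text:
            rows.append(RawRow(**common, affinity_type=AffinityType.KI, affinity_text=ki_text))
            emitted = True
        if ic50_text:
            rows.append(RawRow(**common, affinity_type=AffinityType.IC50, affinity_text=ic50_text))
            emitted = True
        if not emitted:
            rows.append(RawRow(**common, affinity_type=AffinityType.NONE, affinity_text=""))
    return rows


def filter_measurements(rows: list[RawRow]) -> list[RawRow]:
    """Keep rows with a plain positive Ki or IC50 value (no '<'/'>' bounds)."""
    kept = [
        row
        for row in rows
        if row.affinity_type in (AffinityType.KI, AffinityType.IC50)
        and parse_affinity(row.affinity_text) is not None
    ]
    log.info("measurement filter: %d -> %d rows", len(rows), len(kept))
    return kept


def sanitize_and_fingerprint(
    rows: list[RawRow], families: list[str] | None = None
) -> tuple[list[BindingRecord], dict[str, int]]:
    """Parse + sanitize structures and attach one fingerprint per family.

    Returns the surviving records plus drop counters
    (``sanitize_failures``, ``fingerprint_failures``).
    """
    families = list(families) if families is not None else [DEFAULT_FAMILY]
    unknown = [f for f in families if f not in FAMILY_REGISTRY]
    unavailable = [
        f for f in families if f in FAMILY_REGISTRY and not FAMILY_REGISTRY[f].available
    ]
    if unknown or unavailable:
        raise ConfigurationError(
            f"unknown/unavailable fingerprint families {unknown + unavailable}; "
            f"valid ids: {available_families()}"
        )
    records: list[BindingRecord] = []
    counters = {"sanitize_failures": 0, "fingerprint_failures": 0}
    for row in rows:
        mol = Chem.MolFromSmiles(row.smiles) if row.smiles else None
        if mol is None:
            counters["sanitize_failures"] += 1
            continue
        try:
            fps = {fam: fingerprint_mol(mol, fam) for fam in families}
        except Exception:  # a family can balk on exotic structures
            counters["fingerprint_failures"] += 1
            continue
        affinity = parse_affinity(row.affinity_text)
        if affinity is None:  # callers should have filtered already
            continue
        records.append(
            BindingRecord(
                smiles=Chem.MolToSmiles(mol),
                input_smiles=row.smiles,
                monomer_id=row.monomer_id,
                target_name=row.target_name,
                uniprot_primary=row.uniprot_primary,
                affinity_type=row.affinity_type,
                affinity_nM=affinity,
                fingerprints=fps,
            )
        )
    log.info(
        "sanitize/fingerprint: %d -> %d records (%d sanitize, %d fingerprint failures)",
        len(rows), len(records),
        counters["sanitize_failures"], counters["fingerprint_failures"],
    )
    return records, counters


def build_reference_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    families: list[str] | None = None,
) -> ReferenceTable:
    """Compose load -> measurement filter -> sanitize/fingerprint.

    ``families=["path"]`` reproduces the fast build that carries only the
    default path fingerprint.
    """
    families = list(families) if families is not None else [DEFAULT_FAMILY]
    raw = load_bindingdb_tsv(path, dialect)
    measured = filter_measurements(raw)
    records, counters = sanitize_and_fingerprint(measured, families)
    meta = {
        "source": str(path),
        "fingerprint_families": families,
        "stage_counts": {
            "raw": len(raw),
            "measurement_filtered": len(measured),
            "sanitized": len(records),
        },
        "drop_counts": {
            "no_measurement_or_qualifier": len(raw) - len(measured),
            **counters,
        },
        "built_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "toolkit": f"rdkit {rdkit.__version__}",
    }
    return ReferenceTable(records=records, build_meta=meta)


# --- persistence ----------------------------------------------------------

def _record_to_dict(rec: BindingRecord) -> dict:
    return {
        "smiles": rec.smiles,
        "input_smiles": rec.input_smiles,
        "monomer_id": rec.monomer_id,
        "target_name": rec.target_name,
        "uniprot_primary": rec.uniprot_primary,
        "affinity_type": rec.affinity_type.value,
        "affinity_nM": rec.affinity_nM,
        "fingerprints": {
            fam: {"nbits": fp.nbits, "hex": fp.to_hex()}
            for fam, fp in rec.fingerprints.items()
        },
    }


def _record_from_dict(d: dict) -> BindingRecord:
    return BindingRecord(
        smiles=d["smiles"],
        input_smiles=d["input_smiles"],
        monomer_id=d["monomer_id"],
        target_name=d["target_name"],
        uniprot_primary=d["uniprot_primary"],
        affinity_type=AffinityType(d["affinity_type"]),
        affinity_nM=float(d["affinity_nM"]),
        fingerprints={
            fam: BitFingerprint.from_hex(fam, int(spec["nbits"]), spec["hex"])
            for fam, spec in d["fingerprints"].items()
        },
    )


def save_table(table: ReferenceTable, path: str | Path) -> None:
    """Write the table as versioned JSON with hex-encoded fingerprints."""
    payload = {
        "format_version": TABLE_FORMAT_VERSION,
        "build_meta": table.build_meta,
        "records": [_record_to_dict(r) for r in table.records],
    }
    Path(path).write_text(json.dumps(payload))


def load_table(path: str | Path) -> ReferenceTable:
    """Reload a saved table; corrupt or version-mismatched files raise
    :class:`FormatError` rather than yielding a partial table."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"reference table file {path} is corrupt: {exc}") from exc
    version = payload.get("format_version")
    if version != TABLE_FORMAT_VERSION:
        raise FormatError(
            f"unsupported table format version {version!r} "
            f"(expected {TABLE_FORMAT_VERSION})"
        )
    return ReferenceTable(
        records=[_record_from_dict(d) for d in payload["records"]],
        build_meta=payload.get("build_meta", {}),
    )
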