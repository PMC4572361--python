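"""Thin client for the BindingDB RESTful web services.

Two queries are wrapped: ligands known to bind a protein (by UniProt
accession) and protein targets known to bind a compound (by SMILES, with a
server-side chemical-similarity cutoff on the 0-1 scale). Responses are
XML; parsed rows are validated through the same :class:`BindingRecord`
constructor as the TSV path, so both sources share one schema.

The HTTP layer sits behind an injectable transport callable so the whole
module is testable offline with canned XML; network use can also be slowed
unpredictably by traffic, which is why local reference tables are the
default workflow and this client is optional.
"""

from __future__ import annotations

import re
import time
import urllib.error
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

from rdkit import Chem

from .errors import ServiceParseError, TransportError
from .fingerprints import mol_from_smiles
from .reference_table import AffinityType, BindingRecord, parse_affinity

__all__ = [
    "Endpoint",
    "ServiceQuery",
    "BindingDBClient",
    "get_ligands_by_uniprot",
    "get_targets_by_compound",
    "DEFAULT_XML_DIALECT",
]

BASE_URL = "https://bindingdb.org/axis2/services/BDBService"

_UNIPROT_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)

#: logical field -> XML element local-name; the service schema is versioned
#: outside our control, so remap here if it drifts.
DEFAULT_XML_DIALECT: dict[str, str] = {
    "hit": "affinities",
    "monomer_id": "monomerid",
    "smiles": "smile",
    "target_name": "target",
    "affinity_type": "affinity_type",
    "affinity": "affinity",
    "similarity": "similarity",
    "uniprot": "query",
}


class Endpoint(str, Enum):
    LIGANDS_BY_UNIPROT = "getLigandsByUniprot"
    TARGETS_BY_COMPOUND = "getTargetByCompound"


@dataclass(frozen=True)
class ServiceQuery:
    endpoint: Endpoint
    uniprot: str | None = None
    smiles: str | None = None
    similarity_cutoff: float = 1.0
    affinity_cutoff_nM: float = 10_000.0

    def __post_init__(self):
        if (self.uniprot is None) == (self.smiles is None):
            raise ValueError("set exactly one of uniprot / smiles")
        if self.endpoint is Endpoint.LIGANDS_BY_UNIPROT and self.uniprot is None:
            raise ValueError("LIGANDS_BY_UNIPROT requires a uniprot accession")
        if self.endpoint is Endpoint.TARGETS_BY_COMPOUND and self.smiles is None:
            raise ValueError("TARGETS_BY_COMPOUND requires a SMILES")
        if not 0.0 <= self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must be in [0, 1]")


Transport = Callable[[str], bytes]


def _urllib_transport(timeout: float) -> Transport:
    def fetch(url: str) -> bytes:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read()

    return fetch


@dataclass
class BindingDBClient:
    """REST client with retry/backoff; pass ``transport`` to stub the wire."""

    base_url: str = BASE_URL
    transport: Transport | None = None
    timeout: float = 30.0
    retries: int = 2
    backoff: float = 1.0
    xml_dialect: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_XML_DIALECT))

    def _fetch(self, url: str) -> bytes:
        transport = self.transport or _urllib_transport(self.timeout)
        last: Exception | None = None
        for attempt in range(self.retries + 1):
            try:
                return transport(url)
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                last = exc
                if attempt < self.retries:
                    time.sleep(self.backoff * (2 ** attempt))
        raise TransportError(f"request failed after {self.retries + 1} attempts: {last}")

    # -- parsing ----------------------------------------------------------

    def _local(self, elem) -> str:
        return elem.tag.rsplit("}", 1)[-1]

    def _parse_hits(self, payload: bytes, query: ServiceQuery) -> list[BindingRecord]:
        try:
            root = ET.fromstring(payload)
        except ET.ParseError as exc:
            excerpt = payload[:120].decode("utf-8", "replace")
            raise ServiceParseError(f"malformed XML from service: {exc}; payload starts "
                                    f"{excerpt!r}") from exc
        d = self.xml_dialect
        records: list[BindingRecord] = []
        for hit in root.iter():
            if self._local(hit) != d["hit"]:
                continue
            fields = {self._local(child): (child.text or "").strip() for child in hit}
            affinity = parse_affinity(fields.get(d["affinity"], ""))
            if affinity is None or affinity > query.affinity_cutoff_nM:
                continue
            # the server applies the similarity cutoff; re-check defensively
            sim_text = fields.get(d["similarity"], "")
            if sim_text:
                try:
                    if float(sim_text) < query.similarity_cutoff - 1e-9:
                        continue
                except ValueError:
                    pass
            type_text = fields.get(d["affinity_type"], "").replace("_", "").upper()
            if type_text == "KI":
                affinity_type = AffinityType.KI
            elif type_text == "IC50":
                affinity_type = AffinityType.IC50
            else:
                continue
            smiles = fields.get(d["smiles"], "")
            mol = Chem.MolFromSmiles(smiles) if smiles else None
            if mol is None:
                continue
            records.append(
                BindingRecord(
                    smiles=Chem.MolToSmiles(mol),
                    input_smiles=smiles,
                    monomer_id=fields.get(d["monomer_id"], ""),
                    target_name=fields.get(d["target_name"], ""),
                    uniprot_primary=fields.get(d["uniprot"], "") if query.uniprot is None
                    else query.uniprot,
                    affinity_type=affinity_type,
                    affinity_nM=affinity,
                )
            )
        return records

    # -- public queries ---------------------------------------------------

    def get_ligands_by_uniprot(self, query: ServiceQuery) -> list[BindingRecord]:
        """Compounds known to bind the accession, affinity <= cutoff."""
        if query.endpoint is not Endpoint.LIGANDS_BY_UNIPROT:
            raise ValueError("query endpoint mismatch")
        if not _UNIPROT_RE.match(query.uniprot or ""):
            raise ValueError(f"not a syntactically valid UniProt accession: {query.uniprot!r}")
        url = (
            f"{self.base_url}/{Endpoint.LIGANDS_BY_UNIPROT.value}"
            f"?uniprot={urllib.parse.quote(query.uniprot)}"
            f"&cutoff={query.affinity_cutoff_nM:g}&response=application/xml"
        )
        return self._parse_hits(self._fetch(url), query)

    def get_targets_by_compound(self, query: ServiceQuery) -> list[BindingRecord]:
        """Targets known to bind compounds similar to the query SMILES."""
        if query.endpoint is not Endpoint.TARGETS_BY_COMPOUND:
            raise ValueError("query endpoint mismatch")
        canonical = Chem.MolToSmiles(mol_from_smiles(query.smiles))  # validate locally
        url = (
            f"{self.base_url}/{Endpoint.TARGETS_BY_COMPOUND.value}"
            f"?smiles={urllib.parse.quote(canonical)}"
            f"&cutoff={query.similarity_cutoff:g}&response=application/xml"
        )
        return self._parse_hits(self._fetch(url), query)


def get_ligands_by_uniprot(query: ServiceQuery, client: BindingDBClient | None = None):
    return (client or BindingDBClient()).get_ligands_by_uniprot(query)


def get_targets_by_compound(query: ServiceQuery, client: BindingDBClient | None = None):
    return (client or BindingDBClient()).get_targets_by_compound(query)
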