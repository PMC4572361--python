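"""2D chemical fingerprints.

A *family* is a fingerprint generation method (path/Daylight-style, Morgan
circular, MACCS keys, ...). The registry names fourteen families spanning
the CDK and RDKit toolkits' conventions; the ones the installed RDKit
toolkit can generate are marked available and everything else is registered
as a known but unavailable family, so the 3 x N metric enumeration stays
explicit about what N is on this toolkit.

All generators run with their default parameters; the "path" family in
particular is the plain default ``Chem.RDKFingerprint``, which is the single
fingerprint used by the fast target-prediction variant and by the clustering
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from .errors import ComparabilityError, ConfigurationError, FormatError, StructureError

__all__ = [
    "BitFingerprint",
    "FAMILY_REGISTRY",
    "available_families",
    "all_family_ids",
    "fingerprint_mol",
    "fingerprint_smiles",
    "mol_from_smiles",
    "DEFAULT_FAMILY",
]

#: family used by the fast scan variant and by reference-set clustering
DEFAULT_FAMILY = "path"


def mol_from_smiles(smiles: str):
    """Parse and sanitize a SMILES, raising :class:`StructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"SMILES failed to parse/sanitize: {smiles!r}")
    return mol


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary fingerprint tagged with its family.

    Two fingerprints are comparable only when both ``family_id`` and
    ``nbits`` agree; :func:`fmct.similarity.bit_similarity` enforces this.
    """

    family_id: str
    bv: ExplicitBitVect = field(repr=False)

    @property
    def nbits(self) -> int:
        return self.bv.GetNumBits()

    @property
    def popcount(self) -> int:
        return self.bv.GetNumOnBits()

    def to_hex(self) -> str:
        """Serialize to a fixed-width hex string (bit 0 = most significant)."""
        bits = self.bv.ToBitString()
        width = -(-self.nbits // 4)
        return format(int(bits, 2) if bits else 0, f"0{width}x")

    @classmethod
    def from_hex(cls, family_id: str, nbits: int, hexstring: str) -> "BitFingerprint":
        value = int(hexstring, 16)
        bv = ExplicitBitVect(nbits)
        bits = format(value, f"0{nbits}b")
        if len(bits) > nbits:
            raise FormatError(
                f"hex fingerprint for family {family_id!r} does not fit in {nbits} bits"
            )
        for i, ch in enumerate(bits):
            if ch == "1":
                bv.SetBit(i)
        return cls(family_id, bv)

    def __eq__(self, other) -> bool:  # bit-exact equality
        return (
            isinstance(other, BitFingerprint)
            and self.family_id == other.family_id
            and self.nbits == other.nbits
            and self.bv.ToBitString() == other.bv.ToBitString()
        )


# --- generator functions -------------------------------------------------

def _path(mol):
    return Chem.RDKFingerprint(mol)


def _morgan(mol):
    return rdFingerprintGenerator.GetMorganGenerator(radius=2).GetFingerprint(mol)


def _feat_morgan(mol):
    inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, atomInvariantsGenerator=inv)
    return gen.GetFingerprint(mol)


def _atompair(mol):
    return rdFingerprintGenerator.GetAtomPairGenerator().GetFingerprint(mol)


def _torsion(mol):
    return rdFingerprintGenerator.GetTopologicalTorsionGenerator().GetFingerprint(mol)


def _maccs(mol):
    return MACCSkeys.GenMACCSKeys(mol)


def _avalon(mol):
    return pyAvalonTools.GetAvalonFP(mol)


def _layered(mol):
    return Chem.LayeredFingerprint(mol)


def _pattern(mol):
    return Chem.PatternFingerprint(mol)


@dataclass(frozen=True)
class FamilyInfo:
    family_id: str
    label: str
    generator: Callable | None  # None -> known but unavailable on this toolkit

    @property
    def available(self) -> bool:
        return self.generator is not None


#: the fourteen named families; five CDK-only ones have no generator here
FAMILY_REGISTRY: dict[str, FamilyInfo] = {
    info.family_id: info
    for info in [
        FamilyInfo("path", "RDKit topological path (Daylight-style)", _path),
        FamilyInfo("morgan", "Morgan circular, radius 2", _morgan),
        FamilyInfo("feat_morgan", "Feature-class Morgan, radius 2", _feat_morgan),
        FamilyInfo("atompair", "Hashed atom-pair", _atompair),
        FamilyInfo("torsion", "Hashed topological torsion", _torsion),
        FamilyInfo("maccs", "MACCS 166-bit keys", _maccs),
        FamilyInfo("avalon", "Avalon", _avalon),
        FamilyInfo("layered", "RDKit layered", _layered),
        FamilyInfo("pattern", "RDKit pattern (substructure screen)", _pattern),
        FamilyInfo("cdk_standard", "CDK standard hashed path", None),
        FamilyInfo("cdk_extended", "CDK extended hashed path", None),
        FamilyInfo("cdk_estate", "CDK E-state", None),
        FamilyInfo("cdk_pubchem", "CDK PubChem-CACTVS keys", None),
        FamilyInfo("cdk_maccs", "CDK MACCS", None),
    ]
}


def all_family_ids() -> list[str]:
    return list(FAMILY_REGISTRY)


def available_families() -> list[str]:
    return [f for f, info in FAMILY_REGISTRY.items() if info.available]


def fingerprint_mol(mol, family_id: str) -> BitFingerprint:
    """Generate the fingerprint of one family for an RDKit molecule."""
    info = FAMILY_REGISTRY.get(family_id)
    if info is None:
        raise ConfigurationError(
            f"unknown fingerprint family {family_id!r}; valid ids: "
            + ", ".join(all_family_ids())
        )
    if not info.available:
        raise ConfigurationError(
            f"fingerprint family {family_id!r} is not available on this toolkit; "
            "available: " + ", ".join(available_families())
        )
    return BitFingerprint(family_id, info.generator(mol))


def fingerprint_smiles(smiles: str, family_id: str) -> BitFingerprint:
    return fingerprint_mol(mol_from_smiles(smiles), family_id)


def check_comparable(fp_a: BitFingerprint, fp_b: BitFingerprint) -> None:
    if fp_a.family_id != fp_b.family_id or fp_a.nbits != fp_b.nbits:
        raise ComparabilityError(
            f"fingerprints are not comparable: "
            f"{fp_a.family_id}/{fp_a.nbits} vs {fp_b.family_id}/{fp_b.nbits}"
        )
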