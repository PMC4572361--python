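"""Maximum-common-substructure similarity on a 0-1 scale.

Two matching modes are provided:

``connected``
    One connected MCS, straight from RDKit's FMCS implementation.

``fragment`` (default)
    Greedy fragment-tolerant matching: find the connected MCS, remove the
    matched atoms from both molecules, and repeat until no common fragment
    of at least ``min_fragment_atoms`` heavy atoms remains. This emulates
    substructure-mining style similarity, where two molecules that share all
    their pieces but differ in how the pieces are wired still score high.
    It is also the behaviour suggested by drug pairs that a connected MCS
    undervalues (e.g. an ether-linked side chain attached at a different
    position of a shared diaryl core).

Normalizations (all bounded by [0, 1], 1 exactly when the molecules are
substructure-identical):

- ``atom_bond_tanimoto`` (default, chosen by calibration — see
  docs/methods.md): Tanimoto over atoms + bonds,
  (n + m) / (n_a + m_a + n_b + m_b - n - m).
- ``tanimoto``: heavy-atom Tanimoto, n / (n_a + n_b - n).
- ``min``: n / min(n_a, n_b).
"""

from __future__ import annotations

import time
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .errors import StructureError
from .fingerprints import mol_from_smiles

__all__ = ["McsOptions", "McsResult", "mcs_similarity", "NORMALIZATIONS"]

NORMALIZATIONS = ("atom_bond_tanimoto", "tanimoto", "min")
MODES = ("fragment", "connected")


@dataclass(frozen=True)
class McsOptions:
    """Matching and scoring options.

    ``timeout`` is the total per-pair budget in seconds; hitting it is not
    an error — the best match found so far is scored and flagged.
    """

    mode: str = "fragment"
    normalization: str = "atom_bond_tanimoto"
    timeout: float = 60.0
    min_fragment_atoms: int = 1
    ring_matches_ring_only: bool = True
    complete_rings_only: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )


@dataclass
class McsResult:
    """Size of the common substructure and its normalized similarity."""

    n_mcs: int          # heavy atoms matched
    n_mcs_bonds: int    # bonds matched
    n_a: int
    n_b: int
    n_a_bonds: int
    n_b_bonds: int
    similarity: float
    timed_out: bool = False
    fragment_smarts: list[str] = field(default_factory=list)

    def normalized(self, normalization: str) -> float:
        """Similarity under any supported normalization (for audit output)."""
        return _normalize(
            normalization,
            self.n_mcs,
            self.n_mcs_bonds,
            self.n_a,
            self.n_b,
            self.n_a_bonds,
            self.n_b_bonds,
        )


def _normalize(norm, n, m, n_a, n_b, m_a, m_b) -> float:
    if n_a == 0 or n_b == 0:
        raise StructureError("cannot score a molecule with no heavy atoms")
    if norm == "tanimoto":
        return n / (n_a + n_b - n)
    if norm == "min":
        return n / min(n_a, n_b)
    # atoms + bonds Tanimoto
    return (n + m) / ((n_a + m_a) + (n_b + m_b) - (n + m))


def _refresh(mol: Chem.RWMol) -> None:
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)


def _find_mcs(mol_a, mol_b, opts: McsOptions, timeout_s: int):
    return rdFMCS.FindMCS(
        [mol_a, mol_b],
        ringMatchesRingOnly=opts.ring_matches_ring_only,
        completeRingsOnly=opts.complete_rings_only,
        timeout=max(1, timeout_s),
    )


def _match_lone_atoms(mol_a, mol_b) -> int:
    """Pair up residual degree-0 atoms by element (FMCS needs >= 1 bond)."""
    lone = lambda m: Counter(
        at.GetSymbol() for at in m.GetAtoms() if at.GetDegree() == 0
    )
    common = lone(mol_a) & lone(mol_b)
    return sum(common.values())


def mcs_similarity(smiles_a: str, smiles_b: str, opts: McsOptions | None = None) -> McsResult:
    """Compute MCS similarity between two molecules.

    Returns an :class:`McsResult`; ``similarity`` uses ``opts.normalization``
    and the remaining normalizations can be read off the same result via
    :meth:`McsResult.normalized`.
    """
    opts = opts or McsOptions()
    mol_a = mol_from_smiles(smiles_a)
    mol_b = mol_from_smiles(smiles_b)
    n_a, n_b = mol_a.GetNumHeavyAtoms(), mol_b.GetNumHeavyAtoms()
    m_a, m_b = mol_a.GetNumBonds(), mol_b.GetNumBonds()
    if n_a == 0 or n_b == 0:
        raise StructureError("both molecules must have at least one heavy atom")

    deadline = time.monotonic() + opts.timeout
    total_atoms = 0
    total_bonds = 0
    timed_out = False
    fragments: list[str] = []

    work_a, work_b = Chem.RWMol(mol_a), Chem.RWMol(mol_b)
    while work_a.GetNumAtoms() and work_b.GetNumAtoms():
        budget = int(deadline - time.monotonic())
        if budget <= 0:
            timed_out = True
            break
        res = _find_mcs(work_a, work_b, opts, budget)
        if res.canceled:
            timed_out = True
        if res.numAtoms < max(opts.min_fragment_atoms, 2):
            break
        total_atoms += res.numAtoms
        total_bonds += res.numBonds
        fragments.append(res.smartsString)
        if opts.mode == "connected" or res.canceled:
            break
        query = Chem.MolFromSmarts(res.smartsString)
        for work in (work_a, work_b):
            match = work.GetSubstructMatch(query)
            if not match:  # defensive: query must hit its own source
                break
            for idx in sorted(match, reverse=True):
                work.RemoveAtom(idx)
            _refresh(work)

    # single atoms carry no bond, so FMCS cannot see them
    if opts.min_fragment_atoms <= 1 and not timed_out:
        if opts.mode == "fragment":
            total_atoms += _match_lone_atoms(work_a, work_b)
        elif total_atoms == 0:
            total_atoms += min(1, _match_lone_atoms(mol_a, mol_b))

    total_atoms = min(total_atoms, n_a, n_b)
    sim = _normalize(opts.normalization, total_atoms, total_bonds, n_a, n_b, m_a, m_b)
    return McsResult(
        n_mcs=total_atoms,
        n_mcs_bonds=total_bonds,
        n_a=n_a,
        n_b=n_b,
        n_a_bonds=m_a,
        n_b_bonds=m_b,
        similarity=min(1.0, max(0.0, sim)),
        timed_out=timed_out,
        fragment_smarts=fragments,
    )
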