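"""Seeded synthetic fixtures: small BindingDB-style tables with known structure.

The generator plants *scaffold series*: a large drug-like core decorated
with single small substituents at aromatic CH positions. One added atom on
a ~30-heavy-atom core perturbs only a small fraction of its path
fingerprint, so within-series similarity to the core stays high (>= 0.8)
while distinct cores sit far apart — giving known cluster structure at the
standard 0.8 clustering threshold. The undecorated core is always assigned
the lowest (most potent) affinity of its series, so affinity-ordered leader
clustering deterministically elects it leader and representative.

Every artifact ships with a ground-truth manifest (per-row validity,
qualifier status, series and target assignment, planted query compounds);
tests assert against the manifest. The chemistry optimizes testability,
not realism: affinities are log-uniform draws and the compound distribution
looks nothing like a real bioactivity database.

Substituent vocabulary and attachment rules are fixed in code, not
configuration, so the similarity separations stay stable; tests assert the
separations rather than assuming them.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

from rdkit import Chem

from .errors import FmctError
from .fingerprints import DEFAULT_FAMILY, fingerprint_mol
from .reference_table import DEFAULT_DIALECT
from .similarity import Formula, bit_similarity

__all__ = [
    "FixtureSpec",
    "SCAFFOLD_CORES",
    "INVALID_SMILES",
    "make_scaffold_series",
    "make_synthetic_tsv",
    "make_pair_panel",
]

#: Diverse drug-like cores, large enough that a one-atom decoration keeps
#: path-fingerprint similarity to the core above the 0.8 clustering
#: threshold. The first two are deliberately maximally dissimilar (mixed
#: aromatic amide vs. a second, chemically remote scaffold) for tests that
#: need a wide similarity gap.
SCAFFOLD_CORES: tuple[str, ...] = (
    "CN1CCN(CC1)c1ccc(NC(=O)c2ccc(-c3ccc(S(=O)(=O)N4CCOCC4)cc3)cc2)cc1",
    "O=C(OCC1CCCN(C2CCCCC2)C1)C1CCCCC1",
    "O=C(NCCc1ccc2ccccc2c1)c1cccc(N2CCN(Cc3ccc(F)cc3)CC2)c1",
    "O=c1cc(-c2ccc(OCCN3CCCCC3)cc2)oc2cc(OCc3ccccc3)ccc12",
    "CC(=O)Nc1ccc(S(=O)(=O)N2CCc3cc(OCCN4CCCC4)ccc3C2)cc1",
    "O=C(Nc1ccc(N2CCOCC2)cc1)N1CCC(c2nc3ccccc3[nH]2)CC1",
    "COc1ccc2[nH]c(C(=O)NCCN3CCN(c4ccccc4)CC3)cc2c1",
    "O=S(=O)(Nc1ccc2ccccc2c1)c1ccc(N2CCN(C(=O)C3CC3)CC2)cc1",
    "O=C(Cc1ccc(OCc2ccccc2)cc1)NC1CCN(Cc2ccccc2)CC1",
    "CC1(C)CCC(NC(=O)c2cccc(S(=O)(=O)N3CCc4ccccc4C3)c2)CC1",
    "O=C(NC1CCCCC1)c1cc(-c2cccs2)nc2ccccc12",
    "CN(C)CCOC(c1ccc(Cl)cc1)c1ccccc1CCN1CCOCC1",
)

#: planted unparsable structures (unclosed rings, syntax errors, bad valence)
INVALID_SMILES: tuple[str, ...] = ("C1CC", "C(", "N(C)(C)(C)C", "XZY", "C#")

#: one-atom (or methoxy) substituents attached by a single bond
_SUBSTITUENTS: tuple[tuple[str, ...], ...] = (
    ("F",), ("Cl",), ("Br",), ("C",), ("O",), ("N",), ("O", "C"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of one synthetic table; generation is a pure
    function of this spec."""

    n_targets: int = 4
    series_per_target: int = 3
    compounds_per_series: int = 5
    n_invalid_smiles: int = 5
    n_qualifier_rows: int = 5
    affinity_range_nM: tuple[float, float] = (1.0, 10_000.0)
    seed: int = 7

    def __post_init__(self):
        if min(self.n_targets, self.series_per_target, self.compounds_per_series) < 0:
            raise ValueError("counts must be >= 0")
        if min(self.n_invalid_smiles, self.n_qualifier_rows) < 0:
            raise ValueError("counts must be >= 0")
        low, high = self.affinity_range_nM
        if not 0 < low < high:
            raise ValueError("affinity range must satisfy 0 < low < high")


@lru_cache(maxsize=8192)
def _fp(smiles: str):
    return fingerprint_mol(Chem.MolFromSmiles(smiles), DEFAULT_FAMILY)


def _path_sim(smiles_a: str, smiles_b: str) -> float:
    return bit_similarity(_fp(smiles_a), _fp(smiles_b), Formula.TANIMOTO)


def _decorate(core_mol, position: int, substituent: tuple[str, ...]) -> str | None:
    rw = Chem.RWMol(core_mol)
    anchor = position
    for symbol in substituent:
        new_idx = rw.AddAtom(Chem.Atom(symbol))
        rw.AddBond(anchor, new_idx, Chem.BondType.SINGLE)
        anchor = new_idx
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _iter_variants(core_smiles: str):
    """Yield distinct single-substituent variants of a core in a fixed,
    deterministic (position, substituent) order."""
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        raise FmctError(f"core SMILES does not parse: {core_smiles!r}")
    canonical_core = Chem.MolToSmiles(core)
    positions = [
        atom.GetIdx()
        for atom in core.GetAtoms()
        if atom.GetSymbol() == "C"
        and atom.GetTotalNumHs() > 0
        and atom.GetIsAromatic()
    ]
    # fall back to any substitutable carbon for non-aromatic cores
    if not positions:
        positions = [
            atom.GetIdx()
            for atom in core.GetAtoms()
            if atom.GetSymbol() == "C" and atom.GetTotalNumHs() > 0
        ]
    seen = {canonical_core}
    for position in positions:
        for substituent in _SUBSTITUENTS:
            smiles = _decorate(core, position, substituent)
            if smiles and smiles not in seen:
                seen.add(smiles)
                yield smiles


def make_scaffold_series(core_smiles: str, n: int, seed: int = 0) -> list[str]:
    """n distinct valid molecules sharing a core: the core itself plus the
    decorated variants most similar to it.

    Variants are ranked by path-fingerprint similarity to the core (so the
    series is as tight as the core allows) and the seed shuffles within the
    top of that ranking; generation is deterministic for a fixed
    (core, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        raise FmctError(f"core SMILES does not parse: {core_smiles!r}")
    canonical_core = Chem.MolToSmiles(core)
    series = [canonical_core]
    if n == 1:
        return series

    tight_floor = 0.80  # keeps the series together at the clustering threshold
    window_size = 2 * (n - 1)
    window: list[str] = []
    loose: list[tuple[float, str]] = []
    any_variant = False
    for smiles in _iter_variants(core_smiles):
        any_variant = True
        sim = _path_sim(canonical_core, smiles)
        if sim >= tight_floor:
            window.append(smiles)
            if len(window) >= window_size:
                break
        else:
            loose.append((sim, smiles))
    if not any_variant:
        raise FmctError(
            f"core {core_smiles!r} has no substitutable position but n={n} > 1"
        )
    if len(window) < n - 1:
        # small cores cannot stay above the floor; fall back to the closest
        loose.sort(key=lambda item: (-item[0], item[1]))
        window.extend(smiles for _, smiles in loose[: n - 1 - len(window)])
    if len(window) < n - 1:
        raise FmctError(
            f"could only generate {len(window)} of {n - 1} distinct variants "
            f"for core {core_smiles!r}"
        )
    random.Random(seed).shuffle(window)
    series.extend(window[: n - 1])
    return series


def _find_between_query(
    core_smiles: str, member_smiles: str,
    inside_floor: float = 0.72, outside_ceiling: float = 0.68,
) -> str | None:
    """A compound that is a near neighbor of one series *member* but not of
    the series core: double-decorates the member until path similarity to
    the member stays >= inside_floor while similarity to the core falls
    below outside_ceiling. Used to plant queries that sit inside the
    cluster's periphery, which a representative-only reduced table misses.
    """
    budget = 400  # cap on similarity evaluations; the search is best-effort
    for candidate in _iter_variants(member_smiles):
        if budget <= 0:
            break
        budget -= 1
        if _path_sim(candidate, member_smiles) < inside_floor:
            continue
        for candidate2 in _iter_variants(candidate):
            if budget <= 0:
                break
            budget -= 1
            if (
                _path_sim(candidate2, member_smiles) >= inside_floor
                and _path_sim(candidate2, core_smiles) < outside_ceiling
            ):
                return candidate2
    return None


def _core_index(spec: FixtureSpec, target: int, series: int) -> int:
    return (target * spec.series_per_target + series) % len(SCAFFOLD_CORES)


def make_synthetic_tsv(
    spec: FixtureSpec, tsv_path: str | Path, manifest_path: str | Path | None = None
) -> dict:
    """Write a BindingDB-dialect TSV plus its ground-truth manifest.

    Layout: for each target, ``series_per_target`` scaffold series of
    ``compounds_per_series`` compounds with plain Ki/IC50 affinities; then
    ``n_qualifier_rows`` rows with '>'-qualified affinities and
    ``n_invalid_smiles`` rows with planted unparsable SMILES. Output is
    byte-identical for a fixed spec. Returns the manifest (also written to
    ``manifest_path`` when given).

    Each (target, series) slot takes a distinct scaffold core as long as
    ``n_targets * series_per_target`` does not exceed the shipped core
    list, which keeps every planted query's nearest series unique. Two
    query compounds are planted per target against its first series: an
    ``inside`` query (a held-out decoration, similar to the series core)
    and, where the search succeeds, a ``between`` query (similar to one
    decorated member but not to the core).
    """
    rng = random.Random(spec.seed)
    low, high = spec.affinity_range_nM
    header = [
        DEFAULT_DIALECT["smiles"],
        DEFAULT_DIALECT["monomer_id"],
        DEFAULT_DIALECT["target_name"],
        DEFAULT_DIALECT["uniprot"],
        DEFAULT_DIALECT["ki"],
        DEFAULT_DIALECT["ic50"],
    ]
    lines = ["\t".join(header)]
    manifest_rows: list[dict] = []
    queries: list[dict] = []
    monomer_counter = 0

    def log_uniform() -> float:
        return round(math.exp(rng.uniform(math.log(low), math.log(high))), 3)

    def emit(smiles, target_idx, series_idx, valid, qualifier, affinity_text, affinity_type):
        nonlocal monomer_counter
        monomer_id = f"M{monomer_counter:05d}"
        monomer_counter += 1
        if target_idx is None:
            target_name, uniprot = "Unassigned synthetic target", ""
        else:
            target_name = f"Synthetic target {target_idx + 1}"
            uniprot = f"P{10000 + target_idx}"
        ki = affinity_text if affinity_type == "Ki" else ""
        ic50 = affinity_text if affinity_type == "IC50" else ""
        lines.append("\t".join([smiles, monomer_id, target_name, uniprot, ki, ic50]))
        manifest_rows.append(
            {
                "monomer_id": monomer_id,
                "smiles": smiles,
                "target": target_idx,
                "uniprot": uniprot,
                "series": series_idx,
                "valid": valid,
                "qualifier": qualifier,
                "affinity_text": affinity_text,
                "affinity_type": affinity_type,
            }
        )

    for t in range(spec.n_targets):
        for s in range(spec.series_per_target):
            core = SCAFFOLD_CORES[_core_index(spec, t, s)]
            # one extra member of series 0 is held out as the inside query
            n_members = spec.compounds_per_series + (1 if s == 0 else 0)
            series = make_scaffold_series(core, n_members, seed=spec.seed + 31 * t + s)
            if s == 0 and spec.compounds_per_series >= 1:
                inside_query = series.pop()
                queries.append(
                    {
                        "smiles": inside_query,
                        "target": t,
                        "uniprot": f"P{10000 + t}",
                        "series": s,
                        "kind": "inside",
                    }
                )
                for anchor in series[1:]:
                    between = _find_between_query(series[0], anchor)
                    if between is not None:
                        queries.append(
                            {
                                "smiles": between,
                                "target": t,
                                "uniprot": f"P{10000 + t}",
                                "series": s,
                                "kind": "between",
                                "anchor_member": anchor,
                            }
                        )
                        break
            affinities = sorted(log_uniform() for _ in series)
            # most potent value goes to the core so it leads its cluster
            for smiles, affinity in zip(series, affinities):
                affinity_type = rng.choice(["Ki", "IC50"])
                emit(smiles, t, s, True, False, f"{affinity:g}", affinity_type)

    qualifier_pool = (
        make_scaffold_series(SCAFFOLD_CORES[0], max(spec.n_qualifier_rows, 1),
                             seed=spec.seed + 9001)
        if spec.n_qualifier_rows
        else []
    )
    for q in range(spec.n_qualifier_rows):
        emit(
            qualifier_pool[q % len(qualifier_pool)],
            None, None, True, True, f">{log_uniform():g}", rng.choice(["Ki", "IC50"]),
        )
    for i in range(spec.n_invalid_smiles):
        emit(INVALID_SMILES[i % len(INVALID_SMILES)], None, None, False, False,
             f"{log_uniform():g}", "Ki")

    n_rows = len(manifest_rows)
    n_valid = sum(1 for r in manifest_rows if r["valid"] and not r["qualifier"])
    manifest = {
        "spec": asdict(spec),
        "rows": manifest_rows,
        "queries": queries,
        "expected": {
            "raw_rows": n_rows,
            "after_measurement_filter": n_rows - spec.n_qualifier_rows,
            "after_sanitize": n_valid,
            "groups": {
                f"P{10000 + t}": spec.series_per_target * spec.compounds_per_series
                for t in range(spec.n_targets)
            },
            "clusters_per_target": spec.series_per_target,
            "total_clusters": spec.n_targets * spec.series_per_target,
        },
    }
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return manifest


def make_pair_panel(
    spec: FixtureSpec, n_cross: int | None = None
) -> list[tuple[str, str, str]]:
    """Labelled compound pairs for metric profiling and correlation
    filtering: all within-series pairs of two maximally separated scaffold
    series, plus a seeded sample of cross-series pairs.

    Returns (smiles_a, smiles_b, label) with label in {"within", "cross"}.
    This stands in for a large panel of pairs drawn from two unrelated
    targets' binder sets: the point is to span high- and low-similarity
    regimes so metric correlations are estimated over a spread of values.
    """
    rng = random.Random(spec.seed + 4242)
    m = spec.compounds_per_series
    series_a = make_scaffold_series(SCAFFOLD_CORES[0], m, seed=spec.seed + 1)
    series_b = make_scaffold_series(SCAFFOLD_CORES[1], m, seed=spec.seed + 2)
    pairs: list[tuple[str, str, str]] = []
    for series in (series_a, series_b):
        for i in range(m):
            for j in range(i + 1, m):
                pairs.append((series[i], series[j], "within"))
    cross_all = [(a, b) for a in series_a for b in series_b]
    if n_cross is None:
        n_cross = min(len(cross_all), len(pairs))
    for a, b in rng.sample(cross_all, min(n_cross, len(cross_all))):
        pairs.append((a, b, "cross"))
    return pairs
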