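"""Fingerprint similarity metrics and redundancy filtering.

Three bit-vector comparison formulas (Tanimoto, Dice, Cosine) crossed with
the fingerprint-family catalog give the metric enumeration; a Pearson
correlation filter then picks the k metrics that correlate least with each
other over a panel of compound pairs, and those selected metrics are
averaged into a single consensus similarity.

Conventions for degenerate (all-zero) fingerprints: the textbook formulas
are 0/0 there, so we define s = 1 when *both* vectors are empty (two
featureless molecules are indistinguishable to the fingerprint) and s = 0
when exactly one is empty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from math import sqrt

import numpy as np

from .errors import FormatError, StructureError
from .fingerprints import (
    DEFAULT_FAMILY,
    BitFingerprint,
    available_families,
    all_family_ids,
    check_comparable,
    fingerprint_mol,
    mol_from_smiles,
)

__all__ = [
    "Formula",
    "MetricSpec",
    "MetricCatalog",
    "MetricSelection",
    "bit_similarity",
    "rdkit_path_similarity",
    "metric_profiles",
    "correlation_filter",
    "averaged_similarity",
]


class Formula(str, Enum):
    TANIMOTO = "tanimoto"
    DICE = "dice"
    COSINE = "cosine"


@dataclass(frozen=True)
class MetricSpec:
    """One similarity metric = fingerprint family x comparison formula."""

    family_id: str
    formula: Formula

    @property
    def metric_id(self) -> str:
        return f"{self.family_id}:{self.formula.value}"


@dataclass(frozen=True)
class MetricCatalog:
    """Cross product of fingerprint families with the three formulas.

    ``families`` defaults to every family the toolkit can generate; the
    full named roster (including families this toolkit lacks) is exposed via
    ``known_families`` for audit.
    """

    families: tuple[str, ...]

    @classmethod
    def default(cls) -> "MetricCatalog":
        return cls(tuple(available_families()))

    @property
    def known_families(self) -> tuple[str, ...]:
        return tuple(all_family_ids())

    @property
    def metrics(self) -> tuple[MetricSpec, ...]:
        return tuple(
            MetricSpec(fam, formula) for fam in self.families for formula in Formula
        )


def bit_similarity(fp_a: BitFingerprint, fp_b: BitFingerprint, formula: Formula) -> float:
    """Bit-vector similarity: Tanimoto c/(a+b-c), Dice 2c/(a+b), Cosine c/sqrt(ab)."""
    check_comparable(fp_a, fp_b)
    a = fp_a.popcount
    b = fp_b.popcount
    if a == 0 and b == 0:
        return 1.0
    if a == 0 or b == 0:
        return 0.0
    c = (fp_a.bv & fp_b.bv).GetNumOnBits()
    formula = Formula(formula)
    if formula is Formula.TANIMOTO:
        return c / (a + b - c)
    if formula is Formula.DICE:
        return 2.0 * c / (a + b)
    return c / sqrt(a * b)


def rdkit_path_similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto over the default-parameter topological path fingerprint.

    This is the single-fingerprint similarity used by the fast prediction
    variant.
    """
    fp_a = fingerprint_mol(mol_from_smiles(smiles_a), DEFAULT_FAMILY)
    fp_b = fingerprint_mol(mol_from_smiles(smiles_b), DEFAULT_FAMILY)
    return bit_similarity(fp_a, fp_b, Formula.TANIMOTO)


def metric_profiles(
    pairs: list[tuple[str, str]], catalog: MetricCatalog | None = None
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Score every pair under every catalog metric.

    Returns an (n_pairs, n_metrics) array and a list of (pair index, reason)
    for pairs skipped because a structure failed to parse; skipped pairs get
    NaN rows so the row index still lines up with the input.
    """
    catalog = catalog or MetricCatalog.default()
    metrics = catalog.metrics
    out = np.full((len(pairs), len(metrics)), np.nan)
    skipped: list[tuple[int, str]] = []
    fp_cache: dict[tuple[str, str], BitFingerprint] = {}

    def fps_for(smiles: str) -> dict[str, BitFingerprint]:
        mol = mol_from_smiles(smiles)
        result = {}
        for fam in catalog.families:
            key = (smiles, fam)
            if key not in fp_cache:
                fp_cache[key] = fingerprint_mol(mol, fam)
            result[fam] = fp_cache[key]
        return result

    for i, (sa, sb) in enumerate(pairs):
        try:
            fa = fps_for(sa)
            fb = fps_for(sb)
        except StructureError as exc:
            skipped.append((i, str(exc)))
            continue
        for j, spec in enumerate(metrics):
            out[i, j] = bit_similarity(fa[spec.family_id], fb[spec.family_id], spec.formula)
    return out, skipped


@dataclass
class MetricSelection:
    """Outcome of the correlation filter: the retained metrics plus the full
    Pearson matrix they were selected from."""

    selected: list[MetricSpec]
    correlation_matrix: np.ndarray = field(repr=False)
    metric_ids: list[str] = field(default_factory=list)
    panel_description: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": "fmct-selection/1",
                "selected": [m.metric_id for m in self.selected],
                "metric_ids": self.metric_ids,
                "correlation_matrix": self.correlation_matrix.tolist(),
                "panel_description": self.panel_description,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetricSelection":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"selection file is not valid JSON: {exc}") from exc
        if data.get("format_version") != "fmct-selection/1":
            raise FormatError(
                f"unsupported selection format version: {data.get('format_version')!r}"
            )

        def parse_spec(mid: str) -> MetricSpec:
            fam, _, formula = mid.rpartition(":")
            return MetricSpec(fam, Formula(formula))

        return cls(
            selected=[parse_spec(m) for m in data["selected"]],
            correlation_matrix=np.asarray(data["correlation_matrix"], dtype=float),
            metric_ids=list(data["metric_ids"]),
            panel_description=data.get("panel_description", ""),
        )


def _pearson_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pearson r between metric columns; zero-variance columns correlate 0."""
    profiles = np.asarray(profiles, dtype=float)
    valid = ~np.isnan(profiles).any(axis=1)
    data = profiles[valid]
    std = data.std(axis=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            "constant-profile metric(s) at column(s) "
            f"{np.flatnonzero(constant).tolist()}; their correlations are set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _greedy_survivors(absr: np.ndarray, k: int) -> list[int]:
    """Greedy pairwise elimination: repeatedly locate the surviving pair
    with the highest |r| and drop the member with the larger mean |r|
    against the other survivors (ties: drop the later catalog index)."""
    survivors = list(range(absr.shape[0]))
    while len(survivors) > k:
        sub = absr[np.ix_(survivors, survivors)]
        np.fill_diagonal(sub, -1.0)
        i_loc, j_loc = divmod(int(np.argmax(sub)), len(survivors))
        gi, gj = survivors[i_loc], survivors[j_loc]
        others_i = [s for s in survivors if s != gi]
        others_j = [s for s in survivors if s != gj]
        mean_i = absr[gi, others_i].mean()
        mean_j = absr[gj, others_j].mean()
        if mean_i > mean_j:
            drop = gi
        elif mean_j > mean_i:
            drop = gj
        else:
            drop = max(gi, gj)
        survivors.remove(drop)
    return survivors


def _exact_survivors(absr: np.ndarray, k: int) -> list[int]:
    """Exhaustive minimax subset selection: the k-subset whose largest
    pairwise |r| is smallest. Ties fall to the subset with the smaller
    sorted pairwise-|r| spectrum, then to the earlier catalog indices."""
    from itertools import combinations

    n = absr.shape[0]
    best_key = None
    best: tuple[int, ...] | None = None
    for subset in combinations(range(n), k):
        pairs = sorted(
            (absr[a, b] for a, b in combinations(subset, 2)), reverse=True
        )
        key = (tuple(pairs), subset)
        if best_key is None or key < best_key:
            best_key, best = key, subset
    return list(best)  # type: ignore[arg-type]


def _n_subsets(n: int, k: int) -> float:
    from math import comb

    return comb(n, k)


def correlation_filter(
    profiles: np.ndarray,
    k: int,
    metrics: list[MetricSpec] | None = None,
    panel_description: str = "",
    method: str = "auto",
) -> MetricSelection:
    """Keep the k metrics that correlate least with each other.

    ``exact`` (default for catalogs where the subset count is tractable)
    minimizes the maximum pairwise |r| of the retained set by exhaustive
    search with fully documented tie-breaks; ``greedy`` applies pairwise
    elimination (see :func:`_greedy_survivors`) and is used automatically
    when the subset count is too large. Both are deterministic.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a pairs x metrics matrix")
    n_pairs, n_metrics = profiles.shape
    if n_metrics < 2:
        raise ValueError("need at least 2 metrics")
    if np.sum(~np.isnan(profiles).any(axis=1)) < 3:
        raise ValueError("need at least 3 complete pair rows")
    if not (1 <= k <= n_metrics):
        raise ValueError(f"k={k} out of range for {n_metrics} metrics")
    if metrics is None:
        metrics = [MetricSpec(f"m{i}", Formula.TANIMOTO) for i in range(n_metrics)]
    if len(metrics) != n_metrics:
        raise ValueError("metrics list length does not match profile columns")
    if method not in ("auto", "exact", "greedy"):
        raise ValueError("method must be 'auto', 'exact' or 'greedy'")

    corr = _pearson_matrix(profiles)
    absr = np.abs(corr)
    if method == "auto":
        method = "exact" if _n_subsets(n_metrics, k) <= 500_000 else "greedy"
    if method == "exact":
        survivors = _exact_survivors(absr, k)
    else:
        survivors = _greedy_survivors(absr, k)

    return MetricSelection(
        selected=[metrics[i] for i in survivors],
        correlation_matrix=corr,
        metric_ids=[m.metric_id for m in metrics],
        panel_description=panel_description,
    )


def averaged_similarity(
    smiles_a: str, smiles_b: str, selection: MetricSelection
) -> float:
    """Unweighted mean of the selected metrics' similarity scores."""
    if not selection.selected:
        raise ValueError("selection is empty")
    mol_a = mol_from_smiles(smiles_a)
    mol_b = mol_from_smiles(smiles_b)
    fps_a: dict[str, BitFingerprint] = {}
    fps_b: dict[str, BitFingerprint] = {}
    total = 0.0
    for spec in selection.selected:
        if spec.family_id not in fps_a:
            fps_a[spec.family_id] = fingerprint_mol(mol_a, spec.family_id)
            fps_b[spec.family_id] = fingerprint_mol(mol_b, spec.family_id)
        total += bit_similarity(fps_a[spec.family_id], fps_b[spec.family_id], spec.formula)
    return total / len(selection.selected)
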