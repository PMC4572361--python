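"""Bit-vector metrics, the metric catalog, and correlation-based selection."""

import itertools

import numpy as np
import pytest
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from fmct.errors import ComparabilityError, StructureError
from fmct.examples import CLOPERASTINE, DIPHENHYDRAMINE
from fmct.fingerprints import BitFingerprint
from fmct.similarity import (
    Formula,
    MetricCatalog,
    MetricSelection,
    _pearson_matrix,
    averaged_similarity,
    bit_similarity,
    correlation_filter,
    metric_profiles,
    rdkit_path_similarity,
)


def _fp(bits, nbits=8, family="test"):
    bv = ExplicitBitVect(nbits)
    for b in bits:
        bv.SetBit(b)
    return BitFingerprint(family, bv)


class TestBitSimilarity:
    def test_hand_enumerated_values(self):
        # a = 4 bits, b = 6 bits, c = 3 shared
        fa = _fp({0, 1, 2, 3})
        fb = _fp({1, 2, 3, 4, 5, 6})
        assert bit_similarity(fa, fb, Formula.TANIMOTO) == pytest.approx(3 / 7)
        assert bit_similarity(fa, fb, Formula.DICE) == pytest.approx(0.6)
        assert bit_similarity(fa, fb, Formula.COSINE) == pytest.approx(3 / np.sqrt(24))

    def test_identity_is_one(self):
        fa = _fp({0, 3, 5})
        for formula in Formula:
            assert bit_similarity(fa, fa, formula) == 1.0

    def test_disjoint_is_zero(self):
        fa, fb = _fp({0, 1}), _fp({5, 6})
        for formula in Formula:
            assert bit_similarity(fa, fb, formula) == 0.0

    def test_all_zero_conventions(self):
        empty, other = _fp(set()), _fp({1})
        for formula in Formula:
            assert bit_similarity(empty, empty, formula) == 1.0
            assert bit_similarity(empty, other, formula) == 0.0

    def test_incomparable_fingerprints(self):
        with pytest.raises(ComparabilityError):
            bit_similarity(_fp({1}), _fp({1}, family="other"), Formula.TANIMOTO)
        with pytest.raises(ComparabilityError):
            bit_similarity(_fp({1}), _fp({1}, nbits=16), Formula.TANIMOTO)

    def test_against_enumeration_oracle(self):
        """Formulas agree exactly with direct popcount arithmetic on random
        64-bit vectors, and Tanimoto never exceeds Dice."""
        rng = np.random.default_rng(42)
        for _ in range(2000):
            mask_a = int(rng.integers(0, 2**63))
            mask_b = int(rng.integers(0, 2**63))
            fa = _fp({i for i in range(64) if mask_a >> i & 1}, nbits=64)
            fb = _fp({i for i in range(64) if mask_b >> i & 1}, nbits=64)
            a, b = bin(mask_a).count("1"), bin(mask_b).count("1")
            c = bin(mask_a & mask_b).count("1")
            tani = bit_similarity(fa, fb, Formula.TANIMOTO)
            dice = bit_similarity(fa, fb, Formula.DICE)
            cos = bit_similarity(fa, fb, Formula.COSINE)
            if a and b:
                assert tani == pytest.approx(c / (a + b - c), abs=0)
                assert dice == pytest.approx(2 * c / (a + b), abs=0)
                assert cos == pytest.approx(c / np.sqrt(a * b), rel=1e-12)
            assert tani <= dice + 1e-12


class TestPathSimilarity:
    def test_self_similarity(self):
        assert rdkit_path_similarity(CLOPERASTINE, CLOPERASTINE) == 1.0

    def test_symmetry(self):
        assert rdkit_path_similarity(CLOPERASTINE, DIPHENHYDRAMINE) == pytest.approx(
            rdkit_path_similarity(DIPHENHYDRAMINE, CLOPERASTINE)
        )

    def test_unparsable_smiles_names_input(self):
        with pytest.raises(StructureError, match="C1CC"):
            rdkit_path_similarity("C1CC", "CCO")


class TestCatalog:
    def test_enumeration_is_three_per_family(self):
        catalog = MetricCatalog.default()
        assert len(catalog.metrics) == 3 * len(catalog.families)
        assert len(set(catalog.metrics)) == len(catalog.metrics)

    def test_known_roster_includes_unavailable_families(self):
        catalog = MetricCatalog.default()
        assert len(catalog.known_families) == 14
        assert set(catalog.families) < set(catalog.known_families)


class TestMetricProfiles:
    def test_shape_and_range(self):
        catalog = MetricCatalog(("path", "maccs"))
        pairs = [("CCO", "CCN"), ("c1ccccc1", "c1ccccc1C"), ("CCO", "CCO")]
        profiles, skipped = metric_profiles(pairs, catalog)
        assert profiles.shape == (3, 6)
        assert skipped == []
        assert np.nanmin(profiles) >= 0 and np.nanmax(profiles) <= 1
        assert np.allclose(profiles[2], 1.0)  # identical pair

    def test_bad_pair_skipped_not_fatal(self):
        profiles, skipped = metric_profiles(
            [("CCO", "C1CC"), ("CCO", "CCN")], MetricCatalog(("path",))
        )
        assert len(skipped) == 1 and skipped[0][0] == 0
        assert np.isnan(profiles[0]).all() and not np.isnan(profiles[1]).any()


class TestCorrelationFilter:
    def test_duplicate_metric_eliminated(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        selection = correlation_filter(np.column_stack([x, x, y]), k=2)
        ids = {m.family_id for m in selection.selected}
        assert "m2" in ids and len(ids & {"m0", "m1"}) == 1

    def test_k_equal_to_all_is_identity(self):
        rng = np.random.default_rng(1)
        profiles = rng.normal(size=(10, 4))
        selection = correlation_filter(profiles, k=4)
        assert [m.family_id for m in selection.selected] == ["m0", "m1", "m2", "m3"]

    def test_anticorrelated_pair_broken_first(self):
        rng = np.random.default_rng(2)
        m1, m2, m3 = (rng.normal(size=40) for _ in range(3))
        selection = correlation_filter(np.column_stack([m1, m2, m3, -m1]), k=3)
        ids = {m.family_id for m in selection.selected}
        assert len(ids & {"m0", "m3"}) == 1  # |r| = 1 pair loses one member

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        selection = correlation_filter(rng.normal(size=(20, 5)), k=3)
        corr = selection.correlation_matrix
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_metric_warns_and_survives_computation(self):
        rng = np.random.default_rng(4)
        profiles = np.column_stack([rng.normal(size=20), np.full(20, 0.5),
                                    rng.normal(size=20)])
        with pytest.warns(UserWarning, match="constant"):
            selection = correlation_filter(profiles, k=2)
        assert len(selection.selected) == 2

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_minimax_search(self, k):
        """On small catalogs the selection minimizes the maximum pairwise
        |r|, verified against brute-force subset enumeration."""
        rng = np.random.default_rng(100 + k)
        for _ in range(20):
            m = int(rng.integers(max(3, k + 1), 7))
            profiles = (
                rng.normal(size=(25, 3)) @ rng.normal(size=(3, m))
                + 0.4 * rng.normal(size=(25, m))
            )
            selection = correlation_filter(profiles, k)
            got = tuple(sorted(int(s.family_id[1:]) for s in selection.selected))
            absr = np.abs(_pearson_matrix(profiles))

            def max_r(subset):
                return max(absr[a, b] for a, b in itertools.combinations(subset, 2))

            best = min(max_r(s) for s in itertools.combinations(range(m), k))
            assert max_r(got) == pytest.approx(best, abs=1e-12)

    def test_selection_json_roundtrip(self):
        rng = np.random.default_rng(5)
        selection = correlation_filter(rng.normal(size=(15, 4)), k=2,
                                       panel_description="test panel")
        loaded = MetricSelection.from_json(selection.to_json())
        assert [m.metric_id for m in loaded.selected] == [
            m.metric_id for m in selection.selected
        ]
        assert np.allclose(loaded.correlation_matrix, selection.correlation_matrix)


class TestAveragedSimilarity:
    def test_identical_molecules_score_one(self):
        catalog = MetricCatalog(("path", "maccs"))
        selection = MetricSelection(
            selected=list(catalog.metrics), correlation_matrix=np.eye(6)
        )
        assert averaged_similarity("CCO", "CCO", selection) == pytest.approx(1.0)

    def test_mean_of_recomputed_components(self):
        """The averaged score equals the mean of independently computed
        component similarities."""
        catalog = MetricCatalog(("path", "maccs", "morgan"))
        selection = MetricSelection(
            selected=list(catalog.metrics), correlation_matrix=np.eye(9)
        )
        a, b = CLOPERASTINE, DIPHENHYDRAMINE
        profiles, _ = metric_profiles([(a, b)], catalog)
        assert averaged_similarity(a, b, selection) == pytest.approx(
            profiles[0].mean(), abs=1e-12
        )
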