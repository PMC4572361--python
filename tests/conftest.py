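"""Shared fixtures: one synthetic reference set per test session."""

import pytest

from fmct.fixtures import FixtureSpec, make_synthetic_tsv
from fmct.reduction import ReductionConfig, build_reduced_table
from fmct.reference_table import build_reference_table


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec()  # 4 targets x 3 series x 5 compounds, 5+5 bad rows, seed 7


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory, fixture_spec):
    d = tmp_path_factory.mktemp("synthetic")
    tsv = d / "reference.tsv"
    manifest_file = d / "manifest.json"
    manifest = make_synthetic_tsv(fixture_spec, tsv, manifest_file)
    return {"tsv": tsv, "manifest_file": manifest_file, "manifest": manifest}


@pytest.fixture(scope="session")
def manifest(fixture_paths):
    return fixture_paths["manifest"]


@pytest.fixture(scope="session")
def ref_table(fixture_paths):
    return build_reference_table(fixture_paths["tsv"])


@pytest.fixture(scope="session")
def reduced_table(ref_table):
    return build_reduced_table(ref_table, ReductionConfig())
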