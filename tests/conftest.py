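"""Shared fixtures: synthetic assemblies processed once per session."""

from __future__ import annotations

import pytest

from ifacetess.fixtures import FixtureSpec, make_assembly, write_fixture_set
from ifacetess.pipeline import process_assembly


def _process(kind: str, **params):
    assembly, truth = make_assembly(FixtureSpec(kind=kind, params=params))
    result = process_assembly(assembly, n_solvent_samples=128)
    return result, truth


@pytest.fixture(scope="session")
def dimer_result():
    return _process("helix-dimer")


@pytest.fixture(scope="session")
def peptide_result():
    return _process("peptide-complex")


@pytest.fixture(scope="session")
def dna_result():
    return _process("dna-complex")


@pytest.fixture(scope="session")
def tetramer_result():
    return _process("homotetramer")


@pytest.fixture(scope="session")
def dual_mode_results():
    return {mode: _process("dual-mode-pair", mode=mode) for mode in (1, 2)}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_set")
    write_fixture_set(out, seed=0)
    return out
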