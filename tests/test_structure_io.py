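"""Parsing, radii and entry filters."""

import math

import numpy as np
import pytest

from ifacetess.fixtures import FixtureSpec, make_assembly
from ifacetess.structure_io import (
    Assembly, DEFAULT_RADII, DEFAULT_RADIUS, ParseError, FormatError,
    assign_radii, entry_passes_filters, parse_structure, residue_category,
    write_mmcif, write_pdb,
)

ALTLOC_PDB = """\
HEADER    TEST                                    01-JAN-20   1ABC
EXPDTA    X-RAY DIFFRACTION
REMARK   2 RESOLUTION.    2.00 ANGSTROMS.
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.40 10.00           C
ATOM      3  CA BALA A   1      11.700   6.100  -5.200  0.60 10.00           C
ATOM      4  CB AALA A   1      11.000   6.000  -5.000  0.50 10.00           C
ATOM      5  CB BALA A   1      11.100   6.100  -5.100  0.50 10.00           C
ATOM      6  C   ALA A   1      10.947   6.986  -4.129  1.00 10.00           C
ATOM      7  H   ALA A   1       0.000   0.000   0.000  1.00 10.00           H
ATOM      8  N   GLY A   2      10.000   7.000  -4.000  1.00 10.00           N
HETATM    9  O   HOH A 101       0.000   0.000   9.000  1.00 10.00           O
END
"""


@pytest.fixture()
def altloc_assembly(tmp_path):
    p = tmp_path / "1abc.pdb"
    p.write_text(ALTLOC_PDB)
    return parse_structure(p)


def test_empty_file_raises_parse_error(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("")
    with pytest.raises(ParseError, match="empty.pdb"):
        parse_structure(p)


def test_unknown_extension_raises_format_error(tmp_path):
    p = tmp_path / "thing.xyz"
    p.write_text("not a structure")
    with pytest.raises(FormatError):
        parse_structure(p)


def test_fixture_dimer_counts(tmp_path):
    assembly, _ = make_assembly(FixtureSpec("helix-dimer"))
    path = tmp_path / "hdim.pdb"
    write_pdb(assembly, path)
    parsed = parse_structure(path)
    assert len(parsed.chains) == 2
    assert sum(len(c.residues) for c in parsed.chains) == 60


def test_pdb_and_mmcif_render_identically(tmp_path):
    assembly, _ = make_assembly(FixtureSpec("peptide-complex"))
    write_pdb(assembly, tmp_path / "pepc.pdb")
    write_mmcif(assembly, tmp_path / "pepc.cif")
    a = parse_structure(tmp_path / "pepc.pdb")
    b = parse_structure(tmp_path / "pepc.cif")

    def census(asm: Assembly):
        return [(c.chain_id, [(r.auth_seq, r.name, len(r.atoms))
                              for r in c.residues]) for c in asm.chains]
    assert census(a) == census(b)
    assert a.method == b.method
    assert a.resolution == pytest.approx(b.resolution)


def test_round_trip_preserves_hierarchy(tmp_path):
    assembly, _ = make_assembly(FixtureSpec("dna-complex"))
    write_pdb(assembly, tmp_path / "dnac.pdb")
    once = parse_structure(tmp_path / "dnac.pdb")
    write_pdb(once, tmp_path / "dnac2.pdb")
    twice = parse_structure(tmp_path / "dnac2.pdb")
    for ca, cb in zip(once.chains, twice.chains):
        assert ca.chain_id == cb.chain_id
        assert [(r.auth_seq, r.icode, r.name, len(r.atoms))
                for r in ca.residues] == \
               [(r.auth_seq, r.icode, r.name, len(r.atoms))
                for r in cb.residues]


def test_hydrogens_dropped_and_waters_flagged(altloc_assembly):
    chain = altloc_assembly.chains[0]
    names = [a.name for a in chain.residues[0].atoms]
    assert "H" not in names
    water = [r for c in altloc_assembly.chains for r in c.residues
             if r.category == "water"]
    assert len(water) == 1 and water[0].name == "HOH"


def test_altloc_keeps_highest_occupancy_then_alphabetical(altloc_assembly):
    res = altloc_assembly.chains[0].residues[0]
    # no duplicate atom names survive
    names = [a.name for a in res.atoms]
    assert len(names) == len(set(names))
    ca = res.atom("CA")
    assert ca.altloc == "B" and ca.occupancy == pytest.approx(0.6)
    cb = res.atom("CB")   # occupancy tie 0.5/0.5 → first altloc code
    assert cb.altloc == "A"


def test_metadata_parsed(altloc_assembly):
    assert altloc_assembly.entry_id == "1ABC"
    assert altloc_assembly.method == "X-RAY DIFFRACTION"
    assert altloc_assembly.resolution == pytest.approx(2.0)


@pytest.mark.parametrize("name,expected", [
    ("ALA", "standard-aa"), ("MSE", "nonstandard-aa"),
    ("DA", "nucleotide"), ("U", "nucleotide"),
    ("HOH", "water"), ("HEM", "ligand"),
])
def test_residue_category(name, expected):
    assert residue_category(name) == expected


class TestRadii:
    def test_carbon_default(self, altloc_assembly):
        assign_radii(altloc_assembly)
        assert altloc_assembly.chains[0].residues[0].atom("CA").radius == \
            pytest.approx(1.70)

    def test_unknown_element_gets_default_with_warning(self, caplog):
        assembly, _ = make_assembly(FixtureSpec("two-ball"))
        assembly.chains[0].residues[0].atoms[0].element = "XX"
        with caplog.at_level("WARNING", logger="ifacetess"):
            assign_radii(assembly)
        assert assembly.chains[0].residues[0].atoms[0].radius == DEFAULT_RADIUS
        assert any("unknown element" in m for m in caplog.messages)

    def test_idempotent(self, altloc_assembly):
        assign_radii(altloc_assembly)
        first = [a.radius for _r, a in altloc_assembly.iter_atoms()]
        assign_radii(altloc_assembly)
        assert [a.radius for _r, a in altloc_assembly.iter_atoms()] == first
        assert all(r > 0 for r in first)


class TestEntryFilters:
    def _assembly(self, method, resolution):
        return Assembly(entry_id="XXXX", method=method, resolution=resolution,
                        chains=[])

    @pytest.mark.parametrize("method,resolution,expected", [
        ("X-RAY DIFFRACTION", 2.0, True),
        ("ELECTRON MICROSCOPY", 3.99, True),
        ("SOLUTION NMR", None, False),
        ("SOLUTION NMR", 2.0, False),
        ("X-RAY DIFFRACTION", 4.0, False),   # strictly better than 4 Å
        ("X-RAY DIFFRACTION", 4.5, False),
    ])
    def test_truth_table(self, method, resolution, expected):
        assert entry_passes_filters(self._assembly(method, resolution)) is expected

    def test_missing_resolution_rejected_by_default_but_overridable(self):
        asm = self._assembly("ELECTRON MICROSCOPY", None)
        assert entry_passes_filters(asm) is False
        assert entry_passes_filters(asm, accept_missing_resolution=True) is True
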