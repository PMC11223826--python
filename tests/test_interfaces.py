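"""Interface extraction, filters, dedup, binding sites, bond annotation."""

import numpy as np
import pytest

from ifacetess.contacts import ResidueContactMap
from ifacetess.entities import Entity
from ifacetess.interfaces import (
    annotate_bonds, derive_binding_sites, extract_interfaces,
)
from ifacetess.structure_io import Assembly, Atom, Chain, Residue, residue_category


def _residue(chain_id, seq, name, atoms=()):
    res = Residue(chain_id=chain_id, auth_seq=seq, icode="", name=name,
                  category=residue_category(name))
    for i, (aname, el, xyz) in enumerate(atoms):
        res.atoms.append(Atom(serial=i + 1, name=aname, element=el,
                              coords=np.asarray(xyz, dtype=float)))
    return res


def _mini_complex(names_a=("ALA", "ALA"), names_b=("ALA", "ALA"),
                  atoms_a=None, atoms_b=None, kind_b="protein"):
    """Two-entity toy assembly; contact areas supplied separately."""
    res_a = [_residue("A", i + 1, n, (atoms_a or {}).get(i, ()))
             for i, n in enumerate(names_a)]
    res_b = [_residue("B", i + 1, n, (atoms_b or {}).get(i, ()))
             for i, n in enumerate(names_b)]
    assembly = Assembly(entry_id="MINI", method="X-RAY DIFFRACTION",
                        resolution=2.0,
                        chains=[Chain("A", res_a), Chain("B", res_b)])
    ent_a = Entity(entity_id="MINI:A", kind="protein", chain_ids=["A"],
                   residues=res_a, sequence="".join("A" for _ in names_a))
    ent_b = Entity(entity_id="MINI:B", kind=kind_b, chain_ids=["B"],
                   residues=res_b,
                   sequence="" if kind_b == "nucleic" else
                   "".join("A" for _ in names_b))
    return assembly, [ent_a, ent_b], res_a, res_b


def _rcmap(res_a, res_b, areas):
    rc = ResidueContactMap()
    for (i, j), area in areas.items():
        ka, kb = res_a[i].key, res_b[j].key
        if kb < ka:
            ka, kb = kb, ka
        rc.contacts[(ka, kb)] = area
    return rc


class TestAreaFilter:
    def test_interface_over_threshold_retained(self):
        assembly, ents, ra, rb = _mini_complex()
        rc = _rcmap(ra, rb, {(0, 0): 80.0, (1, 1): 20.5})
        assert len(extract_interfaces(assembly, ents, rc)) == 1

    def test_exactly_100_dropped(self):
        assembly, ents, ra, rb = _mini_complex()
        rc = _rcmap(ra, rb, {(0, 0): 60.0, (1, 1): 40.0})
        assert extract_interfaces(assembly, ents, rc) == []

    def test_filter_monotonicity(self):
        assembly, ents, ra, rb = _mini_complex()
        rc = _rcmap(ra, rb, {(0, 0): 120.0})
        low = extract_interfaces(assembly, ents, rc, min_area=50.0)
        high = extract_interfaces(assembly, ents, rc, min_area=150.0)
        assert len(low) >= len(high)
        assert len(high) == 0

    def test_total_area_is_sum_of_contacts(self):
        assembly, ents, ra, rb = _mini_complex()
        rc = _rcmap(ra, rb, {(0, 0): 80.0, (0, 1): 30.0, (1, 1): 20.0})
        iface = extract_interfaces(assembly, ents, rc)[0]
        assert iface.total_area == pytest.approx(130.0)
        assert len(iface.contacts) == 3


class TestDedup:
    def test_homotetramer_collapses_to_one_interface(self, tetramer_result):
        result, truth = tetramer_result
        assert len(result.interfaces) == truth["expected_unique_interfaces"]

    def test_dedup_is_idempotent(self, tetramer_result):
        result, _ = tetramer_result
        again = extract_interfaces(result.assembly, result.entities,
                                   result.rcmap)
        assert [f.interface_id for f in again] == \
            [f.interface_id for f in result.interfaces]

    def test_distinct_interfaces_not_collapsed(self, dual_mode_results):
        # different binding modes share sequences but differ in contacts
        r1, _ = dual_mode_results[1]
        r2, _ = dual_mode_results[2]
        assert len(r1.interfaces) == 1 and len(r2.interfaces) == 1


class TestBindingSites:
    def test_protein_peptide_projects_one_site(self):
        assembly, ents, ra, rb = _mini_complex(kind_b="peptide")
        rc = _rcmap(ra, rb, {(0, 0): 80.0, (1, 0): 45.0})
        iface = extract_interfaces(assembly, ents, rc)[0]
        sites = derive_binding_sites([iface])
        assert len(sites) == 1
        site = sites[0]
        assert site.partner_kind == "peptide"
        assert site.residue_areas == {0: pytest.approx(80.0),
                                      1: pytest.approx(45.0)}
        assert site.total_area == pytest.approx(125.0)

    def test_protein_protein_projects_two_sites(self, dimer_result):
        result, _ = dimer_result
        sites = derive_binding_sites(result.interfaces)
        assert len(sites) == 2
        iface = result.interfaces[0]
        for site in sites:
            assert site.total_area == pytest.approx(iface.total_area)

    def test_protein_nucleic_projects_protein_side_only(self, dna_result):
        result, _ = dna_result
        sites = result.binding_sites
        assert len(sites) == 1
        assert sites[0].partner_kind == "nucleic"
        assert sites[0].protein.kind == "protein"

    def test_area_bookkeeping_across_sites(self, peptide_result):
        result, _ = peptide_result
        iface = result.interfaces[0]
        for site in result.binding_sites:
            assert site.total_area == pytest.approx(iface.total_area)


class TestBonds:
    def _annotated(self, names_a, names_b, atoms_a, atoms_b):
        assembly, ents, ra, rb = _mini_complex(names_a, names_b,
                                               atoms_a, atoms_b)
        rc = _rcmap(ra, rb, {(0, 0): 150.0})
        iface = extract_interfaces(assembly, ents, rc)[0]
        return annotate_bonds(iface, assembly)

    def test_disulfide_at_canonical_bond_length(self):
        iface = self._annotated(
            ("CYS", "ALA"), ("CYS", "ALA"),
            {0: (("SG", "S", (0.0, 0.0, 0.0)), ("CB", "C", (-1.8, 0.0, 0.0)))},
            {0: (("SG", "S", (2.05, 0.0, 0.0)), ("CB", "C", (3.9, 0.0, 0.0)))})
        assert iface.n_disulfides == 1

    def test_salt_bridge_lys_glu(self):
        iface = self._annotated(
            ("LYS", "ALA"), ("GLU", "ALA"),
            {0: (("NZ", "N", (0.0, 0.0, 0.0)), ("CE", "C", (-1.5, 0.0, 0.0)))},
            {0: (("OE1", "O", (3.2, 0.0, 0.0)), ("CD", "C", (4.4, 0.0, 0.0)))})
        assert iface.n_saltbridges == 1
        # NZ→OE1 at 3.2 Å with a trans antecedent also counts as an H-bond
        assert iface.n_hbonds >= 1

    def test_apolar_contact_has_no_bonds(self):
        iface = self._annotated(
            ("ALA", "ALA"), ("ALA", "ALA"),
            {0: (("CB", "C", (0.0, 0.0, 0.0)),)},
            {0: (("CB", "C", (4.0, 0.0, 0.0)),)})
        assert (iface.n_hbonds, iface.n_saltbridges, iface.n_disulfides) \
            == (0, 0, 0)

    def test_distance_cutoffs_respected(self):
        iface = self._annotated(
            ("CYS", "ALA"), ("CYS", "ALA"),
            {0: (("SG", "S", (0.0, 0.0, 0.0)),)},
            {0: (("SG", "S", (2.6, 0.0, 0.0)),)})
        assert iface.n_disulfides == 0
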