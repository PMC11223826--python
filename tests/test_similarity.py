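"""Contact-area-difference similarity measures."""

from dataclasses import dataclass, field

import pytest
from hypothesis import given, settings, strategies as st

from ifacetess.similarity import (
    ResidueCorrespondence, UndefinedSimilarityError,
    binding_site_residue_area_similarity, interface_contact_similarity,
    patch_area_similarity,
)


@dataclass
class FakeInterface:
    contacts: dict = field(default_factory=dict)


@dataclass
class FakeSite:
    residue_areas: dict = field(default_factory=dict)


def ident(n=100):
    return ResidueCorrespondence.identity(n)


class TestInterfaceContacts:
    def test_self_similarity_is_one(self):
        a = FakeInterface({(0, 0): 10.0, (1, 2): 20.0})
        s = interface_contact_similarity(a, a, ident(), ident())
        assert s.value == pytest.approx(1.0)
        assert s.measure == "interface-contacts"

    def test_hand_computed_asymmetric_example(self):
        # A={c1:10, c2:20}, B={c1:10, c2:10, c3:10}:
        # D(A→B)=1−10/30, D(B→A)=1−20/30 → mean 0.5
        a = FakeInterface({(0, 0): 10.0, (1, 1): 20.0})
        b = FakeInterface({(0, 0): 10.0, (1, 1): 10.0, (2, 2): 10.0})
        s = interface_contact_similarity(a, b, ident(), ident())
        assert s.value == pytest.approx(0.5)

    def test_disjoint_contact_sets_score_zero(self):
        a = FakeInterface({(0, 0): 10.0})
        b = FakeInterface({(5, 5): 10.0})
        s = interface_contact_similarity(a, b, ident(), ident())
        assert s.value == pytest.approx(0.0)

    def test_empty_contact_set_raises(self):
        a = FakeInterface({})
        b = FakeInterface({(0, 0): 1.0})
        with pytest.raises(UndefinedSimilarityError):
            interface_contact_similarity(a, b, ident(), ident())

    def test_swapped_side_pairing_is_found(self):
        a = FakeInterface({(0, 1): 10.0, (2, 3): 30.0})
        b = FakeInterface({(1, 0): 10.0, (3, 2): 30.0})   # sides exchanged
        direct = interface_contact_similarity(a, b, ident(), ident())
        assert direct.value < 1.0
        both = interface_contact_similarity(a, b, ident(), ident(),
                                            alt_pairing=(ident(), ident()))
        assert both.value == pytest.approx(1.0)

    def test_symmetry(self):
        a = FakeInterface({(0, 0): 10.0, (1, 1): 25.0})
        b = FakeInterface({(0, 0): 12.0, (2, 2): 5.0})
        ab = interface_contact_similarity(a, b, ident(), ident()).value
        ba = interface_contact_similarity(b, a, ident(), ident()).value
        assert ab == pytest.approx(ba)


class TestBindingSiteResidueAreas:
    def test_identity(self):
        a = FakeSite({0: 30.0, 1: 45.0})
        assert binding_site_residue_area_similarity(a, a, ident()).value == \
            pytest.approx(1.0)

    def test_hand_computed_unmatched_residue_example(self):
        # A={r1:30, r2:45}, B={r1:30}, r2 unmatched:
        # D(A→B)=1−45/75=0.4, D(B→A)=1 → 0.7
        a = FakeSite({0: 30.0, 1: 45.0})
        b = FakeSite({0: 30.0})
        corr = ResidueCorrespondence({0: 0})
        s = binding_site_residue_area_similarity(a, b, corr)
        assert s.value == pytest.approx(0.7)

    def test_scale_invariance(self):
        a = FakeSite({0: 30.0, 1: 45.0, 3: 2.0})
        b = FakeSite({0: 20.0, 1: 50.0})
        base = binding_site_residue_area_similarity(a, b, ident()).value
        a2 = FakeSite({k: 7.5 * v for k, v in a.residue_areas.items()})
        b2 = FakeSite({k: 7.5 * v for k, v in b.residue_areas.items()})
        scaled = binding_site_residue_area_similarity(a2, b2, ident()).value
        assert scaled == pytest.approx(base)

    def test_empty_site_raises(self):
        with pytest.raises(UndefinedSimilarityError):
            binding_site_residue_area_similarity(FakeSite(), FakeSite({0: 1.0}),
                                                 ident())

    @settings(derandomize=True, max_examples=50)
    @given(st.dictionaries(st.integers(0, 8),
                           st.floats(0.1, 100), min_size=1),
           st.dictionaries(st.integers(0, 8),
                           st.floats(0.1, 100), min_size=1))
    def test_range_and_symmetry_property(self, da, db):
        a, b = FakeSite(da), FakeSite(db)
        ab = binding_site_residue_area_similarity(a, b, ident()).value
        ba = binding_site_residue_area_similarity(b, a, ident()).value
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(ba)


class TestPatchAreas:
    def test_permuted_cross_pairings_keep_patch_similarity_one(self):
        # same per-residue marginals, different wiring across the interface
        a = FakeInterface({(0, 0): 10.0, (0, 1): 20.0,
                           (1, 0): 20.0, (1, 1): 10.0})
        b = FakeInterface({(0, 0): 20.0, (0, 1): 10.0,
                           (1, 0): 10.0, (1, 1): 20.0})
        contact = interface_contact_similarity(a, b, ident(), ident())
        patch = patch_area_similarity(a, b, ident(), ident())
        assert patch.value == pytest.approx(1.0)
        assert contact.value == pytest.approx(1.0 / 3.0)
        assert patch.measure == "interface-areas"

    def test_identity_and_disjoint(self):
        a = FakeInterface({(0, 0): 10.0, (1, 1): 20.0})
        assert patch_area_similarity(a, a, ident(), ident()).value == \
            pytest.approx(1.0)
        far = FakeInterface({(7, 7): 3.0})
        assert patch_area_similarity(a, far, ident(), ident()).value == \
            pytest.approx(0.0)

    def test_site_mode_scores_residue_areas(self):
        a = FakeSite({0: 30.0, 1: 45.0})
        b = FakeSite({0: 30.0})
        s = patch_area_similarity(a, b, ResidueCorrespondence({0: 0}),
                                  mode="site")
        assert s.value == pytest.approx(0.7)
        assert s.measure == "site-areas"

    def test_patch_equals_one_when_contacts_identical(self):
        a = FakeInterface({(0, 3): 12.0, (2, 1): 8.0})
        assert patch_area_similarity(a, a, ident(), ident()).value == \
            pytest.approx(1.0)


def test_correspondence_injectivity_enforced():
    with pytest.raises(ValueError):
        ResidueCorrespondence({0: 1, 2: 1})


def test_correspondence_inverse_roundtrip():
    corr = ResidueCorrespondence({0: 3, 1: 5, 9: 0})
    inv = corr.inverse()
    assert inv.pairs == {3: 0, 5: 1, 0: 9}
    assert inv.inverse().pairs == corr.pairs
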