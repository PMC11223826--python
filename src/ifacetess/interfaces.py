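"""Typed binary interfaces and binding sites, filters and bond annotation.

An interaction interface is the set of residue–residue contacts between
two entities; a binding site is the set of protein residues contacting a
partner entity, with per-residue contact areas.  Three interaction types
are kept: protein–protein (PP), protein–peptide (PPep) and
protein–nucleic acid (PNA).  Two filters mirror the database build:
interfaces must have total contact area strictly over 100 Å², and within
one entry near-identical duplicate interfaces (same entity-pair sequence
content, contact similarity ≥ 0.95 under position-identity
correspondence) are collapsed to the representative with the largest
area.

Inter-chain bonds are annotated with standard heavy-atom geometric
criteria: hydrogen bonds (donor–acceptor ≤ 3.5 Å with
antecedent–donor–acceptor angle ≥ 90°), salt bridges (Arg/Lys/His
side-chain N to Asp/Glu carboxylate O ≤ 4.0 Å) and disulfides
(Cys SG–SG ≤ 2.5 Å).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .contacts import ResidueContactMap
from .entities import Entity
from .structure_io import Assembly, Residue, ResidueKey
from .similarity import (
    ResidueCorrespondence, UndefinedSimilarityError,
    interface_contact_similarity,
)

logger = logging.getLogger("ifacetess")

__all__ = [
    "Interface",
    "BindingSite",
    "ITYPE_CODES",
    "extract_interfaces",
    "derive_binding_sites",
    "annotate_bonds",
    "MIN_INTERFACE_AREA",
    "DEDUP_SIMILARITY",
]

#: Interfaces with total area not exceeding this (Å²) are discarded.
MIN_INTERFACE_AREA = 100.0
#: Within-entry duplicate collapse threshold (contact similarity).
DEDUP_SIMILARITY = 0.95

ITYPE_CODES = {
    "protein-protein": "PP",
    "protein-peptide": "PPep",
    "protein-nucleic": "PNA",
}


@dataclass
class Interface:
    entry_id: str
    assembly_id: str
    entity_a: Entity
    entity_b: Entity
    itype: str                       # protein-protein | protein-peptide | protein-nucleic
    contacts: dict = field(default_factory=dict)   # (pos_a, pos_b) -> area
    n_hbonds: int = 0
    n_saltbridges: int = 0
    n_disulfides: int = 0

    @property
    def total_area(self) -> float:
        return float(sum(self.contacts.values()))

    @property
    def interface_id(self) -> str:
        ca = "+".join(self.entity_a.chain_ids)
        cb = "+".join(self.entity_b.chain_ids)
        return (f"{self.entry_id}/{self.assembly_id}:{ca}-{cb}:"
                f"{ITYPE_CODES[self.itype]}")

    def residue_pairs(self):
        """Contacts in author numbering: (ResidueKey, ResidueKey, area)."""
        ka = self.entity_a.residue_keys
        kb = self.entity_b.residue_keys
        for (pa, pb), area in sorted(self.contacts.items()):
            yield ka[pa], kb[pb], area


@dataclass
class BindingSite:
    protein: Entity
    partner: Entity
    partner_kind: str                # protein | peptide | nucleic
    residue_areas: dict = field(default_factory=dict)   # pos -> area
    source_interface: Optional[Interface] = None

    @property
    def total_area(self) -> float:
        return float(sum(self.residue_areas.values()))

    @property
    def site_id(self) -> str:
        src = self.source_interface.interface_id if self.source_interface else "?"
        return f"{src}|{'+'.join(self.protein.chain_ids)}"

    def residues(self):
        keys = self.protein.residue_keys
        for pos, area in sorted(self.residue_areas.items()):
            yield keys[pos], area


_KIND_RANK = {"protein": 0, "peptide": 1, "nucleic": 2}


def _itype(kind_a: str, kind_b: str) -> Optional[str]:
    pair = tuple(sorted((kind_a, kind_b), key=_KIND_RANK.get))
    return {
        ("protein", "protein"): "protein-protein",
        ("protein", "peptide"): "protein-peptide",
        ("protein", "nucleic"): "protein-nucleic",
    }.get(pair)


def extract_interfaces(assembly: Assembly,
                       entities: Sequence[Entity],
                       rcmap: ResidueContactMap,
                       min_area: float = MIN_INTERFACE_AREA,
                       dedup_similarity: float = DEDUP_SIMILARITY,
                       ) -> list[Interface]:
    """Build, filter and de-duplicate the typed interfaces of one assembly.

    Entity pairs without protein involvement (peptide–peptide,
    peptide–nucleic, nucleic–nucleic) are computed but excluded from the
    output; the area filter is strict (``total_area > min_area``).
    """
    owner: dict[ResidueKey, tuple[int, int]] = {}
    for ei, ent in enumerate(entities):
        for pos, key in enumerate(ent.residue_keys):
            owner[key] = (ei, pos)

    raw: dict[tuple[int, int], dict] = {}
    for (ka, kb), area in rcmap.contacts.items():
        oa, ob = owner.get(ka), owner.get(kb)
        if oa is None or ob is None or oa[0] == ob[0]:
            continue
        (ea, pa), (eb, pb) = oa, ob
        if ea > eb:
            ea, eb, pa, pb = eb, ea, pb, pa
        raw.setdefault((ea, eb), {})
        raw[(ea, eb)][(pa, pb)] = raw[(ea, eb)].get((pa, pb), 0.0) + area

    interfaces: list[Interface] = []
    for (ea, eb), contacts in sorted(raw.items()):
        ent_a, ent_b = entities[ea], entities[eb]
        itype = _itype(ent_a.kind, ent_b.kind)
        if itype is None:
            logger.debug("skipping %s-%s contact (%s/%s): type out of scope",
                         ent_a.entity_id, ent_b.entity_id, ent_a.kind, ent_b.kind)
            continue
        # protein side first
        if _KIND_RANK[ent_b.kind] < _KIND_RANK[ent_a.kind]:
            ent_a, ent_b = ent_b, ent_a
            contacts = {(pb, pa): a for (pa, pb), a in contacts.items()}
        iface = Interface(entry_id=assembly.entry_id,
                          assembly_id=assembly.assembly_id,
                          entity_a=ent_a, entity_b=ent_b,
                          itype=itype, contacts=contacts)
        if iface.total_area > min_area:
            interfaces.append(iface)

    return _dedup(interfaces, dedup_similarity)


def _ent_sig_one(e: Entity) -> str:
    if e.kind == "nucleic":
        return "nuc:" + ",".join(r.name for r in e.residues)
    return f"{e.kind}:{e.sequence}"


def _dedup_score(a: Interface, ref: Interface) -> Optional[float]:
    """Contact similarity under position-identity correspondences.

    Evaluates whichever side-pairings are compatible with the two
    interfaces' sequence content (direct and/or swapped) and returns the
    best, or None when the entity pairs differ in sequence content.
    """
    corr_l = ResidueCorrespondence.identity(len(a.entity_a.residues))
    corr_r = ResidueCorrespondence.identity(len(a.entity_b.residues))
    scores = []
    if (_ent_sig_one(a.entity_a) == _ent_sig_one(ref.entity_a)
            and _ent_sig_one(a.entity_b) == _ent_sig_one(ref.entity_b)):
        scores.append(interface_contact_similarity(a, ref, corr_l, corr_r).value)
    if (_ent_sig_one(a.entity_a) == _ent_sig_one(ref.entity_b)
            and _ent_sig_one(a.entity_b) == _ent_sig_one(ref.entity_a)):
        swapped = Interface(
            entry_id=ref.entry_id, assembly_id=ref.assembly_id,
            entity_a=ref.entity_b, entity_b=ref.entity_a, itype=ref.itype,
            contacts={(pb, pa): ar for (pa, pb), ar in ref.contacts.items()})
        scores.append(interface_contact_similarity(a, swapped, corr_l, corr_r).value)
    return max(scores) if scores else None


def _dedup(interfaces: list[Interface], threshold: float) -> list[Interface]:
    """Collapse near-identical interfaces of one entry (idempotent greedy).

    Interfaces are visited largest-first (ties by lexicographic chain
    ids); an interface is dropped when a kept interface with the same
    sequence content matches it at contact similarity ≥ threshold.
    """
    def sort_key(i: Interface):
        # areas compared at output precision so exact copies tie cleanly
        return (-round(i.total_area, 2),
                tuple(i.entity_a.chain_ids), tuple(i.entity_b.chain_ids))

    kept: list[Interface] = []
    for iface in sorted(interfaces, key=sort_key):
        duplicate = False
        for ref in kept:
            try:
                score = _dedup_score(iface, ref)
            except UndefinedSimilarityError:
                continue
            if score is not None and score >= threshold:
                duplicate = True
                break
        if not duplicate:
            kept.append(iface)
    kept.sort(key=lambda i: i.interface_id)
    return kept


def derive_binding_sites(interfaces: Sequence[Interface]) -> list[BindingSite]:
    """Project each interface onto its protein side(s).

    A protein–protein interface yields two binding sites; protein–peptide
    and protein–nucleic interfaces yield one (the protein side).
    """
    sites: list[BindingSite] = []
    for iface in interfaces:
        for side, (ent, partner) in enumerate(
                ((iface.entity_a, iface.entity_b),
                 (iface.entity_b, iface.entity_a))):
            if ent.kind != "protein":
                continue
            areas: dict[int, float] = {}
            for (pa, pb), area in iface.contacts.items():
                pos = pa if side == 0 else pb
                areas[pos] = areas.get(pos, 0.0) + area
            sites.append(BindingSite(protein=ent, partner=partner,
                                     partner_kind=partner.kind,
                                     residue_areas=areas,
                                     source_interface=iface))
    return sites


# ---------------------------------------------------------------------------
# Bond annotation
# ---------------------------------------------------------------------------

HBOND_MAX = 3.5
HBOND_MIN_ANGLE = 90.0
SALTBRIDGE_MAX = 4.0
DISULFIDE_MAX = 2.5

# donor atom -> antecedent atom, per residue name ("*" = any amino acid)
_DONORS = {
    "*": {"N": "CA"},
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"}, "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "TRP": {"NE1": "CD1"}, "CYS": {},
    # nucleic bases
    "DA": {"N6": "C6"}, "A": {"N6": "C6"},
    "DG": {"N1": "C2", "N2": "C2"}, "G": {"N1": "C2", "N2": "C2"},
    "DC": {"N4": "C4"}, "C": {"N4": "C4"},
    "DT": {"N3": "C2"}, "T": {"N3": "C2"}, "U": {"N3": "C2"},
}

_ACCEPTORS = {
    "*": {"O"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
    "DA": {"N1", "N3", "N7"}, "A": {"N1", "N3", "N7"},
    "DG": {"O6", "N3", "N7"}, "G": {"O6", "N3", "N7"},
    "DC": {"O2", "N3"}, "C": {"O2", "N3"},
    "DT": {"O2", "O4"}, "T": {"O2", "O4"}, "U": {"O2", "O4"},
}

_NUCLEIC_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O1P", "O2P",
                               "O3'", "O5'", "O4'", "O2'"}

_BASIC_N = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_ACIDIC_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


def _donors_of(res: Residue):
    out = []
    table = dict(_DONORS.get("*", {})) if res.category in (
        "standard-aa", "nonstandard-aa") else {}
    table.update(_DONORS.get(res.name, {}))
    for dname, aname in table.items():
        d = res.atom(dname)
        if d is None:
            continue
        ante = res.atom(aname)
        out.append((d, ante))
    return out


def _acceptors_of(res: Residue):
    names = set()
    if res.category in ("standard-aa", "nonstandard-aa"):
        names |= _ACCEPTORS.get("*", set())
    if res.category == "nucleotide":
        names |= _NUCLEIC_BACKBONE_ACCEPTORS
        names |= {"O3'", "O5'"}
    names |= _ACCEPTORS.get(res.name, set())
    return [a for a in res.atoms if a.name in names]


def _angle(p_ante, p_donor, p_acc) -> float:
    v1 = p_ante - p_donor
    v2 = p_acc - p_donor
    c = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def annotate_bonds(interface: Interface, assembly: Assembly) -> Interface:
    """Count inter-entity hydrogen bonds, salt bridges and disulfides.

    Restricted to residues appearing in the interface's contact set; the
    interface is modified in place and returned.
    """
    res_by_key = {r.key: r for r in assembly.iter_residues()}
    keys_a = {interface.entity_a.residue_keys[pa]
              for (pa, _pb) in interface.contacts}
    keys_b = {interface.entity_b.residue_keys[pb]
              for (_pa, pb) in interface.contacts}
    res_a = [res_by_key[k] for k in sorted(keys_a) if k in res_by_key]
    res_b = [res_by_key[k] for k in sorted(keys_b) if k in res_by_key]

    n_h = n_s = n_d = 0
    for ra in res_a:
        for rb in res_b:
            n_h += _count_hbonds(ra, rb) + _count_hbonds(rb, ra)
            n_s += _count_saltbridges(ra, rb)
            n_d += _count_disulfides(ra, rb)
    interface.n_hbonds = n_h
    interface.n_saltbridges = n_s
    interface.n_disulfides = n_d
    return interface


def _count_hbonds(donor_res: Residue, acceptor_res: Residue) -> int:
    n = 0
    for donor, ante in _donors_of(donor_res):
        for acc in _acceptors_of(acceptor_res):
            d = float(np.linalg.norm(donor.coords - acc.coords))
            if d > HBOND_MAX:
                continue
            if ante is not None and _angle(ante.coords, donor.coords,
                                           acc.coords) < HBOND_MIN_ANGLE:
                continue
            n += 1
    return n


def _count_saltbridges(ra: Residue, rb: Residue) -> int:
    n = 0
    for basic, acidic in ((ra, rb), (rb, ra)):
        for nn in _BASIC_N.get(basic.name, ()):  # noqa: B007
            na = basic.atom(nn)
            if na is None:
                continue
            for on in _ACIDIC_O.get(acidic.name, ()):
                oa = acidic.atom(on)
                if oa is None:
                    continue
                if float(np.linalg.norm(na.coords - oa.coords)) <= SALTBRIDGE_MAX:
                    n += 1
    return n


def _count_disulfides(ra: Residue, rb: Residue) -> int:
    if ra.name != "CYS" or rb.name != "CYS":
        return 0
    sa, sb = ra.atom("SG"), rb.atom("SG")
    if sa is None or sb is None:
        return 0
    return int(float(np.linalg.norm(sa.coords - sb.coords)) <= DISULFIDE_MAX)
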