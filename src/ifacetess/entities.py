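"""Chain typing and nucleic-duplex joining.

Every polymeric chain is typed as ``protein``, ``peptide`` or ``nucleic``.
Peptides are polypeptide chains with fewer than 20 structurally-resolved
residues, or fewer than 40 when more than half of the resolved residues
are non-standard amino acids.  Nucleic chains that base-pair into a
double-stranded helix are joined into a single nucleic entity, so that a
protein touching either strand of a duplex sees one interaction partner.

Duplex detection here is a purely geometric stand-in for a full
base-pairing annotation: two nucleotides on different chains are treated
as a Watson–Crick-geometry pair when their C1′–C1′ distance falls in
[9.0, 11.5] Å, their glycosidic nitrogens (N1/N9) are within 9.5 Å and
their nearest base-ring atoms are within 4.0 Å; a duplex requires at
least four consecutive such pairs running antiparallel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    Assembly, Chain, Residue, ResidueKey, STANDARD_AA, THREE_TO_ONE,
)

logger = logging.getLogger("ifacetess")

__all__ = [
    "Entity",
    "ClassificationError",
    "classify_chain",
    "detect_and_join_duplexes",
    "build_entities",
    "PEPTIDE_MAX_RESOLVED",
    "PEPTIDE_MAX_RESOLVED_NONSTD",
    "NONSTANDARD_FRACTION",
]

#: Polypeptides with fewer resolved residues than this are peptides.
PEPTIDE_MAX_RESOLVED = 20
#: ... or fewer than this when mostly non-standard.
PEPTIDE_MAX_RESOLVED_NONSTD = 40
NONSTANDARD_FRACTION = 0.5

_PURINES = {"A", "G", "DA", "DG"}
_BASE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")

# duplex stand-in geometry (Å)
C1_DISTANCE_RANGE = (9.0, 11.5)
GLYCOSIDIC_N_MAX = 9.5
BASE_ATOM_MAX = 4.0
MIN_CONSECUTIVE_PAIRS = 4


class ClassificationError(ValueError):
    """Raised for chains that carry no polymer (only ligands/waters)."""


@dataclass
class Entity:
    """A chain, or a joined group of duplex-forming nucleic chains."""

    entity_id: str
    kind: str                      # protein | peptide | nucleic
    chain_ids: list[str]
    residues: list[Residue] = field(default_factory=list)
    sequence: str = ""             # one-letter, protein/peptide only

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def position_of(self) -> dict[ResidueKey, int]:
        return {r.key: i for i, r in enumerate(self.residues)}


def _polymer_split(chain: Chain) -> tuple[list[Residue], list[Residue]]:
    aa = [r for r in chain.residues if r.category in ("standard-aa", "nonstandard-aa")]
    nuc = [r for r in chain.residues if r.category == "nucleotide"]
    return aa, nuc


def classify_chain(chain: Chain) -> str:
    """Type a polymeric chain as ``protein``, ``peptide`` or ``nucleic``."""
    aa, nuc = _polymer_split(chain)
    if len(aa) + len(nuc) < 2:
        raise ClassificationError(
            f"chain {chain.chain_id} is not polymeric (ligands/waters only)")
    if len(nuc) > len(aa):
        if aa:
            logger.info("chain %s is hybrid (%d aa, %d nt): classified nucleic",
                        chain.chain_id, len(aa), len(nuc))
        return "nucleic"
    if nuc:
        logger.info("chain %s is hybrid (%d aa, %d nt): classified polypeptide",
                    chain.chain_id, len(aa), len(nuc))
    resolved = [r for r in aa if r.is_resolved]
    n = len(resolved)
    if n < PEPTIDE_MAX_RESOLVED:
        return "peptide"
    nonstd = sum(1 for r in resolved if r.category == "nonstandard-aa")
    if n < PEPTIDE_MAX_RESOLVED_NONSTD and nonstd > NONSTANDARD_FRACTION * n:
        return "peptide"
    return "protein"


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence of the chain's amino-acid residues in author order.

    Non-standard residues translate to ``X``.
    """
    aa, _ = _polymer_split(chain)
    return "".join(THREE_TO_ONE.get(r.name, "X") for r in aa)


# ---------------------------------------------------------------------------
# Duplex detection
# ---------------------------------------------------------------------------

def _glycosidic_n(res: Residue):
    name = "N9" if res.name in _PURINES else "N1"
    a = res.atom(name)
    if a is None:  # fall back for modified bases
        a = res.atom("N9") or res.atom("N1")
    return a


def _is_wc_pair(ra: Residue, rb: Residue) -> bool:
    c1a, c1b = ra.atom("C1'"), rb.atom("C1'")
    if c1a is None or c1b is None:
        return False
    d = float(np.linalg.norm(c1a.coords - c1b.coords))
    if not (C1_DISTANCE_RANGE[0] <= d <= C1_DISTANCE_RANGE[1]):
        return False
    na, nb = _glycosidic_n(ra), _glycosidic_n(rb)
    if na is None or nb is None:
        return False
    if float(np.linalg.norm(na.coords - nb.coords)) > GLYCOSIDIC_N_MAX:
        return False
    base_a = [a.coords for a in ra.atoms if a.name in _BASE_RING_ATOMS]
    base_b = [a.coords for a in rb.atoms if a.name in _BASE_RING_ATOMS]
    if not base_a or not base_b:
        return False
    pa = np.asarray(base_a)[:, None, :]
    pb = np.asarray(base_b)[None, :, :]
    dmin = np.sqrt(((pa - pb) ** 2).sum(axis=2)).min()
    return bool(dmin <= BASE_ATOM_MAX)


def _chains_form_duplex(res_a: list[Residue], res_b: list[Residue]) -> bool:
    """≥4 consecutive antiparallel Watson–Crick-geometry pairs."""
    # quick bounding-box reject
    coords_a = [a.coords for r in res_a for a in r.atoms]
    coords_b = [a.coords for r in res_b for a in r.atoms]
    if not coords_a or not coords_b:
        return False
    ca, cb = np.mean(coords_a, axis=0), np.mean(coords_b, axis=0)
    span = max(len(res_a), len(res_b)) * 7.0 + 30.0
    if np.linalg.norm(ca - cb) > span:
        return False

    pairs = {(i, j)
             for i, ra in enumerate(res_a)
             for j, rb in enumerate(res_b)
             if _is_wc_pair(ra, rb)}
    if len(pairs) < MIN_CONSECUTIVE_PAIRS:
        return False
    for (i, j) in pairs:
        run = 1
        while (i + run, j - run) in pairs:
            run += 1
            if run >= MIN_CONSECUTIVE_PAIRS:
                return True
    return False


def detect_and_join_duplexes(assembly: Assembly,
                             kinds: dict[str, str]) -> list[Entity]:
    """Group nucleic chains into entities, joining duplex-forming strands.

    ``kinds`` maps chain_id → classification from :func:`classify_chain`.
    Joining is transitive through shared chains (union–find), so a chain
    paired with two others pulls all three into one entity.
    """
    nucleic = [c for c in assembly.chains if kinds.get(c.chain_id) == "nucleic"]
    parent = {c.chain_id: c.chain_id for c in nucleic}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, ca in enumerate(nucleic):
        for cb in nucleic[i + 1:]:
            ra = [r for r in ca.residues if r.category == "nucleotide"]
            rb = [r for r in cb.residues if r.category == "nucleotide"]
            if _chains_form_duplex(ra, rb):
                parent[find(ca.chain_id)] = find(cb.chain_id)

    groups: dict[str, list[Chain]] = {}
    for c in nucleic:
        groups.setdefault(find(c.chain_id), []).append(c)

    entities = []
    for members in groups.values():
        members.sort(key=lambda c: c.chain_id)
        chain_ids = [c.chain_id for c in members]
        residues = [r for c in members for r in c.residues
                    if r.category == "nucleotide"]
        entities.append(Entity(
            entity_id=f"{assembly.entry_id}:{'+'.join(chain_ids)}",
            kind="nucleic",
            chain_ids=chain_ids,
            residues=residues,
        ))
    entities.sort(key=lambda e: e.entity_id)
    return entities


def build_entities(assembly: Assembly) -> list[Entity]:
    """Classify all chains and return the full entity list for an assembly.

    Non-polymeric chains are excluded (logged).  Every polymeric chain
    appears in exactly one entity.
    """
    kinds: dict[str, str] = {}
    for chain in assembly.chains:
        try:
            kinds[chain.chain_id] = classify_chain(chain)
        except ClassificationError:
            logger.info("chain %s excluded from interaction typing "
                        "(non-polymeric)", chain.chain_id)
    entities: list[Entity] = []
    for chain in assembly.chains:
        kind = kinds.get(chain.chain_id)
        if kind in ("protein", "peptide"):
            aa, _ = _polymer_split(chain)
            entities.append(Entity(
                entity_id=f"{assembly.entry_id}:{chain.chain_id}",
                kind=kind,
                chain_ids=[chain.chain_id],
                residues=aa,
                sequence=chain_sequence(chain),
            ))
    entities.extend(detect_and_join_duplexes(assembly, kinds))
    entities.sort(key=lambda e: e.entity_id)
    return entities
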