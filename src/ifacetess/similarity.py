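"""Contact-area-difference similarity between interfaces and binding sites.

All measures follow the bounded contact-area-difference (CAD-score) form:
for a reference object X with areas {x_c} and a comparison object Y with
areas {y_c} read through a residue correspondence,

    D(X→Y) = 1 − Σ_c min(|x_c − y_c|, x_c) / Σ_c x_c

over X's contact set; contacts whose residues have no counterpart under
the correspondence count as fully different (y_c = 0).  The returned
similarity is the arithmetic mean of the two directions, which makes the
measure symmetric — a requirement for clustering — and keeps it in [0, 1]
with self-similarity exactly 1.  The measure is invariant under uniform
scaling of all areas.

Variants:

* ``interface-contacts`` — residue-pair contact areas of two interfaces;
  sensitive to how contacts are wired across the interface.
* ``site-residue-areas`` — per-residue areas of two binding sites.
* ``interface-areas`` / ``site-areas`` (patch variants) — residue-pair
  contacts are first marginalized to per-residue interface areas on each
  side, which tolerates rearrangement of residue–residue contacts across
  the interface while requiring the same surface patch.

For two interfaces the two side-pairings are ambiguous (e.g. homodimers);
both pairings are evaluated and the better one kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "ResidueCorrespondence",
    "SimilarityScore",
    "UndefinedSimilarityError",
    "interface_contact_similarity",
    "binding_site_residue_area_similarity",
    "patch_area_similarity",
]


class UndefinedSimilarityError(ValueError):
    """Similarity of an empty contact/residue set is undefined."""


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Partial injective map from residue positions of A to positions of B."""

    pairs: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self):
        vals = list(self.pairs.values())
        if len(set(vals)) != len(vals):
            raise ValueError("correspondence is not injective")

    def get(self, pos: int) -> Optional[int]:
        return self.pairs.get(pos)

    def inverse(self) -> "ResidueCorrespondence":
        return ResidueCorrespondence({v: k for k, v in self.pairs.items()})

    @staticmethod
    def identity(n: int) -> "ResidueCorrespondence":
        return ResidueCorrespondence({i: i for i in range(n)})


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    measure: str

    def __float__(self) -> float:
        return self.value


def _directional(ref: Mapping, other: Mapping, keymap) -> float:
    """1 − bounded-difference ratio with ``ref`` as the reference.

    ``keymap(key)`` translates a ref key into the other object's key
    space, or None for unmatched residues.
    """
    denom = sum(ref.values())
    if denom <= 0.0 or not ref:
        raise UndefinedSimilarityError("empty reference contact set")
    num = 0.0
    for key, x in ref.items():
        mapped = keymap(key)
        y = other.get(mapped, 0.0) if mapped is not None else 0.0
        num += min(abs(x - y), x)
    return 1.0 - num / denom


def _symmetric(areas_a: Mapping, areas_b: Mapping, fwd, rev) -> float:
    d_ab = _directional(areas_a, areas_b, fwd)
    d_ba = _directional(areas_b, areas_a, rev)
    return 0.5 * (d_ab + d_ba)


def _contact_keymap(corr_left: ResidueCorrespondence,
                    corr_right: ResidueCorrespondence):
    def fwd(key):
        pa, pb = key
        qa, qb = corr_left.get(pa), corr_right.get(pb)
        if qa is None or qb is None:
            return None
        return (qa, qb)
    return fwd


def _pair_score(contacts_a: Mapping, contacts_b: Mapping,
                corr_left: ResidueCorrespondence,
                corr_right: ResidueCorrespondence) -> float:
    fwd = _contact_keymap(corr_left, corr_right)
    rev = _contact_keymap(corr_left.inverse(), corr_right.inverse())
    return _symmetric(contacts_a, contacts_b, fwd, rev)


def interface_contact_similarity(
        A, B,
        corr_left: ResidueCorrespondence,
        corr_right: ResidueCorrespondence,
        alt_pairing: Optional[tuple[ResidueCorrespondence,
                                    ResidueCorrespondence]] = None,
) -> SimilarityScore:
    """Similarity of two interfaces' residue-pair contact areas.

    ``corr_left`` maps A's first side onto B's first side and
    ``corr_right`` the second sides.  ``alt_pairing``, when given, maps
    A's first side onto B's *second* side and vice versa (the swapped
    side-pairing); the better-scoring pairing is kept.
    """
    if not A.contacts or not B.contacts:
        raise UndefinedSimilarityError("interface with empty contact set")
    best = _pair_score(A.contacts, B.contacts, corr_left, corr_right)
    if alt_pairing is not None:
        swapped = {(pb, pa): a for (pa, pb), a in B.contacts.items()}
        alt = _pair_score(A.contacts, swapped, alt_pairing[0], alt_pairing[1])
        best = max(best, alt)
    return SimilarityScore(best, "interface-contacts")


def binding_site_residue_area_similarity(
        A, B, corr: ResidueCorrespondence) -> SimilarityScore:
    """Similarity of two binding sites' per-residue contact areas."""
    if not A.residue_areas or not B.residue_areas:
        raise UndefinedSimilarityError("empty binding site")
    val = _symmetric(A.residue_areas, B.residue_areas,
                     corr.get, corr.inverse().get)
    return SimilarityScore(val, "site-residue-areas")


def _marginalize(contacts: Mapping, side: int) -> dict:
    out: dict = {}
    for (pa, pb), area in contacts.items():
        key = pa if side == 0 else pb
        out[key] = out.get(key, 0.0) + area
    return out


def patch_area_similarity(
        A, B,
        corr_left: ResidueCorrespondence,
        corr_right: Optional[ResidueCorrespondence] = None,
        mode: str = "interface",
        alt_pairing: Optional[tuple[ResidueCorrespondence,
                                    ResidueCorrespondence]] = None,
) -> SimilarityScore:
    """Contact-rearrangement-tolerant (patch) similarity.

    ``mode='interface'``: marginalize residue-pair contacts to per-residue
    areas on each side, score each side with the bounded-difference form
    and average over the two sides.  ``mode='site'``: score the binding
    sites' residue-membership areas directly.
    """
    if mode == "site":
        val = binding_site_residue_area_similarity(A, B, corr_left).value
        return SimilarityScore(val, "site-areas")
    if mode != "interface":
        raise ValueError(f"unknown mode {mode!r}")
    if not A.contacts or not B.contacts:
        raise UndefinedSimilarityError("interface with empty contact set")
    if corr_right is None:
        raise ValueError("corr_right required for mode='interface'")

    def score(corrs, b_contacts):
        sides = []
        for side in (0, 1):
            ma = _marginalize(A.contacts, side)
            mb = _marginalize(b_contacts, side)
            corr = corrs[side]
            sides.append(_symmetric(ma, mb, corr.get, corr.inverse().get))
        return 0.5 * sum(sides)

    best = score((corr_left, corr_right), B.contacts)
    if alt_pairing is not None:
        swapped = {(pb, pa): a for (pa, pb), a in B.contacts.items()}
        best = max(best, score(alt_pairing, swapped))
    return SimilarityScore(best, "interface-areas")
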