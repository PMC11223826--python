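"""Synthetic toy assemblies with machine-readable ground truth.

Every stage of the pipeline is testable without downloads: this module
builds idealized structures — paired α-helices, an extended peptide lying
along a helix, a B-form DNA duplex clamped by a helix, dual-binding-mode
pairs and sequence mutants — writes them as standard PDB files and
records the intended truths (chain classifications, expected duplex
joins, expected interfaces and binding-mode labels) in a JSON sidecar.

Geometry is built from ideal secondary-structure parameters (α-helix
rise 1.5 Å / twist 100° per residue; B-DNA rise 3.4 Å / twist 36° per
base pair) with simplified residues: full backbone, a CB pointing away
from the helix axis and, for designated residues, radially extended
side-chain probe atoms.  The models are deliberately not physically
realistic; they are engineered so that classification rules, the duplex
detector and the contact engine have unambiguous expected outcomes.
Generation is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import (
    Assembly, Atom, Chain, Residue, residue_category, write_pdb,
)

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "make_assembly",
    "make_mutant_series",
    "write_fixture_set",
    "DEFAULT_PROTEIN_SEQ",
]

DEFAULT_PROTEIN_SEQ = "AEKLSTVDRQANHMFWYEIVKLSDRTQEAL"   # 30 aa
DEFAULT_PEPTIDE_SEQ = "KLSEDRTVAQNF"                     # 12 aa
DEFAULT_DNA_SEQ = "ATGCATGCATGC"                         # 12 nt

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class FixtureError(ValueError):
    """Inconsistent fixture specification."""


@dataclass
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------

def _atom(serial, name, element, xyz, radius=0.0):
    return Atom(serial=serial, name=name, element=element,
                coords=np.asarray(xyz, dtype=float), radius=radius)


class _Serial:
    def __init__(self):
        self.n = 0

    def __call__(self):
        self.n += 1
        return self.n


def _helix_chain(chain_id: str, sequence: str, serial: _Serial,
                 rotation: np.ndarray | None = None,
                 translation=(0.0, 0.0, 0.0)) -> Chain:
    """Ideal α-helix along +z (CA radius 2.3 Å, rise 1.5 Å, twist 100°)."""
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    trans = np.asarray(translation, float)

    def place(v):
        return rot @ np.asarray(v, float) + trans

    chain = Chain(chain_id=chain_id)
    for i, letter in enumerate(sequence):
        name = ONE_TO_THREE.get(letter.upper())
        if name is None:
            raise FixtureError(f"unknown residue letter {letter!r}")
        th = math.radians(100.0 * i)
        rhat = np.array([math.cos(th), math.sin(th), 0.0])
        that = np.array([-math.sin(th), math.cos(th), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        ca = 2.3 * rhat + np.array([0.0, 0.0, 1.5 * i])
        res = Residue(chain_id=chain_id, auth_seq=i + 1, icode="",
                      name=name, category=residue_category(name))
        res.atoms.append(_atom(serial(), "N", "N",
                               place(ca - 1.0 * that - 0.9 * zhat + 0.2 * rhat)))
        res.atoms.append(_atom(serial(), "CA", "C", place(ca)))
        c = ca + 1.0 * that + 0.9 * zhat + 0.2 * rhat
        res.atoms.append(_atom(serial(), "C", "C", place(c)))
        res.atoms.append(_atom(serial(), "O", "O",
                               place(c - 1.0 * rhat + 0.6 * zhat)))
        if name != "GLY":
            res.atoms.append(_atom(serial(), "CB", "C", place(ca + 1.53 * rhat)))
        for aname, el, dist in _SIDECHAIN_PROBES.get(name, ()):
            res.atoms.append(_atom(serial(), aname, el,
                                   place(ca + dist * rhat)))
        chain.residues.append(res)
    return chain


# Side-chain probe atoms: radially extended tips used by the bond
# annotation (distance from CA along the outward radial direction, Å).
_SIDECHAIN_PROBES = {
    "CYS": (("SG", "S", 2.8),),
    "LYS": (("NZ", "N", 5.2),),
    "ARG": (("NE", "N", 4.5), ("NH1", "N", 5.8), ("CZ", "C", 5.3)),
    "GLU": (("CD", "C", 3.6), ("OE1", "O", 4.6), ("OE2", "O", 4.4)),
    "ASP": (("CG", "C", 2.6), ("OD1", "O", 3.6), ("OD2", "O", 3.4)),
    "SER": (("OG", "O", 2.6),),
    "THR": (("OG1", "O", 2.6),),
    "GLN": (("CD", "C", 3.6), ("NE2", "N", 4.6), ("OE1", "O", 4.4)),
    "ASN": (("CG", "C", 2.6), ("ND2", "N", 3.6), ("OD1", "O", 3.4)),
    "HIS": (("CG", "C", 2.6), ("ND1", "N", 3.4), ("NE2", "N", 4.2)),
    "TYR": (("CZ", "C", 4.2), ("OH", "O", 5.4)),
}


def _extended_chain(chain_id: str, sequence: str, serial: _Serial,
                    translation=(0.0, 0.0, 0.0),
                    cb_direction=(1.0, 0.0, 0.0)) -> Chain:
    """Extended (β-strand-like) polypeptide along +z, 3.5 Å per residue."""
    trans = np.asarray(translation, float)
    cbdir = np.asarray(cb_direction, float)
    cbdir = cbdir / np.linalg.norm(cbdir)
    chain = Chain(chain_id=chain_id)
    for i, letter in enumerate(sequence):
        name = ONE_TO_THREE.get(letter.upper())
        if name is None:
            raise FixtureError(f"unknown residue letter {letter!r}")
        y = 0.4 * (-1.0) ** i
        ca = np.array([0.0, y, 3.5 * i]) + trans
        res = Residue(chain_id=chain_id, auth_seq=i + 1, icode="",
                      name=name, category=residue_category(name))
        res.atoms.append(_atom(serial(), "N", "N", ca + [0.0, -0.3, -1.3]))
        res.atoms.append(_atom(serial(), "CA", "C", ca))
        res.atoms.append(_atom(serial(), "C", "C", ca + [0.0, 0.3, 1.3]))
        res.atoms.append(_atom(serial(), "O", "O", ca + [0.0, 1.4, 1.5]))
        if name != "GLY":
            res.atoms.append(_atom(serial(), "CB", "C", ca + 1.53 * cbdir))
        chain.residues.append(res)
    return chain


# radius (Å from duplex axis) of each synthetic nucleotide atom
_NT_BACKBONE = (("P", "P", 8.9), ("O5'", "O", 8.0), ("C5'", "C", 7.4),
                ("C4'", "C", 6.8), ("O4'", "O", 5.9), ("C3'", "C", 7.0),
                ("O3'", "O", 7.8), ("C2'", "C", 6.0), ("C1'", "C", 5.25))
_PURINE_BASE = (("N9", "N", 4.2), ("C8", "C", 3.9), ("N7", "N", 2.9),
                ("C5", "C", 3.0), ("C4", "C", 3.3), ("N3", "N", 2.7),
                ("C2", "C", 2.0), ("N1", "N", 1.5), ("C6", "C", 2.2))
_PYRIMIDINE_BASE = (("N1", "N", 4.2), ("C2", "C", 3.4), ("O2", "O", 3.5),
                    ("N3", "N", 2.4), ("C4", "C", 1.5), ("C5", "C", 2.2),
                    ("C6", "C", 3.2))


def _dna_duplex(chain_id_a: str, chain_id_b: str, sequence: str,
                serial: _Serial, translation=(0.0, 0.0, 0.0),
                rise: float = 3.4, twist_deg: float = 36.0) -> tuple[Chain, Chain]:
    """Idealized antiparallel B-form duplex along +z."""
    trans = np.asarray(translation, float)
    n = len(sequence)

    def nucleotide(chain_id, auth_seq, base, theta, z):
        name = "D" + base
        res = Residue(chain_id=chain_id, auth_seq=auth_seq, icode="",
                      name=name, category=residue_category(name))
        atoms = _NT_BACKBONE + (_PURINE_BASE if base in "AG" else _PYRIMIDINE_BASE)
        for aname, el, radius in atoms:
            pos = np.array([radius * math.cos(theta),
                            radius * math.sin(theta), z]) + trans
            res.atoms.append(_atom(serial(), aname, el, pos))
        return res

    ca = Chain(chain_id=chain_id_a)
    for i, base in enumerate(sequence):
        ca.residues.append(nucleotide(chain_id_a, i + 1, base,
                                      math.radians(twist_deg * i), rise * i))
    cb = Chain(chain_id=chain_id_b)
    comp = "".join(_DNA_COMPLEMENT[b] for b in reversed(sequence))
    for j, base in enumerate(comp):
        i = n - 1 - j   # paired residue on the first strand
        cb.residues.append(nucleotide(chain_id_b, j + 1, base,
                                      math.radians(twist_deg * i) + math.pi,
                                      rise * i))
    return ca, cb


def _rot_y(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), 0.0, math.sin(a)],
                     [0.0, 1.0, 0.0],
                     [-math.sin(a), 0.0, math.cos(a)]])


# ---------------------------------------------------------------------------
# Assemblies
# ---------------------------------------------------------------------------

def _assembly(entry_id: str, chains, resolution=2.0,
              method="X-RAY DIFFRACTION") -> Assembly:
    return Assembly(entry_id=entry_id, assembly_id="1", method=method,
                    resolution=resolution, chains=list(chains))


def make_assembly(spec: FixtureSpec) -> tuple[Assembly, dict]:
    """Build a fixture assembly plus its ground-truth record."""
    builders = {
        "two-ball": _make_two_ball,
        "helix-dimer": _make_helix_dimer,
        "homotetramer": _make_homotetramer,
        "peptide-complex": _make_peptide_complex,
        "dna-complex": _make_dna_complex,
        "dual-mode-pair": _make_dual_mode,
    }
    if spec.kind not in builders:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}")
    return builders[spec.kind](spec)


def _make_two_ball(spec: FixtureSpec):
    d = float(spec.params.get("distance", 3.0))
    r = float(spec.params.get("radius", 1.9))
    if d <= 0:
        raise FixtureError("distance must be positive")
    chains = []
    serial = _Serial()
    for cid, x in (("A", 0.0), ("B", d)):
        res = Residue(chain_id=cid, auth_seq=1, icode="", name="ALA",
                      category="standard-aa")
        res.atoms.append(_atom(serial(), "CA", "C", (x, 0.0, 0.0), radius=r))
        chains.append(Chain(chain_id=cid, residues=[res]))
    probe = 1.4
    rp = r + probe
    disk2 = rp * rp - (d / 2.0) ** 2
    truth = {
        "kind": "two-ball",
        "expected_contact_area": math.pi * disk2 if disk2 > 0 else 0.0,
        "expected_single_solvent_area": 4.0 * math.pi * rp * rp,
    }
    return _assembly(spec.params.get("entry_id", "2BAL"), chains), truth


def _dimer_chains(seq_a: str, seq_b: str, serial: _Serial,
                  axis_offset=(8.6, 0.0, 0.75), flip_b: bool = False,
                  z_shift_b: float = 0.0):
    ca = _helix_chain("A", seq_a, serial)
    rot = _rot_y(180.0) if flip_b else None
    off = np.asarray(axis_offset, float) + [0.0, 0.0, z_shift_b]
    if flip_b:
        # keep the flipped helix spanning the same z range
        off = off + [0.0, 0.0, 1.5 * (len(seq_b) - 1)]
    cb = _helix_chain("B", seq_b, serial, rotation=rot, translation=off)
    return ca, cb


def _make_helix_dimer(spec: FixtureSpec):
    seq = spec.params.get("sequence", DEFAULT_PROTEIN_SEQ)
    seq_b = spec.params.get("sequence_b", seq)
    entry = spec.params.get("entry_id", "HDIM")
    ca, cb = _dimer_chains(seq, seq_b, _Serial())
    truth = {
        "kind": "helix-dimer",
        "chain_kinds": {"A": "protein", "B": "protein"},
        "expected_interfaces": [{"itype": "protein-protein",
                                 "chains": ["A", "B"], "min_area": 100.0}],
    }
    return _assembly(entry, [ca, cb]), truth


def _make_homotetramer(spec: FixtureSpec):
    seq = spec.params.get("sequence", DEFAULT_PROTEIN_SEQ)
    entry = spec.params.get("entry_id", "TET4")
    serial = _Serial()
    ca, cb = _dimer_chains(seq, seq, serial)
    cc = _helix_chain("C", seq, serial, translation=(60.0, 0.0, 0.0))
    cd = _helix_chain("D", seq, serial, translation=(68.6, 0.0, 0.75))
    truth = {
        "kind": "homotetramer",
        "chain_kinds": {c: "protein" for c in "ABCD"},
        "expected_unique_interfaces": 1,
    }
    return _assembly(entry, [ca, cb, cc, cd]), truth


def _make_peptide_complex(spec: FixtureSpec):
    seq = spec.params.get("sequence", DEFAULT_PROTEIN_SEQ)
    pep = spec.params.get("peptide", DEFAULT_PEPTIDE_SEQ)
    entry = spec.params.get("entry_id", "PEPC")
    serial = _Serial()
    ca = _helix_chain("A", seq, serial)
    cb = _extended_chain("B", pep, serial, translation=(7.8, 0.0, 1.0),
                         cb_direction=(-1.0, 0.0, 0.0))
    truth = {
        "kind": "peptide-complex",
        "chain_kinds": {"A": "protein", "B": "peptide"},
        "expected_interfaces": [{"itype": "protein-peptide",
                                 "chains": ["A", "B"], "min_area": 100.0}],
    }
    return _assembly(entry, [ca, cb]), truth


def _make_dna_complex(spec: FixtureSpec):
    seq = spec.params.get("sequence", DEFAULT_PROTEIN_SEQ)
    dna = spec.params.get("dna", DEFAULT_DNA_SEQ).upper()
    entry = spec.params.get("entry_id", "DNAC")
    if any(b not in "ACGT" for b in dna):
        raise FixtureError("dna sequence must be over ACGT")
    serial = _Serial()
    cb, cc = _dna_duplex("B", "C", dna, serial)
    # protein helix alongside the duplex, axes parallel
    ca = _helix_chain("A", seq, serial, translation=(13.8, 0.0, 0.0))
    truth = {
        "kind": "dna-complex",
        "chain_kinds": {"A": "protein", "B": "nucleic", "C": "nucleic"},
        "expected_duplex_join": [["B", "C"]],
        "expected_interfaces": [{"itype": "protein-nucleic",
                                 "chains": ["A", "B+C"], "min_area": 100.0}],
    }
    return _assembly(entry, [ca, cb, cc]), truth


def _make_dual_mode(spec: FixtureSpec):
    """Same sequence pair bound in one of two distinct modes.

    Mode 1: partner helix B alongside the N-terminal half of A.
    Mode 2: B flipped by 180° and shifted to the C-terminal half of A —
    a different surface patch with differently wired contacts.
    """
    mode = int(spec.params.get("mode", 1))
    if mode not in (1, 2):
        raise FixtureError("mode must be 1 or 2")
    seq_a = spec.params.get("sequence", DEFAULT_PROTEIN_SEQ)
    seq_b = spec.params.get("sequence_b", "LKRSTADEQVNHFYWMGIEV")   # 20 aa
    entry = spec.params.get("entry_id", f"DM0{mode}")
    serial = _Serial()
    ca = _helix_chain("A", seq_a, serial)
    if mode == 1:
        cb = _helix_chain("B", seq_b, serial, translation=(8.6, 0.0, 0.0))
    else:
        z_hi = 1.5 * (len(seq_a) - len(seq_b))
        cb = _helix_chain("B", seq_b, serial, rotation=_rot_y(180.0),
                          translation=(8.6, 0.0,
                                       z_hi + 1.5 * (len(seq_b) - 1)))
    truth = {
        "kind": "dual-mode-pair",
        "mode": mode,
        "chain_kinds": {"A": "protein", "B": "protein"},
        "expected_interfaces": [{"itype": "protein-protein",
                                 "chains": ["A", "B"], "min_area": 100.0}],
        "expect_distinct_from_other_mode": True,
    }
    return _assembly(entry, [ca, cb]), truth


# ---------------------------------------------------------------------------
# Mutant sequences
# ---------------------------------------------------------------------------

def make_mutant_series(base: str, identities, seed: int = 0) -> list[str]:
    """Sequences differing from ``base`` at uniformly chosen positions.

    Each output hits the requested identity fraction to within one
    residue (``m = round((1 − f)·L)`` substituted positions).
    """
    rng = np.random.default_rng(seed)
    letters = sorted(ONE_TO_THREE)
    out = []
    L = len(base)
    for f in identities:
        if not (0.0 < f <= 1.0):
            raise FixtureError(f"identity {f} outside (0, 1]")
        m = round((1.0 - f) * L)
        if m > L:
            raise FixtureError(f"identity {f} infeasible for length {L}")
        pos = rng.choice(L, size=m, replace=False)
        seq = list(base)
        for p in pos:
            choices = [c for c in letters if c != base[p]]
            seq[p] = choices[rng.integers(len(choices))]
        out.append("".join(seq))
    return out


# ---------------------------------------------------------------------------
# Fixture sets on disk
# ---------------------------------------------------------------------------

STANDARD_SET = ("helix-dimer", "peptide-complex", "dna-complex")


def write_fixture_set(out_dir, seed: int = 0, kinds=STANDARD_SET) -> list[Path]:
    """Write PDB + ground-truth JSON sidecars for a set of fixture kinds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind in kinds:
        spec = FixtureSpec(kind=kind, seed=seed)
        assembly, truth = make_assembly(spec)
        pdb_path = out_dir / f"{assembly.entry_id.lower()}.pdb"
        write_pdb(assembly, pdb_path)
        (out_dir / f"{assembly.entry_id.lower()}.truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True) + "\n")
        written.append(pdb_path)
    return written
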