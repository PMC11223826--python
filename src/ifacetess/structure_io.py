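"""Reading and writing macromolecular structures.

Parses PDB/mmCIF files (optionally gzipped) into a light-weight hierarchy
(:class:`Assembly` → :class:`Chain` → :class:`Residue` → :class:`Atom`),
assigns van der Waals radii and applies the entry-level filters used when
building the interaction database: non-NMR entries with resolution better
than 4 Å.

Hydrogens are dropped at parse time; all downstream geometry (contact
areas, bond annotation) is heavy-atom based.  For alternate locations only
the highest-occupancy conformer of each atom is kept (ties broken by the
alphabetically first altloc code), so a parsed residue never contains two
atoms with the same name.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import gemmi
import numpy as np

logger = logging.getLogger("ifacetess")

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Assembly",
    "ResidueKey",
    "ParseError",
    "FormatError",
    "STANDARD_AA",
    "STANDARD_NUCLEOTIDES",
    "WATER_NAMES",
    "DEFAULT_RADII",
    "DEFAULT_RADIUS",
    "parse_structure",
    "assign_radii",
    "entry_passes_filters",
    "write_pdb",
    "write_mmcif",
    "residue_category",
]


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class FormatError(ValueError):
    """Raised when the file format cannot be determined."""


# ---------------------------------------------------------------------------
# Residue dictionaries
# ---------------------------------------------------------------------------

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Standard ribo- and deoxyribonucleotides.
STANDARD_NUCLEOTIDES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Heavy-atom van der Waals radii (Å), element-keyed.  A single documented
# table used consistently by the tessellation; values follow the common
# Bondi/Rowland set for the biologically dominant elements.
DEFAULT_RADII: Mapping[str, float] = {
    "H": 1.20, "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "FE": 1.456, "MN": 1.61, "CA": 1.71,
    "NA": 2.27, "K": 2.75,
}

#: Fallback radius for elements absent from :data:`DEFAULT_RADII`.
DEFAULT_RADIUS = 1.80


def residue_category(name: str) -> str:
    """Categorize a residue name.

    Returns one of ``standard-aa``, ``nonstandard-aa``, ``nucleotide``,
    ``ligand`` or ``water``, determined solely by the residue name against
    fixed dictionaries (the chemical-component table is consulted for
    non-standard amino acids and modified nucleotides).
    """
    name = name.strip().upper()
    if name in WATER_NAMES:
        return "water"
    if name in STANDARD_AA:
        return "standard-aa"
    if name in STANDARD_NUCLEOTIDES:
        return "nucleotide"
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.found():
        if info.is_water():
            return "water"
        if info.is_amino_acid():
            return "nonstandard-aa"
        if info.is_nucleic_acid():
            return "nucleotide"
    return "ligand"


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    radius: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue within an assembly."""

    chain_id: str
    auth_seq: int
    icode: str
    name: str

    def label(self) -> str:
        ins = self.icode.strip()
        return f"{self.chain_id}/{self.name}{self.auth_seq}{ins}"


@dataclass
class Residue:
    chain_id: str
    auth_seq: int
    icode: str
    name: str
    category: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.auth_seq, self.icode, self.name)

    @property
    def is_resolved(self) -> bool:
        return len(self.atoms) > 0

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def n_resolved(self) -> int:
        return sum(1 for r in self.residues if r.is_resolved)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues
                if r.category in ("standard-aa", "nonstandard-aa", "nucleotide")]


@dataclass
class Assembly:
    entry_id: str
    assembly_id: str = "1"
    method: str = ""
    resolution: Optional[float] = None
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_EXTENSIONS = {
    ".pdb": "pdb", ".ent": "pdb",
    ".cif": "mmcif", ".mmcif": "mmcif",
}


def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes and suffixes[-1] in _EXTENSIONS:
        return _EXTENSIONS[suffixes[-1]]
    raise FormatError(f"cannot determine structure format from extension: {path}")


_RESOLUTION_CIF_KEYS = ("_refine.ls_d_res_high", "_reflns.d_resolution_high",
                        "_em_3d_reconstruction.resolution")


def _mmcif_resolution(path: Path) -> Optional[float]:
    try:
        block = gemmi.cif.read(str(path)).sole_block()
    except (RuntimeError, ValueError):
        return None
    for key in _RESOLUTION_CIF_KEYS:
        val = block.find_value(key)
        if val and val not in (".", "?"):
            try:
                return float(val)
            except ValueError:
                continue
    return None


def _dedup_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _altloc_rank(a.altloc)) > (
                prev.occupancy, _altloc_rank(prev.altloc)):
            by_name[a.name] = a
    return list(by_name.values())


def _altloc_rank(altloc: str) -> float:
    # higher rank wins on occupancy ties → alphabetically first altloc wins
    return -ord(altloc) if altloc else 0.0


def parse_structure(path, format: str = "auto") -> Assembly:
    """Read a PDB or mmCIF file into an :class:`Assembly`.

    Only the first model is read.  Hydrogens are dropped, alternate
    locations reduced to the highest-occupancy conformer, waters retained
    but flagged (category ``water``).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such structure file: {path}")
    if path.stat().st_size == 0 or (path.suffix != ".gz" and not path.read_text(errors="replace").strip()):
        raise ParseError(f"empty structure file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r}")

    coor = gemmi.CoorFormat.Pdb if format == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path}")

    entry_id = ((st.name or path.stem).strip() or path.stem).upper()
    method = st.info["_exptl.method"] if "_exptl.method" in st.info else ""
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    if resolution is None and format == "mmcif":
        resolution = _mmcif_resolution(path)

    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            res = Residue(
                chain_id=gchain.name,
                auth_seq=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                name=gres.name.strip(),
                category=residue_category(gres.name),
            )
            raw: list[Atom] = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                altloc = ga.altloc if ga.altloc and ga.altloc != "\x00" else ""
                raw.append(Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name.upper(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    occupancy=float(ga.occ),
                    altloc=altloc,
                    is_hetero=(gres.het_flag == "H"),
                ))
            res.atoms = _dedup_altlocs(raw)
            if res.atoms or gres.het_flag != "H":
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    if not chains:
        raise ParseError(f"no chains parsed from {path}")
    return Assembly(entry_id=entry_id, method=method,
                    resolution=resolution, chains=chains)


# ---------------------------------------------------------------------------
# Radii
# ---------------------------------------------------------------------------

def assign_radii(assembly: Assembly,
                 table: Mapping[str, float] = DEFAULT_RADII,
                 default: float = DEFAULT_RADIUS) -> Assembly:
    """Assign van der Waals radii in place (and return the assembly).

    Lookup is by element symbol; unknown elements get ``default`` with a
    logged warning.  Idempotent.
    """
    unknown: set[str] = set()
    for _res, atom in assembly.iter_atoms():
        r = table.get(atom.element)
        if r is None:
            unknown.add(atom.element)
            r = default
        atom.radius = r
    for el in sorted(unknown):
        logger.warning("unknown element %r: using default radius %.2f Å", el, default)
    return assembly


# ---------------------------------------------------------------------------
# Entry filters
# ---------------------------------------------------------------------------

def entry_passes_filters(assembly: Assembly,
                         max_resolution: float = 4.0,
                         accept_missing_resolution: bool = False) -> bool:
    """Entry-level filter: non-NMR and resolution strictly better than the cutoff.

    Entries without a reported resolution are rejected by default
    (conservative), which can be overridden with
    ``accept_missing_resolution=True``.
    """
    if "NMR" in assembly.method.upper():
        return False
    if assembly.resolution is None:
        if not accept_missing_resolution:
            logger.info("entry %s rejected: no resolution reported", assembly.entry_id)
            return False
        return True
    return assembly.resolution < max_resolution


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _to_gemmi(assembly: Assembly) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = assembly.entry_id
    if assembly.resolution is not None:
        st.resolution = assembly.resolution
    if assembly.method:
        st.info["_exptl.method"] = assembly.method
    model = gemmi.Model("1")
    for chain in assembly.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.auth_seq, res.icode or " ")
            gres.het_flag = "H" if res.category in ("water", "ligand") else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*map(float, atom.coords))
                ga.occ = atom.occupancy
                ga.serial = atom.serial
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(assembly: Assembly, path) -> None:
    """Write the assembly as a PDB file (PyMOL-loadable)."""
    st = _to_gemmi(assembly)
    st.write_pdb(str(path))
    _prepend_metadata_pdb(assembly, Path(path))


def _prepend_metadata_pdb(assembly: Assembly, path: Path) -> None:
    text = path.read_text()
    header = []
    if assembly.method:
        header.append(f"EXPDTA    {assembly.method}")
    if assembly.resolution is not None:
        header.append(f"REMARK   2 RESOLUTION. {assembly.resolution:7.2f} ANGSTROMS.")
    if header and "EXPDTA" not in text:
        path.write_text("\n".join(header) + "\n" + text)


def write_mmcif(assembly: Assembly, path) -> None:
    """Write the assembly as mmCIF."""
    st = _to_gemmi(assembly)
    doc = st.make_mmcif_document()
    block = doc.sole_block()
    if assembly.resolution is not None:
        block.set_pair("_refine.ls_d_res_high", f"{assembly.resolution:.2f}")
    doc.write_file(str(path))
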