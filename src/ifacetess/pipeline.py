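"""End-to-end pre-processing pipeline and tabular outputs.

Runs the full flow over a directory of structures: parse → entry filters
→ chain typing and duplex joining → tessellation contacts → interface
extraction, filtering and bond annotation → binding sites → sequence
clustering (>95% and >40% identity) with per-cluster MSAs → three-level
structure-based clustering of interfaces and binding sites.  All results
are written as TSV tables with stable column order (areas at 2 decimals,
author residue numbering throughout), plus a JSON cluster manifest that
carries enough per-item data to support incremental updates.

Interface items are clustered for protein–protein interfaces; binding
sites are clustered for all three interaction types (the protein side).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cluster as clustering
from .cluster import ClusterSet, update_clusters
from .contacts import (
    aggregate_to_residues, balls_from_assembly, compute_atom_contacts,
)
from .entities import Entity, build_entities
from .interfaces import (
    BindingSite, Interface, ITYPE_CODES, annotate_bonds,
    derive_binding_sites, extract_interfaces,
)
from .msa import cluster_sequences
from .structure_io import (
    Assembly, ParseError, assign_radii, entry_passes_filters, parse_structure,
)

logger = logging.getLogger("ifacetess")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "summarize",
    "write_contacts_tsv",
    "write_pymol_script",
    "fetch_rcsb_assembly",
    "accession_interface_areas",
    "clamp_dna_contact_counts",
]

_STRUCT_GLOBS = ("*.pdb", "*.ent", "*.cif", "*.mmcif",
                 "*.pdb.gz", "*.ent.gz", "*.cif.gz", "*.mmcif.gz")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    inputs: Sequence   # files and/or directories
    out_dir: Path
    probe: float = 1.4
    min_area: float = 100.0
    max_resolution: float = 4.0
    accept_missing_resolution: bool = False
    levels: Sequence[str] = ("identical", "high", "similar")
    aligner: str = "builtin"
    write_contacts: bool = False
    write_pymol: bool = False
    update_manifest: Optional[Path] = None
    n_solvent_samples: int = 512
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.probe <= 0 or self.min_area <= 0 or self.max_resolution <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# Per-assembly processing
# ---------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    assembly: Assembly
    entities: list
    interfaces: list
    binding_sites: list
    rcmap: object


def process_assembly(assembly: Assembly, probe: float = 1.4,
                     min_area: float = 100.0,
                     n_solvent_samples: int = 512) -> AssemblyResult:
    """Contacts, interfaces and binding sites for one parsed assembly."""
    assign_radii(assembly)
    entities = build_entities(assembly)
    balls, keys = balls_from_assembly(assembly)
    atom_contacts, solvent = compute_atom_contacts(
        balls, probe=probe, n_solvent_samples=n_solvent_samples)
    rcmap = aggregate_to_residues(atom_contacts, solvent, keys)
    interfaces = extract_interfaces(assembly, entities, rcmap,
                                    min_area=min_area)
    for iface in interfaces:
        annotate_bonds(iface, assembly)
    sites = derive_binding_sites(interfaces)
    return AssemblyResult(assembly=assembly, entities=entities,
                          interfaces=interfaces, binding_sites=sites,
                          rcmap=rcmap)


def _collect_inputs(inputs) -> list[Path]:
    files: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            for pat in _STRUCT_GLOBS:
                files.extend(p.glob(pat))
        elif p.exists():
            files.append(p)
        else:
            raise PipelineError(f"input not found: {p}")
    return sorted(set(files))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _entities_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for e in r.entities:
            rows.append({
                "entry": r.assembly.entry_id,
                "assembly": r.assembly.assembly_id,
                "entity_id": e.entity_id,
                "kind": e.kind,
                "chains": "+".join(e.chain_ids),
                "n_residues": len(e.residues),
                "sequence": e.sequence,
            })
    return pd.DataFrame(rows, columns=["entry", "assembly", "entity_id",
                                       "kind", "chains", "n_residues",
                                       "sequence"])


def _interfaces_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for f in r.interfaces:
            rows.append({
                "entry": f.entry_id,
                "assembly": f.assembly_id,
                "interface_id": f.interface_id,
                "itype": ITYPE_CODES[f.itype],
                "chains_a": "+".join(f.entity_a.chain_ids),
                "chains_b": "+".join(f.entity_b.chain_ids),
                "total_area": _fmt(f.total_area),
                "n_contacts": len(f.contacts),
                "n_residues": len({p for p, _q in f.contacts}
                                  | {-q - 1 for _p, q in f.contacts}),
                "n_hbonds": f.n_hbonds,
                "n_saltbridges": f.n_saltbridges,
                "n_disulfides": f.n_disulfides,
            })
    return pd.DataFrame(rows, columns=["entry", "assembly", "interface_id",
                                       "itype", "chains_a", "chains_b",
                                       "total_area", "n_contacts",
                                       "n_residues", "n_hbonds",
                                       "n_saltbridges", "n_disulfides"])


def _sites_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        for s in r.binding_sites:
            rows.append({
                "entry": r.assembly.entry_id,
                "assembly": r.assembly.assembly_id,
                "site_id": s.site_id,
                "protein_entity": s.protein.entity_id,
                "partner_kind": s.partner_kind,
                "n_residues": len(s.residue_areas),
                "total_area": _fmt(s.total_area),
                "residues": ";".join(f"{k.label()}:{a:.2f}"
                                     for k, a in s.residues()),
            })
    return pd.DataFrame(rows, columns=["entry", "assembly", "site_id",
                                       "protein_entity", "partner_kind",
                                       "n_residues", "total_area",
                                       "residues"])


def write_contacts_tsv(result: AssemblyResult, path) -> None:
    """Residue-pair contact table for one assembly (author numbering)."""
    rows = []
    for (ka, kb), area in sorted(result.rcmap.contacts.items()):
        rows.append({
            "chain_a": ka.chain_id, "resnum_a": f"{ka.auth_seq}{ka.icode}",
            "resname_a": ka.name,
            "chain_b": kb.chain_id, "resnum_b": f"{kb.auth_seq}{kb.icode}",
            "resname_b": kb.name,
            "area": _fmt(area),
        })
    pd.DataFrame(rows, columns=["chain_a", "resnum_a", "resname_a", "chain_b",
                                "resnum_b", "resname_b", "area"]
                 ).to_csv(path, sep="\t", index=False)


def write_pymol_script(interface: Interface, path) -> None:
    """PyMOL selection script for an interface's residues."""
    sel_a = sorted({(k.chain_id, k.auth_seq) for k, _k2, _a
                    in interface.residue_pairs()})
    sel_b = sorted({(k2.chain_id, k2.auth_seq) for _k, k2, _a
                    in interface.residue_pairs()})

    def sel(pairs):
        return " or ".join(f"(chain {c} and resi {n})" for c, n in pairs)

    text = (f"# interface {interface.interface_id}\n"
            f"select iface_a, {sel(sel_a)}\n"
            f"select iface_b, {sel(sel_b)}\n"
            "show sticks, iface_a or iface_b\n")
    Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Cluster manifest (supports incremental updates)
# ---------------------------------------------------------------------------

def _item_payload(item) -> dict:
    if isinstance(item, Interface):
        return {
            "kind": "interface",
            "itype": item.itype,
            "seq_a": item.entity_a.sequence,
            "seq_b": item.entity_b.sequence,
            "contacts": [[pa, pb, a] for (pa, pb), a
                         in sorted(item.contacts.items())],
        }
    return {
        "kind": "site",
        "partner_kind": item.partner_kind,
        "protein_seq": item.protein.sequence,
        "areas": [[p, a] for p, a in sorted(item.residue_areas.items())],
    }


def _item_from_payload(item_id: str, payload: dict):
    if payload["kind"] == "interface":
        ent_a = Entity(entity_id=f"{item_id}#A", kind="protein",
                       chain_ids=["A"], sequence=payload["seq_a"])
        ent_b = Entity(entity_id=f"{item_id}#B", kind="protein",
                       chain_ids=["B"], sequence=payload["seq_b"])
        return Interface(entry_id=item_id, assembly_id="1",
                         entity_a=ent_a, entity_b=ent_b,
                         itype=payload["itype"],
                         contacts={(pa, pb): a
                                   for pa, pb, a in payload["contacts"]})
    ent = Entity(entity_id=f"{item_id}#P", kind="protein", chain_ids=["A"],
                 sequence=payload["protein_seq"])
    partner = Entity(entity_id=f"{item_id}#Q", kind=payload["partner_kind"],
                     chain_ids=["B"])
    return BindingSite(protein=ent, partner=partner,
                       partner_kind=payload["partner_kind"],
                       residue_areas={p: a for p, a in payload["areas"]})


def _manifest(iface_levels, site_levels, iface_items, site_items) -> dict:
    def dump_levels(levels):
        return {lvl: {"clusters": [[c, m] for c, m in cs.clusters],
                      "singletons": list(cs.singletons)}
                for lvl, cs in levels.items()}
    payloads = {}
    for iid, item in iface_items.items():
        payloads[iid] = _item_payload(item)
    for sid, item in site_items.items():
        payloads[sid] = _item_payload(item)
    return {
        "threshold": clustering.STRUCT_THRESHOLD,
        "interface_levels": dump_levels(iface_levels),
        "site_levels": dump_levels(site_levels),
        "items": payloads,
    }


def _load_manifest(path) -> tuple[dict, dict, dict]:
    data = json.loads(Path(path).read_text())
    items = {iid: _item_from_payload(iid, p) for iid, p in data["items"].items()}

    def load_levels(key):
        return {lvl: ClusterSet(level=lvl,
                                clusters=[(c, list(m)) for c, m in d["clusters"]],
                                singletons=list(d["singletons"]))
                for lvl, d in data.get(key, {}).items()}
    return load_levels("interface_levels"), load_levels("site_levels"), items


# ---------------------------------------------------------------------------
# Clustering over the whole run
# ---------------------------------------------------------------------------

def _protein_sequences(items_ifaces: dict, items_sites: dict) -> dict:
    seqs = {}
    for item in items_ifaces.values():
        seqs[item.entity_a.entity_id] = item.entity_a.sequence
        seqs[item.entity_b.entity_id] = item.entity_b.sequence
    for item in items_sites.values():
        seqs[item.protein.entity_id] = item.protein.sequence
    return {k: v for k, v in sorted(seqs.items()) if v}


def _cluster_all(iface_items: dict, site_items: dict, aligner: str,
                 levels: Sequence[str]) -> tuple[dict, dict]:
    seqs = _protein_sequences(iface_items, site_items)
    if not seqs:
        empty = {lvl: ClusterSet(level=lvl) for lvl in levels}
        return dict(empty), dict(empty)
    sc95 = cluster_sequences(seqs, 0.95)
    sc40 = cluster_sequences(seqs, 0.40)

    def run(items: dict, kind: str) -> dict:
        objs = list(items.values())
        ids = {id(o): iid for iid, o in items.items()}
        if not objs:
            return {lvl: ClusterSet(level=lvl) for lvl in levels}
        res = clustering.cluster_at_levels(objs, ids, sc95, sc40,
                                           kind=kind, aligner=aligner)
        return {lvl: cs for lvl, cs in res.items() if lvl in levels}

    pp = {iid: it for iid, it in iface_items.items()
          if it.itype == "protein-protein"}
    return run(pp, "interface"), run(site_items, "site")


def _update_all(manifest_path, iface_items: dict, site_items: dict,
                aligner: str, levels: Sequence[str]):
    """Merge new items into a previous run's clusters (old items keep
    their memberships)."""
    old_iface_levels, old_site_levels, old_items = _load_manifest(manifest_path)
    old_ifaces = {iid: it for iid, it in old_items.items()
                  if isinstance(it, Interface)}
    old_sites = {iid: it for iid, it in old_items.items()
                 if isinstance(it, BindingSite)}
    all_ifaces = {**old_ifaces,
                  **{i: x for i, x in iface_items.items()
                     if x.itype == "protein-protein"}}
    all_sites = {**old_sites, **site_items}

    seqs = _protein_sequences(all_ifaces, all_sites)
    sc95 = cluster_sequences(seqs, 0.95) if seqs else []
    sc40 = cluster_sequences(seqs, 0.40) if seqs else []
    from .msa import build_msa
    cidx95 = clustering._seq_cluster_index(sc95)
    cidx40 = clustering._seq_cluster_index(sc40)
    msas95 = {ci: build_msa(cl, aligner=aligner) for ci, cl in enumerate(sc95)}
    msas40 = {ci: build_msa(cl, aligner=aligner) for ci, cl in enumerate(sc40)}

    def sim_fn(items: dict, kind: str, seq_thr: float, measure: str):
        cidx = cidx95 if seq_thr == 0.95 else cidx40
        msas = msas95 if seq_thr == 0.95 else msas40

        def sim(x, y):
            a, b = items[x], items[y]
            try:
                if kind == "interface":
                    return clustering._interface_sim(a, b, cidx, msas, measure)
                return clustering._site_sim(a, b, cidx, msas, measure)
            except clustering.UndefinedSimilarityError:
                return 0.0
        return sim

    def merge(old_levels, items: dict, kind: str) -> dict:
        out = {}
        for lvl, seq_thr, measure in clustering.LEVELS:
            if lvl not in levels:
                continue
            existing = old_levels.get(lvl, ClusterSet(level=lvl))
            known = set(existing.all_items())
            new_ids = sorted(i for i in items if i not in known)
            out[lvl] = update_clusters(existing, new_ids,
                                       sim_fn(items, kind, seq_thr, measure))
        return out

    return (merge(old_iface_levels, all_ifaces, "interface"),
            merge(old_site_levels, all_sites, "site"),
            all_ifaces, all_sites)


def _clusters_table(level: str, iface_cs: ClusterSet, site_cs: ClusterSet,
                    sims: dict) -> pd.DataFrame:
    rows = []
    for kind, cs in (("interface", iface_cs), ("site", site_cs)):
        for centroid, members in cs.clusters:
            for m in members:
                rows.append({"item_kind": kind, "item_id": m, "level": level,
                             "cluster_id": f"{level}:{centroid}",
                             "is_centroid": int(m == centroid),
                             "sim_to_centroid":
                                 _fmt(sims.get((kind, m, centroid), 1.0))})
        for s in cs.singletons:
            rows.append({"item_kind": kind, "item_id": s, "level": level,
                         "cluster_id": f"{level}:{s}", "is_centroid": 1,
                         "sim_to_centroid": _fmt(1.0)})
    return pd.DataFrame(rows, columns=["item_kind", "item_id", "level",
                                       "cluster_id", "is_centroid",
                                       "sim_to_centroid"])


# ---------------------------------------------------------------------------
# Pipeline entry points
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pre-processing flow; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    files = _collect_inputs(config.inputs)
    if not files:
        raise PipelineError("no structure files found in inputs")
    logger.info("stage input: %d file(s)", len(files))

    results: list[AssemblyResult] = []
    n_rejected = 0
    for path in files:
        try:
            assembly = parse_structure(path)
        except (ParseError, ValueError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        if not entry_passes_filters(
                assembly, max_resolution=config.max_resolution,
                accept_missing_resolution=config.accept_missing_resolution):
            logger.info("entry %s rejected by entry filters", assembly.entry_id)
            n_rejected += 1
            continue
        results.append(process_assembly(
            assembly, probe=config.probe, min_area=config.min_area,
            n_solvent_samples=config.n_solvent_samples))
    if not results:
        raise PipelineError("no entries passed filters")
    logger.info("stage entries: %d accepted, %d rejected",
                len(results), n_rejected)

    _entities_table(results).to_csv(out / "entities.tsv", sep="\t", index=False)
    _interfaces_table(results).to_csv(out / "interfaces.tsv", sep="\t",
                                      index=False)
    _sites_table(results).to_csv(out / "binding_sites.tsv", sep="\t",
                                 index=False)
    n_ifaces = sum(len(r.interfaces) for r in results)
    n_sites = sum(len(r.binding_sites) for r in results)
    logger.info("stage interfaces: %d interfaces, %d binding sites",
                n_ifaces, n_sites)

    if config.write_contacts:
        for r in results:
            write_contacts_tsv(
                r, out / f"contacts_{r.assembly.entry_id.lower()}.tsv")
    if config.write_pymol:
        pml = out / "pymol"
        pml.mkdir(exist_ok=True)
        for r in results:
            for f in r.interfaces:
                write_pymol_script(
                    f, pml / (f.interface_id.replace("/", "_")
                              .replace(":", "_") + ".pml"))

    iface_items = {f.interface_id: f for r in results for f in r.interfaces}
    site_items = {s.site_id: s for r in results for s in r.binding_sites}

    if config.update_manifest:
        iface_levels, site_levels, all_ifaces, all_sites = _update_all(
            config.update_manifest, iface_items, site_items,
            config.aligner, config.levels)
    else:
        iface_levels, site_levels = _cluster_all(
            iface_items, site_items, config.aligner, config.levels)
        all_ifaces = {i: x for i, x in iface_items.items()
                      if x.itype == "protein-protein"}
        all_sites = site_items

    # non-PP interfaces are not clustered as interfaces; report them as
    # their own singleton rows so every interface appears at every level
    extra_singletons = sorted(i for i, x in iface_items.items()
                              if x.itype != "protein-protein")
    for lvl in config.levels:
        cs = iface_levels.get(lvl, ClusterSet(level=lvl))
        merged = ClusterSet(level=lvl, clusters=list(cs.clusters),
                            singletons=sorted(
                                list(cs.singletons) + extra_singletons))
        table = _clusters_table(lvl, merged,
                                site_levels.get(lvl, ClusterSet(level=lvl)),
                                sims={})
        table.to_csv(out / f"clusters_{lvl}.tsv", sep="\t", index=False)
        logger.info("stage clustering[%s]: %d interface clusters, "
                    "%d site clusters", lvl,
                    merged.n_clusters(), site_levels[lvl].n_clusters()
                    if lvl in site_levels else 0)

    manifest = _manifest(iface_levels, site_levels, all_ifaces, all_sites)
    (out / "clusters.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out


def summarize(results_dir, itype: Optional[str] = None,
              level: str = "identical") -> pd.DataFrame:
    """Per-entity interaction counts, cross-checked against the tables."""
    results_dir = Path(results_dir)
    for fname in ("entities.tsv", "interfaces.tsv", f"clusters_{level}.tsv"):
        if not (results_dir / fname).exists():
            raise PipelineError(f"missing table: {results_dir / fname}")
    interfaces = pd.read_csv(results_dir / "interfaces.tsv", sep="\t")
    clusters = pd.read_csv(results_dir / f"clusters_{level}.tsv", sep="\t")

    iface_rows = clusters[clusters.item_kind == "interface"]
    if len(iface_rows) != len(interfaces):
        raise PipelineError(
            f"cluster table for level {level!r} disagrees with "
            f"interfaces.tsv ({len(iface_rows)} vs {len(interfaces)})")

    if itype is not None:
        interfaces = interfaces[interfaces.itype == itype]
    rows = []
    for (entry, code), grp in interfaces.groupby(["entry", "itype"]):
        ids = set(grp.interface_id)
        n_clusters = iface_rows[iface_rows.item_id.isin(ids)
                                ].cluster_id.nunique()
        rows.append({"entry": entry, "itype": code,
                     "n_interfaces": len(grp),
                     f"n_clusters_{level}": n_clusters})
    return pd.DataFrame(rows, columns=["entry", "itype", "n_interfaces",
                                       f"n_clusters_{level}"])


# ---------------------------------------------------------------------------
# Accession-anchored checks (require locally cached PDB assemblies)
# ---------------------------------------------------------------------------

def fetch_rcsb_assembly(entry: str, out_path, assembly: int = 1,
                        timeout: float = 10.0) -> Path:
    """Best-effort download of a biological assembly from the PDB archive."""
    import urllib.request
    url = (f"https://files.rcsb.org/download/"
           f"{entry.upper()}.pdb{assembly}.gz")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        out_path.write_bytes(resp.read())
    return out_path


def _cached_assembly(cache_dir: Path, entry: str) -> Assembly:
    cache_dir = Path(cache_dir)
    for pattern in (f"{entry.lower()}.pdb1.gz", f"{entry.lower()}.pdb1",
                    f"{entry.lower()}.pdb", f"{entry.upper()}.pdb1.gz"):
        p = cache_dir / pattern
        if p.exists():
            # .pdb1 is plain PDB under another suffix
            if ".pdb1" in p.suffixes or p.name.endswith(".pdb1"):
                return _parse_pdb1(p)
            return parse_structure(p)
    try:
        p = fetch_rcsb_assembly(entry, cache_dir / f"{entry.lower()}.pdb1.gz")
        return _parse_pdb1(p)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(
            f"structure {entry} not in cache {cache_dir} and could not be "
            f"downloaded ({exc}); place {entry.lower()}.pdb1[.gz] there "
            "to run the accession-anchored checks") from exc


def _parse_pdb1(path: Path) -> Assembly:
    import gzip
    import shutil
    import tempfile
    with tempfile.TemporaryDirectory() as tmp:
        target = Path(tmp) / (path.stem.split(".")[0] + ".pdb")
        if path.name.endswith(".gz"):
            with gzip.open(path, "rb") as fin, open(target, "wb") as fout:
                shutil.copyfileobj(fin, fout)
        else:
            shutil.copy(path, target)
        return parse_structure(target, format="pdb")


def accession_interface_areas(cache_dir, entries=("4MR8", "4MS3")) -> dict:
    """Largest protein–protein interface area per entry (Å²)."""
    out = {}
    for entry in entries:
        assembly = _cached_assembly(cache_dir, entry)
        result = process_assembly(assembly, n_solvent_samples=64)
        out[entry] = max((f.total_area for f in result.interfaces
                          if f.itype == "protein-protein"), default=0.0)
    return out


def clamp_dna_contact_counts(cache_dir, entry: str = "3BEP",
                             residues=(24, 149)) -> dict:
    """Number of protein subunits whose residue N contacts DNA."""
    assembly = _cached_assembly(cache_dir, entry)
    result = process_assembly(assembly, n_solvent_samples=64)
    nucleic_chains = {c for e in result.entities if e.kind == "nucleic"
                      for c in e.chain_ids}
    counts = {n: 0 for n in residues}
    protein_chains = sorted({c for e in result.entities
                             if e.kind == "protein" for c in e.chain_ids})
    for chain in protein_chains:
        for n in residues:
            touches = any(
                ((ka.chain_id == chain and ka.auth_seq == n
                  and kb.chain_id in nucleic_chains)
                 or (kb.chain_id == chain and kb.auth_seq == n
                     and ka.chain_id in nucleic_chains))
                for (ka, kb) in result.rcmap.contacts)
            counts[n] += int(touches)
    return counts
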