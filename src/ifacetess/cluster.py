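"""Taylor–Butina clustering of interfaces and binding sites.

Sphere-exclusion (Taylor–Butina) clustering over a symmetric similarity
matrix: each item's neighbours are the items whose similarity exceeds the
threshold; the unassigned item with the most neighbours (ties broken by
smallest id) is promoted to centroid and takes all its unassigned
neighbours as a cluster; items whose neighbours are exhausted become
singletons.  The algorithm supports cheap incremental updates: new items
join the best existing centroid they match, and only the unmatched
remainder is clustered afresh.

Interfaces and binding sites are clustered inside sequence pre-groups at
three stringency levels:

====================  ==========================  ============================
level                 sequence pre-group          structural measure (> 0.5)
====================  ==========================  ============================
identical             same >95%-identity cluster  contacts / site residue areas
high                  same >40%-identity cluster  contacts / site residue areas
similar               same >40%-identity cluster  patch (per-residue) areas
====================  ==========================  ============================

For interfaces, two items share a pre-group only when *both* proteins
fall in the same respective sequence clusters; residue correspondences
come from the pre-group's MSA columns.  All threshold comparisons are
strict (``>``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .interfaces import BindingSite, Interface
from .msa import Msa, SeqCluster, build_msa, map_residues
from .similarity import (
    ResidueCorrespondence, SimilarityScore, UndefinedSimilarityError,
    binding_site_residue_area_similarity, interface_contact_similarity,
    patch_area_similarity,
)

logger = logging.getLogger("ifacetess")

__all__ = [
    "SimilarityMatrix",
    "ClusterSet",
    "taylor_butina",
    "cluster_at_levels",
    "update_clusters",
    "STRUCT_THRESHOLD",
    "LEVELS",
]

#: Structural similarity threshold (strict >) for cluster membership.
STRUCT_THRESHOLD = 0.5

#: (level name, sequence-identity threshold, structural measure)
LEVELS = (
    ("identical", 0.95, "strict"),
    ("high", 0.40, "strict"),
    ("similar", 0.40, "patch"),
)


class MatrixValidationError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise MatrixValidationError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise MatrixValidationError("similarity matrix is not symmetric")
        if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
            raise MatrixValidationError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise MatrixValidationError("diagonal must be 1 (self-similarity)")
        self.values = v


@dataclass
class ClusterSet:
    level: Optional[str]
    clusters: list = field(default_factory=list)   # (centroid_id, [member_ids])
    singletons: list = field(default_factory=list)

    def all_items(self) -> list:
        out = [m for _c, members in self.clusters for m in members]
        out.extend(self.singletons)
        return out

    def n_clusters(self, count_singletons_as_clusters: bool = True) -> int:
        n = len(self.clusters)
        if count_singletons_as_clusters:
            n += len(self.singletons)
        return n

    def assignment(self) -> dict:
        """item id -> centroid id (singletons map to themselves)."""
        out = {}
        for centroid, members in self.clusters:
            for m in members:
                out[m] = centroid
        for s in self.singletons:
            out[s] = s
        return out


def taylor_butina(matrix: SimilarityMatrix,
                  threshold: float = STRUCT_THRESHOLD) -> ClusterSet:
    """Classic sphere-exclusion clustering of a similarity matrix.

    Neighbour lists use strict comparison (similarity > threshold) and
    are computed once on the full matrix; ids are assigned by neighbour
    count, largest first, ties to the smallest id.
    """
    ids = matrix.ids
    v = matrix.values
    n = len(ids)
    neighbors = [set(np.nonzero(v[i] > threshold)[0]) - {i} for i in range(n)]
    counts = [len(s) for s in neighbors]
    unassigned = set(range(n))
    clusters: list[tuple] = []
    singletons: list = []

    order = sorted(range(n), key=lambda i: (-counts[i], ids[i]))
    for i in order:
        if i not in unassigned:
            continue
        members = neighbors[i] & unassigned - {i}
        unassigned.discard(i)
        if members:
            unassigned -= members
            clusters.append((ids[i], [ids[i]] + sorted(ids[m] for m in members)))
        else:
            # no unassigned neighbours left (true or false singleton)
            singletons.append(ids[i])
    singletons.sort()
    return ClusterSet(level=None, clusters=clusters, singletons=singletons)


# ---------------------------------------------------------------------------
# Level-wise clustering inside sequence pre-groups
# ---------------------------------------------------------------------------

def _seq_cluster_index(seq_clusters: Sequence[SeqCluster]) -> dict:
    return {m: ci for ci, cl in enumerate(seq_clusters) for m in cl.members}


def _corr(msa: Msa, a: str, b: str) -> ResidueCorrespondence:
    if a == b:
        n = len(msa.degapped(a))
        return ResidueCorrespondence.identity(n)
    return map_residues(msa, a, b)


def _interface_sim(a: Interface, b: Interface, cidx: Mapping, msas: Mapping,
                   measure: str) -> float:
    """Similarity of two interfaces with MSA-derived correspondences.

    Tries the side-pairings compatible with the sequence clustering and
    keeps the best.
    """
    ca1, ca2 = cidx[a.entity_a.entity_id], cidx[a.entity_b.entity_id]
    cb1, cb2 = cidx[b.entity_a.entity_id], cidx[b.entity_b.entity_id]
    func = (interface_contact_similarity if measure == "strict"
            else lambda *args, **kw: patch_area_similarity(
                *args, mode="interface", **kw))
    scores = []
    if ca1 == cb1 and ca2 == cb2:
        cl = _corr(msas[ca1], a.entity_a.entity_id, b.entity_a.entity_id)
        cr = _corr(msas[ca2], a.entity_b.entity_id, b.entity_b.entity_id)
        scores.append(func(a, b, cl, cr).value)
    if ca1 == cb2 and ca2 == cb1:
        swapped = Interface(
            entry_id=b.entry_id, assembly_id=b.assembly_id,
            entity_a=b.entity_b, entity_b=b.entity_a, itype=b.itype,
            contacts={(pb, pa): ar for (pa, pb), ar in b.contacts.items()})
        cl = _corr(msas[ca1], a.entity_a.entity_id, b.entity_b.entity_id)
        cr = _corr(msas[ca2], a.entity_b.entity_id, b.entity_a.entity_id)
        scores.append(func(a, swapped, cl, cr).value)
    if not scores:
        return 0.0
    return max(scores)


def _site_sim(a: BindingSite, b: BindingSite, cidx: Mapping, msas: Mapping,
              measure: str) -> float:
    ca, cb = cidx[a.protein.entity_id], cidx[b.protein.entity_id]
    if ca != cb:
        return 0.0
    corr = _corr(msas[ca], a.protein.entity_id, b.protein.entity_id)
    if measure == "strict":
        return binding_site_residue_area_similarity(a, b, corr).value
    return patch_area_similarity(a, b, corr, mode="site").value


def _pregroup_interfaces(items: Sequence[Interface], cidx: Mapping) -> dict:
    groups: dict[tuple, list] = {}
    for it in items:
        key = tuple(sorted((cidx[it.entity_a.entity_id],
                            cidx[it.entity_b.entity_id])))
        groups.setdefault(key, []).append(it)
    return groups


def _pregroup_sites(items: Sequence[BindingSite], cidx: Mapping) -> dict:
    groups: dict[tuple, list] = {}
    for it in items:
        groups.setdefault((cidx[it.protein.entity_id],), []).append(it)
    return groups


def cluster_at_levels(items: Sequence,
                      item_ids: Mapping,
                      seq_clusters_95: Sequence[SeqCluster],
                      seq_clusters_40: Sequence[SeqCluster],
                      kind: str = "interface",
                      aligner: str = "builtin",
                      threshold: float = STRUCT_THRESHOLD) -> dict:
    """Cluster interfaces or binding sites at the three stringency levels.

    ``item_ids`` maps each item (by ``id()``-independent key, i.e. the
    object itself is hashable by identity) to its stable output id.
    Returns ``{level: ClusterSet}``; every item appears in each level's
    partition.  Items that cannot be pre-grouped with anything simply
    form their own clusters.
    """
    msa_cache: dict[tuple, Msa] = {}

    def msas_for(seq_clusters, which):
        out = {}
        for ci, cl in enumerate(seq_clusters):
            key = (which, ci)
            if key not in msa_cache:
                msa_cache[key] = build_msa(cl, aligner=aligner)
            out[ci] = msa_cache[key]
        return out

    results: dict[str, ClusterSet] = {}
    for level, seq_thr, measure in LEVELS:
        seq_clusters = seq_clusters_95 if seq_thr == 0.95 else seq_clusters_40
        which = "95" if seq_thr == 0.95 else "40"
        cidx = _seq_cluster_index(seq_clusters)
        msas = msas_for(seq_clusters, which)
        if kind == "interface":
            groups = _pregroup_interfaces(items, cidx)
            sim = lambda a, b: _interface_sim(a, b, cidx, msas, measure)  # noqa: E731
        elif kind == "site":
            groups = _pregroup_sites(items, cidx)
            sim = lambda a, b: _site_sim(a, b, cidx, msas, measure)  # noqa: E731
        else:
            raise ValueError(f"unknown item kind {kind!r}")

        clusters: list[tuple] = []
        singletons: list = []
        for gkey in sorted(groups):
            group = groups[gkey]
            gids = sorted(item_ids[id(it)] for it in group)
            by_id = {item_ids[id(it)]: it for it in group}
            if len(gids) == 1:
                singletons.append(gids[0])
                continue
            n = len(gids)
            mat = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    try:
                        s = sim(by_id[gids[i]], by_id[gids[j]])
                    except UndefinedSimilarityError:
                        s = 0.0
                    mat[i, j] = mat[j, i] = min(1.0, max(0.0, s))
            cs = taylor_butina(SimilarityMatrix(gids, mat), threshold)
            clusters.extend(cs.clusters)
            singletons.extend(cs.singletons)
        singletons.sort()
        clusters.sort(key=lambda c: c[0])
        results[level] = ClusterSet(level=level, clusters=clusters,
                                    singletons=singletons)
    return results


# ---------------------------------------------------------------------------
# Incremental updates
# ---------------------------------------------------------------------------

def update_clusters(existing: ClusterSet,
                    new_ids: Sequence,
                    sim: Callable,
                    threshold: float = STRUCT_THRESHOLD) -> ClusterSet:
    """Add new items to an existing cluster set without reclustering.

    ``sim(id_a, id_b)`` must return a similarity in [0, 1] for any pair
    drawn from the new ids and existing centroids.  Each new item joins
    the best-matching centroid above the threshold; the unmatched
    remainder is clustered among itself with :func:`taylor_butina` and
    appended.  Existing memberships never change.
    """
    clusters = [(c, list(m)) for c, m in existing.clusters]
    singleton_clusters = {s: None for s in existing.singletons}
    centroids = [c for c, _m in clusters] + list(singleton_clusters)

    leftovers: list = []
    promoted: dict = {}   # singleton centroid -> members list, if it gains members
    for nid in sorted(new_ids):
        best, best_s = None, threshold
        for c in centroids:
            s = sim(nid, c)
            if s > best_s:   # strict: first centroid wins score ties
                best, best_s = c, s
        if best is None:
            leftovers.append(nid)
        elif best in singleton_clusters:
            promoted.setdefault(best, [best]).append(nid)
        else:
            for c, members in clusters:
                if c == best:
                    members.append(nid)
                    break

    for c, members in promoted.items():
        del singleton_clusters[c]
        clusters.append((c, members))

    singletons = sorted(singleton_clusters)
    if leftovers:
        n = len(leftovers)
        mat = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                s = sim(leftovers[i], leftovers[j])
                mat[i, j] = mat[j, i] = min(1.0, max(0.0, s))
        cs = taylor_butina(SimilarityMatrix(leftovers, mat), threshold)
        clusters.extend(cs.clusters)
        singletons.extend(cs.singletons)
        singletons.sort()
    clusters.sort(key=lambda c: c[0])
    return ClusterSet(level=existing.level, clusters=clusters,
                      singletons=singletons)
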