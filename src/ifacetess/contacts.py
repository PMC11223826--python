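"""Interatomic contact surface areas from a tessellation of atomic balls.

The space around a molecule is partitioned with the power (Laguerre)
diagram of the solvent-expanded balls (van der Waals radius + probe,
probe = 1.4 Å by default).  Each atom owns a cell; the face shared by two
adjacent cells, clipped to the union of the solvent-expanded balls, is the
geometric contact between the two atoms and its area (Å²) quantifies the
contact.  Per-atom solvent area is the part of the atom's expanded sphere
not claimed by any neighbouring cell, i.e. the classic solvent-accessible
surface.

Geometry notes.  The bisector of two balls in a power diagram is a plane
(the radical plane).  On that plane, the cell-adjacency constraints
imposed by every other ball are halfplanes, and the clip to the
solvent-expanded envelope reduces to a single disk: for a point of the
face, having minimal power and lying inside *any* expanded ball is
equivalent to its common power being ≤ 0, i.e. lying within
sqrt(R_i² − t²) of the plane's foot point.  A face is therefore a convex
region — disk ∩ halfplanes — whose area is computed exactly (convex
polygon clipping followed by an exact circle/polygon intersection area).
Two balls with equal radii r at distance d with probe p give the
closed-form disk area π·((r+p)² − (d/2)²).

Solvent areas are evaluated by deterministic Fibonacci-lattice sampling
of the expanded sphere (resolution set by ``n_solvent_samples``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Ball",
    "AtomContact",
    "ResidueContactMap",
    "DegeneracyError",
    "compute_atom_contacts",
    "aggregate_to_residues",
    "balls_from_assembly",
    "mc_contact_area",
    "PROBE_RADIUS",
]

#: Default rolling-probe radius (water), Å.
PROBE_RADIUS = 1.4

_MIN_AREA = 1e-9


class DegeneracyError(ValueError):
    """Raised when two balls share (numerically) the same center."""


@dataclass
class Ball:
    center: np.ndarray
    radius: float
    atom_ref: Optional[object] = None


@dataclass(frozen=True)
class AtomContact:
    i: int
    j: int
    area: float


@dataclass
class ResidueContactMap:
    """Residue-pair contact areas plus per-residue solvent areas (Å²)."""

    contacts: dict = field(default_factory=dict)   # (key_a, key_b) -> area
    solvent: dict = field(default_factory=dict)    # key -> area

    def area(self, a, b) -> float:
        if a <= b:
            return self.contacts.get((a, b), 0.0)
        return self.contacts.get((b, a), 0.0)

    def total_area(self) -> float:
        return float(sum(self.contacts.values()))


# ---------------------------------------------------------------------------
# 2-D helpers (exact within floating point)
# ---------------------------------------------------------------------------

def _clip_halfplane(poly: list, a1: float, a2: float, b: float) -> list:
    """Sutherland–Hodgman clip of convex polygon ``poly`` by a1*x+a2*y <= b."""
    if not poly:
        return poly
    out = []
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        d1 = a1 * x1 + a2 * y1 - b
        d2 = a1 * x2 + a2 * y2 - b
        if d1 <= 0.0:
            out.append((x1, y1))
            if d2 > 0.0:
                t = d1 / (d1 - d2)
                out.append((x1 + t * (x2 - x1), y1 + t * (y2 - y1)))
        elif d2 <= 0.0:
            t = d1 / (d1 - d2)
            out.append((x1 + t * (x2 - x1), y1 + t * (y2 - y1)))
    return out


def _circle_poly_area(poly: Sequence, R: float) -> float:
    """Exact area of (convex CCW polygon) ∩ (disk of radius R at origin).

    Sums, over directed polygon edges, the area of the circular triangle
    (origin, p1, p2) clipped to the disk: straight sub-segments inside the
    disk contribute plain triangle areas, sub-segments outside contribute
    circular-sector areas.
    """
    if len(poly) < 3:
        return 0.0
    R2 = R * R
    total = 0.0
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        # segment-circle intersection parameters
        a = dx * dx + dy * dy
        ts = []
        if a > 0.0:
            bq = x1 * dx + y1 * dy
            cq = x1 * x1 + y1 * y1 - R2
            disc = bq * bq - a * cq
            if disc > 0.0:
                sq = math.sqrt(disc)
                for t in ((-bq - sq) / a, (-bq + sq) / a):
                    if 1e-12 < t < 1.0 - 1e-12:
                        ts.append(t)
            ts.sort()
        pts = [(x1, y1)] + [(x1 + t * dx, y1 + t * dy) for t in ts] + [(x2, y2)]
        for m in range(len(pts) - 1):
            ax, ay = pts[m]
            bx, by = pts[m + 1]
            mx, my = 0.5 * (ax + bx), 0.5 * (ay + by)
            if mx * mx + my * my <= R2 * (1.0 + 1e-12):
                total += 0.5 * (ax * by - ay * bx)
            else:
                ang = math.atan2(ay * bx - ax * by, ax * bx + ay * by)
                total += -0.5 * R2 * ang
    return abs(total)


# ---------------------------------------------------------------------------
# Contact computation
# ---------------------------------------------------------------------------

def _pair_face_area(idx_i: int, idx_j: int,
                    centers: np.ndarray, R: np.ndarray,
                    tree: cKDTree, r_max: float) -> float:
    ci, cj = centers[idx_i], centers[idx_j]
    Ri, Rj = R[idx_i], R[idx_j]
    delta = cj - ci
    d = float(np.linalg.norm(delta))
    if d >= Ri + Rj:
        return 0.0
    u = delta / d
    t = (d * d + Ri * Ri - Rj * Rj) / (2.0 * d)
    disk_r2 = Ri * Ri - t * t
    if disk_r2 <= 0.0:
        return 0.0
    disk_r = math.sqrt(disk_r2)
    p0 = ci + t * u

    # orthonormal in-plane frame
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    # any ball that can cut the clipped face lies within disk_r + r_max of p0
    cand = tree.query_ball_point(p0, disk_r + r_max + 1e-9)

    side = disk_r * 1.001
    poly = [(-side, -side), (side, -side), (side, side), (-side, side)]
    ci2 = float(ci @ ci)
    for k in cand:
        if k == idx_i or k == idx_j:
            continue
        ck = centers[k]
        # power_i(x) <= power_k(x)  ⇔  2(ck-ci)·x <= |ck|²-|ci|²+Ri²-Rk²
        av = 2.0 * (ck - ci)
        b = float(ck @ ck) - ci2 + Ri * Ri - R[k] * R[k]
        a1 = float(av @ e1)
        a2 = float(av @ e2)
        b2d = b - float(av @ p0)
        norm2d = math.hypot(a1, a2)
        if norm2d < 1e-12:
            if b2d < 0.0:      # plane-parallel constraint excludes everything
                return 0.0
            continue
        poly = _clip_halfplane(poly, a1, a2, b2d)
        if not poly:
            return 0.0
    return _circle_poly_area(poly, disk_r)


def compute_atom_contacts(balls: Sequence[Ball],
                          probe: float = PROBE_RADIUS,
                          n_solvent_samples: int = 1024,
                          ) -> tuple[list[AtomContact], np.ndarray]:
    """Contact faces and solvent areas for a set of atomic balls.

    Returns the list of positive-area :class:`AtomContact` (i < j) and the
    per-atom solvent-exposed areas (Å²).
    """
    if len(balls) == 0:
        raise ValueError("no balls")
    centers = np.asarray([b.center for b in balls], dtype=float)
    radii = np.asarray([b.radius for b in balls], dtype=float)
    if not np.all(np.isfinite(centers)):
        raise ValueError("non-finite ball center")
    if np.any(radii <= 0.0):
        raise ValueError("all ball radii must be > 0")
    R = radii + probe
    r_max = float(R.max())
    tree = cKDTree(centers)

    close = tree.query_pairs(r=1e-6)
    if close:
        i, j = sorted(close)[0]
        raise DegeneracyError(
            f"coincident ball centers: #{i} ({balls[i].atom_ref}) and "
            f"#{j} ({balls[j].atom_ref})")

    contacts: list[AtomContact] = []
    for i, j in sorted(tree.query_pairs(r=2.0 * r_max)):
        d = float(np.linalg.norm(centers[j] - centers[i]))
        if d >= R[i] + R[j]:
            continue
        area = _pair_face_area(i, j, centers, R, tree, r_max)
        if area > _MIN_AREA:
            contacts.append(AtomContact(i, j, area))

    solvent = _solvent_areas(centers, R, tree, r_max, n_solvent_samples)
    return contacts, solvent


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _solvent_areas(centers: np.ndarray, R: np.ndarray, tree: cKDTree,
                   r_max: float, n_samples: int) -> np.ndarray:
    unit = _fibonacci_sphere(n_samples)
    out = np.empty(len(centers))
    for i in range(len(centers)):
        pts = centers[i] + R[i] * unit
        exposed = np.ones(n_samples, dtype=bool)
        for k in tree.query_ball_point(centers[i], R[i] + r_max):
            if k == i:
                continue
            d2 = ((pts - centers[k]) ** 2).sum(axis=1)
            exposed &= d2 >= R[k] * R[k]
            if not exposed.any():
                break
        out[i] = 4.0 * math.pi * R[i] * R[i] * exposed.mean()
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo reference estimator (used as an independent cross-check)
# ---------------------------------------------------------------------------

def mc_contact_area(balls: Sequence[Ball], i: int, j: int,
                    probe: float = PROBE_RADIUS,
                    n_samples: int = 200_000,
                    rng: Optional[np.random.Generator] = None) -> float:
    """Brute-force sampling estimate of the (i, j) contact face area.

    Samples points uniformly on the radical plane of the two expanded
    balls within the envelope disk and counts those with globally minimal
    (and non-positive) power, checked against *every* ball by direct
    enumeration.  Slow; intended as an oracle for small instances only.
    """
    rng = rng or np.random.default_rng()
    centers = np.asarray([b.center for b in balls], dtype=float)
    R = np.asarray([b.radius for b in balls], dtype=float) + probe
    ci, cj = centers[i], centers[j]
    d = float(np.linalg.norm(cj - ci))
    if d <= 0 or d >= R[i] + R[j]:
        return 0.0
    u = (cj - ci) / d
    t = (d * d + R[i] ** 2 - R[j] ** 2) / (2.0 * d)
    disk_r2 = R[i] ** 2 - t * t
    if disk_r2 <= 0.0:
        return 0.0
    disk_r = math.sqrt(disk_r2)
    p0 = ci + t * u
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    # uniform points in the disk
    rr = disk_r * np.sqrt(rng.random(n_samples))
    th = 2.0 * math.pi * rng.random(n_samples)
    pts = p0 + rr[:, None] * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)

    diff = pts[:, None, :] - centers[None, :, :]
    powers = (diff ** 2).sum(axis=2) - (R ** 2)[None, :]
    pi_ = powers[:, i]
    ok = pi_ <= 0.0 + 1e-9
    ok &= (powers >= pi_[:, None] - 1e-9).all(axis=1)
    return math.pi * disk_r2 * float(ok.mean())


# ---------------------------------------------------------------------------
# Residue aggregation
# ---------------------------------------------------------------------------

def balls_from_assembly(assembly, include_waters: bool = False):
    """Flatten an assembly (with radii assigned) into balls + residue keys.

    Returns ``(balls, residue_keys)`` where ``residue_keys[k]`` identifies
    the residue owning ball ``k``.  Waters are excluded by default: they
    never participate in interfaces.
    """
    balls: list[Ball] = []
    keys = []
    for res in assembly.iter_residues():
        if res.category == "water" and not include_waters:
            continue
        for atom in res.atoms:
            if atom.radius <= 0.0:
                raise ValueError(
                    f"atom {atom.name} of {res.key.label()} has no radius; "
                    "call assign_radii first")
            balls.append(Ball(center=atom.coords, radius=atom.radius,
                              atom_ref=f"{res.key.label()}/{atom.name}"))
            keys.append(res.key)
    return balls, keys


def aggregate_to_residues(atom_contacts: Sequence[AtomContact],
                          solvent_areas: np.ndarray,
                          residue_keys: Sequence) -> ResidueContactMap:
    """Sum atom-level areas to residue level.

    Intra-residue contacts are dropped; residue pairs are stored once in
    canonical (sorted-key) order.
    """
    rc = ResidueContactMap()
    for c in atom_contacts:
        ka, kb = residue_keys[c.i], residue_keys[c.j]
        if ka == kb:
            continue
        if kb < ka:
            ka, kb = kb, ka
        rc.contacts[(ka, kb)] = rc.contacts.get((ka, kb), 0.0) + c.area
    for k, a in zip(residue_keys, solvent_areas):
        rc.solvent[k] = rc.solvent.get(k, 0.0) + float(a)
    return rc
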