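# Methods

## Contact model

Atoms are modelled as balls with element-based van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å, …; unknown elements fall back
to 1.80 Å with a warning).  Hydrogens are discarded at parse time — all
geometry is heavy-atom based — and for alternate locations only the
highest-occupancy conformer is kept (occupancy ties broken by the
alphabetically first altloc code), so the model is deterministic for any
input file.

Space is partitioned by the **power (Laguerre) diagram of the
solvent-expanded balls** (radius + probe, probe 1.4 Å ≈ water,
configurable).  The diagram concept — each atom owns a cell, adjacent
cells share a face whose area measures the contact — admits more than one
flavor; the power diagram was chosen because its bisectors are planes,
which makes exact face evaluation tractable:

* On the radical plane of balls *i, j*, every other ball contributes a
  linear (halfplane) adjacency constraint, and the clip to the
  solvent-expanded envelope reduces to a single disk: for a point of the
  face, lying inside *any* expanded ball is equivalent to the common
  power being ≤ 0.  A face is therefore convex — disk ∩ halfplanes — and
  its area is computed *exactly* by Sutherland–Hodgman halfplane clipping
  followed by an exact circle/convex-polygon intersection (circular
  segments summed per edge).  The two-ball closed form
  π((r+p)² − (d/2)²) is reproduced to machine precision, and random
  instances agree with an independent Monte-Carlo rejection oracle well
  within the stated 2% / 0.1 Å² accuracy contract.
* Only pairs whose expanded spheres intersect can share a clipped face;
  candidate clipping balls are found with a KD-tree (any ball that cuts
  the face lies within disk-radius + max expanded radius of the disk
  center), so the computation is near-linear in atom count for
  molecular densities.
* Coincident ball centers make the diagram degenerate and raise an error
  naming the atoms.

Per-atom **solvent area** is the part of the expanded sphere not claimed
by any neighbouring cell, which for this diagram equals the classic
solvent-accessible surface.  It is evaluated by deterministic
Fibonacci-lattice sampling (default 1024 points/atom in the library, 512
in the pipeline, 128 in most tests; a single exposed sphere is exact at
any sampling density because every point is kept).  Sampled solvent areas
are reproducible bit-for-bit for a fixed orientation but are only
rotation-invariant to the sampling resolution — the tests therefore hold
them to the area-accuracy contract, while face areas are exact.

Waters never participate in interfaces and are excluded from the
tessellation; ligand atoms are retained as space-fillers but form no
entities.

## Entities

Polypeptide chains are proteins unless they have < 20
structurally-resolved residues (≥ 1 heavy atom), or < 40 when more than
half the resolved residues are non-standard amino acids — in which case
they are peptides.  Both comparisons are strict; residue categories come
from fixed dictionaries (20 standard amino acids, standard (deoxy)ribo-
nucleotides, waters) with the chemical-component table deciding
non-standard amino acids vs. ligands.  Hybrid chains are typed by
majority residue class and logged.

Nucleic strands that pair into a double helix are joined into one
entity, so a protein touching either strand sees a single partner.  The
pairing test is a deliberately simple geometric stand-in for a full
base-pair annotation tool: C1′–C1′ ∈ [9.0, 11.5] Å, glycosidic N1/N9
within 9.5 Å, nearest base-ring atoms within 4.0 Å, and at least four
consecutive pairs running antiparallel.  On idealized B-form geometry
(the only duplexes the fixture generator emits) the criterion is
unambiguous; it makes no attempt at wobble/Hoogsteen taxonomy or helix
parameters.

## Interfaces, binding sites, bonds

An interface is the residue-contact set between two entities; only
protein–protein, protein–peptide and protein–nucleic types are emitted.
Interfaces with total area ≤ 100 Å² are dropped (strict, applied before
entry-level de-duplication — filtering first cannot change the surviving
set).  Within one entry, interfaces over sequence-identical entity pairs
with contact similarity ≥ 0.95 under the position-identity correspondence
are collapsed to the largest-area representative (area compared at the
printed 2-decimal precision so exact copies tie; ties broken by
lexicographic chain ids).  The greedy largest-first scan makes the
operation idempotent.

Each interface projects onto its protein side(s) as binding sites
(per-residue summed areas): two sites for protein–protein, one
otherwise.

Inter-entity bonds use standard heavy-atom criteria: hydrogen bonds as
donor–acceptor ≤ 3.5 Å with antecedent–donor–acceptor angle ≥ 90°
(donors/acceptors from fixed per-residue dictionaries, nucleic backbone
and base atoms included); salt bridges as Arg/Lys/His side-chain N to
Asp/Glu carboxylate O ≤ 4.0 Å; disulfides as Cys SG–SG ≤ 2.5 Å.  A
salt-bridge pair that also satisfies the hydrogen-bond geometry counts in
both tallies; the three counts are independent annotations.

## Similarity measures

All measures use the bounded contact-area-difference form
D(X→Y) = 1 − Σ min(|x−y|, x)/Σ x over the reference set, read through a
residue correspondence, and are symmetrized by the arithmetic mean of the
two directions — clustering needs a symmetric measure, and the mean keeps
the score in [0, 1] with self-similarity 1 and invariance under uniform
area scaling.  Residues without a counterpart in the correspondence
(alignment gaps) contribute their full area as difference, penalizing
insertions the same way missing contacts are penalized.

The *contact* variant compares residue-pair areas and is sensitive to how
contacts are wired across the interface.  The *patch/area* variant first
marginalizes each side's contacts to per-residue interface areas and
scores the sides separately (averaged), so a rearrangement of
cross-interface pairings on the same two surface patches scores 1.0.  For
binding sites the stored per-residue areas are already marginal, so the
site-area variant coincides with the site residue-area variant in this
implementation — the site cluster levels *high* and *similar* can
therefore only differ through their pre-groups.  For two interfaces both
side-pairings are evaluated and the better one kept (relevant for
homodimers and symmetric complexes).

## Sequence clustering and correspondences

Greedy incremental clustering in the CD-HIT style: sequences
longest-first (ties by id), each joining the first cluster whose
representative it matches above the identity threshold, else founding a
new cluster.  Identity = identical aligned positions / length of the
shorter sequence, from a deterministic global alignment (match 1,
mismatch −1, gap open −2, extend −0.5).  All identity and similarity
threshold comparisons are strict (> 0.95, > 0.40, > 0.5).  Exact
tie-behaviour of the original greedy tools is not reproduced.

Cluster MSAs come from a built-in center-star progressive aligner (each
member aligned to the representative; pairwise alignments merged on the
representative's coordinates), which is deterministic and
dependency-free; an external MAFFT can be requested per config and falls
back to the built-in aligner with a warning.  Two members' residues
correspond when they share an MSA column with neither row gapped;
correspondences are injective and involutive by construction.

## Taylor–Butina clustering

Neighbour lists are computed once on the full similarity matrix
(similarity > threshold, default 0.5); the unassigned item with the most
neighbours (ties → smallest id, for determinism) becomes a centroid and
claims its unassigned neighbours; items left without unassigned
neighbours become singletons, which the outputs report as clusters of
size one.  Interfaces are pre-grouped so that both partners lie in the
same respective sequence clusters (both assignments tried for swapped
pairs); binding sites by the protein's cluster.  The 40%-identity
pre-groups are reused for both the *high* and *similar* levels.
Incremental updates add each new item to the best-scoring existing
centroid above the threshold (first wins ties) and Taylor–Butina-cluster
the remainder; existing memberships never change, although batch and
incremental runs may partition borderline items differently — both runs
preserve the member-to-centroid similarity contract.

Only protein–protein interfaces are clustered as interfaces; binding
sites are clustered for all three interaction types.  Non-protein–protein
interfaces appear as their own singleton rows in the cluster tables so
that every interface is accounted for at every level.

## Pipeline and outputs

Entries are filtered to non-NMR structures with resolution strictly
better than 4 Å; entries with no reported resolution are rejected by
default (conservative; overridable), a choice the underlying data do not
dictate for resolution-less EM depositions.  Only the first model of a
file is read.  Per-file parse failures are logged and skipped; an empty
surviving set is a hard error.

All tables carry explicit headers, stable column order, author residue
numbering (auth_seq + insertion code) and areas printed with 2 decimals;
given fixed inputs and configuration, reruns are byte-identical.  The
cluster manifest (`clusters.json`) stores per-item contact payloads so a
later run can update clusters without the original structures.

## Synthetic fixtures

The generator emits idealized assemblies built from textbook secondary-
structure parameters: α-helices (rise 1.5 Å, twist 100°/residue, CA
radius 2.3 Å) with full backbone, outward CB and radially extended
side-chain tip atoms for bond-forming residues; extended peptides
(3.5 Å/residue); and an antiparallel B-DNA duplex (rise 3.4 Å, twist 36°,
C1′ at 5.25 Å from the axis so paired C1′–C1′ = 10.5 Å).  Default
compositions are a 30-residue helical homodimer (interface ≈ 645 Å²), a
12-residue peptide ligand (below the 20-residue protein threshold by
construction), a 12-bp duplex, a dual-binding-mode pair (same sequences,
partner docked on the N-terminal vs. flipped on the C-terminal half — 
contact similarity between modes ≪ 0.5), and mutant series hitting a
requested sequence identity to within one residue.

These models exercise every rule of the engine with known ground truth,
but they are not physically realistic: no side-chain packing, no
energetics, idealized geometry only.  Passing tests demonstrate the
correctness of the algorithms and bookkeeping, not biological fidelity on
real assemblies; the accession-anchored checks against deposited PDB
entries cover the latter and require those entries to be available
locally.

## Numerical choices and limitations

* Face areas are exact up to floating point (segment/circle intersection
  tolerances of 1e-12 relative); contacts below 1e-9 Å² are not stored.
* Solvent areas are sampled, not integrated; see the contract above.
* Problem sizes in tests and the acceptance script (≤ 50-ball oracle
  instances, 1000 ≤ 12-item clustering draws, 3–4 fixture assemblies of
  250–800 atoms) were chosen so the whole suite completes in about a
  minute on one CPU while still exercising every code path; all scale
  knobs (sampling densities, instance counts) are explicit parameters.
* Crystal-symmetry expansion is not performed: assemblies are analyzed
  as deposited.
* The duplex detector, bond criteria and built-in aligner are documented
  stand-ins for specialized external tools; they are exact on the
  idealized fixtures but not validated for edge cases of real data
  (modified bases, bifurcated hydrogen bonds, low-complexity
  alignments).
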