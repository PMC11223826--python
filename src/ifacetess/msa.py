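"""Greedy sequence clustering and per-cluster multiple sequence alignments.

Protein sequences are grouped by greedy incremental clustering in the
style of CD-HIT: sequences are considered longest-first (ties broken by
id) and each joins the first existing cluster whose *representative* it
matches at more than the identity threshold, otherwise it founds a new
cluster.  Identity is the number of identical aligned positions divided
by the length of the shorter sequence, computed on a global alignment.

Each cluster gets a multiple sequence alignment.  The default aligner is
a built-in deterministic center-star progressive aligner (every member is
globally aligned to the representative and the pairwise alignments are
merged on the representative's coordinates); an external aligner (MAFFT)
can be requested instead when installed.  Residues of two members are
considered equivalent when they share an MSA column in which neither row
is gapped — this is the residue correspondence used by all structural
similarity measures.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .similarity import ResidueCorrespondence

logger = logging.getLogger("ifacetess")

__all__ = [
    "SeqCluster",
    "Msa",
    "cluster_sequences",
    "build_msa",
    "map_residues",
    "sequence_identity",
    "read_fasta",
    "write_fasta",
]

# Deterministic global-alignment scoring for identity computation and the
# built-in aligner: match 1, mismatch -1, gap open -2, gap extend -0.5.
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1.0, -1.0, -2.0, -0.5


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = _MATCH
    al.mismatch_score = _MISMATCH
    al.open_gap_score = _GAP_OPEN
    al.extend_gap_score = _GAP_EXTEND
    return al


def _align_pair(a: str, b: str) -> tuple[str, str]:
    aln = _aligner().align(a, b)[0]
    rows = str(aln).splitlines()
    # biopython's formatted output varies; reconstruct from aligned blocks
    ga, gb = [], []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        if sa > pa:
            ga.append(a[pa:sa]); gb.append("-" * (sa - pa))
        if sb > pb:
            ga.append("-" * (sb - pb)); gb.append(b[pb:sb])
        ga.append(a[sa:ea]); gb.append(b[sb:eb])
        pa, pb = ea, eb
    if pa < len(a):
        ga.append(a[pa:]); gb.append("-" * (len(a) - pa))
    if pb < len(b):
        ga.append("-" * (len(b) - pb)); gb.append(b[pb:])
    return "".join(ga), "".join(gb)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter length."""
    if not a or not b:
        raise ValueError("empty sequence")
    ga, gb = _align_pair(a, b)
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return ident / min(len(a), len(b))


@dataclass
class SeqCluster:
    representative: str            # sequence id
    members: list[str] = field(default_factory=list)
    identity_threshold: float = 0.0
    sequences: dict = field(default_factory=dict)   # id -> sequence


@dataclass
class Msa:
    rows: dict                     # id -> gapped sequence (equal lengths)

    def __post_init__(self):
        lens = {len(v) for v in self.rows.values()}
        if len(lens) > 1:
            raise ValueError("MSA rows have unequal lengths")

    def degapped(self, member: str) -> str:
        return self.rows[member].replace("-", "")


def cluster_sequences(seqs: dict, threshold: float) -> list[SeqCluster]:
    """Greedy incremental clustering of ``{id: sequence}`` at a threshold.

    Threshold comparisons are strict (identity must exceed the threshold),
    matching the database's "> 95%" / "> 40%" cluster levels.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[SeqCluster] = []
    for sid in order:
        seq = seqs[sid]
        placed = False
        for cl in clusters:
            rep_seq = cl.sequences[cl.representative]
            if seq == rep_seq or sequence_identity(seq, rep_seq) > threshold:
                cl.members.append(sid)
                cl.sequences[sid] = seq
                placed = True
                break
        if not placed:
            clusters.append(SeqCluster(representative=sid, members=[sid],
                                       identity_threshold=threshold,
                                       sequences={sid: seq}))
    return clusters


# ---------------------------------------------------------------------------
# MSA construction
# ---------------------------------------------------------------------------

def _center_star(cluster: SeqCluster) -> Msa:
    rep = cluster.representative
    rep_seq = cluster.sequences[rep]
    others = [m for m in cluster.members if m != rep]
    if not others:
        return Msa({rep: rep_seq})

    # pairwise alignments to the representative
    pair_alns = {m: _align_pair(rep_seq, cluster.sequences[m]) for m in others}

    # master gap pattern: for each rep position, the max insertion length
    # observed immediately before it (and at the end)
    ins = [0] * (len(rep_seq) + 1)
    for ga, _gb in pair_alns.values():
        pos = 0
        run = 0
        for ch in ga:
            if ch == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[len(rep_seq)] = max(ins[len(rep_seq)], run)

    def expand(ga: str, gb: str) -> str:
        """Re-space member row onto the master coordinates."""
        out = []
        pos = 0
        run_chars: list[str] = []
        for cha, chb in zip(ga, gb):
            if cha == "-":
                run_chars.append(chb)
            else:
                out.append("-" * (ins[pos] - len(run_chars)) + "".join(run_chars))
                run_chars = []
                out.append(chb)
                pos += 1
        out.append("-" * (ins[len(rep_seq)] - len(run_chars)) + "".join(run_chars))
        return "".join(out)

    rows = {rep: expand(rep_seq, rep_seq)}
    for m, (ga, gb) in pair_alns.items():
        rows[m] = expand(ga, gb)
    return Msa(rows)


def _run_mafft(cluster: SeqCluster) -> Msa:
    exe = shutil.which("mafft")
    if exe is None:
        raise FileNotFoundError("mafft not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        write_fasta(cluster.sequences, fin)
        proc = subprocess.run(
            [exe, "--localpair", "--maxiterate", "1000", "--quiet", str(fin)],
            capture_output=True, text=True, check=True)
        rows = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(__import__("io").StringIO(proc.stdout),
                                       "fasta")}
    return Msa(rows)


def build_msa(cluster: SeqCluster, aligner: str = "builtin") -> Msa:
    """Align a sequence cluster.

    ``aligner='mafft'`` runs the external L-INS-i aligner when available
    and falls back to the built-in center-star aligner with a warning.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    if aligner == "mafft":
        try:
            return _run_mafft(cluster)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            logger.warning("external aligner failed (%s); using built-in", exc)
    return _center_star(cluster)


def map_residues(msa: Msa, member_a: str, member_b: str) -> ResidueCorrespondence:
    """Pair residue positions of two members sharing ungapped MSA columns."""
    try:
        ra, rb = msa.rows[member_a], msa.rows[member_b]
    except KeyError as exc:
        raise KeyError(f"member {exc.args[0]!r} not in MSA") from exc
    pairs = {}
    pa = pb = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            pairs[pa] = pb
        if x != "-":
            pa += 1
        if y != "-":
            pb += 1
    return ResidueCorrespondence(pairs)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
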