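"""Sequence-side discovery funnel.

Filters tabular BLAST hits by identity and bidirectional coverage, clusters
sequences greedily at an identity cutoff (CD-HIT-style stand-in for
cascaded MMseqs2 clustering), and filters cluster representatives by the
presence of an arginine equivalent to the reference's substrate-binding
arginine (CvFAP R451), also reporting the other two conserved-triad
positions (C432, Y466).

Pairwise identity is computed from a Needleman-Wunsch global alignment
(BLOSUM62, gap open 11 / extend 1, via Biopython); identity = 100 x
matching columns / total alignment columns, gapped columns counted in the
denominator.  'X' never counts as an identity match.  Residue positions are
1-based throughout, matching the usual R451/C432/Y466 notation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "BlastHit",
    "SequenceRecord",
    "ClusterSet",
    "ConservationReport",
    "filter_hits",
    "pairwise_identity",
    "greedy_cluster",
    "conserved_residue_filter",
    "read_blast_table",
    "read_fasta",
    "write_fasta",
    "cluster_table",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

# 12-column BLAST outfmt 6, optionally extended with qlen/slen/qcovs/scovs.
OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]
EXTENDED_COLUMNS = OUTFMT6_COLUMNS + ["qlen", "slen", "qcovs", "scovs"]


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    qcov: float
    scov: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pct_identity", "qcov", "scov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_AA
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClusterSet:
    """Partition of sequences into identity clusters; representative first."""

    clusters: tuple[tuple[str, tuple[str, ...]], ...]
    identity_cutoff: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep, members in self.clusters:
            if rep not in members:
                raise ValueError(f"representative {rep!r} not among its members")
            for m in members:
                if m in seen:
                    raise ValueError(f"sequence {m!r} assigned to two clusters")
                seen.add(m)

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def assignment(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}


@dataclass(frozen=True)
class ConservationReport:
    sequence_id: str
    has_arg_equivalent: bool
    arg_column_residue: str
    cys432_equivalent: str
    tyr466_equivalent: str


# ---------------------------------------------------------------------------
# BLAST hit filtering
# ---------------------------------------------------------------------------

def filter_hits(hits: Sequence[BlastHit], min_identity: float = 30.0,
                min_cov: float = 80.0) -> list[BlastHit]:
    """Identity/bidirectional-coverage filter; stable order.

    Keeps hits with pct_identity >= min_identity and BOTH query and subject
    coverage >= min_cov ("bidirectional" read strictly: both directions).
    """
    return [h for h in hits
            if h.pct_identity >= min_identity
            and h.qcov >= min_cov and h.scov >= min_cov]


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _aligned_strings(a: str, b: str) -> tuple[str, str]:
    aln = _aligner().align(a, b)[0]
    return aln[0], aln[1]


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment percent identity over all alignment columns.

    Computed on a canonical ordering of the pair so the result is exactly
    symmetric regardless of dynamic-programming tie-breaks.
    """
    x, y = a.sequence, b.sequence
    if (x, a.id) > (y, b.id):
        x, y = y, x
    sa, sb = _aligned_strings(x, y)
    cols = len(sa)
    matches = sum(1 for ca, cb in zip(sa, sb)
                  if ca == cb and ca != "-" and ca != "X")
    return 100.0 * matches / cols


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def greedy_cluster(seqs: Sequence[SequenceRecord], cutoff: float = 70.0) -> ClusterSet:
    """Greedy set-cover clustering at an identity cutoff.

    Sequences are sorted by length descending (ties by id ascending); the
    longest unassigned sequence seeds a cluster and recruits every
    unassigned sequence with pairwise identity >= cutoff to it.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(seqs, key=lambda r: (-len(r), r.id))
    assigned: set[str] = set()
    clusters: list[tuple[str, tuple[str, ...]]] = []
    for i, rep in enumerate(order):
        if rep.id in assigned:
            continue
        members = [rep.id]
        assigned.add(rep.id)
        for cand in order[i + 1:]:
            if cand.id in assigned:
                continue
            if pairwise_identity(rep, cand) >= cutoff:
                members.append(cand.id)
                assigned.add(cand.id)
        clusters.append((rep.id, tuple(members)))
    return ClusterSet(tuple(clusters), identity_cutoff=cutoff)


# ---------------------------------------------------------------------------
# conserved-residue filter
# ---------------------------------------------------------------------------

def _map_reference_position(ref_aln: str, seq_aln: str, ref_pos: int) -> str:
    """Residue of the aligned sequence in the column of reference position
    ref_pos (1-based); '-' if the column is gapped or out of range."""
    count = 0
    for ca, cb in zip(ref_aln, seq_aln):
        if ca != "-":
            count += 1
            if count == ref_pos:
                return cb
    return "-"


def conserved_residue_filter(
        reps: Sequence[SequenceRecord], reference: SequenceRecord,
        ref_pos: int = 451, residue: str = "R",
        triad_positions: tuple[int, int] = (432, 466),
) -> tuple[list[SequenceRecord], list[ConservationReport]]:
    """Keep representatives whose alignment column at the reference's
    position ``ref_pos`` holds exactly ``residue``.

    Each representative is globally aligned to the reference; a gap or any
    other residue in the mapped column fails.  The report also records the
    residues equivalent to the other two conserved-triad positions
    (defaults 432 and 466).
    """
    if not 1 <= ref_pos <= len(reference):
        raise ValueError(f"ref_pos={ref_pos} beyond reference length {len(reference)}")
    kept: list[SequenceRecord] = []
    reports: list[ConservationReport] = []
    for rep in reps:
        ref_aln, rep_aln = _aligned_strings(reference.sequence, rep.sequence)
        at = _map_reference_position(ref_aln, rep_aln, ref_pos)
        c_eq = (_map_reference_position(ref_aln, rep_aln, triad_positions[0])
                if triad_positions[0] <= len(reference) else "-")
        y_eq = (_map_reference_position(ref_aln, rep_aln, triad_positions[1])
                if triad_positions[1] <= len(reference) else "-")
        has_arg = at == residue
        reports.append(ConservationReport(rep.id, has_arg, at, c_eq, y_eq))
        if has_arg:
            kept.append(rep)
    return kept, reports


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_blast_table(path, columns: Optional[list[str]] = None) -> list[BlastHit]:
    """Read a headerless BLAST tabular file (outfmt 6 or extended).

    If coverage columns (qcovs/scovs) are absent they are computed from the
    aligned spans and qlen/slen; without either, the table cannot supply
    coverage and a ValueError is raised.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if columns is None:
        if df.shape[1] == len(OUTFMT6_COLUMNS):
            columns = OUTFMT6_COLUMNS
        elif df.shape[1] == len(EXTENDED_COLUMNS):
            columns = EXTENDED_COLUMNS
        elif df.shape[1] == len(OUTFMT6_COLUMNS) + 2:
            columns = OUTFMT6_COLUMNS + ["qlen", "slen"]
        else:
            raise ValueError(f"unrecognized BLAST table width: {df.shape[1]} columns")
    df.columns = columns
    if "qcovs" not in df.columns:
        if not {"qlen", "slen"} <= set(df.columns):
            raise ValueError("need qcovs/scovs or qlen/slen to derive coverage")
        df["qcovs"] = 100.0 * ((df.qend - df.qstart).abs() + 1) / df.qlen
        df["scovs"] = 100.0 * ((df.send - df.sstart).abs() + 1) / df.slen
    hits = [BlastHit(str(r.qseqid), str(r.sseqid), float(r.pident),
                     int(r.length), float(r.qcovs), float(r.scovs),
                     float(r.evalue))
            for r in df.itertuples(index=False)]
    return hits


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, path, "fasta")


def cluster_table(cs: ClusterSet) -> pd.DataFrame:
    rows = [{"representative_id": rep, "member_id": m}
            for rep, members in cs.clusters for m in members]
    return pd.DataFrame(rows, columns=["representative_id", "member_id"])
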