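"""Codon-aware pairwise alignment and per-column site classification.

CDS pairs are aligned through their protein translations (global alignment,
BLOSUM62) and back-mapped to nucleotides, so indels land in whole codons at
codon boundaries; gap columns are then removed, mirroring the usual
align-then-trim workflow. UTRs are aligned directly at the nucleotide level
with affine gaps (gap columns kept, excluded via the comparable flag).

Every aligned column is labelled with its region (5'UTR / CDS / 3'UTR),
its codon degeneracy class (non-degenerate, fourfold, other, noncoding) and
a CpG-context flag. CpG context is the union over the two extant sequences:
a column is CpG if, in either ungapped sequence, the base participates in a
CG dinucleotide (no ancestral sequence is available, and the union keeps
the statistic symmetric in the two species; an intersection mode is
provided as a switch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codons import (
    FOURFOLD_PREFIXES,
    STOP_CODONS,
    is_nondegenerate,
    translate_cds,
)
from .errors import ValidationError
from .orf import strip_stop
from .seqio import TranscriptRecord

REGION_LABELS = ("utr5", "cds", "utr3")
DEGENERACY_LABELS = ("nd", "fourfold", "other", "noncoding")


@dataclass
class PairAlignment:
    """A pairwise transcript (or single-region) alignment with per-column
    region labels and back-references into the ungapped sequences.

    pos_a/pos_b give, per column, the 0-based index into the full ungapped
    sequence of each species (-1 at gap columns); they are what the CpG
    classifier uses to look up dinucleotide neighbours.
    """

    pair_id: str
    a_aln: str
    b_aln: str
    region: np.ndarray  # per-column label from REGION_LABELS
    pos_a: np.ndarray
    pos_b: np.ndarray
    seq_a: str  # full ungapped sequence of species A
    seq_b: str

    def __post_init__(self) -> None:
        n = len(self.a_aln)
        if len(self.b_aln) != n or len(self.region) != n:
            raise ValidationError("PairAlignment: column arrays differ in length")

    def __len__(self) -> int:
        return len(self.a_aln)

    @property
    def codon_pos(self) -> np.ndarray:
        """Position-in-codon (0/1/2) per CDS column, -1 elsewhere.

        Valid because CDS gaps are codon-sized and codon-aligned.
        """
        out = np.full(len(self), -1, dtype=int)
        idx = np.flatnonzero(self.region == "cds")
        out[idx] = np.arange(len(idx)) % 3
        return out

    def cds_columns(self) -> np.ndarray:
        return np.flatnonzero(self.region == "cds")


@dataclass
class SitePartition:
    """Per-column comparability, degeneracy class and CpG flag."""

    comparable: np.ndarray  # bool: no gap and no N in either sequence
    degeneracy: np.ndarray  # label from DEGENERACY_LABELS
    cpg: np.ndarray  # bool


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _nuc_global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _check_cds(cds: str, which: str) -> str:
    cds = strip_stop(cds)
    if len(cds) % 3 != 0:
        raise ValidationError(f"{which}: CDS length {len(cds)} not a multiple of 3")
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in STOP_CODONS:
            raise ValidationError(f"{which}: internal stop codon at {i}")
    return cds


def align_cds_pair(
    cds_a: str, cds_b: str, remove_gap_columns: bool = True
) -> tuple[str, str]:
    """Protein-guided codon alignment of two CDSs.

    Trailing stop codons are stripped; internal stops are an error. The
    protein global alignment is back-mapped to nucleotides so gaps occur in
    codon-sized blocks; with `remove_gap_columns` (default) gap columns are
    then dropped, leaving both rows equal-length and in frame.
    """
    cds_a = _check_cds(cds_a, "cds_a")
    cds_b = _check_cds(cds_b, "cds_b")
    if not cds_a or not cds_b:
        raise ValidationError("align_cds_pair: empty CDS")
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    aln = _protein_aligner().align(prot_a.replace("*", "X"), prot_b.replace("*", "X"))[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    a_nt = "".join(out_a)
    b_nt = "".join(out_b)
    if remove_gap_columns:
        keep = [i for i in range(len(a_nt)) if a_nt[i] != "-" and b_nt[i] != "-"]
        a_nt = "".join(a_nt[i] for i in keep)
        b_nt = "".join(b_nt[i] for i in keep)
    return a_nt, b_nt


def align_nucleotide_pair(a: str, b: str) -> tuple[str, str]:
    """Direct global nucleotide alignment with affine gaps (UTRs)."""
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    aln = _nuc_global_aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _positions(gapped: str, offset: int) -> np.ndarray:
    """Map each alignment column to its ungapped index (+offset), -1 at gaps."""
    out = np.full(len(gapped), -1, dtype=int)
    i = 0
    for col, ch in enumerate(gapped):
        if ch != "-":
            out[col] = offset + i
            i += 1
    return out


def build_pair_alignment(
    rec_a: TranscriptRecord, rec_b: TranscriptRecord, pair_id: str | None = None
) -> PairAlignment:
    """Align the three regions of an annotated ortholog pair and concatenate
    them into one column-labelled alignment.

    Both records must carry region annotations. The CDS block is gap-free
    (gap columns removed); UTR blocks keep their gaps.
    """
    if rec_a.regions is None or rec_b.regions is None:
        raise ValidationError("build_pair_alignment: both records need regions")
    pid = pair_id or f"{rec_a.id}|{rec_b.id}"

    parts_a: list[str] = []
    parts_b: list[str] = []
    labels: list[np.ndarray] = []
    pos_a_parts: list[np.ndarray] = []
    pos_b_parts: list[np.ndarray] = []

    u5a, u5b = align_nucleotide_pair(rec_a.utr5, rec_b.utr5)
    if rec_a.cds or rec_b.cds:
        cda, cdb = align_cds_pair(rec_a.cds, rec_b.cds)
    else:
        cda = cdb = ""
    u3a, u3b = align_nucleotide_pair(rec_a.utr3, rec_b.utr3)

    for region, (ga, gb), (offa, offb) in (
        ("utr5", (u5a, u5b), (rec_a.regions.utr5[0], rec_b.regions.utr5[0])),
        ("cds", (cda, cdb), (rec_a.regions.cds[0], rec_b.regions.cds[0])),
        ("utr3", (u3a, u3b), (rec_a.regions.utr3[0], rec_b.regions.utr3[0])),
    ):
        parts_a.append(ga)
        parts_b.append(gb)
        labels.append(np.full(len(ga), region, dtype="<U5"))
        pos_a_parts.append(_positions(ga, offa))
        pos_b_parts.append(_positions(gb, offb))

    return PairAlignment(
        pair_id=pid,
        a_aln="".join(parts_a),
        b_aln="".join(parts_b),
        region=np.concatenate(labels) if labels else np.array([], dtype="<U5"),
        pos_a=np.concatenate(pos_a_parts),
        pos_b=np.concatenate(pos_b_parts),
        seq_a=rec_a.seq,
        seq_b=rec_b.seq,
    )


def ungapped_pair_alignment(
    rec_a: TranscriptRecord, rec_b: TranscriptRecord, pair_id: str | None = None
) -> PairAlignment:
    """Column-wise alignment of two equal-length, identically partitioned
    records (no alignment search). Used for simulator output, where the two
    sequences descend from one ancestor without indels."""
    if rec_a.regions is None or rec_b.regions is None:
        raise ValidationError("ungapped_pair_alignment: both records need regions")
    if len(rec_a) != len(rec_b) or rec_a.regions != rec_b.regions:
        raise ValidationError("ungapped_pair_alignment: records not colinear")
    n = len(rec_a)
    region = np.full(n, "", dtype="<U5")
    for name in REGION_LABELS:
        s, e = getattr(rec_a.regions, name)
        region[s:e] = name
    pos = np.arange(n)
    return PairAlignment(
        pair_id=pair_id or f"{rec_a.id}|{rec_b.id}",
        a_aln=rec_a.seq,
        b_aln=rec_b.seq,
        region=region,
        pos_a=pos,
        pos_b=pos.copy(),
        seq_a=rec_a.seq,
        seq_b=rec_b.seq,
    )


def comparable_mask(aln: PairAlignment) -> np.ndarray:
    """No gap and no N in either sequence; CDS columns additionally require
    both full codons free of gaps and N (codon context must be readable)."""
    a = np.frombuffer(aln.a_aln.encode(), dtype="S1")
    b = np.frombuffer(aln.b_aln.encode(), dtype="S1")
    ok = (a != b"-") & (b != b"-") & (a != b"N") & (b != b"N")
    cds_idx = aln.cds_columns()
    if len(cds_idx):
        tri = ok[cds_idx].reshape(-1, 3)
        codon_ok = tri.all(axis=1)
        ok[cds_idx] = np.repeat(codon_ok, 3)
    return ok


def _codon_at(aln: PairAlignment, cds_idx: np.ndarray, codon_i: int) -> tuple[str, str]:
    cols = cds_idx[3 * codon_i : 3 * codon_i + 3]
    ca = "".join(aln.a_aln[c] for c in cols)
    cb = "".join(aln.b_aln[c] for c in cols)
    return ca, cb


def classify_degeneracy(aln: PairAlignment, comparable: np.ndarray | None = None) -> np.ndarray:
    """Per-column degeneracy labels.

    fourfold: 3rd codon position whose two-base prefix is identical across
    the pair and is a fourfold family. nd: every sense single-nucleotide
    change at that position is nonsynonymous in both codon contexts.
    Remaining CDS columns are 'other'; non-CDS columns are 'noncoding'.
    """
    if comparable is None:
        comparable = comparable_mask(aln)
    out = np.full(len(aln), "noncoding", dtype="<U9")
    cds_idx = aln.cds_columns()
    if not len(cds_idx):
        return out
    out[cds_idx] = "other"
    for codon_i in range(len(cds_idx) // 3):
        cols = cds_idx[3 * codon_i : 3 * codon_i + 3]
        if not comparable[cols].all():
            continue
        ca, cb = _codon_at(aln, cds_idx, codon_i)
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        for p in range(3):
            if is_nondegenerate(ca, p) and is_nondegenerate(cb, p):
                out[cols[p]] = "nd"
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            out[cols[2]] = "fourfold"
    return out


def classify_cpg(aln: PairAlignment, mode: str = "union") -> np.ndarray:
    """Per-column CpG-context flags.

    A column is CpG when the base at that position participates in a CG
    dinucleotide in either ungapped sequence (`mode="union"`, default) or
    in both (`mode="both"`). First/last positions use only the available
    neighbour. Symmetric in the two sequences.
    """
    if mode not in ("union", "both"):
        raise ValidationError(f"classify_cpg: unknown mode {mode!r}")

    def flags(seq: str, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        n = len(seq)
        for col, p in enumerate(pos):
            if p < 0:
                continue
            base = seq[p]
            if base == "C" and p + 1 < n and seq[p + 1] == "G":
                out[col] = True
            elif base == "G" and p - 1 >= 0 and seq[p - 1] == "C":
                out[col] = True
        return out

    fa = flags(aln.seq_a, aln.pos_a)
    fb = flags(aln.seq_b, aln.pos_b)
    return (fa | fb) if mode == "union" else (fa & fb)


def classify_sites(aln: PairAlignment, cpg_mode: str = "union") -> SitePartition:
    comparable = comparable_mask(aln)
    return SitePartition(
        comparable=comparable,
        degeneracy=classify_degeneracy(aln, comparable),
        cpg=classify_cpg(aln, mode=cpg_mode),
    )


def codon_pairs(aln: PairAlignment, comparable: np.ndarray | None = None) -> list[tuple[str, str]]:
    """Comparable sense-codon pairs of the CDS block (inputs to Ka/Ks)."""
    if comparable is None:
        comparable = comparable_mask(aln)
    cds_idx = aln.cds_columns()
    out = []
    for codon_i in range(len(cds_idx) // 3):
        cols = cds_idx[3 * codon_i : 3 * codon_i + 3]
        if not comparable[cols].all():
            continue
        ca, cb = _codon_at(aln, cds_idx, codon_i)
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        out.append((ca, cb))
    return out


def write_partition_tsv(aln: PairAlignment, part: SitePartition, path) -> None:
    """BED-like per-column dump: pair_id, column, region, degeneracy, cpg,
    comparable (0-based)."""
    with open(path, "w") as fh:
        fh.write("pair_id\tcolumn\tregion\tdegeneracy\tcpg\tcomparable\n")
        for i in range(len(aln)):
            fh.write(
                f"{aln.pair_id}\t{i}\t{aln.region[i]}\t{part.degeneracy[i]}\t"
                f"{int(part.cpg[i])}\t{int(part.comparable[i])}\n"
            )
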