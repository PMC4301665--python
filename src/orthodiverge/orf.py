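"""ORF prediction and transcript region annotation.

Transcripts are partitioned into 5'UTR / CDS / 3'UTR from the top-ranked
open reading frame (longest first — the standard transcript-CDS heuristic).
ORFs are ATG -> stop on either strand; 3'-incomplete ORFs (no stop before
the transcript end, common in pyrosequencing assemblies) are accepted and
clipped to the last full codon. Codon-position GC ("cusp"-style) is computed
over a pooled CDS set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .codons import CODON_TO_AA, STOP_CODONS, revcomp
from .errors import ValidationError
from .seqio import Regions, TranscriptRecord

START_CODON = "ATG"


@dataclass(frozen=True)
class OrfCall:
    """One ORF on a transcript; coordinates are 0-based half-open on the
    stored sequence. `has_stop` is False for 3'-incomplete ORFs."""

    transcript_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    has_stop: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodonPositionGC:
    """Pooled GC%% at codon positions 1/2/3 and overall, over a CDS set."""

    gc1: float
    gc2: float
    gc3: float
    gc_all: float


def _scan_strand(seq: str, min_len_nt: int, allow_partial: bool) -> list[tuple[int, int, bool]]:
    """ATG->stop intervals (start, end, has_stop) on the forward reading of `seq`."""
    out = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon == START_CODON:
                starts.append(i)
            elif codon in STOP_CODONS:
                for s in starts:
                    if i + 3 - s >= min_len_nt:
                        out.append((s, i + 3, True))
                starts = []
            i += 3
        if allow_partial and starts:
            end = i  # last full codon boundary in this frame
            for s in starts:
                if end - s >= min_len_nt:
                    out.append((s, end, False))
    return out


def _protein(seq: str, start: int, end: int, has_stop: bool) -> str:
    cds = seq[start : end - 3] if has_stop else seq[start:end]
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def find_orfs(
    record: TranscriptRecord,
    min_len_nt: int = 150,
    allow_partial: bool = True,
) -> list[OrfCall]:
    """All ATG->stop ORFs >= `min_len_nt` on both strands, longest first;
    ties broken by (+ strand first, then smaller start)."""
    if min_len_nt < 6 or min_len_nt % 3 != 0:
        raise ValidationError("min_len_nt must be >= 6 and a multiple of 3")
    seq = record.seq
    n = len(seq)
    calls: list[OrfCall] = []
    for s, e, has_stop in _scan_strand(seq, min_len_nt, allow_partial):
        calls.append(
            OrfCall(record.id, s, e, "+", s % 3, _protein(seq, s, e, has_stop), has_stop)
        )
    rc = revcomp(seq)
    for s, e, has_stop in _scan_strand(rc, min_len_nt, allow_partial):
        calls.append(
            OrfCall(
                record.id, n - e, n - s, "-", s % 3, _protein(rc, s, e, has_stop), has_stop
            )
        )
    calls.sort(key=lambda c: (-c.length, c.strand != "+", c.start))
    return calls


def annotate_transcript(
    record: TranscriptRecord,
    min_len_nt: int = 150,
    allow_partial: bool = True,
) -> TranscriptRecord | None:
    """Set regions from the top-ranked ORF.

    If the best ORF is on the minus strand the stored sequence is
    reverse-complemented first, so regions are always forward. Returns None
    when no ORF reaches `min_len_nt` (the transcript is non-coding for all
    CDS analyses).
    """
    orfs = find_orfs(record, min_len_nt=min_len_nt, allow_partial=allow_partial)
    if not orfs:
        return None
    top = orfs[0]
    seq = record.seq
    start, end = top.start, top.end
    if top.strand == "-":
        seq = revcomp(seq)
        start, end = len(seq) - top.end, len(seq) - top.start
    regions = Regions(utr5=(0, start), cds=(start, end), utr3=(end, len(seq)))
    return TranscriptRecord(id=record.id, seq=seq, regions=regions)


def annotate_set(
    records: Iterable[TranscriptRecord],
    min_len_nt: int = 150,
    coords: dict[str, tuple[int, int, str]] | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Annotate a whole set; returns (coding, non_coding).

    When `coords` provides a CDS interval for a record it overrides ORF
    prediction (minus-strand coordinates are applied after
    reverse-complementing).
    """
    coding, non_coding = [], []
    for rec in records:
        if coords and rec.id in coords:
            s, e, strand = coords[rec.id]
            seq = rec.seq if strand == "+" else revcomp(rec.seq)
            if strand == "-":
                s, e = len(seq) - e, len(seq) - s
            regions = Regions(utr5=(0, s), cds=(s, e), utr3=(e, len(seq)))
            coding.append(TranscriptRecord(id=rec.id, seq=seq, regions=regions))
            continue
        ann = annotate_transcript(rec, min_len_nt=min_len_nt)
        if ann is None:
            non_coding.append(rec)
        else:
            coding.append(ann)
    return coding, non_coding


def strip_stop(cds: str) -> str:
    """Remove a trailing stop codon if present."""
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def codon_position_gc(cds_set: Sequence[str]) -> CodonPositionGC:
    """Pooled GC%% at each codon position over a set of in-frame CDSs.

    N bases are excluded from numerator and denominator of their position.
    """
    gc = [0, 0, 0]
    tot = [0, 0, 0]
    for cds in cds_set:
        if len(cds) % 3 != 0:
            raise ValidationError(f"CDS length {len(cds)} is not a multiple of 3")
        for i, base in enumerate(cds.upper()):
            pos = i % 3
            if base in "GC":
                gc[pos] += 1
                tot[pos] += 1
            elif base in "AT":
                tot[pos] += 1
    pct = [100.0 * g / t if t else 0.0 for g, t in zip(gc, tot)]
    all_tot = sum(tot)
    gc_all = 100.0 * sum(gc) / all_tot if all_tot else 0.0
    return CodonPositionGC(gc1=pct[0], gc2=pct[1], gc3=pct[2], gc_all=gc_all)
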