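"""Transcript data model, FASTA/TSV readers and writers, and assembly
summary statistics (N50/N90, base composition, GC content).

Sequences are stored upper-case over the alphabet {A, C, G, T, N}; RNA input
(U) is normalised to T at parse time. Region annotations partition a
transcript into 5'UTR / CDS / 3'UTR as half-open intervals on the stored
(forward) orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ParseError, UndefinedStatisticError, ValidationError

_ALLOWED = frozenset("ACGTN")


@dataclass(frozen=True)
class Regions:
    """Half-open 5'UTR / CDS / 3'UTR intervals tiling [0, len(seq))."""

    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def validate(self, seq_len: int) -> None:
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (0 == u5[0] <= u5[1] == c[0] <= c[1] == u3[0] <= u3[1] == seq_len):
            raise ValidationError(
                f"regions {u5}/{c}/{u3} do not tile [0,{seq_len}) in order"
            )
        if (c[1] - c[0]) % 3 != 0:
            raise ValidationError(f"CDS length {c[1] - c[0]} is not a multiple of 3")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: unique id, nucleotide sequence, optional region partition."""

    id: str
    seq: str
    regions: Regions | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        norm = self.seq.upper().replace("U", "T")
        bad = set(norm) - _ALLOWED
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", norm)
        if self.regions is not None:
            self.regions.validate(len(norm))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def utr5(self) -> str:
        self._require_regions()
        return self.seq[self.regions.utr5[0] : self.regions.utr5[1]]

    @property
    def cds(self) -> str:
        self._require_regions()
        return self.seq[self.regions.cds[0] : self.regions.cds[1]]

    @property
    def utr3(self) -> str:
        self._require_regions()
        return self.seq[self.regions.utr3[0] : self.regions.utr3[1]]

    def with_regions(self, regions: Regions | None) -> "TranscriptRecord":
        return replace(self, regions=regions)

    def _require_regions(self) -> None:
        if self.regions is None:
            raise ValidationError(f"record {self.id!r} has no region annotation")


@dataclass(frozen=True)
class AssemblySummary:
    n_seqs: int
    total_bp: int
    mean_len: float
    longest: int
    n50: int
    n90: int
    base_fracs: dict[str, float]
    gc_percent: float

    def to_dict(self) -> dict:
        return {
            "n_seqs": self.n_seqs,
            "total_bp": self.total_bp,
            "mean_len": self.mean_len,
            "longest": self.longest,
            "n50": self.n50,
            "n90": self.n90,
            "base_fracs": self.base_fracs,
            "gc_percent": self.gc_percent,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["item\tvalue"]
        d = self.to_dict()
        fracs = d.pop("base_fracs")
        for k, v in d.items():
            lines.append(f"{k}\t{v}")
        for base, frac in fracs.items():
            lines.append(f"frac_{base}\t{frac}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a multi-FASTA file into TranscriptRecords.

    Sequences are upper-cased and U is mapped to T; duplicate ids and
    characters outside {A,C,G,T,N,U} are rejected.
    """
    path = Path(path)
    # SeqIO silently ignores leading junk; check the header structure ourselves
    # so malformed files fail with a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")

    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(TranscriptRecord(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def assembly_summary(records: Sequence[TranscriptRecord]) -> AssemblySummary:
    """Summary statistics over a transcript set.

    N50 (N90) is the length of the shortest sequence in the smallest
    descending-length prefix whose cumulative length reaches 50% (90%) of
    the total.
    """
    if not records:
        raise ValidationError("assembly_summary: empty record list")
    lengths = np.sort(np.array([len(r) for r in records]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, 0.5 * total)])
    n90 = int(lengths[np.searchsorted(cum, 0.9 * total)])

    counts = {b: 0 for b in "ATCGN"}
    for rec in records:
        for b in counts:
            counts[b] += rec.seq.count(b)
    fracs = {b: counts[b] / total for b in counts}
    non_n = total - counts["N"]
    if non_n == 0:
        raise UndefinedStatisticError("assembly_summary: all bases are N")
    gc = 100.0 * (counts["G"] + counts["C"]) / non_n
    return AssemblySummary(
        n_seqs=len(records),
        total_bp=total,
        mean_len=total / len(records),
        longest=int(lengths[0]),
        n50=n50,
        n90=n90,
        base_fracs=fracs,
        gc_percent=gc,
    )


def gc_content(seq: str) -> float:
    """GC percentage of a sequence; N excluded from the denominator."""
    seq = seq.upper().replace("U", "T")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise UndefinedStatisticError("gc_content: no A/C/G/T bases")
    return 100.0 * gc / (gc + at)


def read_cds_coords(path: str | Path) -> dict[str, tuple[int, int, str]]:
    """Read a CDS-coordinate TSV (`id  cds_start  cds_end  strand`, 0-based
    half-open) used to override ORF prediction."""
    out: dict[str, tuple[int, int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 tab-separated fields")
            tid, start, end, strand = parts
            if strand not in "+-":
                raise ParseError(f"{path}: line {lineno}: strand must be + or -")
            out[tid] = (int(start), int(end), strand)
    return out
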