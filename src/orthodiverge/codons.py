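"""Genetic-code tables and small nucleotide helpers.

All codon bookkeeping in the package (degeneracy classes, NG86 site and
pathway counting, the simulator's selection filter) goes through the
standard genetic code as published in Biopython's codon table #1.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: sense codon -> one-letter amino acid, standard code (61 entries)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T. Identical bases are not a transition."""
    if a == b:
        return False
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no internal stops checked here); '*' for stops."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aas.append("X")
        else:
            aas.append(CODON_TO_AA.get(codon, "*"))
    return "".join(aas)


@lru_cache(maxsize=None)
def codon_neighbors(codon: str, pos: int) -> tuple[str, ...]:
    """The three codons differing from `codon` only at `pos` (stops included)."""
    return tuple(
        codon[:pos] + nt + codon[pos + 1 :] for nt in NUCLEOTIDES if nt != codon[pos]
    )


def _fourfold_prefixes() -> frozenset[str]:
    out = set()
    for p1 in NUCLEOTIDES:
        for p2 in NUCLEOTIDES:
            fam = [p1 + p2 + nt for nt in NUCLEOTIDES]
            aas = {CODON_TO_AA.get(c) for c in fam}
            if len(aas) == 1 and None not in aas:
                out.add(p1 + p2)
    return frozenset(out)


#: two-base prefixes whose four codons all encode the same amino acid
FOURFOLD_PREFIXES: frozenset[str] = _fourfold_prefixes()


@lru_cache(maxsize=None)
def is_nondegenerate(codon: str, pos: int) -> bool:
    """True when every single-nucleotide change at `pos` that yields a sense
    codon changes the amino acid (changes to stop codons are ignored)."""
    aa = CODON_TO_AA[codon]
    saw_sense_neighbor = False
    for nb in codon_neighbors(codon, pos):
        if nb in STOP_CODONS:
            continue
        saw_sense_neighbor = True
        if CODON_TO_AA[nb] == aa:
            return False
    return saw_sense_neighbor
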