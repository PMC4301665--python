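"""Reciprocal-best-hit orthology between two transcript sets.

Candidate pairs are screened with a shared k-mer seed filter (11-mers at the
nucleotide level, 4-mers over six-frame translations) and then scored with a
local Smith-Waterman alignment (Bio.Align.PairwiseAligner). Orthologs are
reciprocal best hits with a continuous aligned region covering >= 50% of the
query in each direction; queries with no nucleotide-level partner are
re-screened at the translated level, after dropping those shorter than
250 bp (too short to translate reliably). One-to-one pairs are those where
each member is the other's unique best hit; everything else paired is
flagged as paralog-involved.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .codons import revcomp, translate_cds
from .errors import ValidationError
from .seqio import TranscriptRecord

log = logging.getLogger(__name__)

NUC_SEED_K = 11
PROT_SEED_K = 4
DEFAULT_MIN_SCORE = {"nucleotide": 50.0, "translated": 50.0}


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    matched_len: int  # bp of the aligned continuous region on the query
    query_cov: float
    level: str  # "nucleotide" | "translated"


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    relationship: str  # "one_to_one" | "many"
    level: str
    score: float
    cov_a: float
    cov_b: float


@dataclass
class OrthologyResult:
    pairs: list[OrthologPair]
    too_short_ids: list[str]
    inventory: dict[str, int] = field(default_factory=dict)


def _nuc_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _prot_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _six_frames(seq: str) -> list[str]:
    frames = []
    for s in (seq, revcomp(seq)):
        for f in range(3):
            frames.append(translate_cds(s[f:]))
    return frames


def _query_span(alignment) -> tuple[int, int]:
    blocks = alignment.aligned[0]
    return int(blocks[0][0]), int(blocks[-1][1])


def _align_nucleotide(aligner, query: str, subject: str) -> tuple[float, int]:
    aln = aligner.align(query, subject)[0]
    qs, qe = _query_span(aln)
    return float(aln.score), qe - qs


def _best_translated(prot_aligner, q_frames, s_frames) -> tuple[float, int]:
    """Best (score, matched aa length on query frame) over 6x6 frame pairs
    sharing a protein seed."""
    best = (float("-inf"), 0)
    for qf in q_frames:
        q_kmers = _kmer_set(qf, PROT_SEED_K)
        if not q_kmers:
            continue
        for sf in s_frames:
            if len(sf) < PROT_SEED_K or not (q_kmers & _kmer_set(sf, PROT_SEED_K)):
                continue
            aln = prot_aligner.align(qf, sf)[0]
            qs, qe = _query_span(aln)
            cand = (float(aln.score), qe - qs)
            if cand > best:
                best = cand
    return best


def similarity_search(
    queries: Sequence[TranscriptRecord],
    subjects: Sequence[TranscriptRecord],
    level: str = "nucleotide",
    min_score: float | None = None,
) -> list[SimilarityHit]:
    """Seed-filtered local-alignment search of every query against subjects.

    Nucleotide level: pairs must share an 11-mer; match/mismatch scoring
    with affine gaps. Translated level: all 6x6 reading-frame pairs under
    BLOSUM62, best frame pair reported; pairs must share a protein 4-mer.
    """
    if not queries or not subjects:
        raise ValidationError("similarity_search: empty query or subject set")
    if level not in ("nucleotide", "translated"):
        raise ValidationError(f"unknown search level {level!r}")
    if min_score is None:
        min_score = DEFAULT_MIN_SCORE[level]

    hits: list[SimilarityHit] = []
    if level == "nucleotide":
        aligner = _nuc_aligner()
        index: dict[str, set[int]] = defaultdict(set)
        for j, sub in enumerate(subjects):
            for kmer in _kmer_set(sub.seq, NUC_SEED_K):
                index[kmer].add(j)
        # also seed against the subject's reverse complement
        rc_cache = [revcomp(s.seq) for s in subjects]
        for j, rc in enumerate(rc_cache):
            for kmer in _kmer_set(rc, NUC_SEED_K):
                index[kmer].add(j)
        for q in queries:
            cands: set[int] = set()
            for kmer in _kmer_set(q.seq, NUC_SEED_K):
                cands |= index.get(kmer, set())
            for j in sorted(cands):
                sub = subjects[j]
                score_f, mlen_f = _align_nucleotide(aligner, q.seq, sub.seq)
                score_r, mlen_r = _align_nucleotide(aligner, q.seq, rc_cache[j])
                score, mlen = max((score_f, mlen_f), (score_r, mlen_r))
                if score >= min_score:
                    hits.append(
                        SimilarityHit(
                            q.id, sub.id, score, mlen, mlen / len(q), "nucleotide"
                        )
                    )
    else:
        prot_aligner = _prot_aligner()
        subj_frames = {s.id: _six_frames(s.seq) for s in subjects}
        for q in queries:
            q_frames = _six_frames(q.seq)
            for sub in subjects:
                score, aa_len = _best_translated(prot_aligner, q_frames, subj_frames[sub.id])
                if score >= min_score:
                    mlen = min(3 * aa_len, len(q))
                    hits.append(
                        SimilarityHit(
                            q.id, sub.id, score, mlen, mlen / len(q), "translated"
                        )
                    )
    return hits


def best_hits(hits: Iterable[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query: highest score, then longest matched region, then
    lexicographically smallest subject id (determinism)."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (h.score, h.matched_len, _NegStr(h.subject_id))
        key_cur = (cur.score, cur.matched_len, _NegStr(cur.subject_id))
        if key_new > key_cur:
            best[h.query_id] = h
    return best


class _NegStr(str):
    """Reverses string ordering so max() prefers the lexicographically
    smaller subject id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def reciprocal_best_hits(
    hits_ab: Iterable[SimilarityHit],
    hits_ba: Iterable[SimilarityHit],
    min_query_cov: float = 0.5,
) -> list[OrthologPair]:
    """Emit (a, b) when b is a's best hit and a is b's best hit, each
    direction covering >= `min_query_cov` of its query.

    relationship is one_to_one only when b is the best hit of no other A
    query and a is the best hit of no other B query.
    """
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    # how many queries chose each subject as their best hit
    chosen_b = defaultdict(int)
    for h in best_ab.values():
        chosen_b[h.subject_id] += 1
    chosen_a = defaultdict(int)
    for h in best_ba.values():
        chosen_a[h.subject_id] += 1

    pairs = []
    for a_id, hab in sorted(best_ab.items()):
        hba = best_ba.get(hab.subject_id)
        if hba is None or hba.subject_id != a_id:
            continue
        if hab.query_cov < min_query_cov or hba.query_cov < min_query_cov:
            continue
        rel = (
            "one_to_one"
            if chosen_b[hab.subject_id] == 1 and chosen_a[a_id] == 1
            else "many"
        )
        pairs.append(
            OrthologPair(
                id_a=a_id,
                id_b=hab.subject_id,
                relationship=rel,
                level=hab.level,
                score=hab.score,
                cov_a=hab.query_cov,
                cov_b=hba.query_cov,
            )
        )
    return pairs


def translated_rescue(
    unmatched: Sequence[TranscriptRecord],
    subjects: Sequence[TranscriptRecord],
    min_translate_bp: int = 250,
    min_query_cov: float = 0.5,
) -> tuple[list[OrthologPair], list[str]]:
    """Second-pass translated search for queries with no nucleotide pair.

    Queries shorter than `min_translate_bp` are dropped (returned as the
    too-short id list); the rest go through a translated reciprocal best
    hit against the subjects.
    """
    too_short = [r.id for r in unmatched if len(r) < min_translate_bp]
    retained = [r for r in unmatched if len(r) >= min_translate_bp]
    log.info(
        "translated rescue: %d queries dropped as < %d bp, %d retained",
        len(too_short), min_translate_bp, len(retained),
    )
    if not retained:
        return [], too_short
    hits_ab = similarity_search(retained, subjects, level="translated")
    hits_ba = similarity_search(subjects, retained, level="translated")
    pairs = reciprocal_best_hits(hits_ab, hits_ba, min_query_cov=min_query_cov)
    return pairs, too_short


def classify_inventory(
    pairs: Sequence[OrthologPair],
    set_a: Sequence[TranscriptRecord],
    set_b: Sequence[TranscriptRecord],
    too_short_ids: Sequence[str] = (),
) -> dict[str, int]:
    """Assign every A transcript exactly one category; categories partition
    set_a: paired (= one_to_one + many) + too_short + species_specific."""
    paired_a = {p.id_a for p in pairs}
    too_short = set(too_short_ids) - paired_a
    n_one = sum(1 for p in pairs if p.relationship == "one_to_one")
    n_many = len(pairs) - n_one
    species_specific = [
        r.id for r in set_a if r.id not in paired_a and r.id not in too_short
    ]
    counts = {
        "paired": len(paired_a),
        "one_to_one": n_one,
        "many": n_many,
        "too_short": len(too_short),
        "species_specific": len(species_specific),
    }
    assert counts["paired"] + counts["too_short"] + counts["species_specific"] == len(set_a)
    return counts


def find_orthologs(
    set_a: Sequence[TranscriptRecord],
    set_b: Sequence[TranscriptRecord],
    min_query_cov: float = 0.5,
    min_translate_bp: int = 250,
) -> OrthologyResult:
    """Full two-pass orthology: nucleotide RBH, then translated rescue."""
    hits_ab = similarity_search(set_a, set_b, level="nucleotide")
    hits_ba = similarity_search(set_b, set_a, level="nucleotide")
    pairs = reciprocal_best_hits(hits_ab, hits_ba, min_query_cov=min_query_cov)
    matched = {p.id_a for p in pairs}
    unmatched = [r for r in set_a if r.id not in matched]
    rescued, too_short = translated_rescue(
        unmatched, set_b, min_translate_bp=min_translate_bp, min_query_cov=min_query_cov
    )
    all_pairs = pairs + rescued
    inventory = classify_inventory(all_pairs, set_a, set_b, too_short)
    return OrthologyResult(pairs=all_pairs, too_short_ids=too_short, inventory=inventory)


def write_pairs_tsv(pairs: Sequence[OrthologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\trelationship\tlevel\tscore\tcov_a\tcov_b\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.relationship}\t{p.level}\t"
                f"{p.score:.1f}\t{p.cov_a:.4f}\t{p.cov_b:.4f}\n"
            )
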