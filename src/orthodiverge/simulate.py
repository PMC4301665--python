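"""Synthetic ortholog-pair generator with known truth.

Each gene starts from a random ancestral transcript (5'UTR + CDS + 3'UTR)
and evolves independently down two branches under an HKY-like point-mutation
process: proposal sites and target bases are drawn proportionally to
pi_target * kappa^[transition] * cpg_mult^[CpG-context transition], the
number of proposals per branch is Poisson(t/2 * length), and coding
selection acts by thinning — nonsynonymous proposals are accepted with
probability min(1, omega) and synonymous proposals with min(1, 1/omega), so
the realized nonsynonymous/synonymous rate ratio is exactly omega for any
omega >= 0 (including omega > 1). Proposals creating stop codons are
rejected, and the start and stop codons are frozen so the true reading
frame stays discoverable by the ORF annotator. CpG context is evaluated on
the current sequence state at proposal time.

Defaults emulate a closely related aphid-like ortholog set: transcript
architecture from the real assembly's averages (CDS ~185 codons, UTRs
~262/283 bp, AT-rich base composition), kappa = 2, omega = 0.2, neutral
divergence t = 0.2 substitutions/site summed over both branches.

Every applied substitution is tallied in a SimTruth bookkeeping object
(region, transition/transversion, CpG context, synonymous/nonsynonymous),
and decoy and paralog transcripts can be appended for orthology testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .codons import CODON_TO_AA, STOP_CODONS, is_transition
from .errors import ValidationError
from .seqio import Regions, TranscriptRecord

NUCS = np.array(list("ACGT"))
_NUC_IDX = {nt: i for i, nt in enumerate("ACGT")}
_TS_TARGET = {"A": "G", "G": "A", "C": "T", "T": "C"}

DEFAULT_BASE_FREQS = (0.3005, 0.1983, 0.1966, 0.3046)  # A, C, G, T


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions the package
    is exercised under."""

    n_pairs: int = 50
    cds_codons: int = 185
    utr5_len: int = 262
    utr3_len: int = 283
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    kappa: float = 2.0
    omega: float = 0.2
    cpg_mult: float = 1.0
    t: float = 0.2  # expected neutral substitutions/site over both branches
    n_decoys: int = 10
    n_paralogs: int = 0
    decoy_len: int | None = None  # None -> same length as the real transcripts
    seed: int = 0

    def validate(self) -> None:
        if any(
            v < 0
            for v in (self.n_pairs, self.cds_codons, self.utr5_len, self.utr3_len,
                      self.n_decoys, self.n_paralogs)
        ):
            raise ValidationError("SimConfig: counts must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-6:
            raise ValidationError("SimConfig: base_freqs must sum to 1")
        if self.kappa < 0 or self.omega < 0 or self.cpg_mult < 1 or self.t < 0:
            raise ValidationError("SimConfig: invalid rate parameter")


@dataclass
class PairTruth:
    ancestor: str
    regions: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    counts_a: dict = field(default_factory=dict)
    counts_b: dict = field(default_factory=dict)
    implants: list = field(default_factory=list)


@dataclass
class SimTruth:
    mapping: list[tuple[str, str]] = field(default_factory=list)
    pairs: dict[str, PairTruth] = field(default_factory=dict)
    decoy_ids: list[str] = field(default_factory=list)
    paralog_of: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mapping": self.mapping,
            "decoy_ids": self.decoy_ids,
            "paralog_of": self.paralog_of,
            "pairs": {k: asdict(v) for k, v in self.pairs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _empty_counts() -> dict:
    return {
        "subs": 0, "ts": 0, "tv": 0, "cpg": 0,
        "syn": 0, "nonsyn": 0,
        "by_region": {"utr5": 0, "cds": 0, "utr3": 0},
    }


class _Lineage:
    """Mutable sequence plus the HKY/CpG proposal machinery for one branch."""

    def __init__(self, seq: str, regions: Regions, cfg: SimConfig,
                 rng: np.random.Generator, frozen: set[int]):
        self.seq = list(seq)
        self.regions = regions
        self.cfg = cfg
        self.rng = rng
        self.frozen = frozen
        self.counts = _empty_counts()
        self.pi = np.asarray(cfg.base_freqs, dtype=float)
        self.rates = np.zeros((len(seq), 4))
        for i in range(len(seq)):
            self._refresh_site(i)

    # -- rate bookkeeping ---------------------------------------------------

    def _is_cpg(self, i: int) -> bool:
        s = self.seq
        if s[i] == "C" and i + 1 < len(s) and s[i + 1] == "G":
            return True
        if s[i] == "G" and i - 1 >= 0 and s[i - 1] == "C":
            return True
        return False

    def _refresh_site(self, i: int) -> None:
        row = np.zeros(4)
        if i not in self.frozen:
            cur = self.seq[i]
            cpg = self._is_cpg(i)
            for nt, j in _NUC_IDX.items():
                if nt == cur:
                    continue
                w = self.pi[j]
                if is_transition(cur, nt):
                    w *= self.cfg.kappa
                    if cpg:
                        w *= self.cfg.cpg_mult
                row[j] = w
        self.rates[i] = row

    def _region_of(self, i: int) -> str:
        if self.regions.cds[0] <= i < self.regions.cds[1]:
            return "cds"
        if i < self.regions.utr5[1]:
            return "utr5"
        return "utr3"

    # -- evolution ----------------------------------------------------------

    def evolve(self, n_proposals: int) -> None:
        omega = self.cfg.omega
        p_nonsyn = min(1.0, omega)
        p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        flat = self.rates.reshape(-1)
        for _ in range(n_proposals):
            cum = np.cumsum(flat)
            total = cum[-1]
            if total <= 0:
                break
            r = self.rng.random() * total
            k = int(np.searchsorted(cum, r, side="right"))
            i, j = divmod(k, 4)
            target = "ACGT"[j]
            cur = self.seq[i]
            region = self._region_of(i)
            if region == "cds":
                cds_start = self.regions.cds[0]
                off = i - cds_start
                ci = off // 3
                codon = "".join(self.seq[cds_start + 3 * ci : cds_start + 3 * ci + 3])
                new_codon = codon[: off % 3] + target + codon[off % 3 + 1 :]
                if new_codon in STOP_CODONS:
                    continue  # stop-creating proposal rejected
                syn = CODON_TO_AA[new_codon] == CODON_TO_AA[codon]
                accept_p = p_syn if syn else p_nonsyn
                if self.rng.random() >= accept_p:
                    continue
            else:
                syn = None
            # apply
            was_cpg = self._is_cpg(i)
            ts = is_transition(cur, target)
            self.seq[i] = target
            self.counts["subs"] += 1
            self.counts["ts"] += ts
            self.counts["tv"] += not ts
            self.counts["cpg"] += was_cpg
            self.counts["by_region"][region] += 1
            if syn is not None:
                self.counts["syn" if syn else "nonsyn"] += 1
            for nb in (i - 1, i, i + 1):
                if 0 <= nb < len(self.seq):
                    self._refresh_site(nb)
            flat = self.rates.reshape(-1)

    def sequence(self) -> str:
        return "".join(self.seq)


def _draw_utr(rng: np.random.Generator, n: int, pi: np.ndarray) -> str:
    if n == 0:
        return ""
    return "".join(NUCS[rng.choice(4, size=n, p=pi)])


def _draw_cds(rng: np.random.Generator, n_codons: int, pi: np.ndarray) -> str:
    """ATG + (n-2) random stop-free codons + a stop codon."""
    if n_codons == 0:
        return ""
    if n_codons < 3:
        raise ValidationError("cds_codons must be 0 or >= 3")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(NUCS[rng.choice(4, size=3, p=pi)])
        if c not in STOP_CODONS:
            codons.append(c)
    stops = sorted(STOP_CODONS)
    w = np.array([np.prod([pi[_NUC_IDX[nt]] for nt in s]) for s in stops])
    codons.append(stops[rng.choice(len(stops), p=w / w.sum())])
    return "".join(codons)


def _frozen_sites(regions: Regions) -> set[int]:
    """Start and stop codon positions, held fixed during evolution."""
    c0, c1 = regions.cds
    if c1 - c0 == 0:
        return set()
    return set(range(c0, c0 + 3)) | set(range(c1 - 3, c1))


def simulate_ortholog_pairs(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], SimTruth]:
    """Generate two diverged transcript sets plus truth bookkeeping.

    Deterministic under config.seed; decoys and paralogs are appended when
    configured.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.base_freqs, dtype=float)
    pi = pi / pi.sum()

    records_a: list[TranscriptRecord] = []
    records_b: list[TranscriptRecord] = []
    truth = SimTruth()

    cds_len = 3 * config.cds_codons
    total_len = config.utr5_len + cds_len + config.utr3_len
    regions = Regions(
        utr5=(0, config.utr5_len),
        cds=(config.utr5_len, config.utr5_len + cds_len),
        utr3=(config.utr5_len + cds_len, total_len),
    )
    frozen = _frozen_sites(regions)

    for g in range(config.n_pairs):
        utr5 = _draw_utr(rng, config.utr5_len, pi)
        cds = _draw_cds(rng, config.cds_codons, pi)
        utr3 = _draw_utr(rng, config.utr3_len, pi)
        ancestor = utr5 + cds + utr3
        gid = f"g{g:04d}"
        pair_records = []
        counts = []
        for branch in ("a", "b"):
            lin = _Lineage(ancestor, regions, config, rng, frozen)
            n_prop = rng.poisson(config.t / 2.0 * total_len)
            lin.evolve(int(n_prop))
            pair_records.append(lin.sequence())
            counts.append(lin.counts)
        id_a, id_b = f"A_{gid}", f"B_{gid}"
        records_a.append(TranscriptRecord(id=id_a, seq=pair_records[0], regions=regions))
        records_b.append(TranscriptRecord(id=id_b, seq=pair_records[1], regions=regions))
        truth.mapping.append((id_a, id_b))
        truth.pairs[gid] = PairTruth(
            ancestor=ancestor,
            regions=(regions.utr5, regions.cds, regions.utr3),
            counts_a=counts[0],
            counts_b=counts[1],
        )

    if config.n_decoys or config.n_paralogs:
        records_a, records_b, truth = add_decoys_and_paralogs(
            records_a, records_b, config, rng, truth
        )
    return records_a, records_b, truth


def add_decoys_and_paralogs(
    records_a: list[TranscriptRecord],
    records_b: list[TranscriptRecord],
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    truth: SimTruth | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], SimTruth]:
    """Append unrelated decoy transcripts (truth: species-specific) and
    duplicated, further-diverged copies of existing A genes (truth: paralog)."""
    if truth is None:
        truth = SimTruth()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pi = np.asarray(config.base_freqs, dtype=float)
    pi = pi / pi.sum()
    records_a = list(records_a)
    records_b = list(records_b)

    dlen = config.decoy_len
    if dlen is None:
        dlen = config.utr5_len + 3 * config.cds_codons + config.utr3_len
    for d in range(config.n_decoys):
        did = f"A_decoy{d:03d}"
        records_a.append(TranscriptRecord(id=did, seq=_draw_utr(rng, dlen, pi)))
        truth.decoy_ids.append(did)

    n_real = len([r for r in records_a if r.regions is not None])
    for k in range(min(config.n_paralogs, n_real)):
        src = records_a[k]
        lin = _Lineage(src.seq, src.regions, config, rng, _frozen_sites(src.regions))
        lin.evolve(int(rng.poisson(config.t / 2.0 * len(src.seq))))
        pid = f"A_par{k:03d}_{src.id}"
        records_a.append(TranscriptRecord(id=pid, seq=lin.sequence(), regions=src.regions))
        truth.paralog_of[pid] = src.id
    return records_a, records_b, truth


def implant_selection_window(
    pair: tuple[TranscriptRecord, TranscriptRecord],
    window_len: int = 57,
    n_nonsyn: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[tuple[TranscriptRecord, TranscriptRecord], dict]:
    """Add `n_nonsyn` extra nonsynonymous substitutions to a random in-frame
    CDS window of the A member; returns the modified pair and the implant
    coordinates (bp offsets within the CDS, 0-based half-open)."""
    rec_a, rec_b = pair
    if rec_a.regions is None:
        raise ValidationError("implant_selection_window: record needs regions")
    if window_len % 3:
        raise ValidationError("window_len must be a multiple of 3")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c0, c1 = rec_a.regions.cds
    coding_len = (c1 - c0) - 3  # stop codon excluded
    if window_len > coding_len - 3:
        raise ValidationError("window longer than CDS")
    # window start within the coding part, past the start codon, codon-aligned
    n_starts = (coding_len - window_len) // 3  # starts at codon 1..n
    start_codon_i = 1 + int(rng.integers(0, n_starts))
    w_start = 3 * start_codon_i
    seq = list(rec_a.seq)
    applied = 0
    guard = 0
    mutated_sites: set[int] = set()
    while applied < n_nonsyn and guard < 10000:
        guard += 1
        off = w_start + int(rng.integers(0, window_len))
        i = c0 + off
        if i in mutated_sites:
            continue
        ci = (i - c0) // 3
        codon = "".join(seq[c0 + 3 * ci : c0 + 3 * ci + 3])
        target = "ACGT"[int(rng.integers(0, 4))]
        if target == seq[i]:
            continue
        new_codon = codon[: (i - c0) % 3] + target + codon[(i - c0) % 3 + 1 :]
        if new_codon in STOP_CODONS or CODON_TO_AA[new_codon] == CODON_TO_AA[codon]:
            continue
        seq[i] = target
        mutated_sites.add(i)
        applied += 1
    if applied < n_nonsyn:
        raise ValidationError("implant_selection_window: could not place mutations")
    new_a = TranscriptRecord(id=rec_a.id, seq="".join(seq), regions=rec_a.regions)
    implant = {"cds_start": w_start, "cds_end": w_start + window_len, "n_nonsyn": applied}
    return (new_a, rec_b), implant
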