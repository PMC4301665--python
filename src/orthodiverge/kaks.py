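"""Ka/Ks estimation, significance testing, binning, and sliding-window scans.

Two estimators are provided and always cross-checkable against each other:

* NG86 — Nei-Gojobori counting. Synonymous/nonsynonymous site fractions per
  codon come from exhaustive single-nucleotide neighbour enumeration (stop
  neighbours excluded from the denominators); differences are averaged over
  all minimal mutational pathways between the two codons, discarding
  pathways that pass through a stop codon. Proportions are corrected for
  multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

* YN — the kappa- and composition-aware approximate method. kappa is
  estimated from fourfold-degenerate and non-degenerate sites with the K80
  correction; site counting weights each neighbour by kappa (transitions)
  and by the F3x4 position-specific nucleotide frequency of the target
  base; pathway-averaged differences are split into transitions and
  transversions, and Ka and Ks are each corrected with the K80 formula.
  When kappa cannot be estimated (no informative differences) the estimator
  falls back to NG86 counting and flags the result.

Significance follows the Fisher exact convention on the 2x2 table of
rounded (site, difference) counts. The sliding-window scan (default 57 bp
window, 6 bp step) runs the estimator per window over the gap-free codon
columns and flags windows with omega > 1 as candidate positively selected
loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.stats import fisher_exact

from .codons import (
    CODON_TO_AA,
    FOURFOLD_PREFIXES,
    NUCLEOTIDES,
    STOP_CODONS,
    codon_neighbors,
    is_nondegenerate,
    is_transition,
)
from .errors import SaturationError, ValidationError
from .sites import PairAlignment, codon_pairs

log = logging.getLogger(__name__)


@dataclass
class KaKsResult:
    pair_id: str
    method: str  # "NG86" | "YN"
    S: float
    N: float
    Sd: float
    Nd: float
    ks: float | None
    ka: float | None
    omega: float | None  # None when Ks == 0 (see flags)
    kappa: float | None = None
    p_value: float | None = None
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def omega_sentinel(self) -> float:
        """omega with Ks=0 cases mapped to +inf (Ka>0) or NaN (Ka=0);
        used for ranking windows, never for binning."""
        if self.omega is not None:
            return self.omega
        if self.ka and self.ka > 0:
            return math.inf
        return math.nan


@dataclass(frozen=True)
class Window:
    start: int  # bp, 0-based half-open on the gap-free CDS alignment
    end: int
    ka: float | None
    ks: float | None
    omega: float | None
    flagged: bool  # omega > 1 (finite or Ks=0 with Ka>0)


@dataclass
class WindowScan:
    pair_id: str
    window_len: int
    step: int
    windows: list[Window]

    def max_omega_window(self) -> Window | None:
        best, best_key = None, -1.0
        for w in self.windows:
            key = w.omega
            if key is None:
                key = math.inf if (w.ka or 0) > 0 else -1.0
            if key > best_key:
                best, best_key = w, key
        return best


# ---------------------------------------------------------------- NG86 sites


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of a sense codon.

    Per position: fraction of sense single-nucleotide neighbours that are
    synonymous; stop neighbours are excluded from the denominator but the
    position still counts one full site (s + n = 3).
    """
    if codon not in CODON_TO_AA:
        raise ValidationError(f"ng86_sites: {codon!r} is not a sense codon")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nb in codon_neighbors(codon, pos):
            if nb in STOP_CODONS:
                continue
            tot += 1
            if CODON_TO_AA[nb] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


# ---------------------------------------------------------- NG86 differences


@dataclass(frozen=True)
class PathwayCounts:
    sd: float
    nd: float
    sd_ts: float
    sd_tv: float
    nd_ts: float
    nd_tv: float
    stop_fallback: bool = False


@lru_cache(maxsize=None)
def pathway_counts(a: str, b: str) -> PathwayCounts:
    """Expected synonymous/nonsynonymous step counts between two sense
    codons, averaged over all minimal pathways; stop-crossing pathways are
    discarded (with a stop-inclusive fallback when every pathway is
    blocked). Transition/transversion split is tracked per step."""
    for c in (a, b):
        if c not in CODON_TO_AA:
            raise ValidationError(f"pathway_counts: {c!r} is not a sense codon")
    diff_pos = tuple(i for i in range(3) if a[i] != b[i])
    if not diff_pos:
        return PathwayCounts(0, 0, 0, 0, 0, 0)

    def tally(allow_stops: bool):
        acc = []
        for order in permutations(diff_pos):
            steps = []
            cur = a
            blocked = False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and not allow_stops:
                    blocked = True
                    break
                steps.append((cur, nxt, pos))
                cur = nxt
            if blocked:
                continue
            sd = nd = sd_ts = sd_tv = nd_ts = nd_tv = 0.0
            for cfrom, cto, pos in steps:
                ts = is_transition(cfrom[pos], cto[pos])
                aa_from = CODON_TO_AA.get(cfrom)
                aa_to = CODON_TO_AA.get(cto)
                syn = aa_from is not None and aa_to is not None and aa_from == aa_to
                if syn:
                    sd += 1
                    sd_ts += ts
                    sd_tv += not ts
                else:
                    nd += 1
                    nd_ts += ts
                    nd_tv += not ts
            acc.append((sd, nd, sd_ts, sd_tv, nd_ts, nd_tv))
        return acc

    acc = tally(allow_stops=False)
    fallback = False
    if not acc:
        acc = tally(allow_stops=True)
        fallback = True
        log.warning(
            "all pathways between %s and %s pass through stops; "
            "using stop-inclusive counting", a, b,
        )
    means = [sum(col) / len(acc) for col in zip(*acc)]
    return PathwayCounts(*means, stop_fallback=fallback)


def ng86_differences(a: str, b: str) -> tuple[float, float]:
    pc = pathway_counts(a, b)
    return pc.sd, pc.nd


# ------------------------------------------------------------- corrections


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValidationError("jukes_cantor: negative proportion")
    if p >= 0.75:
        raise SaturationError(f"Jukes-Cantor undefined for p = {p:.4f} >= 0.75")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def k80_distance(p_ts: float, p_tv: float) -> float:
    """Kimura two-parameter distance from transition/transversion
    proportions."""
    a1 = 1.0 - 2.0 * p_ts - p_tv
    a2 = 1.0 - 2.0 * p_tv
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(
            f"K80 undefined for P = {p_ts:.4f}, Q = {p_tv:.4f}"
        )
    if p_ts == 0 and p_tv == 0:
        return 0.0
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


# ------------------------------------------------------------------- NG86


def _extract_codon_pairs(aln) -> list[tuple[str, str]]:
    if isinstance(aln, PairAlignment):
        return codon_pairs(aln)
    return list(aln)


def ng86_kaks(aln, pair_id: str = "") -> KaKsResult:
    """NG86 Ka/Ks over the comparable sense-codon pairs of an alignment
    (or an explicit list of codon pairs)."""
    pairs = _extract_codon_pairs(aln)
    if not pairs:
        raise ValidationError("ng86_kaks: no comparable codon pairs")
    s_a = s_b = 0.0
    sd = nd = 0.0
    flags: list[str] = []
    for ca, cb in pairs:
        sa, _ = ng86_sites(ca)
        sb, _ = ng86_sites(cb)
        s_a += sa
        s_b += sb
        pc = pathway_counts(ca, cb)
        sd += pc.sd
        nd += pc.nd
        if pc.stop_fallback and "stop_pathway_fallback" not in flags:
            flags.append("stop_pathway_fallback")
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    ks = ka = None
    try:
        ks = jukes_cantor(sd / S) if S > 0 else None
    except SaturationError:
        flags.append("ks_saturated")
    try:
        ka = jukes_cantor(nd / N) if N > 0 else None
    except SaturationError:
        flags.append("ka_saturated")
    omega = None
    if ka is not None and ks is not None:
        if ks > 0:
            omega = ka / ks
        else:
            flags.append("ks_zero")
    return KaKsResult(
        pair_id=pair_id, method="NG86", S=S, N=N, Sd=sd, Nd=nd,
        ks=ks, ka=ka, omega=omega, n_codons=len(pairs), flags=flags,
    )


# --------------------------------------------------------------------- YN


def _f3x4(pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """Position-specific nucleotide frequencies pooled over both sequences."""
    counts = np.zeros((3, 4))
    idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for ca, cb in pairs:
        for pos in range(3):
            counts[pos, idx[ca[pos]]] += 1
            counts[pos, idx[cb[pos]]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    return counts / totals


def estimate_kappa(pairs: Sequence[tuple[str, str]]) -> float | None:
    """kappa from fourfold-degenerate and non-degenerate positions via the
    K80 correction, weighted by site counts; None when not estimable."""
    n4 = ts4 = tv4 = 0
    n0 = ts0 = tv0 = 0
    for ca, cb in pairs:
        for pos in range(3):
            a, b = ca[pos], cb[pos]
            if pos == 2 and ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
                n4 += 1
                if a != b:
                    if is_transition(a, b):
                        ts4 += 1
                    else:
                        tv4 += 1
            elif is_nondegenerate(ca, pos) and is_nondegenerate(cb, pos):
                n0 += 1
                if a != b:
                    if is_transition(a, b):
                        ts0 += 1
                    else:
                        tv0 += 1

    def kappa_class(n, ts, tv):
        if n == 0 or tv == 0:
            return None
        P, Q = ts / n, tv / n
        a1 = 1.0 - 2.0 * P - Q
        a2 = 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return None
        A = -0.5 * math.log(a1) + 0.25 * math.log(a2)
        B = -0.5 * math.log(a2)
        if B <= 0 or A <= 0:
            return None
        return 2.0 * A / B

    k4 = kappa_class(n4, ts4, tv4)
    k0 = kappa_class(n0, ts0, tv0)
    num = den = 0.0
    for k, n in ((k4, n4), (k0, n0)):
        if k is not None:
            num += k * n
            den += n
    return num / den if den else None


def _yn_sites_codon(codon: str, kappa: float, pi: np.ndarray) -> float:
    """Synonymous site fraction of one codon under kappa / F3x4 weighting."""
    aa = CODON_TO_AA[codon]
    idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for nb in codon_neighbors(codon, pos):
            if nb in STOP_CODONS:
                continue
            w = pi[pos, idx[nb[pos]]]
            if is_transition(codon[pos], nb[pos]):
                w *= kappa
            tot_w += w
            if CODON_TO_AA[nb] == aa:
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
    return s


def yn_kaks(
    aln,
    pair_id: str = "",
    kappa: float | None = None,
    freqs: np.ndarray | None = None,
) -> KaKsResult:
    """kappa/composition-aware approximate Ka/Ks.

    `kappa=None` estimates kappa from the data; `freqs` overrides the F3x4
    position frequencies (3x4 array in A,C,G,T order). Falls back to NG86
    counting (flag "kappa_fallback") when kappa cannot be estimated.
    """
    pairs = _extract_codon_pairs(aln)
    if not pairs:
        raise ValidationError("yn_kaks: no comparable codon pairs")
    flags: list[str] = []
    if kappa is None:
        kappa = estimate_kappa(pairs)
        if kappa is None:
            log.warning("%s: kappa not estimable, falling back to NG86 counting", pair_id)
            res = ng86_kaks(pairs, pair_id=pair_id)
            res.method = "YN"
            res.flags = res.flags + ["kappa_fallback"]
            return res
    pi = _f3x4(pairs) if freqs is None else np.asarray(freqs, dtype=float)

    s_a = s_b = 0.0
    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for ca, cb in pairs:
        s_a += _yn_sites_codon(ca, kappa, pi)
        s_b += _yn_sites_codon(cb, kappa, pi)
        pc = pathway_counts(ca, cb)
        sd_ts += pc.sd_ts
        sd_tv += pc.sd_tv
        nd_ts += pc.nd_ts
        nd_tv += pc.nd_tv
        if pc.stop_fallback and "stop_pathway_fallback" not in flags:
            flags.append("stop_pathway_fallback")
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    sd = sd_ts + sd_tv
    nd = nd_ts + nd_tv
    ks = ka = None
    try:
        ks = k80_distance(sd_ts / S, sd_tv / S) if S > 0 else None
    except SaturationError:
        flags.append("ks_saturated")
    try:
        ka = k80_distance(nd_ts / N, nd_tv / N) if N > 0 else None
    except SaturationError:
        flags.append("ka_saturated")
    omega = None
    if ka is not None and ks is not None:
        if ks > 0:
            omega = ka / ks
        else:
            flags.append("ks_zero")
    return KaKsResult(
        pair_id=pair_id, method="YN", S=S, N=N, Sd=sd, Nd=nd,
        ks=ks, ka=ka, omega=omega, kappa=kappa, n_codons=len(pairs), flags=flags,
    )


def kaks_for_alignment(aln, pair_id: str = "", method: str = "YN") -> KaKsResult:
    if method == "YN":
        res = yn_kaks(aln, pair_id=pair_id)
    elif method == "NG86":
        res = ng86_kaks(aln, pair_id=pair_id)
    else:
        raise ValidationError(f"unknown Ka/Ks method {method!r}")
    res.p_value = fisher_pvalue(res)
    return res


# ------------------------------------------------------------------ Fisher


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_pvalue(result: KaKsResult) -> float:
    """Two-sided Fisher exact test on [[Sd, S-Sd], [Nd, N-Nd]] with
    round-half-up integer cells."""
    cells = [
        [_round_half_up(result.Sd), _round_half_up(result.S - result.Sd)],
        [_round_half_up(result.Nd), _round_half_up(result.N - result.Nd)],
    ]
    for row in cells:
        for v in row:
            if v < 0:
                raise ValidationError(f"fisher_pvalue: negative cell in {cells}")
    return float(fisher_exact(cells, alternative="two-sided")[1])


# ----------------------------------------------------------------- binning

BIN_LABELS = (">2", "(1,2]", "(0.5,1]", "<=0.5")


def bin_kaks(results: Sequence[KaKsResult]) -> dict:
    """Partition finite omega values into the selection bins and report
    means. Pairs with undefined omega (Ks = 0, including the Ka>0 +inf
    sentinel cases) are counted separately."""
    bins = {label: 0 for label in BIN_LABELS}
    undefined = 0
    kas, kss, omegas = [], [], []
    for r in results:
        if r.ka is not None:
            kas.append(r.ka)
        if r.ks is not None:
            kss.append(r.ks)
        if r.omega is None:
            undefined += 1
            continue
        omegas.append(r.omega)
        w = r.omega
        if w > 2:
            bins[">2"] += 1
        elif w > 1:
            bins["(1,2]"] += 1
        elif w > 0.5:
            bins["(0.5,1]"] += 1
        else:
            bins["<=0.5"] += 1
    out = dict(bins)
    out["undefined"] = undefined
    out["mean_ka"] = float(np.mean(kas)) if kas else float("nan")
    out["mean_ks"] = float(np.mean(kss)) if kss else float("nan")
    out["mean_omega"] = float(np.mean(omegas)) if omegas else float("nan")
    return out


# ---------------------------------------------------------------- windows


def sliding_window_scan(
    aln,
    window_len: int = 57,
    step: int = 6,
    method: str = "NG86",
    pair_id: str = "",
) -> WindowScan:
    """Ka/Ks per sliding window over the gap-free CDS codon columns.

    Windows are positioned on the gap-column-removed alignment coordinate
    system, 0-based half-open. Alignments shorter than `window_len` yield a
    single whole-alignment window with a warning.
    """
    if window_len % 3 or step % 3:
        raise ValidationError("window_len and step must be multiples of 3")
    pairs = _extract_codon_pairs(aln)
    if isinstance(aln, PairAlignment) and not pair_id:
        pair_id = aln.pair_id
    L = 3 * len(pairs)
    estimator = ng86_kaks if method == "NG86" else yn_kaks

    def window_result(codon_slice, start, end) -> Window:
        try:
            r = estimator(codon_slice, pair_id=pair_id)
        except ValidationError:
            return Window(start, end, None, None, None, False)
        flagged = (r.omega is not None and r.omega > 1) or (
            r.omega is None and (r.ka or 0) > 0 and r.ks == 0
        )
        return Window(start, end, r.ka, r.ks, r.omega, flagged)

    windows = []
    if L < window_len:
        log.warning(
            "%s: alignment (%d bp) shorter than window (%d bp); single window",
            pair_id, L, window_len,
        )
        windows.append(window_result(pairs, 0, L))
    else:
        for start in range(0, L - window_len + 1, step):
            ci, cj = start // 3, (start + window_len) // 3
            windows.append(window_result(pairs[ci:cj], start, start + window_len))
    return WindowScan(pair_id=pair_id, window_len=window_len, step=step, windows=windows)
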