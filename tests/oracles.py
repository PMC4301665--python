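"""Independent brute-force oracle for NG86-style counting.

Deliberately re-derives everything by direct enumeration with Biopython's
translator — shares no logic with the package implementation.
"""

import math
from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa(codon) == "*"


def oracle_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous sites by neighbour enumeration."""
    s = 0.0
    for pos in range(3):
        syn, tot = 0, 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(nb):
                continue
            tot += 1
            if aa(nb) == aa(codon):
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous step counts."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # stop-inclusive fallback
        for order in permutations(diff):
            cur = a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if aa(nxt) == aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_kaks(codon_pairs) -> dict:
    """Whole-alignment NG86 with Jukes-Cantor correction."""
    S = sum(oracle_sites(a)[0] + oracle_sites(b)[0] for a, b in codon_pairs) / 2.0
    N = 3.0 * len(codon_pairs) - S
    Sd = sum(oracle_differences(a, b)[0] for a, b in codon_pairs)
    Nd = sum(oracle_differences(a, b)[1] for a, b in codon_pairs)

    def jc(p):
        if p >= 0.75:
            return None  # saturated
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p else 0.0

    return {
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "ks": jc(Sd / S) if S > 0 else None,
        "ka": jc(Nd / N) if N > 0 else None,
    }
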