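"""Region x context divergence statistics over ortholog-pair alignments.

Produces the divergence-table machinery: for each region (5'UTR, CDS,
non-degenerate sites, fourfold-degenerate sites, 3'UTR) crossed with each
CpG context (all / non-CpG / CpG), the percent of differing comparable
columns, its dispersion across pairs, the total compared kilobases, the
transition/transversion split, and GC / CpG content.

Two averaging modes: per_pair (default — unweighted mean of per-pair
percentages, standard error of that mean across pairs; pairs with no
comparable column in a cell are excluded from that cell, not imputed as
zero) and pooled (100 * total differences / total compared columns). The
compared-kb, ts/tv and content columns are always pooled, so the exact
conservation identity compared(all) = compared(cpg) + compared(non_cpg)
holds in every region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import is_transition
from .errors import ValidationError
from .sites import PairAlignment, SitePartition

REGIONS = ("utr5", "cds", "nd", "fourfold", "utr3")
CONTEXTS = ("all", "non_cpg", "cpg")


@dataclass(frozen=True)
class DiffCounts:
    diffs: int
    compared: int
    ts: int
    tv: int

    @property
    def ts_tv(self) -> float:
        return self.ts / self.tv if self.tv else float("nan")


def _region_mask(aln: PairAlignment, part: SitePartition, region: str) -> np.ndarray:
    if region in ("utr5", "cds", "utr3"):
        return aln.region == region
    if region in ("nd", "fourfold"):
        return part.degeneracy == region
    raise ValidationError(f"unknown region {region!r}")


def _context_mask(part: SitePartition, context: str) -> np.ndarray:
    if context == "all":
        return np.ones(len(part.cpg), dtype=bool)
    if context == "cpg":
        return part.cpg
    if context == "non_cpg":
        return ~part.cpg
    raise ValidationError(f"unknown context {context!r}")


def count_differences(
    aln: PairAlignment, part: SitePartition, region: str, context: str = "all"
) -> DiffCounts:
    """Mismatch / transition / transversion counts over the comparable
    columns of one pair that fall in (region, context)."""
    mask = part.comparable & _region_mask(aln, part, region) & _context_mask(part, context)
    idx = np.flatnonzero(mask)
    diffs = ts = tv = 0
    for i in idx:
        a, b = aln.a_aln[i], aln.b_aln[i]
        if a != b:
            diffs += 1
            if is_transition(a, b):
                ts += 1
            else:
                tv += 1
    return DiffCounts(diffs=diffs, compared=int(len(idx)), ts=ts, tv=tv)


def _content_counts(
    aln: PairAlignment, part: SitePartition, region: str, context: str
) -> tuple[int, int, int]:
    """(gc bases, total bases, cpg columns) pooled over both sequences."""
    mask = part.comparable & _region_mask(aln, part, region) & _context_mask(part, context)
    idx = np.flatnonzero(mask)
    gc = 0
    for i in idx:
        gc += aln.a_aln[i] in "GC"
        gc += aln.b_aln[i] in "GC"
    ncpg = int(part.cpg[idx].sum())
    return gc, 2 * len(idx), ncpg


def divergence_table(
    analyzed: Sequence[tuple[PairAlignment, SitePartition]],
    mode: str = "per_pair",
) -> pd.DataFrame:
    """Divergence statistics for a set of analyzed pairs.

    Returns a DataFrame indexed by (region, context) with columns
    diff_percent, diff_se (standard error of the per-pair mean; NaN in
    pooled mode or with < 2 contributing pairs), compared_kb, ts, tv,
    ts_tv, gc_percent, cpg_percent, n_pairs.
    """
    if not analyzed:
        raise ValidationError("divergence_table: no pairs")
    if mode not in ("per_pair", "pooled"):
        raise ValidationError(f"divergence_table: unknown mode {mode!r}")

    rows = []
    for region in REGIONS:
        for context in CONTEXTS:
            per_pair_pct = []
            tot_d = tot_c = tot_ts = tot_tv = 0
            gc_bases = tot_bases = cpg_cols = 0
            for aln, part in analyzed:
                c = count_differences(aln, part, region, context)
                if c.compared:
                    per_pair_pct.append(100.0 * c.diffs / c.compared)
                tot_d += c.diffs
                tot_c += c.compared
                tot_ts += c.ts
                tot_tv += c.tv
                g, t, ncpg = _content_counts(aln, part, region, context)
                gc_bases += g
                tot_bases += t
                cpg_cols += ncpg
            if mode == "per_pair":
                if per_pair_pct:
                    diff_pct = float(np.mean(per_pair_pct))
                    diff_se = (
                        float(np.std(per_pair_pct, ddof=1) / np.sqrt(len(per_pair_pct)))
                        if len(per_pair_pct) > 1
                        else float("nan")
                    )
                else:
                    diff_pct = diff_se = float("nan")
            else:
                diff_pct = 100.0 * tot_d / tot_c if tot_c else float("nan")
                diff_se = float("nan")
            rows.append(
                {
                    "region": region,
                    "context": context,
                    "diff_percent": diff_pct,
                    "diff_se": diff_se,
                    "diffs": tot_d,
                    "compared_kb": tot_c / 1000.0,
                    "ts": tot_ts,
                    "tv": tot_tv,
                    "ts_tv": tot_ts / tot_tv if tot_tv else float("nan"),
                    "gc_percent": 100.0 * gc_bases / tot_bases if tot_bases else float("nan"),
                    "cpg_percent": 100.0 * cpg_cols / (tot_bases / 2) if tot_bases else float("nan"),
                    "n_pairs": len(per_pair_pct),
                }
            )
    return pd.DataFrame(rows).set_index(["region", "context"])


def context_content(
    analyzed: Sequence[tuple[PairAlignment, SitePartition]]
) -> pd.DataFrame:
    """Per-region GC%% and CpG%% over comparable columns, both sequences of
    every pair pooled."""
    rows = []
    for region in REGIONS:
        gc_bases = tot_bases = cpg_cols = 0
        for aln, part in analyzed:
            g, t, ncpg = _content_counts(aln, part, region, "all")
            gc_bases += g
            tot_bases += t
            cpg_cols += ncpg
        rows.append(
            {
                "region": region,
                "gc_percent": 100.0 * gc_bases / tot_bases if tot_bases else float("nan"),
                "cpg_percent": 100.0 * cpg_cols / (tot_bases / 2) if tot_bases else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("region")
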