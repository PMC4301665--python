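"""End-to-end orchestration: simulate/load -> annotate -> pair -> classify
-> divergence -> Ka/Ks -> sliding-window scan, with a JSON manifest that
records seed, thresholds and per-stage record counts so every filter's
arithmetic is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .divergence import divergence_table
from .errors import OrthodivergeError, ValidationError
from .kaks import bin_kaks, kaks_for_alignment, ng86_kaks, sliding_window_scan
from .orf import annotate_set
from .orthology import find_orthologs, write_pairs_tsv
from .seqio import assembly_summary, read_cds_coords, read_fasta, write_fasta
from .simulate import SimConfig, simulate_ortholog_pairs
from .sites import build_pair_alignment, classify_sites

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta_a: str | None = None
    fasta_b: str | None = None
    cds_coords_a: str | None = None
    cds_coords_b: str | None = None
    sim: SimConfig | None = None
    outdir: str = "orthodiverge_out"
    min_orf_len: int = 150
    min_pair_cds_bp: int = 150
    min_translate_bp: int = 250
    min_query_cov: float = 0.5
    method: str = "YN"
    divergence_mode: str = "per_pair"
    window_len: int = 57
    step: int = 6
    scan_all: bool = False  # False: scan only candidate positive-selection pairs
    seed: int = 0

    def validate(self) -> None:
        if (self.fasta_a is None) != (self.fasta_b is None):
            raise ValidationError("provide both fasta_a and fasta_b, or neither")
        if self.fasta_a is None and self.sim is None:
            raise ValidationError("no input FASTA and no simulation config")
        if self.min_pair_cds_bp <= 0 or self.min_translate_bp <= 0:
            raise ValidationError("thresholds must be positive")
        if self.window_len % 3 or self.step % 3:
            raise ValidationError("window_len and step must be multiples of 3")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; writes TSV/JSON outputs plus manifest.json into
    config.outdir and returns the manifest dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_orf_len": config.min_orf_len,
            "min_pair_cds_bp": config.min_pair_cds_bp,
            "min_translate_bp": config.min_translate_bp,
            "min_query_cov": config.min_query_cov,
        },
        "method": config.method,
        "stages": {},
    }
    stage = "inputs"
    try:
        if config.fasta_a:
            set_a = read_fasta(config.fasta_a)
            set_b = read_fasta(config.fasta_b)
        else:
            sim = config.sim
            set_a, set_b, truth = simulate_ortholog_pairs(sim)
            write_fasta(set_a, out / "speciesA.fasta")
            write_fasta(set_b, out / "speciesB.fasta")
            truth.to_json(out / "truth.json")
        set_a = sorted(set_a, key=lambda r: r.id)
        set_b = sorted(set_b, key=lambda r: r.id)
        manifest["stages"]["inputs"] = {"n_a": len(set_a), "n_b": len(set_b)}

        stage = "summary"
        assembly_summary(set_a).to_json(out / "summary_a.json")
        assembly_summary(set_b).to_json(out / "summary_b.json")

        stage = "annotate"
        coords_a = read_cds_coords(config.cds_coords_a) if config.cds_coords_a else None
        coords_b = read_cds_coords(config.cds_coords_b) if config.cds_coords_b else None
        coding_a, nc_a = annotate_set(set_a, min_len_nt=config.min_orf_len, coords=coords_a)
        coding_b, nc_b = annotate_set(set_b, min_len_nt=config.min_orf_len, coords=coords_b)
        manifest["stages"]["annotate"] = {
            "coding_a": len(coding_a), "non_coding_a": len(nc_a),
            "coding_b": len(coding_b), "non_coding_b": len(nc_b),
        }
        log.info("annotate: %d/%d coding in A, %d/%d in B",
                 len(coding_a), len(set_a), len(coding_b), len(set_b))

        stage = "orthology"
        res = find_orthologs(
            set_a, set_b,
            min_query_cov=config.min_query_cov,
            min_translate_bp=config.min_translate_bp,
        )
        write_pairs_tsv(res.pairs, out / "pairs.tsv")
        manifest["stages"]["orthology"] = dict(res.inventory)

        stage = "alignment"
        ann_a = {r.id: r for r in coding_a}
        ann_b = {r.id: r for r in coding_b}
        analyzed = []
        n_noncoding_pair = 0
        for p in sorted(res.pairs, key=lambda p: (p.id_a, p.id_b)):
            ra, rb = ann_a.get(p.id_a), ann_b.get(p.id_b)
            if ra is None or rb is None:
                n_noncoding_pair += 1
                continue
            aln = build_pair_alignment(ra, rb, pair_id=f"{p.id_a}|{p.id_b}")
            analyzed.append((aln, classify_sites(aln)))
        manifest["stages"]["alignment"] = {
            "aligned_pairs": len(analyzed),
            "pairs_without_cds": n_noncoding_pair,
        }

        stage = "divergence"
        if analyzed:
            table = divergence_table(analyzed, mode=config.divergence_mode)
            table.to_csv(out / "divergence.tsv", sep="\t")
            table.reset_index().to_json(out / "divergence.json", orient="records", indent=1)

        stage = "kaks"
        results = []
        n_short_cds = 0
        n_failed = 0
        kept = []
        for aln, part in analyzed:
            cds_cols = int((aln.region == "cds").sum())
            if cds_cols < config.min_pair_cds_bp:
                n_short_cds += 1
                log.info("%s: CDS alignment %d bp < %d bp, excluded from Ka/Ks",
                         aln.pair_id, cds_cols, config.min_pair_cds_bp)
                continue
            kept.append((aln, part))
            try:
                r = kaks_for_alignment(aln, pair_id=aln.pair_id, method=config.method)
            except OrthodivergeError as exc:
                log.info("%s: Ka/Ks not computable (%s)", aln.pair_id, exc)
                n_failed += 1
                continue
            if r.ka is None or r.ks is None:
                n_failed += 1
                continue
            results.append(r)
        _write_kaks_tsv(results, out / "kaks.tsv")
        bins = bin_kaks(results)
        manifest["stages"]["kaks"] = {
            "pairs_cds_ge_min": len(kept),
            "excluded_short_cds": n_short_cds,
            "not_computable": n_failed,
            "computed": len(results),
            "bins": {k: v for k, v in bins.items() if isinstance(v, int)},
            "mean_ka": bins["mean_ka"],
            "mean_ks": bins["mean_ks"],
            "mean_omega": bins["mean_omega"],
        }

        stage = "scan"
        by_id = {aln.pair_id: aln for aln, _ in kept}
        scan_rows = []
        candidates = [
            r for r in results
            if config.scan_all or (r.omega is not None and r.omega > 1)
            or ("ks_zero" in r.flags and (r.ka or 0) > 0)
        ]
        for r in candidates:
            aln = by_id.get(r.pair_id)
            if aln is None:
                continue
            scan = sliding_window_scan(
                aln, window_len=config.window_len, step=config.step, method="NG86"
            )
            for w in scan.windows:
                scan_rows.append({
                    "pair_id": r.pair_id, "start": w.start, "end": w.end,
                    "ka": w.ka, "ks": w.ks, "omega": w.omega, "flagged": w.flagged,
                })
        pd.DataFrame(
            scan_rows,
            columns=["pair_id", "start", "end", "ka", "ks", "omega", "flagged"],
        ).to_csv(out / "windows.tsv", sep="\t", index=False)
        manifest["stages"]["scan"] = {
            "pairs_scanned": len(candidates),
            "windows": len(scan_rows),
            "windows_flagged": sum(1 for r in scan_rows if r["flagged"]),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _write_kaks_tsv(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tmethod\tKa\tKs\tKa/Ks\tS\tN\tSd\tNd\tkappa\tp_value\n")
        for r in results:
            omega = "inf" if (r.omega is None and (r.ka or 0) > 0) else (
                "NA" if r.omega is None else f"{r.omega:.4f}"
            )
            kappa = "NA" if r.kappa is None else f"{r.kappa:.4f}"
            fh.write(
                f"{r.pair_id}\t{r.method}\t{_fmt(r.ka)}\t{_fmt(r.ks)}\t{omega}\t"
                f"{r.S:.2f}\t{r.N:.2f}\t{r.Sd:.2f}\t{r.Nd:.2f}\t{kappa}\t"
                f"{_fmt(r.p_value)}\n"
            )


def _fmt(x) -> str:
    return "NA" if x is None else f"{x:.5f}"
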