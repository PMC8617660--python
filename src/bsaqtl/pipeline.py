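"""End-to-end orchestration: simulate -> filter -> scan -> call.

Every stage writes plain TSV/JSON artifacts into the output directory, plus
a manifest (config hash, seed, versions, input checksums) that makes the
run reproducible.  One seed governs the whole run; stage RNG streams are
spawned from it in a fixed order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import synthetic_cross as sc
from .bsa_statistics import ScanConfig, compute_track, write_track
from .config import RunConfig, ConfigError, _listify
from .qtl_call import METHODS, call_intervals, consensus, genes_in_intervals, report
from .variant_screen import ScreenError, read_vcf, screen_table, write_snp_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_stage(cfg: RunConfig, out_dir: Path) -> tuple[Path, Path]:
    """Generate the synthetic BC1 dataset declared by cfg.sim."""
    sp = cfg.sim
    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in seeds]
    marker_map = sc.build_marker_map(
        sp.n_chrom, sp.chrom_len_bp, sp.marker_spacing_bp, rngs[0]
    )
    qtl = sc.RestorerQTL(
        chrom=sp.qtl_chrom,
        pos_bp=sp.qtl_pos,
        grade_dist_carrier=tuple(sp.grade_dist_carrier),
        grade_dist_noncarrier=tuple(sp.grade_dist_noncarrier),
    )
    pop = sc.simulate_bc1(marker_map, qtl, sp.pop_size, sp.recomb_rate, rngs[1])
    fbulk, sbulk = sc.select_bulks(
        pop, sp.bulk_size, set(sp.f_grades), set(sp.s_grades), rngs[2]
    )
    f_counts = sc.simulate_bulk_reads(
        fbulk, sp.depth_low, sp.depth_high, sp.error_rate, rngs[3]
    )
    s_counts = sc.simulate_bulk_reads(
        sbulk, sp.depth_low, sp.depth_high, sp.error_rate, rngs[3]
    )
    truth = sc.SimTruth(
        qtl=qtl,
        seed=cfg.seed,
        f_members=fbulk.members,
        s_members=sbulk.members,
        depth_model=f"uniform[{sp.depth_low},{sp.depth_high}]",
        error_rate=sp.error_rate,
    )
    vcf_path = out_dir / "simulated.vcf"
    truth_path = out_dir / "truth.tsv"
    sc.emit_vcf(
        marker_map, f_counts, s_counts, truth, vcf_path, truth_path,
        contaminant_fraction=sp.contaminant_fraction, seed=rngs[4],
    )
    return vcf_path, truth_path


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline; returns a name -> path map of artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    inputs: dict[str, str] = {}

    truth_path: Path | None = None
    if cfg.simulate:
        try:
            vcf_path, truth_path = simulate_stage(cfg, out_dir)
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        artifacts["vcf"] = vcf_path
        artifacts["truth"] = truth_path
        log.info("simulate: wrote %s", vcf_path)
    else:
        vcf_path = Path(cfg.vcf)
        if not vcf_path.exists():
            raise StageError("filter", FileNotFoundError(f"input VCF missing: {vcf_path}"))
        inputs["vcf"] = _sha256(vcf_path)

    try:
        snps, filter_report = screen_table(
            read_vcf(vcf_path, cfg.sample_roles), cfg.screen_config()
        )
    except (ScreenError, OSError, ValueError) as exc:
        raise StageError("filter", exc) from exc
    snp_path = out_dir / "snps.tsv"
    snp_df = write_snp_table(snps, snp_path)
    filter_report.write_json(out_dir / "filter_report.json")
    artifacts["snps"] = snp_path
    artifacts["filter_report"] = out_dir / "filter_report.json"
    log.info("filter: kept %d / %d sites", filter_report.kept, filter_report.total)

    scan_cfg = ScanConfig(**{**asdict(cfg.scan), "seed": cfg.seed,
                             "bulk_size": cfg.sim.bulk_size})
    try:
        track, thresholds = compute_track(snp_df, scan_cfg)
    except Exception as exc:
        raise StageError("scan", exc) from exc
    track_path = out_dir / "track.tsv"
    thresholds_path = out_dir / "thresholds.json"
    write_track(track, thresholds, track_path, thresholds_path)
    artifacts["track"] = track_path
    artifacts["thresholds"] = thresholds_path

    try:
        by_method = {
            m: call_intervals(track, m, thresholds, min_run=cfg.call.min_run)
            for m in METHODS
        }
        cons = consensus(by_method, min_methods=cfg.call.min_methods, track=track)
        intervals = [iv for ivs in by_method.values() for iv in ivs] + cons
        genes = []
        if cfg.annotation:
            genes = genes_in_intervals(
                cons or intervals, cfg.annotation,
                snp_positions=track[["chrom", "pos"]],
            )
        truth = sc.read_truth(truth_path) if truth_path else None
        paths = report(intervals, genes, out_dir, truth=truth)
    except Exception as exc:
        raise StageError("call", exc) from exc
    artifacts.update(paths)

    manifest = {
        "config": _listify(cfg.to_dict()),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(_listify(cfg.to_dict()), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "bsaqtl": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": inputs,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = manifest_path
    return artifacts
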