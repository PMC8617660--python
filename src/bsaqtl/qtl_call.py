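"""QTL interval calling, cross-method consensus, and candidate gene lookup.

Turns per-SNP significance masks into intervals (runs of consecutive
significant SNPs), intersects intervals across methods, and funnels a gene
annotation (GFF3 or BED) through the called regions with optional boolean
attribute filters (e.g. mitochondria-targeted, expressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bsa_statistics import ScanConfig

__all__ = [
    "QTLInterval",
    "GeneRecord",
    "significance_mask",
    "call_intervals",
    "consensus",
    "genes_in_intervals",
    "report",
]

log = logging.getLogger(__name__)

METHODS = ("gprime", "delta", "ed")

#: which track column carries each method's peak statistic
_PEAK_COLUMN = {"gprime": "Gprime", "delta": "delta_smooth", "ed": "ed_fit"}


@dataclass
class QTLInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    method: str
    n_snps: int
    peak_pos: int
    peak_value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    flags: dict = field(default_factory=dict)
    n_variants: int = 0


def significance_mask(track: pd.DataFrame, method: str, thresholds: dict) -> np.ndarray:
    """Per-SNP boolean significance for one method.

    gprime: q <= fdr_q; delta: smoothed delta outside the configured CI
    band; ed: loess-fitted ED^k at or above the threshold.  NaN statistics
    are never significant.
    """
    if method == "gprime":
        return (track["q"].to_numpy() <= thresholds["fdr_q"]) & np.isfinite(
            track["Gprime"].to_numpy()
        )
    if method == "delta":
        level = int(thresholds.get("delta_ci_level", 99))
        lo = track[f"ci{level}_lo"].to_numpy()
        hi = track[f"ci{level}_hi"].to_numpy()
        d = track["delta_smooth"].to_numpy()
        return np.isfinite(d) & ((d < lo) | (d > hi))
    if method == "ed":
        thr = thresholds["ed_threshold"]
        fit = track["ed_fit"].to_numpy()
        if isinstance(thr, dict):
            per = np.array([thr.get(str(c), np.inf) for c in track["chrom"]])
            return np.isfinite(fit) & (fit >= per)
        return np.isfinite(fit) & (fit >= thr)
    raise ValueError(f"unknown method {method!r}")


def call_intervals(
    track: pd.DataFrame,
    method: str,
    thresholds: dict,
    min_run: int = 10,
    max_gap_bp: float | None = None,
) -> list[QTLInterval]:
    """Maximal runs of >= min_run consecutive significant SNPs per chromosome.

    Runs are additionally broken where adjacent significant SNPs are more
    than ``max_gap_bp`` apart (default: the scan window size from the
    thresholds config), so signals are never merged across gaps larger than
    one window.  Boundaries sit at the first/last significant SNP; the peak
    is the SNP with the largest |statistic|.
    """
    if max_gap_bp is None:
        max_gap_bp = thresholds.get("config", {}).get("window_bp", ScanConfig.window_bp)
    mask = significance_mask(track, method, thresholds)
    stat_col = _PEAK_COLUMN[method]
    intervals: list[QTLInterval] = []
    for chrom, idx in track.groupby("chrom", sort=False).indices.items():
        sub_mask = mask[idx]
        pos = track["pos"].to_numpy()[idx]
        stat = track[stat_col].to_numpy()[idx]
        sig = np.flatnonzero(sub_mask)
        if len(sig) == 0:
            continue
        # split runs on non-consecutive indices or over-wide gaps
        breaks = np.flatnonzero(
            (np.diff(sig) != 1) | (np.diff(pos[sig]) > max_gap_bp)
        )
        for run in np.split(sig, breaks + 1):
            if len(run) < min_run:
                continue
            peak_i = run[np.argmax(np.abs(stat[run]))]
            intervals.append(
                QTLInterval(
                    chrom=str(chrom),
                    start=int(pos[run[0]]),
                    end=int(pos[run[-1]]),
                    method=method,
                    n_snps=int(len(run)),
                    peak_pos=int(pos[peak_i]),
                    peak_value=float(stat[peak_i]),
                )
            )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals


def _merged_coverage(intervals: list[QTLInterval]) -> list[tuple[str, int, int]]:
    """Merge to disjoint half-open (chrom, start, end+1) coverage."""
    out: list[tuple[str, int, int]] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start)):
        s, e = iv.start, iv.end + 1
        if out and out[-1][0] == iv.chrom and s <= out[-1][2]:
            out[-1] = (iv.chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((iv.chrom, s, e))
    return out


def consensus(
    intervals_by_method: dict[str, list[QTLInterval]],
    min_methods: int = 2,
    track: pd.DataFrame | None = None,
) -> list[QTLInterval]:
    """Regions covered by intervals from at least ``min_methods`` methods.

    Computed as a sweep over the per-method merged coverage functions; with
    min_methods=1 this is the union.  If a track is supplied, n_snps and the
    peak (by G') are filled from it, otherwise they are left at 0/NaN.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for method, ivs in intervals_by_method.items():
        for chrom, s, e in _merged_coverage(ivs):
            events.setdefault(chrom, []).append((s, +1))
            events.setdefault(chrom, []).append((e, -1))
    out: list[QTLInterval] = []
    for chrom in sorted(events):
        pts = sorted(events[chrom])
        depth = 0
        region_start: int | None = None
        segments: list[tuple[int, int]] = []
        for pos_pt, delta in pts:
            prev = depth
            depth += delta
            if prev < min_methods <= depth:
                region_start = pos_pt
            elif prev >= min_methods > depth and region_start is not None:
                segments.append((region_start, pos_pt))
                region_start = None
        # merge adjacent segments (touching half-open ends)
        merged: list[list[int]] = []
        for s, e in segments:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            start, end = int(s), int(e - 1)
            n_snps, peak_pos, peak_value = 0, start, float("nan")
            if track is not None:
                sel = (track["chrom"] == chrom) & (track["pos"] >= start) & (track["pos"] <= end)
                n_snps = int(sel.sum())
                if n_snps:
                    sub = track.loc[sel]
                    k = sub["Gprime"].abs().idxmax()
                    peak_pos = int(sub.loc[k, "pos"])
                    peak_value = float(sub.loc[k, "Gprime"])
            out.append(
                QTLInterval(chrom=str(chrom), start=start, end=end, method="consensus",
                            n_snps=n_snps, peak_pos=peak_pos, peak_value=peak_value)
            )
    return out


# --- annotation intersection ------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y"}


def _parse_gff3(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                log.warning("%s:%d: malformed GFF3 line skipped", path, lineno)
                continue
            chrom, _, ftype, start, end, _, _, _, attrs = fields
            if ftype.lower() != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                log.warning("%s:%d: non-numeric coordinates skipped", path, lineno)
                continue
            attr_map: dict[str, str] = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID", f"{chrom}:{start}-{end}")
            flags = {
                k: attr_map[k].lower() in _TRUTHY
                for k in attr_map
                if k not in ("ID", "Name", "Parent")
            }
            genes.append(GeneRecord(gene_id, chrom, start_i, end_i, flags))
    return genes


def _parse_bed(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                log.warning("%s:%d: malformed BED line skipped", path, lineno)
                continue
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                log.warning("%s:%d: non-numeric coordinates skipped", path, lineno)
                continue
            flags: dict[str, bool] = {}
            for extra in fields[6:]:
                if "=" in extra:
                    k, v = extra.split("=", 1)
                    flags[k.strip()] = v.strip().lower() in _TRUTHY
            # BED is 0-based half-open; internal coordinates 1-based inclusive
            genes.append(GeneRecord(fields[3], fields[0], start0 + 1, end0, flags))
    return genes


def genes_in_intervals(
    intervals: list[QTLInterval],
    annotation: str | Path,
    flag_filters: dict[str, bool] | None = None,
    snp_positions: pd.DataFrame | None = None,
) -> list[GeneRecord]:
    """Genes overlapping any interval by >= 1 bp, after flag filtering.

    ``annotation`` is GFF3 (gene features with ID= and optional boolean
    attributes) or BED 6+ (flag columns as key=value from column 7 on),
    chosen by extension.  ``snp_positions`` (chrom/pos columns) fills each
    gene's n_variants count.
    """
    path = Path(annotation)
    if path.suffix.lower() in (".bed",):
        genes = _parse_bed(path)
    else:
        genes = _parse_gff3(path)
    cov = _merged_coverage(intervals)
    selected: list[GeneRecord] = []
    for g in genes:
        hit = any(
            c == g.chrom and g.start <= e - 1 and g.end >= s for c, s, e in cov
        )
        if not hit:
            continue
        if flag_filters and any(g.flags.get(k, False) != v for k, v in flag_filters.items()):
            continue
        if snp_positions is not None:
            sel = (
                (snp_positions["chrom"] == g.chrom)
                & (snp_positions["pos"] >= g.start)
                & (snp_positions["pos"] <= g.end)
            )
            g.n_variants = int(sel.sum())
        selected.append(g)
    selected.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return selected


def report(
    intervals: list[QTLInterval],
    genes: list[GeneRecord],
    out_dir: str | Path,
    truth: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write intervals TSV (+BED export), genes TSV, and a text summary.

    Ordering is deterministic (chrom, start).  When a simulation truth
    sidecar is supplied, each interval gains a covers_truth column.  The
    consensus rule (region supported by >= N methods) is a construction of
    this pipeline, and the summary says so.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.method))

    rows = []
    t_chrom = truth.get("qtl_chrom") if truth else None
    t_pos = int(truth["qtl_pos"]) if truth and "qtl_pos" in truth else None
    for iv in ivs:
        row = {
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "method": iv.method, "n_snps": iv.n_snps,
            "peak_pos": iv.peak_pos, "peak_value": iv.peak_value,
        }
        if t_pos is not None:
            row["covers_truth"] = iv.contains(t_chrom, t_pos)
        rows.append(row)
    iv_df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "method", "n_snps", "peak_pos", "peak_value"]
        + (["covers_truth"] if t_pos is not None else []),
    )
    intervals_tsv = out_dir / "intervals.tsv"
    iv_df.to_csv(intervals_tsv, sep="\t", index=False, float_format="%.6g")

    bed_path = out_dir / "intervals.bed"
    with open(bed_path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.method}\n")

    genes_tsv = out_dir / "genes.tsv"
    g_rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
            "n_variants": g.n_variants,
            **{k: v for k, v in sorted(g.flags.items())},
        }
        for g in genes
    ]
    pd.DataFrame(
        g_rows, columns=["gene_id", "chrom", "start", "end", "n_variants"]
        + sorted({k for g in genes for k in g.flags}),
    ).to_csv(genes_tsv, sep="\t", index=False)

    summary_path = out_dir / "summary.txt"
    lines = ["QTL interval report", "==================", ""]
    by_method: dict[str, list[QTLInterval]] = {}
    for iv in ivs:
        by_method.setdefault(iv.method, []).append(iv)
    for method in sorted(by_method):
        lines.append(f"[{method}] {len(by_method[method])} interval(s)")
        for iv in by_method[method]:
            extra = ""
            if t_pos is not None:
                extra = f"  covers_truth={iv.contains(t_chrom, t_pos)}"
            lines.append(
                f"  {iv.chrom}:{iv.start}-{iv.end}  n_snps={iv.n_snps}"
                f"  peak={iv.peak_pos} ({iv.peak_value:.4g}){extra}"
            )
        lines.append("")
    lines.append(
        "note: consensus regions require support from multiple methods; the "
        "combination rule is a convention of this pipeline."
    )
    lines.append("")
    lines.append(f"candidate genes: {len(genes)}")
    for g in genes:
        flags = ",".join(f"{k}={v}" for k, v in sorted(g.flags.items()))
        lines.append(
            f"  {g.gene_id}  {g.chrom}:{g.start}-{g.end}  variants={g.n_variants}"
            + (f"  [{flags}]" if flags else "")
        )
    summary_path.write_text("\n".join(lines) + "\n")

    return {
        "intervals": intervals_tsv,
        "bed": bed_path,
        "genes": genes_tsv,
        "summary": summary_path,
    }
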