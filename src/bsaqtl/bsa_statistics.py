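"""Genome-scan statistics over a screened SNP table.

Three complementary statistics of bulk allele-frequency divergence:

* delta SNP-index, with Monte-Carlo null confidence bands per read depth;
* the G likelihood-ratio statistic, tricube-smoothed to G' and tested
  against a Hampel-trimmed log-normal null with Benjamini-Hochberg FDR;
* the Euclidean distance raised to the fifth power, loess-fitted per
  chromosome with a genome-wide median + 3 SD threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._loess import loess_fit

__all__ = [
    "ScanConfig",
    "snp_index",
    "delta_snp_index",
    "euclidean_distance",
    "ed_power",
    "g_statistic",
    "tricube_smooth",
    "gprime",
    "gprime_pq",
    "DeltaCINull",
    "ed_loess_threshold",
    "compute_track",
    "write_track",
    "read_track",
]

log = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tuning constants for the genome scan; defaults follow the study design."""

    window_bp: float = 1_000_000.0
    fdr_q: float = 0.01
    ed_exponent: float = 5.0
    ci_levels: tuple[int, ...] = (95, 99)
    ci_reps: int = 10_000
    bulk_size: int = 30
    pop_structure: str = "BC1"  # or "F2"
    loess_span: float = 0.3
    loess_degree: int = 2
    #: Hampel trim: drop ln G' above median + hampel_k * MAD before null fit
    hampel_k: float = 5.2
    #: consistency scale turning MAD into a normal-sigma estimate
    mad_scale: float = 1.4826
    #: ED threshold policy: fitted-vs-raw values, genome-wide vs per-chrom
    ed_threshold_on: str = "fitted"  # or "raw"
    ed_threshold_scope: str = "genome"  # or "chromosome"
    #: CI band used for delta-based interval calls
    delta_ci_level: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.ed_exponent < 1:
            raise ValueError("ed_exponent must be >= 1")
        if self.pop_structure not in ("BC1", "F2"):
            raise ValueError("pop_structure must be BC1 or F2")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")


def snp_index(donor_depth, other_depth):
    """Fraction of reads carrying the donor allele; total depth must be > 0."""
    donor_depth = np.asarray(donor_depth, dtype=float)
    other_depth = np.asarray(other_depth, dtype=float)
    total = donor_depth + other_depth
    if np.any(total <= 0):
        raise ValueError("snp_index undefined at zero total depth")
    return donor_depth / total


def delta_snp_index(idx_f, idx_s):
    """Fertile-bulk minus sterile-bulk SNP-index, in [-1, 1]."""
    return np.asarray(idx_f, dtype=float) - np.asarray(idx_s, dtype=float)


def euclidean_distance(idx_f, idx_s):
    """Distance between the bulks' (donor, other) frequency vectors.

    For a biallelic marker this collapses to sqrt(2) * |idxF - idxS|.
    """
    idx_f = np.asarray(idx_f, dtype=float)
    idx_s = np.asarray(idx_s, dtype=float)
    return np.sqrt((idx_f - idx_s) ** 2 + ((1 - idx_f) - (1 - idx_s)) ** 2)


def ed_power(ed, k: float = 5.0):
    """Raise ED to the k-th power (peak sharpening before fitting)."""
    return np.asarray(ed, dtype=float) ** k


def g_statistic(a_f, r_f, a_s, r_s):
    """2x2 likelihood-ratio G over (donor, other) x (F, S) allele depths.

    G = 2 * sum n_i ln(n_i / nhat_i) with nhat from row/column products;
    0 * ln 0 = 0, and a zero row or column total gives G = 0.
    """
    cells = np.stack(
        [np.asarray(x, dtype=float) for x in (a_f, r_f, a_s, r_s)], axis=-1
    )
    if np.any(cells < 0):
        raise ValueError("negative allele depths")
    n = cells.sum(axis=-1)
    row_f = cells[..., 0] + cells[..., 1]
    row_s = cells[..., 2] + cells[..., 3]
    col_a = cells[..., 0] + cells[..., 2]
    col_r = cells[..., 1] + cells[..., 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        expect = (
            np.stack(
                [row_f * col_a, row_f * col_r, row_s * col_a, row_s * col_r], axis=-1
            )
            / n[..., None]
        )
        terms = np.where(cells > 0, cells * np.log(cells / expect), 0.0)
    g = 2.0 * np.nansum(terms, axis=-1)
    degenerate = (row_f == 0) | (row_s == 0) | (col_a == 0) | (col_r == 0) | (n == 0)
    return np.where(degenerate, 0.0, g)


def tricube_smooth(values, positions, window_bp: float):
    """Tricube-kernel weighted mean over a full window of ``window_bp``.

    For a focal position p, neighbours within window_bp / 2 contribute with
    weight (1 - (2D / window_bp)^3)^3 where D is the distance.  Positions
    must be sorted (one chromosome at a time).  NaN values are excluded
    from the averages.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = len(values)
    if n == 0:
        return np.empty(0)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted within a chromosome")
    half = window_bp / 2.0
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    out = np.empty(n)
    finite = np.isfinite(values)
    for i in range(n):
        sl = slice(lo[i], hi[i])
        w = (1.0 - (2.0 * np.abs(positions[sl] - positions[i]) / window_bp) ** 3) ** 3
        w = np.where(finite[sl], np.clip(w, 0.0, None), 0.0)
        wsum = w.sum()
        out[i] = np.dot(w, np.nan_to_num(values[sl])) / wsum if wsum > 0 else np.nan
    return out


def gprime(g_values, positions, window_bp: float):
    """Smoothed G: tricube weighting of per-SNP G within the window."""
    return tricube_smooth(g_values, positions, window_bp)


def gprime_pq(gprime_values, fdr_q: float = 0.01, hampel_k: float = 5.2,
              mad_scale: float = 1.4826):
    """Log-normal null p/q-values for G' and the FDR significance mask.

    The null is fitted on ln G' after Hampel trimming: values above
    median + hampel_k * MAD are dropped, then mu = median and
    sigma = mad_scale * MAD of the retained values.  p = upper normal tail,
    q by Benjamini-Hochberg, mask = (q <= fdr_q).
    """
    gp = np.asarray(gprime_values, dtype=float)
    p = np.ones_like(gp)
    usable = np.isfinite(gp) & (gp > 0)
    if usable.sum() >= 2:
        ln_g = np.log(gp[usable])
        med = np.median(ln_g)
        mad = np.median(np.abs(ln_g - med))
        retained = ln_g[ln_g <= med + hampel_k * mad]
        mu = np.median(retained)
        sigma = mad_scale * np.median(np.abs(retained - mu))
        if sigma <= 0:
            warnings.warn("degenerate constant G' track: sigma-hat is 0; all p = 1")
        else:
            p[usable] = sps.norm.sf((np.log(gp[usable]) - mu) / sigma)
    mask, q, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")[:4]
    return p, q, mask & usable


class DeltaCINull:
    """Monte-Carlo null for the delta SNP-index, memoized per read depth.

    Each replicate draws bulk_size genotypes per bulk under no-QTL
    segregation (BC1: het w.p. 1/2, else hom-recurrent; F2: 1:2:1), forms
    the pooled donor frequency, draws Binomial(depth, freq) donor reads for
    each bulk, and records idxF - idxS.  Bounds are the empirical 2.5/97.5
    and 0.5/99.5 percentiles.
    """

    def __init__(self, cfg: ScanConfig):
        if cfg.ci_reps < 100:
            raise ValueError("ci_reps < 100 gives meaningless quantiles; refusing")
        self.cfg = cfg
        self._cache: dict[int, tuple[float, float, float, float]] = {}

    def _pool_freq(self, rng: np.random.Generator, reps: int) -> np.ndarray:
        bs = self.cfg.bulk_size
        if self.cfg.pop_structure == "BC1":
            hets = rng.binomial(bs, 0.5, size=reps)
            return 0.5 * hets / bs
        # F2: per plant donor-allele dosage ~ Binomial(2, 1/2)
        dosage = rng.binomial(2 * bs, 0.5, size=reps)
        return dosage / (2 * bs)

    def bounds(self, depth: int) -> tuple[float, float, float, float]:
        """(ci95_lo, ci95_hi, ci99_lo, ci99_hi) at the given total bulk depth."""
        depth = int(depth)
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if depth not in self._cache:
            rng = np.random.default_rng([self.cfg.seed, depth])
            reps = self.cfg.ci_reps
            deltas = np.empty(reps)
            f_freq = self._pool_freq(rng, reps)
            s_freq = self._pool_freq(rng, reps)
            idx_f = rng.binomial(depth, f_freq) / depth
            idx_s = rng.binomial(depth, s_freq) / depth
            deltas = idx_f - idx_s
            lo95, hi95 = np.percentile(deltas, [2.5, 97.5])
            lo99, hi99 = np.percentile(deltas, [0.5, 99.5])
            self._cache[depth] = (float(lo95), float(hi95), float(lo99), float(hi99))
        return self._cache[depth]

    def bounds_for(self, depths: np.ndarray) -> np.ndarray:
        """Row-per-SNP bounds array for a vector of depths."""
        depths = np.asarray(depths, dtype=int)
        uniq = np.unique(depths)
        table = {d: self.bounds(int(d)) for d in uniq}
        return np.array([table[int(d)] for d in depths])


def ed_loess_threshold(
    ed5: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    cfg: ScanConfig,
) -> tuple[np.ndarray, float | dict[str, float]]:
    """Per-chromosome loess fit of ED^k against position, plus the threshold.

    Threshold = median(values) + 3 * SD(values) where the values are the
    fitted ones by default (cfg.ed_threshold_on) pooled genome-wide
    (cfg.ed_threshold_scope; per-chromosome returns a dict).  SD is the
    population standard deviation.  Chromosomes too small for the span fall
    back to tricube smoothing with window_bp, with a warning.
    """
    ed5 = np.asarray(ed5, dtype=float)
    positions = np.asarray(positions, dtype=float)
    chroms = np.asarray(chroms)
    fitted = np.full(len(ed5), np.nan)
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        pos_c = positions[m]
        val_c = ed5[m]
        ok = np.isfinite(val_c)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        min_pts = max(10, cfg.loess_degree + 2)
        if n_ok < min_pts or n_ok * cfg.loess_span < cfg.loess_degree + 2:
            log.warning(
                "chromosome %s has %d usable SNPs; falling back to tricube "
                "smoothing for the ED fit", chrom, n_ok,
            )
            fitted[m] = tricube_smooth(val_c, pos_c, cfg.window_bp)
            continue
        sub = np.full(len(val_c), np.nan)
        sub[ok] = loess_fit(pos_c[ok], val_c[ok], span=cfg.loess_span,
                            degree=cfg.loess_degree)
        fitted[m] = sub

    source = fitted if cfg.ed_threshold_on == "fitted" else ed5

    def _thr(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return float("nan")
        return float(np.median(v) + 3.0 * np.std(v))

    if cfg.ed_threshold_scope == "genome":
        return fitted, _thr(source)
    return fitted, {str(c): _thr(source[chroms == c]) for c in pd.unique(chroms)}


TRACK_COLUMNS = [
    "chrom", "pos", "aF", "rF", "aS", "rS",
    "idxF", "idxS", "delta", "delta_smooth",
    "ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi",
    "G", "Gprime", "p", "q",
    "ED", "ED5", "ed_fit",
]


def compute_track(snps: pd.DataFrame, cfg: ScanConfig | None = None,
                  ci_null: DeltaCINull | None = None) -> tuple[pd.DataFrame, dict]:
    """Full per-SNP scan over a screened SNP table.

    Returns the track DataFrame (sorted by chrom, pos; one row per SNP with
    every scan column) and a thresholds dict with the ED threshold, the FDR
    level, and the G' null-fit parameters implicitly encoded in p/q.
    Confidence bands are simulated at each SNP's min bulk depth and then
    tricube-smoothed alongside delta so the bands match the smoothed track.
    """
    cfg = cfg or ScanConfig()
    df = snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True).copy()
    for col in ("aF", "rF", "aS", "rS"):
        if col not in df.columns:
            raise ValueError(f"SNP table missing column {col}")

    df["idxF"] = snp_index(df["aF"], df["rF"])
    df["idxS"] = snp_index(df["aS"], df["rS"])
    df["delta"] = delta_snp_index(df["idxF"], df["idxS"])
    df["G"] = g_statistic(df["aF"], df["rF"], df["aS"], df["rS"])
    df["ED"] = euclidean_distance(df["idxF"], df["idxS"])
    df["ED5"] = ed_power(df["ED"], cfg.ed_exponent)

    ci_null = ci_null or DeltaCINull(cfg)
    depth = np.minimum(df["aF"] + df["rF"], df["aS"] + df["rS"]).to_numpy()
    ci_raw = ci_null.bounds_for(depth)

    delta_smooth = np.empty(len(df))
    gp = np.empty(len(df))
    ci_smooth = np.empty((len(df), 4))
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        pos = df["pos"].to_numpy()[idx].astype(float)
        delta_smooth[idx] = tricube_smooth(df["delta"].to_numpy()[idx], pos, cfg.window_bp)
        gp[idx] = gprime(df["G"].to_numpy()[idx], pos, cfg.window_bp)
        for j in range(4):
            ci_smooth[idx, j] = tricube_smooth(ci_raw[idx, j], pos, cfg.window_bp)
    df["delta_smooth"] = delta_smooth
    df["Gprime"] = gp
    df[["ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi"]] = ci_smooth

    p, q, _ = gprime_pq(df["Gprime"].to_numpy(), cfg.fdr_q, cfg.hampel_k, cfg.mad_scale)
    df["p"] = p
    df["q"] = q

    ed_fit, ed_threshold = ed_loess_threshold(
        df["ED5"].to_numpy(), df["pos"].to_numpy(), df["chrom"].to_numpy(), cfg
    )
    df["ed_fit"] = ed_fit

    thresholds = {
        "ed_threshold": ed_threshold,
        "fdr_q": cfg.fdr_q,
        "delta_ci_level": cfg.delta_ci_level,
        "config": asdict(cfg),
    }
    return df[TRACK_COLUMNS], thresholds


def write_track(track: pd.DataFrame, thresholds: dict,
                track_path: str | Path, thresholds_path: str | Path) -> None:
    track.to_csv(track_path, sep="\t", index=False, float_format="%.10g")
    Path(thresholds_path).write_text(json.dumps(thresholds, indent=2) + "\n")


def read_track(track_path: str | Path, thresholds_path: str | Path | None = None):
    track = pd.read_csv(track_path, sep="\t")
    if thresholds_path is None:
        return track
    thresholds = json.loads(Path(thresholds_path).read_text())
    return track, thresholds
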