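"""Simulation of BC1 bulked-segregant sequencing datasets.

Generates a marker map, a backcross population segregating one dominant
restorer locus with configurable (quantitative) penetrance, phenotypic
extreme bulks, pooled read counts, and a multi-sample VCF plus a ground
truth sidecar, so the downstream screening and scan stages can be tested
without any external sequencing data.

Sample names in the emitted VCF are fixed: ``P596`` (donor parent,
restorer carrier), ``P1318`` (recurrent parent), ``F_bulk``, ``S_bulk``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MarkerMap",
    "RestorerQTL",
    "BC1Individual",
    "Bulk",
    "SimTruth",
    "build_marker_map",
    "simulate_bc1",
    "select_bulks",
    "simulate_bulk_reads",
    "emit_vcf",
    "counts_to_snp_table",
    "read_truth",
]

DONOR_SAMPLE = "P596"
RECURRENT_SAMPLE = "P1318"
FBULK_SAMPLE = "F_bulk"
SBULK_SAMPLE = "S_bulk"

# Default fertility-grade distributions (grades 0..4).  Carriers of the
# dominant restorer allele skew fertile but with incomplete penetrance;
# non-carriers skew sterile with a small misclassification tail.
DEFAULT_CARRIER_GRADES = (0.02, 0.08, 0.20, 0.35, 0.35)
DEFAULT_NONCARRIER_GRADES = (0.60, 0.30, 0.08, 0.02, 0.00)

_BASES = np.array(["A", "C", "G", "T"])


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MarkerMap:
    """Biallelic SNP marker positions plus donor-parent allele assignment.

    ``donor_is_alt[chrom][i]`` is True when the donor parent carries the
    ALT allele at marker ``i`` (and the recurrent parent the REF allele).
    """

    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    donor_is_alt: dict[str, np.ndarray]
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def validate(self) -> None:
        for chrom, pos in self.positions.items():
            if len(pos) == 0:
                raise ConfigurationError(f"no markers on {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(f"positions not strictly increasing on {chrom}")
            if pos[0] < 1 or pos[-1] > self.chrom_lengths[chrom]:
                raise ConfigurationError(f"marker outside {chrom} bounds")
            if np.any(self.ref[chrom] == self.alt[chrom]):
                raise ConfigurationError(f"REF == ALT at a marker on {chrom}")


@dataclass
class RestorerQTL:
    """Dominant restorer locus with per-genotype fertility-grade distributions."""

    chrom: str
    pos_bp: int
    grade_dist_carrier: tuple[float, ...] = DEFAULT_CARRIER_GRADES
    grade_dist_noncarrier: tuple[float, ...] = DEFAULT_NONCARRIER_GRADES

    def __post_init__(self) -> None:
        for name, dist in (
            ("grade_dist_carrier", self.grade_dist_carrier),
            ("grade_dist_noncarrier", self.grade_dist_noncarrier),
        ):
            dist = tuple(float(x) for x in dist)
            if len(dist) != 5 or any(x < 0 for x in dist):
                raise ConfigurationError(f"{name} must be 5 non-negative probabilities")
            if abs(sum(dist) - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} must sum to 1 (got {sum(dist)!r})")
            object.__setattr__(self, name, dist)


@dataclass
class BC1Individual:
    """One backcross plant: het/hom-recurrent state per marker plus a grade.

    ``genotype[chrom]`` is a boolean array over markers, True = heterozygous
    (carries the donor allele), False = homozygous recurrent.
    """

    genotype: dict[str, np.ndarray]
    carrier: bool  # heterozygous at the restorer locus itself
    grade: int

    def __post_init__(self) -> None:
        if not 0 <= self.grade <= 4:
            raise ConfigurationError(f"grade {self.grade} outside [0, 4]")


@dataclass
class Bulk:
    """A phenotypic extreme pool with per-marker donor-allele frequency."""

    label: str
    members: list[int]
    donor_freq: dict[str, np.ndarray]


@dataclass
class SimTruth:
    qtl: RestorerQTL
    seed: int
    f_members: list[int]
    s_members: list[int]
    depth_model: str
    error_rate: float
    extra: dict = field(default_factory=dict)


def build_marker_map(
    n_chrom: int,
    chrom_len_bp: int,
    marker_spacing_bp: int,
    seed: int | np.random.Generator,
) -> MarkerMap:
    """Lay out SNP markers at jittered regular spacing on equal-length chromosomes.

    Jitter is uniform in +/- spacing/4 around the regular grid, preserving
    strict ordering.  A spacing larger than the chromosome yields exactly one
    marker at the midpoint.  Donor alleles are assigned REF or ALT uniformly.
    """
    if n_chrom < 1:
        raise ConfigurationError("n_chrom must be >= 1")
    if chrom_len_bp < 1:
        raise ConfigurationError("chromosome length must be >= 1 bp")
    if marker_spacing_bp < 1:
        raise ConfigurationError("marker spacing must be >= 1 bp")
    rng = _as_rng(seed)
    chrom_lengths: dict[str, int] = {}
    positions: dict[str, np.ndarray] = {}
    donor_is_alt: dict[str, np.ndarray] = {}
    ref: dict[str, np.ndarray] = {}
    alt: dict[str, np.ndarray] = {}
    for c in range(n_chrom):
        name = f"chr{c + 1:02d}"
        chrom_lengths[name] = int(chrom_len_bp)
        if marker_spacing_bp > chrom_len_bp:
            pos = np.array([max(1, chrom_len_bp // 2)], dtype=np.int64)
        else:
            grid = np.arange(marker_spacing_bp, chrom_len_bp + 1, marker_spacing_bp, dtype=np.int64)
            jitter_span = max(1, marker_spacing_bp // 4)
            jitter = rng.integers(-jitter_span, jitter_span + 1, size=len(grid))
            pos = np.clip(grid + jitter, 1, chrom_len_bp)
            pos = np.unique(pos)
        n = len(pos)
        positions[name] = pos
        donor_is_alt[name] = rng.random(n) < 0.5
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        ref[name] = _BASES[ref_idx]
        alt[name] = _BASES[alt_idx]
    mm = MarkerMap(chrom_lengths, positions, donor_is_alt, ref, alt)
    mm.validate()
    return mm


def _haldane_recomb(dist_bp: np.ndarray, recomb_rate: float) -> np.ndarray:
    # Haldane mapping function; recomb_rate in Morgan/bp.
    d = dist_bp * recomb_rate
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def simulate_bc1(
    marker_map: MarkerMap,
    qtl: RestorerQTL,
    n: int,
    recomb_rate: float = 4e-8,
    seed: int | np.random.Generator = 0,
) -> list[BC1Individual]:
    """Simulate ``n`` BC1 individuals as two-state Markov walks along markers.

    Each chromosome starts het or hom-recurrent with probability 1/2 and
    switches state between adjacent loci with the Haldane recombination
    probability.  The restorer locus is walked as a latent position on its
    chromosome; fertility grades are drawn from the genotype-matched
    distribution.  Default ``recomb_rate`` of 4e-8 Morgan/bp is 4 cM/Mb.
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    if qtl.chrom not in marker_map.chrom_lengths:
        raise ConfigurationError(f"QTL chromosome {qtl.chrom!r} not in marker map")
    if not 1 <= qtl.pos_bp <= marker_map.chrom_lengths[qtl.chrom]:
        raise ConfigurationError("QTL position outside chromosome")
    rng = _as_rng(seed)

    genotypes: dict[str, np.ndarray] = {}
    carrier = np.zeros(n, dtype=bool)
    for chrom in marker_map.chroms:
        pos = marker_map.positions[chrom]
        if chrom == qtl.chrom:
            walk_pos = np.sort(np.unique(np.append(pos, qtl.pos_bp)))
        else:
            walk_pos = pos
        m = len(walk_pos)
        start = rng.random(n) < 0.5
        if m > 1:
            r = _haldane_recomb(np.diff(walk_pos).astype(float), recomb_rate)
            switches = rng.random((n, m - 1)) < r[None, :]
            parity = np.cumsum(switches, axis=1) & 1
            states = np.empty((n, m), dtype=bool)
            states[:, 0] = start
            states[:, 1:] = start[:, None] ^ parity.astype(bool)
        else:
            states = start[:, None]
        if chrom == qtl.chrom:
            qtl_col = int(np.searchsorted(walk_pos, qtl.pos_bp))
            carrier = states[:, qtl_col]
            marker_cols = np.searchsorted(walk_pos, pos)
            genotypes[chrom] = states[:, marker_cols]
        else:
            genotypes[chrom] = states

    grades = np.empty(n, dtype=np.int64)
    pc = np.asarray(qtl.grade_dist_carrier)
    pn = np.asarray(qtl.grade_dist_noncarrier)
    n_car = int(carrier.sum())
    grades[carrier] = rng.choice(5, size=n_car, p=pc)
    grades[~carrier] = rng.choice(5, size=n - n_car, p=pn)

    return [
        BC1Individual(
            genotype={c: genotypes[c][i] for c in marker_map.chroms},
            carrier=bool(carrier[i]),
            grade=int(grades[i]),
        )
        for i in range(n)
    ]


def select_bulks(
    pop: Sequence[BC1Individual],
    bulk_size: int,
    f_grades: set[int] = frozenset({3, 4}),
    s_grades: set[int] = frozenset({0, 1}),
    seed: int | np.random.Generator = 0,
) -> tuple[Bulk, Bulk]:
    """Draw the fertile and sterile extreme bulks and pool their donor alleles.

    Members are sampled uniformly without replacement from the eligible grade
    classes.  The pooled donor-allele frequency at a marker is
    (het members) * 0.5 / bulk_size, so BC1 pools live on the exact grid of
    multiples of 0.5/bulk_size.
    """
    rng = _as_rng(seed)
    f_eligible = [i for i, ind in enumerate(pop) if ind.grade in f_grades]
    s_eligible = [i for i, ind in enumerate(pop) if ind.grade in s_grades]
    for label, eligible in (("F", f_eligible), ("S", s_eligible)):
        if len(eligible) < bulk_size:
            raise ConfigurationError(
                f"{label}-bulk needs {bulk_size} plants but only {len(eligible)} "
                f"eligible ({bulk_size - len(eligible)} short)"
            )

    def _make(label: str, eligible: list[int]) -> Bulk:
        members = sorted(rng.choice(eligible, size=bulk_size, replace=False).tolist())
        freq = {
            chrom: np.mean(
                [pop[i].genotype[chrom].astype(float) * 0.5 for i in members], axis=0
            )
            for chrom in pop[0].genotype
        }
        return Bulk(label=label, members=members, donor_freq=freq)

    return _make("F", f_eligible), _make("S", s_eligible)


def simulate_bulk_reads(
    bulk: Bulk,
    depth_low: int = 10,
    depth_high: int = 100,
    error_rate: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Draw pooled read counts per marker: (donor_depth, other_depth).

    Total depth is discrete Uniform[depth_low, depth_high]; donor reads are
    Binomial(depth, f*(1-e) + (1-f)*e) where f is the pooled donor frequency
    and e the per-read miscall rate.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ConfigurationError("error_rate must be in [0, 0.5)")
    if depth_low > depth_high or depth_low < 1:
        raise ConfigurationError("need 1 <= depth_low <= depth_high")
    rng = _as_rng(seed)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, f in bulk.donor_freq.items():
        depth = rng.integers(depth_low, depth_high + 1, size=len(f))
        p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
        donor = rng.binomial(depth, p)
        out[chrom] = (donor, depth - donor)
    return out


# --- VCF emission -----------------------------------------------------------

# Bulk GT-calling convention from the observed donor read fraction, so that
# the S-bulk genotype screening rule is exercisable on simulated data.
BULK_HOM_LOW = 0.15
BULK_HOM_HIGH = 0.85

_FAIL_MODES = ("qual", "qd", "fs", "mq", "mqranksum", "readposranksum")

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher\'s exact test to detect strand bias">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence normalized by depth">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Rank sum test of alt vs ref mapping qualities">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Rank sum test of alt vs ref read position bias">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">',
    f"##bulk_gt_convention=donor read fraction < {BULK_HOM_LOW} hom-recurrent, > {BULK_HOM_HIGH} hom-donor, else het",
]


def _bulk_gt(donor: int, other: int, donor_is_alt: bool) -> str:
    total = donor + other
    if total == 0:
        return "./."
    frac = donor / total
    if frac < BULK_HOM_LOW:
        return "0/0" if donor_is_alt else "1/1"
    if frac > BULK_HOM_HIGH:
        return "1/1" if donor_is_alt else "0/0"
    return "0/1"


def emit_vcf(
    marker_map: MarkerMap,
    f_counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    s_counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    truth: SimTruth,
    vcf_path: str | Path,
    truth_path: str | Path | None = None,
    contaminant_fraction: float = 0.0,
    parent_depth: int = 50,
    file_date: str | None = None,
    seed: int | np.random.Generator | None = None,
) -> Path:
    """Write a 4-sample VCF 4.2 (plain text) plus a ground-truth TSV sidecar.

    Site INFO annotations are drawn from hard-filter-passing ranges; with
    ``contaminant_fraction`` > 0 each site independently becomes a filter
    failure in one randomly chosen annotation.  With a fixed seed the body
    of the file is byte-identical across runs; only the ``##fileDate`` line
    varies unless ``file_date`` is pinned.
    """
    if not 0.0 <= contaminant_fraction <= 1.0:
        raise ConfigurationError("contaminant_fraction must be in [0, 1]")
    rng = _as_rng(truth.seed if seed is None else seed)
    vcf_path = Path(vcf_path)

    lines: list[str] = list(VCF_HEADER_LINES)
    if file_date is not None:
        lines.insert(1, f"##fileDate={file_date}")
    else:
        import datetime

        lines.insert(1, f"##fileDate={datetime.date.today():%Y%m%d}")
    for chrom, length in marker_map.chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{DONOR_SAMPLE}\t{RECURRENT_SAMPLE}\t{FBULK_SAMPLE}\t{SBULK_SAMPLE}"
    )

    for chrom in marker_map.chroms:
        pos = marker_map.positions[chrom]
        dia = marker_map.donor_is_alt[chrom]
        refs = marker_map.ref[chrom]
        alts = marker_map.alt[chrom]
        fd, fo = f_counts[chrom]
        sd, so = s_counts[chrom]
        n = len(pos)
        qual = rng.uniform(100.0, 1000.0, size=n)
        fs = rng.uniform(0.0, 5.0, size=n)
        mq = rng.uniform(50.0, 60.0, size=n)
        qd = rng.uniform(20.0, 35.0, size=n)
        mqrs = rng.uniform(-1.0, 1.0, size=n)
        rprs = rng.uniform(-1.0, 1.0, size=n)
        contaminate = rng.random(n) < contaminant_fraction
        modes = rng.integers(0, len(_FAIL_MODES), size=n)
        fail_vals = {
            "qual": rng.uniform(5.0, 25.0, size=n),
            "qd": rng.uniform(1.0, 10.0, size=n),
            "fs": rng.uniform(25.0, 60.0, size=n),
            "mq": rng.uniform(5.0, 15.0, size=n),
            "mqranksum": rng.uniform(-6.0, -3.5, size=n),
            "readposranksum": rng.uniform(-6.0, -3.5, size=n),
        }
        for i in range(n):
            if contaminate[i]:
                mode = _FAIL_MODES[modes[i]]
                v = fail_vals[mode][i]
                if mode == "qual":
                    qual[i] = v
                elif mode == "qd":
                    qd[i] = v
                elif mode == "fs":
                    fs[i] = v
                elif mode == "mq":
                    mq[i] = v
                elif mode == "mqranksum":
                    mqrs[i] = v
                else:
                    rprs[i] = v
            donor_gt, rec_gt = ("1/1", "0/0") if dia[i] else ("0/0", "1/1")
            if dia[i]:
                donor_ad = (0, parent_depth)
                rec_ad = (parent_depth, 0)
                f_ad = (int(fo[i]), int(fd[i]))
                s_ad = (int(so[i]), int(sd[i]))
            else:
                donor_ad = (parent_depth, 0)
                rec_ad = (0, parent_depth)
                f_ad = (int(fd[i]), int(fo[i]))
                s_ad = (int(sd[i]), int(so[i]))
            f_gt = _bulk_gt(int(fd[i]), int(fo[i]), bool(dia[i]))
            s_gt = _bulk_gt(int(sd[i]), int(so[i]), bool(dia[i]))
            info = (
                f"FS={fs[i]:.3f};MQ={mq[i]:.2f};QD={qd[i]:.2f};"
                f"MQRankSum={mqrs[i]:.3f};ReadPosRankSum={rprs[i]:.3f}"
            )
            fields = [
                chrom,
                str(int(pos[i])),
                ".",
                str(refs[i]),
                str(alts[i]),
                f"{qual[i]:.2f}",
                "PASS",
                info,
                "GT:AD:DP",
                f"{donor_gt}:{donor_ad[0]},{donor_ad[1]}:{sum(donor_ad)}",
                f"{rec_gt}:{rec_ad[0]},{rec_ad[1]}:{sum(rec_ad)}",
                f"{f_gt}:{f_ad[0]},{f_ad[1]}:{sum(f_ad)}",
                f"{s_gt}:{s_ad[0]},{s_ad[1]}:{sum(s_ad)}",
            ]
            lines.append("\t".join(fields))

    vcf_path.write_text("\n".join(lines) + "\n")

    if truth_path is not None:
        rows = [
            ("seed", str(truth.seed)),
            ("qtl_chrom", truth.qtl.chrom),
            ("qtl_pos", str(truth.qtl.pos_bp)),
            ("grade_dist_carrier", ",".join(map(str, truth.qtl.grade_dist_carrier))),
            ("grade_dist_noncarrier", ",".join(map(str, truth.qtl.grade_dist_noncarrier))),
            ("depth_model", truth.depth_model),
            ("error_rate", str(truth.error_rate)),
            ("f_members", ",".join(map(str, truth.f_members))),
            ("s_members", ",".join(map(str, truth.s_members))),
        ]
        Path(truth_path).write_text(
            "key\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
        )
    return vcf_path


def read_truth(path: str | Path) -> dict[str, str]:
    """Parse a truth sidecar TSV into a key->value dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("key\t"):
            raise ValueError(f"{path}: not a truth sidecar")
        for line in fh:
            k, _, v = line.rstrip("\n").partition("\t")
            out[k] = v
    return out


def counts_to_snp_table(
    marker_map: MarkerMap,
    f_counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    s_counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
):
    """Shortcut to a polarized screened-SNP table (skips VCF serialization).

    Useful for calibration experiments where the statistics, not the file
    round-trip, are under test.  Columns match the screening stage output.
    """
    import pandas as pd

    frames = []
    for chrom in marker_map.chroms:
        fd, fo = f_counts[chrom]
        sd, so = s_counts[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": marker_map.positions[chrom],
                    "donor_allele": np.where(marker_map.donor_is_alt[chrom], "ALT", "REF"),
                    "aF": fd,
                    "rF": fo,
                    "aS": sd,
                    "rS": so,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def vcf_body_digest(path: str | Path) -> str:
    """SHA-256 of the VCF minus its ##fileDate line (determinism checks)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for line in fh:
            if line.startswith(b"##fileDate="):
                continue
            h.update(line)
    return h.hexdigest()
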