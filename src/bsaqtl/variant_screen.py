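"""Multi-sample VCF reading, hard filtering, and SNP screening.

Consumes a 4-sample VCF (donor parent, recurrent parent, fertile bulk,
sterile bulk), applies GATK-style site hard filters and four genotype
screening rules, and emits a polarized per-SNP allele-depth table:
donor-allele vs other-allele read counts in each bulk.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "ScreenedSNP",
    "FilterReport",
    "FilterThresholds",
    "ScreenConfig",
    "read_vcf",
    "hard_filter",
    "screen_snp",
    "screen_table",
    "write_snp_table",
    "read_snp_table",
    "ScreenError",
]

ROLES = ("donor", "recurrent", "fbulk", "sbulk")

#: Drop reasons, in the order they are checked.
DROP_REASONS = (
    "multiallelic",
    "missing_fields",
    "low_qual",
    "qd",
    "fs",
    "mq",
    "mqranksum",
    "readposranksum",
    "parent_het",
    "parents_identical",
    "sbulk_mismatch",
    "depth_out_of_range",
)


class ScreenError(RuntimeError):
    """Raised when screening cannot proceed (e.g. nothing survives)."""


@dataclass
class VariantRecord:
    """One VCF site with role-keyed sample calls.

    ``samples[role]`` is a dict with keys ``gt`` (tuple of allele indices or
    None), ``ad`` (tuple of per-allele depths or None) and ``dp``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None
    info: dict[str, float]
    samples: dict[str, dict]
    multiallelic: bool = False


@dataclass
class ScreenedSNP:
    chrom: str
    pos: int
    donor_allele: str  # "REF" or "ALT"
    aF: int  # donor-allele depth, fertile bulk
    rF: int
    aS: int
    rS: int


@dataclass
class FilterThresholds:
    """Site-level hard-filter cutoffs; a record failing any clause is dropped.

    The mapping-quality-by-depth clause is read as GATK's QD annotation.
    Absent INFO keys pass their clause (GATK convention).
    """

    qual_min: float = 30.0
    qd_min: float = 13.0
    fs_max: float = 20.0
    mq_min: float = 20.0
    mqranksum_min: float = -3.0
    readposranksum_min: float = -3.0


@dataclass
class ScreenConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    depth_min: int = 10
    depth_max: int = 100
    #: which roles the depth bounds apply to
    depth_samples: tuple[str, ...] = ("fbulk", "sbulk")


@dataclass
class FilterReport:
    dropped: Counter = field(default_factory=Counter)
    kept: int = 0

    @property
    def total(self) -> int:
        return self.kept + sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": {r: int(self.dropped.get(r, 0)) for r in DROP_REASONS},
            "total": self.total,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_vcf(path: str | Path, sample_roles: dict[str, str]) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF, re-keying samples by role.

    ``sample_roles`` maps each of donor/recurrent/fbulk/sbulk to a sample
    name that must be present in the header; a missing sample is fatal.
    Multi-allelic sites are yielded flagged, not decomposed.
    """
    missing_roles = [r for r in ROLES if r not in sample_roles]
    if missing_roles:
        raise ScreenError(f"sample_roles missing roles: {missing_roles}")
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = set(vcf.header.samples)
        for role in ROLES:
            if sample_roles[role] not in header_samples:
                raise ScreenError(
                    f"role {role!r} maps to sample {sample_roles[role]!r} "
                    f"absent from VCF header (samples: {sorted(header_samples)})"
                )
        for rec in vcf:
            alts = rec.alts or ()
            samples: dict[str, dict] = {}
            for role in ROLES:
                s = rec.samples[sample_roles[role]]
                gt = s.get("GT")
                if gt is not None and any(a is None for a in gt):
                    gt = None
                ad = s.get("AD")
                if ad is not None and any(a is None for a in ad):
                    ad = None
                samples[role] = {
                    "gt": tuple(gt) if gt is not None else None,
                    "ad": tuple(int(a) for a in ad) if ad is not None else None,
                    "dp": s.get("DP"),
                }
            info = {
                k: float(rec.info[k])
                for k in ("FS", "MQ", "QD", "MQRankSum", "ReadPosRankSum")
                if k in rec.info
            }
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref or "",
                alt=",".join(alts) if alts else "",
                qual=rec.qual,
                info=info,
                samples=samples,
                multiallelic=len(alts) > 1,
            )


def hard_filter(rec: VariantRecord, th: FilterThresholds) -> str | None:
    """Return None if the site passes, else the failed clause name.

    Clauses are ORed for rejection; an absent annotation passes its clause.
    """
    if rec.qual is not None and rec.qual < th.qual_min:
        return "low_qual"
    info = rec.info
    if info.get("QD") is not None and info["QD"] < th.qd_min:
        return "qd"
    if info.get("FS") is not None and info["FS"] > th.fs_max:
        return "fs"
    if info.get("MQ") is not None and info["MQ"] < th.mq_min:
        return "mq"
    if info.get("MQRankSum") is not None and info["MQRankSum"] < th.mqranksum_min:
        return "mqranksum"
    if info.get("ReadPosRankSum") is not None and info["ReadPosRankSum"] < th.readposranksum_min:
        return "readposranksum"
    return None


def _is_hom(gt: tuple[int, ...]) -> bool:
    return len(set(gt)) == 1


def screen_snp(rec: VariantRecord, cfg: ScreenConfig) -> ScreenedSNP | tuple[None, str]:
    """Apply the four screening rules to a hard-filter-passing biallelic site.

    Kept iff (1) both parents are homozygous, (2) the parents' genotypes
    differ, (3) the sterile bulk's called genotype equals the recurrent
    parent's, and (4) both bulks' AD-summed depths lie within the configured
    range.  Depths are polarized so the first count is the donor allele.
    """
    donor = rec.samples["donor"]
    recur = rec.samples["recurrent"]
    fbulk = rec.samples["fbulk"]
    sbulk = rec.samples["sbulk"]

    if donor["gt"] is None or recur["gt"] is None or sbulk["gt"] is None:
        return None, "missing_fields"
    if fbulk["ad"] is None or sbulk["ad"] is None:
        return None, "missing_fields"
    if not (_is_hom(donor["gt"]) and _is_hom(recur["gt"])):
        return None, "parent_het"
    if donor["gt"][0] == recur["gt"][0]:
        return None, "parents_identical"
    if tuple(sorted(sbulk["gt"])) != tuple(sorted(recur["gt"])):
        return None, "sbulk_mismatch"

    for role in cfg.depth_samples:
        ad = rec.samples[role]["ad"]
        if ad is None:
            return None, "missing_fields"
        total = sum(ad)
        if not cfg.depth_min <= total <= cfg.depth_max:
            return None, "depth_out_of_range"

    donor_idx = donor["gt"][0]
    other_idx = recur["gt"][0]
    return ScreenedSNP(
        chrom=rec.chrom,
        pos=rec.pos,
        donor_allele="REF" if donor_idx == 0 else "ALT",
        aF=fbulk["ad"][donor_idx],
        rF=fbulk["ad"][other_idx],
        aS=sbulk["ad"][donor_idx],
        rS=sbulk["ad"][other_idx],
    )


def screen_table(
    records: Iterable[VariantRecord],
    cfg: ScreenConfig | None = None,
    allow_empty: bool = False,
) -> tuple[list[ScreenedSNP], FilterReport]:
    """Screen a record stream into a (chrom, pos)-sorted SNP list plus report.

    Conservation (kept + dropped == total) holds by construction and is
    asserted.  Zero surviving SNPs is fatal unless ``allow_empty``.
    """
    cfg = cfg or ScreenConfig()
    report = FilterReport()
    kept: list[ScreenedSNP] = []
    n_read = 0
    for rec in records:
        n_read += 1
        if rec.multiallelic:
            report.dropped["multiallelic"] += 1
            continue
        reason = hard_filter(rec, cfg.thresholds)
        if reason is not None:
            report.dropped[reason] += 1
            continue
        result = screen_snp(rec, cfg)
        if isinstance(result, ScreenedSNP):
            kept.append(result)
            report.kept += 1
        else:
            report.dropped[result[1]] += 1
    assert report.total == n_read, "screen accounting broken"
    kept.sort(key=lambda s: (s.chrom, s.pos))
    if not kept and not allow_empty:
        raise ScreenError(
            "no SNPs survived screening; report: " + json.dumps(report.to_dict())
        )
    return kept, report


SNP_TABLE_COLUMNS = ["chrom", "pos", "donor_allele", "aF", "rF", "aS", "rS"]


def write_snp_table(snps: list[ScreenedSNP], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [(s.chrom, s.pos, s.donor_allele, s.aF, s.rF, s.aS, s.rS) for s in snps],
        columns=SNP_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_snp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SNP_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenError(f"SNP table {path} missing columns {sorted(missing)}")
    return df
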