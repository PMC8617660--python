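"""Shared fixtures: in-memory simulated datasets and a hand-built VCF fixture."""

from __future__ import annotations

import numpy as np
import pytest

from bsaqtl import synthetic_cross as sc

UNIFORM_GRADES = (0.2, 0.2, 0.2, 0.2, 0.2)
PENETRANT_CARRIER = (0.0, 0.0, 0.0, 0.0, 1.0)
PENETRANT_NONCARRIER = (1.0, 0.0, 0.0, 0.0, 0.0)


@pytest.fixture
def small_map():
    return sc.build_marker_map(2, 1_000_000, 50_000, seed=11)


@pytest.fixture
def penetrant_qtl():
    return sc.RestorerQTL(
        chrom="chr01",
        pos_bp=500_000,
        grade_dist_carrier=PENETRANT_CARRIER,
        grade_dist_noncarrier=PENETRANT_NONCARRIER,
    )


def make_null_snp_table(n_chrom=10, chrom_len=20_000_000, spacing=10_000,
                        pop_size=200, bulk_size=30, depth=(10, 100), seed=0):
    """Screened-SNP table from a BC1 simulation with NO phenotype-genotype link.

    Both genotype classes share one grade distribution, so bulk membership is
    independent of genotype at every locus: a genuine null genome scan.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    mm = sc.build_marker_map(n_chrom, chrom_len, spacing, np.random.default_rng(ss[0]))
    qtl = sc.RestorerQTL("chr01", chrom_len // 2,
                         grade_dist_carrier=UNIFORM_GRADES,
                         grade_dist_noncarrier=UNIFORM_GRADES)
    pop = sc.simulate_bc1(mm, qtl, pop_size, seed=np.random.default_rng(ss[1]))
    fbulk, sbulk = sc.select_bulks(pop, bulk_size, {3, 4}, {0, 1},
                                   seed=np.random.default_rng(ss[2]))
    rng = np.random.default_rng(ss[3])
    f_counts = sc.simulate_bulk_reads(fbulk, depth[0], depth[1], 0.0, rng)
    s_counts = sc.simulate_bulk_reads(sbulk, depth[0], depth[1], 0.0, rng)
    return sc.counts_to_snp_table(mm, f_counts, s_counts)


# --- hand-built screening fixture ------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=FS,Number=1,Type=Float,Description="strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="qual by depth">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="read pos rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=chr01,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP596\tP1318\tF_bulk\tS_bulk
"""

_GOOD_INFO = "FS=1.0;MQ=60.0;QD=25.0;MQRankSum=0.0;ReadPosRankSum=0.0"


def _rec(pos, qual="500", info=_GOOD_INFO, alt="G",
         donor="1/1:0,50:50", recur="0/0:50,0:50",
         fbulk="0/1:20,20:40", sbulk="0/0:50,5:55"):
    return f"chr01\t{pos}\t.\tA\t{alt}\t{qual}\tPASS\t{info}\t" \
           f"GT:AD:DP\t{donor}\t{recur}\t{fbulk}\t{sbulk}\n"


def write_screen_fixture(path):
    """VCF with one record per drop reason plus three kept records.

    Returns (path, expected) where expected maps each drop reason to 1 and
    'kept' to 3.
    """
    body = [
        _rec(1000, alt="G,T", donor="1/1:0,50,0:50", recur="0/0:50,0,0:50",
             fbulk="0/1:20,20,0:40", sbulk="0/0:50,5,0:55"),   # multiallelic
        _rec(2000, fbulk="0/1:.:40"),                          # missing_fields (no AD)
        _rec(3000, qual="25"),                                 # low_qual
        _rec(4000, info="FS=1.0;MQ=60.0;QD=5.0;MQRankSum=0.0;ReadPosRankSum=0.0"),   # qd
        _rec(5000, info="FS=25.0;MQ=60.0;QD=25.0;MQRankSum=0.0;ReadPosRankSum=0.0"), # fs
        _rec(6000, info="FS=1.0;MQ=10.0;QD=25.0;MQRankSum=0.0;ReadPosRankSum=0.0"),  # mq
        _rec(7000, info="FS=1.0;MQ=60.0;QD=25.0;MQRankSum=-5.0;ReadPosRankSum=0.0"), # mqranksum
        _rec(8000, info="FS=1.0;MQ=60.0;QD=25.0;MQRankSum=0.0;ReadPosRankSum=-5.0"), # readposranksum
        _rec(9000, donor="0/1:25,25:50"),                      # parent_het
        _rec(10000, donor="0/0:50,0:50"),                      # parents_identical
        _rec(11000, sbulk="0/1:30,25:55"),                     # sbulk_mismatch
        _rec(12000, fbulk="0/1:3,4:7"),                        # depth_out_of_range
        _rec(20000),                                           # kept
        _rec(21000, fbulk="0/1:25,25:50", sbulk="0/0:40,2:42"),  # kept
        _rec(22000, donor="0/0:50,0:50", recur="1/1:0,50:50",
             sbulk="1/1:2,48:50"),                             # kept (donor = REF)
    ]
    path.write_text(_VCF_HEADER + "".join(body))
    expected = {reason: 1 for reason in (
        "multiallelic", "missing_fields", "low_qual", "qd", "fs", "mq",
        "mqranksum", "readposranksum", "parent_het", "parents_identical",
        "sbulk_mismatch", "depth_out_of_range")}
    return path, expected, 3


@pytest.fixture
def screen_fixture(tmp_path):
    return write_screen_fixture(tmp_path / "fixture.vcf")


DEFAULT_ROLES = {"donor": "P596", "recurrent": "P1318",
                 "fbulk": "F_bulk", "sbulk": "S_bulk"}
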