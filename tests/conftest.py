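import numpy as np
import pytest

from aeiscan import (
    AlleleDepthRecord,
    CountTable,
    Genotype,
    SimConfig,
    VariantSite,
    simulate_cohort,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=249250621>
##contig=<ID=chr11,length=135006516>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHAS1\tHAS2\tHAS3
"""


@pytest.fixture
def small_vcf(tmp_path):
    """Three samples, two biallelic SNVs, one triallelic site, one indel."""
    lines = [
        "chr11\t61717365\trs149698\tC\tT\t500\t.\tGENE=BEST1\tGT:AD:DP"
        "\t0/1:30,20:50\t0/0:40,0:40\t0/1:25,26:51",
        "chr1\t1000\trs111\tA\tG\t300\t.\tGENE=GENE1\tGT:AD:DP"
        "\t0/1:10,12:22\t1/1:0,30:30\t./.:.:.",
        "chr1\t2000\trs222\tA\tG,T\t400\t.\t.\tGT:AD:DP"
        "\t0/1:10,5,5:20\t0/2:10,5,5:20\t0/0:20,0,0:20",
        "chr1\t3000\trs333\tAT\tA\t400\t.\t.\tGT:AD:DP"
        "\t0/1:10,10:20\t0/0:20,0:20\t0/0:20,0:20",
    ]
    path = tmp_path / "cohort.vcf"
    path.write_text(VCF_HEADER + "\n".join(lines) + "\n")
    return path


def make_site(pos=1000, rsid="rs1", qual=500.0, gene="GENE1", chrom="chr1"):
    return VariantSite(
        chrom=chrom, pos=pos, ref_allele="A", alt_allele="G",
        rsid=rsid, qual=qual, gene=gene,
    )


def make_het(site, sample, ref, alt):
    return AlleleDepthRecord(site, sample, ref, alt, Genotype.HET)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def het_factory():
    return make_het


def table_from_ratio_counts(counts_by_variant):
    """Build a CountTable from {rsid: {sample: (ref, alt)}} of het records."""
    table = CountTable()
    for i, (rsid, by_sample) in enumerate(counts_by_variant.items()):
        site = make_site(pos=1000 + i * 100, rsid=rsid, gene=f"GENE{i + 1}")
        for sample, (ref, alt) in by_sample.items():
            table.add(make_het(site, sample, ref, alt))
    return table


@pytest.fixture
def ratio_table_factory():
    return table_from_ratio_counts


@pytest.fixture(scope="session")
def default_cohort():
    """Default simulated cohort (52 samples, 200 null + 50 AEI variants)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20170283)
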