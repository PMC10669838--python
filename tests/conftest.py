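import numpy as np
import pytest

from sweepscan import simdata


@pytest.fixture(scope="session")
def neutral_panel():
    """Two populations at nominal divergence 0.10, no sweep."""
    cfg = simdata.SimConfig(
        n_pops=2,
        samples_per_pop=30,
        n_snps=5000,
        fst_matrix=0.10,
        chrom_lengths={"chr1": 5_000_000},
        seed=11,
    )
    return simdata.simulate_populations(cfg)


@pytest.fixture(scope="session")
def sweep_panel():
    """Two populations, one strong sweep in pop1 at 2.45-2.55 Mb."""
    cfg = simdata.SimConfig(
        n_pops=2,
        samples_per_pop=30,
        n_snps=5000,
        fst_matrix=0.10,
        chrom_lengths={"chr1": 5_000_000},
        sweeps=[
            simdata.SweepSpec(
                target_pop="pop1",
                chrom="chr1",
                center=2_500_000,
                half_width=50_000,
                final_freq=0.98,
                carrier_fraction=0.9,
            )
        ],
        seed=12,
    )
    return simdata.simulate_populations(cfg)


@pytest.fixture()
def toy_vcf(tmp_path):
    """3 samples, 5 records of which 2 are not biallelic SNPs."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0|0\t0|2\t1|1
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1
chr1\t400\t.\tT\tTA\t.\tPASS\t.\tGT\t0|0\t0|1\t0|0
chr2\t150\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture()
def toy_gff3(tmp_path):
    """2 genes among mRNA/exon rows, one gene without a Name attribute."""
    text = """##gff-version 3
chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene:G1;Name=ALPHA
chr1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=gene:G1
chr1\tsrc\texon\t100\t150\t.\t+\t.\tParent=t1
chr1\tsrc\texon\t160\t200\t.\t+\t.\tParent=t1
chr1\tsrc\tgene\t500\t900\t.\t-\t.\tID=gene:G2
chr1\tsrc\tmRNA\t500\t900\t.\t-\t.\tID=t2;Parent=gene:G2
chr1\tsrc\texon\t500\t700\t.\t-\t.\tParent=t2
chr1\tsrc\tCDS\t500\t700\t.\t-\t0\tParent=t2
"""
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
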