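import pytest

from inschar import (LabeledCallsetConfig, SyntheticGenomeConfig,
                     generate_genome, generate_labeled_callset)


@pytest.fixture(scope="session")
def synth():
    """Synthetic annotated genome (600 kb), tracks and ME library."""
    return generate_genome(SyntheticGenomeConfig(length=600_000, seed=1))


@pytest.fixture(scope="session")
def genome(synth):
    return synth[0]


@pytest.fixture(scope="session")
def tracks(synth):
    return synth[1]


@pytest.fixture(scope="session")
def me_library(synth):
    return synth[2]


@pytest.fixture(scope="session")
def labeled(synth):
    """Labeled callset of 50 records with known truth types."""
    genome, tracks, lib = synth
    return generate_labeled_callset(genome, tracks, lib,
                                    LabeledCallsetConfig(n=50, seed=2))


TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=UNION,Number=1,Type=String,Description="x">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##FILTER=<ID=LongHomRef,Description="x">
##ALT=<ID=INS,Description="Insertion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t100\ta\tA\tACGT\t.\tPASS\tUNION=Illumina\tGT\t0/1
chr1\t200\tb\tACGT\tA\t.\tPASS\tUNION=Pacbio\tGT\t1/1
chr1\t300\tc\tA\tC\t.\tPASS\t.\tGT\t0/1
chr1\t400\td\tA\t<INS>\t.\tPASS\tSVTYPE=INS\tGT\t1/1
chr1\t500\te\tG\tG{tail}\t.\tPASS\tUNION=Illumina\tGT\t1/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """5-record VCF: 2 resolved insertions, 1 deletion, 1 SNV, 1 symbolic."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF.format(tail="TA" * 40))
    return path
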