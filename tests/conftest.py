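import numpy as np
import pytest
from hypothesis import settings

from sweepscan.types import GenotypeMatrix, HaplotypeMatrix, VariantTable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_variants(positions, chrom="1"):
    n = len(positions)
    return VariantTable([chrom] * n, positions, [f"v{i}" for i in range(n)],
                        ["A"] * n, ["C"] * n, [True] * n)


def make_haps(rows, positions=None, chrom="1"):
    rows = np.asarray(rows, dtype=np.uint8)
    if positions is None:
        positions = 1000 * (np.arange(rows.shape[1]) + 1)
    ids = [f"i{k}" for k in range(rows.shape[0] // 2)]
    return HaplotypeMatrix(rows, ids, make_variants(positions, chrom))


def make_genotypes(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    if positions is None:
        positions = 1000 * (np.arange(dosages.shape[1]) + 1)
    ids = [f"i{k}" for k in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, ids, make_variants(positions, chrom))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def write_vcf(path, body, header=VCF_HEADER):
    path.write_text(header + body)
    return str(path)
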