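import numpy as np
import pytest

from popvar.io import GenotypeMatrix, VariantRecord
from popvar.mutsig import CONTEXT_LABELS, SignatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_vcf(tmp_path):
    """Three-sample VCF with phased/unphased/missing genotypes and one
    multi-allelic row."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\t0/0
chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/1\t1/1
chr1\t300\trs3\tG\tA,C\t.\t.\t.\tGT\t0/1\t0/2\t0/0
chr1\t400\t.\tT\tTA\t.\t.\t.\tGT\t0/0\t0/1\t.|.
"""
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path


def make_matrix(codes, pop_labels=None, ids=None):
    codes = np.asarray(codes, float)
    n_samples, n_variants = codes.shape
    variants = [
        VariantRecord("chr1", 100 + 10 * j, "A", "G", id=(ids[j] if ids else f"v{j}"))
        for j in range(n_variants)
    ]
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(variants, samples, codes, pop_labels)


@pytest.fixture
def disjoint_signatures():
    """Three synthetic signatures with pairwise-disjoint context support."""
    profiles = np.zeros((96, 3))
    profiles[:32, 0] = 1 / 32
    profiles[32:64, 1] = 1 / 32
    profiles[64:, 2] = 1 / 32
    return SignatureMatrix(["sigA", "sigB", "sigC"], profiles)
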