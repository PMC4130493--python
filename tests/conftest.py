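import numpy as np
import pytest

from varstrat.simulate import (
    CohortSpec,
    inject_lowcov_errors,
    simulate_gene_bed,
    simulate_genotypes,
)


def write_text(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture
def toy_vcf(tmp_path):
    """Two samples, four biallelic SNP sites covering het/hom/missing calls."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2",
        "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1",
        "1\t200\t.\tC\tT\t.\t.\t.\tGT\t./.\t0/0",
        "1\t300\t.\tG\tA\t.\t.\t.\tGT\t0/0\t0/1",
        "2\t150\t.\tT\tC\t.\t.\t.\tGT\t1/1\t1/1",
    ]) + "\n"
    return write_text(tmp_path / "toy.vcf", text)


@pytest.fixture
def multiallelic_vcf(tmp_path):
    """One triallelic site over three samples (hand-decomposable)."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
        "1\t500\t.\tG\tA,C\t.\t.\t.\tGT\t0/1\t1/2\t2/2",
    ]) + "\n"
    return write_text(tmp_path / "multi.vcf", text)


@pytest.fixture(scope="session")
def small_truth():
    """A modest two-population cohort reused by read-only tests."""
    spec = CohortSpec(n_samples=(60, 60), n_variants=3000,
                      drift_f=(0.05, 0.05), rng_seed=42)
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def small_observed(small_truth):
    return inject_lowcov_errors(small_truth)


@pytest.fixture(scope="session")
def small_genes(small_truth):
    return simulate_gene_bed(small_truth.spec, n_genes=150)
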