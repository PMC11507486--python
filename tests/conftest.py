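"""Shared fixtures: tiny hand-built cohorts and deterministic hypothesis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tgspipe.cohort_io import GenotypeMatrix, SampleRecord, Variant

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_matrix(dosage, phenotypes=None, chrom="1", pos_start=1000, pos_step=1000,
                sexes=None, rsid_prefix="rs", info=None):
    """Build a GenotypeMatrix from a 2-D dosage list (None = missing)."""
    dosage = np.array(
        [[np.nan if d is None else float(d) for d in row] for row in dosage]
    )
    n, m = dosage.shape
    if phenotypes is None:
        phenotypes = [None] * n
    if sexes is None:
        sexes = ["unknown"] * n
    samples = [
        SampleRecord(sample_id=f"S{i}", phenotype=phenotypes[i], reported_sex=sexes[i])
        for i in range(n)
    ]
    variants = [
        Variant(
            rsid=f"{rsid_prefix}{j}",
            chrom=chrom if isinstance(chrom, str) else chrom[j],
            pos=pos_start + j * pos_step,
            ref="A",
            alt="G",
            info_score=None if info is None else info[j],
        )
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240926)


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written 3-sample, 2-variant VCF exercising GT parsing paths."""
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trsA\tA\tG\t.\t.\tINFO=0.95\tGT\t0/1\t./.\t1/1\n"
        "1\t250\trsB\tT\tC\t.\t.\tINFO=0.55\tGT\t0/0\t0/1\t0/1\n"
    )
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
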