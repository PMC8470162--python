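import numpy as np
import pytest

from snpsig import GenotypeMatrix, SimulationConfig, simulate_cohort
from snpsig.genotypes import MISSING


def build_matrix(columns, allele_labels=None, subject_prefix="S"):
    """Tiny GenotypeMatrix from a dict {snp_id: list of dosages (-1 = missing)}."""
    snp_ids = list(columns)
    n = len(next(iter(columns.values())))
    calls = np.array([columns[s] for s in snp_ids], dtype=np.int8).T
    if allele_labels is None:
        allele_labels = [("A", "G")] * len(snp_ids)
    subject_ids = [f"{subject_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(subject_ids, snp_ids, calls, allele_labels)


def cohort_from_counts(counts_a, counts_b, nocall_a=0, nocall_b=0, snp_id="snp1"):
    """One-SNP cohort whose genotype table reproduces the given counts."""
    dosages, stages = [], []
    for counts, nocall, stage in ((counts_a, nocall_a, 0), (counts_b, nocall_b, 1)):
        for d, c in enumerate(counts):
            dosages += [d] * c
        dosages += [MISSING] * nocall
        stages += [stage] * (sum(counts) + nocall)
    matrix = build_matrix({snp_id: dosages})
    return matrix, np.array(stages, dtype=np.int8)


@pytest.fixture(scope="session")
def rs1999241_cohort():
    """Cohort reproducing the published rs1999241 genotype distribution:
    Stage A 34/44/4 (+1 no-call), Stage B 17/6/11."""
    return cohort_from_counts((34, 44, 4), (17, 6, 11), nocall_a=1,
                              snp_id="rs1999241")


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated 300+300 cohort with 4 strong planted SNPs, desk scale."""
    config = SimulationConfig(
        n_stage_a=300, n_stage_b=300, m_snps=300, n_causal=4,
        causal_or_range=(4.0, 6.0), maf_range=(0.2, 0.4), seed=42,
    )
    matrix, phenotype, truth = simulate_cohort(config)
    return matrix, phenotype, truth


@pytest.fixture(scope="session")
def cohort_scale_phenotype():
    return np.array([0] * 83 + [1] * 34, dtype=np.int8)
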