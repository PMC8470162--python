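"""Core genotype containers.

Genotypes are stored as additive dosages of the alternate allele
(0 = hom-ref, 1 = het, 2 = hom-alt) in a subjects x SNPs int8 array,
with ``MISSING`` (-1) marking no-calls — array probes whose signal fell
below the calling threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: Phenotype coding: Stage A (risk factors only) is the control class,
#: Stage B (structural heart disease, asymptomatic) is the case class.
STAGE_A, STAGE_B = 0, 1
STAGE_LABELS = {STAGE_A: "A", STAGE_B: "B"}


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix with identifiers and allele labels.

    Parameters
    ----------
    subject_ids : list of str
        Row identifiers, unique.
    snp_ids : list of str
        Column identifiers, unique.
    calls : ndarray of int8, shape (n_subjects, n_snps)
        Values in {0, 1, 2, MISSING}.
    allele_labels : list of (str, str)
        Per-SNP (ref, alt) nucleotide pair; the two labels must differ.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    allele_labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject IDs")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP IDs")
        if self.calls.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(self.allele_labels) != len(self.snp_ids):
            raise ValueError("allele_labels length does not match snp_ids")
        for sid, (ref, alt) in zip(self.snp_ids, self.allele_labels):
            if ref == alt:
                raise ValueError(f"SNP {sid}: ref and alt alleles are identical")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not present in matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snp_ids=list(snp_ids),
            calls=self.calls[:, idx].copy(),
            allele_labels=[self.allele_labels[j] for j in idx],
        )

    def subset_subjects(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            subject_ids=[self.subject_ids[i] for i in indices],
            snp_ids=list(self.snp_ids),
            calls=self.calls[indices].copy(),
            allele_labels=list(self.allele_labels),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosage DataFrame (subjects x SNPs) with NaN for missing calls."""
        arr = self.calls.astype(float)
        arr[self.calls == MISSING] = np.nan
        return pd.DataFrame(arr, index=self.subject_ids, columns=self.snp_ids)


@dataclass
class SNPMeta:
    """Array-probe metadata: genomic position and optional gene annotation."""

    snp_id: str
    chromosome: str
    position: int
    gene_symbol: str | None = None
    gene_type: str | None = None

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"SNP {self.snp_id}: empty chromosome")
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1 (1-based)")

    @property
    def locus(self) -> str:
        return f"{self.chromosome}:{self.position}"


def phenotype_from_labels(labels, subject_ids=None) -> np.ndarray:
    """Convert 'A'/'B' stage labels to the 0/1 case coding (B = case)."""
    mapping = {"A": STAGE_A, "B": STAGE_B}
    try:
        y = np.array([mapping[str(l)] for l in labels], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"unknown stage label {e.args[0]!r}; expected 'A' or 'B'")
    return y


def check_aligned(matrix: GenotypeMatrix, phenotype: np.ndarray) -> np.ndarray:
    phenotype = np.asarray(phenotype)
    if phenotype.shape != (matrix.n_subjects,):
        raise ValueError(
            f"phenotype length {phenotype.shape} does not match "
            f"{matrix.n_subjects} subjects"
        )
    if not np.isin(phenotype, (STAGE_A, STAGE_B)).all():
        raise ValueError("phenotype must be coded 0 (Stage A) / 1 (Stage B)")
    return phenotype.astype(np.int8)


@dataclass
class QCReport:
    """Audit trail of the two probe-exclusion rules.

    A probe failing both rules is tallied once, under the monomorphic rule,
    so that the counts always reconcile:
    ``n_input_snps == n_removed_monomorphic + n_removed_missingness + n_retained``.
    """

    n_input_snps: int
    n_removed_monomorphic: int
    n_removed_missingness: int
    n_retained: int
    missing_threshold: float
    per_snp: pd.DataFrame = field(repr=False)  # snp_id, maf, missing_rate, status

    def __post_init__(self) -> None:
        total = self.n_removed_monomorphic + self.n_removed_missingness + self.n_retained
        if total != self.n_input_snps:
            raise ValueError("QC tallies do not reconcile")

    def summary(self) -> str:
        return (
            f"QC: {self.n_input_snps} probes in; removed "
            f"{self.n_removed_monomorphic} monomorphic (MAF = 0) and "
            f"{self.n_removed_missingness} with missing rate > "
            f"{self.missing_threshold:g}; {self.n_retained} retained."
        )
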