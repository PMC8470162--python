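"""Per-SNP case/control association screen.

Each SNP is tested with a Pearson chi-square test on the 2 x G table of
genotype counts (Stage A vs Stage B rows; hom-ref / het / hom-alt
columns), no continuity correction.  No-calls are excluded from the
test: a probe that failed to genotype is not a genotype category.
P-values get a Bonferroni family-wise correction over the number of
tests actually performed, and each SNP carries an allelic odds ratio
oriented to the allele enriched in the case group (Stage B), so the
oriented OR is >= 1 by construction and the complementary allele's OR is
its reciprocal.  Zero cells in the 2 x 2 allele table get the
Haldane–Anscombe 0.5 correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, check_aligned


@dataclass
class GenotypeTable:
    """Per-group genotype counts for one SNP, plus a no-call category."""

    snp_id: str
    counts_a: tuple[int, int, int]  # Stage A: (hom-ref, het, hom-alt)
    counts_b: tuple[int, int, int]  # Stage B
    nocall_a: int = 0
    nocall_b: int = 0

    @property
    def n_a(self) -> int:
        return sum(self.counts_a) + self.nocall_a

    @property
    def n_b(self) -> int:
        return sum(self.counts_b) + self.nocall_b

    def called(self) -> np.ndarray:
        """2 x 3 called-genotype count array (no-calls dropped)."""
        return np.array([self.counts_a, self.counts_b], dtype=float)

    def allele_counts(self) -> np.ndarray:
        """2 x 2 (group x allele) counts: columns (ref, alt)."""
        out = np.empty((2, 2))
        for i, c in enumerate((self.counts_a, self.counts_b)):
            hom_ref, het, hom_alt = c
            out[i, 0] = 2 * hom_ref + het
            out[i, 1] = 2 * hom_alt + het
        return out


@dataclass
class AssociationResult:
    snp_id: str
    chi2: float
    df: int
    p: float
    p_adjusted: float
    allelic_or: float
    passes_screen: bool
    testable: bool = True


def genotype_table(
    matrix: GenotypeMatrix, phenotype: np.ndarray, snp_id: str
) -> GenotypeTable:
    phenotype = check_aligned(matrix, phenotype)
    col = matrix.column(snp_id)
    counts = []
    nocalls = []
    for grp in (0, 1):
        sub = col[phenotype == grp]
        counts.append(tuple(int((sub == d).sum()) for d in (0, 1, 2)))
        nocalls.append(int((sub == MISSING).sum()))
    return GenotypeTable(snp_id, counts[0], counts[1], nocalls[0], nocalls[1])


def _testable_table(table: GenotypeTable) -> np.ndarray | None:
    """Called counts with all-zero genotype columns dropped; None if the
    remaining table cannot support a chi-square test."""
    obs = table.called()
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2 or (obs.sum(axis=1) == 0).any():
        return None
    return obs


def chi2_genotype_test(table: GenotypeTable) -> tuple[float, int, float]:
    """Pearson chi-square on the called-genotype table.

    Returns (chi2, df, p) with df = G - 1 for G non-empty genotype
    categories.  Raises on untestable tables (fewer than two non-empty
    genotype columns, or an empty group).
    """
    obs = _testable_table(table)
    if obs is None:
        raise ValueError(f"SNP {table.snp_id}: untestable genotype table")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def bonferroni(p: float | np.ndarray, m: int):
    """Bonferroni-adjusted p-value: min(1, p * M)."""
    if m < 1:
        raise ValueError("M must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)[()]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / M; screening raw p < alpha/M is
    equivalent to screening adjusted p < alpha."""
    if m < 1:
        raise ValueError("M must be >= 1")
    return alpha / m


def allelic_or(table: GenotypeTable) -> float:
    """Allelic odds ratio oriented to the Stage-B-enriched allele.

    Alleles are counted from genotypes (2 per homozygote, 1 each per
    het).  The risk orientation is the allele with the higher frequency
    in Stage B; with any zero cell, 0.5 is added to all four cells
    before forming the cross-product ratio.
    """
    ac = table.allele_counts()  # rows (A, B), cols (ref, alt)
    tot = ac.sum(axis=1)
    if (tot == 0).any():
        raise ValueError(f"SNP {table.snp_id}: a group has no called alleles")
    freq_alt = ac[:, 1] / tot
    if freq_alt[0] == freq_alt[1]:
        return 1.0  # no enrichment either way; Haldane would distort a tie
    risk_col = 1 if freq_alt[1] > freq_alt[0] else 0
    a = ac[1, risk_col]        # risk alleles in Stage B
    b = ac[1, 1 - risk_col]
    c = ac[0, risk_col]        # risk alleles in Stage A
    d = ac[0, 1 - risk_col]
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def _strictly_enriched(table: GenotypeTable) -> bool:
    """True when some allele is strictly more frequent in Stage B —
    i.e. the raw (uncorrected) oriented OR exceeds 1."""
    ac = table.allele_counts()
    freq = ac / ac.sum(axis=1, keepdims=True)
    return bool(freq[1, 0] != freq[0, 0])


def screen(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the chi-square/Bonferroni/odds-ratio screen over all SNPs.

    The multiplicity M is the number of *testable* SNPs (degenerate
    tables are excluded from both the test and the correction).  A SNP
    passes when its Bonferroni-adjusted p is below ``alpha`` and some
    allele is strictly enriched in Stage B.  Results are sorted by p
    ascending (SNP id breaks ties).
    """
    phenotype = check_aligned(matrix, phenotype)
    calls = matrix.calls
    in_b = phenotype == 1
    # counts[group, dosage, snp] — vectorised over SNPs
    counts = np.empty((2, 3, matrix.n_snps), dtype=float)
    for g, mask in enumerate((~in_b, in_b)):
        sub = calls[mask]
        for d in (0, 1, 2):
            counts[g, d] = (sub == d).sum(axis=0)

    col_tot = counts.sum(axis=0)            # 3 x m
    row_tot = counts.sum(axis=1)            # 2 x m
    nonzero_col = col_tot > 0
    n_cats = nonzero_col.sum(axis=0)
    testable = (n_cats >= 2) & (row_tot > 0).all(axis=0)
    m_tests = int(testable.sum())
    if m_tests == 0:
        raise ValueError("no testable SNPs; cannot run the screen")

    grand = row_tot.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row_tot[:, None, :] * col_tot[None, :, :] / grand
        term = np.where(nonzero_col[None, :, :],
                        (counts - expected) ** 2 / expected, 0.0)
    chi2 = np.where(testable, np.nansum(term, axis=(0, 1)), np.nan)
    df = np.where(testable, n_cats - 1, 0)
    p = np.full(matrix.n_snps, np.nan)
    p[testable] = stats.chi2.sf(chi2[testable], df[testable])

    # oriented allelic OR, Haldane-corrected on zero cells
    ref_ct = 2 * counts[:, 0, :] + counts[:, 1, :]
    alt_ct = 2 * counts[:, 2, :] + counts[:, 1, :]
    tot_ct = ref_ct + alt_ct
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_alt = alt_ct / tot_ct
    risk_is_alt = freq_alt[1] >= freq_alt[0]
    a = np.where(risk_is_alt, alt_ct[1], ref_ct[1])
    b = np.where(risk_is_alt, ref_ct[1], alt_ct[1])
    c = np.where(risk_is_alt, alt_ct[0], ref_ct[0])
    d = np.where(risk_is_alt, ref_ct[0], alt_ct[0])
    zero = np.minimum.reduce([a, b, c, d]) == 0
    a, b, c, d = (x + 0.5 * zero for x in (a, b, c, d))
    enriched = freq_alt[1] != freq_alt[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        oriented_or = np.where(enriched, (a * d) / (b * c), 1.0)
    oriented_or = np.where(testable, oriented_or, np.nan)

    p_adjusted = np.where(testable, np.minimum(1.0, p * m_tests), np.nan)
    passes = testable & enriched & (p_adjusted < alpha)

    out = pd.DataFrame(
        {
            "snp_id": matrix.snp_ids,
            "chi2": chi2,
            "df": df.astype(int),
            "p": p,
            "p_adjusted": p_adjusted,
            "allelic_or": oriented_or,
            "passes_screen": passes,
            "testable": testable,
        }
    )
    m = m_tests
    out = out.sort_values(["p", "snp_id"], na_position="last").reset_index(drop=True)
    out.attrs["n_tests"] = m
    out.attrs["alpha"] = alpha
    return out
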