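"""Synthetic case/control genotype cohorts with planted risk SNPs.

The generator emulates the structure of a small case/control SNP-array
study of preclinical heart failure: a panel of independent biallelic
probes with Hardy–Weinberg genotype frequencies at a per-probe minor
allele frequency drawn from a configurable range, a handful of planted
risk SNPs acting additively on the log-odds of being a case (Stage B),
and the array artifacts the QC stage must catch — monomorphic probes
and probes with elevated missingness.

Disease status follows a logistic liability model

    log-odds(case) = intercept + sum_j beta_j * dosage_j

over the causal SNPs, with the intercept tuned by bisection so the
population case fraction matches the requested Stage B share; subjects
are then sampled retrospectively (draw, assign by status, stop when
both group quotas are filled), which is how a case/control study
ascertains its cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, STAGE_A, STAGE_B

_NUCS = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition knobs for the cohort generator.

    Defaults mirror the target study's cohort (83 Stage A vs 34 Stage B
    genotyped subjects) at desk scale: 5,000 probes standing in for a
    686k-probe array, 10 planted risk SNPs with allelic odds ratios in
    [2.5, 4], a uniform MAF spectrum on [0.05, 0.5], 1% monomorphic and
    2% high-missingness probes, and a 1% per-call no-call rate.
    """

    n_stage_a: int = 83
    n_stage_b: int = 34
    m_snps: int = 5000
    n_causal: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_or_range: tuple[float, float] = (2.5, 4.0)
    frac_monomorphic: float = 0.01
    frac_high_missing: float = 0.02
    base_missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_stage_a <= 0 or self.n_stage_b <= 0:
            raise ValueError("both group sizes must be positive")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.causal_or_range[0] <= 1:
            raise ValueError("causal odds ratios must exceed 1")
        if self.causal_or_range[0] > self.causal_or_range[1]:
            raise ValueError("causal_or_range must be ordered")
        for name in ("frac_monomorphic", "frac_high_missing", "base_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_monomorphic + self.frac_high_missing >= 1:
            raise ValueError("artifact fractions must sum to < 1")
        if not 0 <= self.n_causal <= self.m_snps:
            raise ValueError("n_causal must be in [0, m_snps]")


@dataclass
class TrueSignature:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    causal_snp_ids: list[str]
    causal_log_or: np.ndarray
    intercept: float
    causal_maf: np.ndarray = field(default_factory=lambda: np.empty(0))


def tune_intercept(betas, mafs, target_fraction, seed, tol=1e-4) -> float:
    """Bisection on the intercept so the expected case fraction hits target.

    The expectation is taken over a fixed Monte-Carlo pool of causal
    genotypes (so the objective is deterministic and monotone in the
    intercept); tolerance is on the case fraction.
    """
    rng = np.random.default_rng(seed)
    if betas.size == 0:
        return float(np.log(target_fraction / (1 - target_fraction)))
    g = rng.binomial(2, mafs, size=(20000, mafs.size))
    eta = g @ betas

    def frac(b):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b + eta)))))

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_fraction) < tol:
            return mid
        if f < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig):
    """Generate (GenotypeMatrix, phenotype, TrueSignature) under `config`.

    Deterministic for a fixed config (including the seed).  Raises if
    the retrospective sampler cannot fill a group quota within a
    bounded number of draws.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m, n_a, n_b = config.m_snps, config.n_stage_a, config.n_stage_b
    n_total = n_a + n_b

    snp_ids = [f"snp{j:06d}" for j in range(m)]
    mafs = rng.uniform(*config.maf_range, size=m)

    # artifact / causal probe assignment (disjoint; causal probes stay clean)
    n_mono = int(round(config.frac_monomorphic * m))
    n_hm = int(round(config.frac_high_missing * m))
    perm = rng.permutation(m)
    causal_idx = np.sort(perm[: config.n_causal])
    mono_idx = np.sort(perm[config.n_causal: config.n_causal + n_mono])
    hm_idx = np.sort(perm[config.n_causal + n_mono:
                          config.n_causal + n_mono + n_hm])

    betas = np.log(rng.uniform(*config.causal_or_range, size=config.n_causal))
    causal_mafs = mafs[causal_idx]
    target = n_b / n_total
    intercept = tune_intercept(betas, causal_mafs, target,
                               seed=int(rng.integers(2**31)))

    # retrospective sampling on the causal genotypes only
    max_draws = 2000 * n_total + 10000
    got_a, got_b = [], []
    drawn = 0
    batch = max(4 * n_total, 256)
    while (len(got_a) < n_a or len(got_b) < n_b) and drawn < max_draws:
        g = rng.binomial(2, causal_mafs, size=(batch, config.n_causal))
        eta = intercept + (g @ betas if config.n_causal else 0.0)
        case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        drawn += batch
        for row, is_case in zip(g, case):
            if is_case and len(got_b) < n_b:
                got_b.append(row)
            elif not is_case and len(got_a) < n_a:
                got_a.append(row)
    if len(got_a) < n_a or len(got_b) < n_b:
        short = "Stage A" if len(got_a) < n_a else "Stage B"
        raise RuntimeError(
            f"could not fill the {short} quota within {max_draws} draws; "
            "check the causal odds ratios / group sizes"
        )

    phenotype = np.array([STAGE_A] * n_a + [STAGE_B] * n_b, dtype=np.int8)
    calls = np.empty((n_total, m), dtype=np.int8)
    # non-causal probes are independent of status: draw HWE genotypes directly
    noncausal = np.setdiff1d(np.arange(m), causal_idx)
    calls[:, noncausal] = rng.binomial(
        2, mafs[noncausal], size=(n_total, noncausal.size)
    ).astype(np.int8)
    if config.n_causal:
        causal_block = np.vstack([np.array(got_a), np.array(got_b)])
        calls[:, causal_idx] = causal_block.astype(np.int8)

    calls[:, mono_idx] = 0  # monomorphic: alt allele never observed

    # missingness: completely at random at the base rate, elevated on the
    # designated high-missingness probes (guaranteed to exceed 10%)
    if config.base_missing_rate > 0:
        drop = rng.random(calls.shape) < config.base_missing_rate
        drop[:, hm_idx] = False
        calls[drop] = MISSING
    floor_missing = int(np.floor(0.10 * n_total)) + 1
    for j in hm_idx:
        rate = rng.uniform(0.15, 0.30)
        k = max(int(round(rate * n_total)), floor_missing)
        rows = rng.choice(n_total, size=k, replace=False)
        calls[rows, j] = MISSING

    ref = rng.integers(0, 4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    labels = [(str(_NUCS[r]), str(_NUCS[a])) for r, a in zip(ref, alt)]

    subject_ids = [f"S{i:05d}" for i in range(n_total)]
    matrix = GenotypeMatrix(subject_ids, snp_ids, calls, labels)
    truth = TrueSignature(
        causal_snp_ids=[snp_ids[j] for j in causal_idx],
        causal_log_or=betas,
        intercept=intercept,
        causal_maf=causal_mafs,
    )
    return matrix, phenotype, truth


def realized_allelic_or(matrix: GenotypeMatrix, phenotype, snp_id: str) -> float:
    """Empirical case/control odds ratio of the *alternate* allele.

    Self-check oracle for planted effects: the simulator plants its
    log-odds effect on the alt-allele dosage, so the realized alt-allele
    OR should track exp(beta).  Haldane 0.5 correction on zero cells.
    """
    from .genotypes import check_aligned

    phenotype = check_aligned(matrix, phenotype)
    col = matrix.column(snp_id)
    if (col == MISSING).all():
        raise ValueError(f"SNP {snp_id}: all calls missing")
    counts = np.zeros((2, 2))  # rows (A, B), cols (ref, alt)
    for grp in (0, 1):
        sub = col[(phenotype == grp) & (col != MISSING)]
        counts[grp, 1] = sub.sum()
        counts[grp, 0] = 2 * sub.size - sub.sum()
    if (counts.sum(axis=1) == 0).any():
        raise ValueError(f"SNP {snp_id}: a group has no called alleles")
    if counts.min() == 0:
        counts = counts + 0.5
    return float((counts[1, 1] * counts[0, 0]) / (counts[1, 0] * counts[0, 1]))
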