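"""Simulator calibration: HWE, determinism, null behaviour, planted effects."""

import numpy as np
import pytest
from scipy import stats

from snpsig import (
    SimulationConfig,
    realized_allelic_or,
    simulate_cohort,
)
from snpsig.association import screen
from snpsig.simulate import tune_intercept


def null_config(**kw):
    base = dict(n_causal=0, frac_monomorphic=0.0, frac_high_missing=0.0,
                base_missing_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(n_stage_a=0),
        dict(maf_range=(0.0, 0.3)),
        dict(maf_range=(0.4, 0.2)),
        dict(causal_or_range=(0.9, 2.0)),
        dict(frac_monomorphic=0.6, frac_high_missing=0.5),
        dict(n_causal=10, m_snps=5),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad).validate()


class TestHardyWeinberg:
    def test_genotype_frequencies_at_maf_half(self):
        # at MAF 0.5 HWE gives (1/4, 1/2, 1/4); 3 binomial SEs at n calls
        config = null_config(n_stage_a=5000, n_stage_b=5000, m_snps=40,
                             maf_range=(0.5, 0.5), seed=1)
        matrix, _, _ = simulate_cohort(config)
        n = matrix.calls.size
        for d, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            freq = (matrix.calls == d).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se

    def test_hwe_goodness_of_fit_across_maf_spectrum(self):
        # chi2 GOF vs p^2 / 2pq / q^2 at the realized allele frequency
        # should be rejected at alpha=0.001 for at most ~1% of null SNPs
        config = null_config(n_stage_a=5000, n_stage_b=5000, m_snps=300, seed=2)
        matrix, _, _ = simulate_cohort(config)
        rejected = 0
        for j in range(matrix.n_snps):
            col = matrix.calls[:, j]
            f = col.mean() / 2.0
            expected = col.size * np.array(
                [(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
            observed = np.array([(col == d).sum() for d in (0, 1, 2)])
            chi2 = ((observed - expected) ** 2 / expected).sum()
            if stats.chi2.sf(chi2, 2) < 0.001:
                rejected += 1
        assert rejected <= 0.01 * matrix.n_snps


class TestDeterminismAndQuota:
    def test_same_seed_bit_identical(self):
        config = SimulationConfig(n_stage_a=40, n_stage_b=20, m_snps=200, seed=7,
                                  n_causal=3)
        m1, p1, t1 = simulate_cohort(config)
        m2, p2, t2 = simulate_cohort(config)
        assert (m1.calls == m2.calls).all()
        assert (p1 == p2).all()
        assert t1.causal_snp_ids == t2.causal_snp_ids
        assert (t1.causal_log_or == t2.causal_log_or).all()

    def test_group_quotas_exact(self):
        config = SimulationConfig(n_stage_a=83, n_stage_b=34, m_snps=100, seed=5)
        _, phenotype, _ = simulate_cohort(config)
        assert (phenotype == 0).sum() == 83
        assert (phenotype == 1).sum() == 34

    def test_intercept_matches_target_case_fraction(self):
        betas = np.log(np.array([2.0, 3.0]))
        mafs = np.array([0.3, 0.2])
        b0 = tune_intercept(betas, mafs, 0.3, seed=1)
        rng = np.random.default_rng(99)
        g = rng.binomial(2, mafs, size=(200000, 2))
        frac = np.mean(1 / (1 + np.exp(-(b0 + g @ betas))))
        assert frac == pytest.approx(0.3, abs=0.01)


class TestNullBehaviour:
    def test_null_screen_type_one_error(self):
        # fraction of raw p-values below 0.05 over 2,000 null SNPs,
        # averaged over 10 seeds: the chi-square test on discrete tables
        # is slightly conservative, so allow [0.03, 0.07]
        fracs = []
        for seed in range(10):
            config = null_config(n_stage_a=100, n_stage_b=100, m_snps=2000,
                                 seed=seed)
            matrix, phenotype, _ = simulate_cohort(config)
            result = screen(matrix, phenotype)
            fracs.append(float((result["p"] < 0.05).mean()))
        assert 0.03 < np.mean(fracs) < 0.07

    def test_null_allele_frequencies_equal_between_groups(self):
        config = null_config(n_stage_a=4000, n_stage_b=4000, m_snps=50, seed=3)
        matrix, phenotype, _ = simulate_cohort(config)
        fa = matrix.calls[phenotype == 0].mean(axis=0) / 2
        fb = matrix.calls[phenotype == 1].mean(axis=0) / 2
        assert np.abs(fa - fb).max() < 0.03


class TestInjectedArtifacts:
    def test_artifact_probes_are_exactly_what_qc_removes(self):
        from snpsig import compute_maf, compute_missing_rate

        config = SimulationConfig(n_stage_a=300, n_stage_b=200, m_snps=1000,
                                  n_causal=0, frac_monomorphic=0.02,
                                  frac_high_missing=0.03, seed=11)
        matrix, _, _ = simulate_cohort(config)
        maf = compute_maf(matrix)
        miss = compute_missing_rate(matrix)
        assert int((maf == 0).sum()) == 20
        assert int((miss > 0.10).sum()) == 30
        # high-missingness probes stay polymorphic, so the two sets are disjoint
        assert not ((maf == 0) & (miss > 0.10)).any()


class TestRealizedOddsRatio:
    def test_planted_or_three_within_sampling_envelope(self):
        config = SimulationConfig(n_stage_a=2000, n_stage_b=2000, m_snps=5,
                                  n_causal=1, causal_or_range=(3.0, 3.0),
                                  maf_range=(0.3, 0.3), frac_monomorphic=0,
                                  frac_high_missing=0, base_missing_rate=0,
                                  seed=21)
        matrix, phenotype, truth = simulate_cohort(config)
        realized = realized_allelic_or(matrix, phenotype, truth.causal_snp_ids[0])
        assert 2.4 < realized < 3.75

    def test_null_snp_or_near_one(self):
        config = null_config(n_stage_a=20000, n_stage_b=20000, m_snps=3,
                             maf_range=(0.3, 0.3), seed=13)
        matrix, phenotype, _ = simulate_cohort(config)
        assert realized_allelic_or(matrix, phenotype, matrix.snp_ids[0]) == \
            pytest.approx(1.0, abs=0.05)

    def test_allele_swap_inverts_to_reciprocal(self):
        config = SimulationConfig(n_stage_a=500, n_stage_b=500, m_snps=3,
                                  n_causal=1, seed=17, frac_monomorphic=0,
                                  frac_high_missing=0, base_missing_rate=0)
        matrix, phenotype, truth = simulate_cohort(config)
        sid = truth.causal_snp_ids[0]
        orig = realized_allelic_or(matrix, phenotype, sid)
        j = matrix.snp_index(sid)
        matrix.calls[:, j] = 2 - matrix.calls[:, j]  # relabel ref<->alt
        assert realized_allelic_or(matrix, phenotype, sid) == \
            pytest.approx(1.0 / orig, rel=1e-12)

    def test_all_missing_snp_is_error(self, rs1999241_cohort):
        from snpsig.genotypes import MISSING
        matrix, phenotype = rs1999241_cohort
        broken = matrix.subset_snps(["rs1999241"])
        broken.calls[:] = MISSING
        with pytest.raises(ValueError, match="missing"):
            realized_allelic_or(broken, phenotype, "rs1999241")

    def test_specified_vs_realized_or_rank_agreement(self):
        # planted-effect recovery: one planted SNP per cohort, OR spanning
        # 1.5-4, n = 1,000/group; Spearman rho across the 50 cohorts
        spec_or, real_or = [], []
        for i, orv in enumerate(np.linspace(1.5, 4.0, 50)):
            config = SimulationConfig(
                n_stage_a=1000, n_stage_b=1000, m_snps=2, n_causal=1,
                causal_or_range=(orv, orv), maf_range=(0.2, 0.4),
                frac_monomorphic=0, frac_high_missing=0,
                base_missing_rate=0, seed=100 + i)
            matrix, phenotype, truth = simulate_cohort(config)
            spec_or.append(orv)
            real_or.append(
                realized_allelic_or(matrix, phenotype, truth.causal_snp_ids[0]))
        rho = stats.spearmanr(spec_or, real_or).statistic
        assert rho > 0.9
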