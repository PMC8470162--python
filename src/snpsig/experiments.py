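"""Study-condition experiments: calibration, recovery, and audit runs.

Each function here recomputes one of the package's headline checks from
scratch — worked examples on the published genotype counts, simulator
calibration, family-wise error under the null, end-to-end planted-SNP
recovery, determinism, and the selection-leakage audit.  The analysis
drivers, the test suite, and the results-reproduction script all call
these functions, so every reported number is produced by running the
pipeline, never stored.

Problem sizes are desk scale: the family-wise error simulation uses
5,000-probe cohorts at the 83/34 group sizes, and the recovery runs use
5,000 probes with 500/500 groups at a reduced replicate count (the
ranking stabilises well below B = 100 when ten strong SNPs dominate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, evaluation, qc, selection
from .datasets import genotype_tables_from_counts
from .pipeline import leakage_audit, run_pipeline
from .reporting import welch_t_test
from .simulate import SimulationConfig, simulate_cohort


def _child_seeds(master_seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), int(tag)])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# worked examples on published numbers
# ---------------------------------------------------------------------------

def worked_examples() -> dict:
    """Recompute the in-study worked examples from their printed inputs."""
    thr = association.bonferroni_threshold(0.05, 392885)
    table = genotype_tables_from_counts()["rs1999241"]
    chi2, df, p = association.chi2_genotype_test(table)
    t, wdf, welch_p = welch_t_test(8.74, 8.86, 113, 13.13, 10.32, 49)
    return {
        "bonferroni_per_test_threshold": thr,
        "stage_a_percent_of_recruited": 100.0 * 113 / 162,
        "rs1999241_genotyped_subjects": table.n_a + table.n_b,
        "rs1999241_chi2": chi2,
        "rs1999241_df": df,
        "rs1999241_p": p,
        "rs1999241_allelic_or": association.allelic_or(table),
        "adiponectin_welch_p": welch_p,
    }


# ---------------------------------------------------------------------------
# oracle agreement
# ---------------------------------------------------------------------------

def chi2_oracle_max_abs_diff(n_tables: int = 1000, seed: int = 0) -> float:
    """Max |chi2 - brute-force chi2| over random 2x3 genotype tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    while checked < n_tables:
        counts = rng.integers(0, 40, size=6)
        table = association.GenotypeTable("t", tuple(counts[:3]),
                                          tuple(counts[3:]))
        obs = table.called()
        obs = obs[:, obs.sum(axis=0) > 0]
        if obs.shape[1] < 2 or (obs.sum(axis=1) == 0).any():
            continue
        chi2, _, _ = association.chi2_genotype_test(table)
        row, col, n = obs.sum(axis=1), obs.sum(axis=0), obs.sum()
        brute = sum(
            (obs[i, j] - row[i] * col[j] / n) ** 2 / (row[i] * col[j] / n)
            for i in range(obs.shape[0]) for j in range(obs.shape[1]))
        worst = max(worst, abs(chi2 - brute))
        checked += 1
    return worst


def auc_oracle_max_abs_diff(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |rank AUC - all-pairs AUC| over random tied score vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_vectors:
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = rng.choice([0.0, 0.2, 0.5, 0.9, 1.7], size=n)
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg) / (
            len(pos) * len(neg))
        worst = max(worst, abs(evaluation.auc(scores, labels) - brute))
        done += 1
    return worst


# ---------------------------------------------------------------------------
# simulator calibration
# ---------------------------------------------------------------------------

def hwe_max_z(seed: int = 0, n_subjects: int = 10000, m_snps: int = 40) -> float:
    """Worst genotype-frequency z-score vs HWE expectation at MAF 0.5."""
    config = SimulationConfig(
        n_stage_a=n_subjects // 2, n_stage_b=n_subjects - n_subjects // 2,
        m_snps=m_snps, n_causal=0, maf_range=(0.5, 0.5), frac_monomorphic=0,
        frac_high_missing=0, base_missing_rate=0, seed=seed)
    matrix, _, _ = simulate_cohort(config)
    n = matrix.calls.size
    worst = 0.0
    for d, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
        freq = (matrix.calls == d).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        worst = max(worst, abs(freq - expected) / se)
    return worst


def null_screen_fwer(n_seeds: int = 100, m_snps: int = 5000,
                     master_seed: int = 0) -> dict:
    """Fraction of null cohorts (83/34) with zero Bonferroni passes."""
    clean = 0
    for seed in _child_seeds(master_seed, n_seeds, tag=1):
        config = SimulationConfig(n_stage_a=83, n_stage_b=34, m_snps=m_snps,
                                  n_causal=0, seed=seed)
        matrix, phenotype, _ = simulate_cohort(config)
        filtered, _ = qc.qc_filter(matrix)
        result = association.screen(filtered, phenotype)
        clean += int(result["passes_screen"].sum() == 0)
    return {"fraction_seeds_without_false_positive": clean / n_seeds,
            "n_seeds": n_seeds, "m_snps": m_snps}


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------

RECOVERY_CONFIG = dict(n_stage_a=500, n_stage_b=500, m_snps=5000, n_causal=10,
                       causal_or_range=(3.0, 4.0), maf_range=(0.2, 0.4))


def planted_recovery(n_seeds: int = 20, B: int = 25,
                     master_seed: int = 0) -> dict:
    """Planted SNPs recovered in the ensemble top 10, per master seed."""
    hits = []
    for seed in _child_seeds(master_seed, n_seeds, tag=2):
        config = SimulationConfig(seed=seed, **RECOVERY_CONFIG)
        matrix, phenotype, truth = simulate_cohort(config)
        filtered, _ = qc.qc_filter(matrix)
        result = association.screen(filtered, phenotype)
        dosages = qc.encode_additive(filtered.subset_snps(
            result.loc[result["passes_screen"], "snp_id"].tolist()))
        plan = selection.make_splits(phenotype, B=B, master_seed=seed)
        _, ranked = selection.accumulate_and_rank(plan, dosages, phenotype,
                                                  result, k_select=20)
        top10 = set(ranked.head(10)["snp_id"])
        hits.append(len(top10 & set(truth.causal_snp_ids)))
    return {"hits_per_seed": hits, "median_hits": float(np.median(hits)),
            "n_seeds": n_seeds, "B": B}


def signature_size_recovery(n_seeds: int = 3, B: int = 12,
                            master_seed: int = 0) -> dict:
    """Chosen signature size k* on planted-signal cohorts (signal = 10)."""
    k_stars = []
    for seed in _child_seeds(master_seed, n_seeds, tag=3):
        config = SimulationConfig(seed=seed, **RECOVERY_CONFIG)
        matrix, phenotype, _ = simulate_cohort(config)
        res = run_pipeline(matrix, phenotype, master_seed=seed, B=B,
                           k_grid=[2, 4, 6, 8, 10, 12])
        k_stars.append(res.k_star)
    return {"k_star_per_seed": k_stars,
            "median_k_star": float(np.median(k_stars)),
            "signal_size": RECOVERY_CONFIG["n_causal"], "n_seeds": n_seeds,
            "B": B}


# ---------------------------------------------------------------------------
# determinism and leakage
# ---------------------------------------------------------------------------

def determinism_check(master_seed: int = 0) -> dict:
    """Run the full pipeline twice from one seed; compare outputs exactly."""
    config = SimulationConfig(n_stage_a=150, n_stage_b=150, m_snps=300,
                              n_causal=4, causal_or_range=(4.0, 6.0),
                              maf_range=(0.2, 0.4), seed=master_seed)

    def one_run():
        matrix, phenotype, _ = simulate_cohort(config)
        return run_pipeline(matrix, phenotype, master_seed=master_seed, B=4,
                            k_grid=[1, 2, 3, 4])

    a, b = one_run(), one_run()
    ranked_identical = a.ranked.equals(b.ranked)
    curve_identical = a.curve.table.equals(b.curve.table)
    return {"ranked_identical": ranked_identical,
            "curve_identical": curve_identical,
            "identical": bool(ranked_identical and curve_identical)}


def leakage_audit_over_seeds(n_seeds: int = 20, master_seed: int = 0) -> dict:
    """Mean screen-first vs nested-mode AUC on null cohorts, across seeds."""
    first, nested = [], []
    for seed in _child_seeds(master_seed, n_seeds, tag=4):
        out = leakage_audit(seed=seed)
        first.append(out["screen_first_mean_auc"])
        nested.append(out["nested_mean_auc"])
    first, nested = np.array(first), np.array(nested)
    return {
        "screen_first_mean_auc": float(first.mean()),
        "nested_mode_mean_auc": float(nested.mean()),
        "nested_mode_sd": float(nested.std(ddof=1)),
        "nested_mode_sem": float(nested.std(ddof=1) / np.sqrt(n_seeds)),
        "fraction_screen_first_geq_nested": float(np.mean(first >= nested)),
        "n_seeds": n_seeds,
    }
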