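#!/usr/bin/env python
"""Generate a synthetic case/control SNP cohort with planted risk SNPs.

Defaults mirror the reference study's genotyped cohort — 83 Stage A
(risk factors only) vs 34 Stage B (asymptomatic structural disease)
subjects — on a 5,000-probe panel with 10 planted risk SNPs, plus the
array artifacts the QC step must remove.  Writes PLINK-style .ped/.map,
the TSV dialect, the phenotype table, and the ground-truth signature.

    python analysis/01_simulate_cohort.py --seed 1 --out-prefix results/cohort/sim
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from snpsig import SimulationConfig, simulate_cohort
from snpsig.io import write_phenotype, write_plink, write_tsv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-prefix", type=Path,
                    default=Path("results/cohort/sim"))
    ap.add_argument("--n-stage-a", type=int, default=83)
    ap.add_argument("--n-stage-b", type=int, default=34)
    ap.add_argument("--m-snps", type=int, default=5000)
    ap.add_argument("--n-causal", type=int, default=10)
    ap.add_argument("--or-min", type=float, default=2.5)
    ap.add_argument("--or-max", type=float, default=4.0)
    args = ap.parse_args()

    config = SimulationConfig(
        n_stage_a=args.n_stage_a, n_stage_b=args.n_stage_b,
        m_snps=args.m_snps, n_causal=args.n_causal,
        causal_or_range=(args.or_min, args.or_max), seed=args.seed)
    matrix, phenotype, truth = simulate_cohort(config)

    prefix = args.out_prefix
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_plink(matrix, prefix, phenotype=phenotype)
    write_tsv(matrix, prefix.with_suffix(".tsv"))
    write_phenotype(matrix.subject_ids, phenotype,
                    prefix.parent / (prefix.name + "_phenotype.tsv"))
    pd.DataFrame({
        "snp_id": truth.causal_snp_ids,
        "log_or": truth.causal_log_or,
        "allelic_or": np.exp(truth.causal_log_or),
        "maf": truth.causal_maf,
    }).to_csv(prefix.parent / (prefix.name + "_truth.tsv"),
              sep="\t", index=False)

    print(f"simulated {matrix.n_subjects} subjects "
          f"({args.n_stage_a} Stage A / {args.n_stage_b} Stage B) "
          f"x {matrix.n_snps} SNPs, seed {args.seed}")
    print(f"planted {len(truth.causal_snp_ids)} risk SNPs, "
          f"allelic OR {np.exp(truth.causal_log_or).min():.2f}-"
          f"{np.exp(truth.causal_log_or).max():.2f}; "
          f"liability intercept {truth.intercept:.3f}")
    print(f"wrote {prefix}.ped/.map/.alleles/.tsv and phenotype/truth tables")


if __name__ == "__main__":
    main()
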