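#!/usr/bin/env python
"""Bootstrap ensemble feature selection over the screened SNPs.

B stratified 80:20 train/validation splits; on each training split a
random forest (top-k importance), a linear SVM (top-k |weight|) and a
CV'd L1 logistic LASSO (nonzero support) each nominate SNPs, and SNPs
are ranked by total selection count.  ``--mode nested`` re-screens
inside each training split (leakage-free variant).

    python analysis/04_ensemble_selection.py --seed 1 --B 100
"""

import argparse
import json
from pathlib import Path

from snpsig import accumulate_and_rank, make_splits, screen
from snpsig.io import read_genotypes, read_phenotype
from snpsig.pipeline import _nested_accumulate
from snpsig.qc import encode_additive


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path,
                    default=Path("results/qc/cohort.tsv"))
    ap.add_argument("--pheno", type=Path,
                    default=Path("results/cohort/sim_phenotype.tsv"))
    ap.add_argument("--B", type=int, default=100)
    ap.add_argument("--train-frac", type=float, default=0.80)
    ap.add_argument("--k-select", type=int, default=20)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--mode", choices=("screen_first", "nested"), default="screen_first")
    ap.add_argument("--out-prefix", type=Path, default=Path("results/selection"))
    args = ap.parse_args()

    matrix, _ = read_genotypes(args.inp, format="tsv")
    phenotype = read_phenotype(args.pheno, subject_ids=matrix.subject_ids)
    dosages = encode_additive(matrix)
    plan = make_splits(phenotype, B=args.B, train_fraction=args.train_frac,
                       master_seed=args.seed)
    results = screen(matrix, phenotype, alpha=args.alpha)
    if args.mode == "screen_first":
        counts, ranked = accumulate_and_rank(plan, dosages, phenotype,
                                             results, k_select=args.k_select)
    else:
        counts, ranked = _nested_accumulate(plan, matrix, dosages, phenotype,
                                            args.alpha, args.k_select)

    args.out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ranked.to_csv(args.out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    archive = {f"rep{r}:{m}": list(v) for (r, m), v in counts.archive.items()}
    (args.out_prefix.parent / (args.out_prefix.name + "_archive.json")
     ).write_text(json.dumps(archive, indent=1))
    print(f"mode={args.mode}: ranked {len(ranked)} SNPs over "
          f"{plan.B} replicates x 3 selectors (max count {3 * plan.B})")
    print(ranked.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
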