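#!/usr/bin/env python
"""Top-k signature evaluation across the four classifiers.

For each candidate size k the top-k ranked SNPs are fit with RF, linear
SVM, L1-logistic and a depth-capped decision tree on every training
split and scored on the matching validation split; the minimal k within
tolerance of the best mean AUC is the chosen signature.

    python analysis/05_evaluate_signature.py --seed 1 --k-grid 1:20
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from snpsig import choose_signature, evaluate_topk, make_splits
from snpsig.io import read_genotypes, read_phenotype
from snpsig.qc import encode_additive


def parse_grid(text, upper):
    if ":" in text:
        lo, hi = map(int, text.split(":"))
        return [k for k in range(lo, hi + 1) if k <= upper]
    return [k for k in map(int, text.split(",")) if k <= upper]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path,
                    default=Path("results/qc/cohort.tsv"))
    ap.add_argument("--pheno", type=Path,
                    default=Path("results/cohort/sim_phenotype.tsv"))
    ap.add_argument("--ranked", type=Path, default=Path("results/selection.tsv"))
    ap.add_argument("--k-grid", default="1:20")
    ap.add_argument("--models", default="rf,svm,lasso,tree")
    ap.add_argument("--B", type=int, default=100)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-prefix", type=Path, default=Path("results/evaluation"))
    args = ap.parse_args()

    matrix, _ = read_genotypes(args.inp, format="tsv")
    phenotype = read_phenotype(args.pheno, subject_ids=matrix.subject_ids)
    ranked = pd.read_csv(args.ranked, sep="\t")
    plan = make_splits(phenotype, B=args.B, master_seed=args.seed)
    k_grid = parse_grid(args.k_grid, len(ranked))
    curve = evaluate_topk(encode_additive(matrix), phenotype, ranked, plan,
                          k_grid=k_grid, models=tuple(args.models.split(",")))
    k_star, model_star = choose_signature(curve)
    cm = curve.confusions[(k_star, model_star)]

    args.out_prefix.parent.mkdir(parents=True, exist_ok=True)
    curve.table.to_csv(args.out_prefix.with_suffix(".tsv"), sep="\t",
                       index=False)
    chosen = {"k_star": k_star, "model_star": model_star,
              "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn,
                            "fn": cm.fn},
              "pooled_accuracy": cm.accuracy}
    (args.out_prefix.parent / (args.out_prefix.name + "_chosen.json")
     ).write_text(json.dumps(chosen, indent=2))
    best = curve.table.query("k == @k_star and model == @model_star").iloc[0]
    print(f"chosen signature: top-{k_star} SNPs with {model_star} "
          f"(mean AUC {best['mean_auc']:.3f} +/- {best['sd_auc']:.3f}, "
          f"mean accuracy {best['mean_acc']:.3f})")
    print(f"summed validation confusion matrix: TP={cm.tp} FP={cm.fp} "
          f"TN={cm.tn} FN={cm.fn}")


if __name__ == "__main__":
    main()
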