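#!/usr/bin/env python
"""Chi-square / Bonferroni / odds-ratio screen over the QC'd matrix.

Each SNP gets a Pearson chi-square test on its 2 x G genotype table
(no-calls excluded), a Bonferroni-adjusted p over the number of
testable SNPs, and an allelic odds ratio oriented to the
Stage-B-enriched allele.  SNPs pass when adjusted p < alpha and some
allele is strictly enriched in Stage B.

    python analysis/03_association_screen.py --in results/qc/cohort.tsv \
        --pheno results/cohort/sim_phenotype.tsv --out results/screen.tsv
"""

import argparse
from pathlib import Path

from snpsig import bonferroni_threshold, screen
from snpsig.io import read_genotypes, read_phenotype


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path,
                    default=Path("results/qc/cohort.tsv"))
    ap.add_argument("--pheno", type=Path,
                    default=Path("results/cohort/sim_phenotype.tsv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", type=Path, default=Path("results/screen.tsv"))
    args = ap.parse_args()

    matrix, _ = read_genotypes(args.inp, format="tsv")
    phenotype = read_phenotype(args.pheno, subject_ids=matrix.subject_ids)
    result = screen(matrix, phenotype, alpha=args.alpha)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(args.out, sep="\t", index=False)
    m = result.attrs["n_tests"]
    n_pass = int(result["passes_screen"].sum())
    print(f"tested {m} SNPs; per-test threshold "
          f"{bonferroni_threshold(args.alpha, m):.3e}; {n_pass} passed")
    print(result.head(min(10, n_pass or 5)).to_string(index=False))


if __name__ == "__main__":
    main()
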