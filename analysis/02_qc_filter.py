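#!/usr/bin/env python
"""Apply the two probe-exclusion rules and write the audited matrix.

Removes probes with MAF = 0 (monomorphic) and probes with a missing
rate strictly above the threshold (default 10%), mirroring the QC that
took the reference study's 686,463-probe array to 392,885 analysed SNPs.

    python analysis/02_qc_filter.py --in results/cohort/sim.tsv \
        --out-prefix results/qc/cohort
"""

import argparse
from pathlib import Path

from snpsig import qc_filter
from snpsig.io import read_genotypes, write_tsv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path,
                    default=Path("results/cohort/sim.tsv"))
    ap.add_argument("--missing-max", type=float, default=0.10)
    ap.add_argument("--out-prefix", type=Path, default=Path("results/qc/cohort"))
    args = ap.parse_args()

    matrix, _ = read_genotypes(args.inp, format="tsv")
    filtered, report = qc_filter(matrix, missing_threshold=args.missing_max)

    args.out_prefix.parent.mkdir(parents=True, exist_ok=True)
    write_tsv(filtered, args.out_prefix.with_suffix(".tsv"))
    report.per_snp.to_csv(
        args.out_prefix.parent / (args.out_prefix.name + "_qc_report.tsv"),
        sep="\t", index=False)
    print(report.summary())
    print(f"wrote {args.out_prefix}.tsv and the per-SNP QC report")


if __name__ == "__main__":
    main()
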