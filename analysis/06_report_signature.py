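#!/usr/bin/env python
"""Descriptive reports for a chosen signature.

Writes per-group genotype-frequency tables (with a no-call slice and
chi-square significance flags), the static gene annotation of the
signature SNPs, and the connector-hub proteins of a protein-interaction
edge list seeded with the signature genes.  With no arguments it runs
on the packaged published counts, annotation and synthetic edge list.

    python analysis/06_report_signature.py
"""

import argparse
from pathlib import Path

import pandas as pd

import snpsig
from snpsig import annotate_signature, build_interaction_graph, hub_nodes
from snpsig.association import chi2_genotype_test
from snpsig.datasets import (SIGNATURE_GENES, genotype_tables_from_counts,
                             load_signature_annotation)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--annotation", type=Path,
                    default=snpsig.data_path("signature_annotation.tsv"))
    ap.add_argument("--edges", type=Path,
                    default=snpsig.data_path("ppi_edges_synthetic.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/report"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    # genotype-frequency report from the packaged published counts
    rows = []
    for sid, table in genotype_tables_from_counts().items():
        try:
            _, _, p = chi2_genotype_test(table)
        except ValueError:
            p = float("nan")
        for stage, counts, nocall, n in (("A", table.counts_a, table.nocall_a,
                                          table.n_a),
                                         ("B", table.counts_b, table.nocall_b,
                                          table.n_b)):
            rows.append({"snp_id": sid, "stage": stage, "p": p,
                         **{f"pct_g{i+1}": 100 * c / n
                            for i, c in enumerate(counts)},
                         "pct_no_call": 100 * nocall / n})
    freq = pd.DataFrame(rows)
    freq.to_csv(args.out_dir / "genotype_frequencies.tsv", sep="\t",
                index=False)

    mapping = pd.read_csv(args.annotation, sep="\t", dtype=str)
    ranked_ids = freq["snp_id"].drop_duplicates().tolist()
    records, unmapped, counts = annotate_signature(ranked_ids, mapping)
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        args.out_dir / "signature_annotation.tsv", sep="\t", index=False)
    print(f"{len(records)} signature SNPs annotated "
          f"({counts}); {len(unmapped)} unannotated")

    graph = build_interaction_graph(str(args.edges), SIGNATURE_GENES)
    hubs = hub_nodes(graph)
    pd.DataFrame({"hub": hubs}).to_csv(args.out_dir / "hub_proteins.tsv",
                                       sep="\t", index=False)
    print(f"connector hubs (>= 2 signature-gene neighbours): "
          f"{', '.join(hubs)}")
    if graph.graph["absent_seeds"]:
        print(f"seed genes absent from the edge list: "
              f"{graph.graph['absent_seeds']}")


if __name__ == "__main__":
    main()
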