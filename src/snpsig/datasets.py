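"""Packaged reference tables.

``top20_genotype_counts.tsv`` — published per-group genotype counts for
the 20 top-ranked SNPs of the heart-failure staging study this package
re-implements (83 Stage A vs 34 Stage B genotyped subjects).  The three
genotype-count columns follow the printed category order for each SNP;
for the chi-square worked examples only the category partition matters,
not which category is hom-ref.

``signature_annotation.tsv`` — the 13 annotated signature SNPs with
variant type, gene symbol(s), gene type and expression pattern
(six protein-coding genes, one pseudogene, six ncRNA genes).
KIAA1429 is also known as VIRMA; edge lists must use one symbol.

``ppi_edges_synthetic.tsv`` — a SYNTHETIC protein-interaction edge list
constructed to match the described connectivity of the study's network
figure (five connector hubs each touching two signature genes, plus
single-seed decoy neighbours); it is a stand-in fixture, not a BioGRID
export.
"""

from __future__ import annotations

import pandas as pd

from . import data_path
from .association import GenotypeTable

SIGNATURE_GENES = ("GAD2", "APP", "RASGEF1C", "MACROD2", "DMD", "DOCK1",
                   "PGAM1P5")


def load_top20_genotype_counts() -> pd.DataFrame:
    return pd.read_csv(data_path("top20_genotype_counts.tsv"), sep="\t")


def load_signature_annotation() -> pd.DataFrame:
    return pd.read_csv(data_path("signature_annotation.tsv"), sep="\t", dtype=str)


def load_ppi_edges_synthetic() -> pd.DataFrame:
    return pd.read_csv(data_path("ppi_edges_synthetic.tsv"), sep="\t", dtype=str)


def genotype_tables_from_counts(counts: pd.DataFrame | None = None):
    """Build per-SNP :class:`GenotypeTable` objects from a counts table.

    Expects one Stage A and one Stage B row per SNP with columns
    ``count_g1..count_g3`` and ``count_nocall``; defaults to the
    packaged top-20 table.
    """
    if counts is None:
        counts = load_top20_genotype_counts()
    tables: dict[str, GenotypeTable] = {}
    for sid, grp in counts.groupby("snp_id", sort=False):
        rows = {r.stage: r for r in grp.itertuples()}
        if set(rows) != {"A", "B"}:
            raise ValueError(f"SNP {sid}: need exactly one Stage A and one B row")
        a, b = rows["A"], rows["B"]
        tables[sid] = GenotypeTable(
            snp_id=sid,
            counts_a=(a.count_g1, a.count_g2, a.count_g3),
            counts_b=(b.count_g1, b.count_g2, b.count_g3),
            nocall_a=a.count_nocall,
            nocall_b=b.count_nocall,
        )
    return tables
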