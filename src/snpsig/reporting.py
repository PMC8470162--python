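"""Descriptive outputs: genotype-frequency reports, group comparisons,
signature annotation, and hub detection on a protein-interaction graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import association
from .genotypes import GenotypeMatrix

GENOTYPE_CATEGORIES = ("hom_ref", "het", "hom_alt", "no_call")


def genotype_frequency_report(
    matrix: GenotypeMatrix, phenotype: np.ndarray, snp_ids
) -> pd.DataFrame:
    """Per-SNP, per-group genotype percentages plus the chi-square test.

    Percentages are taken over *all* subjects in the group, so a failed
    call shows up as its own slice; the chi-square p-value is computed
    on the called genotypes only.  Significance flags mark the 0.005
    and 0.001 display thresholds.
    """
    rows = []
    for sid in snp_ids:
        table = association.genotype_table(matrix, phenotype, sid)
        try:
            _, _, p = association.chi2_genotype_test(table)
        except ValueError:
            p = np.nan
        for grp, counts, nocall, n in (
            ("A", table.counts_a, table.nocall_a, table.n_a),
            ("B", table.counts_b, table.nocall_b, table.n_b),
        ):
            all_counts = (*counts, nocall)
            row = {"snp_id": sid, "stage": grp, "n": n, "p": p,
                   "flag": "**" if p < 0.001 else ("*" if p < 0.005 else "")}
            for cat, c in zip(GENOTYPE_CATEGORIES, all_counts):
                row[f"count_{cat}"] = c
                row[f"pct_{cat}"] = 100.0 * c / n
            rows.append(row)
    report = pd.DataFrame(rows)
    pct_cols = [f"pct_{c}" for c in GENOTYPE_CATEGORIES]
    assert np.allclose(report[pct_cols].sum(axis=1), 100.0)
    return report


def welch_t_test(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sample t test from summary statistics.

    Returns (t, df, p) with Satterthwaite degrees of freedom and a
    two-sided p-value.  Used for group comparisons of continuous
    clinical variables reported as mean +/- SD.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class AnnotationRecord:
    snp_id: str
    variant_type: str
    gene_symbol: str
    gene_type: str
    expression_pattern: str


ANNOTATION_COLUMNS = ["snp_id", "variant_type", "gene_symbol",
                      "gene_type", "expression_pattern"]


def annotate_signature(ranked_snp_ids, mapping: pd.DataFrame | str):
    """Static join of the ranked signature against a SNP→gene mapping.

    ``mapping`` is a TSV path or DataFrame with the columns
    ``snp_id, variant_type, gene_symbol, gene_type, expression_pattern``.
    Returns (records in rank order, unmapped snp_ids, counts by gene_type).
    Annotation strings are carried verbatim; a duplicated snp_id in the
    mapping is an error.
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, sep="\t", dtype=str)
    missing_cols = set(ANNOTATION_COLUMNS) - set(mapping.columns)
    if missing_cols:
        raise ValueError(f"mapping lacks column(s) {sorted(missing_cols)}")
    if mapping["snp_id"].duplicated().any():
        dupes = mapping.loc[mapping["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id(s) in mapping: {dupes}")
    by_id = mapping.set_index("snp_id")
    records, unmapped = [], []
    for sid in ranked_snp_ids:
        if sid in by_id.index:
            r = by_id.loc[sid]
            records.append(AnnotationRecord(sid, r.variant_type, r.gene_symbol,
                                            r.gene_type, r.expression_pattern))
        else:
            unmapped.append(sid)
    counts = pd.Series([r.gene_type for r in records]).value_counts().to_dict()
    return records, unmapped, counts


def build_interaction_graph(edges, seeds) -> nx.Graph:
    """Undirected, deduplicated protein-interaction graph with seed set.

    ``edges`` is a TSV path or an iterable of (protein_a, protein_b)
    pairs; self-loops are dropped.  Seed genes absent from the edge
    list are recorded in ``graph.graph['absent_seeds']``.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "read"):
        table = pd.read_csv(edges, sep="\t", dtype=str)
        pairs = table.iloc[:, :2].itertuples(index=False)
    else:
        pairs = edges
    g = nx.Graph()
    for a, b in pairs:
        if a == b:
            continue
        g.add_edge(a, b)
    seeds = set(seeds)
    g.graph["seeds"] = seeds & set(g.nodes)
    g.graph["absent_seeds"] = sorted(seeds - set(g.nodes))
    return g


def hub_nodes(graph: nx.Graph, min_seed_degree: int = 2) -> list[str]:
    """Non-seed proteins adjacent to >= ``min_seed_degree`` seed genes.

    These are the connector proteins through which the signature genes
    interact.  Sorted by seed-degree descending, then name; invariant
    under edge-list order and duplication.
    """
    seeds = graph.graph.get("seeds", set())
    if not seeds:
        raise ValueError("empty seed set")
    scored = []
    for node in graph.nodes:
        if node in seeds:
            continue
        sd = sum(1 for nb in graph.neighbors(node) if nb in seeds)
        if sd >= min_seed_degree:
            scored.append((-sd, node))
    return [name for _negsd, name in sorted(scored)]
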