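"""Readers and writers for genotype, phenotype, and annotation files.

Two genotype dialects are supported:

``ped_map``
    White-space-delimited PLINK-style text: ``<prefix>.ped`` holds one
    subject per line (FID, IID, father, mother, sex, phenotype, then two
    allele characters per SNP; ``0 0`` = no-call) and ``<prefix>.map``
    holds one SNP per line (chromosome, snp_id, genetic distance, bp
    position).  Because a .ped file alone cannot encode which allele is
    the alternate (a monomorphic probe never shows it), the writer also
    emits ``<prefix>.alleles`` (snp_id, ref, alt); the reader uses it
    when present and otherwise orients the minor allele as alt, breaking
    ties lexicographically.

``tsv``
    One header line ``subject_id<TAB>snp:ref:alt ...`` followed by one
    row per subject with additive dosage cells in {0, 1, 2, NA}.

Phenotype files are two-column TSVs (subject_id, stage in {A, B}).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SNPMeta, STAGE_LABELS

_PED_PHENO = {0: "1", 1: "2"}  # PLINK coding: 1 = unaffected (Stage A), 2 = affected


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# PLINK-style .ped/.map
# ---------------------------------------------------------------------------

def write_plink(
    matrix: GenotypeMatrix,
    prefix: str | Path,
    phenotype: np.ndarray | None = None,
    meta: list[SNPMeta] | None = None,
) -> None:
    prefix = Path(prefix)
    if meta is None:
        meta = [SNPMeta(s, "1", j + 1) for j, s in enumerate(matrix.snp_ids)]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for m in meta:
            fh.write(f"{m.chromosome}\t{m.snp_id}\t0\t{m.position}\n")
    with open(prefix.with_suffix(".alleles"), "w") as fh:
        fh.write("snp_id\tref\talt\n")
        for sid, (ref, alt) in zip(matrix.snp_ids, matrix.allele_labels):
            fh.write(f"{sid}\t{ref}\t{alt}\n")
    geno_strings = _dosage_to_allele_pairs(matrix)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, subj in enumerate(matrix.subject_ids):
            pheno = "-9" if phenotype is None else _PED_PHENO[int(phenotype[i])]
            fh.write(" ".join([subj, subj, "0", "0", "0", pheno] + geno_strings[i]))
            fh.write("\n")


def _dosage_to_allele_pairs(matrix: GenotypeMatrix) -> list[list[str]]:
    out = []
    for i in range(matrix.n_subjects):
        row = []
        for j, (ref, alt) in enumerate(matrix.allele_labels):
            d = matrix.calls[i, j]
            if d == MISSING:
                row.append("0 0")
            elif d == 0:
                row.append(f"{ref} {ref}")
            elif d == 1:
                row.append(f"{ref} {alt}")
            else:
                row.append(f"{alt} {alt}")
        out.append(row)
    return out


def _read_map(path: Path) -> list[SNPMeta]:
    meta = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 fields, got {len(parts)}")
            chrom, sid, _cm, pos = parts
            try:
                meta.append(SNPMeta(sid, chrom, int(pos)))
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
    return meta


def _read_alleles(path: Path) -> dict[str, tuple[str, str]]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return {r.snp_id: (r.ref, r.alt) for r in table.itertuples()}


def _read_ped(path: Path, meta: list[SNPMeta]):
    n_snps = len(meta)
    subjects: list[str] = []
    phenos: list[int] = []
    # per-SNP observed allele pairs per subject, as (a1, a2) strings
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{path}:{ln}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2 x {n_snps} SNPs), got {len(parts)}"
                )
            subjects.append(parts[1])
            phenos.append(int(float(parts[5])) if parts[5] != "-9" else -9)
            pairs.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)])
    return subjects, phenos, pairs


def read_plink(prefix: str | Path):
    """Read ``<prefix>.ped`` / ``.map`` (and ``.alleles`` if present).

    Returns (GenotypeMatrix, list[SNPMeta]).  Subjects' PLINK phenotype
    column is ignored here; use :func:`read_phenotype` for stage labels.
    """
    prefix = Path(prefix)
    meta = _read_map(prefix.with_suffix(".map"))
    subjects, _phenos, pairs = _read_ped(prefix.with_suffix(".ped"), meta)
    alleles_path = prefix.with_suffix(".alleles")
    known = _read_alleles(alleles_path) if alleles_path.exists() else {}

    n, m = len(subjects), len(meta)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    labels: list[tuple[str, str]] = []
    for j, mrec in enumerate(meta):
        observed: dict[str, int] = {}
        for i in range(n):
            for a in pairs[i][j]:
                if a != "0":
                    observed[a] = observed.get(a, 0) + 1
        if len(observed) > 2:
            raise ParseError(
                f"{prefix}.ped: SNP {mrec.snp_id} shows more than two alleles: "
                f"{sorted(observed)}"
            )
        if mrec.snp_id in known:
            ref, alt = known[mrec.snp_id]
            extra = set(observed) - {ref, alt}
            if extra:
                raise ParseError(
                    f"{prefix}.ped: SNP {mrec.snp_id} shows allele(s) {sorted(extra)} "
                    f"not in declared pair ({ref}, {alt})"
                )
        elif len(observed) == 2:
            # minor allele as alt; lexicographic tie-break
            (a1, c1), (a2, c2) = sorted(observed.items())
            ref, alt = (a1, a2) if c1 >= c2 else (a2, a1)
        elif len(observed) == 1:
            ref = next(iter(observed))
            alt = "A" if ref != "A" else "G"  # arbitrary distinct placeholder
        else:
            ref, alt = "A", "G"
        labels.append((ref, alt))
        for i in range(n):
            a, b = pairs[i][j]
            if a == "0" or b == "0":
                continue
            calls[i, j] = (a == alt) + (b == alt)
    return GenotypeMatrix(subjects, [m_.snp_id for m_ in meta], calls, labels), meta


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = [
            f"{sid}:{ref}:{alt}"
            for sid, (ref, alt) in zip(matrix.snp_ids, matrix.allele_labels)
        ]
        fh.write("subject_id\t" + "\t".join(header) + "\n")
        for i, subj in enumerate(matrix.subject_ids):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in matrix.calls[i]
            ]
            fh.write(subj + "\t" + "\t".join(cells) + "\n")


def read_tsv(path: str | Path):
    path = Path(path)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}:1: empty file") from None
        if not header or header[0] != "subject_id":
            raise ParseError(f"{path}:1: first header cell must be 'subject_id'")
        snp_ids, labels = [], []
        for cell in header[1:]:
            bits = cell.split(":")
            if len(bits) != 3:
                raise ParseError(
                    f"{path}:1: header cell {cell!r} is not 'snp_id:ref:alt'"
                )
            snp_ids.append(bits[0])
            labels.append((bits[1], bits[2]))
        subjects, rows = [], []
        for ln, parts in enumerate(reader, start=2):
            if not parts:
                continue
            if len(parts) != 1 + len(snp_ids):
                raise ParseError(
                    f"{path}:{ln}: expected {1 + len(snp_ids)} fields, got {len(parts)}"
                )
            subjects.append(parts[0])
            try:
                rows.append(
                    [MISSING if c == "NA" else int(c) for c in parts[1:]]
                )
            except ValueError:
                raise ParseError(
                    f"{path}:{ln}: cells must be 0, 1, 2 or NA"
                ) from None
    calls = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(snp_ids)), np.int8)
    matrix = GenotypeMatrix(subjects, snp_ids, calls, labels)
    meta = [SNPMeta(s, "un", j + 1) for j, s in enumerate(snp_ids)]
    return matrix, meta


def read_genotypes(path: str | Path, format: str = "tsv"):
    """Dispatch to :func:`read_plink` (``ped_map``) or :func:`read_tsv`."""
    if format == "ped_map":
        return read_plink(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Phenotype and ground-truth files
# ---------------------------------------------------------------------------

def write_phenotype(subject_ids, phenotype, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tstage\n")
        for subj, y in zip(subject_ids, phenotype):
            fh.write(f"{subj}\t{STAGE_LABELS[int(y)]}\n")


def read_phenotype(path: str | Path, subject_ids=None) -> np.ndarray:
    """Read a stage TSV; if ``subject_ids`` given, align to that order."""
    from .genotypes import phenotype_from_labels

    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns) != ["subject_id", "stage"]:
        raise ParseError(f"{path}: expected columns subject_id, stage")
    if subject_ids is not None:
        table = table.set_index("subject_id")
        missing = [s for s in subject_ids if s not in table.index]
        if missing:
            raise ParseError(f"{path}: no stage for subject(s) {missing[:5]}")
        table = table.loc[list(subject_ids)].reset_index()
    return phenotype_from_labels(table["stage"].tolist())
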