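"""Probe-level quality control.

Two exclusion rules are applied, mirroring standard array QC for this
kind of case/control screen: probes with a minor allele frequency of 0
(monomorphic) and probes with a missing-call rate strictly above the
threshold (default 0.10; a probe at exactly 10% is retained).  A probe
failing both rules is attributed to the monomorphic rule so the report
tallies are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, QCReport

DEFAULT_MISSING_THRESHOLD = 0.10


def compute_maf(matrix: GenotypeMatrix) -> pd.Series:
    """Per-SNP minor allele frequency over non-missing calls.

    MAF = min(f, 1 - f) where f is the alternate-allele frequency among
    called genotypes; a probe with no called genotypes gets NaN.
    """
    calls = matrix.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(f, 1.0 - f)
    return pd.Series(maf, index=matrix.snp_ids, name="maf")


def compute_missing_rate(matrix: GenotypeMatrix) -> pd.Series:
    """Per-SNP fraction of missing calls, in [0, 1]."""
    rate = (matrix.calls == MISSING).mean(axis=0)
    return pd.Series(rate, index=matrix.snp_ids, name="missing_rate")


def qc_filter(
    matrix: GenotypeMatrix,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the two exclusion rules and return the filtered matrix + audit.

    A probe with every call missing has undefined MAF; it is removed
    under the missingness rule (its missing rate is 1).
    """
    if not 0.0 <= missing_threshold <= 1.0:
        raise ValueError("missing_threshold must be in [0, 1]")
    maf = compute_maf(matrix)
    miss = compute_missing_rate(matrix)

    # NaN MAF (all calls missing) falls to the missingness rule, not this one
    monomorphic = np.nan_to_num(maf.values, nan=1.0) == 0.0
    high_missing = miss.values > missing_threshold
    removed_mono = monomorphic
    removed_miss = high_missing & ~monomorphic  # double failures count as mono
    keep = ~(removed_mono | removed_miss)

    status = np.where(
        removed_mono, "removed_monomorphic",
        np.where(removed_miss, "removed_missingness", "retained"),
    )
    per_snp = pd.DataFrame(
        {"snp_id": matrix.snp_ids, "maf": maf.values,
         "missing_rate": miss.values, "status": status}
    )
    report = QCReport(
        n_input_snps=matrix.n_snps,
        n_removed_monomorphic=int(removed_mono.sum()),
        n_removed_missingness=int(removed_miss.sum()),
        n_retained=int(keep.sum()),
        missing_threshold=missing_threshold,
        per_snp=per_snp,
    )
    if report.n_retained == 0:
        raise ValueError(
            "QC removed every SNP; review the input data or the "
            f"missing-call threshold ({missing_threshold:g})"
        )
    kept_ids = [s for s, k in zip(matrix.snp_ids, keep) if k]
    return matrix.subset_snps(kept_ids), report


def encode_additive(matrix: GenotypeMatrix, impute: str = "mode") -> pd.DataFrame:
    """Complete numeric dosage matrix for the ML selectors.

    Missing calls are imputed per SNP with the column mode (ties broken
    toward the lower dosage) or the column mean.  A column with no
    called genotype cannot be imputed and raises — such probes should
    have been removed by :func:`qc_filter`.
    """
    if impute not in ("mode", "mean"):
        raise ValueError("impute must be 'mode' or 'mean'")
    calls = matrix.calls
    out = calls.astype(float)
    missing = calls == MISSING
    if not missing.any():
        return pd.DataFrame(out, index=matrix.subject_ids, columns=matrix.snp_ids)
    for j in np.nonzero(missing.any(axis=0))[0]:
        obs = calls[~missing[:, j], j]
        if obs.size == 0:
            raise ValueError(
                f"SNP {matrix.snp_ids[j]} has no called genotypes; run QC first"
            )
        if impute == "mode":
            counts = np.bincount(obs, minlength=3)
            fill = float(np.argmax(counts))  # argmax takes the lowest dosage on ties
        else:
            fill = float(obs.mean())
        out[missing[:, j], j] = fill
    return pd.DataFrame(out, index=matrix.subject_ids, columns=matrix.snp_ids)
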