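"""snpsig — SNP-signature discovery for preclinical heart-failure staging.

A reusable implementation of an AI-assisted case/control SNP screening
workflow: genotype QC (monomorphic and high-missingness probe removal),
per-SNP chi-square association testing with Bonferroni correction and
oriented allelic odds ratios, bootstrap ensemble feature selection
(random forest / linear SVM / LASSO over repeated stratified 80:20
splits), top-k signature evaluation across four classifiers, and
descriptive genotype-frequency / annotation / protein-interaction
reporting — together with a synthetic cohort generator so the whole
pipeline is testable without access to a real cohort.
"""

from importlib import resources

from .genotypes import (
    MISSING,
    STAGE_A,
    STAGE_B,
    GenotypeMatrix,
    QCReport,
    SNPMeta,
    phenotype_from_labels,
)
from .simulate import SimulationConfig, TrueSignature, realized_allelic_or, simulate_cohort
from .qc import compute_maf, compute_missing_rate, encode_additive, qc_filter
from .association import (
    AssociationResult,
    GenotypeTable,
    allelic_or,
    bonferroni,
    bonferroni_threshold,
    chi2_genotype_test,
    genotype_table,
    screen,
)
from .selection import (
    SelectionCounts,
    SplitPlan,
    accumulate_and_rank,
    make_splits,
    select_lasso,
    select_rf,
    select_svm,
)
from .evaluation import (
    ConfusionMatrix,
    EvaluationCurve,
    auc,
    choose_signature,
    confusion,
    evaluate_topk,
)
from .reporting import (
    AnnotationRecord,
    annotate_signature,
    build_interaction_graph,
    genotype_frequency_report,
    hub_nodes,
    welch_t_test,
)
from .pipeline import PipelineResult, leakage_audit, run_pipeline, simulate_and_run

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data file (annotation / edge-list fixtures)."""
    return resources.files("snpsig") / "data" / name
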