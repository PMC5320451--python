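"""Circadian targeted-metabolomics screening and biomarker-panel pipeline.

Implements the analysis chain for an around-the-clock plasma metabolomics
cohort study: panel QC (LOD/LLOQ/ULOQ and QC2-CV exclusion, between-plate
QC2 normalization), circadian phase alignment to each animal's dim-light
melatonin onset, per-metabolite two-way ANOVA screening with BH-FDR and
class tabulation, urea-/NO-cycle ratio analysis, and a permutation-filtered
forward-stepwise logistic biomarker panel evaluated by leave-one-sheep-out
cross-validation.  A synthetic-cohort generator provides data with the
study's statistical structure.
"""

__version__ = "0.1.0"

from .data_model import (  # noqa: F401
    CohortDesign,
    ConcentrationTable,
    ValidationError,
    read_concentration_table,
    write_concentration_table,
    write_results_table,
    read_results_table,
)
from .qc import QCThresholds, ExclusionReport, exclude_metabolites, qc2_normalize  # noqa: F401
from .circadian import (  # noqa: F401
    MelatoninProfile,
    PhaseAlignment,
    align_to_dlmo,
    compute_dlmo,
    phase_bin,
)
from .diffstats import (  # noqa: F401
    RatioDefinition,
    UREA_CYCLE_RATIOS,
    bh_fdr,
    compute_ratio_series,
    fit_metabolite_anova,
    group_means_sem,
    screen_metabolites,
    summarize_significance,
)
from .panel import (  # noqa: F401
    MarkerFilterCriteria,
    PanelModel,
    auc,
    auc_by_timepoint,
    fit_logistic,
    losocv_predictions,
    permutation_auc_test,
    pooled_cv_auc,
    preselect_markers,
    roc_curve,
    sensitivity_at_specificity,
    stepwise_build_panels,
)
from .synthetic import (  # noqa: F401
    GeneratedCohort,
    SyntheticConfig,
    generate_cohort,
    generate_kit_fixture,
    generate_melatonin,
    paperlike_config,
)
from .reference import reference_annotation, reference_screen_table  # noqa: F401
from .pipeline import (  # noqa: F401
    PipelineConfig,
    genotype_phase_profiles,
    hierarchical_cluster_order,
    run_pipeline,
)
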