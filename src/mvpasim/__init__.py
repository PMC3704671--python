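"""mvpasim: the statistics of multi-voxel pattern analysis, by simulation.

Generates synthetic block-design BOLD data with a known (usually absent)
class signal and runs the full MVPA decoding pipeline on it — linear-SVM
or correlation classification, random time-point vs Leave-Block-Out
cross-validation, and binomial / T-test / permutation significance
procedures — so that the false-positive rates and performance-inflation
effects of each analysis choice can be measured rather than assumed.
"""

from .sim_core import (ConfigurationError, ExperimentDesign, HRFSpec,
                       LabeledTimeseries, SignalSpec, build_block_labels,
                       convolve_with_hrf, hrf_kernel, inject_signal,
                       make_class_patterns, sample_null_neural,
                       simulate_dataset, trim_initial_volumes)
from .classification import (TrainedClassifier, fit_linear_svm,
                             fit_pearson_classifier, score_accuracy)
from .cross_validation import (FoldResult, PerformanceEstimate, fold_success,
                               leave_block_out_cv, random_timepoint_cv)
from .significance import (NullDistribution, TestResult, binomial_fold_test,
                           block_permutation_null, global_permutation_null,
                           random_balanced_assignment, significance_from_null,
                           t_test_vs_chance)
from .experiments import (ExperimentConfig, FPRResult,
                          NullPerformanceDistribution, SweepResult,
                          estimate_false_positive_rate, hrf_width_sweep,
                          null_performance_distribution,
                          random_cv_inflation_sweep, spatial_corr_sweep,
                          wilson_ci)
from .cli_io import (export_dataset_nifti, parse_config, read_timeseries_csv,
                     write_results, write_timeseries_csv)

__version__ = "0.1.0"

__all__ = [
    "ConfigurationError", "ExperimentDesign", "HRFSpec", "SignalSpec",
    "LabeledTimeseries", "build_block_labels", "sample_null_neural",
    "make_class_patterns", "inject_signal", "hrf_kernel", "convolve_with_hrf",
    "trim_initial_volumes", "simulate_dataset",
    "TrainedClassifier", "fit_linear_svm", "fit_pearson_classifier",
    "score_accuracy",
    "FoldResult", "PerformanceEstimate", "random_timepoint_cv",
    "leave_block_out_cv", "fold_success",
    "NullDistribution", "TestResult", "binomial_fold_test",
    "t_test_vs_chance", "global_permutation_null", "block_permutation_null",
    "random_balanced_assignment", "significance_from_null",
    "ExperimentConfig", "FPRResult", "SweepResult",
    "NullPerformanceDistribution", "estimate_false_positive_rate",
    "null_performance_distribution", "hrf_width_sweep", "spatial_corr_sweep",
    "random_cv_inflation_sweep", "wilson_ci",
    "parse_config", "write_results", "write_timeseries_csv",
    "read_timeseries_csv", "export_dataset_nifti",
]
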