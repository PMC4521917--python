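"""End-to-end orchestration of the sway-variability analysis.

Chains cohort generation (or loading), preprocessing, normalization,
posture-level SOM training, BMU-trajectory mapping, TTvar computation with
group comparisons, and the trajectory-level classification stage.  The SOM
stages expose subsampling and epoch counts so the analysis can run at desk
scale; the map geometry defaults to the full 25 x 25 lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from .normalize import NormalizedArray, apply_normalization, fit_normalization, flatten_for_som
from .preprocess import PostureArray, preprocess_cohort
from .som import BMUTrajectory, SOMModel, TrainingSchedule, data_range_of, init_som, map_trial, train
from .synthetic import CohortConfig, CohortDataset, generate_cohort
from .variability import group_comparison, ttvar_table


@dataclass
class SOMStageConfig:
    """Scale controls for one SOM training stage."""

    rows: int = 25
    cols: int = 25
    epochs: int = 1000
    subsample: int | None = None  # max training rows; None = all
    seed: int = 0


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one cohort."""

    cohort: CohortDataset
    posture: PostureArray
    metrics: pd.DataFrame
    norm_model: object
    normalized: NormalizedArray
    som_input: np.ndarray
    som: SOMModel
    qe_trace: list[float]
    trajectories: list[BMUTrajectory]
    ttvar: pd.DataFrame
    comparisons: dict[int, dict[str, float]]
    trajectory_matrix: np.ndarray | None = None
    trajectory_labels: np.ndarray | None = None
    second_som: SOMModel | None = None
    second_bmus: np.ndarray | None = None
    report: object | None = None


def run_analysis(
    cohort: CohortDataset | None = None,
    cohort_config: CohortConfig | None = None,
    som_config: SOMStageConfig | None = None,
    second_som_config: SOMStageConfig | None = None,
    classify_conditions: tuple[int, ...] = _classify.DEFAULT_CONDITIONS,
    knn_runs: int = 100,
    knn_k: int = 5,
    seed: int = 0,
    run_classification: bool = True,
) -> AnalysisResult:
    """Run the full analysis on a (possibly generated) cohort."""
    rng = np.random.default_rng(seed)
    if cohort is None:
        cohort = generate_cohort(cohort_config or CohortConfig(seed=seed))
    som_config = som_config or SOMStageConfig(seed=seed)
    second_som_config = second_som_config or SOMStageConfig(
        epochs=min(som_config.epochs, 200), seed=seed + 1)

    posture, metrics = preprocess_cohort(cohort.trials)
    norm_model = fit_normalization(
        posture.values, trial_ids=list(posture.index["trial_id"]))
    normalized = apply_normalization(posture.values, norm_model)
    matrix, _ = flatten_for_som(normalized.values, posture.index)

    if som_config.subsample is not None and som_config.subsample < len(matrix):
        rows_idx = rng.choice(len(matrix), size=som_config.subsample,
                              replace=False)
        train_rows = matrix[rows_idx]
    else:
        train_rows = matrix
    som = init_som(som_config.rows, som_config.cols, matrix.shape[1],
                   data_range_of(matrix), seed=som_config.seed)
    som, qe_trace = train(
        som, train_rows, schedule=TrainingSchedule(iterations=som_config.epochs))

    trajectories = [
        map_trial(som, normalized.values[i], trial_id=tid)
        for i, tid in enumerate(posture.index["trial_id"])
    ]
    ttvar_df = ttvar_table(trajectories, posture.index)
    comparisons = group_comparison(ttvar_df)

    result = AnalysisResult(
        cohort=cohort, posture=posture, metrics=metrics,
        norm_model=norm_model, normalized=normalized, som_input=matrix,
        som=som, qe_trace=qe_trace, trajectories=trajectories,
        ttvar=ttvar_df, comparisons=comparisons)

    if run_classification:
        S, labels, _ = _classify.build_trajectory_vectors(
            trajectories, posture.index, conditions=classify_conditions)
        second, bmus = _classify.train_second_som(
            S, rows=second_som_config.rows, cols=second_som_config.cols,
            iterations=second_som_config.epochs, seed=second_som_config.seed)
        report = _classify.knn_classify(
            bmus.astype(float), labels, k=knn_k, runs=knn_runs, seed=seed + 2)
        result.trajectory_matrix = S
        result.trajectory_labels = labels
        result.second_som = second
        result.second_bmus = bmus
        result.report = report
    return result
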