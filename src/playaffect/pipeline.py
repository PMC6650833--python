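"""End-to-end glue: from per-subject recordings to cohort-level results.

These helpers wire the stages together exactly as the method prescribes:
segment calibration recordings into H0/H1, slide 15 s windows in 1 s steps,
compute the configured features per window, assemble labeled datasets,
train the per-subject network, and evaluate under the Study-1 (LOSOCV) or
Study-2 (independent evaluation game) protocol.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .config import PipelineConfig
from .dataset import (
    FeatureSetSpec,
    build_training_set,
    sample_test_set,
    select_eval_levels,
    session_window_features,
    test_window_starts,
)
from .evaluation import EvalResult, cohort_summary, cross_game_evaluate, losocv_evaluate
from .model import ModelConfig
from .rppg import RppgConfig
from .segmentation import AnalysisWindow, enumerate_windows, segment_calibration
from .simulate import SimCohort, SimSubject

log = logging.getLogger("playaffect.pipeline")


def compact_model_config(seed: int = 0) -> ModelConfig:
    """Desk-scale search settings for cohort-level simulation studies:
    4 random-search draws scored by 1 x 5-fold CV, 300 epochs.  Per-subject
    deployment keeps the full 30-draw, 3 x 10-fold default."""
    return ModelConfig(search_iterations=4, cv_folds=5, cv_repeats=1,
                       max_epochs=300, seed=seed)


def rppg_config(cfg: PipelineConfig) -> RppgConfig:
    return RppgConfig(
        band_hz=cfg.band_hz,
        history_max_jump_bpm=cfg.hr_history_max_jump_bpm,
        min_peak_ratio=cfg.min_peak_ratio,
        seed=cfg.seed,
    )


def model_config(cfg: PipelineConfig) -> ModelConfig:
    return ModelConfig(
        search_iterations=cfg.search_iterations,
        cv_folds=cfg.cv_folds,
        cv_repeats=cfg.cv_repeats,
        seed=cfg.seed,
    )


def subject_training_samples(
    subject: SimSubject,
    spec: FeatureSetSpec,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Labeled H0/H1 window samples from a subject's three calibration games."""
    cfg = cfg or PipelineConfig()
    rcfg = rppg_config(cfg)
    features_by_game: dict[int, pd.DataFrame] = {}
    segments_by_game = {}
    for g, session in subject.calibration.items():
        h0, h1, _ = segment_calibration(session.duration_s, cfg.warmup_s,
                                        subject_id=subject.subject_id, game_id=g)
        segments_by_game[g] = (h0, h1)
        # the moving window slides over the whole recording (H0/H1 only label
        # windows); this keeps the HR history constraint threaded through the
        # discarded middle so estimates can track the boredom->stress drift
        windows = enumerate_windows(0.0, session.duration_s,
                                    cfg.window_length_s, cfg.window_step_s)
        features_by_game[g] = session_window_features(
            windows, spec.features, track=session.track, trace=session.trace,
            sensor_t=session.sensor_t, sensor_bpm=session.sensor_bpm, rppg_cfg=rcfg,
        )
    return build_training_set(
        features_by_game, segments_by_game, spec, subject_id=subject.subject_id,
        window_length_s=cfg.window_length_s, window_step_s=cfg.window_step_s,
    )


def subject_test_samples(
    subject: SimSubject,
    reports: pd.DataFrame,
    spec: FeatureSetSpec,
    cfg: PipelineConfig | None = None,
):
    """Independent test set of one subject from their selected evaluation levels.

    Returns ``(samples, selection)``; samples are empty when the subject is
    unevaluable.
    """
    cfg = cfg or PipelineConfig()
    rcfg = rppg_config(cfg)
    own = reports[reports["subject"] == subject.subject_id]
    selection = select_eval_levels(own)
    if selection.unevaluable:
        log.info("subject %s unevaluable: %s", subject.subject_id, selection.reason)
        return pd.DataFrame(columns=[*spec.features, "label", "subject", "source",
                                     "window_start_s"]), selection
    features_by_level = {}
    for lv in [*selection.stress_levels, *selection.boredom_levels]:
        session = subject.evaluation[lv]
        starts = test_window_starts(session.duration_s, cfg.window_length_s,
                                    cfg.sampling_interval_s)
        windows = [AnalysisWindow(s, cfg.window_length_s) for s in starts]
        features_by_level[lv] = session_window_features(
            windows, spec.features, track=session.track, trace=session.trace,
            sensor_t=session.sensor_t, sensor_bpm=session.sensor_bpm, rppg_cfg=rcfg,
        )
    samples = sample_test_set(features_by_level, selection, spec,
                              subject_id=subject.subject_id)
    return samples, selection


def evaluate_cohort_study1(
    cohort: SimCohort,
    spec: FeatureSetSpec,
    cfg: PipelineConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> tuple[list[EvalResult], dict]:
    """LOSOCV per subject; returns per-subject results and the cohort summary
    (including the pooled fold accuracies J used for paired tests)."""
    cfg = cfg or PipelineConfig()
    model_cfg = model_cfg or model_config(cfg)
    results = []
    for subject in cohort.subjects:
        if subject.manifest.excluded:
            log.info("subject %s excluded from Study-1 evaluation", subject.subject_id)
            continue
        samples = subject_training_samples(subject, spec, cfg)
        results.append(losocv_evaluate(samples, spec, model_cfg,
                                       subject_id=subject.subject_id))
    summary = cohort_summary(results)
    summary["J"] = [a for r in results for a in r.fold_accuracies]
    return results, summary


def evaluate_cohort_study2(
    cohort: SimCohort,
    spec: FeatureSetSpec | None = None,
    cfg: PipelineConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> tuple[list[EvalResult], dict]:
    """Full Study-2 protocol over a cohort; unevaluable subjects are excluded
    from the mean-accuracy aggregate with a logged reason."""
    cfg = cfg or PipelineConfig()
    spec = spec or FeatureSetSpec.preset("STUDY2")
    model_cfg = model_cfg or model_config(cfg)
    results = []
    skipped = []
    for subject in cohort.subjects:
        test, selection = subject_test_samples(subject, cohort.reports, spec, cfg)
        if selection.unevaluable or len(test) == 0:
            skipped.append(subject.subject_id)
            continue
        train = subject_training_samples(subject, spec, cfg)
        results.append(cross_game_evaluate(train, test, spec, model_cfg,
                                           subject_id=subject.subject_id))
    summary = cohort_summary(results)
    summary["unevaluable_subjects"] = skipped
    return results, summary
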