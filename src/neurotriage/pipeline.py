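"""End-to-end pipeline: cohort -> filter -> windows -> VMD -> IMF
selection -> sample entropy -> gradient-boosted classification.

Configuration is a nested dataclass tree loadable from YAML; a frozen
copy of the effective configuration is embedded in every report for
provenance.

Evaluation chronology
---------------------
Subjects are recorded in separate sessions, so the dataset-wide time
axis is time within the recording: the evaluation protocol orders the
pooled windows chronologically (all subjects' first seconds, then their
second seconds, ...) and trains on the early half, testing on the late
half.  Every subject appears on both sides of the split while adjacent,
near-duplicate windows never straddle it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .features import (
    SampEnParams,
    extract_feature_table,
    extract_feature_table_from_recordings,
)
from .model_eval import (
    ClassifierConfig,
    CVReport,
    chronological_order,
    DEFAULT_LEAVES_GRID,
    DEFAULT_LR_GRID,
    EvaluationReport,
    cross_validate,
    evaluate,
    fit_classifier,
    grid_search,
    time_ordered_split,
)
from .preprocess import bandpass_filter, read_recording, segment_cohort
from .recording import MultichannelRecording
from .synthetic import generate_cohort
from .vmd import VMDConfig

logger = logging.getLogger("neurotriage")


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort: counts mirror the 26-patient / 29-control study."""
    n_hc: int = 29
    n_mdd: int = 26
    duration_s: float = 90.0
    fs: float = 250.0
    seed: int = 0


@dataclass(frozen=True)
class PreprocessConfig:
    low_hz: float = 1.0
    high_hz: float = 45.0
    filter_order: int = 250
    window_s: float = 1.0
    step_s: float = 1.0


@dataclass(frozen=True)
class SelectionConfig:
    n_keep: int = 4
    rule: str = "centroid"
    min_energy_frac: float = 0.01
    segment: int = 125
    overlap: float = 0.5


@dataclass(frozen=True)
class FeatureConfig:
    kinds: tuple[str, ...] = ("sampen",)
    m: int = 2
    r_factor: float = 0.2
    sub_window: int = 20
    #: "recording": decompose each recording once and window the retained
    #: IMF streams (stable mode identity; default); "window": decompose
    #: every 1-s window independently.
    vmd_scope: str = "recording"


@dataclass(frozen=True)
class EvalConfig:
    test_frac: float = 0.5
    val_frac: float = 0.3
    cv_k: int = 5
    cv_shuffle: bool = False
    run_grid_search: bool = False
    leaves_grid: tuple[int, ...] = DEFAULT_LEAVES_GRID
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vmd: VMDConfig = field(default_factory=VMDConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            return obj

        return clean(asdict(self))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, key):
            section = dict(raw.get(key) or {})
            for f_name, f_val in section.items():
                if isinstance(f_val, list):
                    section[f_name] = tuple(f_val)
            return klass(**section)

        return cls(
            cohort=build(CohortConfig, "cohort"),
            preprocess=build(PreprocessConfig, "preprocess"),
            vmd=build(VMDConfig, "vmd"),
            selection=build(SelectionConfig, "selection"),
            features=build(FeatureConfig, "features"),
            classifier=build(ClassifierConfig, "classifier"),
            eval=build(EvalConfig, "eval"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    feature_table: pd.DataFrame
    n_windows: int
    n_features: int
    report: EvaluationReport
    cv_report: CVReport | None
    best_classifier: ClassifierConfig
    accuracy_grid: pd.DataFrame | None
    config: PipelineConfig


def load_cohort_from_dir(
    input_dir: str | Path,
    format: str = "csv",
    fs: float | None = None,
    n_channels: int = 3,
) -> list[MultichannelRecording]:
    """Read every ``*.csv`` / ``*.edf`` recording in a directory, sorted
    by filename; a ``HC``/``MDD`` filename prefix sets the label."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob(f"*.{format}"))
    if not paths:
        raise FileNotFoundError(f"no *.{format} recordings in {input_dir}")
    recs = []
    for p in paths:
        label = None
        stem = p.stem.upper()
        if stem.startswith("HC"):
            label = "HC"
        elif stem.startswith("MDD"):
            label = "MDD"
        recs.append(read_recording(p, format=format, fs=fs,
                                   n_channels=n_channels, label=label))
    return recs


def build_feature_table(
    cfg: PipelineConfig,
    recordings: list[MultichannelRecording] | None = None,
) -> pd.DataFrame:
    """Generate (or accept) a cohort and run it through filtering,
    windowing, VMD, IMF selection and feature extraction."""
    t0 = time.perf_counter()
    if recordings is None:
        recordings = generate_cohort(
            cfg.cohort.n_hc, cfg.cohort.n_mdd, cfg.cohort.duration_s,
            cfg.cohort.fs, seed=cfg.cohort.seed,
        )
        logger.info("generated %d synthetic recordings", len(recordings))
    filtered = [
        bandpass_filter(r, cfg.preprocess.low_hz, cfg.preprocess.high_hz,
                        order=cfg.preprocess.filter_order)
        for r in recordings
    ]
    sampen = SampEnParams(m=cfg.features.m, r_factor=cfg.features.r_factor)
    if cfg.features.vmd_scope == "recording":
        table = extract_feature_table_from_recordings(
            filtered,
            window_s=cfg.preprocess.window_s,
            step_s=cfg.preprocess.step_s,
            vmd_cfg=cfg.vmd,
            n_keep=cfg.selection.n_keep,
            feature_kinds=cfg.features.kinds,
            sampen=sampen,
            selection_rule=cfg.selection.rule,
            min_energy_frac=cfg.selection.min_energy_frac,
            sub_window=cfg.features.sub_window,
            segment=cfg.selection.segment,
            overlap=cfg.selection.overlap,
        )
    elif cfg.features.vmd_scope == "window":
        ws = segment_cohort(filtered, cfg.preprocess.window_s,
                            cfg.preprocess.step_s)
        logger.info("segmented %d windows [%.1fs]",
                    len(ws), time.perf_counter() - t0)
        table = extract_feature_table(
            ws,
            vmd_cfg=cfg.vmd,
            n_keep=cfg.selection.n_keep,
            feature_kinds=cfg.features.kinds,
            sampen=sampen,
            selection_rule=cfg.selection.rule,
            min_energy_frac=cfg.selection.min_energy_frac,
            sub_window=cfg.features.sub_window,
            segment=cfg.selection.segment,
            overlap=cfg.selection.overlap,
        )
    else:
        raise ValueError("features.vmd_scope must be 'recording' or 'window'")
    logger.info("extracted %d x %d feature table [%.1fs]",
                len(table), table.shape[1] - 3, time.perf_counter() - t0)
    return table


def run_pipeline(
    cfg: PipelineConfig | None = None,
    recordings: list[MultichannelRecording] | None = None,
    feature_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Full screening pipeline, returning the test-set evaluation, the
    cross-validation report and (optionally) the hyperparameter grid."""
    if cfg is None:
        cfg = PipelineConfig()
    if feature_table is None:
        feature_table = build_feature_table(cfg, recordings)
    feature_table = chronological_order(feature_table)
    train, val, test = time_ordered_split(
        feature_table, cfg.eval.test_frac, cfg.eval.val_frac)

    best_cfg = cfg.classifier
    grid = None
    if cfg.eval.run_grid_search and len(val):
        best_cfg, grid = grid_search(train, val, cfg.eval.leaves_grid,
                                     cfg.eval.lr_grid, base_cfg=cfg.classifier)
        logger.info("grid search best: %d leaves, lr %g",
                    best_cfg.num_leaves, best_cfg.learning_rate)

    # final model is refit on the whole training pool (train + validation)
    # once hyperparameters are settled
    pool = pd.concat([train, val], ignore_index=True)
    model = fit_classifier(pool, best_cfg)
    report = evaluate(model, test)
    logger.info("test accuracy %.2f%%", report.accuracy)

    cv_report = None
    if len(pool) >= cfg.eval.cv_k:
        cv_report = cross_validate(pool, best_cfg, k=cfg.eval.cv_k,
                                   seed=best_cfg.seed,
                                   shuffle=cfg.eval.cv_shuffle)
        logger.info("%d-fold CV accuracy %.2f +/- %.2f%%", cfg.eval.cv_k,
                    cv_report.mean["accuracy"], cv_report.sd["accuracy"])

    return PipelineResult(
        feature_table=feature_table,
        n_windows=len(feature_table),
        n_features=feature_table.shape[1] - 3,
        report=report,
        cv_report=cv_report,
        best_classifier=best_cfg,
        accuracy_grid=grid,
        config=cfg,
    )
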