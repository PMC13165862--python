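"""End-to-end orchestration: preprocess -> EKF -> features -> split ->
train -> predict -> agreement report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import RunConfig
from .features import FeatureMatrix, build_feature_matrix
from .io import load_corpus
from .modeling import (
    Dataset,
    HyperparamSpace,
    TrainedModel,
    group_split,
    random_search,
    save_model,
    train_target_model,
)
from .orientation import EkfConfig, EulerSeries, calibrate_gyro_bias, run_ekf
from .preprocess import (
    TARGET_NAMES,
    ForceTrial,
    ImuTrial,
    KineticTargets,
    StanceWindow,
    detect_stance,
    lowpass_filter,
    normalize_kinetics,
    resample_to_stance,
)
from .validation import AgreementReport, build_report

logger = logging.getLogger(__name__)


@dataclass
class ProcessedTrial:
    features: FeatureMatrix
    targets: KineticTargets
    window: StanceWindow
    euler: EulerSeries
    gyro_bias: np.ndarray


def process_trial(
    imu: ImuTrial,
    force: ForceTrial,
    moments: np.ndarray,
    cfg: RunConfig | None = None,
) -> ProcessedTrial:
    """Run one trial through filtering, EKF, stance detection, and
    normalization, producing its aligned feature/target blocks."""
    cfg = cfg or RunConfig()
    acc_f = lowpass_filter(imu.acc, imu.fs_imu, cfg.imu_cutoff_hz, cfg.filter_order)
    gyro_f = lowpass_filter(imu.gyro, imu.fs_imu, cfg.imu_cutoff_hz, cfg.filter_order)
    vgrf_f = lowpass_filter(
        force.vgrf, force.fs_force, cfg.force_cutoff_hz, cfg.filter_order
    )
    bias = calibrate_gyro_bias(
        gyro_f, imu.fs_imu, cfg.static_calibration_duration
    )
    gyro_c = gyro_f - bias
    ekf_cfg = EkfConfig(
        dt=1.0 / imu.fs_imu,
        g=cfg.ekf_g,
        sigma_q=cfg.ekf_sigma_q,
        sigma_a=cfg.ekf_sigma_a,
        static_calibration_duration=cfg.static_calibration_duration,
    )
    euler = run_ekf(acc_f, gyro_c, ekf_cfg)
    window = detect_stance(vgrf_f, cfg.stance_threshold_n, force.fs_force)
    filtered = replace(imu, acc=acc_f, gyro=gyro_c)
    fm = build_feature_matrix(filtered, euler, window)
    vgrf_bw, mom_nmkg = normalize_kinetics(
        vgrf_f, moments, imu.body_weight, imu.body_mass
    )
    vgrf_101 = resample_to_stance(vgrf_bw, window, fs=force.fs_force)
    mom_101 = resample_to_stance(mom_nmkg, window, fs=imu.fs_imu)
    kt = KineticTargets(
        vgrf_bw=vgrf_101,
        moments=mom_101,
        participant_id=imu.participant_id,
        trial_id=imu.trial_id,
    )
    return ProcessedTrial(
        features=fm, targets=kt, window=window, euler=euler, gyro_bias=bias
    )


def build_dataset(
    corpus: list[tuple[ImuTrial, ForceTrial, np.ndarray]],
    cfg: RunConfig | None = None,
) -> tuple[Dataset, list[ProcessedTrial]]:
    processed = []
    for imu, force, moments in corpus:
        try:
            processed.append(process_trial(imu, force, moments, cfg))
        except Exception as exc:
            raise type(exc)(f"preprocessing failed for trial {imu.key}: {exc}") from exc
    return Dataset([(p.features, p.targets) for p in processed]), processed


def train_models(
    train: Dataset, cfg: RunConfig | None = None
) -> dict[str, TrainedModel]:
    """Fit one ensemble per target, optionally preceded by randomized search."""
    cfg = cfg or RunConfig()
    space = HyperparamSpace()
    models = {}
    for target in TARGET_NAMES:
        if cfg.search_n_iter > 0:
            params = random_search(
                train,
                space,
                target,
                n_iter=cfg.search_n_iter,
                folds=cfg.cv_folds,
                seed=cfg.seed,
                grouped_cv=cfg.grouped_cv,
            )
            logger.info("search selected %s for %s", params, target)
        else:
            params = cfg.hyperparameters[target]
            space.validate(params)
        models[target] = train_target_model(train, target, params, seed=cfg.seed)
    return models


@dataclass
class PipelineResult:
    report: AgreementReport
    models: dict[str, TrainedModel]
    train: Dataset
    test: Dataset
    processed: list[ProcessedTrial]
    manifest: dict


def run_pipeline(
    corpus: list[tuple[ImuTrial, ForceTrial, np.ndarray]],
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Full in-memory pipeline on an already-loaded corpus."""
    cfg = cfg or RunConfig()
    dataset, processed = build_dataset(corpus, cfg)
    train, test = group_split(dataset, cfg.test_fraction, cfg.seed)
    models = train_models(train, cfg)
    report = build_report(models, test, smooth_plot=cfg.smooth_plot)
    manifest = cfg.manifest(
        n_trials=len(dataset),
        train_trials=sorted(train.groups),
        test_trials=sorted(test.groups),
    )
    return PipelineResult(
        report=report,
        models=models,
        train=train,
        test=test,
        processed=processed,
        manifest=manifest,
    )


def run_pipeline_from_dir(
    dataset_dir: str | Path,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Disk-to-disk pipeline: loads a dataset directory, writes features,
    stance events, models, the agreement report, and the run manifest."""
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir)
    result = run_pipeline(load_corpus(dataset_dir), cfg)
    features_dir = out_dir / "features"
    targets_dir = out_dir / "targets"
    features_dir.mkdir(parents=True, exist_ok=True)
    targets_dir.mkdir(parents=True, exist_ok=True)
    stance_events = {}
    for p in result.processed:
        key = p.features.key
        p.features.to_csv(features_dir / f"{key}.csv")
        _write_targets_csv(p.targets, targets_dir / f"{key}.csv")
        stance_events[key] = p.window.to_dict()
    (out_dir / "stance_events.json").write_text(json.dumps(stance_events, indent=2))
    models_dir = out_dir / "models"
    for model in result.models.values():
        save_model(model, models_dir)
    result.report.write(out_dir / "report")
    (out_dir / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )
    return result


def _write_targets_csv(kt: KineticTargets, path: Path) -> None:
    import pandas as pd

    from .preprocess import MOMENT_NAMES

    df = pd.DataFrame({"stance_pct": np.arange(101), "vgrf_bw": kt.vgrf_bw})
    for j, name in enumerate(MOMENT_NAMES):
        df[name] = kt.moments[:, j]
    df.to_csv(path, index=False)
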