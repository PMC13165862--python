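"""Structured run configuration with defaults, YAML loading, and manifests.

Every pipeline run emits a manifest (config hash, seeds, package version)
sufficient to reproduce its report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .modeling import DEFAULT_HYPERPARAMETERS
from .orientation import DEFAULT_G


@dataclass
class RunConfig:
    """All tunables of a pipeline run, defaulting to the validated constants.

    Filter cutoffs: IMU 20 Hz, force 30 Hz (4th-order zero-phase
    Butterworth); stance threshold 20 N; EKF at 200 Hz with the gravity
    reference; 80/20 trial-grouped split; optional randomized hyperparameter
    search (n_iter = 0 uses the per-target default hyperparameters).
    """

    imu_cutoff_hz: float = 20.0
    force_cutoff_hz: float = 30.0
    filter_order: int = 4
    stance_threshold_n: float = 20.0
    # EKF
    ekf_dt: float = 0.005
    ekf_g: float = DEFAULT_G
    ekf_sigma_q: float = 1e-4
    ekf_sigma_a: float = 0.5
    static_calibration_duration: float = 0.4
    # split / search / training
    test_fraction: float = 0.2
    seed: int = 0
    search_n_iter: int = 0
    cv_folds: int = 5
    grouped_cv: bool = True
    hyperparameters: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HYPERPARAMETERS.items()}
    )
    # report
    smooth_plot: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def manifest(self, **extra) -> dict:
        return {
            "package_version": __version__,
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            **extra,
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
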