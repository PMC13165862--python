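"""Construction of the 12-feature predictor block on the stance-phase axis.

Nine primary channels (triaxial acceleration, triaxial angular velocity,
three Euler angles) are resampled to the 101-point normalized stance axis;
three derived channels (acceleration magnitude, angular-velocity magnitude,
tilt angle = sqrt(roll² + pitch²)) are then computed pointwise from the
resampled primaries.  There is no explicit stance-percent feature: phase
information enters only implicitly through time normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orientation import EulerSeries
from .preprocess import N_PHASE_POINTS, ImuTrial, StanceWindow, resample_to_stance

#: fixed feature column order; serialized matrices must round-trip this order
FEATURE_NAMES: tuple[str, ...] = (
    "acc_ml",
    "acc_ap",
    "acc_v",
    "gyro_ml",
    "gyro_ap",
    "gyro_v",
    "roll",
    "pitch",
    "yaw",
    "acc_magnitude",
    "gyro_magnitude",
    "tilt_angle",
)

PRIMARY_FEATURES = FEATURE_NAMES[:9]
DERIVED_FEATURES = FEATURE_NAMES[9:]


def vector_magnitude(x: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a 3-channel series (n, 3) -> (n,)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an (n, 3) series")
    return np.linalg.norm(x, axis=1)


def tilt_angle(roll: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Trunk inclination: root sum of squares of roll and pitch (degrees)."""
    roll = np.asarray(roll, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    if roll.shape != pitch.shape:
        raise ValueError("roll and pitch must be aligned")
    return np.sqrt(roll**2 + pitch**2)


@dataclass
class FeatureMatrix:
    """101 x 12 per-trial predictor block in the fixed column order."""

    values: np.ndarray
    participant_id: str
    trial_id: str
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PHASE_POINTS, len(FEATURE_NAMES)):
            raise ValueError(
                f"feature matrix must be ({N_PHASE_POINTS}, {len(FEATURE_NAMES)}), "
                f"got {self.values.shape}"
            )
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise ValueError("feature_names must match the canonical order")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def key(self) -> str:
        return f"{self.participant_id}_{self.trial_id}"

    def column(self, name: str) -> np.ndarray:
        return self.values[:, FEATURE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "stance_pct", np.arange(N_PHASE_POINTS))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, participant_id: str = "", trial_id: str = ""
    ) -> "FeatureMatrix":
        df = pd.read_csv(path)
        missing = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"feature file {path} missing columns: {missing}")
        return cls(
            values=df[list(FEATURE_NAMES)].to_numpy(),
            participant_id=participant_id,
            trial_id=trial_id,
        )


def build_feature_matrix(
    trial: ImuTrial, euler: EulerSeries, window: StanceWindow
) -> FeatureMatrix:
    """Assemble the 12-column feature block for one trial.

    ``trial`` must already be filtered and bias-corrected and ``euler`` must
    come from the EKF run on the same samples.  The nine primary channels are
    resampled onto the 101-point stance axis first; derived channels are then
    computed pointwise from the resampled primaries, so they remain exact
    functions of the stored primary columns.
    """
    if len(euler) != trial.n_samples:
        raise ValueError("Euler series must align sample-for-sample with the trial")
    primaries = np.column_stack(
        [trial.acc, trial.gyro, euler.roll, euler.pitch, euler.yaw]
    )
    resampled = resample_to_stance(primaries, window, fs=trial.fs_imu)
    acc_r, gyro_r = resampled[:, 0:3], resampled[:, 3:6]
    roll_r, pitch_r = resampled[:, 6], resampled[:, 7]
    values = np.column_stack(
        [
            resampled,
            vector_magnitude(acc_r),
            vector_magnitude(gyro_r),
            tilt_angle(roll_r, pitch_r),
        ]
    )
    return FeatureMatrix(
        values=values,
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
    )
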