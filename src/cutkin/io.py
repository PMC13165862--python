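"""Reading and writing the package's delimited-text trial layout.

A dataset directory contains ``participants.csv`` (participant_id,
body_mass_kg, body_weight_n) and a ``trials/`` folder with, per trial,
``<key>_imu.csv`` (time_s + 6 or 9 IMU columns), ``<key>_force.csv``
(time_s, vgrf_n) and ``<key>_moments.csv`` (time_s + 6 moment columns, Nm).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ForceTrial, ImuTrial

IMU_COLUMNS = ["acc_ml", "acc_ap", "acc_v", "gyro_ml", "gyro_ap", "gyro_v"]
MAG_COLUMNS = ["mag_ml", "mag_ap", "mag_v"]
MOMENT_COLUMNS = [
    "m_ankle_sag",
    "m_ankle_fro",
    "m_ankle_tra",
    "m_knee_sag",
    "m_knee_fro",
    "m_knee_tra",
]


def load_participants(dataset_dir: str | Path) -> dict[str, dict]:
    path = Path(dataset_dir) / "participants.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing participant metadata file: {path}")
    df = pd.read_csv(path)
    required = {"participant_id", "body_mass_kg", "body_weight_n"}
    if not required <= set(df.columns):
        raise ValueError(f"{path} must provide columns {sorted(required)}")
    return {
        str(r.participant_id): {
            "body_mass": float(r.body_mass_kg),
            "body_weight": float(r.body_weight_n),
        }
        for r in df.itertuples()
    }


def _infer_fs(time_s: np.ndarray, path: Path) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time axis is not uniformly sampled")
    return float(1.0 / dt[0])


def list_trial_keys(dataset_dir: str | Path) -> list[str]:
    trials_dir = Path(dataset_dir) / "trials"
    return sorted(p.name[: -len("_imu.csv")] for p in trials_dir.glob("*_imu.csv"))


def load_trial(
    dataset_dir: str | Path, key: str, participants: dict[str, dict] | None = None
) -> tuple[ImuTrial, ForceTrial, np.ndarray]:
    """Load one trial's IMU, force, and reference-moment files.

    Returns ``(ImuTrial, ForceTrial, moments)`` with moments (n_imu, 6) in Nm.
    """
    dataset_dir = Path(dataset_dir)
    participants = participants or load_participants(dataset_dir)
    participant_id, trial_id = key.rsplit("_", 1)
    if participant_id not in participants:
        raise KeyError(f"participant {participant_id!r} absent from participants.csv")
    meta = participants[participant_id]
    trials_dir = dataset_dir / "trials"

    imu_path = trials_dir / f"{key}_imu.csv"
    imu_df = pd.read_csv(imu_path)
    missing = [c for c in ["time_s", *IMU_COLUMNS] if c not in imu_df.columns]
    if missing:
        raise ValueError(f"{imu_path} missing columns: {missing}")
    mag = (
        imu_df[MAG_COLUMNS].to_numpy()
        if all(c in imu_df.columns for c in MAG_COLUMNS)
        else None
    )
    imu = ImuTrial(
        participant_id=participant_id,
        trial_id=trial_id,
        fs_imu=_infer_fs(imu_df["time_s"].to_numpy(), imu_path),
        acc=imu_df[IMU_COLUMNS[:3]].to_numpy(),
        gyro=imu_df[IMU_COLUMNS[3:]].to_numpy(),
        mag=mag,
        body_mass=meta["body_mass"],
        body_weight=meta["body_weight"],
    )

    force_path = trials_dir / f"{key}_force.csv"
    force_df = pd.read_csv(force_path)
    if not {"time_s", "vgrf_n"} <= set(force_df.columns):
        raise ValueError(f"{force_path} must provide time_s and vgrf_n")
    force = ForceTrial(
        participant_id=participant_id,
        trial_id=trial_id,
        fs_force=_infer_fs(force_df["time_s"].to_numpy(), force_path),
        vgrf=force_df["vgrf_n"].to_numpy(),
    )

    mom_path = trials_dir / f"{key}_moments.csv"
    mom_df = pd.read_csv(mom_path)
    missing = [c for c in MOMENT_COLUMNS if c not in mom_df.columns]
    if missing:
        raise ValueError(f"{mom_path} missing columns: {missing}")
    moments = mom_df[MOMENT_COLUMNS].to_numpy()
    if moments.shape[0] != imu.n_samples:
        raise ValueError(
            f"{mom_path}: moment series length {moments.shape[0]} does not "
            f"match IMU length {imu.n_samples}"
        )
    return imu, force, moments


def load_corpus(
    dataset_dir: str | Path,
) -> list[tuple[ImuTrial, ForceTrial, np.ndarray]]:
    dataset_dir = Path(dataset_dir)
    keys = list_trial_keys(dataset_dir)
    if not keys:
        raise FileNotFoundError(f"no trials found under {dataset_dir}/trials")
    participants = load_participants(dataset_dir)
    return [load_trial(dataset_dir, key, participants) for key in keys]
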