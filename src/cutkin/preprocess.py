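"""Signal conditioning, stance-phase segmentation, and normalization.

The analysis window for every trial is the stance phase of the cut — initial
contact (IC) to toe-off (TO) — detected on the vertical ground reaction force
(vGRF) with a 20 N threshold.  All waveforms are low-pass filtered
(zero-phase Butterworth), amplitude-normalized (vGRF to body weight, joint
moments to body mass) and time-normalized onto a common 101-point axis
covering 0-100 % of stance in 1 % steps.

Axis convention throughout the package: X = mediolateral (ML),
Y = anteroposterior (AP), Z = vertical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger(__name__)

#: canonical joint-moment channel order (joint x plane)
MOMENT_NAMES: tuple[str, ...] = (
    "ankle_sagittal",
    "ankle_frontal",
    "ankle_transverse",
    "knee_sagittal",
    "knee_frontal",
    "knee_transverse",
)

#: the seven regression targets, in report order
TARGET_NAMES: tuple[str, ...] = ("vgrf",) + MOMENT_NAMES

#: targets whose plane of motion is sagittal (vGRF loads dominantly vertically
#: /sagittally and is grouped with them in performance summaries)
SAGITTAL_TARGETS: tuple[str, ...] = ("vgrf", "ankle_sagittal", "knee_sagittal")
NON_SAGITTAL_TARGETS: tuple[str, ...] = (
    "ankle_frontal",
    "ankle_transverse",
    "knee_frontal",
    "knee_transverse",
)

N_PHASE_POINTS = 101  # 0..100 % stance inclusive, 1 % grid
DEFAULT_STANCE_THRESHOLD_N = 20.0


class NoStanceError(ValueError):
    """No contiguous run of samples reaches the force threshold."""


class DegenerateWindowError(ValueError):
    """Stance window too short to resample."""


@dataclass
class ImuTrial:
    """One trial's trunk-IMU recording plus participant metadata.

    ``acc`` is (n, 3) in m/s², ``gyro`` (n, 3) in °/s, optional ``mag``
    (n, 3) in μT; columns ordered (ML, AP, vertical).
    """

    participant_id: str
    trial_id: str
    fs_imu: float
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None
    body_mass: float
    body_weight: float
    axis_order: tuple[str, str, str] = ("ml", "ap", "vertical")

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if self.acc.shape != self.gyro.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(
                f"acc {self.acc.shape} and gyro {self.gyro.shape} must both be (n, 3)"
            )
        if self.mag is not None and self.mag.shape != self.acc.shape:
            raise ValueError("magnetometer length must match the other IMU channels")
        if self.fs_imu <= 0:
            raise ValueError("fs_imu must be positive")
        if self.body_mass <= 0 or self.body_weight <= 0:
            raise ValueError("body_mass and body_weight must be positive")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_imu

    @property
    def key(self) -> str:
        return f"{self.participant_id}_{self.trial_id}"


@dataclass
class ForceTrial:
    """Force-plate vGRF record for one trial (N, sampled at ``fs_force``)."""

    participant_id: str
    trial_id: str
    fs_force: float
    vgrf: np.ndarray

    def __post_init__(self) -> None:
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        if self.fs_force <= 0:
            raise ValueError("fs_force must be positive")
        if self.vgrf.ndim != 1 or self.vgrf.size == 0:
            raise ValueError("vgrf must be a non-empty 1-D series")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.vgrf.size) / self.fs_force


@dataclass
class StanceWindow:
    """Half-open stance interval [ic_index, to_index) on the force time base."""

    ic_index: int
    to_index: int
    threshold: float
    fs: float

    def __post_init__(self) -> None:
        if not 0 <= self.ic_index < self.to_index:
            raise ValueError("require 0 <= ic_index < to_index")

    @property
    def n_samples(self) -> int:
        return self.to_index - self.ic_index

    @property
    def ic_time(self) -> float:
        return self.ic_index / self.fs

    @property
    def to_time(self) -> float:
        """Time of the last in-stance sample (window is inclusive in time)."""
        return (self.to_index - 1) / self.fs

    @property
    def duration(self) -> float:
        return self.to_time - self.ic_time

    def to_dict(self) -> dict:
        return {
            "ic_index": int(self.ic_index),
            "to_index": int(self.to_index),
            "ic_time_s": self.ic_time,
            "to_time_s": self.to_time,
            "threshold_n": self.threshold,
            "fs_hz": self.fs,
        }


@dataclass
class KineticTargets:
    """The seven normalized reference waveforms on the 101-point stance axis.

    vGRF in multiples of body weight (BW); moments in Nm/kg, ordered per
    :data:`MOMENT_NAMES`.
    """

    vgrf_bw: np.ndarray
    moments: np.ndarray  # (101, 6)
    participant_id: str = ""
    trial_id: str = ""
    units: dict = field(default_factory=lambda: {"vgrf": "BW", "moments": "Nm/kg"})

    def __post_init__(self) -> None:
        self.vgrf_bw = np.asarray(self.vgrf_bw, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        if self.vgrf_bw.shape != (N_PHASE_POINTS,):
            raise ValueError(f"vgrf_bw must have exactly {N_PHASE_POINTS} samples")
        if self.moments.shape != (N_PHASE_POINTS, len(MOMENT_NAMES)):
            raise ValueError(
                f"moments must be ({N_PHASE_POINTS}, {len(MOMENT_NAMES)})"
            )

    def waveform(self, target: str) -> np.ndarray:
        if target == "vgrf":
            return self.vgrf_bw
        if target in MOMENT_NAMES:
            return self.moments[:, MOMENT_NAMES.index(target)]
        raise KeyError(f"unknown target {target!r}; valid: {TARGET_NAMES}")

    @property
    def key(self) -> str:
        return f"{self.participant_id}_{self.trial_id}"


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``sosfiltfilt``) so filtering does not shift
    events in time; ``order`` is the single-pass design order, hence the
    effective attenuation order doubles.

    Parameters
    ----------
    x : array, shape (n,) or (n, k)
        Signal(s); filtering runs along axis 0.
    fs : float
        Sampling rate in Hz.
    cutoff : float
        -3 dB cutoff in Hz; must be below the Nyquist frequency.
    order : int
        Per-pass Butterworth order (default 4).
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )
    sos = _sig.butter(order, cutoff, btype="low", fs=fs, output="sos")
    # sosfiltfilt pads 3*(n_sections*2+1) samples on each side by default
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise ValueError(
            f"signal length {x.shape[0]} too short for stable dual-pass "
            f"filtering (needs > {padlen} samples)"
        )
    return _sig.sosfiltfilt(sos, x, axis=0)


def detect_stance(
    vgrf: np.ndarray,
    threshold: float = DEFAULT_STANCE_THRESHOLD_N,
    fs: float = 1000.0,
) -> StanceWindow:
    """Locate the stance phase as the longest run of vGRF >= threshold.

    IC is the first sample of that run and TO one past its last sample.  A
    single clean contact produces a single run; bounce artifacts produce
    several, in which case the longest (earliest on ties) is taken and the
    ambiguity is logged.
    """
    vgrf = np.asarray(vgrf, dtype=float)
    above = vgrf >= threshold
    if not above.any():
        raise NoStanceError(f"no sample reaches the {threshold} N threshold")
    # run boundaries of the boolean mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    lengths = ends - starts
    if lengths.size > 1:
        logger.info(
            "multiple threshold crossings (%d runs); selecting longest",
            lengths.size,
        )
    best = int(np.argmax(lengths))  # argmax takes the earliest on ties
    return StanceWindow(
        ic_index=int(starts[best]),
        to_index=int(ends[best]),
        threshold=threshold,
        fs=fs,
    )


def resample_to_stance(
    x: np.ndarray,
    window: StanceWindow,
    fs: float | None = None,
    time_s: np.ndarray | None = None,
    n_points: int = N_PHASE_POINTS,
) -> np.ndarray:
    """Linearly interpolate a signal onto the normalized stance-phase axis.

    The stance interval is defined in seconds on the force time base, so a
    signal at a different rate (e.g. 200 Hz IMU vs 1000 Hz force) is mapped
    by time, not by raw sample index.  Pass either ``fs`` (signal assumed to
    start at t = 0) or an explicit ``time_s`` vector.
    """
    x = np.asarray(x, dtype=float)
    if window.n_samples < 2:
        raise DegenerateWindowError("stance window shorter than 2 samples")
    if time_s is None:
        if fs is None:
            raise ValueError("provide fs or time_s")
        time_s = np.arange(x.shape[0]) / fs
    else:
        time_s = np.asarray(time_s, dtype=float)
    if window.ic_time < time_s[0] - 1e-9 or window.to_time > time_s[-1] + 1e-9:
        raise ValueError("stance window lies outside the signal's time base")
    phase_t = np.linspace(window.ic_time, window.to_time, n_points)
    if x.ndim == 1:
        return np.interp(phase_t, time_s, x)
    return np.column_stack(
        [np.interp(phase_t, time_s, x[:, j]) for j in range(x.shape[1])]
    )


def normalize_kinetics(
    vgrf: np.ndarray,
    moments: np.ndarray,
    body_weight: float,
    body_mass: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize vGRF to body weight (-> BW) and moments to body mass (-> Nm/kg).

    Operates on raw-amplitude series of any length (normalization precedes
    time-normalization in the pipeline).
    """
    if body_weight <= 0 or body_mass <= 0:
        raise ValueError("body_weight and body_mass must be positive")
    vgrf = np.asarray(vgrf, dtype=float)
    moments = np.asarray(moments, dtype=float)
    return vgrf / body_weight, moments / body_mass
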