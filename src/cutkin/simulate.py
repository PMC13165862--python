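"""Synthetic cutting-trial generator with ground-truth orientation and
mechanically coupled kinetics.

The generator emulates the study conditions the pipeline assumes — 13
participants x 5 valid 45-degree cutting trials, 200 Hz trunk IMU, 1000 Hz
force plate, stance durations of 200-250 ms — with three layers:

1. **Orientation ground truth.** Trunk attitude follows a band-limited
   roll/pitch sway (up to ±20°) with slow yaw drift (±30°), ramped in after
   a quasi-static lead-in used for gyro-bias calibration.  Angular velocity
   is the exact kinematic inverse of the emitted quaternion path, so the
   gyro channels are drift- and noise-free by construction before the
   configured bias and white noise are added.

2. **Kinetic targets.** vGRF is a 20 N-floored double-bump (impact peak
   near 15-25 % stance, active peak near 50-70 %, 2.2-2.8 BW); sagittal
   moments are single dominant bumps; frontal/transverse moments are
   lower-amplitude biphasic templates with deliberately larger
   trial-to-trial shape jitter, emulating the harder non-sagittal structure.

3. **Mechanical coupling.** The world-frame specific force of the trunk is
   an affine function of the kinetic targets (vertical from vGRF, AP from
   sagittal moments, ML from the ankle frontal moment) and the body angular
   velocity receives weak additive contributions from the frontal/transverse
   moments; ``coupling_strength`` in [0, 1] scales every kinetically
   informative term, so 0 yields IMU signals statistically independent of
   the targets and 1 a deterministic accelerometer-borne mapping.  Sway and
   approach oscillations use per-trial random phases, so they carry no
   systematic stance-phase information.

Waveform templates are smooth analytic bumps with jitter, not
musculoskeletal simulations: the artifact exists to test pipeline
correctness and signal recovery, not human physiology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .orientation import DEFAULT_G, euler_to_quat, quat_from_axis_angle, quat_multiply, quat_to_rotmat
from .preprocess import (
    DEFAULT_STANCE_THRESHOLD_N,
    MOMENT_NAMES,
    ForceTrial,
    ImuTrial,
)

_DEG = np.pi / 180.0

PROFILES = ("static", "tilt_hold", "cutting_sway")


@dataclass
class SyntheticConfig:
    """Study conditions and noise structure of the synthetic corpus."""

    n_participants: int = 13
    trials_per_participant: int = 5
    stance_duration_range: tuple[float, float] = (0.20, 0.25)
    fs_imu: float = 200.0
    fs_force: float = 1000.0
    approach_speed_mean: float = 4.5  # m/s, scales braking/impact amplitudes
    approach_speed_sd: float = 0.5
    body_mass_mean: float = 75.2  # kg
    body_mass_sd: float = 7.1
    coupling_strength: float = 0.85  # 0 = IMU independent of targets
    trial_sway_amp_deg: float = 5.0  # trunk roll/pitch oscillation in trials
    trial_yaw_amp_deg: float = 5.0  # heading drift in trials
    accel_noise_sd: float = 1.0  # m/s^2, sensor noise + soft-tissue artifact
    gyro_noise_sd: float = 5.0  # deg/s, sensor noise + soft-tissue artifact
    gyro_bias_sd: float = 0.5  # deg/s, constant per trial, removed by calibration
    target_noise_frac: float = 0.03  # smooth reference-measurement noise
    sagittal_jitter: float = 0.08  # fractional template shape jitter
    non_sagittal_jitter: float = 0.35
    g: float = DEFAULT_G
    # trial timeline (s)
    static_lead: float = 0.5
    approach_duration: float = 0.5
    exit_duration: float = 0.35
    flight_duration: float = 0.05  # ballistic phase hugging each stance edge
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        for name in ("fs_imu", "fs_force", "static_lead", "approach_duration",
                     "exit_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.stance_duration_range
        if not 0 < lo <= hi:
            raise ValueError("invalid stance_duration_range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stance_duration_range"] = list(self.stance_duration_range)
        return d


@dataclass
class ParticipantMeta:
    participant_id: str
    body_mass: float  # kg
    body_weight: float  # N


@dataclass
class OrientationBundle:
    """Ground-truth orientation path with its exact kinematic inverse."""

    time_s: np.ndarray
    quat: np.ndarray  # (n, 4) scalar-first, sensor->world
    omega_deg: np.ndarray  # (n, 3) body angular velocity, deg/s
    accel_clean: np.ndarray  # (n, 3) gravity-only specific force, m/s^2
    fs: float
    profile: str


@dataclass
class TrialBundle:
    """One fully generated trial: noisy observables plus ground truth."""

    imu: ImuTrial
    force: ForceTrial
    moments_nm: np.ndarray  # (n_imu, 6) natural units, IMU time base
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# smooth building blocks
# ---------------------------------------------------------------------------


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _envelope(t: np.ndarray, t0: float, ramp: float) -> tuple[np.ndarray, np.ndarray]:
    """C1 ramp 0->1 starting at t0, with its time derivative."""
    u = (t - t0) / ramp
    env = _smoothstep(u)
    inside = (u > 0) & (u < 1)
    denv = np.where(inside, (6 * u - 6 * u * u) / ramp, 0.0)
    return env, denv


class _MultiSine:
    """Band-limited random oscillation with analytic derivative."""

    def __init__(self, rng, n_comp, f_range, amplitude):
        self.f = rng.uniform(*f_range, n_comp)
        self.phi = rng.uniform(0, 2 * np.pi, n_comp)
        a = rng.uniform(0.5, 1.0, n_comp)
        self.a = a * amplitude / np.sum(np.abs(a))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.sum(
            self.a[:, None] * np.sin(2 * np.pi * self.f[:, None] * t + self.phi[:, None]),
            axis=0,
        )

    def deriv(self, t: np.ndarray) -> np.ndarray:
        w = 2 * np.pi * self.f
        return np.sum(
            (self.a * w)[:, None] * np.cos(w[:, None] * t + self.phi[:, None]),
            axis=0,
        )


def _gauss_bump(p: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((p - mu) / sigma) ** 2)


def _edge_taper(p: np.ndarray, width: float = 0.08) -> np.ndarray:
    """Smooth 0->1->0 taper over the first/last `width` of the phase axis."""
    return _smoothstep(p / width) * _smoothstep((1.0 - p) / width)


def _euler_rates_to_body(roll, pitch, droll, dpitch, dyaw):
    """Body angular velocity (deg/s) from intrinsic Z-Y-X Euler rates (deg/s)."""
    r = roll * _DEG
    p = pitch * _DEG
    wx = droll - dyaw * np.sin(p)
    wy = dpitch * np.cos(r) + dyaw * np.cos(p) * np.sin(r)
    wz = -dpitch * np.sin(r) + dyaw * np.cos(p) * np.cos(r)
    return np.column_stack([wx, wy, wz])


def _integrate_body_rates(omega_deg: np.ndarray, dt: float) -> np.ndarray:
    """Exact per-step axis-angle integration of body angular velocity."""
    n = omega_deg.shape[0]
    quats = np.empty((n, 4))
    q = np.array([1.0, 0.0, 0.0, 0.0])
    for k in range(n):
        w = omega_deg[k] * _DEG
        angle = np.linalg.norm(w) * dt
        q = quat_multiply(q, quat_from_axis_angle(w, angle))
        q = q / np.linalg.norm(q)
        quats[k] = q
    return quats


def _gravity_in_sensor_series(quats: np.ndarray, g: float) -> np.ndarray:
    out = np.empty((quats.shape[0], 3))
    gv = np.array([0.0, 0.0, g])
    for k in range(quats.shape[0]):
        out[k] = quat_to_rotmat(quats[k]).T @ gv
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_orientation_trajectory(
    cfg: SyntheticConfig,
    profile: str,
    duration: float = 2.0,
    rng: np.random.Generator | None = None,
    tilt_deg: float = 10.0,
    sway_amp_deg: float = 20.0,
    yaw_amp_deg: float = 30.0,
    ramp: float = 0.5,
    env_start: float = 0.0,
) -> OrientationBundle:
    """Ground-truth orientation path for one of the three test profiles.

    ``static`` holds the identity; ``tilt_hold`` a fixed tilt about the ML
    axis; ``cutting_sway`` a band-limited random roll/pitch oscillation
    (amplitude up to ``sway_amp_deg``) with slow yaw drift, ramped in from
    identity over ``ramp`` seconds.  The returned gyro series is the exact
    kinematic inverse of the quaternion path and the clean accelerometer is
    gravity rotated into the sensor frame (linear acceleration is composed
    separately by :func:`generate_imu_from_kinetics`).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; valid: {PROFILES}")
    rng = rng or np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.fs_imu
    n = int(round(duration * cfg.fs_imu))
    t = np.arange(n) * dt
    if profile == "static":
        roll = pitch = yaw = np.zeros(n)
        droll = dpitch = dyaw = np.zeros(n)
    elif profile == "tilt_hold":
        roll = np.full(n, tilt_deg)
        pitch = yaw = np.zeros(n)
        droll = dpitch = dyaw = np.zeros(n)
    else:  # cutting_sway
        env, denv = _envelope(t, env_start, ramp)
        s_roll = _MultiSine(rng, 4, (0.5, 3.0), 0.75 * sway_amp_deg)
        s_pitch = _MultiSine(rng, 4, (0.5, 3.0), 0.75 * sway_amp_deg)
        s_yaw = _MultiSine(rng, 3, (0.2, 0.8), 0.75 * yaw_amp_deg)
        roll = env * s_roll(t)
        pitch = env * s_pitch(t)
        yaw = env * s_yaw(t)
        droll = denv * s_roll(t) + env * s_roll.deriv(t)
        dpitch = denv * s_pitch(t) + env * s_pitch.deriv(t)
        dyaw = denv * s_yaw(t) + env * s_yaw.deriv(t)
    omega = _euler_rates_to_body(roll, pitch, droll, dpitch, dyaw)
    quats = np.stack([euler_to_quat(r, p, y) for r, p, y in zip(roll, pitch, yaw)])
    accel = _gravity_in_sensor_series(quats, cfg.g)
    return OrientationBundle(
        time_s=t, quat=quats, omega_deg=omega, accel_clean=accel,
        fs=cfg.fs_imu, profile=profile,
    )


def generate_kinetic_waveforms(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    body_weight: float,
    speed_factor: float = 1.0,
    n_phase: int = 201,
) -> dict[str, np.ndarray]:
    """Per-trial kinetic templates on a dense phase grid (natural per-kg /
    BW units; amplitudes scale mildly with approach speed).

    Returns a dict with ``phase`` (0..1), ``vgrf_n`` (N, includes the 20 N
    stance floor), and the six moment channels in Nm/kg.  Non-sagittal
    channels receive larger multiplicative+additive shape jitter than
    sagittal ones.
    """
    p = np.linspace(0.0, 1.0, n_phase)
    taper = _edge_taper(p)

    def jitter_field(frac: float) -> np.ndarray:
        # smooth multiplicative perturbation of the template shape
        ms = _MultiSine(rng, 3, (0.8, 2.5), frac)
        return 1.0 + ms(p)

    # --- vGRF: impact + active peak, 2.2-2.8 BW ---------------------------
    a_imp = rng.uniform(0.8, 1.2)
    a_act = rng.uniform(0.9, 1.1)
    raw = a_imp * _gauss_bump(p, rng.uniform(0.15, 0.25), rng.uniform(0.05, 0.08)) \
        + a_act * _gauss_bump(p, rng.uniform(0.50, 0.70), rng.uniform(0.12, 0.18))
    raw *= jitter_field(cfg.sagittal_jitter)
    raw = np.maximum(raw, 0.0) * taper
    vgrf_shape = raw / max(raw.max(), 1e-9)  # unit-peak loading profile
    peak_bw = rng.uniform(2.2, 2.8) * speed_factor
    raw = vgrf_shape * (peak_bw * body_weight - DEFAULT_STANCE_THRESHOLD_N)
    vgrf_n = DEFAULT_STANCE_THRESHOLD_N + raw

    # --- sagittal moments: dominant bump tracking the loading profile ------
    # (sagittal joint moments follow overall vertical loading during stance,
    # so they share a large component with the vGRF shape)
    def sagittal(peak_lo, peak_hi, mu_lo, mu_hi, sign, load_mix=0.45):
        amp = rng.uniform(peak_lo, peak_hi) * speed_factor
        w = _gauss_bump(p, rng.uniform(mu_lo, mu_hi), rng.uniform(0.15, 0.22))
        w = (1.0 - load_mix) * w + load_mix * vgrf_shape
        w = w * jitter_field(cfg.sagittal_jitter)
        return sign * amp * w * taper

    ankle_sag = sagittal(2.0, 2.8, 0.45, 0.60, +1.0)
    knee_sag = sagittal(1.8, 2.6, 0.35, 0.50, +1.0)

    # --- frontal/transverse: low-amplitude biphasic, heavy jitter ----------
    def biphasic(amp_lo, amp_hi):
        amp = rng.uniform(amp_lo, amp_hi) * speed_factor
        b1 = _gauss_bump(p, rng.uniform(0.20, 0.35), rng.uniform(0.07, 0.11))
        b2 = _gauss_bump(p, rng.uniform(0.55, 0.75), rng.uniform(0.09, 0.14))
        w = amp * (b1 - rng.uniform(0.6, 1.0) * b2)
        w = w * jitter_field(cfg.non_sagittal_jitter) \
            + amp * cfg.non_sagittal_jitter * 0.5 * _MultiSine(rng, 3, (1.0, 3.0), 1.0)(p) * taper
        return w * taper

    ankle_fro = biphasic(0.45, 0.80)
    ankle_tra = biphasic(0.30, 0.55)
    knee_fro = biphasic(0.35, 0.65)
    knee_tra = biphasic(0.30, 0.55)

    out = {
        "phase": p,
        "vgrf_n": vgrf_n,
        "ankle_sagittal": ankle_sag,
        "ankle_frontal": ankle_fro,
        "ankle_transverse": ankle_tra,
        "knee_sagittal": knee_sag,
        "knee_frontal": knee_fro,
        "knee_transverse": knee_tra,
    }
    # smooth reference-measurement noise on every target
    for name in MOMENT_NAMES:
        amp = np.abs(out[name]).max()
        out[name] = out[name] + cfg.target_noise_frac * amp * _MultiSine(
            rng, 3, (1.5, 4.0), 1.0
        )(p) * taper
    vamp = vgrf_n.max() - DEFAULT_STANCE_THRESHOLD_N
    noise = cfg.target_noise_frac * vamp * _MultiSine(rng, 3, (1.5, 4.0), 1.0)(p) * taper
    # keep the detection threshold as a hard floor across the whole window
    out["vgrf_n"] = np.maximum(vgrf_n + noise, DEFAULT_STANCE_THRESHOLD_N)
    return out


#: gyro coupling constants, deg/s per Nm/kg (channel <- weighted moments)
_GYRO_COUPLING = {
    "ml": (("knee_frontal", 12.0), ("knee_transverse", 5.0)),
    "ap": (("knee_transverse", 10.0), ("knee_frontal", 5.0)),
    "v": (("ankle_transverse", 12.0), ("knee_transverse", 5.0)),
}
#: accel coupling, m/s^2 per Nm/kg (AP braking from sagittal moments, ML from
#: ankle frontal); vertical couples to vGRF in BW via g
_AP_COUPLING = (("ankle_sagittal", -2.2), ("knee_sagittal", -1.8))
_ML_COUPLING = (("ankle_frontal", 2.5),)


def generate_imu_from_kinetics(
    waveforms: dict[str, np.ndarray],
    sway: OrientationBundle,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    stance_start: float,
    stance_duration: float,
    body_weight: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Compose IMU channels mechanically coupled to the kinetic targets.

    Returns ``(acc_noisy, gyro_noisy_biased, quat_truth, acc_clean)`` on the
    sway bundle's time base.  Body angular velocity = sway rates + coupled
    moment terms; the quaternion path is re-integrated from the total rate so
    the emitted gyro remains its exact kinematic inverse.  The accelerometer
    is the world-frame specific force (vertical from vGRF during stance,
    AP/ML from moment coupling, ballistic dips at the stance edges) rotated
    into the sensor frame.  ``coupling_strength`` scales every kinetically
    informative term.
    """
    t = sway.time_s
    dt = 1.0 / sway.fs
    c = cfg.coupling_strength
    g = cfg.g
    phase_grid = waveforms["phase"]
    t_to = stance_start + stance_duration
    in_stance = (t >= stance_start) & (t <= t_to)
    p_t = np.clip((t - stance_start) / stance_duration, 0.0, 1.0)

    def on_imu(name: str) -> np.ndarray:
        w = np.interp(p_t, phase_grid, waveforms[name])
        return np.where(in_stance, w, 0.0)

    # ---- total body angular velocity --------------------------------------
    omega = sway.omega_deg.copy()
    for axis, terms in zip((0, 1, 2), (_GYRO_COUPLING["ml"], _GYRO_COUPLING["ap"], _GYRO_COUPLING["v"])):
        for name, k in terms:
            omega[:, axis] = omega[:, axis] + c * k * on_imu(name)
    quat_truth = _integrate_body_rates(omega, dt)

    # ---- world-frame specific force ---------------------------------------
    vgrf_bw_t = on_imu("vgrf_n") / body_weight
    support = np.ones_like(t)  # quiet stance / running support, x g
    osc_v = _MultiSine(rng, 2, (2.0, 4.0), 0.08)
    approach = (t > cfg.static_lead) & (t < stance_start)
    # running oscillations fade out before the last pre-contact flight so the
    # filter does not bleed them into the early stance rows
    fade = _smoothstep((stance_start - cfg.flight_duration - 0.05 - t) / 0.08)
    support[approach] += (osc_v(t) * fade)[approach]
    # kinetically informative vertical structure, scaled by the coupling
    stance_level = (1.0 - c) * support + c * vgrf_bw_t
    f_v = g * np.where(in_stance, stance_level, support)
    # ballistic dips hugging the stance edges
    for lo, hi in (
        (stance_start - cfg.flight_duration, stance_start),
        (t_to, t_to + cfg.flight_duration),
    ):
        mask = (t >= lo) & (t < hi)
        f_v[mask] *= 1.0 - c
    # smooth the piecewise transitions a little (30 ms box)
    k = max(1, int(round(0.03 * sway.fs)))
    kernel = np.ones(k) / k
    f_v = np.convolve(f_v, kernel, mode="same")

    f_ap = np.zeros_like(t)
    osc_ap = _MultiSine(rng, 2, (2.0, 4.0), 1.0)
    f_ap[approach] = (osc_ap(t) * fade)[approach]
    for name, k_ap in _AP_COUPLING:
        f_ap = f_ap + c * k_ap * on_imu(name)  # m/s^2 per Nm/kg
    f_ml = np.zeros_like(t)
    for name, k_ml in _ML_COUPLING:
        f_ml += c * k_ml * on_imu(name)

    f_world = np.column_stack([f_ml, f_ap, f_v])
    acc_clean = np.empty_like(f_world)
    for i in range(t.size):
        acc_clean[i] = quat_to_rotmat(quat_truth[i]).T @ f_world[i]

    acc_noisy = acc_clean + rng.normal(0.0, cfg.accel_noise_sd, acc_clean.shape)
    bias = rng.normal(0.0, cfg.gyro_bias_sd, 3)
    gyro_noisy = omega + bias + rng.normal(0.0, cfg.gyro_noise_sd, omega.shape)
    return acc_noisy, gyro_noisy, quat_truth, acc_clean, omega, bias


def generate_participants(cfg: SyntheticConfig, rng: np.random.Generator) -> list[ParticipantMeta]:
    out = []
    for i in range(cfg.n_participants):
        mass = float(np.clip(rng.normal(cfg.body_mass_mean, cfg.body_mass_sd), 50.0, 110.0))
        out.append(
            ParticipantMeta(
                participant_id=f"P{i + 1:02d}",
                body_mass=round(mass, 2),
                body_weight=round(mass * cfg.g, 2),
            )
        )
    return out


def generate_trial(
    cfg: SyntheticConfig,
    participant: ParticipantMeta,
    trial_id: str,
    rng: np.random.Generator,
) -> TrialBundle:
    """Generate one fully coupled cutting trial with ground truth."""
    stance_duration = float(rng.uniform(*cfg.stance_duration_range))
    stance_start = cfg.static_lead + cfg.approach_duration
    total = stance_start + stance_duration + cfg.exit_duration
    speed = rng.normal(cfg.approach_speed_mean, cfg.approach_speed_sd)
    speed_factor = float(np.clip(speed / cfg.approach_speed_mean, 0.8, 1.2))

    # --- force-plate vGRF (1000 Hz) ----------------------------------------
    n_force = int(round(total * cfg.fs_force))
    ic_index = int(round(stance_start * cfg.fs_force))
    n_stance_f = int(round(stance_duration * cfg.fs_force))
    to_index = ic_index + n_stance_f
    waveforms = generate_kinetic_waveforms(
        cfg, rng, participant.body_weight, speed_factor
    )
    vgrf = np.zeros(n_force)
    p_f = np.arange(n_stance_f) / (n_stance_f - 1)
    vgrf[ic_index:to_index] = np.interp(
        p_f, waveforms["phase"], waveforms["vgrf_n"]
    )
    force = ForceTrial(
        participant_id=participant.participant_id,
        trial_id=trial_id,
        fs_force=cfg.fs_force,
        vgrf=vgrf,
    )
    # actual duration between the first/last in-stance force samples
    stance_duration_actual = (n_stance_f - 1) / cfg.fs_force

    # --- orientation sway + coupled IMU (200 Hz) ----------------------------
    # sway ramps in only after the quasi-static calibration lead-in
    sway = generate_orientation_trajectory(
        cfg,
        "cutting_sway",
        duration=total,
        rng=rng,
        ramp=cfg.approach_duration * 0.6,
        env_start=cfg.static_lead,
        sway_amp_deg=cfg.trial_sway_amp_deg,
        yaw_amp_deg=cfg.trial_yaw_amp_deg,
    )
    acc, gyro, quat_truth, acc_clean, omega_total, gyro_bias = generate_imu_from_kinetics(
        waveforms,
        sway,
        cfg,
        rng,
        stance_start=stance_start,
        stance_duration=stance_duration_actual,
        body_weight=participant.body_weight,
    )

    # --- reference moments on the IMU time base (Nm) ------------------------
    t_imu = sway.time_s
    in_stance = (t_imu >= stance_start) & (t_imu <= stance_start + stance_duration_actual)
    p_imu = np.clip((t_imu - stance_start) / stance_duration_actual, 0.0, 1.0)
    moments = np.zeros((t_imu.size, len(MOMENT_NAMES)))
    for j, name in enumerate(MOMENT_NAMES):
        w = np.interp(p_imu, waveforms["phase"], waveforms[name])
        moments[:, j] = np.where(in_stance, w, 0.0) * participant.body_mass

    imu = ImuTrial(
        participant_id=participant.participant_id,
        trial_id=trial_id,
        fs_imu=cfg.fs_imu,
        acc=acc,
        gyro=gyro,
        mag=None,
        body_mass=participant.body_mass,
        body_weight=participant.body_weight,
    )
    truth = {
        "quat": quat_truth,
        "omega_deg": omega_total,
        "acc_clean": acc_clean,
        "gyro_bias": gyro_bias,
        "ic_index": ic_index,
        "to_index": to_index,
        "stance_start_s": stance_start,
        "stance_duration_s": stance_duration_actual,
        "waveforms": waveforms,
        "speed_factor": speed_factor,
    }
    return TrialBundle(imu=imu, force=force, moments_nm=moments, truth=truth)


def generate_trials(cfg: SyntheticConfig) -> tuple[list[ParticipantMeta], list[TrialBundle]]:
    """Generate the full in-memory corpus, reproducible from the config seed.

    Per-trial randomness comes from deterministically spawned substreams of
    one seeded generator.
    """
    root = np.random.SeedSequence(cfg.seed)
    meta_seq, trial_seq = root.spawn(2)
    participants = generate_participants(cfg, np.random.default_rng(meta_seq))
    streams = trial_seq.spawn(cfg.n_participants * cfg.trials_per_participant)
    bundles = []
    i = 0
    for part in participants:
        for j in range(cfg.trials_per_participant):
            rng = np.random.default_rng(streams[i])
            bundles.append(generate_trial(cfg, part, f"T{j + 1}", rng))
            i += 1
    return participants, bundles


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write the corpus in the package's standard delimited-text layout.

    Layout: ``participants.csv``, ``trials/<P>_<T>_{imu,force,moments}.csv``,
    ``ground_truth/<P>_<T>_{quat,clean_imu}.csv`` and a ``manifest.json``
    recording the config, seed, and designed stance windows.
    """
    out_dir = Path(out_dir)
    trials_dir = out_dir / "trials"
    truth_dir = out_dir / "ground_truth"
    trials_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    participants, bundles = generate_trials(cfg)
    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "body_mass_kg": p.body_mass,
                "body_weight_n": p.body_weight,
            }
            for p in participants
        ]
    ).to_csv(out_dir / "participants.csv", index=False)
    manifest_trials = []
    for b in bundles:
        key = b.imu.key
        t = b.imu.time_s
        imu_df = pd.DataFrame(
            {
                "time_s": t,
                "acc_ml": b.imu.acc[:, 0],
                "acc_ap": b.imu.acc[:, 1],
                "acc_v": b.imu.acc[:, 2],
                "gyro_ml": b.imu.gyro[:, 0],
                "gyro_ap": b.imu.gyro[:, 1],
                "gyro_v": b.imu.gyro[:, 2],
            }
        )
        imu_df.round(6).to_csv(trials_dir / f"{key}_imu.csv", index=False)
        pd.DataFrame(
            {"time_s": b.force.time_s, "vgrf_n": b.force.vgrf}
        ).round(6).to_csv(trials_dir / f"{key}_force.csv", index=False)
        mom_df = pd.DataFrame(
            {"time_s": t}
            | {
                f"m_{short}": b.moments_nm[:, j]
                for j, short in enumerate(
                    ("ankle_sag", "ankle_fro", "ankle_tra", "knee_sag", "knee_fro", "knee_tra")
                )
            }
        )
        mom_df.round(6).to_csv(trials_dir / f"{key}_moments.csv", index=False)
        pd.DataFrame(
            {"time_s": t}
            | {f"q{i}": b.truth["quat"][:, i] for i in range(4)}
        ).round(8).to_csv(truth_dir / f"{key}_quat.csv", index=False)
        pd.DataFrame(
            {
                "time_s": t,
                "acc_ml": b.truth["acc_clean"][:, 0],
                "acc_ap": b.truth["acc_clean"][:, 1],
                "acc_v": b.truth["acc_clean"][:, 2],
                "gyro_ml": b.truth["omega_deg"][:, 0],
                "gyro_ap": b.truth["omega_deg"][:, 1],
                "gyro_v": b.truth["omega_deg"][:, 2],
            }
        ).round(6).to_csv(truth_dir / f"{key}_clean_imu.csv", index=False)
        manifest_trials.append(
            {
                "key": key,
                "participant_id": b.imu.participant_id,
                "trial_id": b.imu.trial_id,
                "ic_index": int(b.truth["ic_index"]),
                "to_index": int(b.truth["to_index"]),
                "stance_duration_s": b.truth["stance_duration_s"],
                "gyro_bias_deg_s": [round(float(v), 6) for v in b.truth["gyro_bias"]],
            }
        )
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_trials": len(bundles),
        "trials": manifest_trials,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
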