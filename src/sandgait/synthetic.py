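"""Synthetic multi-participant walking trials with full ground truth.

The generator emulates the study design the package targets: 21 participants
walking at self-selected speed across a hard floor and three sand substrates
whose foot-sinkage depths differ (three floor trials and five trials per sand
walkway).  Every downstream stage gets a parameter-recovery target:

* heel/hallux event markers oscillate fore-aft relative to the sacrum as
  pure cosines, so the coordinate-based event rule recovers the scheduled
  heel-strikes and toe-offs exactly;
* during stance the heel (then hallux) dips below the substrate surface by a
  half-sine of the drawn sinkage depth;
* the centre of mass follows a designed path whose vertical oscillation
  (2 cycles/stride) and forward-speed fluctuation are phase-offset by
  ``ep_ek_phase`` -- 180 deg is the ideal inverted pendulum -- and is emitted
  both as a precomputed ``COM`` channel and implicitly through the
  13-segment marker set;
* lower-limb joint centres follow two-harmonic sagittal joint-angle
  templates via planar forward kinematics;
* EMG channels are burst envelopes modulating band-limited noise.

Default magnitudes (sinkage depth means/sds, sampling rates, walking-speed
ordering across substrates, pendular recovery near 60%) sit in the regime
reported for human walking on wetted building and play sands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core_io import (
    ConfigError,
    DataError,
    EMG_MUSCLES,
    MarkerSchema,
    TrialRecording,
)

G = 9.81  # m s^-2


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SubstrateSpec:
    """One walking surface: sinkage regime, surface height and speed regime."""

    substrate_id: str
    surface_z: float = 0.0  # m above lab floor
    heel_depth_mean: float = 0.0  # cm
    hallux_depth_mean: float = 0.0  # cm
    depth_sd: float = 0.0  # cm
    depth_speed_slope: float = 0.0  # cm per (m/s), within-substrate coupling
    speed_mean: float = 1.35  # m/s
    speed_sd: float = 0.10  # m/s
    n_trials: int = 5

    def validate(self) -> None:
        if min(self.heel_depth_mean, self.hallux_depth_mean, self.depth_sd) < 0:
            raise ConfigError(f"{self.substrate_id}: depths and depth_sd must be >= 0")
        if self.substrate_id == "hard_floor" and (
            self.heel_depth_mean or self.hallux_depth_mean or self.depth_sd
        ):
            raise ConfigError("hard_floor substrate must have zero depths")
        if self.speed_mean <= 0 or self.speed_sd < 0 or self.n_trials < 0:
            raise ConfigError(f"{self.substrate_id}: invalid speed/trial settings")


def default_substrates() -> list[SubstrateSpec]:
    """Hard floor plus the three sands, ordered by increasing sinkage.

    Depth means/sds are the reported heel (2.08/2.68/4.09 cm) and hallux
    (3.43/4.26/5.23 cm) regimes; slower mean speeds pair with deeper
    substrates across specs, while within a substrate faster trials sink
    deeper (positive depth_speed_slope).
    """
    return [
        SubstrateSpec("hard_floor", 0.0, 0.0, 0.0, 0.0, 0.0, 1.38, 0.10, 3),
        SubstrateSpec("wet_building_sand", 0.10, 2.08, 3.43, 0.85, 1.5, 1.32, 0.10, 5),
        SubstrateSpec("dry_building_sand", 0.10, 2.68, 4.26, 1.00, 1.5, 1.24, 0.10, 5),
        SubstrateSpec("play_sand", 0.10, 4.09, 5.23, 0.93, 1.5, 1.18, 0.10, 5),
    ]


#: two-harmonic sagittal joint-angle templates, degrees:
#: angle(s) = mean + a1*cos(2*pi*s + p1) + a2*cos(4*pi*s + p2), s = cycle fraction
DEFAULT_JOINT_TEMPLATES: dict[str, dict[str, float]] = {
    "hip": {"mean": 8.0, "a1": 22.0, "p1": 0.3, "a2": 3.0, "p2": 1.0},
    "knee": {"mean": 25.0, "a1": 15.0, "p1": -2.6, "a2": 18.0, "p2": -0.9},
    "ankle": {"mean": 0.0, "a1": 8.0, "p1": 2.0, "a2": 7.0, "p2": 0.5},
}

#: additive peak-flexion offsets per substrate (deg), mirroring greater
#: flexion / dorsiflexion on deeper substrates
DEFAULT_JOINT_OFFSETS: dict[str, dict[str, float]] = {
    "hard_floor": {"hip": 0.0, "knee": 0.0, "ankle": 0.0},
    "wet_building_sand": {"hip": 2.0, "knee": 2.0, "ankle": 2.0},
    "dry_building_sand": {"hip": 4.0, "knee": 4.0, "ankle": 3.0},
    "play_sand": {"hip": 5.0, "knee": 5.0, "ankle": 4.0},
}

#: burst windows (onset, offset as cycle fractions from ipsilateral
#: heel-strike) and amplitudes (V); textbook gait phasing, generator
#: conveniences only
DEFAULT_EMG_BURSTS: dict[str, list[tuple[float, float, float]]] = {
    "BFL": [(0.0, 0.12, 4.0e-4), (0.85, 1.0, 4.0e-4)],
    "RF": [(0.0, 0.15, 3.5e-4), (0.55, 0.72, 2.5e-4)],
    "VL": [(0.0, 0.20, 4.5e-4)],
    "VM": [(0.0, 0.20, 4.5e-4)],
    "TA": [(0.0, 0.12, 5.0e-4), (0.55, 1.0, 4.0e-4)],
    "LG": [(0.10, 0.50, 5.0e-4)],
    "MG": [(0.10, 0.50, 5.0e-4)],
    "SOL": [(0.12, 0.55, 5.5e-4)],
}


@dataclass
class GaitSimConfig:
    n_participants: int = 21
    strides_per_trial: int = 4
    substrates: list[SubstrateSpec] = field(default_factory=default_substrates)
    cycle_time_mean: float = 1.10  # s
    cycle_time_sd: float = 0.05
    duty_factor: float = 0.62
    com_height: float = 0.95  # m
    com_vertical_amplitude: float = 0.025  # m
    com_speed_amplitude: float = 0.16  # m/s
    com_lateral_amplitude: float = 0.015  # m
    ep_ek_phase: float = 132.0  # deg; 180 = ideal pendulum
    participant_speed_sd: float = 0.08  # m/s, random intercept
    stride_width: float = 0.12  # m
    marker_noise_sd: float = 0.0005  # m
    marker_rate: float = 200.0
    emg_rate: float = 1110.0
    joint_angle_templates: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_JOINT_TEMPLATES.items()}
    )
    joint_offsets: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_JOINT_OFFSETS.items()}
    )
    emg_bursts: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EMG_BURSTS.items()}
    )
    emg_drift_amplitude: float = 2.0e-5  # V, low-frequency baseline drift
    emg_drift_freq: float = 0.8  # Hz
    emg_baseline_sd: float = 5.0e-6  # V
    emg_envelope_only: bool = False  # emit the noise-free envelope itself
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ConfigError("duty_factor must lie strictly between 0 and 1")
        if self.strides_per_trial < 3:
            raise ConfigError("strides_per_trial must be >= 3")
        if not 0.0 <= self.ep_ek_phase < 360.0:
            raise ConfigError("ep_ek_phase must lie in [0, 360)")
        for sd in (
            self.cycle_time_sd,
            self.participant_speed_sd,
            self.marker_noise_sd,
            self.emg_baseline_sd,
        ):
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        if self.n_participants < 1 and any(s.n_trials for s in self.substrates):
            raise ConfigError("need at least one participant")
        for sub in self.substrates:
            sub.validate()

    def to_dict(self) -> dict:
        return asdict(self)


SYNTHETIC_ROLES = (
    "SACR",
    "COM",
    "LHEE",
    "RHEE",
    "LHALL",
    "RHALL",
    "LHIP",
    "RHIP",
    "LKNEE",
    "RKNEE",
    "LANK",
    "RANK",
    "LTOE",
    "RTOE",
    "LSHO",
    "RSHO",
    "LELB",
    "RELB",
    "LWRI",
    "RWRI",
    "C7",
    "HEAD",
)


def synthetic_schema() -> MarkerSchema:
    """Identity schema for the generator's marker set."""
    return MarkerSchema.identity(SYNTHETIC_ROLES)


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from one synthetic trial."""

    trial_id: str
    events: dict  # side -> {"heel_strikes": array, "toe_offs": array}
    strides: pd.DataFrame  # one row per (side, stride)
    emg: pd.DataFrame  # one row per (muscle, stride): envelope integrals
    speed: float  # trial walking speed, m/s
    cycle_time: float  # s

    def validate(self) -> None:
        for side, ev in self.events.items():
            for key in ("heel_strikes", "toe_offs"):
                t = np.asarray(ev[key])
                if not np.all(np.diff(t) > 0):
                    raise DataError(f"{side} {key} not strictly increasing")
        dt = (self.strides.stance_time + self.strides.swing_time - self.strides.cycle_time).abs()
        if (dt > 1e-9).any():
            raise DataError("stance + swing != cycle in ground truth")


# ---------------------------------------------------------------------------
# brute-force pendular-exchange oracle


def oracle_exchange(e_pot: np.ndarray, e_kin: np.ndarray) -> tuple[float, float, float]:
    """Reference R / RA / CO from dense incremental sums.

    Deliberately plain (sample-by-sample loop, no vectorisation) so it is an
    independent code path from the pipeline's exchange_metrics.
    Returns (R %, RA unitless, CO %).
    """
    e_pot = np.asarray(e_pot, float)
    e_kin = np.asarray(e_kin, float)
    if e_pot.shape != e_kin.shape or e_pot.size < 3:
        raise DataError("oracle_exchange needs equal-length series of >= 3 samples")
    if np.ptp(e_kin) == 0.0:
        raise DataError("RA undefined: E_kin is constant")
    w_v = w_f = w_ext = 0.0
    same = moving = 0
    eps = 1e-12
    for i in range(1, len(e_pot)):
        dp = e_pot[i] - e_pot[i - 1]
        dk = e_kin[i] - e_kin[i - 1]
        dtot = dp + dk
        if dp > 0:
            w_v += dp
        if dk > 0:
            w_f += dk
        if dtot > 0:
            w_ext += dtot
        if abs(dp) > eps and abs(dk) > eps:
            moving += 1
            if dp * dk > 0:
                same += 1
    if w_v + w_f == 0:
        raise DataError("R undefined: both energy series are constant")
    r = 100.0 * (w_v + w_f - w_ext) / (w_v + w_f)
    ra = float(np.ptp(e_pot) / np.ptp(e_kin))
    co = 100.0 * same / moving if moving else float("nan")
    return float(r), ra, float(co)


# ---------------------------------------------------------------------------
# building blocks


def joint_template(params: dict[str, float], s: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Evaluate a two-harmonic joint-angle template at cycle fractions ``s``."""
    s = np.asarray(s, float)
    return (
        params["mean"]
        + offset
        + params["a1"] * np.cos(2 * np.pi * s + params["p1"])
        + params["a2"] * np.cos(4 * np.pi * s + params["p2"])
    )


def participant_profile(cfg: GaitSimConfig, participant: int) -> dict:
    """Stable per-participant attributes (deterministic given cfg.seed)."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7919, participant)))
    return {
        "participant_id": f"P{participant:02d}",
        "sex": "female" if participant % 2 == 0 else "male",
        "height": float(np.clip(rng.normal(1.73, 0.10), 1.5, 2.0)),
        "body_mass": float(np.clip(rng.normal(68.5, 9.2), 45.0, 100.0)),
        "speed_intercept": float(rng.normal(0.0, cfg.participant_speed_sd)),
    }


def _com_path(cfg, v, cycle, hs0, t):
    """Designed CoM position and analytic velocity (each (n,3))."""
    phi = math.radians(cfg.ep_ek_phase)
    w2 = 4 * np.pi / cycle  # 2 cycles per stride
    theta = w2 * (t - hs0) - np.pi / 2
    z = cfg.com_height + cfg.com_vertical_amplitude * np.sin(theta)
    vz = cfg.com_vertical_amplitude * w2 * np.cos(theta)
    vx = v + cfg.com_speed_amplitude * np.sin(theta + phi)
    x = v * t - cfg.com_speed_amplitude / w2 * np.cos(theta + phi)
    w1 = 2 * np.pi / cycle
    y = cfg.com_lateral_amplitude * np.sin(w1 * (t - hs0))
    vy = cfg.com_lateral_amplitude * w1 * np.cos(w1 * (t - hs0))
    pos = np.column_stack([x, y, z])
    vel = np.column_stack([vx, vy, vz])
    return pos, vel


def _foot_z(t, hs0, cycle, duty, depths_cm, surface_z, contact_start, lift):
    """Vertical trajectory of a foot marker: stance dips + swing lift.

    ``depths_cm[k]`` is the sinkage depth of scheduled stride k; cycles
    outside the schedule stay on the surface.
    """
    rel = (t - hs0) / cycle
    k = np.floor(rel).astype(int)
    psi = rel - k
    z = np.full_like(t, surface_z, dtype=float)
    in_sched = (k >= 0) & (k < len(depths_cm))
    depth_m = np.where(in_sched, np.take(np.asarray(depths_cm), np.clip(k, 0, len(depths_cm) - 1)) / 100.0, 0.0)
    dip = (psi >= contact_start) & (psi <= duty)
    frac = np.where(dip, (psi - contact_start) / max(duty - contact_start, 1e-9), 0.0)
    z -= np.where(dip, depth_m * np.sin(np.pi * frac), 0.0)
    swing = psi > duty
    sfrac = np.where(swing, (psi - duty) / (1 - duty), 0.0)
    z += np.where(swing, lift * np.sin(np.pi * sfrac), 0.0)
    return z


def _emg_envelope(bursts, s):
    """Burst envelope at cycle fractions ``s`` (half-sine bursts)."""
    env = np.zeros_like(s, dtype=float)
    for on, off, amp in bursts:
        inside = (s >= on) & (s <= off)
        env += np.where(inside, amp * np.sin(np.pi * (s - on) / max(off - on, 1e-9)), 0.0)
    return env


def _bandlimited_noise(n, rate, rng):
    """Unit-variance EMG carrier: white noise band-passed 20-450 Hz."""
    x = rng.standard_normal(n)
    high = min(450.0, 0.45 * rate)
    sos = butter(4, [20.0, high], btype="bandpass", fs=rate, output="sos")
    y = sosfiltfilt(sos, x)
    return y / max(np.std(y), 1e-30)


# ---------------------------------------------------------------------------
# main entry points


def simulate_trial(
    cfg: GaitSimConfig,
    participant: int,
    substrate: SubstrateSpec,
    rng: np.random.Generator,
    trial_index: int = 0,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one walking pass with complete ground truth."""
    cfg.validate()
    substrate.validate()
    prof = participant_profile(cfg, participant)
    v = max(0.5, substrate.speed_mean + prof["speed_intercept"] + rng.normal(0.0, substrate.speed_sd))
    cycle = max(0.6, rng.normal(cfg.cycle_time_mean, cfg.cycle_time_sd))
    duty = cfg.duty_factor
    S = cfg.strides_per_trial
    lead = cycle  # keeps filter transients away from analysed strides
    hs0 = {"left": lead, "right": lead + cycle / 2}
    duration = lead + (S + 0.5) * cycle + lead
    n = int(round(duration * cfg.marker_rate)) + 1
    t = np.arange(n) / cfg.marker_rate

    # ---- event schedule and per-stride sinkage depths
    # depth schedules cover one extra cycle on each side of the scheduled
    # strides (indices -1 .. S), so the partial lead-in/lead-out cycles that
    # still form complete strides carry properly distributed depths
    events = {}
    depths = {}
    n_depth = S + 2
    for side in ("left", "right"):
        hs = hs0[side] + cycle * np.arange(S + 1)
        to = hs[:-1] + duty * cycle
        events[side] = {"heel_strikes": hs, "toe_offs": to}
        dv = v - substrate.speed_mean
        heel_d = np.zeros(n_depth)
        hall_d = np.zeros(n_depth)
        if substrate.heel_depth_mean > 0:
            heel_d = np.maximum(
                0.0,
                substrate.heel_depth_mean
                + substrate.depth_speed_slope * dv
                + rng.normal(0.0, substrate.depth_sd, n_depth),
            )
        if substrate.hallux_depth_mean > 0:
            hall_d = np.maximum(
                0.0,
                substrate.hallux_depth_mean
                + substrate.depth_speed_slope * dv
                + rng.normal(0.0, substrate.depth_sd, n_depth),
            )
        depths[side] = {"heel": heel_d, "hallux": hall_d}

    # ---- designed CoM / pelvis path
    com_pos, com_vel = _com_path(cfg, v, cycle, hs0["left"], t)
    markers: dict[str, np.ndarray] = {}
    markers["COM"] = com_pos.copy()
    markers["SACR"] = com_pos + np.array([0.0, 0.0, 0.03])

    # ---- heel/hallux event + sinkage markers
    b_heel = 0.45 * v * cycle
    b_hall = 0.40 * v * cycle
    lift = 0.05
    width = cfg.stride_width
    for side, ysign in (("left", 1.0), ("right", -1.0)):
        hs_first = hs0[side]
        to_first = hs_first + duty * cycle
        xh = com_pos[:, 0] + b_heel * np.cos(2 * np.pi * (t - hs_first) / cycle)
        xa = com_pos[:, 0] - b_hall * np.cos(2 * np.pi * (t - to_first) / cycle)
        zh = _foot_z(t, hs_first - cycle, cycle, duty, depths[side]["heel"], substrate.surface_z, 0.0, lift)
        za = _foot_z(t, hs_first - cycle, cycle, duty, depths[side]["hallux"], substrate.surface_z, 0.15, lift)
        y = np.full_like(t, ysign * width / 2)
        pre = "L" if side == "left" else "R"
        markers[pre + "HEE"] = np.column_stack([xh, y, zh])
        markers[pre + "HALL"] = np.column_stack([xa, y, za])

    # ---- segment markers: trunk/head/arms rigid with pelvis, legs by FK
    height = prof["height"]
    lt, ls, lf = 0.245 * height, 0.246 * height, 0.15
    lu, lfa = 0.17 * height, 0.15 * height
    hip_w, sho_w = 0.20, 0.36
    base = markers["SACR"]
    markers["C7"] = base + np.array([0.0, 0.0, 0.40])
    markers["HEAD"] = base + np.array([0.0, 0.0, 0.62])
    templates = cfg.joint_angle_templates
    offsets = cfg.joint_offsets.get(substrate.substrate_id, {"hip": 0, "knee": 0, "ankle": 0})
    for side, ysign in (("left", 1.0), ("right", -1.0)):
        s = ((t - hs0[side]) / cycle) % 1.0
        th = np.radians(joint_template(templates["hip"], s, offsets.get("hip", 0.0)))
        tk = np.radians(joint_template(templates["knee"], s, offsets.get("knee", 0.0)))
        ta = np.radians(joint_template(templates["ankle"], s, offsets.get("ankle", 0.0)))
        pre = "L" if side == "left" else "R"
        hip = base + np.array([0.0, ysign * hip_w / 2, -0.05])
        phi_t = th  # segment direction angle from downward vertical toward +x
        knee = hip + lt * np.column_stack([np.sin(phi_t), np.zeros(n), -np.cos(phi_t)])
        phi_s = th - tk
        ank = knee + ls * np.column_stack([np.sin(phi_s), np.zeros(n), -np.cos(phi_s)])
        phi_f = phi_s + np.pi / 2 + ta
        toe = ank + lf * np.column_stack([np.sin(phi_f), np.zeros(n), -np.cos(phi_f)])
        markers[pre + "HIP"] = hip
        markers[pre + "KNEE"] = knee
        markers[pre + "ANK"] = ank
        markers[pre + "TOE"] = toe
        # arms swing in counter-phase with the ipsilateral leg
        alpha = np.radians(12.0) * np.sin(2 * np.pi * s + np.pi)
        sho = base + np.array([0.0, ysign * sho_w / 2, 0.35])
        elb = sho + lu * np.column_stack([np.sin(alpha), np.zeros(n), -np.cos(alpha)])
        wri = elb + lfa * np.column_stack([np.sin(alpha), np.zeros(n), -np.cos(alpha)])
        markers[pre + "SHO"] = sho
        markers[pre + "ELB"] = elb
        markers[pre + "WRI"] = wri

    if cfg.marker_noise_sd > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(0.0, cfg.marker_noise_sd, (n, 3))

    # ---- EMG (left lower limb)
    n_emg = int(round(duration * cfg.emg_rate)) + 1
    te = np.arange(n_emg) / cfg.emg_rate
    s_left = ((te - hs0["left"]) / cycle) % 1.0
    emg: dict[str, np.ndarray] = {}
    env_max: dict[str, float] = {}
    s_dense = np.linspace(0, 1, 4001)
    for muscle in EMG_MUSCLES:
        bursts = cfg.emg_bursts.get(muscle, [])
        env = _emg_envelope(bursts, s_left)
        env_max[muscle] = float(_emg_envelope(bursts, s_dense).max()) if bursts else 0.0
        if cfg.emg_envelope_only:
            emg[muscle] = env
        else:
            carrier = _bandlimited_noise(n_emg, cfg.emg_rate, rng)
            drift = cfg.emg_drift_amplitude * np.sin(
                2 * np.pi * cfg.emg_drift_freq * te + rng.uniform(0, 2 * np.pi)
            )
            emg[muscle] = env * carrier + drift + rng.normal(0.0, cfg.emg_baseline_sd, n_emg)

    # ---- ground truth
    m = prof["body_mass"]
    rows = []
    sd = np.linspace(0.0, 1.0, 2001)
    rom = {
        j: float(np.ptp(joint_template(templates[j], sd)))
        for j in ("hip", "knee", "ankle")
    }
    def stride_oracle(t_start: float, t_end: float) -> tuple[float, float, float]:
        # oracle exchange metrics on the marker frame grid covering the
        # stride (analytic CoM position/velocity, brute-force sums)
        i0 = int(round(t_start * cfg.marker_rate))
        i1 = int(round(t_end * cfg.marker_rate))
        tg = np.arange(i0, i1 + 1) / cfg.marker_rate
        pos_g, vel_g = _com_path(cfg, v, cycle, hs0["left"], tg)
        e_pot_g = m * G * pos_g[:, 2]
        e_kin_g = 0.5 * m * np.sum(vel_g**2, axis=1)
        return oracle_exchange(e_pot_g, e_kin_g)

    for side in ("left", "right"):
        hs = events[side]["heel_strikes"]
        to = events[side]["toe_offs"]
        for k in range(S):
            r_true, ra_true, co_true = stride_oracle(hs[k], hs[k + 1])
            rows.append(
                {
                    "side": side,
                    "stride_index": k,
                    "heel_strike": hs[k],
                    "toe_off": to[k],
                    "end": hs[k + 1],
                    "speed": v,
                    "stride_length": v * cycle,
                    "stride_width": width,
                    "cycle_time": cycle,
                    "stance_time": duty * cycle,
                    "swing_time": (1 - duty) * cycle,
                    "double_support_time": (2 * duty - 1) * cycle,
                    "duty_factor": duty,
                    "heel_sink_depth": depths[side]["heel"][k + 1],
                    "hallux_sink_depth": depths[side]["hallux"][k + 1],
                    "hip_rom": rom["hip"],
                    "knee_rom": rom["knee"],
                    "ankle_rom": rom["ankle"],
                    "r_pct": r_true,
                    "ra": ra_true,
                    "co_pct": co_true,
                }
            )
    strides = pd.DataFrame(rows)

    emg_rows = []
    for muscle in EMG_MUSCLES:
        bursts = cfg.emg_bursts.get(muscle, [])
        # closed form: each half-sine burst integrates to amp*(2/pi)*(off-on)*T
        integral = sum(amp * (2 / np.pi) * (off - on) for on, off, amp in bursts) * cycle
        for k in range(S):
            emg_rows.append(
                {
                    "muscle": muscle,
                    "stride_index": k,
                    "envelope_integral": integral,
                    "nemg_integral": integral / env_max[muscle] if env_max[muscle] else 0.0,
                }
            )
    truth = GroundTruth(
        trial_id=f"{prof['participant_id']}_{substrate.substrate_id}_T{trial_index}",
        events=events,
        strides=strides,
        emg=pd.DataFrame(emg_rows),
        speed=v,
        cycle_time=cycle,
    )
    truth.validate()

    trial = TrialRecording(
        trial_id=truth.trial_id,
        participant_id=prof["participant_id"],
        sex=prof["sex"],
        body_mass=m,
        height=height,
        substrate_id=substrate.substrate_id,
        substrate_surface_z=substrate.surface_z,
        travel_direction=1,
        marker_rate=cfg.marker_rate,
        markers=markers,
        emg_rate=cfg.emg_rate,
        emg=emg,
        t0=0.0,
    )
    return trial, truth


def simulate_study(cfg: GaitSimConfig) -> tuple[list[TrialRecording], list[GroundTruth]]:
    """Generate the full multi-participant, multi-substrate study."""
    cfg.validate()
    trials: list[TrialRecording] = []
    truths: list[GroundTruth] = []
    for p in range(cfg.n_participants):
        for si, sub in enumerate(cfg.substrates):
            for k in range(sub.n_trials):
                rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, p, si, k)))
                trial, truth = simulate_trial(cfg, p, sub, rng, trial_index=k)
                trials.append(trial)
                truths.append(truth)
    return trials, truths
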