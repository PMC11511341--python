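"""Synthetic countermovement-jump trajectories with analytic ground truth.

The generator builds a whole-body CoM height profile from C1 (position and
velocity continuous) piecewise segments:

* quiet stance at the standing CoM height;
* a descent of ``depth_m`` split into a cosine-eased unweighting part
  (velocity 0 -> peak downward velocity at point c) and a braking part with
  parabolic speed decay (peak downward velocity -> 0 at the bottom, point
  d) — the parabola ends with a nonzero deceleration so the countermovement
  bottom is a sharp, localisable minimum, as the high leg-extensor force at
  the turning point makes it in a real jump;
* a push-off whose velocity rises from 0 to ``takeoff_velocity_mps`` at
  lift-off (point f) while the CoM returns exactly to its standing height —
  the shape has one free harmonic so that commanded duration, displacement
  and take-off velocity are all honoured, and its analytic maximum (point e)
  falls at or just before take-off, as in real jumps;
* an exactly ballistic flight of duration 2 v / g (apex g, touchdown h), so
  the flight-time, take-off-velocity and displacement estimates of jump
  height coincide analytically;
* a landing descent to ``landing_depth_m`` (point i) with the same
  parabolic speed decay (impact absorption ends in a sharp bottom), followed
  by a smooth recovery to standing.

Landmark positions are back-generated from a planar two-sided posture model
(feet flat on the ground, shank/thigh/trunk hinged at ankle, knee and hip).
A single crouch parameter drives all three joint rotations; it is inverted
per sample by bisection so that the Dempster whole-body CoM of the generated
landmarks reproduces the target CoM profile to ~1e-12 m.  During flight the
take-off (standing) posture is translated rigidly along the ballistic path.

Measurement error is additive and seeded: independent Gaussian noise plus a
constant bias per landmark, applied to the landmark coordinates (not to the
CoM) so that the mass-weighted noise averaging of the CoM computation is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CmjkitError
from .io import LandmarkTrajectorySet
from .kinematics import DEFAULT_MODEL, SEGMENT_ENDPOINTS, SEGMENTS, SegmentModel
from .variables import GRAVITY, CmjVariables


@dataclass(frozen=True)
class SyntheticJumpSpec:
    """Commanded conditions of one simulated jump.

    Defaults reproduce the magnitudes typical of a recreationally trained
    adult: a ~0.24/0.18 s unweighting/braking split, a 0.30 m
    countermovement, a 2.3 m/s take-off velocity (≈0.27 m flight height) and
    a 0.25 m landing depth.
    """

    sampling_rate_hz: float = 100.0
    stance_s: float = 1.0
    unweighting_s: float = 0.24
    braking_s: float = 0.18
    propulsive_s: float = 0.22
    depth_m: float = 0.30
    takeoff_velocity_mps: float = 2.3
    landing_depth_m: float = 0.25
    recovery_s: float = 0.4
    tail_s: float = 0.4
    stature_m: float = 1.79
    noise_sd_m: float = 0.0
    bias_m: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("sampling_rate_hz", "stance_s", "unweighting_s", "braking_s",
                     "propulsive_s", "depth_m", "takeoff_velocity_mps",
                     "landing_depth_m", "recovery_s", "tail_s", "stature_m"):
            if getattr(self, name) <= 0:
                raise CmjkitError(f"{name} must be positive")
        if self.noise_sd_m < 0:
            raise CmjkitError("noise_sd_m must be non-negative")
        if self.propulsive_s > 2.0 * self.depth_m / self.takeoff_velocity_mps + 1e-12:
            raise CmjkitError(
                "propulsive_s too long: the CoM cannot return to standing height "
                "with the commanded depth and take-off velocity "
                f"(max {2.0 * self.depth_m / self.takeoff_velocity_mps:.3f} s)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic event times and variable values implied by a jump spec."""

    event_times_s: dict
    variables: CmjVariables
    baseline_z_m: float
    toe_baseline_z_m: float
    com_z_m: np.ndarray  # target CoM height per sample
    vz_mps: np.ndarray   # analytic CoM velocity per sample

    def event_index(self, label: str, sampling_rate_hz: float) -> int:
        return int(round(self.event_times_s[label] * sampling_rate_hz))


# ---------------------------------------------------------------------------
# Planar posture model
# ---------------------------------------------------------------------------

class PostureModel:
    """Hinged sagittal body model: fixed flat feet, shank/thigh/trunk chain.

    A crouch parameter ``q`` in [0, 1] rotates the shank forward, the thigh
    backward and the trunk forward by fixed maximal angles; ``q = 0`` is
    upright standing.  Segment lengths are standard stature fractions.
    """

    MARKER_HEIGHT = 0.02  # heel/toe marker centre above ground, m
    SHANK_TILT = 0.9   # rad at q = 1
    THIGH_TILT = 1.9
    TRUNK_TILT = 0.8

    def __init__(self, stature_m: float, model: SegmentModel = DEFAULT_MODEL):
        h = stature_m
        self.model = model
        self.ankle = np.array([0.038 * h, 0.039 * h])
        self.heel = np.array([0.0, self.MARKER_HEIGHT])
        self.big_toe = np.array([0.152 * h, self.MARKER_HEIGHT])
        self.small_toe = np.array([0.137 * h, self.MARKER_HEIGHT])
        self.shank_l = 0.246 * h
        self.thigh_l = 0.245 * h
        self.trunk_l = 0.288 * h

    def landmarks(self, q) -> dict:
        """Landmark coordinates for crouch ``q`` (scalar or (n,) array).

        Returns a map of side-less landmark names to (n, 2) arrays; both body
        sides share the sagittal plane and are identical.
        """
        q = np.atleast_1d(np.asarray(q, float))
        n = len(q)
        tile = lambda p: np.tile(p, (n, 1))
        a1, a2, a3 = self.SHANK_TILT * q, self.THIGH_TILT * q, self.TRUNK_TILT * q
        ankle = tile(self.ankle)
        knee = ankle + self.shank_l * np.column_stack([np.sin(a1), np.cos(a1)])
        hip = knee + self.thigh_l * np.column_stack([-np.sin(a2), np.cos(a2)])
        shoulder = hip + self.trunk_l * np.column_stack([np.sin(a3), np.cos(a3)])
        return {
            "heel": tile(self.heel),
            "big_toe": tile(self.big_toe),
            "small_toe": tile(self.small_toe),
            "ankle": ankle,
            "knee": knee,
            "hip": hip,
            "shoulder": shoulder,
        }

    def com(self, q) -> np.ndarray:
        """Dempster whole-body CoM, shape (n, 2), for crouch ``q``."""
        lm = self.landmarks(q)
        total = 0.0
        for seg in SEGMENTS:
            origin, target = SEGMENT_ENDPOINTS[seg]
            f = self.model.com_fractions[seg]
            sc = lm[origin] + f * (lm[target] - lm[origin])
            total = total + self.model.weights[seg] * sc
        return total / self.model.weight_sum

    def com_z(self, q) -> np.ndarray:
        return self.com(q)[:, 1]

    @property
    def standing_com_z(self) -> float:
        return float(self.com_z(0.0)[0])

    @property
    def max_depth(self) -> float:
        return float(self.standing_com_z - self.com_z(1.0)[0])

    def crouch_for_com_z(self, target_z) -> np.ndarray:
        """Invert ``com_z`` by bisection (monotone in q), per sample."""
        target = np.atleast_1d(np.asarray(target_z, float))
        z0 = self.standing_com_z
        if np.any(target > z0 + 1e-9) or np.any(target < z0 - self.max_depth + 1e-9):
            raise CmjkitError("target CoM height outside the posture model's range")
        lo = np.zeros_like(target)
        hi = np.ones_like(target)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            too_high = self.com_z(mid) > target  # com decreases with q
            lo = np.where(too_high, mid, lo)
            hi = np.where(too_high, hi, mid)
        return 0.5 * (lo + hi)

    def joint_angles(self, q) -> dict:
        """Interior angles (deg) at ankle, knee and hip for crouch ``q``."""
        lm = self.landmarks(q)

        def interior(a, v, b):
            u1, u2 = lm[a] - lm[v], lm[b] - lm[v]
            c = np.sum(u1 * u2, axis=1) / (
                np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)
            )
            return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

        return {
            "ankle": interior("knee", "ankle", "big_toe"),
            "knee": interior("hip", "knee", "ankle"),
            "hip": interior("shoulder", "hip", "knee"),
        }


# ---------------------------------------------------------------------------
# Analytic CoM profile
# ---------------------------------------------------------------------------

class ComProfile:
    """Closed-form CoM height/velocity profile of one simulated jump."""

    def __init__(self, spec: SyntheticJumpSpec, standing_com_z: float,
                 g: float = GRAVITY):
        s = spec
        self.g = g
        self.z0 = standing_com_z
        self.t_move = s.stance_s
        self.t_c = self.t_move + s.unweighting_s
        self.t_d = self.t_c + s.braking_s
        self.t_f = self.t_d + s.propulsive_s
        self.flight_s = 2.0 * s.takeoff_velocity_mps / g
        self.t_g = self.t_f + 0.5 * self.flight_s
        self.t_h = self.t_f + self.flight_s
        self.landing_s = 1.5 * s.landing_depth_m / s.takeoff_velocity_mps
        self.t_i = self.t_h + self.landing_s
        self.t_rec_end = self.t_i + s.recovery_s
        self.t_end = self.t_rec_end + s.tail_s

        # Cosine-eased unweighting displaces v_min*Tu/2; parabolic braking
        # displaces 2*v_min*Tb/3; together they must equal the depth.
        self.v_min = -s.depth_m / (s.unweighting_s / 2.0 + 2.0 * s.braking_s / 3.0)
        self.v_to = s.takeoff_velocity_mps
        # Push-off velocity shape: v(s) = v_to (1 - cos pi s)/2 + B sin(pi s).
        # B makes the push-off displacement equal the commanded depth.
        self.push_b = (s.depth_m / s.propulsive_s - self.v_to / 2.0) * np.pi / 2.0
        if self.push_b < -1e-12:
            raise CmjkitError("inconsistent push-off shape (negative harmonic)")
        self.push_b = max(self.push_b, 0.0)
        if self.push_b > 0:
            s_star = (np.pi - np.arctan(2.0 * self.push_b / self.v_to)) / np.pi
        else:
            s_star = 1.0
        self.t_e = self.t_d + s_star * s.propulsive_s
        self.v_max = float(self._push_v(np.array([s_star]))[0])
        self.spec = s

    # -- piecewise pieces -------------------------------------------------
    def _push_v(self, s):
        return self.v_to * (1 - np.cos(np.pi * s)) / 2.0 + self.push_b * np.sin(np.pi * s)

    def _push_dz(self, s):
        return self.spec.propulsive_s * (
            self.v_to * (s - np.sin(np.pi * s) / np.pi) / 2.0
            + self.push_b * (1 - np.cos(np.pi * s)) / np.pi
        )

    def velocity(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        sp, z0 = self.spec, self.z0
        v = np.zeros_like(t)
        m = (t >= self.t_move) & (t < self.t_c)
        s = (t[m] - self.t_move) / sp.unweighting_s
        v[m] = self.v_min * (1 - np.cos(np.pi * s)) / 2.0
        m = (t >= self.t_c) & (t < self.t_d)
        s = (t[m] - self.t_c) / sp.braking_s
        v[m] = self.v_min * (1 - s**2)
        m = (t >= self.t_d) & (t < self.t_f)
        s = (t[m] - self.t_d) / sp.propulsive_s
        v[m] = self._push_v(s)
        m = (t >= self.t_f) & (t < self.t_h)
        v[m] = self.v_to - self.g * (t[m] - self.t_f)
        m = (t >= self.t_h) & (t < self.t_i)
        s = (t[m] - self.t_h) / self.landing_s
        v[m] = -self.v_to * (1 - s**2)
        m = (t >= self.t_i) & (t < self.t_rec_end)
        s = (t[m] - self.t_i) / sp.recovery_s
        v[m] = (np.pi * sp.landing_depth_m / (2.0 * sp.recovery_s)) * np.sin(np.pi * s)
        return v

    def height(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        sp, z0 = self.spec, self.z0
        z = np.full_like(t, z0)
        m = (t >= self.t_move) & (t < self.t_c)
        s = (t[m] - self.t_move) / sp.unweighting_s
        z[m] = z0 + sp.unweighting_s * self.v_min * (s - np.sin(np.pi * s) / np.pi) / 2.0
        z_c = z0 + sp.unweighting_s * self.v_min / 2.0
        m = (t >= self.t_c) & (t < self.t_d)
        s = (t[m] - self.t_c) / sp.braking_s
        z[m] = z_c + sp.braking_s * self.v_min * (s - s**3 / 3.0)
        z_d = z0 - sp.depth_m
        m = (t >= self.t_d) & (t < self.t_f)
        s = (t[m] - self.t_d) / sp.propulsive_s
        z[m] = z_d + self._push_dz(s)
        m = (t >= self.t_f) & (t < self.t_h)
        tau = t[m] - self.t_f
        z[m] = z0 + self.v_to * tau - 0.5 * self.g * tau**2
        m = (t >= self.t_h) & (t < self.t_i)
        s = (t[m] - self.t_h) / self.landing_s
        z[m] = z0 - self.v_to * self.landing_s * (s - s**3 / 3.0)
        z_i = z0 - sp.landing_depth_m
        m = (t >= self.t_i) & (t < self.t_rec_end)
        s = (t[m] - self.t_i) / sp.recovery_s
        z[m] = z_i + sp.landing_depth_m * (1 - np.cos(np.pi * s)) / 2.0
        return z

    def onset_time(self, onset_fraction: float = 0.05,
                   onset_reference: str = "max_up") -> float:
        """Analytic time at which downward speed first exceeds the threshold."""
        ref = self.v_max if onset_reference == "max_up" else -self.v_min
        thr = onset_fraction * ref
        if thr >= -self.v_min:
            raise CmjkitError("onset threshold exceeds the peak downward speed")
        s_a = np.arccos(1.0 + 2.0 * thr / self.v_min) / np.pi
        return self.t_move + s_a * self.spec.unweighting_s


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def simulate_cmj(
    spec: SyntheticJumpSpec,
    model: SegmentModel = DEFAULT_MODEL,
    onset_fraction: float = 0.05,
    onset_reference: str = "max_up",
    source_label: str = "synthetic",
) -> tuple[LandmarkTrajectorySet, GroundTruth]:
    """Generate one jump trial and its analytic ground truth.

    Returns the (possibly noise/bias-degraded) landmark set and a
    :class:`GroundTruth` holding exact event times and variable values.  The
    onset parameters select the movement-onset definition used for the
    ground-truth point a (they mirror the detector's configuration).
    """
    posture = PostureModel(spec.stature_m, model)
    if spec.depth_m > posture.max_depth - 0.01 or spec.landing_depth_m > posture.max_depth - 0.01:
        raise CmjkitError(
            f"commanded depth exceeds the posture model's range ({posture.max_depth:.2f} m)"
        )
    prof = ComProfile(spec, posture.standing_com_z)
    fs = spec.sampling_rate_hz
    n = int(round(prof.t_end * fs)) + 1
    t = np.arange(n) / fs
    z_target = prof.height(t)
    v_target = prof.velocity(t)

    in_flight = (t > prof.t_f) & (t < prof.t_h)
    q = np.zeros(n)
    q[~in_flight] = posture.crouch_for_com_z(z_target[~in_flight])
    lm_all = posture.landmarks(q)
    dz_flight = z_target[in_flight] - prof.z0
    landmarks: dict[str, np.ndarray] = {}
    for name, arr in lm_all.items():
        arr = arr.copy()
        arr[in_flight, 1] += dz_flight  # rigid ballistic translation
        for side in ("left", "right"):
            landmarks[f"{side}_{name}"] = arr.copy()

    if spec.bias_m != 0.0 or spec.noise_sd_m > 0.0:
        rng = np.random.default_rng(spec.seed)
        for name in landmarks:
            landmarks[name] = (
                landmarks[name]
                + spec.bias_m
                + rng.normal(0.0, spec.noise_sd_m, size=landmarks[name].shape)
            )

    tset = LandmarkTrajectorySet(
        sampling_rate_hz=fs,
        landmarks=landmarks,
        source_label=source_label,
        recording_side="both",
    )

    t_a = prof.onset_time(onset_fraction, onset_reference)
    events = {
        "a": t_a, "c": prof.t_c, "d": prof.t_d, "e": prof.t_e,
        "f": prof.t_f, "g": prof.t_g, "h": prof.t_h, "i": prof.t_i,
    }
    g = prof.g
    h_ballistic = spec.takeoff_velocity_mps**2 / (2.0 * g)
    ang_d = posture.joint_angles(posture.crouch_for_com_z(prof.z0 - spec.depth_m))
    ang_i = posture.joint_angles(posture.crouch_for_com_z(prof.z0 - spec.landing_depth_m))
    gt_vars = CmjVariables(
        unweighting_phase_s=prof.t_c - t_a,
        braking_phase_s=spec.braking_s,
        eccentric_phase_s=prof.t_d - t_a,
        propulsive_phase_s=spec.propulsive_s,
        takeoff_phase_s=prof.t_f - t_a,
        ld_eccentric_phase_s=prof.landing_s,
        flight_time_s=prof.flight_s,
        jump_height_m=h_ballistic,
        countermovement_depth_m=spec.depth_m,
        ld_depth_m=spec.landing_depth_m,
        max_com_vz_mps=prof.v_max,
        takeoff_com_vz_mps=spec.takeoff_velocity_mps,
        min_com_vz_mps=prof.v_min,
        ankle_angle_deg=float(ang_d["ankle"][0]),
        knee_angle_deg=float(ang_d["knee"][0]),
        hip_angle_deg=float(ang_d["hip"][0]),
        ld_ankle_angle_deg=float(ang_i["ankle"][0]),
        ld_knee_angle_deg=float(ang_i["knee"][0]),
        ld_hip_angle_deg=float(ang_i["hip"][0]),
        jump_height_flight_m=g * prof.flight_s**2 / 8.0,
        jump_height_takeoff_v_m=h_ballistic,
        jump_height_max_v_m=prof.v_max**2 / (2.0 * g),
    )
    gt = GroundTruth(
        event_times_s=events,
        variables=gt_vars,
        baseline_z_m=prof.z0,
        toe_baseline_z_m=PostureModel.MARKER_HEIGHT,
        com_z_m=z_target,
        vz_mps=v_target,
    )
    return tset, gt


def sample_jump_spec(
    rng: np.random.Generator,
    noise_sd_m: float = 0.0,
    bias_m: float = 0.0,
    sampling_rate_hz: float = 100.0,
) -> SyntheticJumpSpec:
    """Draw one realistic jump from the simulator's study conditions.

    Countermovement depths span 0.15-0.45 m and take-off velocities
    1.8-2.8 m/s (jump heights ~0.17-0.40 m); unweighting and braking
    durations vary around their defaults.  The push-off duration is tied to
    depth and take-off velocity (a fraction of the kinematic maximum
    ``2 * depth / v``) so every drawn jump is feasible.
    """
    depth = float(rng.uniform(0.15, 0.45))
    v = float(rng.uniform(1.8, 2.8))
    return SyntheticJumpSpec(
        sampling_rate_hz=sampling_rate_hz,
        unweighting_s=float(rng.uniform(0.20, 0.28)),
        braking_s=float(rng.uniform(0.15, 0.21)),
        propulsive_s=float(rng.uniform(0.75, 0.95) * 2.0 * depth / v),
        depth_m=depth,
        takeoff_velocity_mps=v,
        landing_depth_m=float(rng.uniform(0.18, 0.30)),
        noise_sd_m=noise_sd_m,
        bias_m=bias_m,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def degrade(
    tset: LandmarkTrajectorySet,
    bias_m=0.0,
    noise_sd_m: float = 0.0,
    seed: int = 0,
    landmarks=None,
) -> LandmarkTrajectorySet:
    """Copy of a trajectory set with additive measurement error on Z.

    ``bias_m`` is a constant offset — a scalar applied to every selected
    landmark, or a map of landmark id to offset.  ``noise_sd_m`` adds i.i.d.
    Gaussian noise.  Both act on the vertical coordinate only (the horizontal
    coordinate is left untouched); ``landmarks`` restricts the affected ids.
    """
    if noise_sd_m < 0:
        raise CmjkitError("noise_sd_m must be non-negative")
    rng = np.random.default_rng(seed)
    selected = set(landmarks) if landmarks is not None else set(tset.landmarks)
    bias_map = bias_m if isinstance(bias_m, dict) else {k: bias_m for k in selected}
    out = {}
    for name, arr in tset.landmarks.items():
        arr = arr.copy()
        if name in selected:
            arr[:, 1] += bias_map.get(name, 0.0)
            if noise_sd_m > 0:
                arr[:, 1] += rng.normal(0.0, noise_sd_m, size=len(arr))
        out[name] = arr
    return replace(tset, landmarks=out)
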