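"""The 21 per-trial countermovement-jump variables.

Phase durations come from event-index differences divided by the sampling
rate; displacements are relative to the initial resting (quiet-stance) CoM
height; velocities come from the differentiated CoM height.  Three jump
heights are reported alongside the displacement-based one: from flight time
(h = g t^2 / 8), from take-off velocity and from the maximum upward velocity
(h = v^2 / 2g).  On an ideal ballistic flight all of them coincide.

The extrema of the CoM vertical velocity are taken over the ground-contact
push-off interval [a, f] — not the whole trial — so that landing transients
cannot dominate; the minimum then reflects the countermovement descent.
Push-off joint angles are sampled at the eccentric/concentric transition
(event d), landing angles at the landing bottom (event i).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import VariableError
from .events import JumpEvents
from .kinematics import ComTrajectory, JointAngleSeries

#: Standard gravity, m/s^2.
GRAVITY = 9.81

JOINTS = ("ankle", "knee", "hip")


@dataclass
class CmjVariables:
    """The 21 variables of one jump trial (units in the field names)."""

    unweighting_phase_s: float
    braking_phase_s: float
    eccentric_phase_s: float
    propulsive_phase_s: float
    takeoff_phase_s: float
    ld_eccentric_phase_s: float
    flight_time_s: float
    jump_height_m: float
    countermovement_depth_m: float
    ld_depth_m: float
    max_com_vz_mps: float
    takeoff_com_vz_mps: float
    min_com_vz_mps: float
    ankle_angle_deg: float
    knee_angle_deg: float
    hip_angle_deg: float
    ld_ankle_angle_deg: float
    ld_knee_angle_deg: float
    ld_hip_angle_deg: float
    jump_height_flight_m: float
    jump_height_takeoff_v_m: float
    jump_height_max_v_m: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if abs(self.eccentric_phase_s - (self.unweighting_phase_s + self.braking_phase_s)) > 1e-9:
            raise VariableError("eccentric phase must equal unweighting + braking")
        if abs(self.takeoff_phase_s - (self.eccentric_phase_s + self.propulsive_phase_s)) > 1e-9:
            raise VariableError("take-off phase must equal eccentric + propulsive")
        for name in (
            "unweighting_phase_s", "braking_phase_s", "propulsive_phase_s",
            "ld_eccentric_phase_s", "flight_time_s", "countermovement_depth_m",
        ):
            if getattr(self, name) <= 0:
                raise VariableError(f"{name} must be positive")
        if self.jump_height_m < 0:
            raise VariableError("jump height must be non-negative")
        if not (self.min_com_vz_mps < 0 < self.max_com_vz_mps):
            raise VariableError("velocity extrema must bracket zero")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


def compute_variables(
    events: JumpEvents,
    com: ComTrajectory,
    toe_z,
    angles: dict[str, JointAngleSeries],
) -> CmjVariables:
    """Extract the 21 variables of one trial.

    ``angles`` maps joint name (ankle, knee, hip) to its interior-angle
    series; all three joints must be present.
    """
    missing = [j for j in JOINTS if j not in angles]
    if missing:
        raise VariableError(f"missing joint-angle series: {', '.join(missing)}")
    fs = events.sampling_rate_hz
    z = np.asarray(com.com_z_m, float)
    vz = np.asarray(com.vz_mps, float)
    ev = events
    baseline = ev.baseline_z_m

    push = slice(ev.a, ev.f + 1)
    return CmjVariables(
        unweighting_phase_s=(ev.c - ev.a) / fs,
        braking_phase_s=(ev.d - ev.c) / fs,
        eccentric_phase_s=(ev.d - ev.a) / fs,
        propulsive_phase_s=(ev.f - ev.d) / fs,
        takeoff_phase_s=(ev.f - ev.a) / fs,
        ld_eccentric_phase_s=(ev.i - ev.h) / fs,
        flight_time_s=(ev.h - ev.f) / fs,
        jump_height_m=float(z[ev.g] - baseline),
        countermovement_depth_m=float(baseline - z[ev.d]),
        ld_depth_m=float(baseline - z[ev.i]),
        max_com_vz_mps=float(np.max(vz[push])),
        takeoff_com_vz_mps=float(vz[ev.f]),
        min_com_vz_mps=float(np.min(vz[push])),
        ankle_angle_deg=float(angles["ankle"].angle_deg[ev.d]),
        knee_angle_deg=float(angles["knee"].angle_deg[ev.d]),
        hip_angle_deg=float(angles["hip"].angle_deg[ev.d]),
        ld_ankle_angle_deg=float(angles["ankle"].angle_deg[ev.i]),
        ld_knee_angle_deg=float(angles["knee"].angle_deg[ev.i]),
        ld_hip_angle_deg=float(angles["hip"].angle_deg[ev.i]),
        jump_height_flight_m=jump_height_from_flight_time((ev.h - ev.f) / fs),
        jump_height_takeoff_v_m=jump_height_from_velocity(float(vz[ev.f])),
        jump_height_max_v_m=jump_height_from_velocity(float(np.max(vz[push]))),
    )


def jump_height_from_flight_time(t_flight_s: float, g: float = GRAVITY) -> float:
    """Ballistic jump height from flight time: ``h = g t^2 / 8``."""
    if t_flight_s <= 0:
        raise VariableError("flight time must be positive")
    return g * t_flight_s**2 / 8.0


def jump_height_from_velocity(v_mps: float, g: float = GRAVITY) -> float:
    """Ballistic jump height from vertical take-off velocity: ``h = v^2 / 2g``."""
    if v_mps <= 0:
        raise VariableError("take-off velocity must be positive")
    return v_mps**2 / (2.0 * g)
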