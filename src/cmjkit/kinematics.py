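"""Centre-of-mass and joint-angle kinematics for the sagittal plane.

The whole-body centre of mass (CoM) is computed with a four-segment Dempster
model: foot, lower leg, upper leg and upper body, carrying mass fractions of
1.5%, 4.65%, 10% and 43% respectively.  Because the four segments cover only
59.15% of body mass, the weighted mean is renormalised by the weight sum
rather than forced to one:

    XCoM = (0.015 Xfoot + 0.0465 Xlowerleg + 0.10 Xupperleg + 0.43 Xupperbody) / 0.5915

and identically for Z.  Segment CoM positions sit along the marker-to-marker
line: foot at the heel/big-toe midpoint, lower leg at 43.3% of the
ankle-to-knee length (origin at the ankle), upper leg at 43.3% of the
knee-to-hip length (origin at the knee), upper body at the hip/shoulder
midpoint.

Joint angles are interior angles at the middle landmark (180 deg = fully
extended limb); mapping to anatomical flexion/dorsiflexion conventions is
left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CmjkitError, SchemaError
from .io import LandmarkTrajectorySet

SEGMENTS = ("foot", "lower_leg", "upper_leg", "upper_body")

#: (origin landmark, target landmark) per segment; the segment CoM lies at
#: ``origin + fraction * (target - origin)``.
SEGMENT_ENDPOINTS = {
    "foot": ("heel", "big_toe"),
    "lower_leg": ("ankle", "knee"),
    "upper_leg": ("knee", "hip"),
    "upper_body": ("hip", "shoulder"),
}

#: Landmark triples (A, vertex, B) defining each interior joint angle.
JOINT_TRIPLES = {
    "hip": ("shoulder", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "big_toe"),
}


@dataclass(frozen=True)
class SegmentModel:
    """Dempster mass fractions and along-segment CoM locations."""

    weights: dict = field(
        default_factory=lambda: {
            "foot": 0.015,
            "lower_leg": 0.0465,
            "upper_leg": 0.10,
            "upper_body": 0.43,
        }
    )
    com_fractions: dict = field(
        default_factory=lambda: {
            "foot": 0.5,
            "lower_leg": 0.433,
            "upper_leg": 0.433,
            "upper_body": 0.5,
        }
    )

    def __post_init__(self):
        for seg in SEGMENTS:
            if self.weights.get(seg, 0) <= 0:
                raise ValueError(f"segment weight for {seg!r} must be positive")
            f = self.com_fractions.get(seg)
            if f is None or not (0 <= f <= 1):
                raise ValueError(f"com_fraction for {seg!r} must lie in [0, 1]")

    @property
    def weight_sum(self) -> float:
        return sum(self.weights[s] for s in SEGMENTS)


DEFAULT_MODEL = SegmentModel()


@dataclass
class ComTrajectory:
    """Whole-body CoM position, per-segment CoM and vertical velocity."""

    com_x_m: np.ndarray
    com_z_m: np.ndarray
    vz_mps: np.ndarray
    segment_com: dict
    sampling_rate_hz: float

    def __post_init__(self):
        n = len(self.com_z_m)
        if not (len(self.com_x_m) == len(self.vz_mps) == n):
            raise ValueError("CoM series lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.com_z_m)


@dataclass
class JointAngleSeries:
    """Interior angle at one joint, degrees, per sample."""

    joint: str
    side: str
    angle_deg: np.ndarray


def segment_com(
    tset: LandmarkTrajectorySet,
    segment: str,
    side: str,
    model: SegmentModel = DEFAULT_MODEL,
) -> np.ndarray:
    """Per-sample (x, z) CoM of one body segment, shape ``(n, 2)``."""
    if segment not in SEGMENT_ENDPOINTS:
        raise ValueError(f"unknown segment {segment!r}")
    origin_name, target_name = SEGMENT_ENDPOINTS[segment]
    a = tset.series(f"{side}_{origin_name}")
    b = tset.series(f"{side}_{target_name}")
    f = model.com_fractions[segment]
    return a + f * (b - a)


def body_com(
    tset: LandmarkTrajectorySet,
    side: str,
    model: SegmentModel = DEFAULT_MODEL,
    smooth=None,
) -> ComTrajectory:
    """Whole-body CoM trajectory from the seven landmarks of one side.

    ``smooth``, if given, is a callable applied to each coordinate series of
    the segment CoMs before the weighted mean (e.g. a configured
    :func:`moving_average`).
    """
    tset.require_side(side)
    segs = {}
    for seg in SEGMENTS:
        sc = segment_com(tset, seg, side, model)
        if smooth is not None:
            sc = np.column_stack([smooth(sc[:, 0]), smooth(sc[:, 1])])
        segs[seg] = sc
    wsum = model.weight_sum
    com = sum(model.weights[s] * segs[s] for s in SEGMENTS) / wsum
    if not np.all(np.isfinite(com)):
        raise CmjkitError("CoM contains non-finite samples; gap-fill the trajectories first")
    vz = vertical_velocity(com[:, 1], tset.sampling_rate_hz)
    return ComTrajectory(
        com_x_m=com[:, 0],
        com_z_m=com[:, 1],
        vz_mps=vz,
        segment_com=segs,
        sampling_rate_hz=tset.sampling_rate_hz,
    )


def moving_average(series, window_s: float, sampling_rate_hz: float) -> np.ndarray:
    """Centered moving mean with the window truncated at the series edges.

    The window spans ``round(window_s * fs)`` samples (forced odd, minimum 1);
    near the edges it is clipped to the available samples, so the output has
    the input's length and a constant signal is reproduced exactly.
    """
    if window_s < 0:
        raise ValueError("window_s must be non-negative")
    y = np.asarray(series, dtype=float)
    n = len(y)
    w = int(round(window_s * sampling_rate_hz))
    if w <= 1:
        return y.copy()
    half = w // 2
    c = np.concatenate([[0.0], np.cumsum(y)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n, i + half + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def ema_filter(series, alpha: float) -> np.ndarray:
    """Zero-phase exponential moving average.

    The first-order recursion ``y[i] = alpha*x[i] + (1-alpha)*y[i-1]`` is run
    forward and backward over the series and the two passes averaged, so the
    smoothing introduces no net phase lag — single-pass exponential smoothing
    would delay every detected event by roughly ``(1-alpha)/alpha`` samples.
    ``alpha = 1`` is the identity.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    from scipy.signal import lfilter

    b, a = [alpha], [1.0, -(1.0 - alpha)]
    zi = (1 - alpha)  # start the recursion from the first sample itself
    fwd, _ = lfilter(b, a, x, zi=np.array([zi * x[0]]))
    bwd, _ = lfilter(b, a, x[::-1], zi=np.array([zi * x[-1]]))
    return 0.5 * (fwd + bwd[::-1])


def vertical_velocity(com_z, sampling_rate_hz: float) -> np.ndarray:
    """Vertical velocity (m/s) by central differences, one-sided at the edges."""
    z = np.asarray(com_z, dtype=float)
    if len(z) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(z, 1.0 / sampling_rate_hz)


def joint_angle(tset: LandmarkTrajectorySet, joint: str, side: str) -> JointAngleSeries:
    """Interior angle (deg) at a joint, per sample.

    The angle at the vertex landmark between the rays toward its two
    neighbours, via the arc-cosine of the normalised dot product (clipped to
    [-1, 1]).  A zero-length ray makes the angle undefined and raises.
    """
    if joint not in JOINT_TRIPLES:
        raise ValueError(f"unknown joint {joint!r}")
    an, vn, bn = JOINT_TRIPLES[joint]
    a = tset.series(f"{side}_{an}")
    v = tset.series(f"{side}_{vn}")
    b = tset.series(f"{side}_{bn}")
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    bad = np.flatnonzero((n1 == 0) | (n2 == 0))
    if bad.size:
        raise CmjkitError(f"undefined {joint} angle: zero-length ray at sample {bad[0]}")
    cosang = np.clip(np.sum(u1 * u2, axis=1) / (n1 * n2), -1.0, 1.0)
    return JointAngleSeries(joint=joint, side=side, angle_deg=np.degrees(np.arccos(cosang)))
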