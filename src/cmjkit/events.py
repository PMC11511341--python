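"""Rule-based detection of the nine labelled countermovement-jump events.

Events are detected on three series: the CoM vertical position (Z-t), the CoM
vertical velocity (Vz-t) and the big-toe vertical position (Toe Z-t):

=====  ==========================================================
label  definition
=====  ==========================================================
a      movement onset: first sample whose downward speed exceeds a
       fraction (default 5%) of the maximum velocity, found by
       searching backward from c
c      peak downward velocity (end of the unweighting phase)
d      lowest CoM position before take-off (eccentric/concentric
       transition)
e      maximum upward CoM velocity
f      take-off: the toe leaves the ground
g      maximum CoM height (flight apex)
h      touchdown: the toe regains ground contact
i      second-lowest CoM position, at the end of the landing
       eccentric phase
=====  ==========================================================

The label ``b`` is historically unused and no event is defined for it.
Take-off and touchdown come from the toe trace because the toe is the last
point to leave the ground and the first to touch back down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguousTrialError, DetectionError, NoFlightError
from .kinematics import ComTrajectory

EVENT_LABELS = ("a", "c", "d", "e", "f", "g", "h", "i")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds for event detection.

    onset_fraction
        Fraction of the reference velocity that downward speed must exceed to
        mark movement onset (point a).
    onset_reference
        ``"max_up"`` references the onset threshold to the maximum upward
        velocity (point e); ``"max_down"`` to the peak downward speed
        (point c).  Both readings of "5% of the maximum velocity" are
        defensible; ``max_up`` is the default.
    min_height_m
        Floor for the flight threshold on the toe trace (1 cm by default:
        above marker noise, far below a flight excursion).
    stance_window_s
        Length of the initial quiet-stance window used for baselines.
    """

    onset_fraction: float = 0.05
    onset_reference: str = "max_up"
    min_height_m: float = 0.01
    stance_window_s: float = 0.5

    def __post_init__(self):
        if not (0 < self.onset_fraction < 1):
            raise ValueError("onset_fraction must lie in (0, 1)")
        if self.onset_reference not in ("max_up", "max_down"):
            raise ValueError("onset_reference must be 'max_up' or 'max_down'")


@dataclass
class JumpEvents:
    """Sample indices of the eight labelled events of one jump trial."""

    a: int
    c: int
    d: int
    e: int
    f: int
    g: int
    h: int
    i: int
    sampling_rate_hz: float
    baseline_z_m: float = float("nan")
    toe_baseline_z_m: float = float("nan")

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Enforce the event ordering a < c < d < e <= f < g < h <= i."""
        seq = [(l, getattr(self, l)) for l in EVENT_LABELS]
        strict_pairs = {("a", "c"), ("c", "d"), ("d", "e"), ("f", "g"), ("g", "h")}
        for (l1, i1), (l2, i2) in zip(seq, seq[1:]):
            ok = i1 < i2 if (l1, l2) in strict_pairs else i1 <= i2
            if not ok:
                raise DetectionError(
                    f"event ordering violated: {l1}={i1} !< {l2}={i2}"
                )

    def time_s(self, label: str) -> float:
        """Event time in seconds (index / sampling rate)."""
        return getattr(self, label) / self.sampling_rate_hz

    def as_dict(self) -> dict:
        d = {l: int(getattr(self, l)) for l in EVENT_LABELS}
        d.update(
            {f"t_{l}": getattr(self, l) / self.sampling_rate_hz for l in EVENT_LABELS},
            baseline_z_m=self.baseline_z_m,
            toe_baseline_z_m=self.toe_baseline_z_m,
        )
        return d


def quiet_stance_baseline(
    com_z, toe_z, stance_window_s: float, sampling_rate_hz: float
) -> tuple[float, float, float]:
    """Resting baselines from the initial quiet-stance window.

    Returns ``(baseline_z, toe_baseline_z, noise_sd)`` where the baselines are
    means over the first ``stance_window_s`` seconds and ``noise_sd`` is the
    standard deviation of the toe height over the same window.
    """
    com_z = np.asarray(com_z, float)
    toe_z = np.asarray(toe_z, float)
    w = int(round(stance_window_s * sampling_rate_hz))
    if w < 1 or w > len(com_z) or w > len(toe_z):
        raise ValueError(
            f"stance window of {w} samples does not fit the series"
        )
    return float(np.mean(com_z[:w])), float(np.mean(toe_z[:w])), float(np.std(toe_z[:w]))


def _excursions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as (first, last) index pairs."""
    if not mask.any():
        return []
    starts = np.flatnonzero(mask & ~np.r_[False, mask[:-1]])
    ends = np.flatnonzero(mask & ~np.r_[mask[1:], False])
    return list(zip(starts, ends))


def detect_takeoff_touchdown(
    toe_z,
    toe_baseline_z: float,
    noise_sd: float,
    min_height_m: float = 0.01,
) -> tuple[int, int]:
    """Take-off (f) and touchdown (h) sample indices from the toe trace.

    The flight excursion is the longest run of samples above the threshold
    ``toe_baseline + max(min_height_m, 5*noise_sd)``.  Its first index is
    backtracked to the last sample still at ground level (take-off), and its
    last index tracked forward symmetrically (touchdown).  Ground level is
    ``toe_baseline + 3*noise_sd``: a tighter margin produces noise runs
    above it during quiet contact (especially when the series was smoothed,
    which autocorrelates the residual noise) and drags the backtracking away
    from the true lift-off, while three sigmas keeps such runs rare without
    delaying the detected crossing — the toe moves far faster than one noise
    SD per sample around lift-off and touchdown.  Prefer passing the
    *unsmoothed* toe trace: temporal smoothing only spreads the crossings.
    """
    toe_z = np.asarray(toe_z, float)
    thr = toe_baseline_z + max(min_height_m, 5.0 * noise_sd)
    runs = _excursions(toe_z > thr)
    if not runs:
        raise NoFlightError(
            f"no supra-threshold toe excursion (threshold {thr:.4f} m)"
        )
    first, last = max(runs, key=lambda r: r[1] - r[0])
    ground = toe_baseline_z + 3.0 * noise_sd
    f = first
    while f > 0 and toe_z[f - 1] > ground:
        f -= 1
    if f > 0:
        f -= 1  # the last sample at/below ground level
    h = last
    n = len(toe_z)
    while h < n - 1 and toe_z[h + 1] > ground:
        h += 1
    if h < n - 1:
        h += 1
    return int(f), int(h)


def count_flight_excursions(
    toe_z, toe_baseline_z: float, noise_sd: float, min_height_m: float = 0.01,
    min_fraction: float = 0.5,
) -> int:
    """Number of substantial flight excursions in the toe trace.

    Runs shorter than ``min_fraction`` of the longest run are treated as
    noise spikes, not flights.
    """
    toe_z = np.asarray(toe_z, float)
    thr = toe_baseline_z + max(min_height_m, 5.0 * noise_sd)
    runs = _excursions(toe_z > thr)
    if not runs:
        return 0
    longest = max(r[1] - r[0] + 1 for r in runs)
    return sum(1 for r in runs if (r[1] - r[0] + 1) >= min_fraction * longest)


def detect_events(
    com: ComTrajectory,
    toe_z,
    cfg: DetectionConfig = DetectionConfig(),
) -> JumpEvents:
    """Detect all nine events of a single-jump trial.

    Expects series containing exactly one jump (one flight excursion);
    multiple substantial excursions raise :class:`AmbiguousTrialError` and a
    flat or monotone CoM trace raises :class:`DetectionError`.
    """
    z = np.asarray(com.com_z_m, float)
    vz = np.asarray(com.vz_mps, float)
    toe_z = np.asarray(toe_z, float)
    fs = com.sampling_rate_hz
    if len(toe_z) != len(z):
        raise ValueError("toe series length differs from CoM series length")

    baseline_z, toe_baseline, noise_sd = quiet_stance_baseline(
        z, toe_z, cfg.stance_window_s, fs
    )
    n_exc = count_flight_excursions(toe_z, toe_baseline, noise_sd, cfg.min_height_m)
    if n_exc > 1:
        raise AmbiguousTrialError(f"{n_exc} flight excursions found; expected one")
    f, h = detect_takeoff_touchdown(toe_z, toe_baseline, noise_sd, cfg.min_height_m)

    if np.ptp(z[:f]) == 0:
        raise DetectionError("flat CoM trace before take-off")

    # d: lowest CoM position before take-off (countermovement bottom).
    d = int(np.argmin(z[:f]))
    if d == 0:
        raise DetectionError("no countermovement descent before take-off")
    # c: peak downward velocity, before the bottom.
    c = int(np.argmin(vz[: d + 1]))
    # e: peak upward velocity during push-off, (d, f]; ties toward earlier index.
    e = d + 1 + int(np.argmax(vz[d + 1 : f + 1]))
    # Onset threshold.
    if cfg.onset_reference == "max_up":
        v_ref = float(vz[e])
    else:
        v_ref = float(-vz[c])
    if v_ref <= 0:
        raise DetectionError("non-positive reference velocity for onset threshold")
    thr = cfg.onset_fraction * v_ref
    # a: searching backward from c, the first sample whose downward speed
    # exceeds the threshold (backward search is robust to pre-trial fidgeting).
    j = c
    while j > 0 and -vz[j - 1] > thr:
        j -= 1
    a = int(j)
    if a >= c:
        raise DetectionError("movement onset not found before peak downward velocity")

    # g: flight apex; i: landing bottom.
    if h - f < 2:
        raise DetectionError(f"flight of {h - f} samples too short for an apex")
    g = f + 1 + int(np.argmax(z[f + 1 : h]))
    i = h + int(np.argmin(z[h:]))

    return JumpEvents(
        a=a, c=c, d=d, e=e, f=f, g=g, h=h, i=i,
        sampling_rate_hz=fs,
        baseline_z_m=baseline_z,
        toe_baseline_z_m=toe_baseline,
    )
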