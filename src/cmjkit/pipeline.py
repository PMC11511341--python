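"""High-level single-trial analysis: trajectories in, variables out.

``analyze_trial`` wires the modules together: gap filling, optional
resampling, smoothing (moving average for marker-style data, zero-phase
exponential moving average for markerless-style data), Dempster CoM,
event detection and variable extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as tio
from .errors import CmjkitError
from .events import DetectionConfig, JumpEvents, detect_events
from .kinematics import (
    DEFAULT_MODEL,
    JOINT_TRIPLES,
    SegmentModel,
    body_com,
    ema_filter,
    joint_angle,
    moving_average,
)
from .variables import CmjVariables, compute_variables


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the single-trial pipeline.

    smoothing
        ``"none"``, ``"moving_average"`` (window ``window_s``) or ``"ema"``
        (zero-phase, coefficient ``alpha``).  Applied to every landmark
        coordinate before any derived signal, so CoM, toe trace and joint
        angles all see the same filtering.
    resample_hz
        If set, series are first resampled to this rate (e.g. 100 Hz to put
        marker and markerless recordings on one grid).
    """

    side: str = "left"
    smoothing: str = "none"
    window_s: float = 0.05
    alpha: float = 0.3
    gap_fill_method: str = "linear"
    max_gap_s: float = 0.1
    resample_hz: float | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self):
        if self.smoothing not in ("none", "moving_average", "ema"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


def load_config(path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; detection thresholds live
    under a ``detection`` block (``onset_fraction``, ``onset_reference``,
    ``min_height_m``, ``stance_window_s``).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    det = DetectionConfig(**raw.pop("detection", {}))
    return AnalysisConfig(detection=det, **raw)


@dataclass
class TrialResult:
    """Output of one analyzed trial."""

    variables: CmjVariables
    events: JumpEvents
    side: str
    source_label: str


def analyze_trial(
    tset: tio.LandmarkTrajectorySet,
    config: AnalysisConfig = AnalysisConfig(),
    model: SegmentModel = DEFAULT_MODEL,
) -> TrialResult:
    """Run the full pipeline on one trial for one body side."""
    has_gaps = any(not np.all(np.isfinite(a)) for a in tset.landmarks.values())
    if has_gaps:
        tset = tio.gap_fill_set(tset, config.gap_fill_method, config.max_gap_s)
    if config.resample_hz is not None and config.resample_hz != tset.sampling_rate_hz:
        tset = tio.resample(tset, config.resample_hz)

    fs = tset.sampling_rate_hz
    if config.smoothing == "moving_average":
        smooth = lambda y: moving_average(y, config.window_s, fs)
    elif config.smoothing == "ema":
        smooth = lambda y: ema_filter(y, config.alpha)
    else:
        smooth = None
    side = config.side
    tset.require_side(side)
    # Take-off/touchdown come from the raw toe trace: threshold-crossing
    # detection is only degraded by temporal smoothing, which spreads the
    # crossing and autocorrelates the noise.
    toe_z = tset.z(f"{side}_big_toe").copy()
    if smooth is not None:
        tset = tset.map_coords(
            lambda arr: np.column_stack([smooth(arr[:, 0]), smooth(arr[:, 1])])
        )
    com = body_com(tset, side, model)
    events = detect_events(com, toe_z, config.detection)
    angles = {j: joint_angle(tset, j, side) for j in JOINT_TRIPLES}
    variables = compute_variables(events, com, toe_z, angles)
    return TrialResult(
        variables=variables, events=events, side=side, source_label=tset.source_label
    )
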