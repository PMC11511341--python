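"""Reading, writing and resampling of planar landmark trajectories.

A trial is a table of sagittal-plane (X = posterior–anterior, Z = vertical)
coordinates for up to 14 body landmarks (left/right x shoulder, hip, knee,
ankle, heel, small toe, big toe) sampled at a fixed rate.  Two tab-separated
dialects are supported:

* ``internal`` — the package's own minimal layout (normative for tests): a
  key/value header with ``FREQUENCY`` and ``MARKER_NAMES`` lines followed by
  one ``<name>_X``/``<name>_Z`` column pair per landmark.
* ``qualisys`` — a reader shim for the common motion-capture export layout
  (key/value header, then three columns X/Y/Z per marker; the mediolateral
  Y axis is discarded at read time).

Units are meters and seconds internally; the ``qualisys`` reader converts
millimetres when told so via ``units="mm"`` (the unit must be declared
explicitly, it is never guessed).

Missing samples are represented as NaN and must be filled (``gap_fill``)
before kinematic processing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import CmjkitError, GapError, SchemaError, TrajectoryParseError

logger = logging.getLogger(__name__)

SIDES = ("left", "right")
LANDMARK_NAMES = ("shoulder", "hip", "knee", "ankle", "heel", "small_toe", "big_toe")

#: Canonical landmark identifiers, e.g. ``"left_big_toe"``.
LANDMARK_IDS = tuple(f"{s}_{n}" for s in SIDES for n in LANDMARK_NAMES)

#: Built-in name synonyms (after lowercasing and ``_`` normalisation).
DEFAULT_ALIASES: dict[str, str] = {}
for _side, _abbr in (("left", "l"), ("right", "r")):
    for _name in LANDMARK_NAMES:
        _canon = f"{_side}_{_name}"
        _flat = _name.replace("_", "")
        DEFAULT_ALIASES[f"{_abbr}_{_name}"] = _canon
        DEFAULT_ALIASES[f"{_abbr}_{_flat}"] = _canon
        DEFAULT_ALIASES[f"{_side}_{_flat}"] = _canon
        DEFAULT_ALIASES[_canon] = _canon


def _normalize_name(raw: str, aliases: dict[str, str] | None = None) -> str | None:
    """Map a raw column/marker name to a canonical landmark id, or None."""
    key = "".join(c if c.isalnum() else "_" for c in raw.strip().lower())
    while "__" in key:
        key = key.replace("__", "_")
    key = key.strip("_")
    if aliases and key in aliases:
        return aliases[key]
    return DEFAULT_ALIASES.get(key)


@dataclass
class LandmarkTrajectorySet:
    """Equal-length planar coordinate series for a set of body landmarks.

    Attributes
    ----------
    sampling_rate_hz
        Sampling rate of every series, Hz.
    landmarks
        Map from canonical landmark id to an ``(n, 2)`` float array of
        ``(x_m, z_m)`` coordinates in meters.  NaN marks a missing sample.
    t0_s
        Time of the first sample, seconds.
    source_label
        Free-text provenance tag, e.g. ``"marker"`` or ``"markerless"``.
    recording_side
        ``"left"``, ``"right"`` or ``"both"``.
    """

    sampling_rate_hz: float
    landmarks: dict[str, np.ndarray]
    t0_s: float = 0.0
    source_label: str = ""
    recording_side: str = "both"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.landmarks:
            raise SchemaError("landmark map is empty")
        lengths = {len(np.asarray(v)) for v in self.landmarks.values()}
        if len(lengths) != 1:
            raise SchemaError(f"landmark series lengths differ: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise SchemaError("landmark series must have at least 2 samples")
        self.landmarks = {
            k: np.asarray(v, dtype=float).reshape(-1, 2) for k, v in self.landmarks.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.landmarks.values())))

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def series(self, landmark: str) -> np.ndarray:
        """Return the ``(n, 2)`` coordinate array for one landmark id."""
        try:
            return self.landmarks[landmark]
        except KeyError:
            raise SchemaError(f"landmark {landmark!r} not present") from None

    def z(self, landmark: str) -> np.ndarray:
        return self.series(landmark)[:, 1]

    def x(self, landmark: str) -> np.ndarray:
        return self.series(landmark)[:, 0]

    def has_side(self, side: str) -> bool:
        """True if all seven landmarks of ``side`` are present."""
        return all(f"{side}_{n}" in self.landmarks for n in LANDMARK_NAMES)

    def require_side(self, side: str) -> None:
        missing = [f"{side}_{n}" for n in LANDMARK_NAMES if f"{side}_{n}" not in self.landmarks]
        if missing:
            raise SchemaError(f"missing landmarks for side {side!r}: {', '.join(missing)}")

    def copy(self) -> "LandmarkTrajectorySet":
        return replace(self, landmarks={k: v.copy() for k, v in self.landmarks.items()})

    def map_coords(self, fn) -> "LandmarkTrajectorySet":
        """Return a copy with ``fn(arr) -> arr`` applied to every (n,2) series."""
        return replace(self, landmarks={k: np.asarray(fn(v), dtype=float) for k, v in self.landmarks.items()})


def _infer_side(landmarks: dict[str, np.ndarray]) -> str:
    left = all(f"left_{n}" in landmarks for n in LANDMARK_NAMES)
    right = all(f"right_{n}" in landmarks for n in LANDMARK_NAMES)
    if left and right:
        return "both"
    if left:
        return "left"
    if right:
        return "right"
    return "both"


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def read_trajectories(
    path,
    dialect: str = "internal",
    units: str | None = None,
    aliases: dict[str, str] | None = None,
    require_side: str | None = None,
) -> LandmarkTrajectorySet:
    """Read a tab-separated trajectory file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"internal"`` or ``"qualisys"`` (see module docstring).
    units
        ``"m"`` or ``"mm"``.  Mandatory for the ``qualisys`` dialect; for the
        internal dialect it overrides the file's ``UNITS`` header line.
    aliases
        Extra landmark-name synonyms (normalised name -> canonical id),
        e.g. loaded with :func:`load_alias_table`.
    require_side
        If ``"left"``/``"right"``/``"both"``, raise :class:`SchemaError`
        naming the absent landmarks when that side is incomplete.

    Unknown columns are ignored with a logged warning.
    """
    if dialect not in ("internal", "qualisys"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header: dict[str, list[str]] = {}
    i = 0
    for i, ln in enumerate(lines):
        cells = ln.split("\t")
        key = cells[0].strip()
        if key and not _is_number(key):
            header[key.upper()] = [c for c in cells[1:]]
        else:
            break
    else:
        i += 1
    data_lines = [ln for ln in lines[i:] if ln.strip()]

    if "FREQUENCY" not in header or not header["FREQUENCY"]:
        raise TrajectoryParseError(f"{path}: header lacks a FREQUENCY line")
    fs = float(header["FREQUENCY"][0])
    t0 = float(header.get("T0", ["0"])[0] or 0.0)
    source = (header.get("SOURCE", [""]) or [""])[0]
    file_units = (header.get("UNITS", [""]) or [""])[0].strip().lower() or None
    units = units or file_units
    if dialect == "qualisys" and units not in ("m", "mm"):
        raise TrajectoryParseError(
            f"{path}: the qualisys dialect requires an explicit unit declaration "
            "(units='m' or 'mm'); none found in header or arguments"
        )
    scale = 0.001 if units == "mm" else 1.0

    raw_names = header.get("MARKER_NAMES")
    if raw_names is None:
        raise TrajectoryParseError(f"{path}: header lacks a MARKER_NAMES line")
    raw_names = [n for n in raw_names if n.strip()]

    ncols_expected = None
    per_marker = 2 if dialect == "internal" else 3
    # Internal dialect carries an explicit column-header row; skip it if present.
    if data_lines and not _is_number(data_lines[0].split("\t")[0]):
        data_lines = data_lines[1:]
    if not data_lines:
        raise TrajectoryParseError(f"{path}: no data rows")

    rows = []
    for rn, ln in enumerate(data_lines):
        cells = ln.split("\t")
        vals = []
        for c in cells:
            c = c.strip()
            if c == "" or c.upper() in ("NAN", "NULL"):
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(c))
                except ValueError:
                    raise TrajectoryParseError(
                        f"{path}: non-numeric cell {c!r} in data row {rn + 1}"
                    ) from None
        if ncols_expected is None:
            ncols_expected = len(vals)
        elif len(vals) != ncols_expected:
            raise TrajectoryParseError(
                f"{path}: row {rn + 1} has {len(vals)} columns, expected {ncols_expected}"
            )
        rows.append(vals)
    data = np.asarray(rows, dtype=float)

    # The common export sometimes prepends frame and time columns.
    extra = data.shape[1] - per_marker * len(raw_names)
    if extra in (1, 2):
        data = data[:, extra:]
    elif extra != 0:
        raise TrajectoryParseError(
            f"{path}: {data.shape[1]} data columns do not match "
            f"{len(raw_names)} markers x {per_marker}"
        )

    landmarks: dict[str, np.ndarray] = {}
    for j, raw in enumerate(raw_names):
        canon = _normalize_name(raw, aliases)
        if canon is None:
            logger.warning("ignoring unknown landmark column %r", raw)
            continue
        block = data[:, per_marker * j : per_marker * (j + 1)]
        if dialect == "internal":
            xz = block
        else:  # X Y Z -> keep X and Z
            xz = block[:, [0, 2]]
        landmarks[canon] = xz * scale
    if not landmarks:
        raise SchemaError(f"{path}: no recognised landmark columns")

    tset = LandmarkTrajectorySet(
        sampling_rate_hz=fs,
        landmarks=landmarks,
        t0_s=t0,
        source_label=source,
        recording_side=_infer_side(landmarks),
    )
    if require_side in ("left", "right"):
        tset.require_side(require_side)
    elif require_side == "both":
        tset.require_side("left")
        tset.require_side("right")
    return tset


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_trajectories(tset: LandmarkTrajectorySet, path) -> str:
    """Write a trajectory set in the internal TSV dialect; returns ``path``.

    Columns are landmark-major (``<name>_X`` then ``<name>_Z``), one row per
    sample, preceded by a key/value header carrying the sampling rate and
    landmark names.
    """
    names = list(tset.landmarks)
    cols = np.hstack([tset.landmarks[n] for n in names])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"FREQUENCY\t{tset.sampling_rate_hz!r}\n")
        fh.write(f"T0\t{tset.t0_s!r}\n")
        fh.write("UNITS\tm\n")
        fh.write(f"SOURCE\t{tset.source_label}\n")
        fh.write("MARKER_NAMES\t" + "\t".join(names) + "\n")
        fh.write("\t".join(f"{n}_{ax}" for n in names for ax in ("X", "Z")) + "\n")
        for row in cols:
            fh.write("\t".join(f"{v:.9g}" if np.isfinite(v) else "NaN" for v in row) + "\n")
    return str(path)


def load_alias_table(path) -> dict[str, str]:
    """Load a YAML landmark alias table mapping raw names to canonical ids."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    table = {}
    for k, v in raw.items():
        if v not in LANDMARK_IDS:
            raise CmjkitError(f"alias target {v!r} is not a canonical landmark id")
        key = _normalize_name(k) or "".join(c if c.isalnum() else "_" for c in k.strip().lower())
        table[key] = v
    return table


# ---------------------------------------------------------------------------
# Gap filling and resampling
# ---------------------------------------------------------------------------

def gap_fill(
    series: np.ndarray,
    method: str = "linear",
    max_gap: int | None = None,
    poly_order: int = 3,
    poly_flank: int = 5,
) -> np.ndarray:
    """Fill interior NaN gaps of a 1-D series by interpolation.

    Interior gaps of at most ``max_gap`` consecutive missing samples are
    filled; ``method="linear"`` interpolates over the two flanking present
    samples, ``method="polynomial"`` fits a polynomial of ``poly_order``
    over up to ``poly_flank`` present samples on each side.  Present samples
    are never modified.  Leading/trailing gaps and over-long gaps raise
    :class:`GapError`.
    """
    y = np.asarray(series, dtype=float).copy()
    if y.ndim != 1:
        raise ValueError("gap_fill expects a 1-D series")
    missing = ~np.isfinite(y)
    if not missing.any():
        return y
    if missing[0] or missing[-1]:
        raise GapError("leading or trailing gap cannot be filled")
    if method not in ("linear", "polynomial"):
        raise ValueError(f"unknown gap-fill method {method!r}")

    idx = np.arange(len(y))
    # Locate contiguous missing runs.
    starts = np.flatnonzero(missing & ~np.r_[False, missing[:-1]])
    ends = np.flatnonzero(missing & ~np.r_[missing[1:], False])
    for s, e in zip(starts, ends):
        span = e - s + 1
        if max_gap is not None and span > max_gap:
            raise GapError(f"gap of {span} samples at [{s}, {e}] exceeds max_gap={max_gap}")
        if method == "linear":
            y[s : e + 1] = np.interp(idx[s : e + 1], [s - 1, e + 1], [y[s - 1], y[e + 1]])
        else:
            left = idx[max(0, s - poly_flank) : s]
            right = idx[e + 1 : e + 1 + poly_flank]
            support = np.concatenate([left, right])
            support = support[np.isfinite(y[support])]
            order = min(poly_order, len(support) - 1)
            coeffs = np.polyfit(support - s, y[support], order)
            y[s : e + 1] = np.polyval(coeffs, idx[s : e + 1] - s)
    return y


def gap_fill_set(
    tset: LandmarkTrajectorySet, method: str = "linear", max_gap_s: float = 0.1
) -> LandmarkTrajectorySet:
    """Apply :func:`gap_fill` to both coordinates of every landmark.

    ``max_gap_s`` is converted to samples at the set's rate (default 0.1 s:
    occlusions are brief; longer gaps indicate tracking failure).
    """
    max_gap = max(1, int(round(max_gap_s * tset.sampling_rate_hz)))
    return tset.map_coords(
        lambda arr: np.column_stack(
            [gap_fill(arr[:, 0], method, max_gap), gap_fill(arr[:, 1], method, max_gap)]
        )
    )


def resample(tset: LandmarkTrajectorySet, target_hz: float) -> LandmarkTrajectorySet:
    """Linearly resample every series onto a uniform grid at ``target_hz``.

    The new grid spans the original time range (the last partial interval is
    dropped).  Grid-identical input is reproduced exactly.
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    n = tset.n_samples
    duration = (n - 1) / tset.sampling_rate_hz
    m = int(np.floor(duration * target_hz + 1e-9)) + 1
    if m < 2:
        raise ValueError("target grid would have fewer than 2 samples")
    t_old = np.arange(n) / tset.sampling_rate_hz
    t_new = np.arange(m) / target_hz
    out = tset.map_coords(
        lambda arr: np.column_stack(
            [np.interp(t_new, t_old, arr[:, 0]), np.interp(t_new, t_old, arr[:, 1])]
        )
    )
    return replace(out, sampling_rate_hz=float(target_hz))


def align_pair(a, b, max_lag_s: float, sampling_rate_hz: float | None = None) -> float:
    """Residual time offset between two vertical CoM series, seconds.

    Returns the lag maximising the cross-correlation of the demeaned vertical
    series, restricted to ``[-max_lag_s, +max_lag_s]``.  Positive lag means
    ``b`` is delayed relative to ``a``.  Ties are broken toward the smallest
    ``|lag|``, then toward the negative lag.

    ``a``/``b`` may be ComTrajectory objects (their ``com_z_m`` is used) or
    plain 1-D arrays with ``sampling_rate_hz`` given.
    """
    za, fa = _vertical_of(a, sampling_rate_hz)
    zb, fb = _vertical_of(b, sampling_rate_hz)
    if fa != fb:
        raise ValueError("both trajectories must share one sampling rate")
    lag_max = int(round(max_lag_s * fa))
    n = min(len(za), len(zb))
    if n < 2 * lag_max:
        raise ValueError(f"series of {n} samples too short for max_lag of {lag_max} samples")
    za = za[:n] - np.mean(za[:n])
    zb = zb[:n] - np.mean(zb[:n])
    lags = np.arange(-lag_max, lag_max + 1)
    scores = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            scores[k] = float(np.dot(za[: n - lag], zb[lag:]))
        else:
            scores[k] = float(np.dot(za[-lag:], zb[: n + lag]))
    best = scores.max()
    tol = 1e-12 * max(1.0, abs(best))
    tied = lags[scores >= best - tol]
    lag = min(tied, key=lambda l: (abs(l), l))
    return float(lag) / fa


def _vertical_of(obj, fs):
    z = getattr(obj, "com_z_m", None)
    if z is not None:
        return np.asarray(z, float), float(obj.sampling_rate_hz)
    if fs is None:
        raise ValueError("sampling_rate_hz required for plain-array input")
    return np.asarray(obj, float), float(fs)
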