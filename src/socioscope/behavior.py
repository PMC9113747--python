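"""Behavioral segmentation from position tracking.

Derives, from raw tracking in the social-interaction arena:

- a 3 Hz speed series and running/stop state labels (running > 5 cm/s,
  stop < 1 cm/s, strict inequalities),
- zone occupancy (interaction zone > avoidance > peripheral > center
  precedence) and the social-interaction (SI) ratio,
- cage-oriented moving directions θ on a 1 s grid, where θ = 0° means
  moving straight toward the cage center and θ = 180° straight away,
- social approach / leaving bouts: runs of 1 s bins inside the cage half
  with θ < 90° (approach) or θ > 90° (leaving); a run strictly longer
  than 5 s yields one bout consisting of its first 5 s.

All binning uses half-open intervals [t, t + dt) on the session clock.
Invalid tracking frames are excluded from every computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import ArenaGeometry, TrackingSeries

__all__ = [
    "SpeedSeries",
    "SpeedStates",
    "DirectionSeries",
    "Bout",
    "BoutSet",
    "ZoneLabels",
    "compute_speed",
    "label_speed_states",
    "compute_zone_labels",
    "compute_si_ratio",
    "cage_direction_series",
    "detect_bouts",
    "travel_distance",
    "behavior_summary",
]

ZONES = ("IZ", "avoidance", "peripheral", "center")

#: nominal behavioral analysis rate after video downsampling
BEHAVIOR_RATE_HZ = 3.0


def _bin_first_valid(tracking: TrackingSeries, bin_s: float):
    """Index of the first valid frame in each [k*bin_s, (k+1)*bin_s) bin.

    Returns (bin_start_times, frame_index) with bins lacking a valid frame
    omitted, per the flag-and-exclude convention for noisy video frames.
    """
    t = tracking.time_s[tracking.valid]
    idx_valid = np.flatnonzero(tracking.valid)
    if len(t) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    n_bins = int(np.floor(t[-1] / bin_s)) + 1
    edges = np.arange(n_bins + 1) * bin_s
    # first valid frame at or after each bin edge
    first = np.searchsorted(t, edges[:-1], side="left")
    in_bin = (first < len(t)) & (t[np.minimum(first, len(t) - 1)] < edges[1:])
    bins = np.flatnonzero(in_bin)
    return edges[bins], idx_valid[first[bins]]


@dataclass
class SpeedSeries:
    """Instantaneous speed on the downsampled (3 Hz) grid."""

    bin_time_s: np.ndarray
    speed_cm_s: np.ndarray
    bin_s: float = 1.0 / BEHAVIOR_RATE_HZ


@dataclass
class SpeedStates:
    bin_time_s: np.ndarray
    state: np.ndarray  # "running" | "stop" | "neither"
    percent: dict[str, float] = field(default_factory=dict)

    def intervals(self, state: str, bin_s: float = 1.0 / BEHAVIOR_RATE_HZ) -> np.ndarray:
        starts = self.bin_time_s[self.state == state]
        return np.column_stack([starts, starts + bin_s])


@dataclass
class DirectionSeries:
    """Cage-oriented moving direction per 1 s bin.

    ``theta_deg`` is the unsigned angle (0–180°) between the within-bin
    displacement and the line from the bin-start position to the cage
    center; NaN where the displacement is zero or frames are missing.
    """

    bin_time_s: np.ndarray
    theta_deg: np.ndarray
    in_cage_half: np.ndarray
    bin_s: float = 1.0


@dataclass(frozen=True)
class Bout:
    state: str  # "approach" | "leaving"
    start_s: float
    end_s: float


@dataclass
class BoutSet:
    bouts: list[Bout]
    other: np.ndarray  # (n, 2) residual intervals
    session_span: tuple[float, float]

    def intervals(self, state: str) -> np.ndarray:
        sel = [(b.start_s, b.end_s) for b in self.bouts if b.state == state]
        return np.array(sel, dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [b.state for b in self.bouts],
                "start_s": [b.start_s for b in self.bouts],
                "end_s": [b.end_s for b in self.bouts],
            }
        )


@dataclass
class ZoneLabels:
    bin_time_s: np.ndarray
    zone: np.ndarray  # one of ZONES per bin
    bin_s: float
    occupancy_s: dict[str, float] = field(default_factory=dict)

    def intervals(self, zone: str) -> np.ndarray:
        starts = self.bin_time_s[self.zone == zone]
        return np.column_stack([starts, starts + self.bin_s])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_time_s": self.bin_time_s, "zone": self.zone})


def compute_speed(tracking: TrackingSeries, bin_s: float = 1.0 / BEHAVIOR_RATE_HZ) -> SpeedSeries:
    """Downsample tracking and compute instantaneous speed.

    Each bin takes its first valid frame; speed over a bin is the Euclidean
    displacement to the next occupied bin divided by the elapsed time.
    """
    times, idx = _bin_first_valid(tracking, bin_s)
    if len(idx) < 2:
        warnings.warn("fewer than 2 valid tracking frames; empty speed series")
        return SpeedSeries(np.empty(0), np.empty(0), bin_s)
    x = tracking.x_cm[idx]
    y = tracking.y_cm[idx]
    disp = np.hypot(np.diff(x), np.diff(y))
    dt = np.diff(times)
    return SpeedSeries(times[:-1], disp / dt, bin_s)


def label_speed_states(
    speed: SpeedSeries, run_thresh: float = 5.0, stop_thresh: float = 1.0
) -> SpeedStates:
    """Label each bin running (> run_thresh) / stop (< stop_thresh) / neither."""
    if not stop_thresh < run_thresh:
        raise ValueError("stop threshold must be below running threshold")
    state = np.full(len(speed.speed_cm_s), "neither", dtype=object)
    state[speed.speed_cm_s > run_thresh] = "running"
    state[speed.speed_cm_s < stop_thresh] = "stop"
    n = max(len(state), 1)
    pct = {s: 100.0 * np.count_nonzero(state == s) / n for s in ("running", "stop", "neither")}
    return SpeedStates(speed.bin_time_s, state.astype(str), pct)


def compute_zone_labels(
    tracking: TrackingSeries,
    geometry: ArenaGeometry,
    bin_s: float = 1.0 / BEHAVIOR_RATE_HZ,
) -> ZoneLabels:
    """Assign one zone per occupied bin with IZ > avoidance > peripheral > center."""
    times, idx = _bin_first_valid(tracking, bin_s)
    x = tracking.x_cm[idx]
    y = tracking.y_cm[idx]
    zone = np.full(len(idx), "center", dtype=object)
    zone[geometry.in_peripheral_band(x, y)] = "peripheral"
    for rect in geometry.avoidance_rects:
        zone[rect.contains(x, y)] = "avoidance"
    zone[geometry.iz_rect.contains(x, y)] = "IZ"
    occ = {z: bin_s * float(np.count_nonzero(zone == z)) for z in ZONES}
    return ZoneLabels(times, zone.astype(str), bin_s, occ)


def compute_si_ratio(occ_no_target_s: float, occ_target_s: float) -> float:
    """SI ratio = IZ time with target present / IZ time with target absent.

    Returns NaN (with a warning) when the no-target occupancy is zero.
    """
    if occ_no_target_s < 0:
        raise ValueError("occupancy must be non-negative")
    if occ_no_target_s == 0:
        warnings.warn("SI ratio undefined: zero IZ occupancy in the no-target session")
        return float("nan")
    return occ_target_s / occ_no_target_s


def cage_direction_series(
    tracking: TrackingSeries,
    geometry: ArenaGeometry,
    bin_s: float = 1.0,
) -> DirectionSeries:
    """Cage-oriented moving direction θ per bin.

    The moving direction is the displacement from the bin-start position to
    the next bin-start position; the reference vector points from the
    bin-start position to the cage center. Bins with zero displacement or a
    missing frame get θ = NaN and never qualify for bouts.
    """
    times, idx = _bin_first_valid(tracking, bin_s)
    if len(idx) == 0:
        return DirectionSeries(np.empty(0), np.empty(0), np.empty(0, dtype=bool), bin_s)
    x = tracking.x_cm[idx]
    y = tracking.y_cm[idx]
    # displacement to the *next consecutive* bin only
    consecutive = np.isclose(np.diff(times), bin_s)
    dx = np.where(consecutive, np.diff(x), np.nan)
    dy = np.where(consecutive, np.diff(y), np.nan)
    cx, cy = geometry.cage_center
    rx = cx - x[:-1]
    ry = cy - y[:-1]
    dot = dx * rx + dy * ry
    norm = np.hypot(dx, dy) * np.hypot(rx, ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norm > 0, dot / norm, np.nan)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    half = geometry.in_cage_half(x[:-1], y[:-1])
    return DirectionSeries(times[:-1], theta, half, bin_s)


def detect_bouts(direction: DirectionSeries, min_run_s: float = 5.0) -> BoutSet:
    """Extract approach/leaving bouts from the 1 s direction series.

    A candidate run is a maximal block of consecutive qualifying bins
    (inside the cage half, θ strictly < 90° for approach or > 90° for
    leaving; θ = 90° or NaN breaks runs). Runs strictly longer than
    ``min_run_s`` produce one bout spanning the run's first ``min_run_s``
    seconds; everything else is "other" time.
    """
    t = direction.bin_time_s
    bouts: list[Bout] = []
    for state, qual in (
        ("approach", direction.in_cage_half & (direction.theta_deg < 90.0)),
        ("leaving", direction.in_cage_half & (direction.theta_deg > 90.0)),
    ):
        # runs must also be contiguous in time (gaps from missing bins break them)
        i = 0
        n = len(qual)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and qual[j + 1]
                and np.isclose(t[j + 1] - t[j], direction.bin_s)
            ):
                j += 1
            run_dur = (j - i + 1) * direction.bin_s
            if run_dur > min_run_s:
                bouts.append(Bout(state, float(t[i]), float(t[i] + min_run_s)))
            i = j + 1
    bouts.sort(key=lambda b: b.start_s)

    span = (float(t[0]), float(t[-1] + direction.bin_s)) if len(t) else (0.0, 0.0)
    other: list[tuple[float, float]] = []
    cursor = span[0]
    for b in bouts:
        if b.start_s > cursor:
            other.append((cursor, b.start_s))
        cursor = b.end_s
    if cursor < span[1]:
        other.append((cursor, span[1]))
    return BoutSet(bouts, np.array(other, dtype=float).reshape(-1, 2), span)


def travel_distance(
    tracking: TrackingSeries,
    window: tuple[float, float] | None = None,
    bin_s: float = 1.0 / BEHAVIOR_RATE_HZ,
) -> float:
    """Total path length (cm) on the 3 Hz grid within [window_start, window_end)."""
    times, idx = _bin_first_valid(tracking, bin_s)
    if window is not None:
        keep = (times >= window[0]) & (times < window[1])
        times, idx = times[keep], idx[keep]
    if len(idx) < 2:
        return 0.0
    x = tracking.x_cm[idx]
    y = tracking.y_cm[idx]
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def behavior_summary(
    tracking: TrackingSeries, geometry: ArenaGeometry
) -> dict[str, float]:
    """Per-session behavioral scalars (IZ seconds, % running/stop, etc.)."""
    zones = compute_zone_labels(tracking, geometry)
    speed = compute_speed(tracking)
    states = label_speed_states(speed)
    total = zones.bin_s * len(zones.zone)
    return {
        "iz_s": zones.occupancy_s["IZ"],
        "avoidance_s": zones.occupancy_s["avoidance"],
        "pct_avoidance": 100.0 * zones.occupancy_s["avoidance"] / total if total else float("nan"),
        "pct_running": states.percent.get("running", float("nan")),
        "pct_stop": states.percent.get("stop", float("nan")),
        "travel_distance_cm": travel_distance(tracking),
    }
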