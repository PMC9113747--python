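"""Synthetic cohort generator with exact ground truth.

Emulates the structure of a social-interaction electrophysiology study:
paired 150 s no-target / target sessions in a 39.3 × 39.3 cm arena with a
mesh cage against one wall, two-region LFP (dmPFC, BLA) with
behavior-state-dependent band-limited oscillation amplitudes and a
directed dmPFC→BLA coupling, von-Mises phase-locked RS/FS spike trains,
and photostimulation sessions with pulse trains at 4/10/40 Hz.

Design choices:

- Trajectories are *scripted*: sessions are rendered from an explicit
  segment schedule (dwells, transits, straight approach/leaving runs
  aligned to the 1 s analysis grid), so behavioral ground truth is exact
  rather than probabilistic.
- Band oscillators are narrowband filtered noise, strictly band-limited
  in the frequency domain, so each nominal band's power is dominated by
  its own oscillator and round-trip power checks follow amplitude²
  arithmetic. A pure-tone mode exists for analytic tests.
- The BLA trace is a lagged, gained copy of the dmPFC band components
  plus independent noise, which induces one-way Geweke causality.

Every generated bundle passes :func:`socioscope.io_model.validate_session`
and is byte-reproducible under a fixed master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft
import scipy.signal
from scipy.special import i0

from .io_model import (
    ArenaGeometry,
    EventTable,
    LfpChannel,
    SessionBundle,
    SpikeTrain,
    TrackingSeries,
)

__all__ = [
    "BehaviorParams",
    "PopulationSpec",
    "LfpParams",
    "GroupSpec",
    "CohortSpec",
    "TrajectoryTruth",
    "SessionTruth",
    "MouseDataset",
    "gen_trajectory",
    "gen_lfp_pair",
    "gen_spike_trains",
    "gen_stim_session",
    "gen_cohort",
]

TRACKING_RATE_HZ = 15.0

#: Baseline oscillator amplitudes (µV RMS) per band. Slow rhythms dominate,
#: with a distinct 4–7 Hz rhythm and an induced 30–60 Hz rhythm, over a
#: white-noise floor.
DEFAULT_BAND_AMPS: dict[str, float] = {
    "1-4": 15.0,
    "4-7": 30.0,
    "7-10": 10.0,
    "10-30": 6.0,
    "30-60": 15.0,
    "60-100": 3.0,
}

BAND_EDGES: dict[str, tuple[float, float]] = {
    "1-4": (1.0, 4.0),
    "4-7": (4.0, 7.0),
    "7-10": (7.0, 10.0),
    "10-30": (10.0, 30.0),
    "30-60": (30.0, 60.0),
    "60-100": (60.0, 100.0),
}


# ---------------------------------------------------------------------------
# Trajectories


@dataclass
class BehaviorParams:
    """Scripted-session composition (durations in whole seconds)."""

    duration_s: float = 150.0
    n_cycles: int = 3
    approach_s: tuple[int, int] = (7, 9)  # sampled uniformly, inclusive
    leaving_s: tuple[int, int] = (7, 9)
    iz_dwell_s: int = 5  # per cycle, between approach and leaving
    avoidance_dwell_s: int = 4  # per cycle
    center_dwell_s: int = 5
    iz_dwell_no_target_s: int = 10
    avoidance_dwell_no_target_s: int = 5
    pause_s: int = 2
    transit_speed_cms: float = 6.5
    approach_path_cm: float = 10.5


@dataclass
class TrajectoryTruth:
    """Exact per-bin ground truth for one scripted trajectory."""

    state_per_s: np.ndarray  # label per 1 s bin
    bout_intervals: list[tuple[str, float, float]]  # (state, start, end) — first 5 s
    zone_per_bin: np.ndarray  # label per 1/3 s bin (position at bin start)
    zone_occupancy_s: dict[str, float]
    segment_schedule: list[tuple[str, float, float]]


def _zone_of(geometry: ArenaGeometry, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    zone = np.full(np.shape(x), "center", dtype=object)
    zone[geometry.in_peripheral_band(x, y)] = "peripheral"
    for rect in geometry.avoidance_rects:
        zone[rect.contains(x, y)] = "avoidance"
    zone[geometry.iz_rect.contains(x, y)] = "IZ"
    return zone.astype(str)


def _waypoints(geometry: ArenaGeometry) -> dict[str, tuple[float, float]]:
    # Canonical scripted locations for wall_side="top".
    cx, cy = geometry.cage_center
    h = geometry.box_height
    return {
        "staging": (cx, h / 2 + 1.5),  # just inside the cage half
        "near_cage": (cx, geometry.cage_rect.y0 - 1.3),
        "iz": (cx, geometry.iz_rect.y0 + 2.0),
        "avoidance": (4.5, 4.5),
        "center": (cx, 12.0),
    }


def gen_trajectory(
    geometry: ArenaGeometry,
    session_type: str,
    params: BehaviorParams | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[TrackingSeries, TrajectoryTruth]:
    """Render a scripted 15 Hz trajectory with exact behavioral ground truth.

    Target sessions contain ``n_cycles`` approach → IZ-dwell → leaving →
    avoidance-dwell cycles separated by stationary pauses; no-target
    sessions contain only dwells and transits. Approach runs move in a
    straight line through the cage center (θ = 0 on every 1 s bin) and
    leaving runs directly away (θ = 180°); both stay inside the cage half.
    """
    if geometry.wall_side != "top":
        raise NotImplementedError("scripted trajectories assume wall_side='top'")
    params = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    wp = _waypoints(geometry)

    # -- build the schedule: list of (kind, duration_s, end_position)
    segments: list[tuple[str, int, tuple[float, float]]] = []
    pos = wp["center"]

    def add_transit(target: tuple[float, float]) -> None:
        nonlocal pos
        dist = float(np.hypot(target[0] - pos[0], target[1] - pos[1]))
        if dist < 1e-9:
            return
        dur = max(int(np.ceil(dist / params.transit_speed_cms)), 1)
        segments.append(("transit", dur, target))
        pos = target

    def add_dwell(kind: str, dur: int) -> None:
        if dur > 0:
            segments.append((kind, dur, pos))

    def add_run(kind: str, dur: int) -> None:
        nonlocal pos
        cx, cy = geometry.cage_center
        direction = 1.0 if kind == "approach" else -1.0
        ux, uy = cx - pos[0], cy - pos[1]
        norm = float(np.hypot(ux, uy))
        ux, uy = ux / norm, uy / norm
        path = params.approach_path_cm
        end = (pos[0] + direction * ux * path, pos[1] + direction * uy * path)
        segments.append((kind, dur, end))
        pos = end

    add_dwell("dwell_center", params.center_dwell_s)
    if session_type == "target":
        for _ in range(params.n_cycles):
            add_transit(wp["staging"])
            add_dwell("pause", params.pause_s)
            add_run("approach", int(rng.integers(params.approach_s[0], params.approach_s[1] + 1)))
            add_dwell("dwell_iz", params.iz_dwell_s)
            add_run("leaving", int(rng.integers(params.leaving_s[0], params.leaving_s[1] + 1)))
            add_dwell("pause", params.pause_s)
            add_transit(wp["avoidance"])
            add_dwell("dwell_avoidance", params.avoidance_dwell_s)
            add_transit(wp["center"])
            add_dwell("dwell_center", params.center_dwell_s)
    else:
        add_transit(wp["iz"])
        add_dwell("dwell_iz", params.iz_dwell_no_target_s)
        add_transit(wp["avoidance"])
        add_dwell("dwell_avoidance", params.avoidance_dwell_no_target_s)
        add_transit(wp["center"])
        add_dwell("dwell_center", params.center_dwell_s)

    # -- render at 15 Hz, truncating to the session duration
    n_frames = int(round(params.duration_s * TRACKING_RATE_HZ))
    t = np.arange(n_frames) / TRACKING_RATE_HZ
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    state_per_s = np.full(int(params.duration_s), "dwell_center", dtype=object)
    bout_intervals: list[tuple[str, float, float]] = []
    schedule: list[tuple[str, float, float]] = []

    cursor = 0.0
    cur = wp["center"]
    for kind, dur, end in segments:
        if cursor >= params.duration_s:
            break
        t0, t1 = cursor, min(cursor + dur, params.duration_s)
        sl = slice(int(round(t0 * TRACKING_RATE_HZ)), int(round(t1 * TRACKING_RATE_HZ)))
        frac = (t[sl] - t0) / dur
        x[sl] = cur[0] + frac * (end[0] - cur[0])
        y[sl] = cur[1] + frac * (end[1] - cur[1])
        state_per_s[int(t0) : int(t1)] = kind
        schedule.append((kind, t0, t1))
        complete = t1 - t0 >= dur
        if kind in ("approach", "leaving") and complete and dur > 5:
            bout_intervals.append((kind, t0, t0 + 5.0))
        cursor = t1
        cur = end
    if cursor < params.duration_s:  # fill remainder with a stationary dwell
        sl = slice(int(round(cursor * TRACKING_RATE_HZ)), n_frames)
        x[sl], y[sl] = cur
        state_per_s[int(cursor) :] = "dwell_center" if session_type != "target" else "pause"
        schedule.append(("pause", cursor, params.duration_s))

    tracking = TrackingSeries(
        time_s=t, x_cm=x, y_cm=y, valid=np.ones(n_frames, dtype=bool)
    )
    # exact zone label per 1/3 s bin (position at bin start, frame 0 of each bin)
    starts = np.arange(0, n_frames, int(TRACKING_RATE_HZ / 3))
    zone = _zone_of(geometry, x[starts], y[starts])
    occupancy = {z: float(np.count_nonzero(zone == z)) / 3.0 for z in
                 ("IZ", "avoidance", "peripheral", "center")}
    truth = TrajectoryTruth(
        state_per_s=state_per_s.astype(str),
        bout_intervals=bout_intervals,
        zone_per_bin=zone,
        zone_occupancy_s=occupancy,
        segment_schedule=schedule,
    )
    return tracking, truth


# ---------------------------------------------------------------------------
# LFP


@dataclass
class LfpParams:
    fs_hz: float = 2000.0
    band_amps: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_AMPS))
    noise_sd: float = 10.0
    coupling_gain: float = 0.7
    coupling_lag_s: float = 0.010
    mode: str = "narrowband"  # or "tone"


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS noise strictly band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = scipy.fft.rfft(white)
    f = scipy.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = scipy.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _tone(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    f0 = 0.5 * (band[0] + band[1])
    phase = rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.cos(2 * np.pi * f0 * np.arange(n) / fs + phase)


def _state_gain_series(
    n: int,
    fs: float,
    state_intervals: dict[str, np.ndarray] | None,
    gains: dict[str, float] | None,
) -> np.ndarray:
    g = np.ones(n)
    if not state_intervals or not gains:
        return g
    t_idx = np.arange(n)
    for state, gain in gains.items():
        ivs = state_intervals.get(state)
        if ivs is None:
            continue
        for s, e in np.asarray(ivs, dtype=float).reshape(-1, 2):
            g[(t_idx >= int(round(s * fs))) & (t_idx < int(round(e * fs)))] = gain
    return g


def gen_lfp_pair(
    duration_s: float,
    params: LfpParams | None = None,
    state_intervals: dict[str, np.ndarray] | None = None,
    state_gains: dict[str, dict[str, float]] | None = None,
    session_gains: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[LfpChannel, LfpChannel, dict[str, np.ndarray]]:
    """Generate a coupled dmPFC/BLA channel pair.

    ``session_gains`` multiplies a band's amplitude over the whole session
    (e.g. the target-session 4–7 Hz multiplier); ``state_gains[band][state]``
    multiplies it within that state's intervals. The BLA channel is the sum
    of the dmPFC band components delayed by ``coupling_lag_s`` and scaled by
    ``coupling_gain``, plus independent white noise (one-way dmPFC→BLA
    influence). Returns (dmpfc, bla, dmpfc band components).
    """
    params = params or LfpParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * params.fs_hz))
    make = _narrowband_noise if params.mode == "narrowband" else _tone

    components: dict[str, np.ndarray] = {}
    for band, amp in params.band_amps.items():
        edges = BAND_EDGES[band]
        base = make(rng, n, params.fs_hz, edges)
        gain = amp * (session_gains or {}).get(band, 1.0)
        series = gain * _state_gain_series(
            n, params.fs_hz, state_intervals, (state_gains or {}).get(band)
        )
        components[band] = series * base

    summed = np.sum(list(components.values()), axis=0)
    dmpfc = summed + params.noise_sd * rng.standard_normal(n)
    lag = int(round(params.coupling_lag_s * params.fs_hz))
    lagged = np.zeros(n)
    if lag < n:
        lagged[lag:] = summed[: n - lag]
    bla = params.coupling_gain * lagged + params.noise_sd * rng.standard_normal(n)

    ch_a = LfpChannel("dmPFC", params.fs_hz, dmpfc.astype(np.float32), "dmPFC_0")
    ch_b = LfpChannel("BLA", params.fs_hz, bla.astype(np.float32), "BLA_0")
    return ch_a, ch_b, components


# ---------------------------------------------------------------------------
# Spikes


@dataclass
class PopulationSpec:
    """Per-mouse spiking population with state-dependent phase locking."""

    n_rs: int = 6
    n_fs: int = 2
    rs_rate_hz: tuple[float, float] = (2.0, 8.0)
    fs_rate_hz: tuple[float, float] = (12.0, 25.0)
    rs_width_ms: tuple[float, float] = (0.7, 1.1)
    fs_width_ms: tuple[float, float] = (0.2, 0.45)
    #: von-Mises concentration per class per behavioral state
    kappa: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "RS": {"approach": 0.3, "leaving": 0.3, "other": 0.3},
            "FS": {"approach": 0.3, "leaving": 1.5, "other": 0.5},
        }
    )


def gen_spike_trains(
    phase_deg: np.ndarray,
    fs_hz: float,
    duration_s: float,
    spec: PopulationSpec | None = None,
    state_intervals: dict[str, np.ndarray] | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[list[SpikeTrain], dict[str, dict]]:
    """Inhomogeneous-Poisson spike trains phase-locked to ``phase_deg``.

    Spike rate is ``r0 · exp(κ_state · cos(φ(t) − φ_pref)) / I0(κ_state)``,
    simulated by thinning, so the mean rate within each state stays ≈ r0.
    Returns the trains plus per-unit ground truth (class, rate, width,
    preferred phase, κ per state).
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    phi = np.radians(np.asarray(phase_deg, dtype=float))
    n_samples = len(phi)

    state_code = np.full(n_samples, "other", dtype=object)
    if state_intervals:
        idx = np.arange(n_samples)
        for state, ivs in state_intervals.items():
            for s, e in np.asarray(ivs, dtype=float).reshape(-1, 2):
                state_code[(idx >= int(round(s * fs_hz))) & (idx < int(round(e * fs_hz)))] = state

    trains: list[SpikeTrain] = []
    truth: dict[str, dict] = {}
    unit_plan = [("RS", i) for i in range(spec.n_rs)] + [("FS", i) for i in range(spec.n_fs)]
    for cls, i in unit_plan:
        if cls == "RS":
            r0 = rng.uniform(*spec.rs_rate_hz)
            width = rng.uniform(*spec.rs_width_ms)
        else:
            r0 = rng.uniform(*spec.fs_rate_hz)
            width = rng.uniform(*spec.fs_width_ms)
        kappas = spec.kappa[cls]
        phi_pref = rng.uniform(-np.pi, np.pi)

        lam_max = r0 * max(np.exp(k) / i0(k) for k in kappas.values())
        n_cand = rng.poisson(lam_max * duration_s)
        cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
        samp = np.clip(np.round(cand * fs_hz).astype(int), 0, n_samples - 1)
        k_at = np.array([kappas.get(s, kappas["other"]) for s in state_code[samp]])
        lam = r0 * np.exp(k_at * np.cos(phi[samp] - phi_pref)) / i0(k_at)
        keep = rng.uniform(0.0, 1.0, n_cand) < lam / lam_max
        unit_id = f"{cls.lower()}{i:02d}"
        trains.append(SpikeTrain(unit_id, cand[keep], baseline_rate_hz=r0, spike_width_ms=width))
        truth[unit_id] = {
            "class": cls,
            "rate_hz": r0,
            "width_ms": width,
            "phi_pref_deg": float(np.degrees(phi_pref)),
            "kappa": dict(kappas),
        }
    return trains, truth


# ---------------------------------------------------------------------------
# Sessions, stimulation and cohorts


@dataclass
class SessionTruth:
    trajectory: TrajectoryTruth | None
    state_intervals: dict[str, np.ndarray]
    session_gains: dict[str, float]
    state_gains: dict[str, dict[str, float]]
    units: dict[str, dict]
    components: dict[str, np.ndarray] | None = None


@dataclass
class GroupSpec:
    n_mice: int
    #: whole-session amplitude multipliers applied in the *target* session
    target_session_gains: dict[str, float] = field(
        default_factory=lambda: {"4-7": 1.10, "30-60": 0.97}
    )
    #: within-target-session amplitude multipliers per behavioral state
    state_gains: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"4-7": {"approach": 0.8, "leaving": 1.0}}
    )
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    lfp: LfpParams = field(default_factory=LfpParams)


@dataclass
class CohortSpec:
    groups: dict[str, GroupSpec]
    master_seed: int = 0
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    with_spikes: bool = True

    @classmethod
    def default(cls, n_per_group: int = 10, master_seed: int = 0) -> "CohortSpec":
        """Two-group study: a control-like and a socially deficient group.

        The deficient group carries a larger target-session 4–7 Hz gain,
        no approach-related 4–7 Hz suppression, and more avoidance dwell /
        less IZ dwell (SI ratio < 1).
        """
        wt = GroupSpec(n_mice=n_per_group)
        ko = GroupSpec(
            n_mice=n_per_group,
            target_session_gains={"4-7": 1.25, "30-60": 0.97},
            state_gains={},
            behavior=replace(
                BehaviorParams(), iz_dwell_s=2, avoidance_dwell_s=10, n_cycles=2
            ),
        )
        return cls(groups={"wild_type": wt, "shank3_ko": ko}, master_seed=master_seed)


@dataclass
class MouseDataset:
    mouse_id: str
    group: str
    sessions: dict[str, SessionBundle]
    truth: dict[str, SessionTruth]


def _bout_state_intervals(truth: TrajectoryTruth) -> dict[str, np.ndarray]:
    out: dict[str, list[list[float]]] = {"approach": [], "leaving": []}
    for state, s, e in truth.bout_intervals:
        out[state].append([s, e])
    return {k: np.array(v, dtype=float).reshape(-1, 2) for k, v in out.items()}


def gen_mouse(
    mouse_id: str,
    group: str,
    gspec: GroupSpec,
    geometry: ArenaGeometry,
    seed: np.random.SeedSequence | int,
    with_spikes: bool = True,
) -> MouseDataset:
    """Generate one mouse's paired no-target/target sessions."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(6)
    sessions: dict[str, SessionBundle] = {}
    truths: dict[str, SessionTruth] = {}
    for k, label in enumerate(("no_target", "target")):
        rng_traj = np.random.default_rng(seeds[k])
        tracking, traj_truth = gen_trajectory(geometry, label, gspec.behavior, rng_traj)
        is_target = label == "target"
        state_ivs = _bout_state_intervals(traj_truth) if is_target else {}
        session_gains = gspec.target_session_gains if is_target else {}
        state_gains = gspec.state_gains if is_target else {}
        ch_a, ch_b, comps = gen_lfp_pair(
            gspec.behavior.duration_s,
            gspec.lfp,
            state_intervals=state_ivs,
            state_gains=state_gains,
            session_gains=session_gains,
            seed=np.random.default_rng(seeds[2 + k]),
        )
        spikes: list[SpikeTrain] = []
        units_truth: dict[str, dict] = {}
        if with_spikes and is_target:
            # true 4–7 Hz phase from the generated component (peak ↔ 0°)
            comp = comps["4-7"]
            phase = np.degrees(np.angle(scipy.signal.hilbert(comp)))
            spikes, units_truth = gen_spike_trains(
                phase,
                gspec.lfp.fs_hz,
                gspec.behavior.duration_s,
                gspec.population,
                state_intervals=state_ivs,
                seed=np.random.default_rng(seeds[4]),
            )
        events = EventTable(
            np.array([0.0]), np.array([gspec.behavior.duration_s]), ["session"]
        )
        sessions[label] = SessionBundle(
            mouse_id=mouse_id,
            group=group,
            session_label=label,
            geometry=geometry,
            tracking=tracking,
            lfp=[ch_a, ch_b],
            spikes=spikes,
            events=events,
        )
        truths[label] = SessionTruth(
            trajectory=traj_truth,
            state_intervals=state_ivs,
            session_gains=dict(session_gains),
            state_gains={k2: dict(v) for k2, v in state_gains.items()},
            units=units_truth,
        )
    return MouseDataset(mouse_id, group, sessions, truths)


def gen_cohort(spec: CohortSpec) -> list[MouseDataset]:
    """Generate a full cohort; per-mouse streams derive from the master seed."""
    master = np.random.SeedSequence(spec.master_seed)
    total = sum(g.n_mice for g in spec.groups.values())
    seeds = master.spawn(total)
    cohort: list[MouseDataset] = []
    i = 0
    for group, gspec in spec.groups.items():
        for j in range(gspec.n_mice):
            cohort.append(
                gen_mouse(
                    f"{group}_{j:02d}",
                    group,
                    gspec,
                    spec.geometry,
                    seeds[i],
                    with_spikes=spec.with_spikes,
                )
            )
            i += 1
    return cohort


def gen_stim_session(
    protocol_hz: float,
    response_map: dict[str, float] | None = None,
    duration_s: float = 600.0,
    epoch_s: float = 2.0,
    period_s: float = 30.0,
    lfp_params: LfpParams | None = None,
    geometry: ArenaGeometry | None = None,
    mouse_id: str = "stim_00",
    group: str = "pv_cre_chr2",
    seed: int | np.random.Generator | None = 0,
) -> tuple[SessionBundle, SessionTruth]:
    """Photostimulation target session: pulse trains in periodic epochs.

    ``protocol_hz`` ∈ {4, 10, 40}; pulses within each epoch have width equal
    to half the inter-pulse interval. Epochs of ``epoch_s`` recur every
    ``period_s`` (first onset at ``period_s``). LFP band amplitudes are
    multiplied by ``response_map`` during epochs.
    """
    if protocol_hz not in (4.0, 10.0, 40.0):
        raise ValueError("protocol must be 4, 10 or 40 Hz")
    response_map = response_map or {}
    geometry = geometry or ArenaGeometry()
    lfp_params = lfp_params or LfpParams()
    rng = np.random.default_rng(seed)

    onsets = np.arange(period_s, duration_s - epoch_s + 1e-9, period_s)
    epochs = np.column_stack([onsets, onsets + epoch_s])
    pulse_width = 0.5 / protocol_hz
    pulse_onsets = np.concatenate(
        [o + np.arange(int(round(epoch_s * protocol_hz))) / protocol_hz for o in onsets]
    )

    events = EventTable(
        onset_s=np.concatenate([[0.0], onsets, pulse_onsets]),
        duration_s=np.concatenate(
            [[duration_s], np.full(len(onsets), epoch_s), np.full(len(pulse_onsets), pulse_width)]
        ),
        label=["session"] + ["stim_epoch"] * len(onsets) + ["stim_pulse"] * len(pulse_onsets),
    )
    order = np.argsort(events.onset_s, kind="stable")
    events = EventTable(
        events.onset_s[order], events.duration_s[order], [events.label[i] for i in order]
    )

    behavior = BehaviorParams(duration_s=duration_s, n_cycles=0)
    tracking, traj_truth = gen_trajectory(geometry, "no_target", behavior, rng)
    state_ivs = {"stim": epochs}
    state_gains = {band: {"stim": g} for band, g in response_map.items()}
    ch_a, ch_b, comps = gen_lfp_pair(
        duration_s,
        lfp_params,
        state_intervals=state_ivs,
        state_gains=state_gains,
        seed=rng,
    )
    bundle = SessionBundle(
        mouse_id=mouse_id,
        group=group,
        session_label="target",
        geometry=geometry,
        tracking=tracking,
        lfp=[ch_a, ch_b],
        spikes=[],
        events=events,
    )
    truth = SessionTruth(
        trajectory=traj_truth,
        state_intervals=state_ivs,
        session_gains={},
        state_gains=state_gains,
        units={},
    )
    return bundle, truth
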