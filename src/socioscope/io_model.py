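"""Session data model and on-disk session-directory format.

A recording session is stored as one directory:

``session.json``
    metadata (mouse id, group, session label), arena geometry, per-stream
    sampling rates and the LFP channel map.
``tracking.csv``
    columns ``time_s,x_cm,y_cm,valid`` — position samples on the video clock.
``lfp_<region>.f32`` / ``lfp_<region>.csv``
    channel-interleaved little-endian float32 samples (µV), or an
    inspectable CSV dialect (``time_s,ch0,ch1,...``) declared in
    ``session.json``.
``spikes.csv``
    columns ``unit_id,time_s`` — sorted spike times per unit.
``units.csv``
    columns ``unit_id,baseline_rate_hz,spike_width_ms``.
``events.csv``
    columns ``onset_s,duration_s,label`` — session markers and
    photostimulation epochs/pulses.

Conventions used throughout the package: the session clock starts at 0 s,
positions are in cm with the origin at the arena's bottom-left corner
(x rightward, y upward), LFP samples are in µV, and all events/bins use
half-open interval semantics ``[onset, onset + duration)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "Rect",
    "ArenaGeometry",
    "TrackingSeries",
    "LfpChannel",
    "SpikeTrain",
    "EventTable",
    "SessionBundle",
    "ValidationIssue",
    "ValidationReport",
    "read_session",
    "write_session",
    "validate_session",
]

WallSide = Literal["top", "bottom", "left", "right"]

#: Groups that may appear in session metadata.
GROUPS = (
    "wild_type",
    "shank3_ko",
    "defeated",
    "defeated_control",
    "pv_cre_chr2",
    "pv_cre_yfp",
)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in arena coordinates (cm)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x, y):
        """Vectorized inclusive point-in-rectangle test."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def as_list(self) -> list[float]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass(frozen=True)
class ArenaGeometry:
    """Square social-interaction arena with a mesh cage against one wall.

    Zones (all in cm, arena coordinates):

    - ``cage_rect``: footprint of the mesh cage, centered against ``wall_side``.
    - ``iz_rect``: interaction zone, a rectangle extending around the cage.
    - ``avoidance_rects``: two square zones projecting from the corners of
      the wall opposite the cage.
    - peripheral band: strip of width ``peripheral_band_width`` along the
      walls (membership decided after IZ/avoidance precedence).
    """

    box_width: float = 39.3
    box_height: float = 39.3
    cage_rect: Rect = field(default=None)  # type: ignore[assignment]
    iz_rect: Rect = field(default=None)  # type: ignore[assignment]
    avoidance_rects: tuple[Rect, Rect] = field(default=None)  # type: ignore[assignment]
    peripheral_band_width: float = 5.0
    wall_side: WallSide = "top"

    def __post_init__(self) -> None:
        # Fill in the default study geometry when zone rectangles are omitted:
        # a 6.5 cm x 10 cm cage centered against the top wall, a 14.5 x 24 cm
        # interaction zone extending 8 cm around it, and 9 x 9 cm avoidance
        # squares in the two corners opposite the cage.
        if self.cage_rect is None or self.iz_rect is None or self.avoidance_rects is None:
            if self.wall_side != "top":
                raise ValueError(
                    "default zone rectangles are only generated for wall_side='top'"
                )
            w, h = self.box_width, self.box_height
            cage = Rect((w - 10.0) / 2, h - 6.5, (w + 10.0) / 2, h)
            iz = Rect((w - 24.0) / 2, h - 14.5, (w + 24.0) / 2, h)
            avoid = (Rect(0.0, 0.0, 9.0, 9.0), Rect(w - 9.0, 0.0, w, 9.0))
            object.__setattr__(self, "cage_rect", self.cage_rect or cage)
            object.__setattr__(self, "iz_rect", self.iz_rect or iz)
            object.__setattr__(self, "avoidance_rects", self.avoidance_rects or avoid)

    @property
    def cage_center(self) -> tuple[float, float]:
        return self.cage_rect.center

    def in_cage_half(self, x, y):
        """Points in the half of the arena containing the cage.

        The boundary (the midline) is inclusive toward the cage side.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.wall_side == "top":
            return y >= self.box_height / 2
        if self.wall_side == "bottom":
            return y <= self.box_height / 2
        if self.wall_side == "right":
            return x >= self.box_width / 2
        return x <= self.box_width / 2

    def in_peripheral_band(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        b = self.peripheral_band_width
        return (
            (x <= b)
            | (x >= self.box_width - b)
            | (y <= b)
            | (y >= self.box_height - b)
        )

    def to_dict(self) -> dict:
        return {
            "box_width": self.box_width,
            "box_height": self.box_height,
            "cage_rect": self.cage_rect.as_list(),
            "iz_rect": self.iz_rect.as_list(),
            "avoidance_rects": [r.as_list() for r in self.avoidance_rects],
            "peripheral_band_width": self.peripheral_band_width,
            "wall_side": self.wall_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            box_width=d["box_width"],
            box_height=d["box_height"],
            cage_rect=Rect(*d["cage_rect"]),
            iz_rect=Rect(*d["iz_rect"]),
            avoidance_rects=tuple(Rect(*r) for r in d["avoidance_rects"]),
            peripheral_band_width=d["peripheral_band_width"],
            wall_side=d["wall_side"],
        )


@dataclass
class TrackingSeries:
    """Position tracking samples. Invalid frames are flagged, never dropped."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    valid: np.ndarray
    frame_rate_hz: float = 15.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackingSeries):
            return NotImplemented
        return (
            np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.x_cm, other.x_cm)
            and np.array_equal(self.y_cm, other.y_cm)
            and np.array_equal(self.valid, other.valid)
            and self.frame_rate_hz == other.frame_rate_hz
        )


@dataclass
class LfpChannel:
    """One continuous LFP channel (µV)."""

    region: str
    fs_hz: float
    samples: np.ndarray
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if not self.channel_id:
            self.channel_id = f"{self.region}_0"

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs_hz

    def __eq__(self, other) -> bool:
        if not isinstance(other, LfpChannel):
            return NotImplemented
        return (
            self.region == other.region
            and self.fs_hz == other.fs_hz
            and self.channel_id == other.channel_id
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit plus waveform features."""

    unit_id: str
    spike_times_s: np.ndarray
    baseline_rate_hz: float
    spike_width_ms: float

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and np.array_equal(self.spike_times_s, other.spike_times_s)
            and self.baseline_rate_hz == other.baseline_rate_hz
            and self.spike_width_ms == other.spike_width_ms
        )


SESSION_LABELS = ("no_target", "target")


@dataclass
class EventTable:
    """Rows of (onset_s, duration_s, label), half-open intervals."""

    onset_s: np.ndarray
    duration_s: np.ndarray
    label: list[str]

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        self.label = list(self.label)

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(np.empty(0), np.empty(0), [])

    def __len__(self) -> int:
        return len(self.label)

    def select(self, label: str) -> "EventTable":
        idx = [i for i, l in enumerate(self.label) if l == label]
        return EventTable(
            self.onset_s[idx], self.duration_s[idx], [self.label[i] for i in idx]
        )

    def intervals(self, label: str | None = None) -> np.ndarray:
        """(n, 2) array of [start, end) intervals, optionally for one label."""
        tab = self if label is None else self.select(label)
        return np.column_stack([tab.onset_s, tab.onset_s + tab.duration_s])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onset_s, "duration_s": self.duration_s, "label": self.label}
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return (
            np.array_equal(self.onset_s, other.onset_s)
            and np.array_equal(self.duration_s, other.duration_s)
            and self.label == other.label
        )


@dataclass
class SessionBundle:
    """One recording session: tracking, LFP, spikes, events, metadata."""

    mouse_id: str
    group: str
    session_label: str  # "no_target" | "target"
    geometry: ArenaGeometry
    tracking: TrackingSeries
    lfp: list[LfpChannel] = field(default_factory=list)
    spikes: list[SpikeTrain] = field(default_factory=list)
    events: EventTable = field(default_factory=EventTable.empty)
    extra: dict = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for ch in self.lfp:
            if ch.region not in seen:
                seen.append(ch.region)
        return seen

    def channels(self, region: str) -> list[LfpChannel]:
        chans = [ch for ch in self.lfp if ch.region == region]
        if not chans:
            raise KeyError(
                f"session {self.mouse_id}/{self.session_label} has no LFP "
                f"channels for region {region!r}"
            )
        return chans

    @property
    def duration_s(self) -> float:
        cands = [float(self.tracking.time_s[-1]) if len(self.tracking) else 0.0]
        cands += [ch.duration_s for ch in self.lfp]
        return max(cands)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented

        def chan_key(ch: LfpChannel):
            return (ch.region, ch.channel_id)

        return (
            self.mouse_id == other.mouse_id
            and self.group == other.group
            and self.session_label == other.session_label
            and self.geometry == other.geometry
            and self.tracking == other.tracking
            # channel/unit order is not semantically meaningful
            and sorted(self.lfp, key=chan_key) == sorted(other.lfp, key=chan_key)
            and sorted(self.spikes, key=lambda s: s.unit_id)
            == sorted(other.spikes, key=lambda s: s.unit_id)
            and self.events == other.events
        )


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationIssue:
    severity: Literal["ERROR", "WARNING"]
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, message))  # type: ignore[arg-type]

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "ERROR"]

    @property
    def ok(self) -> bool:
        return not self.issues

    def raise_on_error(self) -> None:
        if self.errors:
            msgs = "; ".join(i.message for i in self.errors)
            raise ValueError(f"session validation failed: {msgs}")


#: Highest analysis frequency (Hz); LFP sampling must exceed twice this.
MAX_ANALYSIS_FREQ_HZ = 250.0


def validate_session(
    bundle: SessionBundle, max_analysis_freq_hz: float = MAX_ANALYSIS_FREQ_HZ
) -> ValidationReport:
    """Check every data-model invariant; reports issues, never raises.

    Out-of-bounds tracking positions are additionally flagged invalid in
    place (the frames are retained so the on-disk record is unchanged).
    """
    rep = ValidationReport()
    geo = bundle.geometry

    if bundle.group not in GROUPS:
        rep.add("WARNING", f"unknown group label {bundle.group!r}")
    if bundle.session_label not in SESSION_LABELS:
        rep.add("ERROR", f"unknown session label {bundle.session_label!r}")

    # Geometry invariants
    box = Rect(0.0, 0.0, geo.box_width, geo.box_height)
    for name, rect in [("cage_rect", geo.cage_rect), ("iz_rect", geo.iz_rect)] + [
        (f"avoidance_rects[{i}]", r) for i, r in enumerate(geo.avoidance_rects)
    ]:
        inside = (
            rect.x0 >= box.x0 - 1e-9
            and rect.y0 >= box.y0 - 1e-9
            and rect.x1 <= box.x1 + 1e-9
            and rect.y1 <= box.y1 + 1e-9
        )
        if not inside:
            rep.add("ERROR", f"geometry: {name} exceeds arena bounds")
    czx, czy = geo.cage_center
    if not geo.iz_rect.contains(czx, czy):
        rep.add("ERROR", "geometry: iz_rect does not cover the cage front")

    # Tracking invariants
    tr = bundle.tracking
    if len(tr):
        if np.any(np.diff(tr.time_s) <= 0):
            rep.add("ERROR", "tracking: timestamps not strictly increasing")
        oob = tr.valid & ~(
            (tr.x_cm >= 0)
            & (tr.x_cm <= geo.box_width)
            & (tr.y_cm >= 0)
            & (tr.y_cm <= geo.box_height)
        )
        if np.any(oob):
            rep.add(
                "WARNING",
                f"tracking: {int(oob.sum())} frame(s) out of bounds; flagged invalid",
            )
            tr.valid = tr.valid & ~oob

    # LFP invariants
    for ch in bundle.lfp:
        if ch.fs_hz <= 2 * max_analysis_freq_hz:
            rep.add(
                "ERROR",
                f"lfp {ch.channel_id}: fs={ch.fs_hz} Hz violates Nyquist for "
                f"{max_analysis_freq_hz} Hz analyses",
            )
        if not np.all(np.isfinite(ch.samples)):
            rep.add("ERROR", f"lfp {ch.channel_id}: non-finite samples")

    # Spike invariants
    span = bundle.duration_s
    for st in bundle.spikes:
        if st.n_spikes and np.any(np.diff(st.spike_times_s) < 0):
            rep.add("ERROR", f"spikes {st.unit_id}: spike times not sorted")
        elif st.n_spikes and (
            st.spike_times_s[0] < 0 or st.spike_times_s[-1] > span + 1e-9
        ):
            rep.add("WARNING", f"spikes {st.unit_id}: spike times outside session span")
        if st.baseline_rate_hz < 0:
            rep.add("ERROR", f"spikes {st.unit_id}: negative baseline rate")

    # Event invariants
    ev = bundle.events
    if len(ev):
        if np.any(np.diff(ev.onset_s) < 0):
            rep.add("ERROR", "events: onsets not sorted")
        if np.any(ev.duration_s < 0):
            rep.add("ERROR", "events: negative duration")
        marks = ev.select("session")
        ivs = marks.intervals()
        for i in range(len(ivs) - 1):
            if ivs[i + 1, 0] < ivs[i, 1]:
                rep.add("ERROR", "events: overlapping session markers")
    return rep


# ---------------------------------------------------------------------------
# Reading / writing


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing session file: {path}")
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory into a validated :class:`SessionBundle`."""
    path = Path(path)
    meta_path = _require(path / "session.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise IOError(f"corrupt session.json in {path}: {exc}") from exc

    geometry = ArenaGeometry.from_dict(meta["geometry"])

    tr_df = pd.read_csv(_require(path / "tracking.csv"), float_precision="round_trip")
    tracking = TrackingSeries(
        time_s=tr_df["time_s"].to_numpy(),
        x_cm=tr_df["x_cm"].to_numpy(),
        y_cm=tr_df["y_cm"].to_numpy(),
        valid=tr_df["valid"].to_numpy(dtype=bool),
        frame_rate_hz=float(meta.get("tracking_rate_hz", 15.0)),
    )

    lfp: list[LfpChannel] = []
    for region, chan_meta in meta.get("lfp", {}).items():
        fs = float(chan_meta["fs_hz"])
        ids = list(chan_meta["channel_ids"])
        dialect = chan_meta.get("dialect", "f32")
        if dialect == "f32":
            fname = _require(path / f"lfp_{region}.f32")
            raw = np.fromfile(fname, dtype="<f4")
            if len(ids) and len(raw) % len(ids):
                raise IOError(
                    f"corrupt {fname.name}: {len(raw)} samples not divisible by "
                    f"{len(ids)} channels"
                )
            data = raw.reshape(-1, len(ids))
        elif dialect == "csv":
            fname = _require(path / f"lfp_{region}.csv")
            df = pd.read_csv(fname, float_precision="round_trip")
            data = df[[f"ch{i}" for i in range(len(ids))]].to_numpy(dtype=np.float32)
        else:
            raise IOError(f"unknown LFP dialect {dialect!r} for region {region}")
        for i, cid in enumerate(ids):
            lfp.append(LfpChannel(region=region, fs_hz=fs, samples=data[:, i], channel_id=cid))

    spikes: list[SpikeTrain] = []
    units_path = path / "units.csv"
    if units_path.exists():
        units_df = pd.read_csv(units_path, dtype={"unit_id": str}, float_precision="round_trip")
        spikes_df = pd.read_csv(
            path / "spikes.csv", dtype={"unit_id": str}, float_precision="round_trip"
        ) if (path / "spikes.csv").exists() else pd.DataFrame(columns=["unit_id", "time_s"])
        by_unit = dict(tuple(spikes_df.groupby("unit_id", sort=False)))
        for row in units_df.itertuples(index=False):
            grp = by_unit.get(row.unit_id)
            times = grp["time_s"].to_numpy() if grp is not None else np.empty(0)
            spikes.append(
                SpikeTrain(
                    unit_id=str(row.unit_id),
                    spike_times_s=times,
                    baseline_rate_hz=float(row.baseline_rate_hz),
                    spike_width_ms=float(row.spike_width_ms),
                )
            )

    events = EventTable.empty()
    ev_path = path / "events.csv"
    if ev_path.exists():
        ev_df = pd.read_csv(ev_path, float_precision="round_trip")
        if len(ev_df):
            events = EventTable(
                ev_df["onset_s"].to_numpy(),
                ev_df["duration_s"].to_numpy(),
                [str(l) for l in ev_df["label"]],
            )

    bundle = SessionBundle(
        mouse_id=str(meta["mouse_id"]),
        group=str(meta["group"]),
        session_label=str(meta["session_label"]),
        geometry=geometry,
        tracking=tracking,
        lfp=lfp,
        spikes=spikes,
        events=events,
    )
    validate_session(bundle).raise_on_error()
    return bundle


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write the canonical session-directory layout (deterministic ordering)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    lfp_meta: dict[str, dict] = {}
    for region in bundle.regions:
        chans = bundle.channels(region)
        fs = {ch.fs_hz for ch in chans}
        if len(fs) != 1:
            raise ValueError(f"mixed sampling rates within region {region}")
        lfp_meta[region] = {
            "fs_hz": chans[0].fs_hz,
            "channel_ids": [ch.channel_id for ch in chans],
            "dialect": "f32",
        }
        data = np.column_stack([ch.samples for ch in chans]).astype("<f4")
        data.tofile(path / f"lfp_{region}.f32")

    meta = {
        "mouse_id": bundle.mouse_id,
        "group": bundle.group,
        "session_label": bundle.session_label,
        "tracking_rate_hz": bundle.tracking.frame_rate_hz,
        "geometry": bundle.geometry.to_dict(),
        "lfp": lfp_meta,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    tr = bundle.tracking
    pd.DataFrame(
        {"time_s": tr.time_s, "x_cm": tr.x_cm, "y_cm": tr.y_cm, "valid": tr.valid}
    ).to_csv(path / "tracking.csv", index=False)

    pd.DataFrame(
        {
            "unit_id": [st.unit_id for st in bundle.spikes],
            "baseline_rate_hz": [st.baseline_rate_hz for st in bundle.spikes],
            "spike_width_ms": [st.spike_width_ms for st in bundle.spikes],
        }
    ).to_csv(path / "units.csv", index=False)
    if bundle.spikes:
        spk = pd.concat(
            [
                pd.DataFrame({"unit_id": st.unit_id, "time_s": st.spike_times_s})
                for st in bundle.spikes
            ],
            ignore_index=True,
        )
    else:
        spk = pd.DataFrame({"unit_id": pd.Series(dtype=str), "time_s": pd.Series(dtype=float)})
    spk.to_csv(path / "spikes.csv", index=False)

    bundle.events.to_frame().to_csv(path / "events.csv", index=False)
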