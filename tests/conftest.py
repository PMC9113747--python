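import numpy as np
import pytest

from socioscope.io_model import (
    ArenaGeometry,
    EventTable,
    LfpChannel,
    SessionBundle,
    SpikeTrain,
    TrackingSeries,
)


@pytest.fixture(scope="session")
def geometry() -> ArenaGeometry:
    return ArenaGeometry()


def make_tracking(duration_s=10.0, rate=15.0, x0=10.0, y0=10.0, vx=0.0, vy=0.0):
    t = np.arange(int(duration_s * rate)) / rate
    return TrackingSeries(
        time_s=t,
        x_cm=x0 + vx * t,
        y_cm=y0 + vy * t,
        valid=np.ones(len(t), dtype=bool),
    )


def make_lfp(signal, fs=2000.0, region="dmPFC", channel_id="dmPFC_0"):
    return LfpChannel(region=region, fs_hz=fs, samples=signal, channel_id=channel_id)


def sine_lfp(freq_hz, amplitude=1.0, duration_s=10.0, fs=2000.0, phase=0.0, **kw):
    t = np.arange(int(duration_s * fs)) / fs
    return make_lfp(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs=fs, **kw)


@pytest.fixture
def minimal_bundle(geometry) -> SessionBundle:
    """150 s no-target session with one LFP channel and no spike trains."""
    rng = np.random.default_rng(0)
    return SessionBundle(
        mouse_id="m00",
        group="wild_type",
        session_label="no_target",
        geometry=geometry,
        tracking=make_tracking(duration_s=150.0),
        lfp=[make_lfp(rng.standard_normal(150 * 2000).astype(np.float32))],
        spikes=[],
        events=EventTable(np.array([0.0]), np.array([150.0]), ["session"]),
    )


def random_bundle(seed: int, geometry: ArenaGeometry) -> SessionBundle:
    """Small random-but-valid session bundle for round-trip property tests."""
    rng = np.random.default_rng(seed)
    dur = float(rng.integers(2, 6))
    n_tr = int(dur * 15)
    tracking = TrackingSeries(
        time_s=np.arange(n_tr) / 15.0,
        x_cm=rng.uniform(1, 38, n_tr),
        y_cm=rng.uniform(1, 38, n_tr),
        valid=rng.uniform(size=n_tr) > 0.1,
    )
    lfp = []
    for region, n_ch in (("dmPFC", int(rng.integers(1, 3))), ("BLA", int(rng.integers(0, 2)))):
        for i in range(n_ch):
            lfp.append(
                LfpChannel(
                    region,
                    2000.0,
                    rng.standard_normal(int(dur * 2000)).astype(np.float32),
                    f"{region}_{i}",
                )
            )
    spikes = []
    for i in range(int(rng.integers(0, 4))):
        n_sp = int(rng.integers(0, 30))
        spikes.append(
            SpikeTrain(
                f"u{i:02d}",
                np.sort(rng.uniform(0, dur, n_sp)),
                baseline_rate_hz=float(rng.uniform(1, 20)),
                spike_width_ms=float(rng.uniform(0.2, 1.2)),
            )
        )
    events = EventTable(np.array([0.0]), np.array([dur]), ["session"])
    return SessionBundle(
        mouse_id=f"m{seed:03d}",
        group="wild_type",
        session_label="no_target",
        geometry=geometry,
        tracking=tracking,
        lfp=lfp,
        spikes=spikes,
        events=events,
    )
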