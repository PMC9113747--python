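"""End-to-end property checks of the analysis chain on synthetic data.

Each function builds its inputs with the synthetic generator (or a direct
construction), runs the corresponding analysis operation, and returns the
measured quantity together with its theoretical expectation. They back
both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import scipy.signal
from scipy.special import i0, i1

from . import behavior as bhv
from . import pipeline as ppl
from . import spectral as spc
from . import spikes as spk
from . import synthetic as syn
from .io_model import ArenaGeometry, LfpChannel, TrackingSeries

__all__ = [
    "mvl_estimator_check",
    "shuffle_type_i_rate",
    "power_ratio_recovery",
    "coherence_checks",
    "granger_directionality",
    "behavior_exactness",
    "stim_evoked_checks",
    "direction_recovery",
    "determinism_check",
]


def _seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# 1. MVL estimator calibration


def mvl_estimator_check(seed: int = 0, n: int = 50_000, kappa: float = 1.0) -> dict:
    """MVL of von-Mises phases vs the Bessel-ratio expectation I1(κ)/I0(κ),
    plus the exact perfectly-locked and perfectly-uniform limits."""
    rng = np.random.default_rng(seed)
    phases = np.degrees(rng.vonmises(0.0, kappa, size=n))
    mvl, _ = spk.mean_vector_length(phases)
    locked, _ = spk.mean_vector_length(np.full(1000, 37.0))
    uniform, _ = spk.mean_vector_length(np.arange(0.0, 360.0, 30.0) - 180.0)
    return {
        "mvl": mvl,
        "expected": float(i1(kappa) / i0(kappa)),
        "mvl_locked": locked,
        "mvl_uniform": uniform,
        "n": n,
    }


# ---------------------------------------------------------------------------
# 2. Shuffle-test type-I calibration


def shuffle_type_i_rate(
    seed: int = 0,
    n_units: int = 500,
    n_spikes: int = 100,
    n_shuffle: int = 1000,
    duration_s: float = 150.0,
) -> dict:
    """Fraction of phase-independent Poisson units called significant.

    Spike times are uniform (homogeneous Poisson conditioned on count) and
    carry no phase preference, so the nominal rate is 5%.
    """
    rng_lfp, rng_units = _seeds(seed, 2)
    ch, _, _ = syn.gen_lfp_pair(duration_s, syn.LfpParams(fs_hz=1000.0), seed=rng_lfp)
    phase = spk.instantaneous_phase(ch, (4.0, 7.0))
    n_sig = 0
    for _ in range(n_units):
        times = np.sort(rng_units.uniform(0.0, duration_s, n_spikes))
        res = spk.shuffle_null(times, phase, n_shuffle=n_shuffle, seed=rng_units)
        n_sig += int(res.significant)
    return {"significant_fraction": n_sig / n_units, "nominal": 0.05, "n": n_units}


# ---------------------------------------------------------------------------
# 3. Session power-ratio recovery


def power_ratio_recovery(
    seed: int = 0, amp_ratio: float = 1.2, duration_s: float = 150.0
) -> dict:
    """Target/no-target 4–7 Hz power ratio for a known amplitude ratio.

    Expectation is 100·amp_ratio² (power ∝ amplitude²); a Welch-periodogram
    band-ratio provides an independent cross-check on the same signals.
    """
    rng_a, rng_b = _seeds(seed, 2)
    band = (4.0, 7.0)
    no_target, _, _ = syn.gen_lfp_pair(duration_s, seed=rng_a)
    target, _, _ = syn.gen_lfp_pair(
        duration_s, session_gains={"4-7": amp_ratio}, seed=rng_b
    )
    freqs = spc.log_freq_grid()
    freqs = freqs[(freqs >= band[0]) & (freqs < band[1])]
    tf_t = spc.morlet_power(target, freqs)
    tf_n = spc.morlet_power(no_target, freqs)
    ratio = spc.session_power_ratio(tf_t, tf_n, band)

    def welch_band(ch: LfpChannel) -> float:
        f, pxx = scipy.signal.welch(
            np.asarray(ch.samples, float), fs=ch.fs_hz, nperseg=int(4 * ch.fs_hz)
        )
        sel = (f >= band[0]) & (f < band[1])
        return float(pxx[sel].mean())

    oracle = 100.0 * welch_band(target) / welch_band(no_target)
    return {
        "ratio_pct": ratio,
        "expected_pct": 100.0 * amp_ratio**2,
        "periodogram_pct": oracle,
        "n": int(duration_s * target.fs_hz),
    }


# ---------------------------------------------------------------------------
# 4. Coherence analytics


def coherence_checks(seed: int = 0, duration_s: float = 150.0, fs: float = 2000.0) -> dict:
    """Identical channels → magnitude coherence 1 everywhere; adding
    independent noise of equal power → magnitude-squared coherence 1/2."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    x = rng.standard_normal(n)
    a = LfpChannel("dmPFC", fs, x, "a")
    twin = LfpChannel("BLA", fs, x.copy(), "b")
    noisy = LfpChannel("BLA", fs, x + rng.standard_normal(n), "c")

    coh_same = spc.coherence_spectrum(a, twin)
    sel = (coh_same.freqs_hz >= 1.0) & (coh_same.freqs_hz <= 70.0)
    coh_noise = spc.coherence_spectrum(a, noisy)
    msc = coh_noise.msc[sel]
    return {
        "identical_min": float(coh_same.coherence[sel].min()),
        "msc_equal_noise": float(msc.mean()),
        "magnitude_equal_noise": float(coh_noise.coherence[sel].mean()),
        "n": n,
    }


# ---------------------------------------------------------------------------
# 5. Granger directionality


def _simulate_var1(
    rng: np.random.Generator, n: int, coupling: float, ar: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    burn = 500
    x = np.zeros(n + burn)
    y = np.zeros(n + burn)
    ex = rng.standard_normal(n + burn)
    ey = rng.standard_normal(n + burn)
    for t in range(1, n + burn):
        x[t] = ar * x[t - 1] + ex[t]
        y[t] = ar * y[t - 1] + coupling * x[t - 1] + ey[t]
    return x[burn:], y[burn:]


def granger_directionality(
    seed: int = 0, n: int = 30_000, coupling: float = 0.5, fs: float = 200.0
) -> dict:
    """Directed spectral causality on a VAR(1) with one-way x→y coupling.

    The reference value is the Geweke spectrum evaluated at the *true*
    coefficients; the reverse direction and a decoupled pair should both be
    near zero.
    """
    rng_c, rng_0 = _seeds(seed, 2)
    band = (4.0, 7.0)
    x, y = _simulate_var1(rng_c, n, coupling)
    a = LfpChannel("dmPFC", fs, x, "x")
    b = LfpChannel("BLA", fs, y, "y")
    gc = spc.granger_spectrum(a, b)

    true_coefs = np.array([[[0.8, 0.0], [coupling, 0.8]]])
    f_true, _ = spc.geweke_spectrum_from_var(true_coefs, np.eye(2), gc.freqs_hz, fs)
    sel = (gc.freqs_hz >= band[0]) & (gc.freqs_hz < band[1])
    closed_form = float(f_true[sel].mean())

    x0, y0 = _simulate_var1(rng_0, n, 0.0)
    gc0 = spc.granger_spectrum(
        LfpChannel("dmPFC", fs, x0, "x0"), LfpChannel("BLA", fs, y0, "y0")
    )
    return {
        "forward": gc.band_mean(band, "a_to_b"),
        "closed_form": closed_form,
        "reverse": gc.band_mean(band, "b_to_a"),
        "null_forward": gc0.band_mean(band, "a_to_b"),
        "null_reverse": gc0.band_mean(band, "b_to_a"),
        "var_order": gc.var_order,
        "n": n,
    }


# ---------------------------------------------------------------------------
# 6. Behavior segmentation exactness


def _piecewise_speed_tracking(segments: list[tuple[float, float]]) -> TrackingSeries:
    """15 Hz trajectory with piecewise-constant speed (cm/s), bouncing in x."""
    rate = syn.TRACKING_RATE_HZ
    per_bin = int(rate / 3)  # frames per 1/3 s bin
    bin_speeds = np.concatenate([np.full(int(d * 3), v) for d, v in segments])
    x_frames: list[np.ndarray] = []
    pos, direction = 8.0, 1.0
    for v in bin_speeds:
        step = direction * v / 3.0  # bounce only at bin boundaries
        if not 5.0 <= pos + step <= 35.0:
            direction = -direction
            step = -step
        x_frames.append(pos + step * np.arange(per_bin) / per_bin)
        pos += step
    x_frames.append(np.array([pos]))  # final bin-start position
    x = np.concatenate(x_frames)
    n = len(x)
    t = np.arange(n) / rate
    return TrackingSeries(t, x, np.full(n, 10.0), np.ones(n, dtype=bool))


def behavior_exactness(seed: int = 0) -> dict:
    """Scripted trajectories must be recovered exactly by the behavior module.

    Checks bout boundaries, zone occupancy and SI ratio against the
    generator's ground truth, and speed-state fractions / travel distance
    against construction values (half-open bin semantics).
    """
    geometry = ArenaGeometry()
    rng_t, rng_n = _seeds(seed, 2)
    params = syn.BehaviorParams()
    tracking_t, truth_t = syn.gen_trajectory(geometry, "target", params, rng_t)
    tracking_n, truth_n = syn.gen_trajectory(geometry, "no_target", params, rng_n)

    direction = bhv.cage_direction_series(tracking_t, geometry)
    bouts = bhv.detect_bouts(direction)
    detected = [(b.state, b.start_s, b.end_s) for b in bouts.bouts]
    expected = [(s, float(t0), float(t1)) for s, t0, t1 in truth_t.bout_intervals]
    bout_err = 0.0 if detected == expected else float("inf")

    zones = bhv.compute_zone_labels(tracking_t, geometry)
    zone_err = max(
        abs(zones.occupancy_s[z] - truth_t.zone_occupancy_s[z])
        for z in ("IZ", "avoidance", "peripheral", "center")
    )

    zones_n = bhv.compute_zone_labels(tracking_n, geometry)
    si = bhv.compute_si_ratio(zones_n.occupancy_s["IZ"], zones.occupancy_s["IZ"])
    si_expected = truth_t.zone_occupancy_s["IZ"] / truth_n.zone_occupancy_s["IZ"]

    # piecewise-constant speed construction: 60 s at 0.5, 30 s at 6, 60 s at 3 cm/s
    segs = [(60.0, 0.5), (30.0, 6.0), (60.0, 3.0)]
    tr = _piecewise_speed_tracking(segs)
    speed = bhv.compute_speed(tr)
    states = bhv.label_speed_states(speed)
    n_bins = len(speed.speed_cm_s)  # one fewer than positions
    exp_stop = 100.0 * (60 * 3) / n_bins
    exp_run = 100.0 * (30 * 3) / n_bins
    dist = bhv.travel_distance(tr)
    exp_dist = (60 * 3) * 0.5 / 3 + (30 * 3) * 6 / 3 + (60 * 3) * 3 / 3

    return {
        "n_bouts": len(detected),
        "bout_boundary_error_s": bout_err,
        "zone_occupancy_error_s": float(zone_err),
        "si_ratio": si,
        "si_expected": si_expected,
        "pct_stop": states.percent["stop"],
        "pct_stop_expected": exp_stop,
        "pct_running": states.percent["running"],
        "pct_running_expected": exp_run,
        "travel_cm": dist,
        "travel_cm_expected": exp_dist,
    }


# ---------------------------------------------------------------------------
# 7. Stimulation-evoked power change


def stim_evoked_checks(
    seed: int = 0,
    duration_s: float = 600.0,
    epoch_s: float = 10.0,
    n_stim: int = 7,
    n_control: int = 4,
) -> dict:
    """30–60 Hz amplitude ×1.5 during stim epochs → +125%; identity → ~0%.

    Mirrors the study design: 10 min sessions with 10 s stimulation epochs
    every 30 s, averaged over a stimulated group and a (no-response)
    control group.
    """
    rngs = _seeds(seed, n_stim + n_control)
    band = (30.0, 60.0)
    freqs = spc.log_freq_grid()
    freqs = freqs[(freqs >= band[0]) & (freqs < band[1])]

    def run(response: dict, rng) -> float:
        bundle, _ = syn.gen_stim_session(
            40.0, response, duration_s=duration_s, epoch_s=epoch_s, seed=rng
        )
        tf = spc.morlet_power(bundle.channels("dmPFC")[0], freqs)
        return spc.stim_evoked_power_change(tf, bundle.events, band)

    change = float(np.mean([run({"30-60": 1.5}, r) for r in rngs[:n_stim]]))
    identity = float(np.mean([run({}, r) for r in rngs[n_stim:]]))
    return {
        "change_pct": change,
        "expected_pct": 100.0 * (1.5**2 - 1.0),
        "identity_change_pct": identity,
        "n": n_stim + n_control,
    }


# ---------------------------------------------------------------------------
# 8. End-to-end direction recovery


def _fast_config(seed: int) -> ppl.AnalysisConfig:
    # coarser frequency grid and fewer shuffles keep replicate cohorts cheap;
    # the contrasts under test involve band means and MVL differences only
    return ppl.AnalysisConfig(
        summary_bands=("4-7",),
        freq_points_per_decade=20,
        coherence=False,
        granger=False,
        regions=("dmPFC",),
        n_shuffle=200,
        seed=seed,
    )


def direction_recovery(
    seed: int = 0, n_replicates: int = 20, n_per_group: int = 10
) -> dict:
    """Fraction of replicate cohorts recovering each configured effect
    direction with one-sided p < 0.05.

    Effects: larger target-session 4–7 Hz power ratio in the deficient
    group; lower approach- than leaving-state 4–7 Hz z in the control
    group; higher FS phase locking during leaving than approach.
    """
    wins = {"group_ratio": 0, "approach_z": 0, "fs_mvl": 0}
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    for r in range(n_replicates):
        rs = int(rep_seeds[r])
        spec = syn.CohortSpec.default(n_per_group=n_per_group, master_seed=rs)
        cohort = syn.gen_cohort(spec)
        tables = ppl.run_full_analysis(cohort, _fast_config(rs))
        df = tables.mouse_summary

        wt = df[df["group"] == "wild_type"]
        ko = df[df["group"] == "shank3_ko"]
        res = ppl.two_sample_compare(
            wt["dmPFC_ratio_4-7"].to_numpy(),
            ko["dmPFC_ratio_4-7"].to_numpy(),
            paired=False,
            alternative="less",
        )
        wins["group_ratio"] += int(res["p"] < 0.05)

        res = ppl.two_sample_compare(
            wt["dmPFC_z_4-7_approach"].to_numpy(),
            wt["dmPFC_z_4-7_leaving"].to_numpy(),
            paired=True,
            alternative="less",
        )
        wins["approach_z"] += int(res["p"] < 0.05)

        pl = tables.phase_locking
        fs_units = pl[(pl["unit_class"] == "FS") & (~pl["excluded"])]
        piv = fs_units.pivot_table(
            index=["mouse_id", "unit_id"], columns="state", values="mvl"
        )
        res = ppl.two_sample_compare(
            piv["approach"].to_numpy(), piv["leaving"].to_numpy(),
            paired=True, alternative="less",
        )
        wins["fs_mvl"] += int(res["p"] < 0.05)
    return {
        **{k: v / n_replicates for k, v in wins.items()},
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# 9. Determinism


def determinism_check(seed: int, out_dir: str | Path) -> dict:
    """Identical seeds and config must give byte-identical result CSVs."""
    out_dir = Path(out_dir)
    names = ["mouse_summary.csv", "phase_locking.csv", "group_stats.csv"]
    runs = []
    for tag in ("run1", "run2"):
        spec = syn.CohortSpec.default(n_per_group=1, master_seed=seed)
        cohort = syn.gen_cohort(spec)
        tables = ppl.run_full_analysis(cohort, _fast_config(seed))
        d = out_dir / tag
        ppl.make_report(tables, d, _fast_config(seed), plots=False)
        runs.append(d)
    identical = all(
        filecmp.cmp(runs[0] / n, runs[1] / n, shallow=False)
        for n in names
        if (runs[0] / n).exists() or (runs[1] / n).exists()
    )
    return {"identical": bool(identical), "n": 2}
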