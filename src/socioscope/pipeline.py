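"""Cohort-level orchestration, group statistics and report tables.

Runs behavior → spectral → spikes per session, aggregates electrodes to
one value per mouse *before* any group statistic, and applies the study's
statistical conventions: paired t-tests for within-mouse contrasts,
Mann-Whitney U for independent group contrasts, one-way ANOVA for
three-group screens, Bonferroni correction, and an F-test variance screen
that routes non-normal-looking data to the nonparametric test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bhv
from . import spectral as spc
from . import spikes as spk
from .io_model import SessionBundle, read_session
from .synthetic import MouseDataset

__all__ = [
    "AnalysisConfig",
    "ResultTables",
    "run_full_analysis",
    "analyze_mouse",
    "bonferroni",
    "two_sample_compare",
    "group_compare",
    "make_report",
]


@dataclass
class AnalysisConfig:
    """Resolved analysis parameters; every run logs this object."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(spc.DEFAULT_BANDS)
    )
    summary_bands: tuple[str, ...] = ("4-7", "30-60")
    freq_points_per_decade: int = 60
    fmin_hz: float = 1.0
    fmax_hz: float = 250.0
    omega0: float = 6.0
    power_bin_s: float = 0.010
    zscore_baseline: str = "target_only"  # or "both_sessions"
    spike_band: str = "4-7"
    n_shuffle: int = 1000
    seed: int = 0
    var_max_order: int = 20
    coherence: bool = True
    granger: bool = True
    regions: tuple[str, ...] | None = None  # None: analyze all present
    alpha: float = 0.05

    def freqs(self) -> np.ndarray:
        return spc.log_freq_grid(self.fmin_hz, self.fmax_hz, self.freq_points_per_decade)

    def band_freqs(self) -> np.ndarray:
        """Grid restricted to the summary bands (plus interior points)."""
        f = self.freqs()
        keep = np.zeros(len(f), dtype=bool)
        for name in self.summary_bands:
            lo, hi = self.bands[name]
            keep |= (f >= lo) & (f < hi)
        return f[keep]

    def to_json(self) -> str:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        d = json.loads(text)
        d["bands"] = {k: tuple(v) for k, v in d.get("bands", {}).items()}
        d["summary_bands"] = tuple(d.get("summary_bands", ("4-7", "30-60")))
        return cls(**d)


@dataclass
class ResultTables:
    mouse_summary: pd.DataFrame
    phase_locking: pd.DataFrame
    group_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    errors: list[str] = field(default_factory=list)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m·p)."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("need p in [0,1] and m >= 1")
    return min(1.0, m * p)


def two_sample_compare(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool,
    alternative: str = "two-sided",
    normality_alpha: float = 0.05,
) -> dict:
    """Two-sample comparison with an F-test variance screen.

    Equal-looking variances (F-test p ≥ alpha) use the parametric route
    (paired t / two-sample t); otherwise the nonparametric counterpart
    (Wilcoxon signed-rank / Mann-Whitney U).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)] if not paired else a
    b = b[np.isfinite(b)] if not paired else b
    if paired:
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
    if min(len(a), len(b)) < 2:
        return {"test": "skipped", "statistic": np.nan, "p": np.nan, "n": min(len(a), len(b))}

    # F test of the variance ratio as the normality/parametric screen
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f_stat, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f_stat, dfn, dfd = vb / va if va > 0 else np.inf, len(b) - 1, len(a) - 1
    f_p = 2 * min(stats.f.sf(f_stat, dfn, dfd), stats.f.cdf(f_stat, dfn, dfd))
    parametric = f_p >= normality_alpha

    if paired:
        if parametric:
            res = stats.ttest_rel(a, b, alternative=alternative)
            name = "paired_t"
        else:
            res = stats.wilcoxon(a, b, alternative=alternative)
            name = "wilcoxon"
    else:
        if parametric:
            res = stats.ttest_ind(a, b, alternative=alternative)
            name = "t_ind"
        else:
            res = stats.mannwhitneyu(a, b, alternative=alternative)
            name = "mann_whitney_u"
    return {
        "test": name,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(min(len(a), len(b))),
        "variance_f_p": float(f_p),
    }


# ---------------------------------------------------------------------------
# Per-mouse analysis


def _session_band_power(
    bundle: SessionBundle, region: str, config: AnalysisConfig, freqs: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-band power series averaged across the region's electrodes."""
    out: dict[str, list[np.ndarray]] = {b: [] for b in config.summary_bands}
    for ch in bundle.channels(region):
        tf = spc.morlet_power(ch, freqs, config.omega0, config.power_bin_s)
        for b in config.summary_bands:
            out[b].append(spc.band_power_series(tf, config.bands[b]))
    return {b: np.mean(v, axis=0) for b, v in out.items()}


def analyze_mouse(
    sessions: dict[str, SessionBundle],
    config: AnalysisConfig,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Analyze one mouse's paired sessions.

    Returns (summary row, per-unit phase-locking table). Electrode-level
    quantities are averaged within the mouse before anything else.
    """
    seed = config.seed if seed is None else seed
    target = sessions["target"]
    no_target = sessions.get("no_target")
    geometry = target.geometry
    freqs = config.band_freqs()
    row: dict = {"mouse_id": target.mouse_id, "group": target.group}

    # --- behavior
    zones_t = bhv.compute_zone_labels(target.tracking, geometry)
    row.update({f"target_{k}": v for k, v in bhv.behavior_summary(target.tracking, geometry).items()})
    if no_target is not None:
        zones_n = bhv.compute_zone_labels(no_target.tracking, geometry)
        row["si_ratio"] = bhv.compute_si_ratio(
            zones_n.occupancy_s["IZ"], zones_t.occupancy_s["IZ"]
        )
    direction = bhv.cage_direction_series(target.tracking, geometry)
    bouts = bhv.detect_bouts(direction)
    row["n_approach_bouts"] = len(bouts.intervals("approach"))
    row["n_leaving_bouts"] = len(bouts.intervals("leaving"))

    # --- spectral power per region
    state_ivs = {
        "approach": bouts.intervals("approach"),
        "leaving": bouts.intervals("leaving"),
    }
    analysis_regions = [
        r for r in target.regions if config.regions is None or r in config.regions
    ]
    for region in analysis_regions:
        power_t = _session_band_power(target, region, config, freqs)
        power_n = (
            _session_band_power(no_target, region, config, freqs)
            if no_target is not None and region in no_target.regions
            else None
        )
        bin_t = np.arange(len(next(iter(power_t.values())))) * config.power_bin_s
        for b in config.summary_bands:
            if power_n is not None:
                denom = power_n[b].mean()
                row[f"{region}_ratio_{b}"] = (
                    100.0 * power_t[b].mean() / denom if denom > 0 else np.nan
                )
            if config.zscore_baseline == "both_sessions" and power_n is not None:
                baseline = np.concatenate([power_n[b], power_t[b]])
            else:
                baseline = power_t[b]
            z = spc.zscore_power(power_t[b], baseline)
            means = spc.state_mean_power(z, bin_t, state_ivs, config.power_bin_s)
            row[f"{region}_z_{b}_approach"] = means["approach"]
            row[f"{region}_z_{b}_leaving"] = means["leaving"]

    # --- interregional coherence / causality
    if config.coherence and len(analysis_regions) >= 2:
        r1, r2 = analysis_regions[:2]
        coh_means = {b: [] for b in config.summary_bands}
        gc_fwd = {b: [] for b in config.summary_bands}
        gc_rev = {b: [] for b in config.summary_bands}
        for ch1 in target.channels(r1):
            for ch2 in target.channels(r2):
                coh = spc.coherence_spectrum(ch1, ch2)
                for b in config.summary_bands:
                    coh_means[b].append(coh.band_mean(config.bands[b]))
                if config.granger:
                    gc = spc.granger_spectrum(ch1, ch2, config.var_max_order)
                    for b in config.summary_bands:
                        gc_fwd[b].append(gc.band_mean(config.bands[b], "a_to_b"))
                        gc_rev[b].append(gc.band_mean(config.bands[b], "b_to_a"))
        for b in config.summary_bands:
            row[f"coherence_{b}"] = float(np.mean(coh_means[b]))
            if config.granger:
                row[f"gc_{r1}_to_{r2}_{b}"] = float(np.mean(gc_fwd[b]))
                row[f"gc_{r2}_to_{r1}_{b}"] = float(np.mean(gc_rev[b]))

    # --- spike phase locking within behavior
    pl_rows: list[dict] = []
    if target.spikes and len(bouts.intervals("approach")) and len(bouts.intervals("leaving")):
        units_df = pd.DataFrame(
            {
                "unit_id": [s.unit_id for s in target.spikes],
                "baseline_rate_hz": [s.baseline_rate_hz for s in target.spikes],
                "spike_width_ms": [s.spike_width_ms for s in target.spikes],
            }
        )
        classes = spk.classify_units(units_df).set_index("unit_id")["unit_class"]
        region = target.regions[0]
        band = spc.SPIKE_BANDS[config.spike_band]
        phase = spk.instantaneous_phase(target.channels(region)[0], band)
        rng = np.random.default_rng(seed)
        for unit in target.spikes:
            appr, leav, excluded = spk.behavior_locked_mvl(
                unit, phase, bouts, n_shuffle=config.n_shuffle, seed=rng
            )
            for res in (appr, leav):
                pl_rows.append(
                    {
                        "mouse_id": target.mouse_id,
                        "group": target.group,
                        "unit_id": unit.unit_id,
                        "unit_class": classes[unit.unit_id],
                        "band": config.spike_band,
                        "state": res.state,
                        "mvl": res.mvl,
                        "preferred_phase_deg": res.preferred_phase_deg,
                        "p": res.shuffle_p,
                        "significant": res.significant,
                        "excluded": excluded,
                        "n_spikes": res.n_spikes,
                    }
                )
    return row, pd.DataFrame(pl_rows)


def run_full_analysis(
    cohort: list[MouseDataset] | list[dict[str, SessionBundle]] | str | Path,
    config: AnalysisConfig | None = None,
) -> ResultTables:
    """Analyze a cohort (in-memory datasets or a directory of session dirs).

    Per-session failures are logged and skipped; the result carries an
    error summary.
    """
    config = config or AnalysisConfig()
    if isinstance(cohort, (str, Path)):
        cohort = load_cohort_dir(Path(cohort))

    rows: list[dict] = []
    pl_tables: list[pd.DataFrame] = []
    errors: list[str] = []
    rng = np.random.default_rng(config.seed)
    for item in cohort:
        sessions = item.sessions if isinstance(item, MouseDataset) else item
        mouse_seed = int(rng.integers(0, 2**31 - 1))
        try:
            row, pl = analyze_mouse(sessions, config, seed=mouse_seed)
        except Exception as exc:  # noqa: BLE001 — per-session failures must not kill the run
            mouse = next(iter(sessions.values())).mouse_id
            errors.append(f"{mouse}: {exc}")
            continue
        rows.append(row)
        if len(pl):
            pl_tables.append(pl)
    summary = pd.DataFrame(rows)
    phase_locking = (
        pd.concat(pl_tables, ignore_index=True) if pl_tables else pd.DataFrame()
    )
    tables = ResultTables(summary, phase_locking, errors=errors)
    tables.group_stats = group_compare(tables, config)
    return tables


def load_cohort_dir(path: Path) -> list[dict[str, SessionBundle]]:
    """Load ``<mouse>__<session_label>`` session directories into pairs."""
    by_mouse: dict[str, dict[str, SessionBundle]] = {}
    for d in sorted(p for p in path.iterdir() if (p / "session.json").exists()):
        bundle = read_session(d)
        by_mouse.setdefault(bundle.mouse_id, {})[bundle.session_label] = bundle
    return list(by_mouse.values())


# ---------------------------------------------------------------------------
# Group statistics


def group_compare(tables: ResultTables, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Standard contrasts over the mouse-summary and phase-locking tables.

    - per group: approach vs leaving state z (paired, within-mouse),
    - between first two groups: band power ratios and SI ratio (independent),
    - retained (non-excluded) units per class: approach vs leaving MVL (paired).

    Undefined SI ratios are excluded with a logged count; Bonferroni is
    applied within each family of band-wise contrasts.
    """
    config = config or AnalysisConfig()
    df = tables.mouse_summary
    out: list[dict] = []
    if df.empty:
        return pd.DataFrame()
    groups = list(dict.fromkeys(df["group"]))

    def add(name: str, res: dict, m: int = 1) -> None:
        res = dict(res)
        res["contrast"] = name
        res["p_corrected"] = bonferroni(res["p"], m) if np.isfinite(res["p"]) else np.nan
        out.append(res)

    band_cols = [c for c in df.columns if "_z_" in c and c.endswith("_approach")]
    for g in groups:
        sub = df[df["group"] == g]
        for col_a in band_cols:
            col_l = col_a.replace("_approach", "_leaving")
            add(
                f"{g}: {col_a.replace('_approach', '')} approach vs leaving",
                two_sample_compare(
                    sub[col_a].to_numpy(), sub[col_l].to_numpy(), paired=True
                ),
                m=len(band_cols),
            )
    if len(groups) >= 2:
        g1, g2 = groups[0], groups[1]
        a, b = df[df["group"] == g1], df[df["group"] == g2]
        ratio_cols = [c for c in df.columns if "_ratio_" in c]
        for col in ratio_cols:
            add(
                f"{g1} vs {g2}: {col}",
                two_sample_compare(a[col].to_numpy(), b[col].to_numpy(), paired=False),
                m=len(ratio_cols),
            )
        if "si_ratio" in df.columns:
            sa, sb = a["si_ratio"].to_numpy(), b["si_ratio"].to_numpy()
            n_undef = int(np.isnan(sa).sum() + np.isnan(sb).sum())
            if n_undef:
                warnings.warn(f"excluding {n_undef} undefined SI ratio(s) from group test")
            add(f"{g1} vs {g2}: si_ratio", two_sample_compare(sa[~np.isnan(sa)], sb[~np.isnan(sb)], paired=False))

    pl = tables.phase_locking
    if len(pl):
        retained = pl[~pl["excluded"]]
        for cls in ("RS", "FS"):
            sub = retained[retained["unit_class"] == cls]
            piv = sub.pivot_table(
                index=["mouse_id", "unit_id"], columns="state", values="mvl"
            )
            if {"approach", "leaving"} <= set(piv.columns):
                add(
                    f"{cls} retained units: MVL approach vs leaving",
                    two_sample_compare(
                        piv["approach"].to_numpy(), piv["leaving"].to_numpy(), paired=True
                    ),
                    m=2,
                )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Reports


def make_report(
    tables: ResultTables,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    plots: bool = True,
) -> list[Path]:
    """Write result CSVs, basic plots and a run manifest. CSV bytes are
    deterministic for identical inputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    manifest = {
        "config": json.loads(config.to_json()),
        "n_mice": int(len(tables.mouse_summary)),
        "errors": tables.errors,
        "versions": _versions(),
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)

    for name, df in [
        ("mouse_summary.csv", tables.mouse_summary),
        ("phase_locking.csv", tables.phase_locking),
        ("group_stats.csv", tables.group_stats),
    ]:
        if df is None or df.empty:
            continue
        p = out_dir / name
        df.to_csv(p, index=False)
        written.append(p)

    if plots and not tables.mouse_summary.empty:
        df = tables.mouse_summary
        ratio_cols = [c for c in df.columns if "_ratio_" in c]
        if ratio_cols:
            fig, ax = plt.subplots(figsize=(6, 4))
            df.boxplot(column=ratio_cols, by="group", ax=ax, rot=45)
            ax.axhline(100, color="k", lw=0.5)
            ax.set_ylabel("target/no-target power (%)")
            fig.tight_layout()
            fig.savefig(out_dir / "power_ratios.png", dpi=100)
            plt.close(fig)
            written.append(out_dir / "power_ratios.png")
        z_cols = [c for c in df.columns if "_z_" in c]
        if z_cols:
            fig, ax = plt.subplots(figsize=(6, 4))
            df[z_cols].mean().plot.bar(ax=ax)
            ax.set_ylabel("mean z-scored power")
            fig.tight_layout()
            fig.savefig(out_dir / "state_power.png", dpi=100)
            plt.close(fig)
            written.append(out_dir / "state_power.png")
        if len(tables.phase_locking):
            piv = tables.phase_locking.pivot_table(
                index=["mouse_id", "unit_id", "unit_class"], columns="state", values="mvl"
            ).reset_index()
            if {"approach", "leaving"} <= set(piv.columns):
                fig, ax = plt.subplots(figsize=(4.5, 4.5))
                for cls, marker in (("RS", "^"), ("FS", "x")):
                    sub = piv[piv["unit_class"] == cls]
                    ax.scatter(sub["approach"], sub["leaving"], marker=marker, label=cls)
                lim = max(piv[["approach", "leaving"]].max().max() * 1.1, 0.1)
                ax.plot([0, lim], [0, lim], "k--", lw=0.5)
                ax.set_xlabel("MVL (approach)")
                ax.set_ylabel("MVL (leaving)")
                ax.legend()
                fig.tight_layout()
                fig.savefig(out_dir / "mvl_scatter.png", dpi=100)
                plt.close(fig)
                written.append(out_dir / "mvl_scatter.png")
    return written


def _versions() -> dict[str, str]:
    import matplotlib
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }
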