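"""End-to-end session pipeline.

``run_pipeline`` executes simulate-or-load -> behavioral segmentation ->
spectral power -> PAC -> SWR detection for one session and writes
diff-friendly per-stage outputs (CSV tables, JSON summaries) plus a
provenance manifest.  The statistics stage operates on a cohort-level
observations CSV and is exposed separately (``run_stats``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, io, pac, spectral, swr
from .synthetic import EXPLORATION, IMMOBILITY, SessionConfig, gen_session

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis knobs; defaults are the printed analysis parameters."""

    lfp_path: str | None = None
    tracking_path: str | None = None
    out_dir: str = "hippolfp_out"
    simulate: bool = True
    session: dict = field(default_factory=dict)   # SessionConfig overrides
    pyramidal_channel: int | str = "pyramidal"
    radiatum_channel: int | str = "radiatum"
    frame_rate: float = 30.0
    arena_side_m: float = 1.0
    inner_fraction: float = 0.5
    speed_threshold: float = behavior.SPEED_THRESHOLD_M_S
    zero_tol: float = behavior.ZERO_SPEED_TOL_M_S
    min_epoch_s: float = 1.0
    ripple_core_sd: float = 3.0
    ripple_edge_sd: float = 2.0
    ripple_min_dur_ms: float = 30.0
    ripple_min_psf_hz: float = 140.0
    sw_thresh_sd: float = 2.5
    slow_gamma_band: tuple[float, float] = (30.0, 45.0)
    comodulogram_max_epochs: int = 4
    analysis_fs: float = 1200.0   # spectral/PAC rate after decimation
    stats_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__annotations__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded)."""
        d = asdict(self)
        for key in ("lfp_path", "tracking_path", "out_dir"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.simulate or cfg.lfp_path is None:
        sess = SessionConfig(seed=cfg.seed, **cfg.session)
        rec, tracking_df, truth = gen_session(sess)
        return rec, tracking_df, truth
    rec = (
        io.read_lfp_h5(cfg.lfp_path)
        if str(cfg.lfp_path).endswith((".h5", ".hdf5"))
        else io.read_lfp_raw(cfg.lfp_path)
    )
    if cfg.tracking_path is None or not Path(cfg.tracking_path).exists():
        raise FileNotFoundError(
            f"tracking file not found: {cfg.tracking_path}"
        )
    tracking_df = io.read_tracking_csv(cfg.tracking_path)
    return rec, tracking_df, None


def _channel_index(rec: io.LfpRecording, ch: int | str) -> int:
    if isinstance(ch, str):
        return rec.channel_labels.index(ch)
    return int(ch)


def segment_behavior(cfg: PipelineConfig, rec, tracking_df):
    track = behavior.TrackingTrace.from_dataframe(
        tracking_df, cfg.frame_rate, cfg.arena_side_m, ttl_s=rec.ttl_s
    )
    speed = behavior.compute_speed(track)
    labels = behavior.classify_frames(speed, cfg.speed_threshold, cfg.zero_tol)
    epochs = behavior.frames_to_epochs(
        labels, track.t_s, cfg.frame_rate, cfg.min_epoch_s
    )
    epochs = behavior.align_to_lfp(
        epochs, track.ttl_s, rec.ttl_s, rec.fs, rec.n_samples
    )
    return track, labels, epochs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every per-session stage; write outputs; return results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, tracking_df, truth = _load_or_simulate(cfg)
    if cfg.simulate:
        io.write_lfp_h5(out / "session.h5", rec)
        io.write_tracking_csv(out / "tracking.csv", tracking_df)

    track, labels, epochs = segment_behavior(cfg, rec, tracking_df)
    behavior.epochs_to_frame(epochs).to_csv(out / "epochs.csv", index=False)
    metrics = behavior.openfield_metrics(track, cfg.inner_fraction)
    metrics.per_epoch.to_csv(out / "openfield_windows.csv", index=False)

    by_state = {
        s: [e for e in epochs if e.state == s]
        for s in (EXPLORATION, IMMOBILITY)
    }
    by_state = {s: eps for s, eps in by_state.items() if eps}

    # spectral and PAC run at the decimated analysis rate; SWR detection
    # decimates internally after its own band-pass
    from scipy.signal import resample_poly
    from fractions import Fraction

    frac = Fraction(cfg.analysis_fs / rec.fs).limit_denominator(1000)
    ds = np.vstack(
        [resample_poly(ch, frac.numerator, frac.denominator)
         for ch in rec.data]
    )
    scale = cfg.analysis_fs / rec.fs

    def _ds_epochs(eps):
        return [
            behavior.BehaviorEpoch(
                e.state, e.start_s, e.end_s,
                int(round(e.start_sample * scale)),
                min(int(round(e.end_sample * scale)), ds.shape[1]),
            )
            for e in eps
        ]

    by_state_ds = {s: _ds_epochs(eps) for s, eps in by_state.items()}
    power_table = spectral.state_band_powers(ds, cfg.analysis_fs, by_state_ds)
    power_table.to_csv(out / "band_power.csv", index=False)
    top3 = spectral.top_channel_table(power_table)
    top3.to_csv(out / "band_power_top3.csv", index=False)

    pyr = rec.channel(_channel_index(rec, cfg.pyramidal_channel))
    rad = rec.channel(_channel_index(rec, cfg.radiatum_channel))
    pyr_ds = ds[_channel_index(rec, cfg.pyramidal_channel)]

    tpac_rows = []
    comods = {}
    for state, eps in by_state_ds.items():
        big = sorted(eps, key=lambda e: -e.duration_s)
        big = big[: cfg.comodulogram_max_epochs]
        comod = pac.comodulogram(pyr_ds, cfg.analysis_fs, big)
        comods[state] = comod
        pd.DataFrame(
            comod.mi_matrix,
            index=pd.Index(comod.phase_freqs, name="phase_hz"),
            columns=comod.amp_freqs,
        ).to_csv(out / f"comodulogram_{state}.csv")
        for phase_band, amp_band in pac.TPAC_BAND_PAIRS.get(state, []):
            series = pac.tpac(pyr_ds, cfg.analysis_fs, eps, phase_band,
                              amp_band)
            tpac_rows.append(
                {
                    "state": state,
                    "phase_band": f"{phase_band[0]}-{phase_band[1]}",
                    "amp_band": f"{amp_band[0]}-{amp_band[1]}",
                    "mi_mean": series.mean,
                    "mi_sem": series.sem,
                    "n_windows": len(series.mi_values),
                }
            )
    tpac_df = pd.DataFrame(tpac_rows)
    tpac_df.to_csv(out / "tpac.csv", index=False)

    all_eps = [e for eps in by_state.values() for e in eps]
    rp = swr.ripple_power(pyr, rec.fs, all_eps)
    ripples = swr.detect_ripples(
        rp, cfg.ripple_core_sd, cfg.ripple_edge_sd,
        cfg.ripple_min_dur_ms, cfg.ripple_min_psf_hz,
    )
    sws = swr.detect_sharp_waves(
        rad, rec.fs, thresh_sd=cfg.sw_thresh_sd, epochs=all_eps
    )
    events = swr.pair_events(ripples, sws)
    swr.attach_slow_gamma(events, pyr, rec.fs, tuple(cfg.slow_gamma_band))
    swr.events_to_frame(events).to_csv(out / "swr_events.csv", index=False)
    try:
        ratio = swr.occurrence_ratio(events, all_eps)
    except ValueError:
        ratio = float("nan")

    summary = {
        "n_epochs": len(epochs),
        "state_durations_s": behavior.state_durations(epochs),
        "total_distance_m": metrics.total_distance_m,
        "inner_time_s": metrics.inner_time_s,
        "inner_entries": metrics.inner_entries,
        "n_swr_events": len(events),
        "swr_occurrence_ratio": ratio,
        "comodulogram_peak": {
            s: c.argmax_bin() for s, c in comods.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "numpy_version": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "recording": rec, "epochs": epochs, "power": power_table,
        "tpac": tpac_df, "comodulograms": comods, "events": events,
        "occurrence_ratio": ratio, "summary": summary, "truth": truth,
    }


def run_stats(
    observations: pd.DataFrame,
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
) -> dict:
    """Fit the mixed-model layer per measure on a long observations table.

    Columns: subject, genotype, state (optional for two-factor measures),
    trial, measure, value.  Measures with a state column get the
    three-factor design; the rest the two-factor design with the
    interaction-dropping rule.
    """
    from .stats import analyze_measure, t2_outliers

    results = {}
    for measure, g in observations.groupby("measure"):
        g = g.copy()
        has_state = "state" in g.columns and g["state"].notna().all() \
            and g["state"].nunique() > 1
        group_cols = ("genotype", "state", "trial") if has_state \
            else ("genotype", "trial")
        keep = t2_outliers(g, value_cols=["value"], group_cols=group_cols,
                           alpha=alpha)
        g = g[keep]
        res = analyze_measure(
            g, design="three_factor" if has_state else "two_factor",
            alpha=alpha,
        )
        results[measure] = {
            "formula": res.formula,
            "reduced": res.reduced,
            "converged": res.converged,
            "n_excluded": int((~keep).sum()),
            "params": {_k: float(v) for _k, v in res.params.items()},
            "pvalues": {_k: float(v) for _k, v in res.pvalues.items()},
            "random_intercept_var": res.random_intercept_var,
            "posthoc": (
                res.posthoc.to_dict("records")
                if res.posthoc is not None else None
            ),
        }
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "models.json").write_text(
            json.dumps(results, indent=1, default=float)
        )
    return results
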