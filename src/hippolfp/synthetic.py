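"""Synthetic CA1 session generator.

Produces complete sessions — a 16-channel laminar LFP, an animal-tracking
trace, and a ground-truth record — with the statistical structure the
analysis pipeline assumes: 1/f^alpha background noise, behavioral-state-
gated theta, gamma whose amplitude envelope is modulated by theta phase
with controllable depth, sharp wave-ripple events injected jointly on the
pyramidal and radiatum channels, and a tracking path whose frame-to-frame
speeds respect the behavioral-state thresholds strictly.

Every generator is deterministic given its seed, and every injected event
is recorded in the ground truth so detector sensitivity, precision and
feature bias can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.signal.windows import tukey

from .io import LfpRecording

EXPLORATION = "exploration"
GROOMING = "grooming"
IMMOBILITY = "wake_immobility"
STATES = (EXPLORATION, GROOMING, IMMOBILITY)

# per-frame locomotion speeds (m/s) used when a bout of each state is
# scripted: exploration must exceed 0.05, grooming must sit strictly
# inside (0, 0.05], immobility is exactly zero
DEFAULT_STATE_SPEEDS = {EXPLORATION: 0.15, GROOMING: 0.02, IMMOBILITY: 0.0}


def _per_state(value, states=STATES) -> dict:
    """Broadcast a scalar to a per-state mapping, or validate a mapping."""
    if isinstance(value, Mapping):
        return {s: float(value.get(s, 0.0)) for s in states}
    return {s: float(value) for s in states}


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    Amplitudes are in microvolts.  ``theta_amp`` and ``pac_depth`` accept
    either a scalar or a per-state mapping; ``swr_rate_per_state`` is
    events/s by state.  The default sampling rate is 2500 Hz to keep
    desk-scale runtimes; 25000 Hz reproduces the acquisition rate of the
    wireless headstage the simulator emulates.
    """

    state_schedule: Sequence[tuple[str, float]] = (
        (EXPLORATION, 60.0),
        (IMMOBILITY, 60.0),
    )
    fs: float = 2500.0
    n_channels: int = 16
    pyramidal_channel: int = 7
    radiatum_channel: int = 11
    noise_exponent: float = 1.0
    noise_amp: float = 30.0
    theta_freq: float = 8.0
    theta_amp: float | Mapping[str, float] = 60.0
    gamma_freq: float = 70.0
    gamma_amp: float | Mapping[str, float] = 20.0
    pac_depth: float | Mapping[str, float] = 0.8
    swr_rate_per_state: Mapping[str, float] = field(
        default_factory=lambda: {IMMOBILITY: 0.3, EXPLORATION: 0.05}
    )
    ripple_freq: float = 180.0
    ripple_dur_ms: float = 60.0
    ripple_amp: float = 100.0
    sw_amp: float = 150.0
    sw_width_ms: float = 70.0
    frame_rate: float = 30.0
    arena_side_m: float = 1.0
    ttl_interval_s: float = 10.0
    lamina_attenuation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        depths = _per_state(self.pac_depth)
        for s, d in depths.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"pac_depth[{s}]={d} outside [0, 1]")
        if not self.state_schedule:
            raise ValueError("state_schedule is empty")
        for state, dur in self.state_schedule:
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if dur <= 0:
                raise ValueError("state durations must be positive")
        top = max(self.gamma_freq, self.ripple_freq, self.theta_freq)
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} violates Nyquist for {top} Hz")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.state_schedule))


@dataclass
class GroundTruth:
    """Everything the generator injected, for downstream validation."""

    swr_times: list[tuple[float, float, int]]        # joint ripple+SW
    sw_times: list[tuple[float, float, int]] = field(default_factory=list)
    ripple_only_times: list[tuple[float, float, int]] = field(
        default_factory=list
    )
    sw_only_times: list[tuple[float, float, int]] = field(
        default_factory=list
    )
    state_labels: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=object)
    )
    frame_t_s: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pac_depth_by_state: dict[str, float] = field(default_factory=dict)
    band_power_targets: dict[str, float] = field(default_factory=dict)


def schedule_bounds(
    state_schedule: Sequence[tuple[str, float]],
) -> list[tuple[str, float, float]]:
    """(state, start_s, end_s) for each scheduled bout, half-open."""
    out, t = [], 0.0
    for state, dur in state_schedule:
        out.append((state, t, t + dur))
        t += dur
    return out


def state_at(state_schedule, t: float) -> str:
    for state, lo, hi in schedule_bounds(state_schedule):
        if lo <= t < hi:
            return state
    return state_schedule[-1][0]


# ---------------------------------------------------------------------------
# background noise

def gen_background(
    duration_s: float,
    fs: float,
    noise_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    rms: float = 1.0,
    f_floor: float = 3.0,
) -> np.ndarray:
    """Zero-mean Gaussian noise with a ~1/f^alpha power spectrum.

    Spectral shaping in the frequency domain: white Gaussian noise is
    scaled by f^(-alpha/2) and inverse-transformed, then normalized to the
    requested RMS.  alpha=0 gives white noise.  Below ``f_floor`` the
    spectrum rolls off (second-order high-pass shape) instead of diverging — recorded LFP is high-passed
    by the acquisition chain, and an unbounded power law would park a
    large fraction of the variance below the resolution of any 1-s
    analysis window.  ``f_floor=0`` gives the pure power law.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    with np.errstate(divide="ignore"):
        f_eff = np.maximum(f, f_floor)
        shape = np.where(f > 0, f_eff ** (-noise_exponent / 2.0), 0.0)
        if f_floor > 0:
            low = (f > 0) & (f < f_floor)
            shape[low] *= (f[low] / f_floor) ** 2
    x = np.fft.irfft(spec * shape, n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


# ---------------------------------------------------------------------------
# phase-amplitude-coupled oscillation

def pac_envelope(
    t: np.ndarray, f_phase: float, pac_depth: float, amp_gamma: float
) -> np.ndarray:
    """Gamma amplitude envelope modulated by the slow-rhythm phase.

    A(t) = amp_gamma * [1 - d + d * (1 + cos(2 pi f_phase t)) / 2]; the
    envelope is maximal (amp_gamma) at phase 0 of the slow rhythm and
    shrinks to amp_gamma*(1-d) at the trough.
    """
    slow = np.cos(2 * np.pi * f_phase * t)
    return amp_gamma * (1.0 - pac_depth + pac_depth * (1.0 + slow) / 2.0)


def gen_pac_signal(
    f_phase: float,
    f_amp: float,
    pac_depth: float,
    amp_phase: float,
    amp_gamma: float,
    duration_s: float,
    fs: float,
    seed: int | None = None,
    noise_rms: float = 0.0,
    noise_exponent: float = 1.0,
    freq_jitter_hz: float = 0.0,
) -> np.ndarray:
    """Slow oscillation plus a fast oscillation whose envelope follows it.

    ``freq_jitter_hz`` > 0 lets the slow rhythm's instantaneous frequency
    wander (slow Gaussian excursions of that SD around ``f_phase``), as
    hippocampal theta does in vivo; the envelope follows the wandering
    phase, so the coupling itself is untouched.  A non-periodic slow
    phase is what makes time-shift surrogates destroy the coupling.
    """
    if not 0.0 <= pac_depth <= 1.0:
        raise ValueError(f"pac_depth={pac_depth} outside [0, 1]")
    if f_amp <= f_phase:
        raise ValueError("f_amp must exceed f_phase")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if freq_jitter_hz > 0:
        rng = default_rng(0 if seed is None else seed + 104729)
        # smooth (<1 Hz) frequency excursions
        drift = gen_background(duration_s, fs, 0.0, rng, rms=1.0)
        sos_n = max(int(fs), 8)
        kernel = np.hanning(sos_n)
        kernel /= kernel.sum()
        drift = np.convolve(drift, kernel, mode="same")
        drift *= freq_jitter_hz / max(drift.std(), 1e-12)
        slow_phase = 2 * np.pi * np.cumsum(f_phase + drift) / fs
    else:
        slow_phase = 2 * np.pi * f_phase * t
    cos_slow = np.cos(slow_phase)
    envelope = amp_gamma * (
        1.0 - pac_depth + pac_depth * (1.0 + cos_slow) / 2.0
    )
    x = amp_phase * cos_slow + envelope * np.cos(2 * np.pi * f_amp * t)
    if noise_rms > 0:
        x += gen_background(
            duration_s, fs, noise_exponent, 0 if seed is None else seed,
            rms=noise_rms,
        )
    return x


# ---------------------------------------------------------------------------
# sharp wave-ripple events

def ripple_waveform(
    fs: float, freq: float, dur_ms: float, amp: float, taper: float = 0.15
) -> np.ndarray:
    """Tapered-cosine-windowed sinusoidal ripple burst.

    The Tukey window's flat plateau keeps the detected supra-threshold
    extent close to the injected duration; taper=1.0 recovers a Hann
    window.
    """
    n = max(int(round(dur_ms / 1000.0 * fs)), 2)
    t = np.arange(n) / fs
    return amp * tukey(n, alpha=taper) * np.sin(2 * np.pi * freq * t)


def sharp_wave_waveform(
    fs: float, width_ms: float, amp: float, rise_ms: float = 8.0
) -> np.ndarray:
    """Negative deflection: fast cosine-ramp rise, Gaussian decay.

    Total support is roughly rise + 2.5 sigma of the decay; width_ms sets
    the Gaussian decay scale (sigma = width/2.355, the FWHM convention).
    """
    sigma = (width_ms / 1000.0) / 2.355
    n_rise = max(int(round(rise_ms / 1000.0 * fs)), 2)
    n_decay = max(int(round(3.0 * sigma * fs)), 2)
    rise = -amp * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise)) / 2.0
    t_dec = np.arange(1, n_decay + 1) / fs
    decay = -amp * np.exp(-(t_dec ** 2) / (2 * sigma ** 2))
    return np.concatenate([rise, decay])


def _place_events(
    rng: np.random.Generator,
    windows: list[tuple[float, float]],
    rates: Mapping[str, float] | None,
    n_forced: int | None,
    event_dur_s: float,
    schedule: Sequence[tuple[str, float]] | None,
    max_tries: int = 10000,
) -> list[float]:
    """Draw non-overlapping event start times (seconds).

    Either Poisson counts per scheduled state bout (``rates``) or a fixed
    number of events uniform over the given windows (``n_forced``).
    Collisions are resolved by resampling the colliding start time.
    """
    starts: list[float] = []

    def collides(s: float) -> bool:
        return any(abs(s - o) < event_dur_s * 1.5 for o in starts)

    def sample_in(lo: float, hi: float) -> float | None:
        hi_eff = hi - event_dur_s
        if hi_eff <= lo:
            return None
        for _ in range(max_tries):
            s = rng.uniform(lo, hi_eff)
            if not collides(s):
                return s
        raise RuntimeError("could not place non-overlapping event")

    if n_forced is not None:
        for _ in range(n_forced):
            lo, hi = windows[rng.integers(len(windows))]
            s = sample_in(lo, hi)
            if s is not None:
                starts.append(s)
    else:
        assert schedule is not None and rates is not None
        for state, lo, hi in schedule_bounds(schedule):
            rate = float(rates.get(state, 0.0)) if rates else 0.0
            if rate <= 0:
                continue
            n_ev = rng.poisson(rate * (hi - lo))
            for _ in range(n_ev):
                s = sample_in(lo, hi)
                if s is not None:
                    starts.append(s)
    return sorted(starts)


def inject_swr_events(
    pyr: np.ndarray,
    rad: np.ndarray,
    starts_s: Sequence[float],
    fs: float,
    ripple_freq: float,
    ripple_dur_ms: float,
    ripple_amp: float,
    sw_amp: float,
    sw_width_ms: float = 70.0,
    taper: float = 0.15,
    with_ripple: bool = True,
    with_sw: bool = True,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Add ripple bursts / sharp waves at the given start times, in place.

    Ripple and sharp wave are co-centered.  Returns the (start, end)
    intervals actually injected for each component.
    """
    rip = ripple_waveform(fs, ripple_freq, ripple_dur_ms, ripple_amp, taper)
    sw = sharp_wave_waveform(fs, sw_width_ms, sw_amp)
    rip_ivals, sw_ivals = [], []
    n = len(pyr)
    for s in starts_s:
        i0 = int(round(s * fs))
        if i0 < 0 or i0 + len(rip) > n:
            continue
        center = i0 + len(rip) // 2
        if with_ripple:
            pyr[i0:i0 + len(rip)] += rip
            rip_ivals.append((i0 / fs, (i0 + len(rip)) / fs))
        if with_sw:
            j0 = center - len(sw) // 2
            j0 = max(j0, 0)
            j1 = min(j0 + len(sw), n)
            rad[j0:j1] += sw[: j1 - j0]
            sw_ivals.append((j0 / fs, j1 / fs))
    return rip_ivals, sw_ivals


def gen_swr_train(
    state_schedule: Sequence[tuple[str, float]],
    swr_rate_per_state: Mapping[str, float],
    ripple_freq: float,
    ripple_dur_ms: float,
    ripple_amp: float,
    sw_amp: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    sw_width_ms: float = 70.0,
    taper: float = 0.15,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float, int]]]:
    """Poisson sharp wave-ripple trains as additive traces.

    Event counts are Poisson per scheduled bout at that state's rate; each
    event injects a ripple burst on the pyramidal trace and a co-centered
    sharp wave on the radiatum trace, never overlapping another event.
    Returns (pyramidal additive trace, radiatum additive trace,
    ground-truth (start_s, end_s, channel=-1) ripple intervals).
    """
    if not state_schedule:
        raise ValueError("state_schedule is empty")
    if any(r < 0 for r in dict(swr_rate_per_state).values()):
        raise ValueError("rates must be >= 0")
    if ripple_dur_ms <= 0:
        raise ValueError("ripple_dur_ms must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else default_rng(seed)
    duration_s = sum(d for _, d in state_schedule)
    n = int(round(duration_s * fs))
    pyr = np.zeros(n)
    rad = np.zeros(n)
    starts = _place_events(
        rng, [], swr_rate_per_state, None, ripple_dur_ms / 1000.0,
        state_schedule,
    )
    rip_ivals, _ = inject_swr_events(
        pyr, rad, starts, fs, ripple_freq, ripple_dur_ms, ripple_amp,
        sw_amp, sw_width_ms, taper,
    )
    truth = [(a, b, -1) for a, b in rip_ivals]
    return pyr, rad, truth


# ---------------------------------------------------------------------------
# tracking

def gen_tracking(
    state_schedule: Sequence[tuple[str, float]],
    frame_rate: float = 30.0,
    arena_size: float = 1.0,
    seed: int | np.random.Generator = 0,
    state_speeds: Mapping[str, float] | None = None,
    turn_sd_rad: float = 0.4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Arena path whose per-frame speed encodes the scheduled state.

    The step into frame i has the magnitude of frame i's state speed, so a
    downstream speed classifier recovers the schedule exactly.  Direction
    follows a wrapped random walk; steps that would leave the arena are
    reflected (preserving magnitude).  Returns the tracking DataFrame
    (frame, t_s, x_m, y_m) and per-frame ground-truth labels.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if arena_size <= 0:
        raise ValueError("arena_size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else default_rng(seed)
    speeds = dict(DEFAULT_STATE_SPEEDS)
    if state_speeds:
        speeds.update(state_speeds)
    duration_s = sum(d for _, d in state_schedule)
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    labels = np.array(
        [state_at(state_schedule, ti) for ti in t], dtype=object
    )
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0] = y[0] = arena_size / 2.0
    heading = rng.uniform(0, 2 * np.pi)
    margin = 1e-6
    for i in range(1, n_frames):
        step = speeds[labels[i]] / frame_rate
        if step == 0.0:
            x[i], y[i] = x[i - 1], y[i - 1]
            continue
        heading += rng.normal(0.0, turn_sd_rad)
        dx, dy = step * np.cos(heading), step * np.sin(heading)
        # reflect off walls, preserving step magnitude
        for _ in range(4):
            nx, ny = x[i - 1] + dx, y[i - 1] + dy
            if nx < 0 or nx > arena_size:
                dx = -dx
                heading = np.pi - heading
                continue
            if ny < 0 or ny > arena_size:
                dy = -dy
                heading = -heading
                continue
            break
        x[i] = np.clip(x[i - 1] + dx, margin, arena_size - margin)
        y[i] = np.clip(y[i - 1] + dy, margin, arena_size - margin)
    df = pd.DataFrame(
        {"frame": np.arange(n_frames), "t_s": t, "x_m": x, "y_m": y}
    )
    return df, labels


# ---------------------------------------------------------------------------
# full session

def gen_session(
    cfg: SessionConfig,
) -> tuple[LfpRecording, pd.DataFrame, GroundTruth]:
    """Assemble a full synthetic session from one config.

    Each channel carries independent 1/f background.  The pyramidal
    channel carries full-amplitude theta + PAC gamma + ripple bursts; the
    radiatum channel carries attenuated theta + sharp waves; the remaining
    channels carry attenuated rhythms only.  TTL pulses are emitted from
    t=0 at a fixed interval and stored identically in the LFP container
    and the tracking ground truth (shared clock).
    """
    rng = default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    theta_amp = _per_state(cfg.theta_amp)
    gamma_amp = _per_state(cfg.gamma_amp)
    depth = _per_state(cfg.pac_depth)

    # per-sample state gating
    amp_theta_t = np.zeros(n)
    amp_gamma_t = np.zeros(n)
    depth_t = np.zeros(n)
    for state, lo, hi in schedule_bounds(cfg.state_schedule):
        i0, i1 = int(round(lo * cfg.fs)), min(int(round(hi * cfg.fs)), n)
        amp_theta_t[i0:i1] = theta_amp[state]
        amp_gamma_t[i0:i1] = gamma_amp[state]
        depth_t[i0:i1] = depth[state]

    slow = np.cos(2 * np.pi * cfg.theta_freq * t)
    theta = amp_theta_t * slow
    envelope = amp_gamma_t * (1.0 - depth_t + depth_t * (1.0 + slow) / 2.0)
    gamma = envelope * np.cos(2 * np.pi * cfg.gamma_freq * t)

    pyr_add = np.zeros(n)
    rad_add = np.zeros(n)
    starts = _place_events(
        rng, [], cfg.swr_rate_per_state, None,
        cfg.ripple_dur_ms / 1000.0, cfg.state_schedule,
    )
    rip_ivals, sw_ivals = inject_swr_events(
        pyr_add, rad_add, starts, cfg.fs, cfg.ripple_freq,
        cfg.ripple_dur_ms, cfg.ripple_amp, cfg.sw_amp, cfg.sw_width_ms,
    )

    data = np.empty((cfg.n_channels, n))
    att = cfg.lamina_attenuation
    for ch in range(cfg.n_channels):
        bg = gen_background(
            cfg.duration_s, cfg.fs, cfg.noise_exponent, rng,
            rms=cfg.noise_amp,
        )
        if ch == cfg.pyramidal_channel:
            data[ch] = bg + theta + gamma + pyr_add
        elif ch == cfg.radiatum_channel:
            data[ch] = bg + 0.5 * theta + rad_add
        else:
            data[ch] = bg + att * (theta + gamma)

    labels = [
        "pyramidal" if ch == cfg.pyramidal_channel
        else "radiatum" if ch == cfg.radiatum_channel
        else f"ch{ch}"
        for ch in range(cfg.n_channels)
    ]
    ttl = np.arange(0.0, cfg.duration_s, cfg.ttl_interval_s)
    rec = LfpRecording(data=data, fs=cfg.fs, channel_labels=labels, ttl_s=ttl)

    tracking, frame_labels = gen_tracking(
        cfg.state_schedule, cfg.frame_rate, cfg.arena_side_m, rng
    )
    truth = GroundTruth(
        swr_times=[(a, b, cfg.pyramidal_channel) for a, b in rip_ivals],
        sw_times=[(a, b, cfg.radiatum_channel) for a, b in sw_ivals],
        state_labels=frame_labels,
        frame_t_s=tracking["t_s"].to_numpy(),
        pac_depth_by_state=depth,
        band_power_targets={"theta_amp_" + s: a for s, a in theta_amp.items()},
    )
    return rec, tracking, truth


def gen_swr_benchmark(
    n_joint: int = 100,
    n_ripple_only: int = 20,
    n_sw_only: int = 20,
    duration_s: float = 600.0,
    fs: float = 2500.0,
    ripple_freq: float = 180.0,
    ripple_dur_ms: float = 60.0,
    snr: float = 5.0,
    sw_snr: float = 8.0,
    noise_amp: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Standard detector benchmark: joint events plus unmatched distractors.

    Ripple amplitude is set to ``snr`` times the in-band (120-250 Hz)
    standard deviation of the 1/f background; sharp waves are scaled by
    ``sw_snr`` against the 0.5-40 Hz band (larger by default — radiatum
    sharp waves stand far above the slow background in vivo, and the
    20 ms minimum-duration rule makes marginal-amplitude deflections
    fragmentation-prone).  Returns the pyramidal trace,
    the radiatum trace and the ground truth listing joint, ripple-only
    and sharp-wave-only intervals separately.
    """
    from scipy.signal import butter, sosfiltfilt

    rng = default_rng(seed)
    pyr = gen_background(duration_s, fs, 1.0, rng, rms=noise_amp)
    rad = gen_background(duration_s, fs, 1.0, rng, rms=noise_amp)

    sos_rip = butter(4, [120, 250], btype="bandpass", fs=fs, output="sos")
    sigma_rip = sosfiltfilt(sos_rip, pyr).std()
    sos_sw = butter(4, [0.5, 40], btype="bandpass", fs=fs, output="sos")
    sigma_sw = sosfiltfilt(sos_sw, rad).std()
    # "snr" is defined against the event peak as seen through the
    # detection band, so each waveform is calibrated by its own filter
    # gain (the 40 Hz lowpass shaves the sharp wave's fast rise)
    rip_wave = ripple_waveform(fs, ripple_freq, ripple_dur_ms, 1.0)
    pad = np.zeros(int(fs))
    gain_rip = np.abs(
        sosfiltfilt(sos_rip, np.r_[pad, rip_wave, pad])
    ).max()
    sw_wave = sharp_wave_waveform(fs, 70.0, 1.0)
    gain_sw = np.abs(sosfiltfilt(sos_sw, np.r_[pad, sw_wave, pad])).max()
    ripple_amp = snr * sigma_rip / gain_rip
    sw_amp = sw_snr * sigma_sw / gain_sw

    window = [(1.0, duration_s - 1.0)]
    ev_dur = max(ripple_dur_ms / 1000.0, 0.3)
    starts = _place_events(
        rng, window, None, n_joint + n_ripple_only + n_sw_only, ev_dur, None
    )
    rng.shuffle(starts)
    joint = sorted(starts[:n_joint])
    rip_only = sorted(starts[n_joint:n_joint + n_ripple_only])
    sw_only = sorted(starts[n_joint + n_ripple_only:])

    j_rip, j_sw = inject_swr_events(
        pyr, rad, joint, fs, ripple_freq, ripple_dur_ms, ripple_amp, sw_amp
    )
    r_rip, _ = inject_swr_events(
        pyr, rad, rip_only, fs, ripple_freq, ripple_dur_ms, ripple_amp,
        sw_amp, with_sw=False,
    )
    _, s_sw = inject_swr_events(
        pyr, rad, sw_only, fs, ripple_freq, ripple_dur_ms, ripple_amp,
        sw_amp, with_ripple=False,
    )
    truth = GroundTruth(
        swr_times=[(a, b, 0) for a, b in j_rip],
        sw_times=[(a, b, 1) for a, b in j_sw + s_sw],
        ripple_only_times=[(a, b, 0) for a, b in r_rip],
        sw_only_times=[(a, b, 1) for a, b in s_sw],
    )
    return pyr, rad, truth
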