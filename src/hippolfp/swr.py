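"""Sharp wave-ripple detection and event features.

Ripples: the pyramidal-layer signal is band-passed 120-250 Hz (zero-phase
Butterworth in second-order sections), downsampled to 1200 Hz, segmented
by behavioral epoch, and each segment is z-scored, rectified, and
smoothed with an 8-ms rectangular window to form the ripple power signal.
Candidate events are runs with at least one sample above mean + 3 SD of
the segment's power signal, expanded bidirectionally to the last sample
above mean + 2 SD; events shorter than 30 ms or with a peak spectral
frequency below 140 Hz are discarded.

Sharp waves: the stratum-radiatum signal is band-passed 0.5-40 Hz and the
magnitude of the filtered signal thresholded at mean + 2.5 SD; events
lasting 20-400 ms are kept.  Only ripples that co-occur (overlap in time)
with a sharp wave survive; per-event features (duration, peak spectral
frequency, 120-250 Hz band power, slow-gamma power and peak frequency)
and the exploration/immobility occurrence-rate ratio are then computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import BehaviorEpoch
from .synthetic import EXPLORATION, IMMOBILITY

log = logging.getLogger(__name__)

RIPPLE_BAND = (120.0, 250.0)
SW_BAND = (0.5, 40.0)
SLOW_GAMMA_BAND = (30.0, 45.0)
TARGET_FS = 1200.0


@dataclass
class SwrEvent:
    channel: int
    state: str
    start_s: float
    end_s: float
    psf_hz: float
    band_power: float
    slow_gamma_power: float = np.nan
    slow_gamma_psf_hz: float = np.nan
    paired_sw: bool = False
    trial: int = 1

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class SharpWaveEvent:
    channel: int
    start_s: float
    end_s: float

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class RipplePowerSignal:
    """Per-epoch ripple power (z-units) plus the band-passed trace."""

    fs: float
    segments: list[dict]  # start_s, state, power, filtered


def _bandpass_sos(fs: float, band: tuple[float, float], order: int = 8):
    lo, hi = band
    hi = min(hi, 0.99 * fs / 2)
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def ripple_power(
    x: np.ndarray,
    fs_in: float,
    epochs: Sequence[BehaviorEpoch] | None = None,
    band: tuple[float, float] = RIPPLE_BAND,
    fs_out: float = TARGET_FS,
    smooth_ms: float = 8.0,
    filter_order: int = 8,
) -> RipplePowerSignal:
    """Band-pass, decimate, then z-score/rectify/smooth per epoch."""
    if fs_in < 2 * fs_out:
        raise ValueError(
            f"fs_in={fs_in} too low to decimate to {fs_out} Hz"
        )
    x = np.asarray(x, float)
    sos = _bandpass_sos(fs_in, band, filter_order)
    filtered = sps.sosfiltfilt(sos, x)
    filt_ds = _resample_to(filtered, fs_in, fs_out)
    # a constant (or in-band-silent) input leaves only numerical filter
    # residue; z-scoring that residue would manufacture unit-variance
    # noise, so such segments are flagged degenerate instead
    sd_floor = 1e-9 * max(float(np.abs(x).max()), 1e-30)
    if epochs is None:
        epochs = [BehaviorEpoch("all", 0.0, len(x) / fs_in, 0, len(x))]
    win = max(int(round(smooth_ms / 1000.0 * fs_out)), 1)
    kernel = np.ones(win) / win
    segments = []
    for ep in epochs:
        s0 = int(round(ep.start_sample * fs_out / fs_in))
        s1 = int(round(ep.end_sample * fs_out / fs_in))
        s1 = min(s1, len(filt_ds))
        seg = filt_ds[s0:s1]
        if len(seg) < int(0.030 * fs_out):
            log.info(
                "skipping %s segment at %.3f s: shorter than 30 ms",
                ep.state, ep.start_s,
            )
            continue
        sd = seg.std()
        if sd <= sd_floor:
            log.warning("degenerate (constant) segment at %.3f s", ep.start_s)
            z = np.zeros_like(seg)
        else:
            z = (seg - seg.mean()) / sd
        power = np.convolve(np.abs(z), kernel, mode="same")
        segments.append(
            {
                "start_s": s0 / fs_out,
                "state": ep.state,
                "power": power,
                "filtered": seg,
            }
        )
    return RipplePowerSignal(fs=fs_out, segments=segments)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(idx[::2], idx[1::2]))


def event_psf(
    filtered_event: np.ndarray,
    fs: float,
    band: tuple[float, float] = RIPPLE_BAND,
) -> float:
    """Peak spectral frequency of an event trace within ``band``.

    The periodogram is zero-padded to at least 1 Hz resolution.
    """
    n = len(filtered_event)
    if n < int(0.020 * fs):
        raise ValueError("event too short for a spectral peak estimate")
    nfft = max(int(fs), n)
    f, p = sps.periodogram(filtered_event, fs=fs, nfft=nfft, window="hann")
    mask = (f >= band[0]) & (f <= band[1])
    return float(f[mask][np.argmax(p[mask])])


def _event_band_power(
    filtered_event: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    nfft = max(int(fs), len(filtered_event))
    f, p = sps.periodogram(filtered_event, fs=fs, nfft=nfft, window="hann")
    df = f[1] - f[0]
    return float(p[(f >= band[0]) & (f < band[1])].sum() * df)


def detect_ripples(
    rp: RipplePowerSignal,
    core_sd: float = 3.0,
    edge_sd: float = 2.0,
    min_dur_ms: float = 30.0,
    min_psf_hz: float = 140.0,
    psf_band: tuple[float, float] = RIPPLE_BAND,
) -> list[SwrEvent]:
    """Dual-threshold ripple detection on the power signal.

    Thresholds are mean + k*SD of each segment's own power signal.  Runs
    above the edge threshold that contain at least one sample above the
    core threshold become candidates (maximal runs are disjoint by
    construction, which realizes the merge-on-touch rule); candidates are
    then filtered by duration and by peak spectral frequency.
    """
    events: list[SwrEvent] = []
    fs = rp.fs
    for seg in rp.segments:
        power = seg["power"]
        mu, sd = power.mean(), power.std()
        if sd == 0:
            continue
        core = mu + core_sd * sd
        edge = mu + edge_sd * sd
        for i0, i1 in _runs_above(power > edge):
            if not np.any(power[i0:i1] > core):
                continue
            dur_ms = (i1 - i0) / fs * 1000.0
            if dur_ms < min_dur_ms:
                continue
            trace = seg["filtered"][i0:i1]
            psf = event_psf(trace, fs, psf_band)
            if psf < min_psf_hz:
                continue
            events.append(
                SwrEvent(
                    channel=-1,
                    state=seg["state"],
                    start_s=seg["start_s"] + i0 / fs,
                    end_s=seg["start_s"] + i1 / fs,
                    psf_hz=psf,
                    band_power=_event_band_power(trace, fs, psf_band),
                )
            )
    events.sort(key=lambda e: e.start_s)
    return events


def detect_sharp_waves(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = SW_BAND,
    thresh_sd: float = 2.5,
    dur_ms: tuple[float, float] = (20.0, 400.0),
    epochs: Sequence[BehaviorEpoch] | None = None,
    filter_order: int = 4,
) -> list[SharpWaveEvent]:
    """Threshold detection of sharp waves on the radiatum channel.

    Applied to the magnitude of the band-passed signal (polarity-
    agnostic), thresholded at mean + ``thresh_sd`` * SD of the magnitude;
    events outside the 20-400 ms duration window are discarded.
    """
    sos = _bandpass_sos(fs, band, filter_order)
    filtered = sps.sosfiltfilt(sos, np.asarray(x, float))
    windows = (
        [(ep.start_sample, ep.end_sample) for ep in epochs]
        if epochs is not None else [(0, len(x))]
    )
    events: list[SharpWaveEvent] = []
    for s0, s1 in windows:
        seg = np.abs(filtered[s0:s1])
        if len(seg) < int(dur_ms[0] / 1000.0 * fs):
            continue
        thr = seg.mean() + thresh_sd * seg.std()
        for i0, i1 in _runs_above(seg > thr):
            d = (i1 - i0) / fs * 1000.0
            if dur_ms[0] <= d <= dur_ms[1]:
                events.append(
                    SharpWaveEvent(
                        channel=-1,
                        start_s=(s0 + i0) / fs,
                        end_s=(s0 + i1) / fs,
                    )
                )
    events.sort(key=lambda e: e.start_s)
    return events


def pair_events(
    ripples: list[SwrEvent], sharp_waves: list[SharpWaveEvent]
) -> list[SwrEvent]:
    """Keep only ripples whose interval overlaps some sharp wave."""
    out = []
    j = 0
    sws = sorted(sharp_waves, key=lambda e: e.start_s)
    for rip in sorted(ripples, key=lambda e: e.start_s):
        while j < len(sws) and sws[j].end_s <= rip.start_s:
            j += 1
        k = j
        paired = False
        while k < len(sws) and sws[k].start_s < rip.end_s:
            if min(rip.end_s, sws[k].end_s) > max(rip.start_s, sws[k].start_s):
                paired = True
                break
            k += 1
        if paired:
            rip.paired_sw = True
            out.append(rip)
    return out


def slow_gamma_features(
    x: np.ndarray,
    fs: float,
    event: SwrEvent,
    band: tuple[float, float] = SLOW_GAMMA_BAND,
    min_window_s: float = 0.100,
) -> tuple[float, float]:
    """Slow-gamma band power and peak frequency over the event window.

    Windows shorter than 100 ms are extended symmetrically around the
    event center (the spectral resolution of a 30 ms window cannot
    resolve a 15-Hz-wide band).
    """
    c = (event.start_s + event.end_s) / 2.0
    half = max((event.end_s - event.start_s) / 2.0, min_window_s / 2.0)
    i0 = max(int((c - half) * fs), 0)
    i1 = min(int((c + half) * fs), len(x))
    seg = np.asarray(x[i0:i1], float)
    nfft = max(int(fs), len(seg))
    f, p = sps.periodogram(seg - seg.mean(), fs=fs, nfft=nfft, window="hann")
    df = f[1] - f[0]
    mask = (f >= band[0]) & (f <= band[1])
    power = float(p[mask].sum() * df)
    psf = float(f[mask][np.argmax(p[mask])])
    return power, psf


def attach_slow_gamma(
    events: list[SwrEvent], x: np.ndarray, fs: float,
    band: tuple[float, float] = SLOW_GAMMA_BAND,
) -> None:
    for ev in events:
        ev.slow_gamma_power, ev.slow_gamma_psf_hz = slow_gamma_features(
            x, fs, ev, band
        )


def occurrence_ratio(
    events: list[SwrEvent],
    epochs: Sequence[BehaviorEpoch],
    state_a: str = EXPLORATION,
    state_b: str = IMMOBILITY,
) -> float:
    """Occurrence-rate ratio (events/s in A) / (events/s in B)."""
    dur = {state_a: 0.0, state_b: 0.0}
    for ep in epochs:
        if ep.state in dur:
            dur[ep.state] += ep.duration_s
    if dur[state_b] <= 0:
        raise ValueError(f"degenerate input: zero {state_b} duration")
    if dur[state_a] <= 0:
        raise ValueError(f"degenerate input: zero {state_a} duration")
    n_a = sum(1 for e in events if e.state == state_a)
    n_b = sum(1 for e in events if e.state == state_b)
    if n_b == 0:
        return float("inf")
    return (n_a / dur[state_a]) / (n_b / dur[state_b])


def events_to_frame(events: list[SwrEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": e.channel, "state": e.state, "trial": e.trial,
                "start_s": e.start_s, "end_s": e.end_s,
                "duration_ms": e.duration_ms, "psf_hz": e.psf_hz,
                "band_power": e.band_power,
                "slow_gamma_power": e.slow_gamma_power,
                "slow_gamma_psf_hz": e.slow_gamma_psf_hz,
                "paired_sw": e.paired_sw,
            }
            for e in events
        ]
    )


def match_events(
    detected: list[SwrEvent],
    truth: Sequence[tuple[float, float]],
) -> tuple[int, int, int]:
    """(true positives, false positives, false negatives) by interval
    overlap; each truth interval matches at most one detection."""
    used = [False] * len(truth)
    tp = fp = 0
    for ev in detected:
        hit = False
        for k, (a, b) in enumerate(truth):
            if used[k]:
                continue
            if min(ev.end_s, b) > max(ev.start_s, a):
                used[k] = True
                hit = True
                break
        tp += hit
        fp += not hit
    fn = used.count(False)
    return tp, fp, fn
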