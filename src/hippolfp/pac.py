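"""Theta-gamma phase-amplitude coupling.

The coupling strength between a slow rhythm's phase and a fast rhythm's
amplitude envelope is quantified by the envelope-normalized mean vector
length (MVL) modulation index

    MI = | <A(t) * exp(i*phi(t))> | / <A(t)>,

where phi is the analytic-signal phase of the band-passed slow component
and A the analytic-signal envelope of the band-passed fast component.
The normalization bounds MI in [0, 1] and makes it invariant to amplitude
rescaling of either signal, so subjects with different electrode gains
are comparable.  A sinusoidally modulated envelope A = 1 + cos(phi) gives
MI = 1/2 in the continuous limit.

Surfaces: single-pair MI, the 1-Hz-binned comodulogram over theta
(5-12 Hz) x gamma (30-120 Hz), time-resolved PAC (MI per 1-s window of
each behavioral epoch), circular-shift surrogates for significance, and
an 18-bin Kullback-Leibler MI as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng
from scipy import signal as sps

#: tPAC band pairs of interest by behavioral state (phase Hz, amplitude Hz)
TPAC_BAND_PAIRS = {
    "exploration": [((6.5, 10.0), (55.0, 90.0)), ((6.5, 9.0), (35.0, 45.0))],
    "wake_immobility": [((6.5, 9.0), (60.0, 90.0))],
}


@dataclass
class MiEstimate:
    mi: float
    phase_band: tuple[float, float] | None = None
    amp_band: tuple[float, float] | None = None
    n_samples: int = 0


@dataclass
class Comodulogram:
    phase_freqs: np.ndarray   # bin centers, Hz
    amp_freqs: np.ndarray     # bin centers, Hz
    mi_matrix: np.ndarray     # (n_phase, n_amp)
    n_epochs: int = 0

    def argmax_bin(self) -> tuple[float, float]:
        i, j = np.unravel_index(
            int(np.argmax(self.mi_matrix)), self.mi_matrix.shape
        )
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


@dataclass
class TPacSeries:
    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    mi_values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def mean(self) -> float:
        return float(np.mean(self.mi_values))

    @property
    def sem(self) -> float:
        n = len(self.mi_values)
        return float(np.std(self.mi_values, ddof=1) / np.sqrt(n)) if n > 1 \
            else np.nan


def _twopass_corners(sos: np.ndarray, fs: float, f_grid: np.ndarray):
    """Measured -3 dB corners of the forward-backward (squared) response."""
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * f_grid / fs)
    mag2 = np.abs(h) ** 2  # filtfilt applies |H|^2
    above = mag2 >= 1.0 / np.sqrt(2.0)
    if not above.any():
        return None
    idx = np.flatnonzero(above)
    return float(f_grid[idx[0]]), float(f_grid[idx[-1]])


from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=4096)
def _design_sos(
    fs: float, lo: float, hi: float, order: int, correction: bool
) -> np.ndarray:
    """Butterworth band-pass SOS whose two-pass -3 dB corners land on the
    requested edges (iteratively calibrated; filtfilt squares |H|)."""
    d_lo, d_hi = lo, hi
    if correction:
        # initial guess from the lowpass-prototype relation
        c = (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))
        d_lo, d_hi = lo * c, min(hi / c, 0.995 * fs / 2)
        f_grid = np.linspace(max(lo / 4, 0.01), min(3 * hi, fs / 2), 8192)
        for _ in range(4):
            sos = sps.butter(
                order, [d_lo, d_hi], btype="bandpass", fs=fs, output="sos"
            )
            meas = _twopass_corners(sos, fs, f_grid)
            if meas is None:
                break
            m_lo, m_hi = meas
            if abs(m_lo - lo) < 0.02 and abs(m_hi - hi) < 0.02:
                break
            d_lo = max(d_lo * lo / max(m_lo, 1e-9), 0.01)
            d_hi = min(d_hi * hi / max(m_hi, 1e-9), 0.995 * fs / 2)
    return sps.butter(order, [d_lo, d_hi], btype="bandpass", fs=fs,
                      output="sos")


def bandpass(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 4,
    corner_correction: bool = True,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, SOS)."""
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs/2})")
    sos = _design_sos(float(fs), float(lo), float(hi), order,
                      bool(corner_correction))
    return sps.sosfiltfilt(sos, np.asarray(x, float))


def edge_samples(fs: float, f_lo: float, n_cycles: float = 2.0) -> int:
    """Samples to discard at each epoch edge (filter transient guard)."""
    return int(round(n_cycles * fs / f_lo))


def phase_and_envelope(
    filtered_phase_sig: np.ndarray,
    filtered_amp_sig: np.ndarray,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic-signal phase (rad) and magnitude envelope."""
    xp = np.asarray(filtered_phase_sig, float)
    xa = np.asarray(filtered_amp_sig, float)
    if len(xp) != len(xa):
        raise ValueError("phase and amplitude signals differ in length")
    if np.ptp(xp) == 0 or np.ptp(xa) == 0:
        raise ValueError("degenerate input: constant signal")
    n = len(xp)
    nfast = int(2 ** np.ceil(np.log2(n))) if n & (n - 1) else n
    phase = np.angle(sps.hilbert(xp, N=nfast)[:n])
    env = np.abs(sps.hilbert(xa, N=nfast)[:n])
    return phase, env


def mvl_mi(phase: np.ndarray, envelope: np.ndarray) -> MiEstimate:
    """Envelope-normalized mean-vector-length modulation index."""
    phase = np.asarray(phase, float)
    env = np.asarray(envelope, float)
    if len(phase) != len(env):
        raise ValueError("phase and envelope differ in length")
    s = env.sum()
    if s <= 0:
        raise ValueError("degenerate input: zero mean envelope")
    vec = np.abs(np.sum(env * np.exp(1j * phase))) / s
    return MiEstimate(mi=float(vec), n_samples=len(phase))


def kl_mi(phase: np.ndarray, envelope: np.ndarray, n_bins: int = 18) -> float:
    """Binned Kullback-Leibler modulation index (cross-check estimator).

    The envelope is averaged within phase bins; the KL divergence of the
    normalized distribution from uniform, over log(n_bins), gives the MI.
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    mean_amp = np.array(
        [envelope[idx == b].mean() if np.any(idx == b) else 0.0
         for b in range(n_bins)]
    )
    p = mean_amp / mean_amp.sum()
    p = np.where(p > 0, p, 1e-12)
    return float((np.log(n_bins) + np.sum(p * np.log(p))) / np.log(n_bins))


def _epoch_slices(epochs) -> list[tuple[int, int]]:
    out = []
    for ep in epochs:
        if hasattr(ep, "start_sample"):
            out.append((ep.start_sample, ep.end_sample))
        else:
            out.append((int(ep[0]), int(ep[1])))
    return out


def pair_mi(
    x: np.ndarray,
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    discard_edges: bool = True,
) -> MiEstimate:
    """MI of one signal stretch for one (phase band, amplitude band) pair."""
    ph = bandpass(x, fs, phase_band)
    am = bandpass(x, fs, amp_band)
    phase, env = phase_and_envelope(ph, am)
    if discard_edges:
        e = edge_samples(fs, phase_band[0])
        if 2 * e < len(phase):
            phase, env = phase[e:-e], env[e:-e]
    est = mvl_mi(phase, env)
    est.phase_band, est.amp_band = phase_band, amp_band
    return est


def comodulogram(
    x: np.ndarray,
    fs: float,
    epochs,
    phase_range: tuple[float, float] = (5.0, 12.0),
    amp_range: tuple[float, float] = (30.0, 120.0),
    phase_bw: float = 2.0,
    amp_bw_factor: float = 3.0,
) -> Comodulogram:
    """MI for every 1-Hz (phase, amplitude) bin pair, averaged over epochs.

    Phase bins are centered at integer Hz with full width ``phase_bw``;
    each amplitude bin's filter width is ``amp_bw_factor`` times the phase
    frequency of the pair.  Width 2x the phase frequency would place the
    modulation sidebands (amp +/- phase) exactly on the -3 dB corners and
    halve the measured coupling; 3x keeps them inside the passband.
    """
    slices = [
        (s0, s1) for s0, s1 in _epoch_slices(epochs) if s1 - s0 >= int(fs)
    ]
    if not slices:
        raise ValueError("no epoch of at least 1 s")
    pf = np.arange(np.ceil(phase_range[0]), np.floor(phase_range[1]) + 1)
    af = np.arange(np.ceil(amp_range[0]), np.floor(amp_range[1]) + 1)
    mi = np.zeros((len(pf), len(af)))
    for s0, s1 in slices:
        seg = x[s0:s1]
        for i, fp in enumerate(pf):
            ph_f = bandpass(seg, fs, (fp - phase_bw / 2, fp + phase_bw / 2))
            e = edge_samples(fs, fp - phase_bw / 2)
            nfast = int(2 ** np.ceil(np.log2(len(ph_f)))) \
                if len(ph_f) & (len(ph_f) - 1) else len(ph_f)
            phase = np.angle(sps.hilbert(ph_f, N=nfast)[:len(ph_f)])
            for j, fa in enumerate(af):
                half = amp_bw_factor * fp / 2.0
                am_f = bandpass(seg, fs, (max(fa - half, 1.0), fa + half))
                env = np.abs(sps.hilbert(am_f, N=nfast)[:len(am_f)])
                if 2 * e < len(phase):
                    est = mvl_mi(phase[e:-e], env[e:-e])
                else:
                    est = mvl_mi(phase, env)
                mi[i, j] += est.mi
    mi /= len(slices)
    return Comodulogram(
        phase_freqs=pf, amp_freqs=af, mi_matrix=mi, n_epochs=len(slices)
    )


def group_comodulogram(comods: list[Comodulogram]) -> Comodulogram:
    """Group average: mean of subject MI matrices on a shared grid."""
    ref = comods[0]
    mats = np.stack([c.mi_matrix for c in comods])
    return Comodulogram(
        phase_freqs=ref.phase_freqs, amp_freqs=ref.amp_freqs,
        mi_matrix=mats.mean(axis=0), n_epochs=sum(c.n_epochs for c in comods),
    )


def local_maxima(
    comod: Comodulogram,
    min_fraction_of_peak: float = 0.6,
    min_prominence: float = 0.2,
    smooth_bins: int = 3,
) -> list[tuple[float, float]]:
    """(phase, amp) centers of local maxima along the amplitude axis of the
    best phase row.

    The row is lightly smoothed, then peaks are kept if they exceed
    ``min_fraction_of_peak`` of the row maximum with prominence at least
    ``min_prominence`` of it — filtering the low single-sideband beat
    artifacts that flank every genuine coupling mode.
    """
    i_best = int(np.argmax(comod.mi_matrix.max(axis=1)))
    row = comod.mi_matrix[i_best]
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        row = np.convolve(row, kernel, mode="same")
    peaks, _ = sps.find_peaks(
        row,
        height=min_fraction_of_peak * row.max(),
        prominence=min_prominence * row.max(),
    )
    out = [
        (float(comod.phase_freqs[i_best]), float(comod.amp_freqs[j]))
        for j in peaks
    ]
    if not out:  # monotone row: global max sits on the boundary
        out = [comod.argmax_bin()]
    return out


def tpac(
    x: np.ndarray,
    fs: float,
    epochs,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    epoch_len_s: float = 1.0,
) -> TPacSeries:
    """Time-resolved PAC: MI per non-overlapping 1-s window.

    Filtering and the analytic transform run over the whole behavioral
    epoch (edge guard discarded once per epoch), then the interior is cut
    into ``epoch_len_s`` windows; the remainder is discarded.
    """
    win = int(round(epoch_len_s * fs))
    values = []
    for s0, s1 in _epoch_slices(epochs):
        seg = x[s0:s1]
        if len(seg) < win:
            continue
        ph_f = bandpass(seg, fs, phase_band)
        am_f = bandpass(seg, fs, amp_band)
        phase, env = phase_and_envelope(ph_f, am_f)
        e = edge_samples(fs, phase_band[0])
        if 2 * e < len(phase) - win:
            phase, env = phase[e:-e], env[e:-e]
        for k in range(len(phase) // win):
            sl = slice(k * win, (k + 1) * win)
            values.append(mvl_mi(phase[sl], env[sl]).mi)
    if not values:
        raise ValueError("no complete tPAC window in any epoch")
    return TPacSeries(
        phase_band=phase_band, amp_band=amp_band,
        mi_values=np.asarray(values),
    )


def surrogate_mi(
    phase: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    n_surrogates: int = 200,
    min_shift_s: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Null MI distribution from circular time-shifts of the envelope."""
    rng = default_rng(seed)
    n = len(envelope)
    min_shift = int(min_shift_s * fs)
    if 2 * min_shift >= n:
        raise ValueError("signal too short for the minimum surrogate shift")
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    return np.array(
        [mvl_mi(phase, np.roll(envelope, s)).mi for s in shifts]
    )
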