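"""Welch spectra, band powers and normalized-power summaries.

Per behavioral state, Welch periodogram segments (1-s Hann windows, 50%
overlap, constant detrend) are pooled across all epochs of that state
with equal segment weight.  Band power is the rectangle-rule integral of
the density over a half-open [lo, hi) band; normalized power divides by
the total power over 0.5-250 Hz, making every reported fraction invariant
to the absolute amplitude (and hence to electrode impedance/placement
gain differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import BehaviorEpoch


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")


#: canonical analysis bands (half-open intervals, Hz)
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.4, 4.0),
    BandDefinition("theta_low", 5.0, 8.0),
    BandDefinition("theta_high", 8.0, 12.0),
    BandDefinition("slow_gamma", 30.0, 45.0),
    BandDefinition("fast_gamma", 60.0, 120.0),
    BandDefinition("hfo", 120.0, 250.0),
)

TOTAL_POWER_RANGE = (0.5, 250.0)


@dataclass
class Psd:
    freqs: np.ndarray
    density: np.ndarray   # power density, units^2/Hz
    n_segments: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> Psd:
    """One-sided Welch PSD (Hann taper, density scaling)."""
    x = np.asarray(x, float)
    nperseg = int(round(window_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"signal of {len(x)} samples shorter than the "
            f"{nperseg}-sample Welch window"
        )
    noverlap = int(round(nperseg * overlap))
    f, p = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    k = 1 + (len(x) - nperseg) // (nperseg - noverlap)
    return Psd(freqs=f, density=p, n_segments=k)


def pooled_psd(
    x: np.ndarray,
    fs: float,
    epochs: Sequence[BehaviorEpoch | tuple[int, int]],
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> Psd:
    """Welch PSD pooled over epochs with equal weight per segment."""
    acc = None
    total_k = 0
    for ep in epochs:
        if isinstance(ep, BehaviorEpoch):
            s0, s1 = ep.start_sample, ep.end_sample
        else:
            s0, s1 = ep
        seg = x[s0:s1]
        if len(seg) < int(round(window_s * fs)):
            continue
        psd = welch_psd(seg, fs, window_s, overlap)
        w = psd.n_segments
        acc = psd.density * w if acc is None else acc + psd.density * w
        total_k += w
        freqs = psd.freqs
    if acc is None:
        raise ValueError("no epoch long enough for the Welch window")
    return Psd(freqs=freqs, density=acc / total_k, n_segments=total_k)


def band_power(psd: Psd, band: BandDefinition | tuple[float, float]) -> float:
    """Rectangle-rule integral of the density over [f_lo, f_hi)."""
    lo, hi = (band.f_lo, band.f_hi) if isinstance(band, BandDefinition) \
        else band
    if lo < psd.freqs[0] - psd.df or hi > psd.freqs[-1] + psd.df:
        raise ValueError(f"band [{lo}, {hi}) outside the PSD grid")
    mask = (psd.freqs >= lo) & (psd.freqs < hi)
    return float(psd.density[mask].sum() * psd.df)


def normalized_band_power(
    psd: Psd,
    band: BandDefinition | tuple[float, float],
    total: tuple[float, float] = TOTAL_POWER_RANGE,
) -> float:
    """Band power as a fraction of total power over ``total``."""
    tot = band_power(psd, total)
    if tot <= 0:
        raise ValueError("degenerate input: zero total power")
    return band_power(psd, band) / tot


def state_band_powers(
    data: np.ndarray,
    fs: float,
    epochs_by_state: dict[str, Sequence[BehaviorEpoch]],
    bands: Iterable[BandDefinition] = CANONICAL_BANDS,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Absolute and normalized band power per (channel, state, band).

    ``data`` is (n_channels, n_samples); epochs carry LFP sample indices.
    """
    bands = list(bands)
    rows = []
    for state, epochs in epochs_by_state.items():
        for ch in range(data.shape[0]):
            psd = pooled_psd(data[ch], fs, epochs, window_s, overlap)
            tot = band_power(psd, TOTAL_POWER_RANGE)
            for b in bands:
                p = band_power(psd, b)
                rows.append(
                    {
                        "channel": ch, "state": state, "band": b.name,
                        "abs_power": p,
                        "norm_power": p / tot if tot > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def top_channel_summary(
    power_table: pd.DataFrame, band: str, k: int = 3
) -> float:
    """Mean normalized power over the k channels with the highest power.

    Channel ranking is per band, pooled across states (mean over states),
    so the same channel set enters the within-subject state comparison.
    """
    sub = power_table[power_table["band"] == band]
    by_ch = sub.groupby("channel")["norm_power"].mean()
    if len(by_ch) < k:
        raise ValueError(f"need >= {k} channels, got {len(by_ch)}")
    top = by_ch.sort_values(ascending=False).index[:k]
    return float(sub[sub["channel"].isin(top)]["norm_power"].mean())


def top_channel_table(
    power_table: pd.DataFrame, k: int = 3
) -> pd.DataFrame:
    """Per (state, band) top-k-channel mean normalized power."""
    rows = []
    for band in power_table["band"].unique():
        sub = power_table[power_table["band"] == band]
        by_ch = sub.groupby("channel")["norm_power"].mean()
        top = set(by_ch.sort_values(ascending=False).index[:k])
        for state, g in sub[sub["channel"].isin(top)].groupby("state"):
            rows.append(
                {
                    "state": state, "band": band,
                    "norm_power_top3": float(g["norm_power"].mean()),
                }
            )
    return pd.DataFrame(rows)
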