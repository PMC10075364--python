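"""Behavioral-state segmentation and open-field metrics.

Tracking speed is classified frame-by-frame into exploration (> 0.05 m/s),
grooming (0-0.05 m/s) and wake immobility (0 m/s, within a numeric
tolerance); grooming and sub-second runs are discarded, and the surviving
epochs are mapped onto LFP sample indices through the shared TTL pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import EXPLORATION, GROOMING, IMMOBILITY

SPEED_THRESHOLD_M_S = 0.05   # exploration vs grooming boundary
ZERO_SPEED_TOL_M_S = 1e-3    # "0 m/s" immobility, robust to tracker jitter


@dataclass
class TrackingTrace:
    """Animal position samples on a shared clock with the LFP TTLs."""

    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    frame_rate: float
    arena_side_m: float = 1.0
    ttl_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_rate: float = 30.0,
        arena_side_m: float = 1.0,
        ttl_s=None,
    ) -> "TrackingTrace":
        return cls(
            t_s=df["t_s"].to_numpy(float),
            x_m=df["x_m"].to_numpy(float),
            y_m=df["y_m"].to_numpy(float),
            frame_rate=frame_rate,
            arena_side_m=arena_side_m,
            ttl_s=np.asarray(ttl_s if ttl_s is not None else [], float),
        )

    @property
    def n_frames(self) -> int:
        return len(self.t_s)


@dataclass
class BehaviorEpoch:
    """Half-open [start_s, end_s) interval of one behavioral state."""

    state: str
    start_s: float
    end_s: float
    start_sample: int | None = None
    end_sample: int | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class OpenFieldMetrics:
    total_distance_m: float
    inner_time_s: float
    inner_distance_m: float
    inner_entries: int
    per_epoch: pd.DataFrame  # one row per 5-min window


def compute_speed(
    tracking: TrackingTrace, smooth_window: int = 0
) -> np.ndarray:
    """Frame-to-frame speed in m/s; speed[0] copies speed[1].

    ``smooth_window`` > 1 applies a centered moving median of that many
    frames (off by default).
    """
    if tracking.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    dx = np.diff(tracking.x_m)
    dy = np.diff(tracking.y_m)
    speed = np.empty(tracking.n_frames)
    speed[1:] = np.hypot(dx, dy) * tracking.frame_rate
    speed[0] = speed[1]
    if smooth_window > 1:
        speed = (
            pd.Series(speed)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    return speed


def classify_frames(
    speed: np.ndarray,
    threshold: float = SPEED_THRESHOLD_M_S,
    zero_tol: float = ZERO_SPEED_TOL_M_S,
) -> np.ndarray:
    """Per-frame state label from speed.

    > threshold -> exploration; (zero_tol, threshold] -> grooming;
    <= zero_tol -> wake immobility.
    """
    speed = np.asarray(speed, float)
    if np.any(speed < 0):
        raise ValueError("speeds must be non-negative")
    labels = np.where(
        speed > threshold,
        EXPLORATION,
        np.where(speed > zero_tol, GROOMING, IMMOBILITY),
    )
    return labels.astype(object)


def frames_to_epochs(
    labels: np.ndarray,
    t_s: np.ndarray,
    frame_rate: float,
    min_dur_s: float = 1.0,
    drop: Sequence[str] = (GROOMING,),
) -> list[BehaviorEpoch]:
    """Maximal same-label runs -> epochs; drop grooming and short runs.

    Epoch end is one frame period past the last frame of the run, so
    consecutive epochs tile the trial before dropping.  Dropped runs leave
    gaps: surviving epochs keep their original times (no merging across
    removed material).
    """
    labels = np.asarray(labels, dtype=object)
    t_s = np.asarray(t_s, float)
    if len(labels) != len(t_s):
        raise ValueError("labels and t_s must have equal length")
    if len(labels) == 0:
        return []
    dt = 1.0 / frame_rate
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    epochs = []
    for i0, i1 in zip(starts, ends):
        state = labels[i0]
        ep = BehaviorEpoch(
            state=state, start_s=float(t_s[i0]), end_s=float(t_s[i1 - 1] + dt)
        )
        if state in drop or ep.duration_s < min_dur_s - 1e-9:
            continue
        epochs.append(ep)
    return epochs


def align_to_lfp(
    epochs: list[BehaviorEpoch],
    tracking_ttl_s: np.ndarray,
    lfp_ttl_s: np.ndarray,
    fs: float,
    n_samples: int | None = None,
) -> list[BehaviorEpoch]:
    """Map epoch times from the camera clock to LFP sample indices.

    An affine map lfp_t = a * cam_t + b is least-squares fit through the
    matched TTL pairs (one shared pulse gives a pure offset, two or more
    also estimate clock drift).  Sample indices are half-open and clipped
    to the recording when its length is known.
    """
    cam = np.asarray(tracking_ttl_s, float)
    lfp = np.asarray(lfp_ttl_s, float)
    m = min(len(cam), len(lfp))
    if m == 0:
        raise ValueError("alignment failure: no shared TTL pulses")
    cam, lfp = cam[:m], lfp[:m]
    if m == 1:
        a, b = 1.0, float(lfp[0] - cam[0])
    else:
        a, b = np.polyfit(cam, lfp, 1)
    out = []
    for ep in epochs:
        s0 = int(round((a * ep.start_s + b) * fs))
        s1 = int(round((a * ep.end_s + b) * fs))
        if n_samples is not None:
            s0 = max(0, min(s0, n_samples))
            s1 = max(0, min(s1, n_samples))
        out.append(
            BehaviorEpoch(
                state=ep.state, start_s=ep.start_s, end_s=ep.end_s,
                start_sample=s0, end_sample=s1,
            )
        )
    return out


def openfield_metrics(
    tracking: TrackingTrace,
    inner_fraction: float = 0.5,
    window_s: float = 300.0,
) -> OpenFieldMetrics:
    """Distance and inner-area occupancy, whole-trial and per 5-min window.

    The inner area is a centered square whose side is ``inner_fraction``
    of the arena side.  Entries are counted on outside-to-inside
    transitions; each frame-to-frame displacement is attributed to the
    window and area of its destination frame.  The last partial window is
    kept and flagged.
    """
    if not 0.0 < inner_fraction < 1.0:
        raise ValueError("inner_fraction must be in (0, 1)")
    side = tracking.arena_side_m
    lo = side * (1 - inner_fraction) / 2.0
    hi = side - lo
    inside = (
        (tracking.x_m >= lo) & (tracking.x_m <= hi)
        & (tracking.y_m >= lo) & (tracking.y_m <= hi)
    )
    step = np.concatenate(
        [[0.0], np.hypot(np.diff(tracking.x_m), np.diff(tracking.y_m))]
    )
    dt = 1.0 / tracking.frame_rate
    # an entry is an outside->inside transition; starting inside is not one
    entries_mask = np.concatenate([[False], inside[1:] & ~inside[:-1]])

    t0 = tracking.t_s[0]
    win_idx = np.floor((tracking.t_s - t0) / window_s).astype(int)
    rows = []
    for w in range(win_idx.max() + 1):
        sel = win_idx == w
        full = (tracking.t_s[sel][-1] - (t0 + w * window_s)) >= (
            window_s - 1.5 * dt
        )
        rows.append(
            {
                "window": w,
                "total_distance_m": float(step[sel].sum()),
                "inner_time_s": float(inside[sel].sum() * dt),
                "inner_distance_m": float(step[sel][inside[sel]].sum()),
                "inner_entries": int(entries_mask[sel].sum()),
                "partial": not full,
            }
        )
    per_epoch = pd.DataFrame(rows)
    entries_total = int(entries_mask.sum())
    return OpenFieldMetrics(
        total_distance_m=float(step.sum()),
        inner_time_s=float(inside.sum() * dt),
        inner_distance_m=float(step[inside].sum()),
        inner_entries=entries_total,
        per_epoch=per_epoch,
    )


def epochs_to_frame(epochs: list[BehaviorEpoch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "state": ep.state,
                "start_s": ep.start_s,
                "end_s": ep.end_s,
                "start_sample": ep.start_sample,
                "end_sample": ep.end_sample,
            }
            for ep in epochs
        ]
    )


def state_durations(epochs: list[BehaviorEpoch]) -> dict[str, float]:
    out: dict[str, float] = {}
    for ep in epochs:
        out[ep.state] = out.get(ep.state, 0.0) + ep.duration_s
    return out
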