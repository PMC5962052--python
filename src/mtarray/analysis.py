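"""Steady-state summaries, length distributions, and closed-form oracles.

The steady-state convention follows the simulation protocol: run to
10,000 s, time-average each output over a late window (default the last
2,000 s), then average across replicate seeds.  Plateau detection checks
both the rolling mean and the rolling standard deviation, since the
standard deviation relaxes more slowly than the mean and is the stricter
indicator that a stochastic series has equilibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

from .engine import Trajectory

__all__ = [
    "SteadyStateSummary",
    "steady_state_summary",
    "plateau_reached",
    "half_time",
    "length_histogram",
    "radial_fraction_histogram",
    "is_bounded",
    "dogterom_leibler_mean",
]


@dataclass(frozen=True)
class SteadyStateSummary:
    """Across-replicate mean ± sd of the three steady-state outputs,
    time-averaged within ``window`` seconds of simulated time."""

    window: Tuple[float, float]
    n_mt: Tuple[float, float]
    mean_length: Tuple[float, float]
    free_conc: Tuple[float, float]
    n_replicates: int


def _window_average(traj: Trajectory, window: Tuple[float, float]) -> Tuple[float, float, float]:
    t0, t1 = window
    mask = (traj.t >= t0) & (traj.t <= t1)
    if not mask.any():
        raise ValueError(f"window {window} outside simulated span")
    return (
        float(traj.n_mt[mask].mean()),
        float(np.nanmean(traj.mean_length[mask])),
        float(traj.free_conc[mask].mean()),
    )


def steady_state_summary(
    trajectories: Iterable[Trajectory], window: Tuple[float, float]
) -> SteadyStateSummary:
    """Time-average within ``window`` per replicate, then mean ± sd
    (sample sd) across replicates."""
    per_rep = np.array([_window_average(tr, window) for tr in trajectories])
    if per_rep.size == 0:
        raise ValueError("at least one trajectory is required")
    means = per_rep.mean(axis=0)
    sds = (
        per_rep.std(axis=0, ddof=1)
        if per_rep.shape[0] > 1
        else np.zeros(3)
    )
    return SteadyStateSummary(
        window=window,
        n_mt=(means[0], sds[0]),
        mean_length=(means[1], sds[1]),
        free_conc=(means[2], sds[2]),
        n_replicates=per_rep.shape[0],
    )


def _rel_change(a: float, b: float) -> float:
    denom = max(abs(a), abs(b))
    return 0.0 if denom == 0 else abs(b - a) / denom


def plateau_reached(series, window: int, rel_tol: float = 0.05) -> bool:
    """True iff both the mean and the sd of the series are stable between
    the last two non-overlapping windows of ``window`` samples.

    "Stable" means a relative change below ``rel_tol``.
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if series.size <= 2 * window:
        raise ValueError(
            f"series of {series.size} samples too short for two windows of {window}"
        )
    w1 = series[-2 * window : -window]
    w2 = series[-window:]
    mean_ok = _rel_change(w1.mean(), w2.mean()) < rel_tol
    sd_ok = _rel_change(w1.std(), w2.std()) < rel_tol
    return bool(mean_ok and sd_ok)


def half_time(series, t) -> float:
    """Time of the midpoint crossing between the initial value and the
    final asymptote.

    The baseline is ``series[0]`` (the pre-transition value); the
    asymptote is the mean of the last 10% of samples.  The crossing time
    is linearly interpolated between samples and measured on the ``t``
    axis supplied.  Returns NaN when the series never crosses the
    midpoint (including constant series).
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.shape != t.shape:
        raise ValueError("series and t must have the same shape")
    if series.size < 2:
        return math.nan
    baseline = series[0]
    k = max(1, int(round(0.1 * series.size)))
    final = float(series[-k:].mean())
    if final == baseline:
        return math.nan
    mid = 0.5 * (baseline + final)
    crossed = series <= mid if final < baseline else series >= mid
    idx = np.flatnonzero(crossed)
    idx = idx[idx > 0]
    if idx.size == 0:
        return math.nan
    i = int(idx[0])
    y0, y1 = series[i - 1], series[i]
    if y1 == y0:
        return float(t[i])
    frac = (mid - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def length_histogram(
    lengths, bin_width: float = 1.0, max_radius: float = 25.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of lengths in right-closed bins over [0, max_radius].

    Bin ``j`` covers ``(j·w, (j+1)·w]`` (the first bin also includes 0),
    so a length exactly at ``max_radius`` lands in the last bin.  Returns
    ``(counts, edges)``; counts sum to the number of lengths.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size and (lengths.min() < 0 or lengths.max() > max_radius):
        raise ValueError(f"lengths outside [0, {max_radius}]")
    n_bins = int(math.ceil(max_radius / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max_radius  # final bin may be narrower
    counts = np.zeros(n_bins, dtype=np.int64)
    if lengths.size:
        idx = np.ceil(lengths / bin_width).astype(np.int64) - 1
        idx[idx < 0] = 0
        idx[idx >= n_bins] = n_bins - 1
        np.add.at(counts, idx, 1)
    return counts, edges


def radial_fraction_histogram(lengths, radius: float) -> np.ndarray:
    """Fractions of lengths in 5 equal bins of length/radius.

    Bins are [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0]
    (last bin closed).  Fractions sum to 1; an empty input returns zeros.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        return np.zeros(5)
    frac = lengths / radius
    if frac.min() < 0 or frac.max() > 1:
        raise ValueError(f"lengths outside [0, {radius}]")
    counts, _ = np.histogram(frac, bins=np.linspace(0, 1, 6))
    return counts / lengths.size


def is_bounded(v_g: float, v_s: float, k_c: float, k_r: float) -> bool:
    """Whether constant-parameter unconfined growth is bounded
    (``v_s·k_c > v_g·k_r``), yielding a stationary length distribution."""
    return v_s * k_c > v_g * k_r


def dogterom_leibler_mean(v_g: float, v_s: float, k_c: float, k_r: float) -> float:
    """Mean of the stationary exponential length distribution for an
    unconfined microtubule at constant tubulin:
    ``v_g·v_s / (v_s·k_c − v_g·k_r)``.

    Returns ``inf`` in the unbounded regime (no stationary distribution).
    """
    for name, v in (("v_g", v_g), ("v_s", v_s), ("k_c", k_c), ("k_r", k_r)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if not is_bounded(v_g, v_s, k_c, k_r):
        return math.inf
    return v_g * v_s / (v_s * k_c - v_g * k_r)


def load_lengths(path) -> np.ndarray:
    """Read a plain-text one-column list of tip lengths (μm)."""
    lengths = np.loadtxt(path, ndmin=1)
    if lengths.ndim != 1:
        raise ValueError(f"{path}: expected one length per row")
    return lengths
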