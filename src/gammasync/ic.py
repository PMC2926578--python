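"""Instantaneous coupling (IC): windowed maximum lagged cross-correlation.

The IC between a base signal X and another signal Y over a window
[Z_i, Z_{i+w}] spanning w half-cycles of X is

    IC = max_h  corr( {x_t}, {y_{t+h}} ),  t in [Z_i, Z_{i+w}],

the maximum over lags h of the Pearson correlation between the base
segment and the lag-shifted segment of Y, with both means recomputed
inside the window for every lag. The lag range runs a little more than
one half-cycle of the base in each direction. Sliding the window by m
half-cycles yields a time series of IC estimates, one row per window,
one column per non-base channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .errors import (
    DegenerateCorrelationError,
    DegenerateWindowError,
    EdgeWindowError,
    InsufficientCyclesError,
)
from .preprocess import CyclePartition, GammaSignal

__all__ = [
    "WindowSpec",
    "ICWindow",
    "ICSeries",
    "ICConfidence",
    "windowed_max_crosscorr",
    "default_lag_bound",
    "ic_series",
    "clip_unit_interval",
    "fisher_ci",
    "CLIP_FLOOR",
    "CLIP_CEIL",
]

#: Clipping limits applied before beta-family modeling.
CLIP_FLOOR = 1e-5
CLIP_CEIL = 0.99999


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: w half-cycles per window, increment m."""

    w: int = 6
    m: int = 2

    def __post_init__(self):
        if not (isinstance(self.w, int) and isinstance(self.m, int)):
            raise ValueError("w and m must be integers")
        if not (1 <= self.m < self.w):
            raise ValueError(f"need 1 <= m < w, got w={self.w}, m={self.m}")


@dataclass(frozen=True)
class ICWindow:
    """One window's IC estimate and the lag at which it was attained."""

    start: int
    end: int
    lag_at_max: int
    ic: float


@dataclass
class ICSeries:
    """IC estimates for all windows (rows) against all channels (columns)."""

    windows: np.ndarray  # (N', 2) start/end sample indices, inclusive
    U: np.ndarray  # (N', J)
    lags: np.ndarray  # (N', J) maximizing lag per entry
    channel_labels: list[str]
    base_label: str = ""
    n_dropped_left: int = 0
    n_dropped_right: int = 0

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=int).reshape(-1, 2)
        self.U = np.asarray(self.U, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        if self.U.shape != (self.windows.shape[0], len(self.channel_labels)):
            raise ValueError("U must be (n_windows, n_channels)")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.U.shape[1]

    def centers(self) -> np.ndarray:
        """Window midpoints in samples, for mapping states back to time."""
        return self.windows.mean(axis=1)


@dataclass(frozen=True)
class ICConfidence:
    """A (1 - alpha) confidence interval for a true coupling value."""

    lower: float
    upper: float
    level: float


def default_lag_bound(start: int, end: int, w: int) -> int:
    """Lag range for a window: one half-cycle of the base, and a little more.

    Returns round((end - start) / w) + 1 with round-half-away-from-zero,
    i.e. approximately the mean half-cycle length in samples, plus one.
    """
    if end <= start or w < 1:
        raise ValueError("need end > start and w >= 1")
    ratio = (end - start) / w
    return int(math.floor(ratio + 0.5)) + 1


def _lag_order(lag_bound: int) -> np.ndarray:
    """Lags in tie-break preference order: 0, +1, -1, +2, -2, ..."""
    order = [0]
    for a in range(1, lag_bound + 1):
        order.extend((a, -a))
    return np.array(order, dtype=int)


def windowed_max_crosscorr(
    base: GammaSignal | np.ndarray,
    other: GammaSignal | np.ndarray,
    start: int,
    end: int,
    lag_bound: int,
) -> ICWindow:
    """Maximum lagged Pearson correlation over one window.

    ``start``/``end`` are inclusive sample indices into both signals.
    For each lag h in [-lag_bound, lag_bound], the base segment
    x[start:end] is correlated with y[start+h:end+h]; the means of both
    segments are recomputed per lag. Ties in the maximum are broken by
    the smallest |h|, then the positive h.

    Raises
    ------
    EdgeWindowError
        If any lag-shifted segment of ``other`` falls outside the epoch.
    DegenerateWindowError
        If either windowed segment has zero variance.
    """
    x = base.values if isinstance(base, GammaSignal) else np.asarray(base, float)
    y = other.values if isinstance(other, GammaSignal) else np.asarray(other, float)
    T = y.size
    if not (0 <= start < end < x.size):
        raise ValueError(f"invalid window [{start}, {end}] for signal of length {x.size}")
    if end - start + 1 < 4:
        raise ValueError("window must contain at least 4 samples")
    if start - lag_bound < 0 or end + lag_bound > T - 1:
        raise EdgeWindowError(
            f"lags up to +/-{lag_bound} leave [0, {T - 1}] for window [{start}, {end}]"
        )

    xs = x[start : end + 1]
    xc = xs - xs.mean()
    sx = np.sqrt(np.dot(xc, xc))
    if sx == 0.0:
        raise DegenerateWindowError("base segment has zero variance")

    best_r = -np.inf
    best_h = 0
    for h in _lag_order(lag_bound):
        ys = y[start + h : end + h + 1]
        yc = ys - ys.mean()
        sy = np.sqrt(np.dot(yc, yc))
        if sy == 0.0:
            raise DegenerateWindowError(f"other segment has zero variance at lag {h}")
        r = np.dot(xc, yc) / (sx * sy)
        if r > best_r:  # strict: earlier (preferred) lags win ties
            best_r = r
            best_h = int(h)
    return ICWindow(start=start, end=end, lag_at_max=best_h, ic=float(best_r))


def ic_series(
    base: GammaSignal,
    others: list[GammaSignal],
    partition: CyclePartition,
    spec: WindowSpec = WindowSpec(),
) -> ICSeries:
    """IC time series of a base signal against J other channels.

    Windows follow the schedule [Z_1, Z_{1+w}], [Z_{1+m}, Z_{1+m+w}], ...
    over the half-cycle boundaries of the base. Windows whose lag range
    would leave the epoch are dropped from either end and counted in
    ``n_dropped_left`` / ``n_dropped_right``.
    """
    if not others:
        raise ValueError("need at least one non-base channel")
    T = len(base)
    for o in others:
        if len(o) != T or o.rate != base.rate:
            raise ValueError("all signals must share length and sampling rate")
    Z = partition.boundaries
    N = Z.size
    if N < spec.w + 1:
        raise InsufficientCyclesError(
            f"partition has {N} boundaries; need at least w + 1 = {spec.w + 1}"
        )

    n_planned = (N - 1 - spec.w) // spec.m + 1
    feasible = []
    for k in range(n_planned):
        a = Z[k * spec.m]
        b = Z[k * spec.m + spec.w]
        L = default_lag_bound(a, b, spec.w)
        feasible.append(a - L >= 0 and b + L <= T - 1)
    feasible = np.asarray(feasible, dtype=bool)

    # drop only contiguous infeasible runs at the two ends
    keep_from = int(np.argmax(feasible)) if feasible.any() else n_planned
    keep_to = n_planned - int(np.argmax(feasible[::-1])) if feasible.any() else n_planned
    if keep_from >= keep_to:
        raise InsufficientCyclesError("no window fits inside the epoch with its lag range")

    rows = []
    wins = []
    lags = []
    for k in range(keep_from, keep_to):
        a = Z[k * spec.m]
        b = Z[k * spec.m + spec.w]
        L = default_lag_bound(a, b, spec.w)
        row = np.empty(len(others))
        lag_row = np.empty(len(others), dtype=int)
        for j, o in enumerate(others):
            icw = windowed_max_crosscorr(base, o, int(a), int(b), L)
            row[j] = icw.ic
            lag_row[j] = icw.lag_at_max
        rows.append(row)
        lags.append(lag_row)
        wins.append((int(a), int(b)))

    return ICSeries(
        windows=np.asarray(wins, dtype=int),
        U=np.asarray(rows),
        lags=np.asarray(lags, dtype=int),
        channel_labels=[o.label for o in others],
        base_label=base.label,
        n_dropped_left=keep_from,
        n_dropped_right=n_planned - keep_to,
    )


def clip_unit_interval(
    series: ICSeries, floor: float = CLIP_FLOOR, ceil: float = CLIP_CEIL
) -> ICSeries:
    """Clip IC estimates into [floor, ceil] ahead of beta-family modeling.

    Nonpositive estimates become ``floor`` (default 0.00001) and values
    of one (or more) become ``ceil`` (default 0.99999); interior values
    are untouched. Returns a new ICSeries; the input is not modified.
    """
    U = np.clip(series.U, floor, ceil)
    return ICSeries(
        windows=series.windows.copy(),
        U=U,
        lags=series.lags.copy(),
        channel_labels=list(series.channel_labels),
        base_label=series.base_label,
        n_dropped_left=series.n_dropped_left,
        n_dropped_right=series.n_dropped_right,
    )


def fisher_ci(r_star: float, n: int, alpha: float = 0.05) -> ICConfidence:
    """Fisher-z confidence interval for a true coupling value.

    With z = arctanh(r*) and half-width z_{alpha/2} / sqrt(n - 1), the
    interval is (tanh(z - half), tanh(z + half)). ``n`` defaults, at the
    call sites of this package, to the window's sample count.

    Raises
    ------
    DegenerateCorrelationError
        If |r*| = 1 (the transform diverges).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    if abs(r_star) >= 1.0:
        raise DegenerateCorrelationError("|r*| = 1 has an undefined Fisher z")
    z = np.arctanh(r_star)
    half = spstats.norm.ppf(1.0 - alpha / 2.0) / math.sqrt(n - 1)
    return ICConfidence(
        lower=float(np.tanh(z - half)),
        upper=float(np.tanh(z + half)),
        level=1.0 - alpha,
    )
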