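"""Synthetic test-data generators: the frequency-modulated signal pair
used to validate the variable-window IC estimator, and MVB mixture
datasets for the statistical layer.

The signal pair

    X(t) = sin{ 2 pi [70 + 10 sin(0.5 pi t)] t },
    Y(t) = sin{ 2 pi [50 + 10 sin(0.5 pi (t - 2))] t },

sampled at 1500 Hz over 20 s, has instantaneous frequencies oscillating
in 60-80 Hz and 40-60 Hz that meet at 60 Hz simultaneously. Because the
modulation is time-varying, the *observed* frequency (cycles actually
exhibited per unit time, estimated from zero-crossing counts in a
+/-0.05 s window) differs from the instantaneous frequency and swings
far wider; the two signals synchronize wherever the observed-frequency
difference crosses zero. Dividing that difference by 130 Hz places it
on a -1..1 scale for direct comparison with IC estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .ic import ICWindow, default_lag_bound, windowed_max_crosscorr
from .mvb import MVBParams, mvb_sample
from .preprocess import zero_cross_indicator

__all__ = [
    "ChirpPair",
    "ObservedFrequencySeries",
    "gen_chirp_pair",
    "observed_frequency",
    "normalized_freq_diff",
    "fixed_window_ic",
    "gen_mixture_dataset",
    "FREQ_DIFF_SCALE",
]

#: Full scale of the observed-frequency difference of the default pair, Hz.
FREQ_DIFF_SCALE = 130.0


@dataclass
class ChirpPair:
    """The frequency-modulated test pair on a shared uniform time grid."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float


@dataclass
class ObservedFrequencySeries:
    """Observed frequency (Hz) at each interior sample time."""

    t: np.ndarray
    f_obs: np.ndarray
    index: np.ndarray  # sample indices into the originating signal


def gen_chirp_pair(rate: float = 1500.0, duration: float = 20.0) -> ChirpPair:
    """Generate the frequency-modulated signal pair.

    The grid is t_k = k / rate for k = 0 .. duration * rate inclusive
    (30001 samples at the defaults), which makes integer-cycle times
    such as t = 1 s for X and t = 2 s for Y exact zeros.
    """
    n = int(round(duration * rate))
    t = np.arange(n + 1) / rate
    x = np.sin(2 * np.pi * (70.0 + 10.0 * np.sin(0.5 * np.pi * t)) * t)
    y = np.sin(2 * np.pi * (50.0 + 10.0 * np.sin(0.5 * np.pi * (t - 2.0))) * t)
    return ChirpPair(t=t, x=x, y=y, rate=rate)


def observed_frequency(
    sig: np.ndarray, rate: float, half_width: float = 0.05
) -> ObservedFrequencySeries:
    """Observed frequency from windowed zero-crossing counts.

    At each interior sample time t, the zero crossings of the signal in
    [t - half_width, t + half_width] (both endpoint samples included)
    are counted, halved (two crossings per cycle), and divided by the
    window length. Crossings follow the same convention as the
    half-cycle partition: a crossing sits at the first sample after a
    sign change, exact zeros belonging to the following half-cycle.
    The first and last ``half_width`` seconds are excluded.
    """
    sig = np.asarray(sig, dtype=float)
    hw = int(round(half_width * rate))
    if sig.size <= 2 * hw:
        raise ValueError("signal shorter than one counting window")
    cross = zero_cross_indicator(sig).astype(int)
    csum = np.concatenate([[0], np.cumsum(cross)])
    idx = np.arange(hw, sig.size - hw)
    counts = csum[idx + hw + 1] - csum[idx - hw]
    f_obs = counts / 2.0 / (2.0 * half_width)
    return ObservedFrequencySeries(t=idx / rate, f_obs=f_obs, index=idx)


def normalized_freq_diff(
    fx: ObservedFrequencySeries,
    fy: ObservedFrequencySeries,
    scale: float = FREQ_DIFF_SCALE,
) -> np.ndarray:
    """(f_obs of X - f_obs of Y) / scale on their common grid."""
    if fx.t.shape != fy.t.shape or not np.allclose(fx.t, fy.t):
        raise AlignmentError("observed-frequency series are on different grids")
    return (fx.f_obs - fy.f_obs) / scale


def fixed_window_ic(
    base: np.ndarray,
    other: np.ndarray,
    width: int,
    step: int,
    lag_bound: int,
) -> list[ICWindow]:
    """IC on fixed-width windows [k*step, k*step + width], for comparison.

    Same maximum-lagged-correlation computation as the variable-window
    estimator; windows whose lag range leaves the epoch are skipped.
    """
    if width < 4:
        raise ValueError("width must be at least 4 samples")
    base = np.asarray(base, dtype=float)
    other = np.asarray(other, dtype=float)
    out = []
    start = 0
    while start + width < base.size:
        end = start + width
        if start - lag_bound >= 0 and end + lag_bound <= base.size - 1:
            out.append(windowed_max_crosscorr(base, other, start, end, lag_bound))
        start += step
    return out


def variable_window_increment(w: int) -> int:
    """Increment m = w / 3, rounded to the nearest positive integer."""
    return max(1, int(round(w / 3.0)))


def gen_mixture_dataset(
    pis: np.ndarray,
    thetas: list[MVBParams],
    n: int,
    seed: int | np.random.Generator = 0,
):
    """Sample (U, true_states) from a p-state MVB mixture.

    States are drawn from Categorical(pis), then each row from the MVB
    of its state via the gamma-ratio sampler. ``true_states`` is
    1-based to match the fitted state sequence.
    """
    pis = np.asarray(pis, dtype=float)
    if pis.ndim != 1 or pis.size != len(thetas):
        raise ValueError("need one mixing probability per component")
    if np.any(pis <= 0) or abs(pis.sum() - 1.0) > 1e-9:
        raise ValueError("mixing probabilities must be positive and sum to 1")
    J = thetas[0].J
    if any(t.J != J for t in thetas):
        raise ValueError("all components must share the dimension J")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rng.choice(pis.size, size=n, p=pis)
    U = np.empty((n, J))
    for k in range(pis.size):
        mask = labels == k
        if mask.any():
            U[mask] = mvb_sample(thetas[k], int(mask.sum()), seed=rng)
    return U, labels + 1
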