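"""Quantitative readouts: EMG model, linearity, superposition, synchrony.

The corticospinal readout is the fixed linear map ``m = W r_e`` from
cortical-point e-rates to muscle activations; because the cortical
interactions themselves are (near) linear, EMG vectors evoked by joint
activation of points sum linearly -- the model's account of the
microstimulation-summation result.  The remaining functions quantify how
close a response family is to linear, how well responses superpose, and
how asynchronous a spike raster is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EMGReadout",
    "emg_readout",
    "random_emg_readout",
    "linear_fit_r2",
    "linearity_deviation",
    "superposition_error",
    "synchrony_index",
    "isi_cv",
    "spectrum_peak_ratio",
]

#: floor used in relative-error denominators (spikes/s)
EPS_RATE = 1e-9


@dataclass(frozen=True)
class EMGReadout:
    """Fixed cortical-point -> muscle weight matrix (M muscles x K points)."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        object.__setattr__(self, "W", W)
        if not np.all(np.isfinite(W)):
            raise ValueError("EMG weights must be finite")

    @property
    def n_muscles(self) -> int:
        return self.W.shape[0]

    @property
    def n_points(self) -> int:
        return self.W.shape[1]


def emg_readout(w: EMGReadout, r_e) -> np.ndarray:
    """Muscle activation vector ``m = W r_e`` (linear by construction)."""
    r_e = np.atleast_1d(np.asarray(r_e, dtype=float))
    if r_e.shape != (w.n_points,):
        raise ValueError(f"rate vector has shape {r_e.shape}, expected ({w.n_points},)")
    return w.W @ r_e


def random_emg_readout(n_muscles: int, n_points: int, seed: int = 0) -> EMGReadout:
    """Seeded non-negative demo weight matrix (the model fixes only linearity,
    not particular weights)."""
    rng = np.random.default_rng(seed)
    return EMGReadout(rng.uniform(0.0, 1.0, size=(n_muscles, n_points)))


def _ls_line(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef = np.polyfit(x, y, 1)
    return np.polyval(coef, x)


def linear_fit_r2(x, y) -> float:
    """Coefficient of determination of the best least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yh = _ls_line(x, y)
    ss_res = np.sum((y - yh) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    if ss_tot == 0:
        return 1.0
    return float(1.0 - ss_res / ss_tot)


def linearity_deviation(x, y) -> float:
    """Max relative deviation of a response curve from its best-fit line.

    ``max |y - yhat| / max |y|`` for the least-squares line ``yhat``;
    0 for exactly linear data.  Scale-invariant in y.  Requires at least
    three points and a non-degenerate x grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate grid: x values are all equal")
    yh = _ls_line(x, y)
    denom = max(np.max(np.abs(y)), EPS_RATE)
    return float(np.max(np.abs(y - yh)) / denom)


def superposition_error(r_both, r_a, r_b) -> float:
    """Relative failure of linear summation of steady responses.

    ``||r_both - (r_a + r_b)||_inf / max(||r_both||_inf, eps)``.
    """
    r_both = np.atleast_1d(np.asarray(r_both, dtype=float))
    r_a = np.atleast_1d(np.asarray(r_a, dtype=float))
    r_b = np.atleast_1d(np.asarray(r_b, dtype=float))
    if not (r_both.shape == r_a.shape == r_b.shape):
        raise ValueError("rate vectors must have equal shape")
    num = np.max(np.abs(r_both - (r_a + r_b)))
    den = max(np.max(np.abs(r_both)), EPS_RATE)
    return float(num / den)


# -- spike-train statistics -------------------------------------------------

def _bin_counts(times_ms: np.ndarray, t_start: float, t_stop: float,
                bin_ms: float) -> np.ndarray:
    edges = np.arange(t_start, t_stop + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(times_ms, bins=edges)
    return counts


def synchrony_index(raster, bin_ms: float = 1.0, t_start: float = 200.0,
                    t_stop: float | None = None, point: int | None = None,
                    population: str | None = "e") -> float:
    """Population-count Fano factor: Var(count)/Mean(count) per bin.

    For independent (asynchronous) Poisson-like trains the index is ~1;
    population-wide synchrony inflates it (perfect synchrony of N identical
    trains gives ~N).  The first 200 ms are discarded by default to skip
    the onset transient.
    """
    times = raster.select_times(point=point, population=population)
    t_stop = t_stop if t_stop is not None else raster.duration_ms
    if t_stop <= t_start:
        raise ValueError("empty analysis window")
    counts = _bin_counts(times, t_start, t_stop, bin_ms)
    if counts.size == 0 or counts.mean() == 0:
        raise ValueError("no spikes in the analysis window")
    return float(counts.var() / counts.mean())


def isi_cv(raster, t_start: float = 200.0, point: int | None = None,
           population: str | None = "e", min_spikes: int = 3) -> float:
    """Mean inter-spike-interval coefficient of variation across neurons.

    Neurons with fewer than ``min_spikes`` spikes in the window are
    skipped; ~1 for Poisson-like irregular firing, ~0 for clock-like.
    """
    mean_cv = 0.0
    n = 0
    for t in raster.spike_trains(point=point, population=population):
        t = t[t >= t_start]
        if t.size < min_spikes:
            continue
        isi = np.diff(t)
        if isi.mean() == 0:
            continue
        mean_cv += isi.std() / isi.mean()
        n += 1
    if n == 0:
        raise ValueError("no neuron has enough spikes for an ISI CV")
    return mean_cv / n


def spectrum_peak_ratio(rate_t: np.ndarray, rate: np.ndarray,
                        f_lo: float = 20.0, f_hi: float = 120.0) -> float:
    """Peak-to-median power ratio of a population-rate series in a band.

    A flat (asynchronous) spectrum gives a ratio of a few; a network
    oscillation produces a sharp peak well above the band median.  Input
    times in ms, uniform sampling assumed.
    """
    from scipy import signal

    dt_s = (rate_t[1] - rate_t[0]) / 1000.0
    f, p = signal.periodogram(rate - np.mean(rate), fs=1.0 / dt_s)
    band = (f >= f_lo) & (f <= f_hi)
    if not np.any(band):
        raise ValueError("band outside resolvable frequencies")
    med = np.median(p[band])
    if med == 0:
        return 1.0
    return float(np.max(p[band]) / med)
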