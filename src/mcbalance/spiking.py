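"""Spiking counterpart of the rate model: K points of conductance-based
integrate-and-fire neurons with random connectivity and conduction delays.

Each cortical point holds ``N_e`` two-compartment excitatory cells (a
passive dendrite coupled to an integrate-and-fire soma, which gives the
population its saturating open-loop f/I curve) and ``N_i`` one-compartment
inhibitory cells.  Every neuron receives, on average, ``K_rec_e``
excitatory and ``K_rec_i`` inhibitory inputs drawn at random from its own
point; e-cells of other points project with mean in-degrees
``K_e_between[k, l]`` / ``K_i_between[k, l]`` and arrive after the
conduction delay ``delays_ms[k, l]``.  Inhibition stays local.

Synapses are instantaneous conductance changes: a presynaptic spike at a
synapse of amplitude ``g`` (nS) delivers the charge of a brief conductance
pulse, ``g * pulse_ms * (E_rev - V)``, as a jump of the postsynaptic
membrane potential.  The printed amplitudes are interpreted as pulses of
one fixed unit width (``pulse_ms``, default 0.25 ms), which puts unitary
somatic PSPs in the 0.5--2.5 mV range so that a few tens of presynaptic
spikes reach threshold, as the rate-model construction assumes.  For
e-cells, a fraction ``dendritic_fraction`` (default 80%) of synapses of
every kind -- external ones included -- sits on the dendrite, where the
coupling conductance attenuates their somatic effect.

External drive is an independent Poisson aggregate per neuron with rate
``C_ext * r_o,k(t)``.

Integration: exponential propagation of the (linear) membrane equations
between events with a fixed step ``dt`` (default 0.05 ms); spike
deliveries are rounded to the grid, and zero-delay (within-point) events
take effect on the following step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .transfer import TwoCompartmentParams

__all__ = [
    "SingleCompartmentParams",
    "SpikingParams",
    "Connectivity",
    "SpikeRaster",
    "build_connectivity",
    "simulate_spiking",
    "population_rate",
]


@dataclass(frozen=True)
class SingleCompartmentParams:
    """Biophysics of the one-compartment i-cell (input conductance 0.1 uS,
    capacitance 0.7 nF, same threshold/rest/reset/reversals as the e-cell)."""

    C_m: float = 0.7    # nF
    g_L: float = 0.1    # uS
    V_T: float = -60.0  # mV
    V_r: float = -75.0
    V_reset: float = -75.0
    E_exc: float = 0.0
    E_inh: float = -85.0

    def __post_init__(self) -> None:
        if not (self.C_m > 0 and self.g_L > 0):
            raise ValueError("C_m and g_L must be > 0")
        if self.V_reset > self.V_T:
            raise ValueError("V_reset must not exceed V_T")


def _as_int_matrix(x, K, name):
    if x is None:
        return np.zeros((K, K), dtype=int)
    x = np.asarray(x)
    if x.shape != (K, K):
        raise ValueError(f"{name} must be {K}x{K}")
    return x.astype(int)


@dataclass
class SpikingParams:
    """Sizes, in-degrees, conductances and delays of the spiking network.

    Defaults are the full-scale single-point parameters (8000 e-cells,
    2000 i-cells, 1000/1000 within-point in-degrees, printed conductance
    amplitudes in nS).  Use :meth:`scaled` for reduced ("desk-scale")
    networks: populations and in-degrees shrink by ``scale`` while the
    conductance amplitudes grow by ``1/sqrt(scale)``, preserving the
    magnitude of the synaptic-current fluctuations that drive irregular
    firing.
    """

    n_points: int = 1
    N_e: int = 8000
    N_i: int = 2000
    K_rec_e: int = 1000
    K_rec_i: int = 1000
    K_e_between: np.ndarray | None = None   # K x K mean in-degrees, zero diag
    K_i_between: np.ndarray | None = None
    delays_ms: np.ndarray | None = None     # K x K conduction delays
    g_ext_e: float = 10.66  # nS per external spike onto e-cells
    g_ext_i: float = 1.18   # ... onto i-cells
    g_ee: float = 5.33      # per network e-spike onto e-cells
    g_ie: float = 1.18      # per network e-spike onto i-cells
    g_ei: float = 56.0      # per network i-spike onto e-cells
    g_ii: float = 8.30      # per network i-spike onto i-cells
    dendritic_fraction: float = 0.8
    C_ext: float = 1000.0   # external input spikes/s per unit r_o
    pulse_ms: float = 0.25  # unit width of the instantaneous conductance pulse
    cell_e: TwoCompartmentParams = field(default_factory=TwoCompartmentParams)
    cell_i: SingleCompartmentParams = field(default_factory=SingleCompartmentParams)

    def __post_init__(self) -> None:
        K = self.n_points
        self.K_e_between = _as_int_matrix(self.K_e_between, K, "K_e_between")
        self.K_i_between = _as_int_matrix(self.K_i_between, K, "K_i_between")
        if self.delays_ms is None:
            self.delays_ms = np.zeros((K, K))
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        if self.delays_ms.shape != (K, K):
            raise ValueError(f"delays_ms must be {K}x{K}")
        if np.any(self.delays_ms < 0) or np.any(np.diag(self.delays_ms) != 0):
            raise ValueError("delays must be >= 0 with a zero diagonal")
        if not (self.N_e > 0 and self.N_i > 0):
            raise ValueError("population sizes must be positive")
        if self.K_rec_e > self.N_e or self.K_rec_i > self.N_i:
            raise ValueError("within-point in-degree exceeds population size")
        if np.any(self.K_e_between > self.N_e) or np.any(self.K_i_between > self.N_e):
            raise ValueError("between-point in-degree exceeds e-population size")
        if not (0.0 <= self.dendritic_fraction <= 1.0):
            raise ValueError("dendritic_fraction must lie in [0, 1]")

    # -- layout helpers ---------------------------------------------------
    @property
    def n_e_total(self) -> int:
        return self.n_points * self.N_e

    @property
    def n_total(self) -> int:
        return self.n_points * (self.N_e + self.N_i)

    def e_slice(self, k: int) -> slice:
        return slice(k * self.N_e, (k + 1) * self.N_e)

    def i_slice(self, k: int) -> slice:
        off = self.n_e_total
        return slice(off + k * self.N_i, off + (k + 1) * self.N_i)

    def open_loop(self) -> "SpikingParams":
        """Copy with all recurrent connections removed (isolated cells under
        external drive only): the spiking open-loop f/I configuration."""
        import dataclasses
        K = self.n_points
        return dataclasses.replace(
            self, K_rec_e=0, K_rec_i=0,
            K_e_between=np.zeros((K, K), dtype=int),
            K_i_between=np.zeros((K, K), dtype=int))

    def i_drive_calibration(self) -> float:
        """Factor equalising external drive across populations.

        Ratio of external charge per spike, in units of each cell's
        threshold charge ``C (V_T - V_r)``, between e-cells (dendritic
        attenuation included) and i-cells.  Applied to the three i-target
        conductance amplitudes it enforces the rate model's
        ``q_eo = q_io`` convention; it also restores the regime in which a
        few tens of presynaptic spikes bring either cell type to
        threshold.  Computed from the biophysical parameters only.
        """
        ce, ci = self.cell_e, self.cell_i
        att = ce.attenuation
        eff_e = self.g_ext_e * (1 - self.dendritic_fraction
                                + self.dendritic_fraction * att)
        per_thr_e = eff_e / (ce.C_m * (ce.V_T - ce.V_r))
        per_thr_i = self.g_ext_i / (ci.C_m * (ci.V_T - ci.V_r))
        return per_thr_e / per_thr_i

    @staticmethod
    def scaled(scale: float = 0.25, n_points: int = 1, w_e=None, w_i=None,
               delays_ms=None, calibrate_i: bool = True,
               **overrides) -> "SpikingParams":
        """Reduced-scale network mirroring the rate-model couplings.

        Populations and mean in-degrees shrink by ``scale`` while
        conductance amplitudes grow by ``1/sqrt(scale)``; between-point
        mean in-degrees follow the rate-model coupling ratios,
        ``K_between = round(1000 * w * scale)`` (the reference coupling
        w = 0.2 maps to 200 at full scale).  With ``calibrate_i`` (the
        default) the three i-target amplitudes are additionally multiplied
        by :meth:`i_drive_calibration`, which the balanced operating
        regime requires; see the package methods note.
        """
        if not (0 < scale <= 1):
            raise ValueError("scale must lie in (0, 1]")
        gf = 1.0 / np.sqrt(scale)
        kw = dict(
            n_points=n_points,
            N_e=int(round(8000 * scale)), N_i=int(round(2000 * scale)),
            K_rec_e=int(round(1000 * scale)), K_rec_i=int(round(1000 * scale)),
            C_ext=1000.0 * scale,
            g_ext_e=10.66 * gf, g_ext_i=1.18 * gf, g_ee=5.33 * gf,
            g_ie=1.18 * gf, g_ei=56.0 * gf, g_ii=8.30 * gf,
        )
        if w_e is not None:
            w_e = np.asarray(w_e, dtype=float)
            w_i = np.asarray(w_i if w_i is not None else w_e, dtype=float)
            kw["K_e_between"] = np.round(1000 * w_e * scale).astype(int)
            kw["K_i_between"] = np.round(1000 * w_i * scale).astype(int)
        if delays_ms is not None:
            kw["delays_ms"] = np.asarray(delays_ms, dtype=float)
        kw.update(overrides)
        p = SpikingParams(**kw)
        if calibrate_i:
            c = p.i_drive_calibration()
            p.g_ext_i *= c
            p.g_ie *= c
            p.g_ii *= c
        return p


# channel codes: 0 = exc->soma, 1 = inh->soma, 2 = exc->dendrite, 3 = inh->dendrite
_N_CHAN = 4


@dataclass
class Connectivity:
    """Realised wiring in compressed sparse rows keyed by source neuron.

    ``targets[indptr[s]:indptr[s+1]]`` lists the postsynaptic neurons of
    source ``s`` (global ids: e-cells of all points first, then i-cells),
    with per-edge synaptic channel, conduction delay and charge-integral
    weight (``g * pulse_ms``, nS*ms).
    """

    params: SpikingParams
    indptr: np.ndarray      # (n_total + 1,)
    targets: np.ndarray     # int32
    channel: np.ndarray     # uint8
    delay_ms: np.ndarray    # float32 per edge
    weight: np.ndarray      # float32 per edge (nS*ms)
    seed: int

    @property
    def n_edges(self) -> int:
        return self.targets.size

    def in_degree(self, kind: str = "all") -> np.ndarray:
        """Realised in-degree per neuron; kind in {'all', 'e', 'i'}."""
        p = self.params
        if kind == "all":
            sel = np.ones(self.targets.size, dtype=bool)
        else:
            src = np.repeat(np.arange(p.n_total), np.diff(self.indptr))
            is_e_src = src < p.n_e_total
            sel = is_e_src if kind == "e" else ~is_e_src
        return np.bincount(self.targets[sel], minlength=p.n_total)


def _draw_block(rng, n_t, n_s, p, exclude_diag):
    """i.i.d. Bernoulli(p) adjacency for one (target, source) block; returns
    (t_idx, s_idx) arrays.  Chunked over targets to bound memory."""
    if p <= 0 or n_t == 0 or n_s == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    ts, ss = [], []
    chunk = max(1, int(4e6 // max(n_s, 1)))
    for lo in range(0, n_t, chunk):
        hi = min(lo + chunk, n_t)
        mask = rng.random((hi - lo, n_s)) < p
        if exclude_diag:
            rows = np.arange(lo, hi)
            cols = rows[rows < n_s]
            mask[cols - lo, cols] = False
        t_loc, s_loc = np.nonzero(mask)
        ts.append(t_loc + lo)
        ss.append(s_loc)
    return np.concatenate(ts), np.concatenate(ss)


def build_connectivity(p: SpikingParams, seed: int = 0) -> Connectivity:
    """Draw the random wiring (deterministic for a given seed).

    Every potential (source, target) pair is an independent Bernoulli draw
    with probability ``K / N_source`` (no self-connections), so realised
    in-degrees are binomial with the specified means.  Dendritic placement
    of each e-cell synapse is an independent draw with probability
    ``dendritic_fraction``.
    """
    rng = np.random.default_rng(seed)
    K = p.n_points
    src_l, tgt_l, chan_l, dly_l, wgt_l = [], [], [], [], []

    def add_edges(t_glob, s_glob, is_exc, target_is_e, delay, g):
        n = t_glob.size
        if n == 0:
            return
        if target_is_e:
            dend = rng.random(n) < p.dendritic_fraction
            chan = np.where(dend, 2 if is_exc else 3, 0 if is_exc else 1)
        else:
            chan = np.full(n, 0 if is_exc else 1)
        src_l.append(s_glob.astype(np.int64))
        tgt_l.append(t_glob.astype(np.int64))
        chan_l.append(chan.astype(np.uint8))
        dly_l.append(np.full(n, delay, dtype=np.float32))
        # charge integral in uS*ms so that weight / C[nF] is dimensionless
        wgt_l.append(np.full(n, g * 1e-3 * p.pulse_ms, dtype=np.float32))

    for kt in range(K):
        for target_is_e in (True, False):
            t_off = (p.e_slice(kt) if target_is_e else p.i_slice(kt)).start
            n_t = p.N_e if target_is_e else p.N_i
            g_from_e = p.g_ee if target_is_e else p.g_ie
            g_from_i = p.g_ei if target_is_e else p.g_ii
            # within-point e sources
            t, s = _draw_block(rng, n_t, p.N_e, p.K_rec_e / p.N_e,
                               exclude_diag=target_is_e)
            add_edges(t + t_off, s + p.e_slice(kt).start, True, target_is_e,
                      0.0, g_from_e)
            # within-point i sources
            t, s = _draw_block(rng, n_t, p.N_i, p.K_rec_i / p.N_i,
                               exclude_diag=not target_is_e)
            add_edges(t + t_off, s + p.i_slice(kt).start, False, target_is_e,
                      0.0, g_from_i)
            # between-point e sources
            kb = p.K_e_between if target_is_e else p.K_i_between
            for ks in range(K):
                if ks == kt or kb[kt, ks] == 0:
                    continue
                t, s = _draw_block(rng, n_t, p.N_e, kb[kt, ks] / p.N_e, False)
                add_edges(t + t_off, s + p.e_slice(ks).start, True, target_is_e,
                          float(p.delays_ms[kt, ks]), g_from_e)

    if src_l:
        src = np.concatenate(src_l)
        order = np.argsort(src, kind="stable")
        src = src[order]
        targets = np.concatenate(tgt_l)[order].astype(np.int32)
        channel = np.concatenate(chan_l)[order]
        delay_ms = np.concatenate(dly_l)[order]
        weight = np.concatenate(wgt_l)[order]
        indptr = np.zeros(p.n_total + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
    else:
        targets = np.empty(0, dtype=np.int32)
        channel = np.empty(0, dtype=np.uint8)
        delay_ms = np.empty(0, dtype=np.float32)
        weight = np.empty(0, dtype=np.float32)
        indptr = np.zeros(p.n_total + 1, dtype=np.int64)
    return Connectivity(p, indptr, targets, channel, delay_ms, weight, seed)


@dataclass
class SpikeRaster:
    """Spike events of one simulation: (time ms, global neuron id)."""

    times_ms: np.ndarray
    neuron: np.ndarray
    duration_ms: float
    params: SpikingParams

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    # -- id decoding ------------------------------------------------------
    def _pop_point(self):
        p = self.params
        is_e = self.neuron < p.n_e_total
        point = np.where(is_e, self.neuron // p.N_e,
                         (self.neuron - p.n_e_total) // p.N_i).astype(np.int16)
        return is_e, point

    def _mask(self, point=None, population=None):
        is_e, pt = self._pop_point()
        m = np.ones(self.neuron.size, dtype=bool)
        if population == "e":
            m &= is_e
        elif population == "i":
            m &= ~is_e
        elif population is not None:
            raise ValueError("population must be 'e', 'i' or None")
        if point is not None:
            m &= pt == point
        return m

    def select_times(self, point=None, population=None) -> np.ndarray:
        return self.times_ms[self._mask(point, population)]

    def spike_trains(self, point=None, population=None, max_neurons=None):
        """Yield per-neuron spike-time arrays (sorted), optionally capped."""
        m = self._mask(point, population)
        nrn, t = self.neuron[m], self.times_ms[m]
        order = np.lexsort((t, nrn))
        nrn, t = nrn[order], t[order]
        ids, starts = np.unique(nrn, return_index=True)
        bounds = np.append(starts, nrn.size)
        n_yield = ids.size if max_neurons is None else min(max_neurons, ids.size)
        for j in range(n_yield):
            yield t[bounds[j]:bounds[j + 1]]

    def mean_rate(self, point=None, population="e", t_start=0.0,
                  t_stop=None) -> float:
        """Time-averaged population rate (spikes/s per neuron)."""
        p = self.params
        t_stop = t_stop if t_stop is not None else self.duration_ms
        times = self.select_times(point, population)
        n_spk = np.count_nonzero((times >= t_start) & (times < t_stop))
        n_pop = (p.N_e if population == "e" else p.N_i)
        if point is None:
            n_pop *= p.n_points
        return n_spk / (n_pop * (t_stop - t_start) / 1000.0)

    def to_dataframe(self) -> pd.DataFrame:
        is_e, pt = self._pop_point()
        return pd.DataFrame({
            "time_ms": self.times_ms,
            "neuron": self.neuron,
            "point": pt,
            "population": np.where(is_e, "e", "i"),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def population_rate(raster: SpikeRaster, bin_ms: float = 1.0, point: int | None = 0,
                    population: str = "e"):
    """Binned population rate time series, spikes/s per neuron.

    Returns (bin centers ms, rates); counts per bin divided by
    ``bin_ms * population size``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    p = raster.params
    times = raster.select_times(point=point, population=population)
    edges = np.arange(0.0, raster.duration_ms + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(times, bins=edges)
    n_pop = (p.N_e if population == "e" else p.N_i) * (p.n_points if point is None else 1)
    rates = counts / (n_pop * bin_ms / 1000.0)
    return (edges[:-1] + bin_ms / 2), rates


def _apply_jumps(V, f_e, f_i, E_exc, E_inh):
    """Integrate simultaneous excitatory/inhibitory conductance pulses.

    Exact solution of ``dV/dt = g_e(E_e - V) + g_i(E_i - V)`` over the
    pulse: exponential relaxation toward the conductance-weighted reversal
    potential, which cannot overshoot however large the pulse.
    """
    f_tot = f_e + f_i
    v_inf = (f_e * E_exc + f_i * E_inh) / np.maximum(f_tot, 1e-30)
    return np.where(f_tot > 0, v_inf + (V - v_inf) * np.exp(-f_tot), V)


def _e_propagator(cell: TwoCompartmentParams, dt: float) -> np.ndarray:
    A = np.array([
        [-(cell.g_s + cell.g_c) / cell.C_m, cell.g_c / cell.C_m],
        [cell.g_c / cell.C_d, -(cell.g_D + cell.g_c) / cell.C_d],
    ])  # 1/ms
    return expm(A * dt)


def simulate_spiking(conn: Connectivity, drive, duration_ms: float,
                     dt: float = 0.05, seed: int = 0,
                     v_init: str = "uniform") -> SpikeRaster:
    """Advance the network and record spikes.

    ``drive`` is a per-point external rate vector (spikes/s, constant) or
    a callable/:class:`~mcbalance.rate.InputDrive` mapping time (ms) to
    such a vector; each neuron receives an independent Poisson aggregate
    of rate ``C_ext * r_o,k(t)``.  Separate seeded streams are used for
    the external drive and the initial voltages (wiring has its own seed
    in :func:`build_connectivity`), so rasters are reproducible
    event-for-event.
    """
    p = conn.params
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms for the event grid")
    K, N = p.n_points, p.n_total
    n_e_tot = p.n_e_total
    drive_fn = drive if callable(drive) else (lambda t, _r=np.atleast_1d(
        np.asarray(drive, dtype=float)): _r)
    r0 = np.atleast_1d(np.asarray(drive_fn(0.0), dtype=float))
    if r0.shape != (K,):
        raise ValueError(f"drive must provide {K} per-point rates")

    ss = np.random.SeedSequence([int(seed), 0x5eed])
    rng_drive, rng_init = [np.random.default_rng(s) for s in ss.spawn(2)]

    ce, ci = p.cell_e, p.cell_i
    P = _e_propagator(ce, dt)
    decay_i = float(np.exp(-dt * ci.g_L / ci.C_m))

    Vs = rng_init.uniform(ce.V_r, ce.V_T, n_e_tot)
    Vd = rng_init.uniform(ce.V_r, ce.V_T, n_e_tot)
    Vi = rng_init.uniform(ci.V_r, ci.V_T, N - n_e_tot)
    if v_init == "rest":
        Vs[:] = ce.V_r
        Vd[:] = ce.V_r
        Vi[:] = ci.V_r

    n_steps = int(round(duration_ms / dt))
    delay_steps = np.maximum(np.round(conn.delay_ms / dt).astype(np.int64), 1)
    n_slots = int(delay_steps.max(initial=1)) + 1
    acc = np.zeros((n_slots, N, _N_CHAN), dtype=np.float32)
    acc_flat = acc.reshape(-1)
    slot_stride = N * _N_CHAN

    a_ext_e = np.float32(p.g_ext_e * 1e-3 * p.pulse_ms)
    a_ext_i = np.float32(p.g_ext_i * 1e-3 * p.pulse_ms)
    point_of_e = np.repeat(np.arange(K), p.N_e)
    point_of_i = np.repeat(np.arange(K), p.N_i)

    spk_t, spk_id = [], []
    e_ids = np.arange(n_e_tot)
    i_ids = np.arange(n_e_tot, N)

    for step in range(n_steps):
        t = step * dt
        slot = step % n_slots
        A = acc[slot]

        # external Poisson input (thinned onto dendrite/soma for e-cells)
        r_o = np.atleast_1d(np.asarray(drive_fn(t), dtype=float))
        lam = p.C_ext * r_o * dt * 1e-3
        if np.any(lam > 0):
            cnt_e = rng_drive.poisson(lam[point_of_e])
            nd = rng_drive.binomial(cnt_e, p.dendritic_fraction)
            ext_e = np.zeros((n_e_tot, _N_CHAN), dtype=np.float32)
            ext_e[:, 0] = (cnt_e - nd) * a_ext_e
            ext_e[:, 2] = nd * a_ext_e
            cnt_i = rng_drive.poisson(lam[point_of_i])
            Ae = A[:n_e_tot] + ext_e
            Ai0 = A[n_e_tot:, 0] + cnt_i * a_ext_i
        else:
            Ae = A[:n_e_tot]
            Ai0 = A[n_e_tot:, 0]

        # membrane propagation (exact for the linear leak dynamics)
        dVs = Vs - ce.V_r
        dVd = Vd - ce.V_r
        Vs = ce.V_r + P[0, 0] * dVs + P[0, 1] * dVd
        Vd = ce.V_r + P[1, 0] * dVs + P[1, 1] * dVd
        Vi = ci.V_r + (Vi - ci.V_r) * decay_i

        # synaptic jumps: exact relaxation toward the weighted reversal,
        # V -> V_inf + (V - V_inf) exp(-(f_e + f_i)), f = sum(a)/C
        Vs = _apply_jumps(Vs, Ae[:, 0] / ce.C_m, Ae[:, 1] / ce.C_m,
                          ce.E_exc, ce.E_inh)
        Vd = _apply_jumps(Vd, Ae[:, 2] / ce.C_d, Ae[:, 3] / ce.C_d,
                          ce.E_exc, ce.E_inh)
        Vi = _apply_jumps(Vi, Ai0 / ci.C_m, A[n_e_tot:, 1] / ci.C_m,
                          ci.E_exc, ci.E_inh)

        A[:] = 0.0

        # threshold crossings and resets
        me = Vs >= ce.V_T
        mi = Vi >= ci.V_T
        spikers = None
        if me.any() or mi.any():
            se = e_ids[me]
            si = i_ids[mi]
            Vs[me] = ce.V_reset
            Vi[mi] = ci.V_reset
            spikers = np.concatenate([se, si])
            spk_id.append(spikers.astype(np.int32))
            spk_t.append(np.full(spikers.size, t + dt, dtype=np.float32))

            # deliver to targets (rounded to the grid; min latency one step)
            starts = conn.indptr[spikers]
            ends = conn.indptr[spikers + 1]
            n_edges = ends - starts
            tot = int(n_edges.sum())
            if tot:
                idx = np.repeat(starts + n_edges - n_edges.cumsum(), n_edges) \
                    + np.arange(tot)
                tgt = conn.targets[idx]
                dslot = (step + delay_steps[idx]) % n_slots
                flat = dslot * slot_stride + tgt.astype(np.int64) * _N_CHAN \
                    + conn.channel[idx]
                np.add.at(acc_flat, flat, conn.weight[idx])

        if step % 4000 == 0:
            for name, arr in (("e-soma", Vs), ("e-dendrite", Vd), ("i", Vi)):
                if not np.all(np.isfinite(arr)):
                    bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                    raise FloatingPointError(
                        f"non-finite voltage ({name} neuron {bad}) at t={t:.2f} ms")

    times = np.concatenate(spk_t) if spk_t else np.empty(0, dtype=np.float32)
    ids = np.concatenate(spk_id) if spk_id else np.empty(0, dtype=np.int32)
    return SpikeRaster(times, ids, duration_ms, p)
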