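"""Non-linear rate dynamics of K coupled cortical points.

Each cortical point is an excitatory (e) and an inhibitory (i) population
with Rushton--Naka transfer functions, evolving as

    tau_a dr_a,k/dt = -r_a,k + f_a(I_a,k),   a in {e, i},

with input currents

    I_a,k = q_ao r_o,k + q_ae r_e,k - q_ai r_i,k + sum_{l != k} w_a,kl r_e,l.

Within-point synaptic magnitudes ``q_ab`` are stored as positive numbers;
the inhibitory sign lives in the current equation.  Between-point coupling
is purely excitatory (e-cell collaterals) with strengths ``w_e`` (onto
e-cells) and ``w_i`` (onto i-cells); inhibition stays local.  A point's
master-inhibitory (MI) gain ``G_i`` scales the maximum rate of its i-cell
population, ``r_max,i -> G_i * r_max,i``, which is the model's
disinhibition knob.

Integration uses a fixed-step classical Runge--Kutta scheme; steady states
are found by damped fixed-point iteration on the self-consistency
equations with a root-finder fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .transfer import TransferParams, naka_rushton

__all__ = [
    "PopulationParams",
    "PointParams",
    "CouplingMatrices",
    "RateState",
    "RateTrajectory",
    "InputDrive",
    "RateNetwork",
    "ConvergenceError",
    "point_currents",
    "integrate_rates",
    "steady_state",
    "io_curve",
]


class ConvergenceError(RuntimeError):
    """Raised when a steady state cannot be found (instability/oscillation)."""


@dataclass(frozen=True)
class PopulationParams:
    """Dynamics of one population: time constant (ms) and f/I curve."""

    tau: float = 10.0
    transfer: TransferParams = field(default_factory=TransferParams)

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class PointParams:
    """Within-point synaptic magnitudes (charge/spike) and MI gain.

    Defaults are the reference single-point parameter set (q_ee = 0.67,
    q_ei = 1.7, q_ie = 1, q_ii = 2, unit external weights).  All values
    are stored as magnitudes; subtraction of the inhibitory terms happens
    in the current equations.  ``G_i`` in [0, 1] scales the i-cell ceiling.
    """

    q_eo: float = 1.0
    q_ee: float = 0.67
    q_ei: float = 1.7
    q_ie: float = 1.0
    q_io: float = 1.0
    q_ii: float = 2.0
    G_i: float = 1.0

    def __post_init__(self) -> None:
        for name in ("q_eo", "q_ee", "q_ei", "q_ie", "q_io", "q_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (magnitude convention)")
        if not (0.0 <= self.G_i <= 1.0):
            raise ValueError(f"G_i must lie in [0, 1], got {self.G_i}")

    def scaled(self, lam: float) -> "PointParams":
        """All synaptic magnitudes multiplied by ``lam`` (balance scaling)."""
        return PointParams(
            q_eo=lam * self.q_eo, q_ee=lam * self.q_ee, q_ei=lam * self.q_ei,
            q_ie=lam * self.q_ie, q_io=lam * self.q_io, q_ii=lam * self.q_ii,
            G_i=self.G_i,
        )


@dataclass(frozen=True)
class CouplingMatrices:
    """Between-point e-collateral strengths onto e-cells and i-cells.

    ``w_e[k, l]`` (``w_i[k, l]``) is the strength from the e-cells of
    point ``l`` onto the e-cells (i-cells) of point ``k``.  Diagonals are
    zero: within-point terms live in :class:`PointParams`.
    """

    w_e: np.ndarray
    w_i: np.ndarray

    def __post_init__(self) -> None:
        w_e = np.asarray(self.w_e, dtype=float)
        w_i = np.asarray(self.w_i, dtype=float)
        object.__setattr__(self, "w_e", w_e)
        object.__setattr__(self, "w_i", w_i)
        if w_e.shape != w_i.shape or w_e.ndim != 2 or w_e.shape[0] != w_e.shape[1]:
            raise ValueError("w_e and w_i must be square matrices of equal shape")
        for name, w in (("w_e", w_e), ("w_i", w_i)):
            if np.any(np.diag(w) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
            if np.any(w < 0):
                raise ValueError(f"{name} entries must be >= 0")

    @property
    def K(self) -> int:
        return self.w_e.shape[0]

    @staticmethod
    def none(K: int) -> "CouplingMatrices":
        """Uncoupled points (all-zero matrices)."""
        z = np.zeros((K, K))
        return CouplingMatrices(z, z.copy())

    def scaled(self, lam: float) -> "CouplingMatrices":
        return CouplingMatrices(lam * self.w_e, lam * self.w_i)


@dataclass
class RateState:
    """Instantaneous e- and i-population rates of all K points (spikes/s)."""

    r_e: np.ndarray
    r_i: np.ndarray

    def __post_init__(self) -> None:
        self.r_e = np.atleast_1d(np.asarray(self.r_e, dtype=float))
        self.r_i = np.atleast_1d(np.asarray(self.r_i, dtype=float))
        if self.r_e.shape != self.r_i.shape:
            raise ValueError("r_e and r_i must have equal shape")

    @property
    def K(self) -> int:
        return self.r_e.size

    @staticmethod
    def zeros(K: int) -> "RateState":
        return RateState(np.zeros(K), np.zeros(K))

    def copy(self) -> "RateState":
        return RateState(self.r_e.copy(), self.r_i.copy())


@dataclass
class RateTrajectory:
    """Rates sampled on a regular time grid (ms)."""

    t: np.ndarray          # (T,)
    r_e: np.ndarray        # (T, K)
    r_i: np.ndarray        # (T, K)

    @property
    def K(self) -> int:
        return self.r_e.shape[1]

    def final_state(self) -> RateState:
        return RateState(self.r_e[-1].copy(), self.r_i[-1].copy())

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: time_ms, point, population, rate_spk_s."""
        T, K = self.r_e.shape
        frames = []
        for pop, arr in (("e", self.r_e), ("i", self.r_i)):
            frames.append(pd.DataFrame({
                "time_ms": np.repeat(self.t, K),
                "point": np.tile(np.arange(K), T),
                "population": pop,
                "rate_spk_s": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class InputDrive:
    """External drive time course ``r_o,k(t)`` (spikes/s, never negative).

    Built from the factory methods: :meth:`constant`, :meth:`step` (zero
    baseline until an onset time) and :meth:`ramp` (linear between two
    values).  Calling the object with a time in ms returns the K-vector of
    external rates.
    """

    def __init__(self, K: int, fn: Callable[[float], np.ndarray], label: str = "custom"):
        self.K = K
        self._fn = fn
        self.label = label

    def __call__(self, t: float) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self._fn(t), dtype=float))
        if r.shape != (self.K,):
            raise ValueError(f"drive returned shape {r.shape}, expected ({self.K},)")
        if np.any(r < 0):
            raise ValueError("external drive must be non-negative")
        return r

    @staticmethod
    def constant(rates) -> "InputDrive":
        r = np.atleast_1d(np.asarray(rates, dtype=float))
        return InputDrive(r.size, lambda t: r, label="constant")

    @staticmethod
    def step(rates, t_on: float = 0.0) -> "InputDrive":
        r = np.atleast_1d(np.asarray(rates, dtype=float))
        z = np.zeros_like(r)
        return InputDrive(r.size, lambda t: r if t >= t_on else z, label="step")

    @staticmethod
    def ramp(rates0, rates1, t0: float, t1: float) -> "InputDrive":
        r0 = np.atleast_1d(np.asarray(rates0, dtype=float))
        r1 = np.atleast_1d(np.asarray(rates1, dtype=float))
        if t1 <= t0:
            raise ValueError("ramp requires t1 > t0")

        def fn(t: float) -> np.ndarray:
            if t <= t0:
                return r0
            if t >= t1:
                return r1
            lam = (t - t0) / (t1 - t0)
            return (1 - lam) * r0 + lam * r1

        return InputDrive(r0.size, fn, label="ramp")


class RateNetwork:
    """K fully interconnected cortical points with rate dynamics.

    Parameters
    ----------
    points : PointParams or sequence of PointParams
        Within-point weights and MI gain; a single instance is replicated.
    W : CouplingMatrices, optional
        Between-point couplings; defaults to uncoupled.
    pop_e, pop_i : PopulationParams
        Time constant and transfer function of each population.  The
        effective i-cell ceiling at point k is ``G_i,k * r_max,i``.
    """

    def __init__(self, points, W: CouplingMatrices | None = None,
                 pop_e: PopulationParams | None = None,
                 pop_i: PopulationParams | None = None, K: int | None = None):
        if isinstance(points, PointParams):
            if K is None:
                K = 1 if W is None else W.K
            points = [points] * K
        self.points: list[PointParams] = list(points)
        self.K = len(self.points)
        self.W = W if W is not None else CouplingMatrices.none(self.K)
        if self.W.K != self.K:
            raise ValueError(f"coupling matrices are {self.W.K}x{self.W.K} but K={self.K}")
        self.pop_e = pop_e if pop_e is not None else PopulationParams()
        self.pop_i = pop_i if pop_i is not None else PopulationParams()
        # vectorised parameter views
        self._q = {name: np.array([getattr(p, name) for p in self.points])
                   for name in ("q_eo", "q_ee", "q_ei", "q_ie", "q_io", "q_ii")}
        self._G = np.array([p.G_i for p in self.points])

    # -- parameters -------------------------------------------------------
    def scaled(self, lam: float) -> "RateNetwork":
        """Network with all synaptic weights (q and w) multiplied by lam."""
        return RateNetwork([p.scaled(lam) for p in self.points], self.W.scaled(lam),
                           self.pop_e, self.pop_i)

    @property
    def r_max_i_eff(self) -> np.ndarray:
        return self._G * self.pop_i.transfer.r_max

    # -- currents and transfer -------------------------------------------
    def currents(self, state: RateState, r_o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Net input currents (I_e, I_i) at every point."""
        r_o = np.atleast_1d(np.asarray(r_o, dtype=float))
        if r_o.shape != (self.K,) or state.K != self.K:
            raise ValueError("dimension mismatch between state, drive and network")
        q = self._q
        between_e = self.W.w_e @ state.r_e
        between_i = self.W.w_i @ state.r_e
        I_e = q["q_eo"] * r_o + q["q_ee"] * state.r_e - q["q_ei"] * state.r_i + between_e
        I_i = q["q_io"] * r_o + q["q_ie"] * state.r_e - q["q_ii"] * state.r_i + between_i
        return I_e, I_i

    def f_e(self, I_e: np.ndarray) -> np.ndarray:
        return naka_rushton(I_e, self.pop_e.transfer)

    def f_i(self, I_i: np.ndarray) -> np.ndarray:
        # MI gain enters exclusively as a scaled i-cell ceiling
        t = self.pop_i.transfer
        base = naka_rushton(I_i, TransferParams(t.r_max, t.I_half, t.I_T))
        return self._G * base

    def _rhs(self, r_e: np.ndarray, r_i: np.ndarray, r_o: np.ndarray):
        I_e, I_i = self.currents(RateState(r_e, r_i), r_o)
        d_e = (-r_e + self.f_e(I_e)) / self.pop_e.tau
        d_i = (-r_i + self.f_i(I_i)) / self.pop_i.tau
        return d_e, d_i

    # -- integration ------------------------------------------------------
    def integrate(self, drive: InputDrive, t_span: tuple[float, float],
                  dt: float | None = None, initial: RateState | None = None) -> RateTrajectory:
        """Integrate the rate equations with fixed-step classical RK4.

        ``dt`` defaults to ``min(tau_e, tau_i) / 20``.  Raises if the state
        becomes non-finite, naming the first offending point/population.
        """
        if dt is None:
            dt = min(self.pop_e.tau, self.pop_i.tau) / 20.0
        if not (dt > 0):
            raise ValueError("dt must be > 0")
        t0, t1 = t_span
        n = int(np.ceil((t1 - t0) / dt))
        state = initial.copy() if initial is not None else RateState.zeros(self.K)
        t_out = t0 + dt * np.arange(n + 1)
        r_e_out = np.empty((n + 1, self.K))
        r_i_out = np.empty((n + 1, self.K))
        r_e, r_i = state.r_e, state.r_i
        r_e_out[0], r_i_out[0] = r_e, r_i
        for j in range(n):
            t = t0 + j * dt
            ro0, ro_h, ro1 = drive(t), drive(t + dt / 2), drive(t + dt)
            k1e, k1i = self._rhs(r_e, r_i, ro0)
            k2e, k2i = self._rhs(r_e + dt / 2 * k1e, r_i + dt / 2 * k1i, ro_h)
            k3e, k3i = self._rhs(r_e + dt / 2 * k2e, r_i + dt / 2 * k2i, ro_h)
            k4e, k4i = self._rhs(r_e + dt * k3e, r_i + dt * k3i, ro1)
            r_e = np.maximum(r_e + dt / 6 * (k1e + 2 * k2e + 2 * k3e + k4e), 0.0)
            r_i = np.maximum(r_i + dt / 6 * (k1i + 2 * k2i + 2 * k3i + k4i), 0.0)
            if not (np.all(np.isfinite(r_e)) and np.all(np.isfinite(r_i))):
                bad_pop = "e" if not np.all(np.isfinite(r_e)) else "i"
                arr = r_e if bad_pop == "e" else r_i
                k_bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise FloatingPointError(
                    f"non-finite rate at t={t + dt:.3f} ms, point {k_bad}, population {bad_pop}")
            r_e_out[j + 1], r_i_out[j + 1] = r_e, r_i
        return RateTrajectory(t_out, r_e_out, r_i_out)

    # -- steady state -----------------------------------------------------
    def map_once(self, r_e: np.ndarray, r_i: np.ndarray, r_o: np.ndarray):
        """One application of the fixed-point map r -> f(I(r))."""
        I_e, I_i = self.currents(RateState(r_e, r_i), r_o)
        return self.f_e(I_e), self.f_i(I_i)

    def steady_state(self, r_o, initial: RateState | None = None,
                     damping: float = 0.1, max_iter: int = 20000,
                     tol_res: float = 1e-8, tol_step: float = 1e-10) -> RateState:
        """Self-consistent fixed point of the rate equations.

        Damped fixed-point iteration on the steady-state equations, refined
        by a root finder; if the iteration cycles (which the undamped map
        does at large synaptic weights even when the rate dynamics are
        stable) a long forward integration of the dynamics is used as a
        rescue before the final refinement.  The returned state has
        residual ``|r - f(I(r))|`` below ``tol_res`` spikes/s.  Raises
        :class:`ConvergenceError` when no solution is reached, which for
        physiological parameters signals instability or oscillation.
        """
        r_o = np.atleast_1d(np.asarray(r_o, dtype=float))
        if r_o.shape != (self.K,):
            raise ValueError(f"drive must have shape ({self.K},)")
        if initial is not None:
            r_e, r_i = initial.r_e.copy(), initial.r_i.copy()
        else:
            r_e = np.zeros(self.K)
            r_i = np.zeros(self.K)
        eta = damping
        for _ in range(max_iter):
            f_e, f_i = self.map_once(r_e, r_i, r_o)
            new_e = (1 - eta) * r_e + eta * f_e
            new_i = (1 - eta) * r_i + eta * f_i
            step = max(np.max(np.abs(new_e - r_e)), np.max(np.abs(new_i - r_i)))
            scale = max(np.max(np.abs(new_e)), np.max(np.abs(new_i)), 1.0)
            r_e, r_i = new_e, new_i
            if step < tol_step * scale:
                break
        res = self._residual(r_e, r_i, r_o)
        if res > tol_res:
            r_e, r_i, res = self._root_refine(r_e, r_i, r_o)
        if res > tol_res:
            # rescue: follow the stable attractor of the dynamics, then refine
            traj = self.integrate(InputDrive.constant(r_o), (0.0, 3000.0),
                                  initial=RateState(np.maximum(r_e, 0.0),
                                                    np.maximum(r_i, 0.0)))
            fin = traj.final_state()
            r_e, r_i, res = self._root_refine(fin.r_e, fin.r_i, r_o)
        if res > tol_res:
            raise ConvergenceError(
                f"steady state did not converge (residual {res:.3e} spikes/s); "
                "the configuration may be unstable or oscillatory")
        return RateState(np.maximum(r_e, 0.0), np.maximum(r_i, 0.0))

    def _residual(self, r_e, r_i, r_o) -> float:
        f_e, f_i = self.map_once(r_e, r_i, r_o)
        return float(max(np.max(np.abs(r_e - f_e)), np.max(np.abs(r_i - f_i))))

    def _root_refine(self, r_e, r_i, r_o):
        def fun(x):
            re, ri = x[:self.K], x[self.K:]
            fe, fi = self.map_once(re, ri, r_o)
            return np.concatenate([re - fe, ri - fi])

        sol = optimize.root(fun, np.concatenate([r_e, r_i]), method="hybr",
                            options={"xtol": 1e-13})
        re, ri = sol.x[:self.K], sol.x[self.K:]
        return re, ri, self._residual(re, ri, r_o)

    # -- curves -----------------------------------------------------------
    def io_curve(self, drive_grid: Sequence, point: int = 0, population: str = "e",
                 return_states: bool = False):
        """Steady-state rate of one population/point over a grid of drives.

        ``drive_grid`` entries may be scalars (applied to point 0 of a
        single-point network, zeros elsewhere... scalars require K == 1) or
        K-vectors.  Solves are warm-started along the grid.
        """
        if population not in ("e", "i"):
            raise ValueError("population must be 'e' or 'i'")
        inputs, rates, states = [], [], []
        prev: RateState | None = None
        for g in drive_grid:
            g_arr = np.atleast_1d(np.asarray(g, dtype=float))
            if g_arr.size == 1 and self.K == 1:
                r_o = g_arr
                x_val = float(g_arr[0])
            elif g_arr.shape == (self.K,):
                r_o = g_arr
                x_val = float(np.max(g_arr))
            else:
                raise ValueError("grid entry has wrong dimension")
            try:
                st = self.steady_state(r_o, initial=prev)
            except ConvergenceError as err:
                raise ConvergenceError(f"io_curve failed at drive {g!r}: {err}") from err
            prev = st
            inputs.append(x_val)
            rates.append(st.r_e[point] if population == "e" else st.r_i[point])
            states.append(st)
        inputs = np.asarray(inputs)
        rates = np.asarray(rates)
        if return_states:
            return inputs, rates, states
        return inputs, rates


# -- thin functional wrappers (spec operation surface) ---------------------

def point_currents(state: RateState, drive, points, W: CouplingMatrices,
                   pop_e: PopulationParams | None = None,
                   pop_i: PopulationParams | None = None):
    """Net input currents (I_e, I_i) for all points at the given state."""
    net = RateNetwork(points, W, pop_e, pop_i)
    return net.currents(state, drive)


def integrate_rates(points, W, drive: InputDrive, t_span, dt=None,
                    initial: RateState | None = None,
                    pop_e: PopulationParams | None = None,
                    pop_i: PopulationParams | None = None) -> RateTrajectory:
    return RateNetwork(points, W, pop_e, pop_i).integrate(drive, t_span, dt, initial)


def steady_state(points, W, drive, pop_e: PopulationParams | None = None,
                 pop_i: PopulationParams | None = None, **kw) -> RateState:
    return RateNetwork(points, W, pop_e, pop_i).steady_state(drive, **kw)


def io_curve(points, W, drive_grid, point=0, population="e",
             pop_e: PopulationParams | None = None,
             pop_i: PopulationParams | None = None):
    return RateNetwork(points, W, pop_e, pop_i).io_curve(drive_grid, point, population)
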