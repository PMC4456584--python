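"""Analytic layer: balance approximations, stability, and MI-gain formula.

In the balanced regime the large excitatory and inhibitory currents nearly
cancel, so at the operating point the net inputs satisfy I_e, I_i ~ 0 and
the steady rates follow from linear algebra on the synaptic weights alone:

* single point:  r_e = A_e r_o,  r_i = A_i r_o  with
  ``A_e = (q_eo q_ii - q_io q_ei) / (q_ei q_ie - q_ee q_ii)`` (and the
  analogous A_i);
* K points: eliminating the i-rates yields an effective linear system
  ``q_hat_eo r_o + M r_e = 0`` with ``M_kk = q_hat_ee``,
  ``M_kl = w_hat_e,kl`` and hats meaning ``x_hat = x_e - (q_ei/q_ii) x_i``.

Stability of a point follows from the Jacobian of the rate equations
linearised at the balance operating point (transfer slope r_max / I_half),
giving the two inequalities ``q_ie q_ei > q_ee q_ii`` (no cross-feedback
oscillation) and ``gamma_i q_ii > gamma_e q_ee`` (auto-inhibition dominates
auto-excitation), with ``gamma_a = r_max,a / (tau_a I_half,a)``.

The finite-ceiling correction to the balance gain -- the closed-form
response gain with MI-neuron disinhibition -- keeps the leading
transfer-function terms ``alpha_e = I_half,e / r_max,e`` and
``alpha_i = I_half,i / (G r_max,i)``; lowering G raises alpha_i and with it
the gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rate import (CouplingMatrices, PointParams, PopulationParams, RateNetwork,
                   RateState, RateTrajectory, InputDrive)
from .transfer import TransferParams, naka_rushton_deriv

__all__ = [
    "BalanceGains",
    "EffectiveCoupling",
    "StabilityReport",
    "MiGainCoeffs",
    "single_point_balance",
    "effective_coupling",
    "network_balance_rates",
    "jacobian_at_balance",
    "system_jacobian",
    "finite_difference_jacobian",
    "linear_equivalent_network",
    "linear_equivalent_trajectory",
    "linear_fixed_point",
    "mi_gain",
]


@dataclass(frozen=True)
class BalanceGains:
    """Steady-state gains of r_e and r_i with respect to r_o (dimensionless)."""

    A_e: float
    A_i: float

    def to_dict(self) -> dict:
        return {"A_e": self.A_e, "A_i": self.A_i}


@dataclass(frozen=True)
class EffectiveCoupling:
    """Effective linear system after eliminating the i-cell rates."""

    q_hat_eo: float
    q_hat_ee: float
    w_hat: np.ndarray
    M: np.ndarray


@dataclass(frozen=True)
class StabilityReport:
    """Per-point linear stability diagnostics at the balance operating point."""

    jacobian: np.ndarray         # 2x2, 1/ms
    eigenvalues: np.ndarray      # complex pair
    gamma_e: float               # r_max,e / (tau_e I_half,e), 1/ms
    gamma_i: float
    cond_cross: bool             # q_ie q_ei > q_ee q_ii
    cond_auto: bool              # gamma_i q_ii > gamma_e q_ee
    stable: bool
    marginal: bool = False       # |Re lambda| within tolerance of zero

    def to_dict(self) -> dict:
        return {
            "jacobian": self.jacobian.tolist(),
            "eigenvalues_re": np.real(self.eigenvalues).tolist(),
            "eigenvalues_im": np.imag(self.eigenvalues).tolist(),
            "gamma_e": self.gamma_e, "gamma_i": self.gamma_i,
            "cond_cross": self.cond_cross, "cond_auto": self.cond_auto,
            "stable": self.stable, "marginal": self.marginal,
        }


@dataclass(frozen=True)
class MiGainCoeffs:
    """Finite-ceiling gain of r_e w.r.t. r_o under MI disinhibition."""

    alpha_e: float
    alpha_i: float
    gain: float


def single_point_balance(p: PointParams) -> BalanceGains:
    """Balance-approximation gains A_e, A_i of an isolated point.

    Warns (rather than errors) when a gain is non-positive, since
    positivity is a physiological-validity requirement, not an algebraic
    one.  Raises on a vanishing denominator (degenerate balance).
    """
    den = p.q_ei * p.q_ie - p.q_ee * p.q_ii
    if den == 0:
        raise ZeroDivisionError("degenerate balance: q_ei q_ie - q_ee q_ii = 0")
    A_e = (p.q_eo * p.q_ii - p.q_io * p.q_ei) / den
    A_i = (p.q_eo * p.q_ie - p.q_io * p.q_ee) / den
    if (p.q_eo > 0 or p.q_io > 0) and (A_e <= 0 or A_i <= 0):
        warnings.warn("balance gains are not both positive; the balanced "
                      "solution is not physiological for this parameter set",
                      stacklevel=2)
    return BalanceGains(A_e, A_i)


def effective_coupling(points, W: CouplingMatrices) -> EffectiveCoupling:
    """Effective connectivity of the K-point balance approximation.

    Assumes identical within-point weights across points (the model's
    convention); uses point 0's parameters.
    """
    p = points[0] if not isinstance(points, PointParams) else points
    if p.q_ii == 0:
        raise ZeroDivisionError("q_ii must be non-zero to eliminate the i-rates")
    ratio = p.q_ei / p.q_ii
    q_hat_eo = p.q_eo - ratio * p.q_io
    q_hat_ee = p.q_ee - ratio * p.q_ie
    w_hat = W.w_e - ratio * W.w_i
    M = w_hat.copy()
    np.fill_diagonal(M, q_hat_ee)
    return EffectiveCoupling(q_hat_eo, q_hat_ee, w_hat, M)


def network_balance_rates(points, W: CouplingMatrices, drive) -> tuple[np.ndarray, np.ndarray]:
    """Balance-approximation rates (r_e, r_i) of the K-point network.

    Solves ``r_e = -q_hat_eo M^{-1} r_o`` and recovers the i-rates from the
    i-cell balance condition.  Raises ``numpy.linalg.LinAlgError`` for a
    singular effective matrix.
    """
    if isinstance(points, PointParams):
        points = [points] * W.K
    r_o = np.atleast_1d(np.asarray(drive, dtype=float))
    if r_o.shape != (W.K,):
        raise ValueError(f"drive must have shape ({W.K},)")
    eff = effective_coupling(points, W)
    r_e = -eff.q_hat_eo * np.linalg.solve(eff.M, r_o)
    p = points[0]
    r_i = (p.q_io * r_o + p.q_ie * r_e + W.w_i @ r_e) / p.q_ii
    return r_e, r_i


# -- stability -------------------------------------------------------------

def jacobian_at_balance(p: PointParams, pop_e: PopulationParams | None = None,
                        pop_i: PopulationParams | None = None,
                        tol: float = 1e-10) -> StabilityReport:
    """Stability of one point, linearised at the balance operating point.

    The transfer-function slope is taken at I = 0+ (``r_max / I_half``),
    so the Jacobian is ``[[g_e q_ee, -g_e q_ei], [g_i q_ie, -g_i q_ii]]``
    with ``g_a = gamma_a = r_max,a / (tau_a I_half,a)``.  ``stable`` holds
    when the trace is negative and the determinant positive, which is
    exactly the conjunction of ``cond_cross`` and ``cond_auto``; marginal
    spectra (|Re lambda| < tol) are reported unstable with
    ``marginal=True``.
    """
    pop_e = pop_e if pop_e is not None else PopulationParams()
    pop_i = pop_i if pop_i is not None else PopulationParams()
    te, ti = pop_e.transfer, pop_i.transfer
    r_max_i = p.G_i * ti.r_max
    gamma_e = te.r_max / (pop_e.tau * te.I_half)
    gamma_i = r_max_i / (pop_i.tau * ti.I_half)
    J = np.array([[gamma_e * p.q_ee, -gamma_e * p.q_ei],
                  [gamma_i * p.q_ie, -gamma_i * p.q_ii]])
    eig = np.linalg.eigvals(J)
    cond_cross = p.q_ie * p.q_ei > p.q_ee * p.q_ii
    cond_auto = gamma_i * p.q_ii > gamma_e * p.q_ee
    marginal = bool(np.any(np.abs(np.real(eig)) < tol))
    stable = bool(np.all(np.real(eig) < -tol))
    if marginal:
        warnings.warn("marginal eigenvalue at the balance point; reported unstable",
                      stacklevel=2)
        stable = False
    return StabilityReport(J, eig, gamma_e, gamma_i, cond_cross, cond_auto,
                           stable, marginal)


def system_jacobian(net: RateNetwork, state: RateState, drive) -> np.ndarray:
    """Analytic 2K x 2K Jacobian of the full nonlinear rate system.

    Evaluated at an arbitrary state (typically a numeric fixed point),
    with the transfer slope taken at the actual input currents.  Variable
    order is ``[r_e,0..K-1, r_i,0..K-1]``; units 1/ms.
    """
    K = net.K
    r_o = np.atleast_1d(np.asarray(drive, dtype=float))
    I_e, I_i = net.currents(state, r_o)
    te, ti = net.pop_e.transfer, net.pop_i.transfer
    fp_e = naka_rushton_deriv(I_e, te)
    fp_i = net._G * np.asarray(naka_rushton_deriv(I_i, ti))
    q = net._q
    J = np.zeros((2 * K, 2 * K))
    # e rows
    dIe_dre = np.diag(q["q_ee"]) + net.W.w_e
    dIe_dri = np.diag(-q["q_ei"])
    J[:K, :K] = (np.atleast_1d(fp_e)[:, None] * dIe_dre - np.eye(K)) / net.pop_e.tau
    J[:K, K:] = (np.atleast_1d(fp_e)[:, None] * dIe_dri) / net.pop_e.tau
    # i rows
    dIi_dre = np.diag(q["q_ie"]) + net.W.w_i
    dIi_dri = np.diag(-q["q_ii"])
    J[K:, :K] = (np.atleast_1d(fp_i)[:, None] * dIi_dre) / net.pop_i.tau
    J[K:, K:] = (np.atleast_1d(fp_i)[:, None] * dIi_dri - np.eye(K)) / net.pop_i.tau
    return J


def finite_difference_jacobian(net: RateNetwork, state: RateState, drive,
                               h: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of the rate equations (oracle for tests)."""
    K = net.K
    r_o = np.atleast_1d(np.asarray(drive, dtype=float))

    def rhs(x):
        d_e, d_i = net._rhs(x[:K], x[K:], r_o)
        return np.concatenate([d_e, d_i])

    x0 = np.concatenate([state.r_e, state.r_i])
    J = np.zeros((2 * K, 2 * K))
    for j in range(2 * K):
        step = h * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (rhs(xp) - rhs(xm)) / (2 * step)
    return J


# -- linear equivalent system ---------------------------------------------

class _LinearRateNetwork(RateNetwork):
    """Rate network with f replaced by the scaled linear current map.

    The transfer function becomes ``gamma_a * I_a`` with
    ``gamma_a = r_max,a / I_half,a`` (for i-cells, ``G r_max,i``): no
    rectification and no ceiling, so it tracks the nonlinear system at
    mid-range drives and overshoots it at high rates.
    """

    def f_e(self, I_e):
        te = self.pop_e.transfer
        return (te.r_max / te.I_half) * np.asarray(I_e, dtype=float)

    def f_i(self, I_i):
        ti = self.pop_i.transfer
        return self._G * (ti.r_max / ti.I_half) * np.asarray(I_i, dtype=float)


def linear_equivalent_network(points, W=None, pop_e=None, pop_i=None, K=None) -> RateNetwork:
    return _LinearRateNetwork(points, W, pop_e, pop_i, K=K)


def linear_equivalent_trajectory(points, W, drive: InputDrive, t_span, dt=None,
                                 initial: RateState | None = None,
                                 pop_e=None, pop_i=None) -> RateTrajectory:
    """Integrate the linear-equivalent system (same RK4 grid as the rate model)."""
    return linear_equivalent_network(points, W, pop_e, pop_i).integrate(
        drive, t_span, dt, initial)


def linear_fixed_point(points, W, drive, pop_e=None, pop_i=None) -> RateState:
    """Closed-form fixed point of the linear-equivalent system."""
    net = linear_equivalent_network(points, W, pop_e, pop_i)
    K = net.K
    r_o = np.atleast_1d(np.asarray(drive, dtype=float))
    te, ti = net.pop_e.transfer, net.pop_i.transfer
    g_e = te.r_max / te.I_half
    g_i = net._G * (ti.r_max / ti.I_half)
    q = net._q
    A = np.zeros((2 * K, 2 * K))
    A[:K, :K] = np.eye(K) - g_e * (np.diag(q["q_ee"]) + net.W.w_e)
    A[:K, K:] = g_e * np.diag(q["q_ei"])
    A[K:, :K] = -g_i[:, None] * (np.diag(q["q_ie"]) + net.W.w_i)
    A[K:, K:] = np.eye(K) + g_i[:, None] * np.diag(q["q_ii"])
    b = np.concatenate([g_e * q["q_eo"] * r_o, g_i * q["q_io"] * r_o])
    x = np.linalg.solve(A, b)
    return RateState(x[:K], x[K:])


# -- stability boundary sweep ----------------------------------------------

def numeric_balanced_stability(net: RateNetwork, drive,
                               t_probe: float = 1500.0) -> bool:
    """Does forward integration settle onto the balanced branch?

    Integrates the nonlinear dynamics from the balance-approximation
    state and requires that the trajectory (i) stops moving (late
    peak-to-peak variation below 1% of the rate scale: no oscillation)
    and (ii) stays in the neighbourhood of the balanced solution (no
    runaway to the saturated branch).
    """
    r_o = np.atleast_1d(np.asarray(drive, dtype=float))
    try:
        re_b, ri_b = network_balance_rates(net.points, net.W, r_o)
    except np.linalg.LinAlgError:
        return False
    if np.any(re_b <= 0) or np.any(ri_b <= 0):
        return False
    cap_e = 0.95 * net.pop_e.transfer.r_max
    cap_i = 0.95 * net.r_max_i_eff
    init = RateState(np.clip(re_b, 0.0, cap_e), np.clip(ri_b, 0.0, cap_i))
    traj = net.integrate(InputDrive.constant(r_o), (0.0, t_probe), initial=init)
    scale = max(np.max(init.r_e), np.max(init.r_i), 1.0)

    def window_ptp(lo, hi):
        sl = slice(int(lo * traj.t.size), max(int(hi * traj.t.size), int(lo * traj.t.size) + 2))
        return max(np.ptp(traj.r_e[sl], axis=0).max(),
                   np.ptp(traj.r_i[sl], axis=0).max())

    early, late = window_ptp(0.0, 0.2), window_ptp(0.8, 1.0)
    contracting = late < 0.01 * scale or late < 0.5 * early
    near = max(np.max(np.abs(traj.r_e[-1] - init.r_e)),
               np.max(np.abs(traj.r_i[-1] - init.r_i))) < max(0.25 * scale, 2.0)
    return bool(contracting and near)


def stability_sweep(q_ee_grid, q_ii_grid, q_ei: float = 1.7, q_ie: float = 1.0,
                    G_i: float = 1.0,
                    pop_e: PopulationParams | None = None,
                    pop_i: PopulationParams | None = None,
                    weight_scale: float = 4.0, drive: float = 10.0):
    """Analytic vs numerically observed stability over a (q_ee, q_ii) grid.

    Each cell evaluates the balance-point inequalities and probes the
    nonlinear dynamics (at ``weight_scale`` times the grid weights, which
    leaves the analytic conditions unchanged but tightens the balanced
    regime).  Returns a tidy table: grid coordinates, the two analytic
    conditions, the leading eigenvalue real part and both verdicts.
    """
    import pandas as pd

    pop_e = pop_e if pop_e is not None else PopulationParams()
    pop_i = pop_i if pop_i is not None else PopulationParams()
    rows = []
    for q_ee in q_ee_grid:
        for q_ii in q_ii_grid:
            p = PointParams(q_ee=q_ee, q_ii=q_ii, q_ei=q_ei, q_ie=q_ie, G_i=G_i)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = jacobian_at_balance(p, pop_e, pop_i)
            net = RateNetwork(p.scaled(weight_scale), K=1, pop_e=pop_e, pop_i=pop_i)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                numeric = numeric_balanced_stability(net, [drive])
            rows.append({
                "q_ee": q_ee, "q_ii": q_ii,
                "cond_cross": rep.cond_cross, "cond_auto": rep.cond_auto,
                "eig_re_max": float(np.max(np.real(rep.eigenvalues))),
                "analytic_stable": rep.stable, "numeric_stable": numeric,
            })
    return pd.DataFrame(rows)


# -- MI-neuron gain ---------------------------------------------------------

def mi_gain(p: PointParams, transfer_e: TransferParams | None = None,
            transfer_i: TransferParams | None = None, G: float = 1.0) -> MiGainCoeffs:
    """Closed-form response gain d r_e / d r_o under MI disinhibition.

    ``gain = [q_eo (q_ii + alpha_i) - q_io q_ei] /
    [q_ei q_ie - (q_ee - alpha_e)(q_ii + alpha_i)]`` with
    ``alpha_e = I_half,e / r_max,e`` and
    ``alpha_i = I_half,i / (G r_max,i)``.  In the limit alpha -> 0 this
    reduces to the balance gain A_e.  Raises when the denominator is
    non-positive (loss of the balanced regime).
    """
    if not (0 < G <= 1):
        raise ValueError(f"G must lie in (0, 1], got {G}")
    te = transfer_e if transfer_e is not None else TransferParams()
    ti = transfer_i if transfer_i is not None else TransferParams()
    alpha_e = te.I_half / te.r_max
    alpha_i = ti.I_half / (G * ti.r_max)
    den = p.q_ei * p.q_ie - (p.q_ee - alpha_e) * (p.q_ii + alpha_i)
    if den <= 0:
        raise ValueError("mi_gain denominator <= 0: balance is lost for these "
                         f"parameters (den={den:.4g})")
    gain = (p.q_eo * (p.q_ii + alpha_i) - p.q_io * p.q_ei) / den
    return MiGainCoeffs(alpha_e, alpha_i, gain)
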