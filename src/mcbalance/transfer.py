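"""Open-loop neuronal transfer functions.

Two descriptions of how input current maps to firing rate:

* :func:`naka_rushton` -- the saturating first-order Rushton--Naka f/I
  relation used for both the excitatory and inhibitory populations of a
  cortical point.  It is parameterised by the maximum rate ``r_max``, the
  half-saturation input ``I_half`` and a rectifying threshold ``I_T``.
* :func:`two_comp_rate` -- the first-order firing-rate approximation of a
  two-compartment (soma + passive dendrite) integrate-and-fire neuron,
  which motivates the saturating shape: dendritic current is attenuated by
  the coupling factor ``g_c / (g_c + g_D)`` before reaching the spike
  generator.

Unit convention: inputs to the Rushton--Naka function are dimensionless
drive in units where synaptic products ``q * r`` compare directly to
``I_half = 25`` (the paper's rate-like current units); rates are in
spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransferParams",
    "TwoCompartmentParams",
    "naka_rushton",
    "naka_rushton_deriv",
    "two_comp_rate",
]


@dataclass(frozen=True)
class TransferParams:
    """Parameters of the Rushton--Naka f/I curve.

    Attributes
    ----------
    r_max : float
        Maximum firing rate (spikes/s).  Default 250, the in-vitro value
        for cat motor-cortex neurons adopted for both populations.
    I_half : float
        Input at which the rate reaches ``r_max / 2`` above threshold.
        Default 25 (drive units).
    I_T : float
        Rectification threshold.  Default 0 (supra-threshold activation).
    """

    r_max: float = 250.0
    I_half: float = 25.0
    I_T: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_max > 0):
            raise ValueError(f"r_max must be > 0, got {self.r_max}")
        if not (self.I_half > 0):
            raise ValueError(f"I_half must be > 0, got {self.I_half}")
        if self.I_T < 0:
            raise ValueError(f"I_T must be >= 0, got {self.I_T}")


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Biophysics of the two-compartment (soma + dendrite) e-cell.

    Defaults are the in-vitro cat layer-5 pyramidal values: somatic /
    dendritic capacitances 0.175 / 0.525 nF, somatic leak 0.06 uS,
    dendritic conductance 0.12 uS, soma--dendrite coupling 0.06 uS,
    threshold -60 mV, rest and reset -75 mV, synaptic reversals 0 / -85 mV.
    """

    C_m: float = 0.175  # nF, somatic
    C_d: float = 0.525  # nF, dendritic
    g_s: float = 0.06   # uS, somatic leak
    g_D: float = 0.12   # uS, dendritic
    g_c: float = 0.06   # uS, coupling
    V_T: float = -60.0  # mV
    V_r: float = -75.0  # mV
    V_reset: float = -75.0  # mV
    E_exc: float = 0.0  # mV
    E_inh: float = -85.0  # mV

    def __post_init__(self) -> None:
        for name in ("C_m", "C_d", "g_s", "g_D"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (self.g_c > 0):
            raise ValueError("g_c must be > 0")
        if self.V_reset > self.V_T:
            raise ValueError("V_reset must not exceed V_T")
        if not (self.E_inh < self.V_T < self.E_exc):
            raise ValueError("require E_inh < V_T < E_exc")

    @property
    def attenuation(self) -> float:
        """Dendrite-to-soma current attenuation ``g_c / (g_c + g_D)``."""
        return self.g_c / (self.g_c + self.g_D)


def naka_rushton(I, p: TransferParams):
    """Rushton--Naka transfer function ``|(I-I_T)/(I_half+(I-I_T))|+ * r_max``.

    Half-rectified: returns 0 for ``I <= I_T``; strictly increasing and
    bounded below ``r_max`` for ``I > I_T``.  Accepts scalars or arrays.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite input current passed to naka_rushton")
    x = np.maximum(I - p.I_T, 0.0)
    out = p.r_max * x / (p.I_half + x)
    return out if out.ndim else float(out)


def naka_rushton_deriv(I, p: TransferParams):
    """Slope ``df/dI`` of the Rushton--Naka curve.

    Equal to ``r_max * I_half / (I_half + I - I_T)**2`` above threshold and
    0 below; at ``I = I_T`` the right-hand slope ``r_max / I_half`` is
    returned (the balance-analysis linearisation point).
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite input current passed to naka_rushton_deriv")
    x = I - p.I_T
    out = np.where(x >= 0, p.r_max * p.I_half / (p.I_half + np.maximum(x, 0.0)) ** 2, 0.0)
    return out if out.ndim else float(out)


def two_comp_rate(I_s, I_d, p: TwoCompartmentParams):
    """First-order firing rate of the two-compartment cell.

    ``r = [I_s + g_c/(g_c+g_D) * I_d] / [C_m (V_T - V_r)]``, floored at 0.
    With currents in nA, capacitance in nF and voltage in mV the result is
    in spikes/ms; the formula is homogeneous, so any consistent unit
    system may be used.
    """
    I_s = np.asarray(I_s, dtype=float)
    I_d = np.asarray(I_d, dtype=float)
    if not (np.all(np.isfinite(I_s)) and np.all(np.isfinite(I_d))):
        raise ValueError("non-finite input current passed to two_comp_rate")
    rate = (I_s + p.attenuation * I_d) / (p.C_m * (p.V_T - p.V_r))
    out = np.maximum(rate, 0.0)
    return out if out.ndim else float(out)
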