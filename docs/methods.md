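# Methods

## The model

A *cortical point* is a local patch of motor cortex reduced to one
excitatory (e) and one inhibitory (i) population with firing-rate
dynamics

    tau_a dr_a,k/dt = -r_a,k + f_a(I_a,k),        a in {e, i},  k = 1..K,

where the transfer function is a half-rectified first-order
Rushton–Naka curve

    f_a(I) = |(I - I_T,a) / (I_half,a + (I - I_T,a))|_+  *  r_max,a ,

the saturating shape motivated by a two-compartment (soma + passive
dendrite) description of layer-5 pyramidal cells, in which dendritic
current is attenuated by g_c/(g_c + g_D) before reaching the spike
generator.  Input currents combine external drive, within-point
recurrence and between-point excitation:

    I_a,k = q_ao r_o,k + q_ae r_e,k - q_ai r_i,k + sum_{l != k} w_a,kl r_e,l .

Within-point synaptic magnitudes `q_ab` are stored as positive numbers
(the minus sign on the inhibitory term lives in the equation); only
e-cell collaterals project between points, so inhibition is local.  A
point's master-inhibitory (MI) interneurons are not simulated as a
population: their effect is a multiplicative gain 0 <= G <= 1 on the
i-cell ceiling, `r_max,i -> G r_max,i`, the model's disinhibition knob.

When the synaptic magnitudes are large compared with I_half, the stable
operating point is *balanced*: recurrent inhibition nearly cancels the
excitatory drive in both populations, the net currents are small against
their components, and the steady rates follow from linear algebra on the
weights alone — for one point `r_e = A_e r_o`, `r_i = A_i r_o` with

    A_e = (q_eo q_ii - q_io q_ei) / (q_ei q_ie - q_ee q_ii),
    A_i = (q_eo q_ie - q_io q_ee) / (q_ei q_ie - q_ee q_ii),

and for K points, after eliminating the i-rates, the effective linear
system `q_hat_eo r_o + M r_e = 0` with `M_kk = q_ee - (q_ei/q_ii) q_ie`,
`M_kl = w_e,kl - (q_ei/q_ii) w_i,kl`, `q_hat_eo = q_eo - (q_ei/q_ii) q_io`.
Stability of a point, from the Jacobian linearised at the balance
operating point (transfer slope r_max/I_half), requires
`q_ie q_ei > q_ee q_ii` (no cross-feedback oscillation) and
`gamma_i q_ii > gamma_e q_ee` with `gamma_a = r_max,a/(tau_a I_half,a)`
(auto-inhibition dominates auto-excitation).  The corticospinal readout
is the fixed linear map `m = W r_e`, so linear summation of cortical
outputs carries over to muscle activations exactly.

## Default parameters

| quantity | default | unit | note |
|---|---|---|---|
| r_max,e, r_max,i | 250 | spikes/s | in-vitro ceiling; the MI-gain preset uses r_max,i = 300 (printed for that configuration) |
| I_half | 25 | drive units | inputs are dimensionless drive in units where q·r compares directly to I_half |
| I_T | 0 | drive units | supra-threshold stimulation regime |
| q_ee, q_ei, q_ie, q_ii | 0.67, 1.7, 1, 2 | charge/spike | reference within-point magnitudes |
| q_eo, q_io | 1, 1 | charge/spike | never printed in the source material; chosen so that the three-point balance solve reproduces the documented 45 spikes/s worked example |
| w (adjacent / distal) | 0.2 / 0.02 | charge/spike | symmetric, equal onto e and i targets |
| tau_e, tau_i | 10 | ms | transients only; steady states are tau-free |
| G | 1 | – | MI gain; swept in the disinhibition presets |

## Numerics

* **Integration** — fixed-step classical Runge–Kutta on the rate
  equations, `dt = min(tau)/20`; rates floored at zero each step;
  non-finite states raise naming the point/population/time.
* **Steady states** — damped fixed-point iteration on `r = f(I(r))`
  (damping 0.1, relative step tolerance 1e-10), refined by a hybrid
  Powell root solve; if the undamped map cycles (it does at large
  weights even when the dynamics are stable) a 3 s forward integration
  rescues the iterate before the final refinement.  Accepted residual:
  1e-8 spikes/s.  Non-convergence raises, signalling instability or
  oscillation.
* **Jacobians** — the per-point stability report evaluates the transfer
  slope at I = 0+, i.e. r_max/I_half (the balance-limit convention);
  the full-system Jacobian for oracle comparisons uses the analytic
  slope at the actual operating currents.  Eigenvalue stability is
  decided on real parts with tolerance 1e-10; marginal spectra are
  reported unstable with a flag.
* **Linear-equivalent system** — f replaced by `(r_max/I_half) I` with
  no rectification or ceiling; its fixed point is a single linear solve.

## Spiking counterpart

Each point holds N_e two-compartment LIF e-cells (somatic/dendritic
capacitance 0.175/0.525 nF, conductances 0.06/0.12 µS, coupling
0.06 µS) and N_i one-compartment LIF i-cells (0.7 nF, 0.1 µS); threshold
-60 mV, rest and reset -75 mV, synaptic reversals 0/-85 mV.  Wiring is
i.i.d. Bernoulli with mean within-point in-degrees 1000 (e) and 1000 (i)
at full scale; between-point in-degrees mirror the rate-model coupling
ratios (`K = round(1000 w)` at full scale, so 200 adjacent / 20 distal);
80 % of synapses of every kind, external included, sit on the e-cell
dendrite; conduction delays are 10 ms between adjacent points and 20 ms
for the distal pair (linear in the 1 mm spacing).  External drive is an
independent Poisson aggregate per neuron at rate `C_ext r_o,k`
(C_ext = 1000 at full scale).

**Synaptic unit convention.**  Synapses are "instantaneous conductance
changes", which leaves the delivered charge per spike undefined until a
pulse integral is fixed.  The package interprets a printed amplitude
g (nS) as a rectangular pulse of fixed unit width `pulse_ms = 0.25 ms`,
delivered exactly: the membrane relaxes toward the conductance-weighted
reversal by `exp(-(sum g dt)/C)`, which cannot overshoot however many
events coincide.  This width puts unitary somatic PSPs in the 0.5–2.5 mV
range, i.e. a few tens of presynaptic spikes reach threshold, the regime
the rate-model construction assumes.

**Calibration of i-cell synapses.**  Taken at face value, the printed
i-target amplitudes (1.18, 1.18, 8.30 nS onto 0.7 nF) make i-cells about
17× less sensitive per presynaptic spike, in threshold-charge units,
than e-cells — roughly 250 spikes to threshold — which violates the
model's own stability inequality (`gamma_i q_ii > gamma_e q_ee`) under
*any* uniform pulse convention (the conversion factor cancels from the
inequality), and in simulation produces an ignition to a >900 spikes/s
runaway state instead of the balanced regime.  The spiking presets
therefore multiply the three i-target amplitudes by one factor computed
from the biophysical constants alone: the ratio of external charge per
spike, measured in units of each cell's threshold charge C (V_T − V_r),
between e-cells (dendritic attenuation included) and i-cells,

    calibration = (C_i / C_m,e) * (g_ext,e (0.2 + 0.8 g_c/(g_c+g_D)) / g_ext,i)
                = 4 * 4.216 = 16.86 .

This enforces the same `q_eo = q_io` convention the rate model uses,
restores "a few tens" of spikes to threshold for both cell types (≈30
for i-cells), and restores the stability inequality.  It is an explicit,
documented flag of the preset builder (`calibrate_i`); the raw printed
amplitudes remain the dataclass defaults.

**Desk scale.**  The default presets run at scale 0.25: populations and
in-degrees shrink ×0.25 (2000/500 per point, in-degrees 250/250, C_ext
250) while amplitudes grow ×2 = 1/sqrt(0.25), preserving the size of the
synaptic-current fluctuations that drive irregular firing.  Full scale
(8000/2000) is available by `scale=1`.  Integration uses exponential
propagation of the linear membrane equations with dt = 0.05 ms; spike
deliveries are rounded to the grid and zero-delay (within-point) events
take effect on the following step.  Separate seeded streams drive
wiring, external Poisson input and initial voltages (uniform in
[V_r, V_T)), so rasters reproduce event-for-event.  There is no
refractory period; dynamics are reset-only.

## What the presets emulate — and what they do not

The figure presets generate the study conditions themselves (no external
data): step and ramp drives, I/O grids, coupled-point activation
patterns, disinhibition sweeps.  They emulate stationary motor-command
inputs to a homogeneous, fully connected set of points.  They do not
model spatial structure within a point, synaptic kinetics or short-term
plasticity (efficacy is assumed at steady state), an explicit spiking MI
population, or realistic corticospinal weight matrices (the demo W is a
seeded random non-negative matrix; only its linearity matters).  Passing
tests therefore demonstrate the internal consistency of the balanced
mechanism at these parameters, not a fit to recorded cortical data.

## Known limitations and honest discrepancies

* **The balance approximation is moderate, not asymptotic, at the
  printed weights.**  With q's of order one, balance-approximation rates
  deviate from the nonlinear fixed point by ~6 % at mid drives and more
  where rates approach the ceiling.  Concretely: the three-point worked
  example's closed-form solve gives 44.9 spikes/s at point-3 (the
  documented value), while the full nonlinear fixed point gives
  32.4 spikes/s, because the balance solution for the driven point
  (265 spikes/s) exceeds r_max = 250 and saturation propagates.
  Likewise the single-point I/O curve over drives 25–300 has a linear-fit
  R² of 0.990 (not 0.995+); scaling all weights ×4 reaches 0.9953, and
  the approximation error shrinks monotonically with weight scale, as
  the theory says it should.
* **Without inhibition the point saturates at 86 % of r_max at minimal
  drive** (the fixed point of r = f(5 + 0.67 r) is 214 spikes/s), i.e.
  "near-maximal" is approximate at these parameters.
* **The balance-limit stability inequalities are exact only at small
  rates.**  The slopes in the Jacobian are taken at I = 0+; at operating
  points with appreciable rates the true boundary shifts, and with
  gamma_i < gamma_e (reduced G or slow i-cells) the finite-weight system
  can hold a rectification-driven relaxation oscillation alongside the
  stable fixed point.  The stability sweep is therefore run at small
  drive, where analytic and observed verdicts agree to within one grid
  cell across the cross-feedback boundary.
* **Problem sizes.**  The shipped sweeps and spiking runs are sized for
  a laptop CPU: stability sweeps 8×8 with 1.5 s probes, spiking presets
  at scale 0.25 with 0.6–2 s simulated per run.  All sizes are ordinary
  keyword arguments.
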