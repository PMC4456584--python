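"""Figure presets: ready-made experiment configurations and runners.

Each preset builds the corresponding network, runs it, and returns a
result bundle of plain tables (pandas) and scalar metrics; writers in
:func:`run_preset` put them on disk as CSV/JSON next to a provenance
record.  All presets are deterministic given (seed, scale).

Reference parameter notes
-------------------------
* ``fig2``/``fig3``/``fig4`` -- the single cortical point with the
  reference weights (q_ee 0.67, q_ei 1.7, q_ie 1, q_ii 2, unit external
  weights); fig3 removes all inhibition, fig4 adds the linear-equivalent
  comparison.
* ``fig6`` -- three points, couplings 0.2 between adjacent points and
  0.02 between the distal pair (both onto e- and i-cells), symmetric.
* ``fig7`` -- two weakly coupled points (w = 0.02); the receiving point's
  feedback-inhibition strength q_ei is swept with q_ii fixed.
* ``fig8`` -- two points coupled at 0.2; the receiving point's MI gain G
  is swept over {1, 0.7, 0.5, 0.3}.  The i-cell ceiling is 300 spikes/s
  in this configuration (the printed value for the MI-gain analysis; the
  couplings are read as w_e = w_i = 0.2).
* ``fig9``/``fig10`` -- desk-scale spiking networks (single point; three
  points with 10/20 ms conduction delays).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import linear_fixed_point, network_balance_rates
from .metrics import (isi_cv, linear_fit_r2, linearity_deviation,
                      spectrum_peak_ratio, superposition_error, synchrony_index)
from .rate import CouplingMatrices, PointParams, PopulationParams, RateNetwork
from .spiking import (SpikingParams, build_connectivity, population_rate,
                      simulate_spiking)
from .transfer import TransferParams, naka_rushton

__all__ = ["PRESETS", "run_preset", "run_sweep", "fig6_coupling",
           "three_point_network", "single_point_network"]


# -- network builders -------------------------------------------------------

def fig6_coupling(w_adjacent: float = 0.2, w_distal: float = 0.02) -> CouplingMatrices:
    """Symmetric three-point couplings: adjacent 0.2, distal 0.02."""
    w = np.array([[0.0, w_adjacent, w_distal],
                  [w_adjacent, 0.0, w_adjacent],
                  [w_distal, w_adjacent, 0.0]])
    return CouplingMatrices(w, w.copy())


def single_point_network(**point_kw) -> RateNetwork:
    return RateNetwork(PointParams(**point_kw), K=1)


def three_point_network(**point_kw) -> RateNetwork:
    return RateNetwork(PointParams(**point_kw), fig6_coupling())


def three_point_delays(adjacent_ms: float = 10.0) -> np.ndarray:
    """Conduction delays, linear in separation (1 mm adjacent -> 10 ms)."""
    d = adjacent_ms
    return np.array([[0.0, d, 2 * d], [d, 0.0, d], [2 * d, d, 0.0]])


def _curve(net: RateNetwork, grid, point=0):
    rows = []
    prev = None
    K = net.K
    for v in grid:
        drive = np.zeros(K)
        drive[0] = v
        st = net.steady_state(drive, initial=prev)
        prev = st
        rows.append((v, st.r_e[point], st.r_i[point]))
    return pd.DataFrame(rows, columns=["drive_spk_s", "r_e_spk_s", "r_i_spk_s"])


# -- rate-model presets -----------------------------------------------------

def preset_fig2(seed=0, scale=None, drive_max=300.0, n_grid=25, **point_kw):
    """Single-point I/O curves: balanced closed loop vs open loop."""
    net = single_point_network(**point_kw)
    grid = np.linspace(0.0, drive_max, n_grid)
    closed = _curve(net, grid)
    open_rates = naka_rushton(grid * net.points[0].q_eo, net.pop_e.transfer)
    curve = closed.assign(r_open_spk_s=open_rates)
    sel = grid >= 25.0
    metrics = {
        "r2_closed_e": linear_fit_r2(grid[sel], closed.r_e_spk_s[sel]),
        "r2_closed_i": linear_fit_r2(grid[sel], closed.r_i_spk_s[sel]),
        "r2_open": linear_fit_r2(grid[sel], open_rates[sel]),
        "slope_e": float(np.polyfit(grid[sel], closed.r_e_spk_s[sel], 1)[0]),
    }
    return {"curves": {"io_curve": curve}, "metrics": metrics}


def preset_fig3(seed=0, scale=None, drive_max=300.0, n_grid=13, r_o_min=5.0):
    """No feedback inhibition (q_ei = q_ii = 0): saturation at minimal input."""
    net = single_point_network(q_ei=0.0, q_ii=0.0)
    grid = np.unique(np.append(np.linspace(0.0, drive_max, n_grid), r_o_min))
    curve = _curve(net, grid)
    at_min = net.steady_state([r_o_min])
    metrics = {
        "r_e_at_minimal_drive": float(at_min.r_e[0]),
        "r_max_e": net.pop_e.transfer.r_max,
        "fraction_of_max": float(at_min.r_e[0] / net.pop_e.transfer.r_max),
    }
    return {"curves": {"io_curve": curve}, "metrics": metrics}


def preset_fig4(seed=0, scale=None, drive_max=400.0, n_grid=17):
    """Nonlinear balanced network vs its linear-equivalent system."""
    net = single_point_network()
    grid = np.linspace(0.0, drive_max, n_grid)
    nl = _curve(net, grid)
    lin = [linear_fixed_point(net.points, net.W, [v]).r_e[0] for v in grid]
    curve = nl.assign(r_e_linear_spk_s=lin)
    mid = (grid >= 50) & (grid <= 200)
    rel = np.abs(curve.r_e_linear_spk_s[mid] - curve.r_e_spk_s[mid]) \
        / np.maximum(curve.r_e_spk_s[mid], 1e-9)
    metrics = {
        "max_rel_gap_mid_drive": float(rel.max()),
        "linear_exceeds_at_top": bool(curve.r_e_linear_spk_s.iloc[-1]
                                      > curve.r_e_spk_s.iloc[-1]),
    }
    return {"curves": {"comparison": curve}, "metrics": metrics}


def preset_fig6(seed=0, scale=None, drive_max=300.0, n_grid=7):
    """Three points: response plane of the undriven point-3."""
    net = three_point_network()
    grid = np.linspace(0.0, drive_max, n_grid)
    rows = []
    prev = None
    for d1 in grid:
        for d2 in grid:
            st = net.steady_state([d1, d2, 0.0], initial=prev)
            prev = st
            rows.append((d1, d2, st.r_e[2]))
    surface = pd.DataFrame(rows, columns=["drive_1", "drive_2", "r_e_point3"])
    re_b, _ = network_balance_rates(net.points, net.W, [0.0, drive_max, 0.0])
    st = net.steady_state([0.0, drive_max, 0.0])
    # planarity: residual of the best-fit plane through the surface
    A = np.c_[surface.drive_1, surface.drive_2, np.ones(len(surface))]
    coef, *_ = np.linalg.lstsq(A, surface.r_e_point3, rcond=None)
    resid = surface.r_e_point3 - A @ coef
    metrics = {
        "r_e3_balance_at_0_300_0": float(re_b[2]),
        "r_e3_nonlinear_at_0_300_0": float(st.r_e[2]),
        "plane_max_residual_spk_s": float(np.max(np.abs(resid))),
        "plane_rel_residual": float(np.max(np.abs(resid))
                                    / max(surface.r_e_point3.max(), 1e-9)),
    }
    return {"curves": {"response_plane": surface}, "metrics": metrics}


def preset_fig7(seed=0, scale=None, q_ei_values=(1.85, 1.5, 1.2),
                drive_max=300.0, n_grid=13, w: float = 0.02):
    """Distal coupling revealed by reducing q_ei at the receiving point."""
    wm = np.array([[0.0, w], [w, 0.0]])
    W = CouplingMatrices(wm, wm.copy())
    grid = np.linspace(0.0, drive_max, n_grid)
    curves, slopes = {}, {}
    for q_ei in q_ei_values:
        net = RateNetwork([PointParams(), PointParams(q_ei=q_ei)], W)
        c = _curve(net, grid, point=1)
        curves[f"q_ei_{q_ei:g}"] = c
        slopes[f"{q_ei:g}"] = float(np.polyfit(grid, c.r_e_spk_s, 1)[0])
    return {"curves": curves, "metrics": {"gain_vs_q_ei": slopes}}


def preset_fig8(seed=0, scale=None, G_values=(1.0, 0.7, 0.5, 0.3),
                drive_max=300.0, n_grid=13, w: float = 0.2,
                r_max_i: float = 300.0):
    """MI-neuron gain control at the receiving point (G sweep)."""
    wm = np.array([[0.0, w], [w, 0.0]])
    W = CouplingMatrices(wm, wm.copy())
    pop_i = PopulationParams(transfer=TransferParams(r_max=r_max_i))
    grid = np.linspace(0.0, drive_max, n_grid)
    curves, slopes, devs = {}, {}, {}
    for G in G_values:
        net = RateNetwork([PointParams(), PointParams(G_i=G)], W, pop_i=pop_i)
        c = _curve(net, grid, point=1)
        curves[f"G_{G:g}"] = c
        slopes[f"{G:g}"] = float(np.polyfit(grid, c.r_e_spk_s, 1)[0])
        devs[f"{G:g}"] = linearity_deviation(grid, c.r_e_spk_s.to_numpy())
    return {"curves": curves,
            "metrics": {"gain_vs_G": slopes, "linearity_deviation_vs_G": devs}}


# -- spiking presets --------------------------------------------------------

def _spiking_io(params: SpikingParams, drives, duration_ms, seed, t_skip):
    conn = build_connectivity(params, seed=seed)
    rows = []
    for j, d in enumerate(drives):
        ras = simulate_spiking(conn, [float(d)], duration_ms, seed=seed + 101 + j)
        rows.append((d, ras.mean_rate(population="e", t_start=t_skip),
                     ras.mean_rate(population="i", t_start=t_skip)))
    return pd.DataFrame(rows, columns=["drive_spk_s", "r_e_spk_s", "r_i_spk_s"])


def preset_fig9(seed=0, scale=0.25, drives=(10, 25, 50, 75, 100, 150),
                duration_ms=600.0, step_duration_ms=1000.0, t_skip=250.0):
    """Single spiking point: step response and closed- vs open-loop I/O."""
    p = SpikingParams.scaled(scale=scale)
    conn = build_connectivity(p, seed=seed)
    ras = simulate_spiking(conn, [50.0], step_duration_ms, seed=seed + 1)
    t, rate = population_rate(ras, bin_ms=1.0, point=0, population="e")
    step = pd.DataFrame({"time_ms": t, "rate_e_spk_s": rate})
    closed = _spiking_io(p, drives, duration_ms, seed, t_skip)
    open_ = _spiking_io(p.open_loop(), drives, duration_ms, seed, t_skip)
    drives = np.asarray(drives, dtype=float)
    knee = drives >= 50.0
    metrics = {
        "r2_closed_e": linear_fit_r2(drives[knee], closed.r_e_spk_s[knee]),
        "r2_closed_i": linear_fit_r2(drives[knee], closed.r_i_spk_s[knee]),
        "r2_open_e": linear_fit_r2(drives[knee], open_.r_e_spk_s[knee]),
        "isi_cv": isi_cv(ras, t_start=t_skip, population="e"),
        "synchrony_index": synchrony_index(ras, t_start=t_skip, population="e"),
    }
    return {"curves": {"step_rate": step, "io_closed": closed, "io_open": open_},
            "metrics": metrics}


def preset_fig10(seed=0, scale=0.25, drive=60.0, duration_ms=2000.0,
                 t_skip=500.0):
    """Three spiking points with conduction delays: superposition and
    asynchrony under joint vs separate activation of points 1 and 3."""
    p = SpikingParams.scaled(scale=scale, n_points=3,
                             w_e=fig6_coupling().w_e,
                             delays_ms=three_point_delays())
    conn = build_connectivity(p, seed=seed)

    def run(dr, s):
        ras = simulate_spiking(conn, np.asarray(dr, dtype=float), duration_ms,
                               seed=s)
        rates = np.array([ras.mean_rate(point=k, population="e", t_start=t_skip)
                          for k in range(3)])
        return rates, ras

    r_both, ras_both = run([drive, 0.0, drive], seed + 11)
    r_a, _ = run([drive, 0.0, 0.0], seed + 12)
    r_b, _ = run([0.0, 0.0, drive], seed + 13)
    t, rate = population_rate(ras_both, bin_ms=1.0, point=0, population="e")
    m = t >= t_skip
    metrics = {
        "rates_both": r_both.tolist(),
        "rates_point1_only": r_a.tolist(),
        "rates_point3_only": r_b.tolist(),
        "superposition_error": superposition_error(r_both, r_a, r_b),
        "synchrony_index": synchrony_index(ras_both, t_start=t_skip,
                                           point=0, population="e"),
        "isi_cv": isi_cv(ras_both, t_start=t_skip, point=0, population="e"),
        "spectrum_peak_ratio_20_120Hz": spectrum_peak_ratio(t[m], rate[m]),
    }
    raster = ras_both.to_dataframe()
    return {"curves": {"raster_joint": raster}, "metrics": metrics}


PRESETS = {
    "fig2": preset_fig2, "fig3": preset_fig3, "fig4": preset_fig4,
    "fig6": preset_fig6, "fig7": preset_fig7, "fig8": preset_fig8,
    "fig9": preset_fig9, "fig10": preset_fig10,
}


def run_preset(name: str, overrides: dict | None = None, out_dir=None,
               seed: int = 0, scale: float = 0.25) -> dict:
    """Run a named preset and optionally write its result bundle.

    Writes each table as ``<preset>_<curve>.csv``, the metrics as JSON and
    a provenance record (resolved arguments, seed, version, timestamp).
    Identical (name, overrides, seed, scale) reproduce identical outputs.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    overrides = dict(overrides or {})
    result = PRESETS[name](seed=seed, scale=scale, **overrides)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cname, df in result["curves"].items():
            df.to_csv(out / f"{name}_{cname}.csv", index=False)
        (out / f"{name}_metrics.json").write_text(
            json.dumps(result["metrics"], indent=2, default=float))
        prov = {"preset": name, "seed": seed, "scale": scale,
                "overrides": overrides, "version": __version__,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
        (out / f"{name}_provenance.json").write_text(json.dumps(prov, indent=2))
    return result


def run_sweep(name: str, param: str, values, out_dir=None, seed: int = 0,
              scale: float = 0.25) -> pd.DataFrame:
    """One preset run per value of a scalar preset parameter.

    ``param`` must name a scalar keyword of the preset (e.g. ``drive`` or
    ``w``); each run's scalar metrics become one row of the returned
    table.
    """
    rows = []
    for v in values:
        try:
            res = run_preset(name, {param: v}, seed=seed, scale=scale)
        except TypeError as err:
            raise ValueError(f"{param!r} is not a scalar parameter of preset "
                             f"{name!r}: {err}") from err
        flat = {"param": param, "value": v}
        for k, m in res["metrics"].items():
            if np.isscalar(m):
                flat[k] = m
        rows.append(flat)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{name}_sweep_{param}.csv", index=False)
    return df
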