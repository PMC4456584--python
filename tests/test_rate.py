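import numpy as np
import pytest

from mcbalance.balance import network_balance_rates, single_point_balance
from mcbalance.rate import (ConvergenceError, CouplingMatrices, InputDrive,
                            PointParams, RateNetwork, RateState,
                            point_currents)
from mcbalance.transfer import TransferParams, naka_rushton


class TestCurrents:
    def test_zero_state_zero_drive(self, three_net):
        I_e, I_i = three_net.currents(RateState.zeros(3), np.zeros(3))
        assert np.all(I_e == 0) and np.all(I_i == 0)

    def test_single_external_term(self):
        p = PointParams(q_eo=1.0, q_ee=0, q_ei=0, q_ie=0, q_io=0, q_ii=0)
        net = RateNetwork(p, K=1)
        I_e, I_i = net.currents(RateState.zeros(1), [10.0])
        assert I_e[0] == pytest.approx(10.0)
        assert I_i[0] == 0.0

    def test_currents_cancel_at_balance_rates(self, single_net):
        """At the balance-approximation rates the net currents vanish."""
        g = single_point_balance(single_net.points[0])
        st = RateState([100 * g.A_e], [100 * g.A_i])
        I_e, I_i = single_net.currents(st, [100.0])
        assert I_e[0] == pytest.approx(0.0, abs=1e-9)
        assert I_i[0] == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention(self):
        """Inhibitory rates subtract; between-point input is excitatory."""
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        net = RateNetwork(PointParams(), CouplingMatrices(w, w.copy()))
        I_e, _ = net.currents(RateState([10.0, 20.0], [5.0, 0.0]), [0.0, 0.0])
        p = net.points[0]
        assert I_e[0] == pytest.approx(p.q_ee * 10 - p.q_ei * 5 + 0.5 * 20)

    def test_dimension_mismatch(self, three_net):
        with pytest.raises(ValueError):
            three_net.currents(RateState.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            point_currents(RateState.zeros(3), np.zeros(2), three_net.points,
                           three_net.W)


class TestIntegration:
    def test_zero_drive_stays_at_rest(self, single_net):
        traj = single_net.integrate(InputDrive.constant([0.0]), (0, 100))
        assert np.all(traj.r_e == 0) and np.all(traj.r_i == 0)

    def test_converges_to_steady_state(self, three_net):
        """Forward integration and the fixed-point solver agree."""
        drive = np.array([50.0, 120.0, 10.0])
        traj = three_net.integrate(InputDrive.constant(drive), (0, 1500))
        st = three_net.steady_state(drive)
        assert traj.r_e[-1] == pytest.approx(st.r_e, rel=1e-6, abs=1e-6)
        assert traj.r_i[-1] == pytest.approx(st.r_i, rel=1e-6, abs=1e-6)

    def test_initial_condition_independence(self, single_net):
        drive = InputDrive.constant([80.0])
        t1 = single_net.integrate(drive, (0, 1200))
        t2 = single_net.integrate(drive, (0, 1200),
                                  initial=RateState([200.0], [10.0]))
        assert t1.r_e[-1] == pytest.approx(t2.r_e[-1], abs=1e-6)

    def test_step_drive_transient(self, single_net):
        drive = InputDrive.step([100.0], t_on=50.0)
        traj = single_net.integrate(drive, (0, 400))
        before = traj.r_e[traj.t < 50]
        assert np.all(before == 0)
        assert traj.r_e[-1, 0] > 50

    def test_trajectory_dataframe(self, single_net):
        traj = single_net.integrate(InputDrive.constant([50.0]), (0, 10), dt=1.0)
        df = traj.to_dataframe()
        assert set(df.columns) == {"time_ms", "point", "population", "rate_spk_s"}
        assert len(df) == 2 * len(traj.t)
        assert np.all(df.rate_spk_s >= 0)


class TestSteadyState:
    def test_zero_drive(self, three_net):
        st = three_net.steady_state(np.zeros(3))
        assert np.all(st.r_e == 0) and np.all(st.r_i == 0)

    def test_single_point_near_balance_gains(self, single_net):
        """Nonlinear rates track the balance prediction within a few %."""
        st = single_net.steady_state([100.0])
        g = single_point_balance(single_net.points[0])
        assert st.r_e[0] == pytest.approx(100 * g.A_e, rel=0.07)
        assert st.r_i[0] == pytest.approx(100 * g.A_i, rel=0.10)

    def test_residual_is_tiny(self, three_net):
        st = three_net.steady_state([0.0, 150.0, 30.0])
        f_e, f_i = three_net.map_once(st.r_e, st.r_i, np.array([0.0, 150.0, 30.0]))
        assert np.max(np.abs(st.r_e - f_e)) < 1e-8
        assert np.max(np.abs(st.r_i - f_i)) < 1e-8

    def test_no_inhibition_saturates_near_max(self):
        """Without feedback inhibition a minimal input drives the point to a
        near-maximal rate: the positive root of r = f(r_o + q_ee r)."""
        net = RateNetwork(PointParams(q_ei=0.0, q_ii=0.0), K=1)
        st = net.steady_state([5.0])
        # closed-form oracle: r (I_half + r_o + q_ee r) = r_max (r_o + q_ee r)
        p = net.points[0]
        t = net.pop_e.transfer
        roots = np.roots([p.q_ee, t.I_half + 5.0 - t.r_max * p.q_ee,
                          -t.r_max * 5.0])
        expected = roots[roots > 0][0]
        assert st.r_e[0] == pytest.approx(expected, rel=1e-9)
        assert st.r_e[0] > 0.8 * t.r_max
        assert st.r_e[0] < t.r_max

    def test_rates_stay_below_ceiling(self, three_net):
        st = three_net.steady_state([300.0, 300.0, 300.0])
        assert np.all(st.r_e < three_net.pop_e.transfer.r_max)
        assert np.all(st.r_i < three_net.r_max_i_eff)

    def test_wrong_drive_shape(self, three_net):
        with pytest.raises(ValueError):
            three_net.steady_state([1.0, 2.0])


class TestIOCurve:
    def test_zero_grid(self, single_net):
        x, y = single_net.io_curve([np.array([0.0])])
        assert x[0] == 0.0 and y[0] == 0.0

    def test_open_loop_reduces_to_transfer_function(self):
        """With all recurrent weights zero the I/O curve is the f/I curve."""
        p = PointParams(q_eo=1.0, q_ee=0, q_ei=0, q_ie=0, q_io=1.0, q_ii=0)
        net = RateNetwork(p, K=1)
        grid = [np.array([v]) for v in (0.0, 25.0, 100.0, 300.0)]
        x, y = net.io_curve(grid)
        assert y == pytest.approx(naka_rushton(x, net.pop_e.transfer), rel=1e-9)

    def test_monotone_in_drive(self, single_net):
        _, y = single_net.io_curve([np.array([v]) for v in np.linspace(0, 300, 13)])
        assert np.all(np.diff(y) > 0)


class TestBalanceRegimeProperties:
    def test_balance_currents_small_at_scaled_weights(self, single_net):
        """At 4x weights the net currents are deep in the balanced regime:
        small against I_half at low rates (where the transfer inverse is
        near zero) and tiny against the individual synaptic currents at
        mid-range rates."""
        net = single_net.scaled(4.0)
        I_half = net.pop_e.transfer.I_half
        st = net.steady_state([25.0])
        I_e, I_i = net.currents(st, [25.0])
        assert abs(I_e[0]) < 0.2 * I_half
        assert abs(I_i[0]) < 0.2 * I_half
        st = net.steady_state([100.0])
        I_e, _ = net.currents(st, [100.0])
        p = net.points[0]
        inhibition = p.q_ei * st.r_i[0]       # one of the large components
        assert abs(I_e[0]) < 0.05 * inhibition

    def test_weight_scaling_improves_linearisation(self, single_net):
        """Scaling all weights leaves balance gains fixed and shrinks the
        gap between the nonlinear rates and the balance prediction."""
        g0 = single_point_balance(single_net.points[0])
        gaps = []
        for lam in (1.0, 2.0, 4.0):
            net = single_net.scaled(lam)
            g = single_point_balance(net.points[0])
            assert g.A_e == pytest.approx(g0.A_e)   # gains are scale-free
            st = net.steady_state([100.0])
            gaps.append(abs(st.r_e[0] - 100 * g0.A_e) / (100 * g0.A_e))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_mid_range_linearity(self, three_net):
        """Steady responses superpose within 5% for mid-range drives."""
        d1 = np.array([80.0, 0.0, 0.0])
        d2 = np.array([0.0, 60.0, 20.0])
        a, b = 0.6, 0.4
        r1 = three_net.steady_state(d1).r_e
        r2 = three_net.steady_state(d2).r_e
        r12 = three_net.steady_state(a * d1 + b * d2).r_e
        combo = a * r1 + b * r2
        err = np.max(np.abs(r12 - combo)) / np.max(np.abs(r12))
        assert err < 0.05

    def test_undriven_point_response_is_planar(self, three_net):
        """Point-3's response to joint drive of points 1 and 2 lies on the
        plane spanned by its single-input responses."""
        grid = np.linspace(0.0, 200.0, 5)
        pts = []
        for d1 in grid:
            for d2 in grid:
                st = three_net.steady_state([d1, d2, 0.0])
                pts.append((d1, d2, st.r_e[2]))
        pts = np.array(pts)
        A = np.c_[pts[:, 0], pts[:, 1], np.ones(len(pts))]
        coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
        resid = np.max(np.abs(pts[:, 2] - A @ coef))
        assert resid < 0.05 * np.max(pts[:, 2])


class TestValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            PointParams(q_ei=-1.7)

    def test_gain_out_of_range(self):
        with pytest.raises(ValueError):
            PointParams(G_i=1.5)

    def test_coupling_diagonal_must_be_zero(self):
        w = np.array([[0.1, 0.2], [0.2, 0.0]])
        with pytest.raises(ValueError):
            CouplingMatrices(w, np.zeros((2, 2)))

    def test_drive_negative_rejected(self):
        d = InputDrive.constant([5.0])
        d._fn = lambda t: np.array([-1.0])
        with pytest.raises(ValueError):
            d(0.0)
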