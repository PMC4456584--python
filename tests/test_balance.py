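import warnings

import numpy as np
import pytest

from mcbalance.balance import (finite_difference_jacobian, jacobian_at_balance,
                               linear_equivalent_trajectory, linear_fixed_point,
                               mi_gain, network_balance_rates,
                               single_point_balance, system_jacobian)
from mcbalance.rate import (CouplingMatrices, InputDrive, PointParams,
                            PopulationParams, RateNetwork)
from mcbalance.transfer import TransferParams


class TestSinglePointBalance:
    def test_no_external_weights(self):
        g = single_point_balance(PointParams(q_eo=0.0, q_io=0.0))
        assert g.A_e == 0.0 and g.A_i == 0.0

    def test_reference_gains(self, ref_point):
        """A_e = 0.3/0.36, A_i = 0.33/0.36 for the reference weights."""
        g = single_point_balance(ref_point)
        assert g.A_e == pytest.approx(0.3 / 0.36)
        assert g.A_i == pytest.approx(0.33 / 0.36)

    def test_scale_invariance(self, ref_point):
        g0 = single_point_balance(ref_point)
        g5 = single_point_balance(ref_point.scaled(5.0))
        assert g5.A_e == pytest.approx(g0.A_e) and g5.A_i == pytest.approx(g0.A_i)

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            single_point_balance(PointParams(q_ee=1.0, q_ii=1.0, q_ei=1.0, q_ie=1.0))

    def test_nonpositive_gain_warns(self):
        with pytest.warns(UserWarning):
            single_point_balance(PointParams(q_ee=0.1, q_ii=0.1, q_ei=1.0, q_ie=1.0))


class TestNetworkBalance:
    def test_zero_drive(self, three_net):
        r_e, r_i = network_balance_rates(three_net.points, three_net.W, np.zeros(3))
        assert np.all(r_e == 0) and np.all(r_i == 0)

    def test_three_point_linear_solve_oracle(self, three_net):
        """Matches an independently assembled 3x3 effective linear system."""
        drive = np.array([0.0, 300.0, 0.0])
        r_e, _ = network_balance_rates(three_net.points, three_net.W, drive)
        # oracle: build q_hat/w_hat by hand (ratio q_ei/q_ii = 0.85)
        q_hat_eo, q_hat_ee = 1 - 0.85, 0.67 - 0.85
        M = 0.15 * three_net.W.w_e.copy()
        np.fill_diagonal(M, q_hat_ee)
        expected = -q_hat_eo * np.linalg.solve(M, drive)
        assert r_e == pytest.approx(expected, rel=1e-12)
        assert r_e[2] == pytest.approx(44.91, abs=0.01)
        assert r_e[1] == pytest.approx(264.97, abs=0.01)

    def test_reduces_to_single_point(self, ref_point):
        W1 = CouplingMatrices(np.zeros((1, 1)), np.zeros((1, 1)))
        r_e, r_i = network_balance_rates([ref_point], W1, [100.0])
        g = single_point_balance(ref_point)
        assert r_e[0] == pytest.approx(100 * g.A_e)
        assert r_i[0] == pytest.approx(100 * g.A_i)

    def test_i_rates_satisfy_i_balance(self, three_net):
        drive = np.array([50.0, 100.0, 0.0])
        r_e, r_i = network_balance_rates(three_net.points, three_net.W, drive)
        p = three_net.points[0]
        lhs = p.q_ii * r_i
        rhs = p.q_io * drive + p.q_ie * r_e + three_net.W.w_i @ r_e
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestStability:
    def test_reference_point_is_stable(self, ref_point):
        rep = jacobian_at_balance(ref_point)
        assert rep.cond_cross        # 1.7 * 1 > 0.67 * 2
        assert rep.cond_auto         # gamma equal: 2 > 0.67
        assert rep.stable
        assert np.all(np.real(rep.eigenvalues) < 0)

    def test_no_inhibition_is_unstable(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = jacobian_at_balance(PointParams(q_ei=0.0, q_ii=0.0))
        assert not rep.stable
        assert not rep.cond_cross

    def test_pure_feedback_inhibition_is_stable(self):
        rep = jacobian_at_balance(PointParams(q_ee=0.0, q_ii=3.0))
        assert rep.stable

    def test_stable_iff_both_conditions(self):
        """The trace/determinant verdict coincides with the two inequalities."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            q = rng.uniform(0.1, 3.0, size=4)
            p = PointParams(q_ee=q[0], q_ei=q[1], q_ie=q[2], q_ii=q[3])
            rep = jacobian_at_balance(p)
            if not rep.marginal:
                assert rep.stable == (rep.cond_cross and rep.cond_auto)

    def test_analytic_jacobian_matches_finite_difference(self, three_net):
        """Eigenvalues of the analytic Jacobian at the numeric fixed point
        agree with a central-difference Jacobian to high precision."""
        drive = np.array([40.0, 120.0, 5.0])
        st = three_net.steady_state(drive)
        J = system_jacobian(three_net, st, drive)
        J_fd = finite_difference_jacobian(three_net, st, drive)
        ev = np.sort_complex(np.linalg.eigvals(J))
        ev_fd = np.sort_complex(np.linalg.eigvals(J_fd))
        assert np.max(np.abs(ev - ev_fd) / np.abs(ev)) < 1e-4


class TestLinearEquivalent:
    def test_zero_drive(self, ref_point):
        traj = linear_equivalent_trajectory([ref_point], None,
                                            InputDrive.constant([0.0]), (0, 100))
        assert np.all(traj.r_e == 0)

    def test_tracks_nonlinear_at_mid_drive(self, single_net):
        lf = linear_fixed_point(single_net.points, single_net.W, [100.0])
        st = single_net.steady_state([100.0])
        assert lf.r_e[0] == pytest.approx(st.r_e[0], rel=0.10)

    def test_exceeds_nonlinear_at_high_drive(self, single_net):
        """No ceiling in the linear system: it overshoots at high rates."""
        lf = linear_fixed_point(single_net.points, single_net.W, [400.0])
        st = single_net.steady_state([400.0])
        assert lf.r_e[0] > st.r_e[0]

    def test_trajectory_converges_to_linear_fixed_point(self, ref_point):
        traj = linear_equivalent_trajectory([ref_point], None,
                                            InputDrive.constant([100.0]), (0, 1000))
        lf = linear_fixed_point([ref_point], None, [100.0])
        assert traj.r_e[-1, 0] == pytest.approx(lf.r_e[0], rel=1e-6)


class TestMiGain:
    def test_monotone_in_disinhibition(self, ref_point):
        """Reducing the MI gain G strictly raises the response gain."""
        t300 = TransferParams(r_max=300.0)
        gains = [mi_gain(ref_point, transfer_i=t300, G=G).gain
                 for G in (1.0, 0.8, 0.6, 0.45, 0.3)]
        assert np.all(np.diff(gains) > 0)

    def test_limit_recovers_balance_gain(self, ref_point):
        """alpha -> 0 (huge ceilings) recovers the balance gain A_e."""
        huge = TransferParams(r_max=1e9)
        g = mi_gain(ref_point, transfer_e=huge, transfer_i=huge, G=1.0)
        assert g.gain == pytest.approx(single_point_balance(ref_point).A_e, rel=1e-6)

    def test_reference_value(self, ref_point):
        """Hand arithmetic: [1*(2.1) - 1.7] / [1.7 - 0.57*2.1] = 0.795."""
        g = mi_gain(ref_point, G=1.0)
        assert g.alpha_e == pytest.approx(0.1)
        assert g.alpha_i == pytest.approx(0.1)
        assert g.gain == pytest.approx(0.4 / 0.503, rel=1e-9)

    def test_gain_predicts_io_slope(self, single_net):
        """The closed form matches the numerical steady-state slope at
        mid-range drives."""
        g = mi_gain(single_net.points[0], G=1.0).gain
        r1 = single_net.steady_state([90.0]).r_e[0]
        r2 = single_net.steady_state([110.0]).r_e[0]
        slope = (r2 - r1) / 20.0
        assert slope == pytest.approx(g, rel=0.05)

    def test_invalid_G(self, ref_point):
        with pytest.raises(ValueError):
            mi_gain(ref_point, G=0.0)

    def test_lost_balance_raises(self):
        p = PointParams(q_ee=3.0, q_ei=0.1, q_ie=0.1, q_ii=2.0)
        with pytest.raises(ValueError):
            mi_gain(p, G=1.0)
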