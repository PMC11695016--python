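"""Continuous-time physics: closed-form and independent numerical oracles."""
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gaitopt import _jet as J
from gaitopt import dynamics as dyn
from gaitopt.model import MuscleTendonParams, PassiveMomentParams


@pytest.fixture(scope="module")
def params():
    return MuscleTendonParams(f_max_iso=1500.0, l_opt=0.10, l_ts=0.13,
                              alpha_opt=math.radians(8.0), v_max=10.0)


# ---------------------------------------------------------------------------
# muscle geometry
# ---------------------------------------------------------------------------

class TestMuscleGeometry:
    def test_zero_velocity_gives_zero_mt_velocity(self, healthy_model):
        m = healthy_model.muscles[0]
        q = {j: 0.3 for j in m.spanned_joints}
        qd = {j: 0.0 for j in m.spanned_joints}
        _, v_mt, _ = dyn.muscle_geometry(q, qd, m)
        assert v_mt == pytest.approx(0.0, abs=1e-15)

    def test_constant_arm_linear_length_change(self, healthy_model):
        m = next(mm for mm in healthy_model.muscles
                 if mm.name.startswith("vasti"))
        (r0, r1), = m.arms.values()
        assert r1 == 0.0
        j = m.spanned_joints[0]
        l0, _, _ = dyn.muscle_geometry({j: 0.0}, {j: 0.0}, m)
        l1, _, _ = dyn.muscle_geometry({j: 0.5}, {j: 0.0}, m)
        assert l1 - l0 == pytest.approx(-r0 * 0.5, abs=1e-14)

    def test_velocity_is_negative_arm_weighted_rates(self, healthy_model):
        rng = np.random.default_rng(1)
        m = next(mm for mm in healthy_model.muscles
                 if len(mm.spanned_joints) == 2)
        q = {j: rng.uniform(-0.4, 0.6) for j in m.spanned_joints}
        qd = {j: rng.normal() for j in m.spanned_joints}
        _, v_mt, arms = dyn.muscle_geometry(q, qd, m)
        expected = -sum(arms[j] * qd[j] for j in m.spanned_joints)
        assert v_mt == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# Hill muscle-tendon equilibrium
# ---------------------------------------------------------------------------

class TestHillEquilibrium:
    def test_slack_passive_free_equilibrium_is_exact_zero(self, params):
        l_mt = params.l_opt * math.cos(params.alpha_opt) + params.l_ts
        r = dyn.hill_equilibrium_residual(0.0, 0.0, 0.0, l_mt, 0.0, params)
        assert float(J.value(r)) == pytest.approx(0.0, abs=1e-14)

    def test_isometric_maximum_force(self, params):
        ca = math.cos(params.alpha_opt)
        lt_n = float(J.value(dyn.tendon_length_from_force(ca)))
        l_mt = params.l_opt * ca + params.l_ts * lt_n
        r = dyn.hill_equilibrium_residual(1.0, ca, 0.0, l_mt, 0.0, params)
        assert float(J.value(r)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("a,l_scale", [(0.2, 1.00), (0.5, 1.02),
                                           (0.9, 0.98), (1.0, 1.04)])
    def test_bisection_oracle_zeroes_residual(self, params, a, l_scale):
        l_mt = (params.l_opt * math.cos(params.alpha_opt)
                + params.l_ts) * l_scale
        ft = dyn.solve_equilibrium_f_tilde(a, l_mt, params)
        r = dyn.hill_equilibrium_residual(a, ft, 0.0, l_mt, 0.0, params)
        assert abs(float(J.value(r))) < 1e-10

    def test_equilibrium_unique_in_bracket(self, params):
        """The residual is strictly decreasing in f_tilde, so the bracket
        [0, 3] contains exactly one root."""
        l_mt = params.l_opt * math.cos(params.alpha_opt) + params.l_ts
        ft = np.linspace(0.0, 3.0, 400)
        r = dyn.hill_equilibrium_residual(0.6, ft, 0.0,
                                          np.full_like(ft, l_mt),
                                          np.zeros_like(ft), params)
        assert np.all(np.diff(r) < 0.0)
        assert np.sum(np.diff(np.sign(r)) != 0) == 1


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------

class TestActivationDynamics:
    def test_equilibrium_rate_is_zero(self):
        assert float(J.value(dyn.activation_dynamics_residual(
            0.4, 0.4, 0.0))) == pytest.approx(0.0, abs=1e-12)

    def test_full_excitation_step_rate(self):
        # residual = 0 defines adot = (1 - 0) / tau_act
        r = dyn.activation_dynamics_residual(1.0, 0.0, 1.0 / dyn.TAU_ACT)
        assert float(J.value(r)) == pytest.approx(0.0, abs=1e-10)

    def test_step_response_matches_closed_form(self):
        # the closed form holds while the rate blend is saturated on the
        # activation side (e - a well above the blend width)
        sol = solve_ivp(
            lambda t, a: [(1.0 - a[0]) * float(J.value(
                dyn.activation_rate(1.0, a[0])))],
            (0.0, 0.02), [0.0], rtol=1e-10, atol=1e-12, dense_output=True)
        t = np.linspace(0.0, 0.02, 20)
        expected = 1.0 - np.exp(-t / dyn.TAU_ACT)
        assert np.allclose(sol.sol(t)[0], expected, atol=1e-6)

    def test_mpk_first_order_lag_closed_form(self):
        tau = 0.03
        sol = solve_ivp(lambda t, a: [(1.0 - a[0]) / tau], (0.0, 0.1), [0.0],
                        rtol=1e-12, atol=1e-14, dense_output=True)
        t = np.linspace(0.0, 0.1, 11)
        assert np.allclose(sol.sol(t)[0], 1.0 - np.exp(-t / tau), atol=1e-8)
        # residual form agrees
        r = dyn.mpk_activation_residual(1.0, 0.25, (1.0 - 0.25) / tau, tau)
        assert float(J.value(r)) == pytest.approx(0.0, abs=1e-14)

    def test_infinite_time_constant_freezes_activation(self):
        r = dyn.mpk_activation_residual(1.0, 0.2, 0.0, 1e12)
        assert abs(float(J.value(r))) < 1e-12


# ---------------------------------------------------------------------------
# passive joint moments & MPK damper
# ---------------------------------------------------------------------------

class TestPassiveMoment:
    P = PassiveMomentParams(k1=2.0, k2=5.0, q_lower=-0.3, q_upper=1.0, b=0.1)

    def test_negligible_inside_range(self):
        mid = 0.5 * (self.P.q_lower + self.P.q_upper)
        m = float(J.value(dyn.passive_joint_moment(mid, 0.0, self.P)))
        assert abs(m) < 0.01

    def test_resists_and_stiffens_beyond_upper_limit(self):
        d10 = math.radians(10.0)
        d5 = math.radians(5.0)
        m10 = float(J.value(dyn.passive_joint_moment(
            self.P.q_upper + d10, 0.0, self.P)))
        m5 = float(J.value(dyn.passive_joint_moment(
            self.P.q_upper + d5, 0.0, self.P)))
        assert m10 < 0 and m5 < 0
        assert abs(m10) > abs(m5)

    def test_pure_damping_midrange(self):
        p = PassiveMomentParams(k1=0.0, k2=5.0, q_lower=-1.0, q_upper=1.0,
                                b=0.7)
        m = float(J.value(dyn.passive_joint_moment(0.0, 1.0, p)))
        assert m == pytest.approx(-0.7, abs=1e-12)


class TestMPKDamper:
    @pytest.mark.parametrize("a,d,qd,expected", [
        (1.0, 1.0, 1.0, 1.0),
        (0.5, 0.75, -2.0, -0.75),
        (0.0, 1.0, 5.0, 0.0),
    ])
    def test_bilinear_law(self, a, d, qd, expected):
        assert float(J.value(dyn.mpk_damper_moment(a, d, qd))) \
            == pytest.approx(expected, abs=1e-14)

    def test_dissipative_for_any_state(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 100)
        qd = rng.normal(0, 5, 100)
        t = dyn.mpk_damper_moment(a, 0.75, qd)
        assert np.all(t * qd >= 0.0)


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------

class TestHuntCrossley:
    def test_airborne_sphere_produces_negligible_force(self, amputee_model):
        c = amputee_model.contacts[0]
        fx, fy = dyn.hunt_crossley_force((0.0, c.radius + 0.05), (0.0, 0.0), c)
        assert abs(float(J.value(fy))) < 1e-6
        assert abs(float(J.value(fx))) < 1e-6

    def test_static_normal_force_formula(self, amputee_model):
        c = amputee_model.contacts[0]
        delta = 0.01
        _, fy = dyn.hunt_crossley_force((0.0, c.radius - delta), (0.0, 0.0), c)
        assert float(J.value(fy)) == pytest.approx(
            c.stiffness * delta ** 1.5, rel=1e-3)

    def test_rapid_separation_never_adheres(self, amputee_model):
        c = amputee_model.contacts[0]
        for vy in (0.5, 2.0, 10.0):
            _, fy = dyn.hunt_crossley_force((0.0, c.radius - 0.01),
                                            (0.0, vy), c)
            assert float(J.value(fy)) >= 0.0

    def test_normal_force_nondecreasing_in_penetration(self, amputee_model):
        c = amputee_model.contacts[0]
        depths = np.linspace(-0.01, 0.03, 200)
        fy = [float(J.value(dyn.hunt_crossley_force(
            (0.0, c.radius - d), (0.0, 0.0), c)[1])) for d in depths]
        assert np.all(np.diff(fy) >= 0.0)


# ---------------------------------------------------------------------------
# metabolic rate
# ---------------------------------------------------------------------------

class TestMetabolicRate:
    MP = dyn.MetabolicModelParams()

    def test_rest_rate_small_and_nonnegative(self, params):
        e = dyn.metabolic_rate(0.0, 0.0, 1.0, 0.0, params, self.MP)
        basal_floor = self.MP.basal_rate * dyn.muscle_mass(params, self.MP)
        assert 0.0 <= float(J.value(e)) <= max(basal_floor, 1.0)

    def test_strictly_increasing_in_activation(self, params):
        a = np.linspace(0.0, 1.0, 50)
        e = dyn.metabolic_rate(a, 0.3, 1.0, -0.2, params, self.MP)
        assert np.all(np.diff(J.value(e)) > 0.0)

    def test_smoothing_negligible_away_from_switches(self, params):
        for v in (-0.5, 0.4):
            smooth = float(J.value(dyn.metabolic_rate(
                0.6, 0.5, 1.0, v, params, self.MP, smooth=True)))
            raw = float(J.value(dyn.metabolic_rate(
                0.6, 0.5, 1.0, v, params, self.MP, smooth=False)))
            assert smooth == pytest.approx(raw, rel=0.01)


# ---------------------------------------------------------------------------
# skeletal dynamics
# ---------------------------------------------------------------------------

def _pendulum_oracle_torques(model, q):
    """Independent gravity-compensation torques for the hanging IL leg,
    computed from first principles (sum of m*g*horizontal-lever)."""
    th = model.segments["thigh_il"]
    sh = model.segments["shank_il"]
    ft = model.segments["foot_il"]
    g = model.gravity
    th_t = q[3]
    th_s = q[3] - q[4]
    hip = np.zeros(2)
    knee = hip + th.length * np.array([math.sin(th_t), -math.cos(th_t)])
    ankle = knee + sh.length * np.array([math.sin(th_s), -math.cos(th_s)])
    com_t = hip + th.com_offset * np.array([math.sin(th_t), -math.cos(th_t)])
    com_s = knee + sh.com_offset * np.array([math.sin(th_s), -math.cos(th_s)])
    com_f = ankle + ft.com_offset * np.array([math.cos(th_s), math.sin(th_s)])
    lever = lambda c, p, m: m * g * (p[0] - c[0])
    tau_hip = (lever(hip, com_t, th.mass) + lever(hip, com_s, sh.mass)
               + lever(hip, com_f, ft.mass))
    tau_knee = -(lever(knee, com_s, sh.mass) + lever(knee, com_f, ft.mass))
    return tau_hip, tau_knee


class TestSkeletalDynamics:
    def test_static_gravity_compensation_matches_pendulum_oracle(
            self, healthy_model):
        q = np.zeros(9)
        q[3], q[4] = 0.4, 0.7
        tau_hip, tau_knee = _pendulum_oracle_torques(healthy_model, q)
        moments = [0.0] * 9
        moments[3], moments[4] = tau_hip, tau_knee
        # balance the pelvis coordinates so the whole residual vanishes
        total_w = healthy_model.total_segment_mass() * healthy_model.gravity
        res = dyn.skeletal_dynamics_residual(
            list(q), [0.0] * 9, [0.0] * 9, moments, {}, healthy_model)
        vals = np.array([float(J.value(r)) for r in res])
        assert abs(vals[3]) < 1e-9
        assert abs(vals[4]) < 1e-9
        assert vals[1] == pytest.approx(total_w, rel=1e-12)

    def test_zero_gravity_static_residual_vanishes(self, healthy_model):
        import copy
        m = copy.deepcopy(healthy_model)
        m.gravity = 0.0
        res = dyn.skeletal_dynamics_residual(
            [0.1] * 9, [0.0] * 9, [0.0] * 9, [0.0] * 9, {}, m)
        assert max(abs(float(J.value(r))) for r in res) < 1e-12

    def test_dimension_mismatch_raises(self, healthy_model):
        with pytest.raises(ValueError):
            dyn.skeletal_dynamics_residual([0.0] * 5, [0.0] * 9, [0.0] * 9,
                                           [0.0] * 9, {}, healthy_model)

    def test_passive_double_pendulum_conserves_energy(self, healthy_model):
        """Forward-integrate the unactuated linkage (pelvis pinned via large
        accel solve on leg coordinates only) and check energy drift."""
        model = healthy_model
        skel = dyn.PlanarSkeleton(model)
        free = [3, 4]                      # IL hip and knee swing freely

        def accel(q34, qd34):
            q = np.zeros(9)
            qd = np.zeros(9)
            q[3], q[4] = q34
            qd[3], qd[4] = qd34
            base = np.array([float(J.value(v)) for v in
                             skel.inverse_dynamics(list(q), list(qd),
                                                   [0.0] * 9)])
            cols = []
            for i in free:
                qdd = np.zeros(9)
                qdd[i] = 1.0
                col = np.array([float(J.value(v)) for v in
                                skel.inverse_dynamics(list(q), list(qd),
                                                      list(qdd))])
                cols.append(col[free] - base[free])
            M = np.array(cols).T
            return np.linalg.solve(M, -base[free])

        def rhs(t, y):
            qdd = accel(y[:2], y[2:])
            return np.concatenate([y[2:], qdd])

        def energy(y):
            q = np.zeros(9)
            qd = np.zeros(9)
            q[3], q[4] = y[:2]
            qd[3], qd[4] = y[2:]
            th = model.segments["thigh_il"]
            sh = model.segments["shank_il"]
            ft = model.segments["foot_il"]
            th_t, th_s = q[3], q[3] - q[4]
            w_t = qd[3]
            w_s = qd[3] - qd[4]
            hip = np.zeros(2)
            knee = hip + th.length * np.array([math.sin(th_t),
                                               -math.cos(th_t)])
            ke = pe = 0.0
            for seg, org, ang, w in ((th, hip, th_t, w_t),
                                     (sh, knee, th_s, w_s)):
                com = org + seg.com_offset * np.array([math.sin(ang),
                                                       -math.cos(ang)])
                vel_org = (np.zeros(2) if seg is th else
                           th.length * w_t * np.array([math.cos(th_t),
                                                       math.sin(th_t)]))
                vel = vel_org + seg.com_offset * w * np.array(
                    [math.cos(ang), math.sin(ang)])
                ke += 0.5 * seg.mass * vel @ vel + 0.5 * seg.inertia_zz * w**2
                pe += seg.mass * model.gravity * com[1]
            # foot: treat as point mass at its COM for this oracle
            ankle = knee + sh.length * np.array([math.sin(th_s),
                                                 -math.cos(th_s)])
            com_f = ankle + ft.com_offset * np.array([math.cos(th_s),
                                                      math.sin(th_s)])
            v_ank = (th.length * w_t * np.array([math.cos(th_t),
                                                 math.sin(th_t)])
                     + sh.length * w_s * np.array([math.cos(th_s),
                                                   math.sin(th_s)]))
            v_f = v_ank + ft.com_offset * w_s * np.array(
                [-math.sin(th_s), math.cos(th_s)])
            ke += 0.5 * ft.mass * v_f @ v_f + 0.5 * ft.inertia_zz * w_s ** 2
            pe += ft.mass * model.gravity * com_f[1]
            return ke + pe

        y0 = np.array([0.6, 0.2, 0.0, 0.0])
        sol = solve_ivp(rhs, (0.0, 1.0), y0, rtol=1e-11, atol=1e-12)
        drift = abs(energy(sol.y[:, -1]) - energy(y0))
        assert drift < 1e-6


def test_residuals_are_c1_smooth(amputee_model):
    """Finite-difference gradients of the assembled path residuals agree with
    the analytic (AD) gradients at random states."""
    gd = dyn.GaitDynamics(amputee_model)
    rng = np.random.default_rng(7)
    n_pts = 100
    nm = gd.n_mus
    q = rng.normal(0.0, 0.3, (n_pts, 9))
    q[:, 1] += 0.95
    qd = rng.normal(0.0, 1.0, (n_pts, 9))
    qdd = rng.normal(0.0, 10.0, (n_pts, 9))
    a = rng.uniform(0.05, 0.95, (n_pts, nm))
    ft = rng.uniform(0.01, 1.2, (n_pts, nm))
    dft = rng.normal(0.0, 5.0, (n_pts, nm))
    ampk = rng.uniform(0.0, 1.0, n_pts)

    cols = ([q[:, i] for i in range(9)] + [qd[:, i] for i in range(9)]
            + [qdd[:, i] for i in range(9)]
            + [a[:, i] for i in range(nm)] + [ft[:, i] for i in range(nm)]
            + [dft[:, i] for i in range(nm)] + [ampk])
    jets = J.seed(*cols)

    def evaluate(v):
        qq = v[0:9]
        qqd = v[9:18]
        qqdd = v[18:27]
        aa = v[27:27 + nm]
        fft = v[27 + nm:27 + 2 * nm]
        ddft = v[27 + 2 * nm:27 + 3 * nm]
        am = v[-1]
        return (gd.eom_residuals(qq, qqd, qqdd, fft, am)
                + gd.hill_residuals(qq, qqd, aa, fft, ddft))

    outs = evaluate(jets)
    vals0 = np.array([np.broadcast_to(J.value(o), (n_pts,)) for o in outs])
    eps = 1e-6
    rng2 = np.random.default_rng(8)
    direction = rng2.normal(size=len(cols))
    direction /= np.abs(direction).max()
    up = [c + eps * direction[i] for i, c in enumerate(cols)]
    dn = [c - eps * direction[i] for i, c in enumerate(cols)]
    vals_up = np.array([np.broadcast_to(J.value(o), (n_pts,))
                        for o in evaluate(up)])
    vals_dn = np.array([np.broadcast_to(J.value(o), (n_pts,))
                        for o in evaluate(dn)])
    fd = (vals_up - vals_dn) / (2.0 * eps)
    ad = np.array([np.broadcast_to(J.grad(o), (n_pts, len(cols)))
                   @ direction for o in outs])
    scale = np.maximum(np.abs(fd), 1.0)
    assert np.max(np.abs(ad - fd) / scale) < 1e-5
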