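"""Continuous-time physics of the planar gait model.

Everything evaluated inside the optimal-control problems lives here: Hill
muscle-tendon equilibrium in implicit (tendon-force-state) form, activation
dynamics, exponential passive joint moments, Hunt-Crossley foot-ground
contact, the prosthetic-knee damper and its first-order activation lag, a
smooth muscle metabolic-rate model, and the skeletal equations of motion of
the bilateral planar linkage expressed as an implicit residual.

All functions are C1-smooth and accept either plain numpy arrays or
:class:`gaitopt._jet.Jet` forward-AD values, so the collocation layer obtains
exact constraint Jacobians by seeding jets.

Sign conventions: hip flexion, knee flexion and ankle dorsiflexion positive;
x forward, y up; gravity acts along -y; the ground is the plane y = 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _jet as J
from ._jet import cos, exp, log, sigmoid, sin, softplus, sqrt, tanh
from .model import (ContactSphereSpec, ModelSpec, MuscleSpec,
                    MuscleTendonParams, PassiveMomentParams)

COORDS = ("pelvis_tx", "pelvis_ty", "pelvis_tilt",
          "hip_il", "knee_il", "ankle_il",
          "hip_cl", "knee_cl", "ankle_cl")

# --- Hill-type curve constants (smooth closed forms) -----------------------
_KT = 35.0                 # tendon exponential shape
_E0T = 0.049               # tendon strain at maximal isometric force
_C1T = 1.0 / (math.exp(_KT * _E0T) - 1.0)
_GAMMA_FL = 0.45           # active force-length gaussian width
_KP_PAS = 4.0              # passive force-length exponential shape
_E0_PAS = 0.6              # passive strain scale
_KV = 6.0                  # force-velocity logistic steepness
_FV_ECC = 1.4              # eccentric plateau
_BETA_DAMP = 0.01          # normalized fiber damping (regularizes inversion)

TAU_ACT = 0.015            # s, activation time constant
TAU_DEACT = 0.060          # s, deactivation time constant

_PEN_EPS = 1e-4            # m, contact penetration smoothing scale
_CLAMP_BETA = 0.1          # Hunt-Crossley dissipation-bracket smooth clamp


# ---------------------------------------------------------------------------
# muscle geometry
# ---------------------------------------------------------------------------

def muscle_geometry(q: dict, qdot: dict, muscle: MuscleSpec):
    """Musculotendon length, velocity and moment arms at a pose.

    ``q``/``qdot`` map joint names to angles (rad) and rates (rad/s).  Moment
    arm about joint j is r_j(q_j) = r0 + r1*q_j and the length polynomial is
    built so r_j = -d(l_mt)/d(q_j) exactly; v_mt = -sum_j r_j * qdot_j.
    """
    l_mt = muscle.l_ref
    v_mt = 0.0
    arms = {}
    for jname, (r0, r1) in muscle.arms.items():
        qj = q[jname]
        rj = r0 + r1 * qj
        arms[jname] = rj
        l_mt = l_mt - (r0 * qj + 0.5 * r1 * qj * qj)
        if qdot is not None:
            v_mt = v_mt - rj * qdot[jname]
    return l_mt, v_mt, arms


# ---------------------------------------------------------------------------
# Hill muscle-tendon model, implicit formulation
# ---------------------------------------------------------------------------

def tendon_force_length(lt_norm):
    """Normalized tendon force from normalized tendon length (zero at slack)."""
    return _C1T * (exp(_KT * (lt_norm - 1.0)) - 1.0)


def tendon_length_from_force(f_tilde):
    """Inverse tendon curve; defined for f_tilde > -c1 (slack regime smooth)."""
    return 1.0 + log(f_tilde / _C1T + 1.0) / _KT


def active_force_length(l_norm):
    return exp(-((l_norm - 1.0) / _GAMMA_FL) ** 2)


def passive_force_length(l_norm):
    return (exp(_KP_PAS * (l_norm - 1.0) / _E0_PAS) - 1.0) / (math.exp(_KP_PAS) - 1.0)


def force_velocity(v_norm):
    """Smooth Hill-type force-velocity: 1 at isometric, ~0 at -v_max,
    eccentric plateau 1.4."""
    return _FV_ECC / (1.0 + (_FV_ECC - 1.0) * exp(-_KV * v_norm))


def fiber_state(f_tilde, l_mt, p: MuscleTendonParams):
    """Fiber length, cosine of pennation and normalized fiber length implied
    by the tendon-force state (constant-width pennation model)."""
    lt = p.l_ts * tendon_length_from_force(f_tilde)
    w = p.l_opt * math.sin(p.alpha_opt)
    proj = l_mt - lt
    lf = sqrt(proj * proj + w * w)
    cos_a = proj / lf
    return lf, cos_a, lf / p.l_opt


def fiber_velocity(f_tilde, f_tilde_dot, l_mt, v_mt, p: MuscleTendonParams):
    """Fiber lengthening rate (m/s) implied by the implicit tendon dynamics."""
    lt_dot = p.l_ts * f_tilde_dot / (_KT * (f_tilde + _C1T))
    _, cos_a, _ = fiber_state(f_tilde, l_mt, p)
    return cos_a * (v_mt - lt_dot)


def hill_equilibrium_residual(a, f_tilde, f_tilde_dot, l_mt, v_mt,
                              p: MuscleTendonParams):
    """Dimensionless fiber/tendon force balance; zero defines feasible
    f_tilde_dot given the states.  Formulated with normalized tendon force as
    the muscle state, so the tendon-length rate enters through f_tilde_dot."""
    lf, cos_a, l_norm = fiber_state(f_tilde, l_mt, p)
    lt_dot = p.l_ts * f_tilde_dot / (_KT * (f_tilde + _C1T))
    vf = cos_a * (v_mt - lt_dot)
    v_norm = vf / (p.v_max * p.l_opt)
    f_fiber = (a * active_force_length(l_norm) * force_velocity(v_norm)
               + passive_force_length(l_norm) + _BETA_DAMP * v_norm)
    return f_fiber * cos_a - f_tilde


def equilibrium_f_tilde(a, l_mt, p: MuscleTendonParams, v_mt=0.0,
                        iters: int = 90):
    """Static equilibrium tendon force by vectorized bisection
    (f_tilde_dot = 0).  The Hill residual is strictly decreasing in f_tilde
    at fixed inputs, so a single bracket [0, 3] suffices.  Used to seed
    muscle states; the collocated problems use the implicit residual instead.
    """
    a = np.asarray(a, dtype=float)
    l_mt = np.asarray(l_mt, dtype=float)
    a, l_mt, v_mt = np.broadcast_arrays(a, l_mt, np.asarray(v_mt, dtype=float))
    lo = np.zeros_like(a)
    hi = np.full_like(a, 3.0)
    flo = hill_equilibrium_residual(a, lo, 0.0, l_mt, v_mt, p)
    fhi = hill_equilibrium_residual(a, hi, 0.0, l_mt, v_mt, p)
    if np.any(fhi > 0):  # pragma: no cover - pathological parameters
        raise ValueError("no equilibrium bracket for f_tilde in [0, 3]")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = hill_equilibrium_residual(a, mid, 0.0, l_mt, v_mt, p)
        lo = np.where(fm > 0, mid, lo)
        hi = np.where(fm > 0, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(flo <= 0, 0.0, out)


def solve_equilibrium_f_tilde(a: float, l_mt: float, p: MuscleTendonParams,
                              v_mt: float = 0.0) -> float:
    return float(equilibrium_f_tilde(a, l_mt, p, v_mt))


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------

def activation_rate(e, a, tau_act: float = TAU_ACT, tau_deact: float = TAU_DEACT,
                    steepness: float = 100.0):
    """Smoothly blended activation/deactivation rate constant (1/s)."""
    s = sigmoid(steepness * (e - a))
    return 1.0 / tau_deact + (1.0 / tau_act - 1.0 / tau_deact) * s


def activation_dynamics_residual(e, a, adot, tau_act: float = TAU_ACT,
                                 tau_deact: float = TAU_DEACT):
    """First-order excitation-to-activation dynamics residual (1/s)."""
    return adot - (e - a) * activation_rate(e, a, tau_act, tau_deact)


def mpk_activation_residual(e_mpk, a_mpk, a_mpk_dot, tau_mpk: float):
    """Prosthetic-knee activation: plain first-order lag."""
    return a_mpk_dot - (e_mpk - a_mpk) / tau_mpk


def mpk_damper_moment(a_mpk, d_mpk, qdot):
    """Resistive damper moment magnitude T = a * D * qdot (N m).

    Signed like the knee rate, so T*qdot >= 0; the equations of motion apply
    it with a minus sign (it always opposes knee motion).
    """
    return a_mpk * d_mpk * qdot


# ---------------------------------------------------------------------------
# passive joint moments
# ---------------------------------------------------------------------------

def passive_joint_moment(q, qdot, p: PassiveMomentParams):
    """Double-exponential joint-limit moment + damping + linear spring (N m)."""
    m = p.k1 * exp(-p.k2 * (q - p.q_lower)) - p.k1 * exp(p.k2 * (q - p.q_upper))
    return m - p.b * qdot - p.k_lin * q


# ---------------------------------------------------------------------------
# foot-ground contact
# ---------------------------------------------------------------------------

def hunt_crossley_force(pos, vel, c: ContactSphereSpec):
    """World-frame (fx, fy) on a sphere centered at ``pos`` moving at ``vel``.

    Penetration is smoothed with a softplus of scale 1e-4 m; the
    Hunt-Crossley dissipation bracket is smoothly clamped nonnegative so
    rapid separation never produces adhesion.  Tangential force is smoothed
    Coulomb friction against the ground plane y = 0.
    """
    x, y = pos
    vx, vy = vel
    arg = (c.radius - y) / _PEN_EPS
    delta = _PEN_EPS * softplus(arg)
    ddot = -vy * sigmoid(arg)
    bracket = 1.0 + 1.5 * c.dissipation * ddot
    clamped = _CLAMP_BETA * softplus(bracket / _CLAMP_BETA)
    fn = c.stiffness * delta ** 1.5 * clamped
    ft = -fn * c.mu * tanh(vx / c.v_t)
    return ft, fn


# ---------------------------------------------------------------------------
# metabolic rate
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModelParams:
    basal_rate: float = 1.2       # W/kg whole-body basal
    sigma: float = 2.5e5          # Pa, muscle specific tension (mass estimate)
    rho: float = 1059.7           # kg/m^3 muscle density
    h_act: float = 40.0           # W/kg activation+maintenance heat scale
    h_short: float = 100.0        # W/kg shortening heat scale
    smoothing: float = 0.1        # W, softplus scale for positive-part terms

    def __post_init__(self):
        if self.basal_rate < 0 or self.smoothing <= 0:
            raise ValueError("basal_rate >= 0 and smoothing > 0 required")


def muscle_mass(p: MuscleTendonParams, mp: MetabolicModelParams) -> float:
    return p.f_max_iso / mp.sigma * mp.rho * p.l_opt


def metabolic_rate(a, f_tilde, l_norm, v_norm, p: MuscleTendonParams,
                   mp: MetabolicModelParams, smooth: bool = True):
    """Smooth nonnegative per-muscle metabolic power (W).

    Activation/maintenance heat scales with activation, shortening heat with
    activation times smoothed shortening speed, and positive mechanical fiber
    work is added; all positive parts use a softplus of scale ``smoothing``.
    The whole-body basal term is added separately by the caller.
    """
    m = muscle_mass(p, mp)
    vf = v_norm * p.v_max * p.l_opt          # m/s, fiber lengthening rate
    power = f_tilde * p.f_max_iso * (-vf)    # W, positive when shortening
    if smooth:
        s = mp.smoothing
        shortening = s * softplus(-v_norm / s)
        work = s * softplus(power / s)
    else:
        shortening = np.maximum(0.0, -v_norm)
        work = np.maximum(0.0, power)
    heat = m * (mp.h_act * a + mp.h_short * a * shortening)
    return heat + work


# ---------------------------------------------------------------------------
# planar skeleton: kinematics and implicit equations of motion
# ---------------------------------------------------------------------------

def _perp(px, py):
    return -py, px


class PlanarSkeleton:
    """Bilateral planar linkage (HAT + 2 x thigh/shank/foot).

    Generalized coordinates (order :data:`COORDS`): pelvis translation x, y
    (position of the shared hip center), HAT tilt (forward lean positive),
    then hip/knee/ankle flexion per side.  The equations of motion are
    evaluated as a generalized inverse-dynamics residual via virtual work,
    which is exact for this tree and cheap to differentiate.
    """

    _LEGS = {"il": (3, 4, 5), "cl": (6, 7, 8)}

    def __init__(self, model: ModelSpec):
        self.model = model
        self.g = model.gravity
        s = model.segments
        self.hat = s["hat"]
        self.legs = {side: (s[f"thigh_{side}"], s[f"shank_{side}"], s[f"foot_{side}"])
                     for side in ("il", "cl")}

    # -- kinematics ---------------------------------------------------
    def leg_points(self, q, side):
        """Hip, knee, ankle positions and absolute segment angles of a leg."""
        i_h, i_k, i_a = self._LEGS[side]
        thigh, shank, foot = self.legs[side]
        hip = (q[0], q[1])
        th_t = q[2] + q[i_h]                 # thigh absolute angle
        th_s = th_t - q[i_k]                 # shank absolute angle
        th_f = th_s + q[i_a]                 # foot forward-axis angle
        knee = (hip[0] + thigh.length * sin(th_t),
                hip[1] - thigh.length * cos(th_t))
        ankle = (knee[0] + shank.length * sin(th_s),
                 knee[1] - shank.length * cos(th_s))
        return hip, knee, ankle, th_t, th_s, th_f

    def contact_sphere_center(self, q, sphere: ContactSphereSpec):
        side = sphere.segment.split("_")[1]
        _, _, ankle, _, _, th_f = self.leg_points(q, side)
        cx, cy = cos(th_f), sin(th_f)
        lx, ly = sphere.location
        return (ankle[0] + lx * cx - ly * cy,
                ankle[1] + lx * cy + ly * cx)

    def _body_kinematics(self, q, qdot, qddot):
        """Per-segment COM position/acceleration, angle data and the joint
        centers needed for virtual-work rows."""
        px, py, tilt = q[0], q[1], q[2]
        vx, vy, tiltd = qdot[0], qdot[1], qdot[2]
        ax, ay, tiltdd = qddot[0], qddot[1], qddot[2]
        hip = (px, py)
        hip_v = (vx, vy)
        hip_a = (ax, ay)

        bodies = []   # (segment, com, com_acc, theta_dd, dof_rows)
        # dof_rows: list of (dof index, sign, center) for rotational DoF
        # affecting this body; translations handled implicitly.

        # HAT: com above hip center along (sin t, cos t)
        cth, sth = cos(tilt), sin(tilt)
        r = self.hat.com_offset
        com = (px + r * sth, py + r * cth)
        com_a = (ax + r * (tiltdd * cth - tiltd * tiltd * sth),
                 ay + r * (-tiltdd * sth - tiltd * tiltd * cth))
        bodies.append((self.hat, com, com_a, tiltdd, [(2, 1.0, hip)]))

        for side, (i_h, i_k, i_a) in self._LEGS.items():
            thigh, shank, foot = self.legs[side]
            th_t = tilt + q[i_h]
            th_s = th_t - q[i_k]
            th_f = th_s + q[i_a]
            w_t = tiltd + qdot[i_h]
            w_s = w_t - qdot[i_k]
            w_f = w_s + qdot[i_a]
            al_t = tiltdd + qddot[i_h]
            al_s = al_t - qddot[i_k]
            al_f = al_s + qddot[i_a]

            def down_pt(origin, origin_a, L, th, w, al):
                s_, c_ = sin(th), cos(th)
                p = (origin[0] + L * s_, origin[1] - L * c_)
                a = (origin_a[0] + L * (al * c_ - w * w * s_),
                     origin_a[1] + L * (al * s_ + w * w * c_))
                return p, a

            knee, knee_a = down_pt(hip, hip_a, thigh.length, th_t, w_t, al_t)
            ankle, ankle_a = down_pt(knee, knee_a, shank.length, th_s, w_s, al_s)
            com_t, coma_t = down_pt(hip, hip_a, thigh.com_offset, th_t, w_t, al_t)
            com_s, coma_s = down_pt(knee, knee_a, shank.com_offset, th_s, w_s, al_s)
            # foot COM forward of the ankle along the foot axis
            c_, s_ = cos(th_f), sin(th_f)
            rf = foot.com_offset
            com_f = (ankle[0] + rf * c_, ankle[1] + rf * s_)
            coma_f = (ankle_a[0] + rf * (-al_f * s_ - w_f * w_f * c_),
                      ankle_a[1] + rf * (al_f * c_ - w_f * w_f * s_))

            rows_t = [(2, 1.0, hip), (i_h, 1.0, hip)]
            rows_s = rows_t + [(i_k, -1.0, knee)]
            rows_f = rows_s + [(i_a, 1.0, ankle)]
            bodies.append((thigh, com_t, coma_t, al_t, rows_t))
            bodies.append((shank, com_s, coma_s, al_s, rows_s))
            bodies.append((foot, com_f, coma_f, al_f, rows_f))
        return bodies

    def inverse_dynamics(self, q, qdot, qddot):
        """Generalized forces required to produce ``qddot`` (gravity included,
        no external or joint forces): tau_req_i = sum_b m_b (a_b - g).J_b,i
        + I_b alpha_b dtheta_b/dq_i."""
        bodies = self._body_kinematics(q, qdot, qddot)
        res = [0.0] * 9
        for seg, com, com_a, th_dd, rows in bodies:
            fx = seg.mass * com_a[0]
            fy = seg.mass * (com_a[1] + self.g)
            res[0] = res[0] + fx
            res[1] = res[1] + fy
            for (i, sign, center) in rows:
                jx, jy = _perp(com[0] - center[0], com[1] - center[1])
                res[i] = res[i] + sign * (fx * jx + fy * jy)
                res[i] = res[i] + sign * seg.inertia_zz * th_dd
        return res

    def external_force_rows(self, q, sphere: ContactSphereSpec):
        """Virtual-work rows for a force at a contact sphere center."""
        side = sphere.segment.split("_")[1]
        i_h, i_k, i_a = self._LEGS[side]
        hip, knee, ankle, th_t, th_s, th_f = self.leg_points(q, side)
        p = self.contact_sphere_center(q, sphere)
        rows = [(2, 1.0, hip, p), (i_h, 1.0, hip, p),
                (i_k, -1.0, knee, p), (i_a, 1.0, ankle, p)]
        return p, rows

    def contact_sphere_velocity(self, q, qdot, sphere: ContactSphereSpec):
        side = sphere.segment.split("_")[1]
        i_h, i_k, i_a = self._LEGS[side]
        p, rows = self.external_force_rows(q, sphere)
        vx = qdot[0]
        vy = qdot[1]
        for (i, sign, center, point) in rows:
            jx, jy = _perp(point[0] - center[0], point[1] - center[1])
            vx = vx + sign * jx * qdot[i]
            vy = vy + sign * jy * qdot[i]
        return p, (vx, vy)


def skeletal_dynamics_residual(q, qdot, qddot, joint_moments, contact_forces,
                               model: ModelSpec):
    """Implicit equations of motion of the planar linkage (one residual per
    DoF, N or N m): required generalized force minus applied joint moments and
    contact contributions; zero iff the dynamics are satisfied.

    ``joint_moments`` is a length-9 sequence in :data:`COORDS` order (pelvis
    entries normally zero).  ``contact_forces`` maps sphere index ->
    (fx, fy[, torque]) applied at that sphere's center.
    """
    if len(q) != 9 or len(qdot) != 9 or len(qddot) != 9 or len(joint_moments) != 9:
        raise ValueError("expected 9 generalized coordinates/moments")
    skel = PlanarSkeleton(model)
    res = skel.inverse_dynamics(q, qdot, qddot)
    for i in range(9):
        res[i] = res[i] - joint_moments[i]
    if contact_forces:
        for si, f in contact_forces.items():
            sphere = model.contacts[si]
            p, rows = skel.external_force_rows(q, sphere)
            fx, fy = f[0], f[1]
            torque = f[2] if len(f) > 2 else None
            res[0] = res[0] - fx
            res[1] = res[1] - fy
            for (i, sign, center, point) in rows:
                jx, jy = _perp(point[0] - center[0], point[1] - center[1])
                res[i] = res[i] - sign * (fx * jx + fy * jy)
                if torque is not None:
                    res[i] = res[i] - sign * torque
    return res


# ---------------------------------------------------------------------------
# assembled model dynamics used by the collocation layer
# ---------------------------------------------------------------------------

class GaitDynamics:
    """All path residuals of one model variant, vectorized & AD-compatible.

    States: q (9), qdot (9), muscle activations a, normalized tendon forces
    f_tilde, and (amputee) MPK activation.  The path constraints evaluated at
    each collocation point are the 9 equation-of-motion residuals and one Hill
    equilibrium residual per muscle.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.skel = PlanarSkeleton(model)
        self.muscles = list(model.muscles)
        self.n_mus = len(self.muscles)
        self.has_mpk = model.prosthesis is not None
        self.coord_index = {name: i for i, name in enumerate(COORDS)}
        # residual scaling keeps EOM rows O(1) for the NLP
        mg = model.body_mass * model.gravity
        self.eom_scale = 1.0 / mg
        self._q_of = [
            {j: self.coord_index[j] for j in m.arms} for m in self.muscles]

    def joint_moments(self, q, qdot, ftilde, a_mpk=None):
        """Applied generalized moments: muscle + passive + MPK damper."""
        tau = [0.0] * 9
        for k, (m, jmap) in enumerate(zip(self.muscles, self._q_of)):
            force = ftilde[k] * m.params.f_max_iso
            for j, i in jmap.items():
                r0, r1 = m.arms[j]
                tau[i] = tau[i] + (r0 + r1 * q[i]) * force
        for jname, joint in self.model.joints.items():
            if joint.passive is None:
                continue
            i = self.coord_index[jname]
            tau[i] = tau[i] + passive_joint_moment(q[i], qdot[i], joint.passive)
        if self.has_mpk and a_mpk is not None:
            i = self.coord_index["knee_il"]
            tau[i] = tau[i] - mpk_damper_moment(
                a_mpk, self.model.prosthesis.d_mpk, qdot[i])
        return tau

    def contact_forces(self, q, qdot):
        """Per-sphere world forces and friction torque at the sphere center."""
        out = []
        for sphere in self.model.contacts:
            p, v = self.skel.contact_sphere_velocity(q, qdot, sphere)
            fx, fy = hunt_crossley_force(p, v, sphere)
            torque = -sphere.radius * fx    # friction acts at the sphere bottom
            out.append((sphere, p, fx, fy, torque))
        return out

    def eom_residuals(self, q, qdot, qddot, ftilde, a_mpk=None, scaled=True):
        tau = self.joint_moments(q, qdot, ftilde, a_mpk)
        res = self.skel.inverse_dynamics(q, qdot, qddot)
        for i in range(9):
            res[i] = res[i] - tau[i]
        for sphere, p, fx, fy, torque in self.contact_forces(q, qdot):
            _, rows = self.skel.external_force_rows(q, sphere)
            res[0] = res[0] - fx
            res[1] = res[1] - fy
            for (i, sign, center, point) in rows:
                jx, jy = _perp(point[0] - center[0], point[1] - center[1])
                res[i] = res[i] - sign * (fx * jx + fy * jy + torque)
        if scaled:
            res = [r * self.eom_scale for r in res]
        return res

    def hill_residuals(self, q, qdot, a, ftilde, dftilde):
        out = []
        for k, (m, jmap) in enumerate(zip(self.muscles, self._q_of)):
            qloc = {j: q[i] for j, i in jmap.items()}
            qdloc = {j: qdot[i] for j, i in jmap.items()}
            l_mt, v_mt, _ = muscle_geometry(qloc, qdloc, m)
            out.append(hill_equilibrium_residual(
                a[k], ftilde[k], dftilde[k], l_mt, v_mt, m.params))
        return out

    def metabolic_total(self, q, qdot, a, ftilde,
                        mp: MetabolicModelParams):
        """Whole-body metabolic rate (W) including the basal term.

        Fiber kinematics are evaluated at quasi-static tendon (f_tilde_dot=0),
        which is the standard approximation for effort costs.
        """
        total = mp.basal_rate * self.model.body_mass
        for k, (m, jmap) in enumerate(zip(self.muscles, self._q_of)):
            qloc = {j: q[i] for j, i in jmap.items()}
            qdloc = {j: qdot[i] for j, i in jmap.items()}
            l_mt, v_mt, _ = muscle_geometry(qloc, qdloc, m)
            p = m.params
            lf, cos_a, l_norm = fiber_state(ftilde[k], l_mt, p)
            vf = cos_a * v_mt
            v_norm = vf / (p.v_max * p.l_opt)
            total = total + metabolic_rate(a[k], ftilde[k], l_norm, v_norm,
                                           p, mp)
        return total
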