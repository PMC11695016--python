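"""Optimal-control problems: muscle-tendon parameter estimation and
predictive gait, transcribed by third-order Radau direct collocation.

Both problems share the transcription machinery: states are degree-3
Lagrange polynomials per mesh interval with dynamics enforced at the Radau
IIA points (which include the interval end, so mesh continuity is implicit),
controls (the state derivatives) are resolved at the same nodes, and the resulting NLP is
solved by the augmented-Lagrangian solver in :mod:`gaitopt._nlp` with exact
constraint Jacobians from forward-mode AD.

The predictive problem minimizes an integral effort cost (muscle activations
squared, squared whole-body metabolic rate, squared coordinate
accelerations, squared state derivatives and squared prosthetic-knee
excitation) divided by the distance traveled by the pelvis, subject to the
full implicit dynamics, periodicity of all states except the pelvis forward
position, and an imposed average gait speed with the cycle time free.

The estimation problem reproduces measured joint moments with the muscle
redundancy resolved by minimizing activations, optimal fiber length, reserve
actuation and state derivatives, while scaling each muscle's maximal
isometric force, optimal fiber length and tendon slack length within
[50%, 200%] of the generic values.
"""
from __future__ import annotations

import copy
import math
import types
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import CubicSpline

from . import _jet as J
from . import dynamics as dyn
from . import synthetic as syn
from ._nlp import NLPEval, SolverStats, solve_alm
from .model import ModelSpec, MuscleTendonParams


# ---------------------------------------------------------------------------
# Radau IIA coefficients and generic transcription
# ---------------------------------------------------------------------------

def radau_coefficients(degree: int = 3):
    """Collocation nodes, differentiation matrix and quadrature weights.

    Nodes are the right-Radau points on (0, 1]; the differentiation matrix D
    maps the state values at the interpolation points [0, c1..cd] to the
    state time-derivative at each collocation node: sum_m D[j,m] x_m =
    h * xdot(c_j).
    """
    if degree != 3:
        raise NotImplementedError("only third-order Radau is provided")
    s6 = math.sqrt(6.0)
    nodes = np.array([(4.0 - s6) / 10.0, (4.0 + s6) / 10.0, 1.0])
    taus = np.concatenate([[0.0], nodes])
    d = np.zeros((3, 4))
    weights = np.zeros(3)
    for m in range(4):
        # Lagrange basis polynomial over the 4 interpolation points
        coeffs = np.poly1d([1.0])
        for i in range(4):
            if i != m:
                coeffs *= np.poly1d([1.0, -taus[i]]) / (taus[m] - taus[i])
        dpoly = coeffs.deriv()
        for jj in range(3):
            d[jj, m] = dpoly(nodes[jj])
        if m > 0:
            ipoly = coeffs.integ()
            weights[m - 1] = ipoly(1.0) - ipoly(0.0)
    return nodes, d, weights


@dataclass
class CollocationGrid:
    n_mesh: int
    degree: int = 3
    t_i: float = 0.0
    t_f: float = 1.0      # free in the predictive problem (initial guess)

    def __post_init__(self):
        if self.n_mesh < 1:
            raise ValueError("n_mesh must be >= 1")
        if not self.t_f > self.t_i:
            raise ValueError("t_f must exceed t_i")


@dataclass
class ObjectiveWeights:
    """Weight factors of the two objective functionals."""
    w_e1: float = 10.0     # activations squared
    w_e2: float = 1.0      # optimal fiber length (1/m)
    w_e3: float = 0.1      # reserve actuators squared (1/(N m)^2)
    w_e4: float = 1e-3     # state-derivative regularization (normalized rates)
    w_p1: float = 100.0    # activations squared
    w_p2: float = 1e-4     # squared metabolic rate (1/W^2)
    w_p3: float = 0.01     # squared coordinate accelerations
    w_p4: float = 0.05     # state-derivative regularization
    w_p5: float = 1.0      # squared MPK excitation

    def __post_init__(self):
        if any(getattr(self, f) < 0 for f in vars(self)):
            raise ValueError("objective weights must be >= 0")


@dataclass
class ReserveActuator:
    joint: str
    re: np.ndarray        # N m trajectory on the collocation grid
    bound: float = 300.0


class RadauTranscription:
    """Generic third-order Radau transcription of an implicit ODE.

    ``residual(t, x, xdot) -> r`` defines the dynamics (r = 0 on
    trajectories).  This small self-contained system (solved with a damped
    Newton iteration) backs the transcription-order tests and utility
    integrations; the gait NLPs use the same coefficients through their own
    assembly.
    """

    def __init__(self, residual: Callable, grid: CollocationGrid, x0: np.ndarray):
        self.residual = residual
        self.grid = grid
        self.x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        self.nx = self.x0.size
        self.nodes, self.D, self.weights = radau_coefficients(grid.degree)
        self.n_mesh = grid.n_mesh
        self.h = (grid.t_f - grid.t_i) / grid.n_mesh
        self.n_var = self.n_mesh * 3 * self.nx

    def times(self) -> np.ndarray:
        """Times of the collocation states (mesh-interval Radau nodes)."""
        k = np.arange(self.n_mesh)[:, None]
        return (self.grid.t_i + (k + self.nodes[None, :]) * self.h).ravel()

    def residuals(self, z: np.ndarray) -> np.ndarray:
        X = z.reshape(self.n_mesh, 3, self.nx)
        out = np.empty_like(X)
        prev = self.x0
        t0 = self.grid.t_i
        for k in range(self.n_mesh):
            pts = np.vstack([prev, X[k]])           # (4, nx)
            dx = self.D @ pts                       # (3, nx) = h * xdot
            for j in range(3):
                t = t0 + (k + self.nodes[j]) * self.h
                out[k, j] = self.residual(t, X[k, j], dx[j] / self.h)
            prev = X[k, -1]
        return out.ravel()

    def solve(self, tol: float = 1e-12, maxiter: int = 50) -> np.ndarray:
        """Solve the collocation system; returns states at all collocation
        points, shape (n_mesh, 3, nx).  Newton with finite-difference
        Jacobian (the systems this entry point serves are small)."""
        z = np.tile(self.x0, self.n_mesh * 3)
        for _ in range(maxiter):
            r = self.residuals(z)
            if np.max(np.abs(r)) < tol:
                break
            jac = np.empty((r.size, z.size))
            eps = 1e-7
            for i in range(z.size):
                zp = z.copy()
                zp[i] += eps
                jac[:, i] = (self.residuals(zp) - r) / eps
            z = z - np.linalg.solve(jac, r)
        return z.reshape(self.n_mesh, 3, self.nx)

    def endpoint(self, z_or_states=None) -> np.ndarray:
        states = self.solve() if z_or_states is None else z_or_states
        return states[-1, -1]


def transcribe_radau(residual: Callable, grid: CollocationGrid,
                     x0: np.ndarray) -> RadauTranscription:
    """Transcribe an implicit ODE into its collocation system."""
    return RadauTranscription(residual, grid, x0)


# ---------------------------------------------------------------------------
# initial guesses
# ---------------------------------------------------------------------------

@dataclass
class Guess:
    T: float
    X: np.ndarray          # (1 + 3*n_mesh, nx) states at interpolation points
    U: np.ndarray          # (3*n_mesh, nu) controls at the collocation nodes
    source: str = "synthetic_nominal"


def _template_kinematics(model: ModelSpec, s_pct: np.ndarray, speed: float,
                         cycle_time: float) -> np.ndarray:
    """Joint-space pose at percent-cycle samples from the nominal templates."""
    d2r = math.pi / 180.0
    thigh = model.segments["thigh_il"].length
    shank = model.segments["shank_il"].length
    sphere = model.contacts[0]
    ankle_h = sphere.radius + abs(sphere.location[1])
    # stance penetration that roughly balances half body weight per foot
    delta0 = (0.5 * model.body_mass * model.gravity
              / (2.0 * sphere.stiffness)) ** (2.0 / 3.0)
    ty0 = thigh + shank + ankle_h - delta0
    q = np.zeros((s_pct.size, 9))
    q[:, 0] = speed * cycle_time * s_pct / 100.0
    # lowest at double support (0/50%), highest over the stance leg
    q[:, 1] = ty0 - 0.008 * np.cos(2.0 * np.pi * 2.0 * s_pct / 100.0)
    q[:, 2] = 0.04
    for c, joint in ((3, "hip"), (4, "knee"), (5, "ankle")):
        tmpl = syn.ANGLE_TEMPLATES_DEG[joint]
        q[:, c] = syn.template_curve(tmpl, s_pct) * d2r
        q[:, c + 3] = syn.template_curve(tmpl, np.mod(s_pct + 50.0, 100.0)) * d2r
    return q


def make_initial_guess(source: str, grid: CollocationGrid, model: ModelSpec,
                       target_speed: float, cycle_time: float = 1.1,
                       trial: Optional[dict] = None,
                       prior: Optional["PredictionResult"] = None,
                       seed: Optional[int] = None,
                       perturbation: float = 0.0) -> Guess:
    """Full state/control guess on the collocation grid.

    Sources: ``synthetic_nominal`` (template gait kinematics), ``trial_file``
    (a dict of percent-cycle joint-angle curves in degrees, e.g. read from a
    storage file), ``prior_solution`` (reuse a converged result exactly).
    Muscle states are seeded at activation 0.1 with tendon forces at static
    equilibrium; an optional seeded smooth perturbation supports multistart.
    """
    ocp = GaitPredictionOCP(model, PredictionProblemSpec(
        target_speed=target_speed, grid=grid))
    nodes, _, _ = radau_coefficients(grid.degree)
    K = grid.n_mesh
    # percent-cycle location of every interpolation point (0 plus Radau nodes)
    s_pts = np.concatenate([[0.0],
                            (100.0 * (np.arange(K)[:, None] + nodes[None, :])
                             / K).ravel()])

    if source == "prior_solution":
        if prior is None:
            raise ValueError("prior_solution guess needs a prior result")
        return Guess(T=prior.T, X=prior.X.copy(), U=prior.U.copy(),
                     source=source)

    if source == "trial_file":
        if trial is None:
            raise ValueError("trial_file guess needs trial curves")
        needed = ["hip_il", "knee_il", "ankle_il", "hip_cl", "knee_cl",
                  "ankle_cl"]
        missing = [c for c in needed if c not in trial]
        if missing:
            raise ValueError(f"trial is missing channels: {missing}")
        d2r = math.pi / 180.0
        q = _template_kinematics(model, s_pts, target_speed, cycle_time)
        grid101 = np.arange(101.0)
        for c, name in ((3, "hip_il"), (4, "knee_il"), (5, "ankle_il"),
                        (6, "hip_cl"), (7, "knee_cl"), (8, "ankle_cl")):
            spl = CubicSpline(grid101, np.asarray(trial[name], float))
            q[:, c] = spl(s_pts) * d2r
    elif source == "synthetic_nominal":
        q = _template_kinematics(model, s_pts, target_speed, cycle_time)
    else:
        raise ValueError(f"unknown guess source {source!r}")

    if perturbation > 0.0:
        rng = np.random.default_rng(seed)
        for c in range(2, 9):
            amp = perturbation * rng.standard_normal()
            ph = rng.uniform(0, 1)
            q[:, c] = q[:, c] + amp * np.sin(
                2 * np.pi * (s_pts / 100.0 + ph))

    # periodic splines give velocities and accelerations
    t_pts = cycle_time * s_pts / 100.0
    t_mid = cycle_time * (np.arange(K) + 0.5) / K
    qd = np.zeros_like(q)
    qdd_u = np.zeros((3 * K, 9))
    qd[:, 0] = target_speed
    for c in range(1, 9):
        q[-1, c] = q[0, c]      # enforce exact periodicity for the spline
        spl = CubicSpline(t_pts, q[:, c], bc_type="periodic")
        qd[:, c] = spl(t_pts, 1)
        qdd_u[:, c] = spl(t_pts[1:], 2)

    nm = ocp.nm
    X = np.zeros((1 + 3 * K, ocp.nx))
    X[:, :9] = q
    X[:, 9:18] = qd
    X[:, 18:18 + nm] = 0.1
    for k, mus in enumerate(ocp.dyn.muscles):
        jmap = ocp.dyn._q_of[k]
        qloc = {j: q[:, i] for j, i in jmap.items()}
        l_mt, _, _ = dyn.muscle_geometry(qloc, None, mus)
        X[:, 18 + nm + k] = dyn.equilibrium_f_tilde(0.1, l_mt, mus.params)
    if ocp.has_mpk:
        X[:, -1] = 0.2
    U = np.zeros((3 * K, ocp.nu))
    U[:, :9] = qdd_u
    if ocp.has_mpk:
        U[:, -1] = 0.2
    return Guess(T=cycle_time, X=X, U=U, source=source)


# ---------------------------------------------------------------------------
# predictive gait OCP
# ---------------------------------------------------------------------------

@dataclass
class PredictionProblemSpec:
    target_speed: float
    condition: str = "REF"
    grid: CollocationGrid = field(default_factory=lambda: CollocationGrid(50))
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    initial_guess: str = "synthetic_nominal"
    cycle_time_guess: float = 1.1
    metabolic: dyn.MetabolicModelParams = field(
        default_factory=dyn.MetabolicModelParams)
    feas_tol: float = 1e-6
    opt_tol: float = 1e-4
    max_outer: int = 40
    inner_maxiter: int = 30
    mu0: float = 100.0
    # contact-stiffness continuation: solve with softened ground first and
    # warm-start the stiffer stages (the Hunt-Crossley force is the one
    # severely non-quadratic term; without homotopy the line searches crawl)
    continuation: tuple = (3e4,)
    stage_feas_tol: float = 1e-4
    stage_opt_tol: float = 1e-3
    stage_max_outer: int = 16

    def __post_init__(self):
        if self.target_speed <= 0:
            raise ValueError("target_speed must be > 0")


@dataclass
class PredictionResult:
    T: float
    dist: float
    X: np.ndarray
    U: np.ndarray
    objective: float
    objective_terms: dict
    solver_stats: SolverStats
    converged: bool
    model: ModelSpec
    spec: PredictionProblemSpec
    times: np.ndarray          # times of the state interpolation points

    def state_names(self):
        names = list(dyn.COORDS) + [f"{c}_vel" for c in dyn.COORDS]
        names += [f"a_{m.name}" for m in self.model.muscles]
        names += [f"ft_{m.name}" for m in self.model.muscles]
        if self.model.prosthesis is not None:
            names.append("a_mpk")
        return names

    def gait_curves(self, n: int = 101) -> dict[str, np.ndarray]:
        """States resampled onto the 0-100% cycle grid (angles in degrees)."""
        s = np.linspace(0.0, 1.0, n) * self.T
        out = {}
        for i, name in enumerate(self.state_names()):
            spl = CubicSpline(self.times, self.X[:, i])
            vals = spl(s)
            if name in dyn.COORDS[2:] or name == "pelvis_tilt":
                vals = np.degrees(vals)
            out[name] = vals
        return out


class GaitPredictionOCP:
    """Assembly of the predictive gait NLP for one model variant."""

    def __init__(self, model: ModelSpec, spec: PredictionProblemSpec):
        self.model = model
        self.spec = spec
        self.dyn = dyn.GaitDynamics(model)
        self.nm = self.dyn.n_mus
        self.has_mpk = self.dyn.has_mpk
        self.nx = 18 + 2 * self.nm + (1 if self.has_mpk else 0)
        self.nu = 9 + 2 * self.nm + (1 if self.has_mpk else 0)
        self.K = spec.grid.n_mesh
        self.npts = 3 * self.K
        self.nsp = 1 + self.npts
        # controls live at the collocation nodes (state derivatives must be
        # resolved wherever the implicit dynamics are imposed)
        self.nz = 1 + self.nsp * self.nx + self.npts * self.nu
        self.nodes, self.D, self.b = radau_coefficients(spec.grid.degree)
        self.obj_scale = 0.05

        # slices into the state/control vectors
        self.s_q = slice(0, 9)
        self.s_qd = slice(9, 18)
        self.s_a = slice(18, 18 + self.nm)
        self.s_ft = slice(18 + self.nm, 18 + 2 * self.nm)
        self.i_ampk = self.nx - 1 if self.has_mpk else None
        self.u_qdd = slice(0, 9)
        self.u_adot = slice(9, 9 + self.nm)
        self.u_dft = slice(9 + self.nm, 9 + 2 * self.nm)
        self.i_empk = self.nu - 1 if self.has_mpk else None

        self._build_scales_and_bounds()
        self._idx4 = (3 * np.arange(self.K)[:, None]
                      + np.arange(4)[None, :])            # (K, 4) point idx

    # -- variable scaling and bounds ---------------------------------
    def _build_scales_and_bounds(self):
        m = self.model
        xs = np.ones(self.nx)
        xs[self.s_qd] = 10.0
        us = np.ones(self.nu)
        us[self.u_qdd] = 100.0
        us[self.u_adot] = 50.0
        us[self.u_dft] = 50.0
        self.x_scale, self.u_scale = xs, us

        qlo = np.array([-10.0, m.pelvis_ty_range[0], m.pelvis_tilt_range[0]]
                       + [m.joints[j].range[0] for j in dyn.COORDS[3:]])
        qhi = np.array([1000.0, m.pelvis_ty_range[1], m.pelvis_tilt_range[1]]
                       + [m.joints[j].range[1] for j in dyn.COORDS[3:]])
        xlo = np.concatenate([qlo, np.full(9, -25.0), np.full(self.nm, 0.0),
                              np.full(self.nm, 0.0)])
        xhi = np.concatenate([qhi, np.full(9, 25.0), np.full(self.nm, 1.0),
                              np.full(self.nm, 2.5)])
        xlo[9] = -8.0
        xhi[9] = 8.0
        if self.has_mpk:
            xlo = np.append(xlo, 0.0)
            xhi = np.append(xhi, 1.0)
        ulo = np.concatenate([np.full(9, -400.0), np.full(self.nm, -80.0),
                              np.full(self.nm, -400.0)])
        uhi = -ulo.copy()
        if self.has_mpk:
            ulo = np.append(ulo, 0.0)
            uhi = np.append(uhi, 1.0)
        self.x_lo, self.x_hi, self.u_lo, self.u_hi = xlo, xhi, ulo, uhi
        # physiological cycle-time window; also excludes a degenerate
        # fast-stepping basin far from observed gait cadences
        self.T_lo, self.T_hi = 0.8, 1.5

    # -- packing ------------------------------------------------------
    def pack(self, T: float, X: np.ndarray, U: np.ndarray) -> np.ndarray:
        return np.concatenate([[T], X.ravel(), U.ravel()])

    def unpack(self, z: np.ndarray):
        T = z[0]
        X = z[1:1 + self.nsp * self.nx].reshape(self.nsp, self.nx)
        U = z[1 + self.nsp * self.nx:].reshape(self.npts, self.nu)
        return T, X, U

    def scale_vector(self) -> np.ndarray:
        return np.concatenate([[1.0],
                               np.tile(self.x_scale, self.nsp),
                               np.tile(self.u_scale, self.npts)])

    def bounds_scaled(self) -> np.ndarray:
        s = self.scale_vector()
        lo = np.concatenate([[self.T_lo], np.tile(self.x_lo, self.nsp),
                             np.tile(self.u_lo, self.npts)]) / s
        hi = np.concatenate([[self.T_hi], np.tile(self.x_hi, self.nsp),
                             np.tile(self.u_hi, self.npts)]) / s
        return np.column_stack([lo, hi])

    # -- AD evaluation of path constraints and objective integrand ----
    def _path_and_objective(self, X, U, T, need_jac: bool):
        npts, nm = self.npts, self.nm
        xloc = X[1:, :]                       # collocation nodes
        urep = U                              # controls at the same nodes
        cols = ([xloc[:, i] for i in range(self.nx)]
                + [urep[:, i] for i in range(self.nu)])
        if need_jac:
            vars_ = J.seed(*cols)
        else:
            vars_ = cols
        xv = vars_[:self.nx]
        uv = vars_[self.nx:]
        q = xv[0:9]
        qd = xv[9:18]
        a = xv[18:18 + nm]
        ft = xv[18 + nm:18 + 2 * nm]
        ampk = xv[self.i_ampk] if self.has_mpk else None
        qdd = uv[0:9]
        adot = uv[9:9 + nm]
        dft = uv[9 + nm:9 + 2 * nm]
        empk = uv[self.i_empk] if self.has_mpk else None

        eom = self.dyn.eom_residuals(q, qd, qdd, ft, ampk)
        hill = self.dyn.hill_residuals(q, qd, a, ft, dft)
        residuals = eom + hill

        w = self.spec.weights
        t1 = sum(ai * ai for ai in a)
        edot = self.dyn.metabolic_total(q, qd, a, ft, self.spec.metabolic)
        t2 = edot * edot
        t3 = sum(qi * qi for qi in qdd)
        t4 = sum(x * x for x in adot) + sum(x * x for x in dft)
        integrand = w.w_p1 * t1 + w.w_p2 * t2 + w.w_p3 * t3 + w.w_p4 * t4
        terms = [t1, t2, t3, t4]
        if self.has_mpk:
            t5 = empk * empk
            integrand = integrand + w.w_p5 * t5
            terms.append(t5)
        outputs = residuals + [integrand] + terms

        vals = np.empty((npts, len(outputs)))
        for i, o in enumerate(outputs):
            vals[:, i] = np.broadcast_to(J.value(o), (npts,))
        if not need_jac:
            return vals, None
        ndir = self.nx + self.nu
        jac = np.zeros((npts, len(outputs), ndir))
        for i, o in enumerate(outputs):
            g = J.grad(o)
            if g is not None:
                jac[:, i, :] = np.broadcast_to(g, (npts, ndir))
        return vals, jac

    # -- collocation right-hand side ----------------------------------
    def _rhs(self, X, U):
        """f(x, u) for every collocation node, shape (npts, nx)."""
        nm = self.nm
        xloc = X[1:, :]
        urep = U
        F = np.empty((self.npts, self.nx))
        F[:, 0:9] = xloc[:, 9:18]
        F[:, 9:18] = urep[:, 0:9]
        F[:, 18:18 + nm] = urep[:, 9:9 + nm]
        F[:, 18 + nm:18 + 2 * nm] = urep[:, 9 + nm:9 + 2 * nm]
        if self.has_mpk:
            tau = self.model.prosthesis.tau_mpk
            F[:, -1] = (urep[:, -1] - xloc[:, -1]) / tau
        return F

    # -- full constraint evaluation -----------------------------------
    def constraints(self, z: np.ndarray, need_jac: bool = False):
        """Equality/inequality constraint values (scaled) and, optionally, a
        closure for transposed-Jacobian products."""
        T, X, U = self.unpack(z)
        h = T / self.K
        nm, nx, nu, K, npts = self.nm, self.nx, self.nu, self.K, self.npts

        F = self._rhs(X, U)
        PX = X[self._idx4]                                   # (K, 4, nx)
        colloc = (np.einsum("jm,kmx->kjx", self.D, PX)
                  - h * F.reshape(K, 3, nx)) / self.x_scale  # (K, 3, nx)

        path_vals, path_jac = self._path_and_objective(X, U, T, need_jac)
        n_res = 9 + nm
        path = path_vals[:, :n_res]

        per_idx = np.array([i for i in range(nx) if i != 0])
        periodic = (X[0, per_idx] - X[-1, per_idx]) / self.x_scale[per_idx]
        speed = np.array([X[-1, 0] - X[0, 0] - self.spec.target_speed * T])

        c_eq = np.concatenate([colloc.ravel(), path.ravel(), periodic, speed])

        # activation-rate inequalities (linear, scaled by time constants)
        arep = X[1:, self.s_a]
        adot_rep = U[:, self.u_adot]
        g1 = dyn.TAU_ACT * adot_rep - (1.0 - arep)
        g2 = -arep - dyn.TAU_DEACT * adot_rep
        c_in = np.concatenate([g1.ravel(), g2.ravel()])

        if not need_jac:
            return c_eq, c_in, path_vals, None
        return c_eq, c_in, path_vals, (path_jac, F)

    # -- objective -----------------------------------------------------
    def _objective_from_path(self, z, path_vals, path_jac=None, F=None):
        """Integral cost normalized by the traveled distance.

        The distance equals target_speed * T through the imposed speed
        constraint, so that product is used as the (always positive)
        denominator; at any feasible point it equals the pelvis travel.
        """
        T, X, U = self.unpack(z)
        h = T / self.K
        w_node = (h * self.b)[None, :].repeat(self.K, axis=0).ravel()  # (npts,)
        integrand = path_vals[:, 9 + self.nm]
        dist = self.spec.target_speed * T
        I = float(w_node @ integrand)
        obj = self.obj_scale * I / dist
        return obj, I, dist, w_node

    def objective_breakdown(self, z: np.ndarray) -> dict:
        """Per-term weighted integrals (divided by distance) and the total."""
        T, X, U = self.unpack(z)
        c_eq, c_in, path_vals, _ = self.constraints(z, need_jac=False)
        _, I, dist, w_node = self._objective_from_path(z, path_vals)
        w = self.spec.weights
        names = ["activation", "metabolic", "acceleration", "derivatives"]
        ws = [w.w_p1, w.w_p2, w.w_p3, w.w_p4]
        if self.has_mpk:
            names.append("mpk_excitation")
            ws.append(w.w_p5)
        out = {}
        total = 0.0
        for i, (name, wi) in enumerate(zip(names, ws)):
            val = wi * float(w_node @ path_vals[:, 9 + self.nm + 1 + i]) / dist
            out[name] = val
            total += val
        out["total"] = total
        return out

    # -- NLPEval assembly ---------------------------------------------
    def _jac_structure(self):
        """Precompute COO indices (and constant data blocks) of the equality
        Jacobian.  Data order: D-part, state couplings, control couplings,
        free-time column, dense path blocks, periodicity, speed."""
        nx, nu, nm = self.nx, self.nu, self.nm
        K, npts, nsp = self.K, self.npts, self.nsp
        n_res = 9 + nm
        xsc = self.x_scale
        xoff, uoff = 1, 1 + nsp * nx

        def xcol(p, s):
            return xoff + p * nx + s

        def ucol(p, s):
            return uoff + p * nu + s

        p_ = np.arange(npts)
        s_ = np.arange(nx)
        rows_cs = (p_[:, None] * nx + s_[None, :])          # colloc row (p, s)

        rows, cols, const = [], [], []
        # A: D-part (constant data)
        for m in range(4):
            rows.append(rows_cs.ravel())
            cols.append(xcol(3 * (p_ // 3)[:, None] + m, s_[None, :]).ravel())
            const.append((self.D[p_ % 3, m][:, None] / xsc[None, :]).ravel())
        self._nA = 4 * npts * nx
        # B: q-rows couple to qdot states, factor -h (base data stored)
        sq = np.arange(9)
        rows.append((p_[:, None] * nx + sq[None, :]).ravel())
        cols.append(xcol(p_[:, None] + 1, 9 + sq[None, :]).ravel())
        self._baseB = np.tile(-1.0 / xsc[sq], npts)
        # C: MPK activation self-coupling, factor +h/tau
        if self.has_mpk:
            rows.append(p_ * nx + (nx - 1))
            cols.append(xcol(p_ + 1, nx - 1))
            self._baseC = np.full(npts, 1.0 / xsc[nx - 1])
        else:
            self._baseC = np.zeros(0)
        # D: control couplings, factor -h (with 1/tau on the MPK excitation)
        srow = np.arange(9, 18 + 2 * nm)
        ucols = np.arange(0, 9 + 2 * nm)
        rows.append((p_[:, None] * nx + srow[None, :]).ravel())
        cols.append(ucol(p_[:, None], ucols[None, :]).ravel())
        baseD = np.tile(-1.0 / xsc[srow], npts)
        if self.has_mpk:
            rows.append(p_ * nx + (nx - 1))
            cols.append(ucol(p_, nu - 1))
            tau = self.model.prosthesis.tau_mpk
            baseD = np.concatenate([baseD, np.full(npts, -1.0 / tau)])
            self._baseC = self._baseC / tau
        self._baseD = baseD
        # E: free-time column
        rows.append(rows_cs.ravel())
        cols.append(np.zeros(npts * nx, dtype=int))
        # F: dense path blocks
        n_colloc = K * 3 * nx
        r_ = np.arange(n_res)
        prow = (n_colloc + p_[:, None] * n_res + r_[None, :])   # (npts, n_res)
        loc_cols = np.concatenate([xcol(0, np.arange(nx)), ucol(0, np.arange(nu))])
        pc = np.empty((npts, nx + nu), dtype=int)
        pc[:, :nx] = xcol(p_[:, None] + 1, np.arange(nx)[None, :])             - xcol(1, 0) + xcol(1, 0)
        pc[:, :nx] = xcol(p_[:, None] + 1, np.arange(nx)[None, :])
        pc[:, nx:] = ucol(p_[:, None], np.arange(nu)[None, :])
        rows.append(np.repeat(prow[:, :, None], nx + nu, axis=2).ravel())
        cols.append(np.repeat(pc[:, None, :], n_res, axis=1).ravel())
        # G: periodicity
        per_idx = np.array([i for i in range(nx) if i != 0])
        n_path = npts * n_res
        gr = n_colloc + n_path + np.arange(per_idx.size)
        rows.append(np.concatenate([gr, gr]))
        cols.append(np.concatenate([xcol(0, per_idx), xcol(nsp - 1, per_idx)]))
        self._dataG = np.concatenate([1.0 / xsc[per_idx], -1.0 / xsc[per_idx]])
        # H: speed
        hrow = n_colloc + n_path + per_idx.size
        rows.append(np.array([hrow, hrow, hrow]))
        cols.append(np.array([xcol(nsp - 1, 0), xcol(0, 0), 0]))
        self._dataH = np.array([1.0, -1.0, -self.spec.target_speed])

        self._jrows = np.concatenate(rows)
        self._jcols = np.concatenate(cols)
        self._dataA = np.concatenate(const)
        self._n_eq = n_colloc + n_path + per_idx.size + 1
        self._col_scale = self.scale_vector()[self._jcols]

        # constant inequality Jacobian (activation-rate constraints), scaled
        sc = self.scale_vector()
        ri, ci, di = [], [], []
        for blk, (da, dadot) in enumerate([(1.0, dyn.TAU_ACT),
                                           (-1.0, -dyn.TAU_DEACT)]):
            base = blk * npts * nm
            r2 = base + p_[:, None] * nm + np.arange(nm)[None, :]
            ri += [r2.ravel(), r2.ravel()]
            ci += [xcol(p_[:, None] + 1, 18 + np.arange(nm)[None, :]).ravel(),
                   ucol(p_[:, None], 9 + np.arange(nm)[None, :]).ravel()]
            di += [np.full(npts * nm, da), np.full(npts * nm, dadot)]
        ci_all = np.concatenate(ci)
        self._J_in = sp.coo_matrix(
            (np.concatenate(di) * sc[ci_all],
             (np.concatenate(ri), ci_all)),
            shape=(2 * npts * nm, self.nz)).tocsr()

    def _assemble_jac(self, h, F, path_jac):
        """Sparse equality Jacobian (scaled variables) at the current point."""
        n_res = 9 + self.nm
        data = np.concatenate([
            self._dataA,
            h * self._baseB,
            h * self._baseC,
            h * self._baseD,
            (-F / (self.K * self.x_scale)).ravel(),
            path_jac[:, :n_res, :].ravel(),
            self._dataG,
            self._dataH,
        ])
        J = sp.coo_matrix((data * self._col_scale,
                           (self._jrows, self._jcols)),
                          shape=(self._n_eq, self.nz)).tocsr()
        return J

    def make_evaluator(self):
        sc = self.scale_vector()
        n_res = 9 + self.nm
        self._jac_structure()

        def evaluate(z_s: np.ndarray) -> NLPEval:
            z = z_s * sc
            T, _, _ = self.unpack(z)
            h = T / self.K
            c_eq, c_in, path_vals, jac_data = self.constraints(z, need_jac=True)
            path_jac, F = jac_data
            obj, I, dist, w_node = self._objective_from_path(z, path_vals)

            grad = np.zeros(self.nz)
            gint = path_jac[:, n_res, :]                   # (npts, ndir)
            coeff = self.obj_scale * w_node / dist
            self._scatter_local(grad, coeff[:, None] * gint)
            # integral weight depends on T: w_node = (T/K) b, and the
            # denominator is target_speed * T
            bfull = np.tile(self.b, self.K)
            grad[0] += self.obj_scale * float(
                (bfull / self.K) @ path_vals[:, n_res]) / dist
            grad[0] -= self.obj_scale * I * self.spec.target_speed / dist ** 2

            J_eq = self._assemble_jac(h, F, path_jac)

            # diagonal Gauss-Newton curvature of the objective (the effort
            # terms are sums of squares; the metabolic term contributes
            # through its gradient outer-product diagonal)
            w = self.spec.weights
            hd = np.zeros(self.nz)
            loc = np.zeros((self.npts, self.nx + self.nu))
            loc[:, 18:18 + self.nm] = 2.0 * w.w_p1
            loc[:, self.nx:self.nx + 9] = 2.0 * w.w_p3
            loc[:, self.nx + 9:self.nx + 9 + 2 * self.nm] = 2.0 * w.w_p4
            if self.has_mpk:
                loc[:, self.nx + self.nu - 1] = 2.0 * w.w_p5
            t2 = np.maximum(path_vals[:, n_res + 2], 1e-12)
            dedot = path_jac[:, n_res + 2, :] ** 2 / (2.0 * t2[:, None])
            loc += w.w_p2 * 2.0 * dedot * 0.5
            loc *= coeff[:, None]
            self._scatter_local(hd, loc)
            hd *= sc * sc

            return NLPEval(obj=obj, grad=grad * sc, c_eq=c_eq, c_in=c_in,
                           J_eq=J_eq, J_in=self._J_in, hess_diag=hd)

        def evaluate_light(z_s: np.ndarray):
            z = z_s * sc
            c_eq, c_in, path_vals, _ = self.constraints(z, need_jac=False)
            obj, _, _, _ = self._objective_from_path(z, path_vals)
            return obj, c_eq, c_in

        return evaluate, evaluate_light

    def _scatter_local(self, g: np.ndarray, loc: np.ndarray):
        """Scatter per-node local gradients (npts, nx+nu) into the flat z
        gradient."""
        Xb = g[1:1 + self.nsp * self.nx].reshape(self.nsp, self.nx)
        Xb[1:, :] += loc[:, :self.nx]
        Ub = g[1 + self.nsp * self.nx:].reshape(self.npts, self.nu)
        Ub += loc[:, self.nx:]

    # -- solve ---------------------------------------------------------
    def solve(self, guess: Guess, verbose: bool = False,
              lam0=None, eta0=None) -> PredictionResult:
        z0 = self.pack(guess.T, guess.X, guess.U)
        sc = self.scale_vector()
        bounds = self.bounds_scaled()
        z0_s = np.clip(z0 / sc, bounds[:, 0], bounds[:, 1])
        # normalize the objective by its value at the guess: conditioning aid,
        # and a common rescaling of all weights then cancels exactly
        _, _, pv0, _ = self.constraints(z0_s * sc, need_jac=False)
        _, I0, dist0, _ = self._objective_from_path(z0_s * sc, pv0)
        self.obj_scale = 1.0 / max(abs(I0 / dist0), 1e-8)
        evaluate, evaluate_light = self.make_evaluator()
        z_s, stats = solve_alm(evaluate, evaluate_light, z0_s, bounds,
                               feas_tol=self.spec.feas_tol,
                               opt_tol=self.spec.opt_tol,
                               max_outer=self.spec.max_outer,
                               inner_maxiter=self.spec.inner_maxiter,
                               mu0=self.spec.mu0,
                               schur_col=0, lam0=lam0, eta0=eta0,
                               verbose=verbose)
        z = z_s * sc
        T, X, U = self.unpack(z)
        dist = float(X[-1, 0] - X[0, 0])
        terms = self.objective_breakdown(z)
        k = np.arange(self.K)[:, None]
        times = np.concatenate(
            [[0.0], ((k + self.nodes[None, :]) * (T / self.K)).ravel()])
        return PredictionResult(
            T=float(T), dist=dist, X=X, U=U,
            objective=terms["total"], objective_terms=terms,
            solver_stats=stats, converged=stats.converged,
            model=self.model, spec=self.spec, times=times)

    def verify(self, result: PredictionResult) -> dict:
        """Independent post-hoc residual check at every collocation point."""
        z = self.pack(result.T, result.X, result.U)
        c_eq, c_in, _, _ = self.constraints(z, need_jac=False)
        return {"eq_inf": float(np.max(np.abs(c_eq))),
                "ineq_inf": float(np.max(np.maximum(c_in, 0.0)))}


def predict_gait(spec: PredictionProblemSpec, model: ModelSpec,
                 guess: Optional[Guess] = None,
                 warm_from: Optional[PredictionResult] = None,
                 verbose: bool = False) -> PredictionResult:
    """Solve the predictive gait problem for one model/condition.

    Models without a prosthesis carry no MPK state/excitation, so the
    corresponding excitation penalty is absent from their objective.
    """
    if warm_from is not None:
        spec = copy.deepcopy(spec)
        spec.continuation = ()
        spec.mu0 = 1e4        # multipliers are warm: start with a firm penalty
        guess = Guess(T=warm_from.T, X=warm_from.X.copy(),
                      U=warm_from.U.copy(), source="prior_solution")
        ocp = GaitPredictionOCP(model, spec)
        result = ocp.solve(guess, verbose=verbose,
                           lam0=warm_from.solver_stats.lam,
                           eta0=warm_from.solver_stats.eta)
        if not result.converged:
            warnings.warn(
                f"gait prediction did not converge: "
                f"{result.solver_stats.status} "
                f"(feasibility {result.solver_stats.feas_inf:.2e})",
                stacklevel=2)
        return result
    for k_soft in spec.continuation:
        if any(c.stiffness <= k_soft for c in model.contacts):
            continue
        soft_model = copy.deepcopy(model)
        for c in soft_model.contacts:
            c.stiffness = k_soft
        soft_spec = copy.deepcopy(spec)
        soft_spec.feas_tol = spec.stage_feas_tol
        soft_spec.opt_tol = spec.stage_opt_tol
        soft_spec.max_outer = spec.stage_max_outer
        if guess is None:
            # the nominal pelvis height depends on the ground stiffness, so
            # the cold-start guess is built against the softened stage model
            guess = make_initial_guess(spec.initial_guess, spec.grid,
                                       soft_model, spec.target_speed,
                                       cycle_time=spec.cycle_time_guess)
        stage = GaitPredictionOCP(soft_model, soft_spec).solve(
            guess, verbose=verbose)
        guess = Guess(T=stage.T, X=stage.X, U=stage.U, source="continuation")
        prev_k = k_soft
        # hand-off correction: the softer ground was penetrated deeper, so
        # raise the pelvis by the static penetration difference
        next_k = min(c.stiffness for c in model.contacts)
        for kk in spec.continuation:
            if prev_k < kk < next_k:
                next_k = kk
        w_half = 0.5 * model.body_mass * model.gravity / 2.0
        shift = ((w_half / prev_k) ** (2.0 / 3.0)
                 - (w_half / next_k) ** (2.0 / 3.0))
        guess.X[:, 1] += shift
    if guess is None:
        guess = make_initial_guess(spec.initial_guess, spec.grid, model,
                                   spec.target_speed,
                                   cycle_time=spec.cycle_time_guess)
    ocp = GaitPredictionOCP(model, spec)
    result = ocp.solve(guess, verbose=verbose)
    if not result.converged:
        warnings.warn(
            f"gait prediction did not converge: {result.solver_stats.status} "
            f"(feasibility {result.solver_stats.feas_inf:.2e}); trajectories "
            "returned for diagnosis", stacklevel=2)
    return result


def multistart(spec: PredictionProblemSpec, model: ModelSpec, n_starts: int,
               seed: int = 0, perturbation: float = 0.05) -> list[PredictionResult]:
    """Re-solve from smoothly perturbed guesses; all objectives reported."""
    out = []
    for i in range(n_starts):
        guess = make_initial_guess(spec.initial_guess, spec.grid, model,
                                   spec.target_speed,
                                   cycle_time=spec.cycle_time_guess,
                                   seed=seed + i,
                                   perturbation=0.0 if i == 0 else perturbation)
        out.append(GaitPredictionOCP(model, spec).solve(guess))
    return out


# ---------------------------------------------------------------------------
# muscle-tendon parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class EstimationProblemSpec:
    times: np.ndarray                 # trial sample times (one cycle)
    q: np.ndarray                     # hip angle trajectory (rad)
    qdot: np.ndarray
    moments: np.ndarray               # hip moment trajectory (N m)
    grid: CollocationGrid = field(default_factory=lambda: CollocationGrid(25))
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    param_bounds: tuple[float, float] = (0.5, 2.0)
    reserve_bound: float = 300.0
    fix_params: bool = False          # solve redundancy at generic parameters
    feas_tol: float = 1e-6
    opt_tol: float = 1e-7
    max_outer: int = 30
    inner_maxiter: int = 30


@dataclass
class EstimationResult:
    multipliers: dict                   # muscle -> {f_max_iso, l_opt, l_ts}
    params: dict                        # muscle -> personalized params
    activations: np.ndarray             # (npts, nm)
    tendon_forces: np.ndarray
    reserves: np.ndarray                # (K,)
    reserve_rms: float
    moment_residual_inf: float
    objective: float
    solver_stats: SolverStats
    converged: bool


class EstimationOCP:
    """Muscle redundancy + parameter personalization on the IL hip."""

    PKEYS = ("f_max_iso", "l_opt", "l_ts")

    def __init__(self, model: ModelSpec, spec: EstimationProblemSpec):
        self.model = model
        self.spec = spec
        self.muscles = [m for m in model.muscles_on("il") if "hip_il" in m.arms]
        if not self.muscles:
            raise ValueError("no IL hip muscles to personalize")
        self.nm = len(self.muscles)
        self.K = spec.grid.n_mesh
        self.npts = 3 * self.K
        self.nsp = 1 + self.npts
        self.nx = 2 * self.nm
        self.nu = 2 * self.nm + 1          # adot, dft, reserve
        self.np_ = 3 * self.nm
        self.nz = self.nsp * self.nx + self.npts * self.nu + self.np_
        self.nodes, self.D, self.b = radau_coefficients(spec.grid.degree)
        self._idx4 = (3 * np.arange(self.K)[:, None] + np.arange(4)[None, :])

        # prescribed kinematics at all interpolation points
        t = np.asarray(spec.times, float)
        Tcyc = spec.grid.t_f - spec.grid.t_i
        tg = np.concatenate([t, [t[0] + Tcyc]])

        def psp(vals):
            return CubicSpline(tg, np.concatenate([vals, [vals[0]]]),
                               bc_type="periodic")

        self.t_pts = np.concatenate(
            [[0.0], ((np.arange(self.K)[:, None] + self.nodes[None, :])
                     * (Tcyc / self.K)).ravel()])
        qs, qds, ms = psp(spec.q), psp(spec.qdot), psp(spec.moments)
        self.q_pts = qs(self.t_pts)
        self.qd_pts = qds(self.t_pts)
        self.m_pts = ms(self.t_pts[1:])
        self.lmt = np.empty((self.npts, self.nm))
        self.vmt = np.empty((self.npts, self.nm))
        self.rarm = np.empty((self.npts, self.nm))
        qn = self.q_pts[1:]
        qdn = self.qd_pts[1:]
        for k, mus in enumerate(self.muscles):
            r0, r1 = mus.arms["hip_il"]
            self.rarm[:, k] = r0 + r1 * qn
            self.lmt[:, k] = mus.l_ref - (r0 * qn + 0.5 * r1 * qn * qn)
            self.vmt[:, k] = -self.rarm[:, k] * qdn
        self.h = Tcyc / self.K
        self.m_scale = 1.0 / max(1.0, np.max(np.abs(self.m_pts)))

    # -- packing -------------------------------------------------------
    def unpack(self, z):
        X = z[:self.nsp * self.nx].reshape(self.nsp, self.nx)
        U = z[self.nsp * self.nx:self.nsp * self.nx
              + self.npts * self.nu].reshape(self.npts, self.nu)
        P = z[-self.np_:].reshape(self.nm, 3)
        return X, U, P

    def pack(self, X, U, P):
        return np.concatenate([X.ravel(), U.ravel(), P.ravel()])

    def bounds(self):
        lo_x = np.concatenate([np.zeros(self.nm), np.zeros(self.nm)])
        hi_x = np.concatenate([np.ones(self.nm), np.full(self.nm, 2.5)])
        lo_u = np.concatenate([np.full(self.nm, -80.0), np.full(self.nm, -400.0),
                               [-self.spec.reserve_bound]])
        hi_u = -lo_u
        pb = self.spec.param_bounds
        if self.spec.fix_params:
            lo_p = np.ones(self.np_) - 1e-12
            hi_p = np.ones(self.np_) + 1e-12
        else:
            lo_p = np.full(self.np_, pb[0])
            hi_p = np.full(self.np_, pb[1])
        lo = np.concatenate([np.tile(lo_x, self.nsp), np.tile(lo_u, self.npts),
                             lo_p])
        hi = np.concatenate([np.tile(hi_x, self.nsp), np.tile(hi_u, self.npts),
                             hi_p])
        return np.column_stack([lo, hi])

    def _param_objects(self, P_jets):
        """Per-muscle parameter namespaces with (possibly Jet) scaled values."""
        out = []
        for k, mus in enumerate(self.muscles):
            p = mus.params
            out.append(types.SimpleNamespace(
                f_max_iso=p.f_max_iso * P_jets[k][0],
                l_opt=p.l_opt * P_jets[k][1],
                l_ts=p.l_ts * P_jets[k][2],
                alpha_opt=p.alpha_opt, v_max=p.v_max))
        return out

    def _path(self, X, U, P, need_jac):
        nm, npts = self.nm, self.npts
        xloc = X[1:, :]
        urep = U
        cols = ([xloc[:, i] for i in range(self.nx)]
                + [urep[:, i] for i in range(self.nu)]
                + [np.full(npts, P[k, j]) for k in range(nm) for j in range(3)])
        vars_ = J.seed(*cols) if need_jac else cols
        a = vars_[0:nm]
        ft = vars_[nm:2 * nm]
        adot = vars_[self.nx:self.nx + nm]
        dft = vars_[self.nx + nm:self.nx + 2 * nm]
        re = vars_[self.nx + 2 * nm]
        pj = [vars_[self.nx + self.nu + 3 * k:self.nx + self.nu + 3 * k + 3]
              for k in range(nm)]
        params = self._param_objects(pj)

        outputs = []
        for k in range(nm):
            outputs.append(dyn.hill_equilibrium_residual(
                a[k], ft[k], dft[k], self.lmt[:, k], self.vmt[:, k], params[k]))
        mom = re * 1.0
        for k in range(nm):
            mom = mom + self.rarm[:, k] * ft[k] * params[k].f_max_iso
        outputs.append((mom - self.m_pts) * self.m_scale)

        w = self.spec.weights
        t_act = sum(ai * ai for ai in a)
        t_lopt = sum(params[k].l_opt for k in range(nm))
        t_res = re * re
        t_der = sum(x * x for x in adot) + sum(x * x for x in dft)
        integrand = (w.w_e1 * t_act + w.w_e2 * t_lopt + w.w_e3 * t_res
                     + w.w_e4 * t_der)
        outputs += [integrand, t_act, t_lopt, t_res, t_der]

        vals = np.empty((npts, len(outputs)))
        for i, o in enumerate(outputs):
            vals[:, i] = np.broadcast_to(J.value(o), (npts,))
        if not need_jac:
            return vals, None
        ndir = self.nx + self.nu + self.np_
        jac = np.zeros((npts, len(outputs), ndir))
        for i, o in enumerate(outputs):
            g = J.grad(o)
            if g is not None:
                jac[:, i, :] = np.broadcast_to(g, (npts, ndir))
        return vals, jac

    def constraints(self, z, need_jac=False):
        X, U, P = self.unpack(z)
        F = np.empty((self.npts, self.nx))
        F[:, :2 * self.nm] = U[:, :2 * self.nm]
        PX = X[self._idx4]
        colloc = (np.einsum("jm,kmx->kjx", self.D, PX)
                  - self.h * F.reshape(self.K, 3, self.nx))
        path_vals, path_jac = self._path(X, U, P, need_jac)
        n_res = self.nm + 1
        periodic = X[0, :] - X[-1, :]
        c_eq = np.concatenate([colloc.ravel(),
                               path_vals[:, :n_res].ravel(), periodic])
        arep = X[1:, :self.nm]
        adot_rep = U[:, :self.nm]
        g1 = dyn.TAU_ACT * adot_rep - (1.0 - arep)
        g2 = -arep - dyn.TAU_DEACT * adot_rep
        c_in = np.concatenate([g1.ravel(), g2.ravel()])
        return c_eq, c_in, path_vals, path_jac

    def scale_vector(self) -> np.ndarray:
        xs = np.ones(self.nx)
        us = np.concatenate([np.full(self.nm, 30.0), np.full(self.nm, 100.0),
                             [0.5 / self.m_scale]])
        return np.concatenate([np.tile(xs, self.nsp), np.tile(us, self.npts),
                               np.ones(self.np_)])

    def objective_value(self, z) -> float:
        """Raw (unnormalized) objective integral at a point."""
        w_node = (self.h * self.b)[None, :].repeat(self.K, axis=0).ravel()
        _, _, path_vals, _ = self.constraints(z, need_jac=False)
        return float(w_node @ path_vals[:, self.nm + 1])

    def _jac_structure(self):
        """Precompute COO indices / constant data of the equality Jacobian."""
        nx, nu, nm = self.nx, self.nu, self.nm
        K, npts, nsp = self.K, self.npts, self.nsp
        n_res = nm + 1
        uoff = nsp * nx
        poff = uoff + npts * nu

        def xcol(p, s):
            return p * nx + s

        def ucol(p, s):
            return uoff + p * nu + s

        p_ = np.arange(npts)
        s_ = np.arange(nx)
        rows_cs = (p_[:, None] * nx + s_[None, :])
        rows, cols, const = [], [], []
        # D-part (constant)
        for m in range(4):
            rows.append(rows_cs.ravel())
            cols.append(xcol(3 * (p_ // 3)[:, None] + m, s_[None, :]).ravel())
            const.append(np.repeat(self.D[p_ % 3, m], nx))
        # state derivatives from controls (constant, -h)
        rows.append(rows_cs.ravel())
        cols.append(ucol(p_[:, None], s_[None, :]).ravel())
        const.append(np.full(npts * nx, -self.h))
        self._data_const = np.concatenate(const)
        # dense path blocks
        n_colloc = K * 3 * nx
        r_ = np.arange(n_res)
        prow = (n_colloc + p_[:, None] * n_res + r_[None, :])
        pc = np.empty((npts, nx + nu + self.np_), dtype=int)
        pc[:, :nx] = xcol(p_[:, None] + 1, np.arange(nx)[None, :])
        pc[:, nx:nx + nu] = ucol(p_[:, None], np.arange(nu)[None, :])
        pc[:, nx + nu:] = poff + np.arange(self.np_)[None, :]
        rows.append(np.repeat(prow[:, :, None], pc.shape[1], axis=2).ravel())
        cols.append(np.repeat(pc[:, None, :], n_res, axis=1).ravel())
        # periodicity (all states)
        n_path = npts * n_res
        gr = n_colloc + n_path + np.arange(nx)
        rows.append(np.concatenate([gr, gr]))
        cols.append(np.concatenate([xcol(0, s_), xcol(nsp - 1, s_)]))
        self._dataG = np.concatenate([np.ones(nx), -np.ones(nx)])
        self._jrows = np.concatenate(rows)
        self._jcols = np.concatenate(cols)
        self._n_eq = n_colloc + n_path + nx
        self._col_scale = self.scale_vector()[self._jcols]

        sc = self.scale_vector()
        ri, ci, di = [], [], []
        for blk, (da, dadot) in enumerate([(1.0, dyn.TAU_ACT),
                                           (-1.0, -dyn.TAU_DEACT)]):
            base = blk * npts * nm
            r2 = base + p_[:, None] * nm + np.arange(nm)[None, :]
            ri += [r2.ravel(), r2.ravel()]
            ci += [xcol(p_[:, None] + 1, np.arange(nm)[None, :]).ravel(),
                   ucol(p_[:, None], np.arange(nm)[None, :]).ravel()]
            di += [np.full(npts * nm, da), np.full(npts * nm, dadot)]
        ci_all = np.concatenate(ci)
        self._J_in = sp.coo_matrix(
            (np.concatenate(di) * sc[ci_all],
             (np.concatenate(ri), ci_all)),
            shape=(2 * npts * nm, self.nz)).tocsr()

    def make_evaluator(self, obj_scale: float = 0.1):
        n_res = self.nm + 1
        w_node = (self.h * self.b)[None, :].repeat(self.K, axis=0).ravel()
        sc = self.scale_vector()
        self._jac_structure()

        def evaluate(z_s):
            z = z_s * sc
            c_eq, c_in, path_vals, path_jac = self.constraints(z, need_jac=True)
            obj = obj_scale * float(w_node @ path_vals[:, n_res])
            grad = np.zeros(self.nz)
            self._scatter_local(grad,
                                obj_scale * w_node[:, None]
                                * path_jac[:, n_res, :])
            data = np.concatenate([self._data_const,
                                   path_jac[:, :n_res, :].ravel(),
                                   self._dataG])
            J_eq = sp.coo_matrix((data * self._col_scale,
                                  (self._jrows, self._jcols)),
                                 shape=(self._n_eq, self.nz)).tocsr()
            w = self.spec.weights
            hd = np.zeros(self.nz)
            loc = np.zeros((self.npts, self.nx + self.nu + self.np_))
            loc[:, :self.nm] = 2.0 * w.w_e1
            loc[:, self.nx:self.nx + 2 * self.nm] = 2.0 * w.w_e4
            loc[:, self.nx + 2 * self.nm] = 2.0 * w.w_e3
            loc *= (obj_scale * w_node)[:, None]
            self._scatter_local(hd, loc)
            hd *= sc * sc
            return NLPEval(obj=obj, grad=grad * sc, c_eq=c_eq, c_in=c_in,
                           J_eq=J_eq, J_in=self._J_in, hess_diag=hd)

        def evaluate_light(z_s):
            z = z_s * sc
            c_eq, c_in, path_vals, _ = self.constraints(z, need_jac=False)
            obj = obj_scale * float(w_node @ path_vals[:, n_res])
            return obj, c_eq, c_in

        return evaluate, evaluate_light

    def _scatter_local(self, g, loc):
        Xb = g[:self.nsp * self.nx].reshape(self.nsp, self.nx)
        Xb[1:, :] += loc[:, :self.nx]
        Ub = g[self.nsp * self.nx:self.nsp * self.nx
               + self.npts * self.nu].reshape(self.npts, self.nu)
        Ub += loc[:, self.nx:self.nx + self.nu]
        Pb = g[-self.np_:]
        Pb += loc[:, self.nx + self.nu:].sum(axis=0)

    def initial_guess(self):
        X = np.zeros((self.nsp, self.nx))
        X[:, :self.nm] = 0.1
        for k, mus in enumerate(self.muscles):
            r0, r1 = mus.arms["hip_il"]
            q = self.q_pts
            lmt = mus.l_ref - (r0 * q + 0.5 * r1 * q * q)
            X[:, self.nm + k] = dyn.equilibrium_f_tilde(0.1, lmt, mus.params)
        U = np.zeros((self.npts, self.nu))
        # seed the reserve with the unmet moment
        mom = np.zeros(self.npts)
        for k, mus in enumerate(self.muscles):
            mom += self.rarm[:, k] * X[1:, self.nm + k] * mus.params.f_max_iso
        U[:, -1] = np.clip(self.m_pts - mom,
                           -self.spec.reserve_bound, self.spec.reserve_bound)
        P = np.ones((self.nm, 3))
        return self.pack(X, U, P)

    def solve(self, verbose: bool = False) -> EstimationResult:
        z0 = self.initial_guess()
        bounds = self.bounds()
        z0 = np.clip(z0, bounds[:, 0], bounds[:, 1])
        # normalize the objective by its value at the guess: conditioning aid,
        # and a common rescaling of all weights then cancels exactly
        obj_scale = 1.0 / max(abs(self.objective_value(z0)), 1e-3)
        sc = self.scale_vector()
        ev, ev_light = self.make_evaluator(obj_scale)
        z_s, stats = solve_alm(ev, ev_light, z0 / sc, bounds / sc[:, None],
                               feas_tol=self.spec.feas_tol,
                               opt_tol=self.spec.opt_tol,
                               max_outer=self.spec.max_outer,
                               inner_maxiter=self.spec.inner_maxiter,
                               verbose=verbose)
        z = z_s * sc
        X, U, P = self.unpack(z)
        c_eq, _, path_vals, _ = self.constraints(z, need_jac=False)
        mom_res = path_vals[:, self.nm] / self.m_scale
        mults = {}
        params = {}
        for k, mus in enumerate(self.muscles):
            mults[mus.name] = dict(zip(self.PKEYS, P[k]))
            p = mus.params
            params[mus.name] = MuscleTendonParams(
                f_max_iso=p.f_max_iso * P[k, 0], l_opt=p.l_opt * P[k, 1],
                l_ts=p.l_ts * P[k, 2], alpha_opt=p.alpha_opt, v_max=p.v_max)
        reserves = U[:, -1]
        return EstimationResult(
            multipliers=mults, params=params,
            activations=X[1:, :self.nm], tendon_forces=X[1:, self.nm:],
            reserves=reserves,
            reserve_rms=float(np.sqrt(np.mean(reserves ** 2))),
            moment_residual_inf=float(np.max(np.abs(mom_res))),
            objective=stats.objective, solver_stats=stats,
            converged=stats.converged)


def estimate_parameters(spec: EstimationProblemSpec, model: ModelSpec,
                        verbose: bool = False) -> EstimationResult:
    """Personalize IL-hip muscle-tendon parameters from joint-moment trials."""
    result = EstimationOCP(model, spec).solve(verbose=verbose)
    if not result.converged:
        warnings.warn(
            "parameter estimation did not converge: "
            f"{result.solver_stats.status} "
            f"(feasibility {result.solver_stats.feas_inf:.2e})", stacklevel=2)
    return result
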