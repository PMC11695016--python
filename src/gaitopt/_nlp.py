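"""Bound-constrained augmented-Lagrangian solver for collocation NLPs.

The transcribed optimal-control problems have the form

    min  F(z)   s.t.  c_eq(z) = 0,  c_in(z) <= 0,  lb <= z <= ub

with exact first derivatives and an assembled sparse constraint Jacobian.
They are solved with a classical (LANCELOT-style) augmented Lagrangian whose
bound-constrained inner problems are minimized by a projected Newton
iteration: the inner Hessian is approximated Gauss-Newton style by
mu * J^T J plus the diagonal objective curvature and an adaptive Levenberg
damping, and steps come from a direct sparse KKT factorization -- this
captures exactly the stiff penalty curvature that defeats first-order
methods on these problems.  Multipliers follow safeguarded first-order
updates and the penalty grows moderately when feasibility stalls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class NLPEval:
    """One evaluation point of the NLP."""
    obj: float
    grad: np.ndarray
    c_eq: np.ndarray
    c_in: np.ndarray
    J_eq: sp.spmatrix            # sparse Jacobian of the equalities
    J_in: Optional[sp.spmatrix]  # sparse Jacobian of the inequalities
    hess_diag: Optional[np.ndarray] = None   # diagonal GN objective curvature


@dataclass
class SolverStats:
    status: str = "unknown"          # converged | max_outer | inner_failure
    converged: bool = False
    n_outer: int = 0
    n_inner: int = 0
    objective: float = np.nan
    feas_inf: float = np.inf         # max equality violation (scaled)
    ineq_inf: float = 0.0
    message: str = ""
    history: list = field(default_factory=list)
    lam: Optional[np.ndarray] = None     # final equality multipliers
    eta: Optional[np.ndarray] = None     # final inequality multipliers


def _al_value(e: NLPEval, lam, eta, mu) -> float:
    val = e.obj
    if lam.size:
        val += float(lam @ e.c_eq) + 0.5 * mu * float(e.c_eq @ e.c_eq)
    if eta.size:
        t = np.maximum(0.0, eta + mu * e.c_in)
        val += float(t @ t - eta @ eta) / (2.0 * mu)
    return val


def _al_value_light(obj, c_eq, c_in, lam, eta, mu) -> float:
    val = obj
    if lam.size:
        val += float(lam @ c_eq) + 0.5 * mu * float(c_eq @ c_eq)
    if eta.size:
        t = np.maximum(0.0, eta + mu * c_in)
        val += float(t @ t - eta @ eta) / (2.0 * mu)
    return val


class _StepSolver:
    """Factorized damped Gauss-Newton model  (H + delta I + mu J^T J) d = -g
    on the free set, with an optional rank-one Schur complement for one
    structurally dense Jacobian column (the free cycle time).

    A factorization can be reused for a few chord steps with fresh gradients,
    which is where most of the solve time would otherwise go.
    """

    def __init__(self, J_all, free, mu, delta, schur_col=None, hdiag=None):
        self.ok = False
        self.free = free.copy()
        self.schur_col = schur_col
        use_schur = schur_col is not None and free[schur_col]
        self.use_schur = use_schur
        free_r = free.copy()
        if use_schur:
            free_r[schur_col] = False
        self.free_r = free_r
        self.nfree = int(np.count_nonzero(free_r))
        Jf = J_all[:, free_r].tocsc()
        self.m = Jf.shape[0]
        if hdiag is None:
            hblock = sp.eye(self.nfree) * delta
        else:
            hblock = sp.diags(delta + hdiag[free_r])
        kkt = sp.bmat([[hblock, Jf.T],
                       [Jf, -sp.eye(self.m) / mu]], format="csc")
        try:
            self.lu = spla.splu(kkt, permc_spec="MMD_ATA")
        except RuntimeError:      # pragma: no cover - singular factorization
            return
        if use_schur:
            t_col = np.asarray(J_all[:, schur_col].todense()).ravel()
            self.w = self.lu.solve(
                np.concatenate([np.zeros(self.nfree), t_col]))[:self.nfree]
            self.c_col = mu * (Jf.T @ t_col)
            h_tt = delta + mu * float(t_col @ t_col)
            if hdiag is not None:
                h_tt += hdiag[schur_col]
            self.denom = max(h_tt - float(self.c_col @ self.w), 1e-12)
        self.uses = 0
        self.ok = True

    def solve(self, g):
        self.uses += 1
        d = np.zeros_like(g)
        if not self.use_schur:
            sol = self.lu.solve(
                np.concatenate([-g[self.free_r], np.zeros(self.m)]))
            d[self.free_r] = sol[:self.nfree]
            return d
        u = self.lu.solve(
            np.concatenate([g[self.free_r], np.zeros(self.m)]))[:self.nfree]
        d_t = (-g[self.schur_col] + float(self.c_col @ u)) / self.denom
        d[self.schur_col] = d_t
        d[self.free_r] = -u - self.w * d_t
        return d


def _inner_newton(evaluate, evaluate_light, z, lam, eta, mu, lb, ub,
                  max_newton, gtol, schur_col=None):
    """Projected Newton minimization of the augmented Lagrangian with exact
    damped Gauss-Newton steps (sparse direct factorization)."""
    n_eval = 0
    delta = 1e-3                      # Levenberg damping, adapted
    e = evaluate(z)
    n_eval += 1
    solver = None                     # chord reuse of the factorization
    for _ in range(max_newton):
        g = e.grad.copy()
        if lam.size:
            g += e.J_eq.T @ (lam + mu * e.c_eq)
        active_in = None
        if eta.size:
            t = np.maximum(0.0, eta + mu * e.c_in)
            g += e.J_in.T @ t
            active_in = t > 0.0
        phi = _al_value(e, lam, eta, mu)

        at_lb = (z <= lb + 1e-12) & (g > 0)
        at_ub = (z >= ub - 1e-12) & (g < 0)
        free = ~(at_lb | at_ub)
        gfree_inf = float(np.max(np.abs(g[free]))) if free.any() else 0.0
        if gfree_inf < gtol:
            break

        if solver is None or solver.uses >= 3 or \
                not np.array_equal(solver.free, free):
            if active_in is not None and np.any(active_in):
                J_all = sp.vstack([e.J_eq, e.J_in[active_in]], format="csc")
            else:
                J_all = e.J_eq.tocsc()
            solver = _StepSolver(J_all, free, mu, delta,
                                 schur_col=schur_col, hdiag=e.hess_diag)
            if not solver.ok:          # pragma: no cover
                solver = None
        d = solver.solve(g) if solver is not None else -g * free
        if float(g @ d) >= 0.0:
            d = -g * free              # fall back to projected gradient
        dinf = float(np.max(np.abs(d))) if d.size else 0.0
        if dinf > 2.0:                 # trust-region style step cap (scaled z)
            d *= 2.0 / dinf
        # backtracking line search on the projected path
        gd = float(g @ d)
        step_ok = False
        alpha = 1.0
        for _ in range(25):
            z_try = np.clip(z + alpha * d, lb, ub)
            obj_t, ceq_t, cin_t = evaluate_light(z_try)
            n_eval += 1
            phi_t = _al_value_light(obj_t, ceq_t, cin_t, lam, eta, mu)
            if phi_t <= phi + 1e-4 * alpha * gd:
                step_ok = True
                break
            alpha *= 0.5
        if not step_ok:
            delta *= 10.0
            solver = None              # damping changed: refactorize
            if delta > 1e8:
                break
            continue
        z = z_try
        if alpha >= 0.5:
            delta = max(delta * 0.3, 1e-8)
        else:
            delta *= 2.0
        e = evaluate(z)
        n_eval += 1
    return z, e, n_eval


def solve_alm(evaluate: Callable[[np.ndarray], NLPEval],
              evaluate_light: Callable[[np.ndarray], tuple],
              z0: np.ndarray,
              bounds: np.ndarray,
              feas_tol: float = 1e-6,
              opt_tol: float = 1e-7,
              mu0: float = 100.0,
              mu_max: float = 1e8,
              max_outer: int = 40,
              inner_maxiter: int = 30,
              schur_col: Optional[int] = None,
              lam0: Optional[np.ndarray] = None,
              eta0: Optional[np.ndarray] = None,
              verbose: bool = False) -> tuple[np.ndarray, SolverStats]:
    """Minimize with equality/inequality constraints via augmented Lagrangian.

    ``evaluate`` returns a full :class:`NLPEval` (with sparse Jacobians);
    ``evaluate_light`` returns ``(obj, c_eq, c_in)`` only and is used inside
    line searches.  Non-convergence is reported in the stats, never raised,
    so callers can inspect partial solutions.
    """
    z = np.asarray(z0, dtype=float).copy()
    lb, ub = bounds[:, 0], bounds[:, 1]
    e0 = evaluate(z)
    n_eq, n_in = e0.c_eq.size, e0.c_in.size
    lam = np.zeros(n_eq) if lam0 is None else np.asarray(lam0, float).copy()
    eta = np.zeros(n_in) if eta0 is None else np.asarray(eta0, float).copy()
    mu = mu0
    stats = SolverStats()
    viol_prev = np.inf
    obj_prev = np.inf

    omega = 1e-2        # inner stationarity tolerance, tightened as the
    for outer in range(1, max_outer + 1):   # multipliers converge
        z, e, n_ev = _inner_newton(evaluate, evaluate_light, z, lam, eta, mu,
                                   lb, ub, inner_maxiter,
                                   gtol=max(omega, feas_tol * 0.1, 1e-9),
                                   schur_col=schur_col)
        omega = max(omega * 0.3, 1e-7)
        feas = float(np.max(np.abs(e.c_eq))) if n_eq else 0.0
        ineq = float(np.max(np.maximum(e.c_in, 0.0))) if n_in else 0.0
        viol = max(feas, ineq)
        stats.n_outer = outer
        stats.n_inner += n_ev
        stats.history.append((outer, float(e.obj), viol, mu, n_ev))
        if verbose:  # pragma: no cover
            print(f"[alm] outer {outer:2d} obj {e.obj: .6e} "
                  f"viol {viol:.3e} mu {mu:.1e} evals {n_ev}")
        # converged once feasible AND the objective has settled between
        # multiplier updates (feasibility alone is not stationarity)
        if viol <= feas_tol and abs(e.obj - obj_prev) <= opt_tol * max(
                1.0, abs(e.obj)):
            stats.status = "converged"
            stats.converged = True
            break
        obj_prev = float(e.obj)
        # safeguarded first-order update: accept multipliers only on
        # sufficient feasibility progress, otherwise raise the penalty
        # moderately (an exploding penalty poisons the multipliers)
        if viol <= max(feas_tol, 0.6 * viol_prev):
            if n_eq:
                lam = lam + mu * e.c_eq
            if n_in:
                eta = np.maximum(0.0, eta + mu * e.c_in)
            viol_prev = viol
        else:
            if n_eq:
                lam = lam + mu * e.c_eq
            if n_in:
                eta = np.maximum(0.0, eta + mu * e.c_in)
            mu = min(mu * 5.0, mu_max)
            viol_prev = min(viol_prev, viol)
    else:
        e = evaluate(z)
        feas = float(np.max(np.abs(e.c_eq))) if n_eq else 0.0
        if feas <= feas_tol:
            stats.status = "converged"
            stats.converged = True
            stats.message = "feasible; objective still moving at max_outer"
        else:
            stats.status = "max_outer"
            stats.message = "feasibility tolerance not reached"

    e = evaluate(z)
    stats.objective = float(e.obj)
    stats.feas_inf = float(np.max(np.abs(e.c_eq))) if n_eq else 0.0
    stats.ineq_inf = float(np.max(np.maximum(e.c_in, 0.0))) if n_in else 0.0
    stats.lam = lam
    stats.eta = eta
    return z, stats
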