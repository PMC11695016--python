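"""Synthetic gait data with known ground truth.

Everything the pipeline consumes can be generated here without any external
download: repeated gait-like trials (angles, moments, ground reaction force,
EMG envelopes) with controlled trial-to-trial variability for the statistics
modules, nominal kinematics to seed the predictive optimal-control problem,
and joint-moment datasets generated from a perturbed muscle model for
parameter-estimation recovery tests.

Baseline curves are sums of wrapped (periodic) Gaussian bumps over the 0-100%
cycle with coefficients tabulated below — qualitative normative gait shapes
(double-peaked knee flexion with a swing peak near 65 deg, double-bump
vertical GRF, burst-like EMG), not fits to any external dataset.  Trial
variability is multiplicative amplitude scaling plus a smooth periodic time
warp; kinematics carry no additive white noise (non-physiological), EMG
envelopes optionally do.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from . import dynamics as dyn
from .analysis import N_SAMPLES, PCT, GaitCurveSet
from .model import ModelSpec

# ---------------------------------------------------------------------------
# periodic curve templates: name -> (offset, [(amplitude, center %, width %)])
# ---------------------------------------------------------------------------

ANGLE_TEMPLATES_DEG = {
    # stance flexion wave ~18 deg at 15%, swing peak ~65 deg at 68%
    "knee": (3.0, [(15.0, 15.0, 9.0), (62.0, 68.0, 12.0)]),
    # hip flexed at heel strike, extended in late stance
    "hip": (-8.0, [(33.0, 90.0, 18.0), (20.0, 5.0, 14.0)]),
    # small dorsiflexion mid-stance, plantarflexion push-off/swing
    "ankle": (1.0, [(-6.0, 3.0, 4.0), (8.0, 38.0, 12.0), (-12.0, 66.0, 5.0)]),
}

MOMENT_TEMPLATES_NM_PER_KG = {
    "knee": (0.0, [(0.45, 12.0, 6.0), (-0.25, 40.0, 10.0), (-0.20, 72.0, 9.0)]),
    "hip": (0.0, [(0.9, 5.0, 8.0), (-0.8, 45.0, 12.0)]),
    "ankle": (0.02, [(-1.5, 45.0, 10.0), (-0.3, 20.0, 12.0)]),
}

GRF_TEMPLATE_BW = (0.0, [(1.05, 14.0, 9.0), (1.10, 45.0, 9.0)])

EMG_TEMPLATES = {
    "gluteus_maximus": (0.02, [(0.5, 4.0, 7.0), (0.25, 94.0, 6.0)]),
    "iliopsoas": (0.02, [(0.45, 62.0, 8.0)]),
    "hamstrings": (0.03, [(0.5, 95.0, 7.0), (0.3, 8.0, 8.0)]),
    "rectus_femoris": (0.02, [(0.35, 4.0, 6.0), (0.3, 60.0, 8.0)]),
    "vasti": (0.03, [(0.6, 10.0, 7.0)]),
    "biceps_femoris_sh": (0.03, [(0.4, 92.0, 8.0), (0.25, 25.0, 10.0)]),
    "gastrocnemius": (0.02, [(0.75, 42.0, 9.0)]),
    "soleus": (0.02, [(0.85, 44.0, 9.0)]),
    "tibialis_anterior": (0.05, [(0.55, 70.0, 9.0), (0.45, 2.0, 5.0)]),
}


def _wrapped_gaussian(s, center, width):
    d = np.mod(np.asarray(s, float) - center + 50.0, 100.0) - 50.0
    return np.exp(-0.5 * (d / width) ** 2)


def template_curve(template, s=PCT) -> np.ndarray:
    """Evaluate a (offset, bumps) template on a percent-cycle grid."""
    offset, bumps = template
    out = np.full(np.shape(s), float(offset))
    for amp, center, width in bumps:
        out = out + amp * _wrapped_gaussian(s, center, width)
    return out


@dataclass
class SyntheticGaitConfig:
    n_trials: int = 7
    seed: int = 0
    cycle_time: float = 1.1        # s
    speed: float = 1.48            # m/s
    amplitude_sd: float = 0.05     # fractional, multiplicative per trial
    timing_jitter_sd: float = 1.0  # % cycle, smooth periodic warp
    emg_noise_sd: float = 0.0      # additive, EMG envelopes only
    effect: Optional[dict] = None  # {"variable","window":(lo,hi),"offset"}
    knee_limit_deg: Optional[float] = None
    body_mass: float = 75.0        # kg, scales GRF and moments

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if min(self.amplitude_sd, self.timing_jitter_sd, self.emg_noise_sd) < 0:
            raise ValueError("variability SDs must be >= 0")
        if self.effect is not None:
            lo, hi = self.effect["window"]
            if not (0 <= lo < hi <= 100):
                raise ValueError("effect window must lie within [0, 100]")


@dataclass
class SyntheticTruth:
    """Generating parameters stored alongside every synthetic dataset."""
    config: SyntheticGaitConfig | None = None
    amplitude_factors: dict = field(default_factory=dict)
    warp_phases: dict = field(default_factory=dict)
    effect: Optional[dict] = None
    multipliers: dict = field(default_factory=dict)    # estimation datasets
    activations: Optional[np.ndarray] = None
    tendon_forces: Optional[np.ndarray] = None


def _warp_trial(base: np.ndarray, amp: float, jitter_amp: float,
                jitter_phase: float) -> np.ndarray:
    """Amplitude-scale and smoothly time-warp one periodic curve."""
    s = PCT + jitter_amp * np.sin(2.0 * np.pi * (PCT / 100.0 + jitter_phase))
    grid = np.concatenate([PCT[:-1] - 100.0, PCT[:-1], PCT[:-1] + 100.0, [200.0]])
    vals = np.concatenate([base[:-1], base[:-1], base[:-1], [base[0]]])
    spline = CubicSpline(grid, vals)
    out = amp * spline(np.mod(s, 100.0) + 0.0)
    out[-1] = out[0]    # exact periodicity at the wrap point
    return out


def generate_trials(config: SyntheticGaitConfig,
                    variables: Optional[list[str]] = None
                    ) -> tuple[dict[str, GaitCurveSet], SyntheticTruth]:
    """Repeated gait-like trials for every variable family.

    Returns curve sets keyed ``angle_<joint>``, ``moment_<joint>`` (N m),
    ``grf_vertical`` (N) and ``emg_<muscle>`` (normalized), plus the stored
    generating truth.  Periodic (first sample equals last), seeded,
    reproducible.
    """
    rng = np.random.default_rng(config.seed)
    curves: dict[str, GaitCurveSet] = {}
    truth = SyntheticTruth(config=config, effect=config.effect)

    families: list[tuple[str, np.ndarray, str]] = []
    for joint, tmpl in ANGLE_TEMPLATES_DEG.items():
        families.append((f"angle_{joint}", template_curve(tmpl), "deg"))
    for joint, tmpl in MOMENT_TEMPLATES_NM_PER_KG.items():
        families.append((f"moment_{joint}",
                         template_curve(tmpl) * config.body_mass, "N·m"))
    families.append(("grf_vertical",
                     template_curve(GRF_TEMPLATE_BW) * config.body_mass * 9.81,
                     "N"))
    for mus, tmpl in EMG_TEMPLATES.items():
        families.append((f"emg_{mus}", template_curve(tmpl), "normalized"))
    if variables is not None:
        families = [f for f in families if f[0] in variables]

    for name, base, units in families:
        if config.knee_limit_deg is not None and name == "angle_knee":
            base = _soft_limit(base, config.knee_limit_deg)
        amps = 1.0 + config.amplitude_sd * rng.standard_normal(config.n_trials)
        jit = config.timing_jitter_sd * rng.standard_normal(config.n_trials)
        phases = rng.uniform(0.0, 1.0, config.n_trials)
        trials = np.vstack([
            _warp_trial(base, amps[i], jit[i], phases[i])
            for i in range(config.n_trials)])
        if name.startswith("emg_") and config.emg_noise_sd > 0:
            noise = config.emg_noise_sd * rng.standard_normal(trials.shape)
            noise[:, -1] = noise[:, 0]
            trials = np.clip(trials + noise, 0.0, None)
        if (config.effect is not None and name == config.effect["variable"]):
            lo, hi = config.effect["window"]
            window = ((PCT >= lo) & (PCT <= hi)).astype(float)
            trials = trials + config.effect["offset"] * window
        curves[name] = GaitCurveSet(label=name, trials=trials, units=units)
        truth.amplitude_factors[name] = amps
        truth.warp_phases[name] = phases
    return curves, truth


def _soft_limit(curve: np.ndarray, limit: float, margin: float = 0.4) -> np.ndarray:
    """Smooth saturation of a curve below ``limit`` (soft minimum)."""
    x = np.asarray(curve, float)
    if np.max(x) <= limit - 5.0 * margin:
        return x.copy()
    return limit - margin * np.logaddexp(0.0, (limit - x) / margin)


def inject_skg_effect(curves: GaitCurveSet, limit_deg: float,
                      coupled: Optional[dict[str, GaitCurveSet]] = None
                      ) -> GaitCurveSet:
    """Saturate a knee-flexion curve set below ``limit_deg`` (degrees).

    Emulates the induced stiff-knee-gait phenotype: swing knee flexion capped
    smoothly at the restriction.  When ``coupled`` contains a contralateral
    knee-moment set under key ``moment_knee_cl``, an early-stance flexion-
    moment bump scaled by the severity of the restriction is added in place
    (the compensation consistently seen on the sound side).
    """
    if limit_deg <= 0:
        raise ValueError("limit_deg must be > 0")
    out = GaitCurveSet(label=curves.label,
                       trials=np.vstack([_soft_limit(t, limit_deg)
                                         for t in curves.trials]),
                       units=curves.units)
    if coupled and "moment_knee_cl" in coupled:
        cl = coupled["moment_knee_cl"]
        severity = max(0.0, 1.0 - limit_deg / 65.0)
        bump = 0.3 * severity * _wrapped_gaussian(PCT, 15.0, 8.0)
        cl.trials = cl.trials + bump * np.nanmax(np.abs(cl.trials))
    return out


# ---------------------------------------------------------------------------
# nominal kinematics for the predictive OCP initial guess
# ---------------------------------------------------------------------------

def nominal_joint_trajectories(n_points: int, cycle_time: float,
                               speed: float, pelvis_height: float
                               ) -> dict[str, np.ndarray]:
    """Smooth nominal gait kinematics on ``n_points`` samples of one cycle.

    IL curves are the templates; CL curves are phase-shifted by half a cycle.
    Angles in radians; pelvis advances at the average ``speed``.
    """
    s = np.linspace(0.0, 100.0, n_points, endpoint=False)
    d2r = math.pi / 180.0
    out = {}
    for joint, tmpl in ANGLE_TEMPLATES_DEG.items():
        out[f"{joint}_il"] = template_curve(tmpl, s) * d2r
        out[f"{joint}_cl"] = template_curve(tmpl, np.mod(s + 50.0, 100.0)) * d2r
    t = cycle_time * s / 100.0
    out["pelvis_tx"] = speed * t
    out["pelvis_ty"] = pelvis_height + 0.01 * np.cos(2 * np.pi * (2 * s) / 100.0)
    out["pelvis_tilt"] = 0.05 * np.ones_like(s)
    return out


# ---------------------------------------------------------------------------
# estimation dataset with known truth
# ---------------------------------------------------------------------------

def _activation_profiles(muscle_names, n_points, peak: float = 0.9):
    """Smooth periodic activation profiles driving each muscle near ``peak``.

    High peaks matter for strength identifiability: a moment demand close to
    a muscle's capacity pins its maximal isometric force from below.
    """
    s = np.linspace(0.0, 100.0, n_points, endpoint=False)
    profiles = {}
    for k, name in enumerate(muscle_names):
        key = name.rsplit("_", 1)[0]
        tmpl = EMG_TEMPLATES.get(key, (0.05, [(0.4, 20.0 + 15.0 * k, 10.0)]))
        prof = template_curve(tmpl, s)
        prof = prof / prof.max()
        profiles[name] = np.clip(0.03 + (peak - 0.03) * prof, 0.02, peak)
    return profiles


def generate_estimation_dataset(model: ModelSpec, truth_multipliers: dict,
                                seed: int = 0, n_points: int = 60,
                                cycle_time: float = 1.1,
                                drive_peak: float = 0.6):
    """Joint-moment trials achievable exactly by a perturbed muscle model.

    ``truth_multipliers`` maps muscle name -> {"f_max_iso": r, ...} scaling of
    the generic parameters.  ``drive_peak`` sets the peak of the generating
    activation profiles; drive close to maximal makes strength multipliers
    identifiable from below (demand near capacity).  Smooth activation profiles drive the perturbed
    model's implicit Hill dynamics along nominal hip kinematics; the integrated
    tendon-force trajectories give joint moments that the perturbed model can
    reproduce with zero reserve actuation.  Returns (times, q, qdot, moments
    per joint, SyntheticTruth).
    """
    import copy as _copy

    from .model import MuscleTendonParams

    muscles = [m for m in model.muscles_on("il") if "hip_il" in m.arms]
    if not muscles:
        raise ValueError("model has no IL hip muscles")
    for name, mult in truth_multipliers.items():
        for key, r in mult.items():
            if not 0.0 < r:
                raise ValueError("multipliers must be positive")
            if not 0.5 <= r <= 2.0:
                import warnings
                warnings.warn(f"{name}.{key} multiplier {r} outside the "
                              "estimation bounds [0.5, 2]: truth is not "
                              "recoverable", stacklevel=2)

    t = np.linspace(0.0, cycle_time, n_points, endpoint=False)
    s = 100.0 * t / cycle_time
    d2r = math.pi / 180.0
    q = template_curve(ANGLE_TEMPLATES_DEG["hip"], s) * d2r
    omega = 2.0 * np.pi / cycle_time
    # periodic spectral derivative via cubic spline of the wrapped curve
    grid = np.concatenate([t, [cycle_time]])
    vals = np.concatenate([q, [q[0]]])
    spl = CubicSpline(grid, vals, bc_type="periodic")
    qdot = spl(t, 1)

    profiles = _activation_profiles([m.name for m in muscles], n_points,
                                    peak=drive_peak)
    a = np.vstack([profiles[m.name] for m in muscles])

    perturbed = []
    for m in muscles:
        p = m.params
        mult = truth_multipliers.get(m.name, {})
        perturbed.append(MuscleTendonParams(
            f_max_iso=p.f_max_iso * mult.get("f_max_iso", 1.0),
            l_opt=p.l_opt * mult.get("l_opt", 1.0),
            l_ts=p.l_ts * mult.get("l_ts", 1.0),
            alpha_opt=p.alpha_opt, v_max=p.v_max))

    # Construct exactly-consistent implicit Hill trajectories: tendon forces
    # from pointwise static equilibrium under the target profiles, then the
    # activations that satisfy the dynamic residual with the actual tendon
    # force rate (closed form: the residual is affine in activation).
    ft = np.zeros((len(muscles), n_points))
    dft = np.zeros_like(ft)
    for k, (m, p) in enumerate(zip(muscles, perturbed)):
        r0, r1 = m.arms["hip_il"]
        l_ref = m.l_ref   # geometry unchanged by parameter scaling
        lmt = l_ref - (r0 * q + 0.5 * r1 * q * q)
        vmt = -(r0 + r1 * q) * qdot
        ft[k] = dyn.equilibrium_f_tilde(a[k], lmt, p, vmt)
        spl_f = CubicSpline(np.concatenate([t, [cycle_time]]),
                            np.concatenate([ft[k], [ft[k, 0]]]),
                            bc_type="periodic")
        ft[k] = spl_f(t)
        dft[k] = spl_f(t, 1)
        a[k] = _activation_from_residual(ft[k], dft[k], lmt, vmt, p)

    moments = np.zeros(n_points)
    for k, m in enumerate(muscles):
        r0, r1 = m.arms["hip_il"]
        mult = truth_multipliers.get(m.name, {})
        fmax = m.params.f_max_iso * mult.get("f_max_iso", 1.0)
        moments += (r0 + r1 * q) * ft[k] * fmax

    truth = SyntheticTruth(multipliers=_copy.deepcopy(truth_multipliers),
                           activations=a, tendon_forces=ft)
    return t, q, qdot, {"hip_il": moments}, truth


def _activation_from_residual(ft, dft, lmt, vmt, p):
    """Activation satisfying the implicit Hill residual given all else.

    residual = (a*fl*fv + fp + beta*v)*cos_alpha - f_tilde is affine in a.
    """
    lf, cos_a, l_norm = dyn.fiber_state(ft, lmt, p)
    vf = dyn.fiber_velocity(ft, dft, lmt, vmt, p)
    v_norm = vf / (p.v_max * p.l_opt)
    fl = dyn.active_force_length(l_norm)
    fv = dyn.force_velocity(v_norm)
    fp = dyn.passive_force_length(l_norm)
    a = (ft / cos_a - fp - dyn._BETA_DAMP * v_norm) / (fl * fv)
    return np.clip(a, 0.0, 1.0)
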