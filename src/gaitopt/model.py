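"""Musculoskeletal model variants for predictive gait simulation.

The default model is a bilateral sagittal-plane linkage: a single
head-arms-trunk (HAT) segment carrying the pelvis translation (x, y) and tilt,
plus hip/knee/ankle pin joints per leg, nine Hill-type muscles per leg, and
two foot-ground contact spheres per foot.  Variant operations transform a
scaled healthy model into the study conditions: knee-disarticulation amputee
with a variable-damping microprocessor knee (MPK) and an
energy-storage-and-return (ESR) prosthetic foot, the hypothetical-healthy
mirror of the amputee, the flexion-limiting knee orthosis, and stiff-knee-gait
(SKG) passive-limit restrictions.

Sides are tagged ``il`` (ipsilateral: prosthetic/orthosis side) and ``cl``
(contralateral).  Angles are radians internally; config files use degrees.
"""
from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import yaml

D2R = math.pi / 180.0

SIDES = ("il", "cl")


class ModelValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SegmentSpec:
    name: str
    mass: float           # kg
    length: float         # m
    com_offset: float     # m from proximal joint
    inertia_zz: float     # kg m^2 about COM, sagittal axis

    def __post_init__(self):
        if self.mass < 0:
            raise ModelValidationError(f"segment {self.name}: mass < 0")
        if self.length <= 0:
            raise ModelValidationError(f"segment {self.name}: length <= 0")
        if not (0.0 <= self.com_offset <= self.length):
            raise ModelValidationError(
                f"segment {self.name}: com_offset outside [0, length]")


@dataclass
class PassiveMomentParams:
    """Exponential joint-limit moment with damping and optional linear spring.

    M(q, qdot) = k1*exp(-k2*(q - q_lower)) - k1*exp(k2*(q - q_upper))
                 - b*qdot - k_lin*q
    """
    k1: float = 0.0        # N m
    k2: float = 0.0        # 1/rad
    q_lower: float = -1.0  # rad
    q_upper: float = 1.0   # rad
    b: float = 0.0         # N m s / rad
    k_lin: float = 0.0     # N m / rad (MTP / ESR spring; else 0)

    def __post_init__(self):
        if min(self.k1, self.k2, self.b, self.k_lin) < 0:
            raise ModelValidationError("passive moment coefficients must be >= 0")
        if not self.q_lower < self.q_upper:
            raise ModelValidationError("passive moment requires q_lower < q_upper")


@dataclass
class JointSpec:
    name: str
    kind: str              # {"pin", "translation"}
    parent: str
    child: str
    range: tuple[float, float]   # rad (or m for translations)
    locked: bool = False
    passive: Optional[PassiveMomentParams] = None

    def __post_init__(self):
        if self.kind not in ("pin", "translation"):
            raise ModelValidationError(f"joint {self.name}: bad kind {self.kind}")
        if not self.range[0] < self.range[1]:
            raise ModelValidationError(f"joint {self.name}: range lower >= upper")


@dataclass
class ContactSphereSpec:
    segment: str
    location: tuple[float, float]  # m, in segment frame
    radius: float                  # m
    stiffness: float               # N m^-3/2
    dissipation: float             # s/m
    mu: float                      # friction coefficient
    v_t: float                     # m/s, friction smoothing velocity

    def __post_init__(self):
        if self.radius <= 0 or self.stiffness <= 0:
            raise ModelValidationError("contact sphere needs radius, stiffness > 0")
        if self.dissipation < 0 or self.mu < 0:
            raise ModelValidationError("contact dissipation and mu must be >= 0")


@dataclass
class MuscleTendonParams:
    f_max_iso: float   # N
    l_opt: float       # m, optimal fiber length
    l_ts: float        # m, tendon slack length
    alpha_opt: float   # rad, pennation at optimal fiber length
    v_max: float       # optimal fiber lengths / s

    def __post_init__(self):
        if min(self.f_max_iso, self.l_opt, self.l_ts, self.v_max) <= 0:
            raise ModelValidationError("muscle-tendon parameters must be > 0")
        if not 0 <= self.alpha_opt < math.pi / 2:
            raise ModelValidationError("alpha_opt must lie in [0, pi/2)")


@dataclass
class MuscleSpec:
    """One musculotendon actuator with polynomial path geometry.

    ``arms`` maps joint name -> (r0, r1): moment arm r(q) = r0 + r1*q.  The
    musculotendon length is l_ref - sum_j (r0*q_j + r1*q_j^2/2), which makes
    r = -dl/dq exact by construction.
    """
    name: str
    params: MuscleTendonParams
    arms: dict[str, tuple[float, float]]
    l_ref: float    # m, musculotendon length at the neutral pose

    @property
    def spanned_joints(self) -> list[str]:
        return list(self.arms)


@dataclass
class ProsthesisSpec:
    d_mpk: float                       # N m s / rad, damper coefficient
    mpk_passive: PassiveMomentParams   # hyperextension stop + flexion limit
    tau_mpk: float                     # s, MPK activation time constant
    esr_passive: PassiveMomentParams   # prosthetic ankle (ESR) elasticity
    shank_mass: float                  # kg
    foot_mass: float                   # kg

    def __post_init__(self):
        if self.d_mpk < 0:
            raise ModelValidationError("d_mpk must be >= 0")
        if self.tau_mpk <= 0:
            raise ModelValidationError("tau_mpk must be > 0")


@dataclass
class ModelSpec:
    segments: dict[str, SegmentSpec]
    joints: dict[str, JointSpec]
    muscles: list[MuscleSpec]
    contacts: list[ContactSphereSpec]
    variant: str                        # healthy|amputee|hypothetical_healthy|orthosis
    body_mass: float                    # kg, configured total
    height: float                       # m
    gravity: float = 9.81
    prosthesis: Optional[ProsthesisSpec] = None
    pelvis_ty_range: tuple[float, float] = (0.6, 1.2)
    pelvis_tilt_range: tuple[float, float] = (-0.6, 0.6)

    def total_segment_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def muscles_on(self, side: str) -> list[MuscleSpec]:
        return [m for m in self.muscles if m.name.endswith("_" + side)]

    def coordinate_names(self) -> list[str]:
        names = ["pelvis_tx", "pelvis_ty", "pelvis_tilt"]
        for side in SIDES:
            names += [f"hip_{side}", f"knee_{side}", f"ankle_{side}"]
        return names

    def validate(self) -> None:
        if abs(self.total_segment_mass() - self.body_mass) > 1e-9:
            raise ModelValidationError(
                f"segment masses sum to {self.total_segment_mass():.12g} kg, "
                f"configured body mass is {self.body_mass:.12g} kg")
        for m in self.muscles:
            for j in m.spanned_joints:
                if j not in self.joints:
                    raise ModelValidationError(
                        f"muscle {m.name} spans unknown joint {j}")
                if self.joints[j].locked:
                    raise ModelValidationError(
                        f"muscle {m.name} spans locked joint {j}")
        if self.variant == "amputee":
            if self.prosthesis is None:
                raise ModelValidationError("amputee variant requires a prosthesis")
            for m in self.muscles_on("il"):
                bad = {j for j in m.spanned_joints
                       if j in (f"knee_il", f"ankle_il")}
                if bad:
                    raise ModelValidationError(
                        f"amputee IL muscle {m.name} spans {sorted(bad)}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_default_config() -> dict:
    text = resources.files("gaitopt").joinpath("data/reference_model.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _passive_from_cfg(cfg: dict) -> PassiveMomentParams:
    return PassiveMomentParams(
        k1=float(cfg.get("k1", 0.0)), k2=float(cfg.get("k2", 0.0)),
        q_lower=float(cfg.get("q_lower_deg", -60.0)) * D2R,
        q_upper=float(cfg.get("q_upper_deg", 60.0)) * D2R,
        b=float(cfg.get("b", 0.0)), k_lin=float(cfg.get("k_lin", 0.0)))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_reference_model(mass: float, height: float,
                          config: Optional[dict] = None) -> ModelSpec:
    """Build the scaled bilateral healthy model.

    Segment lengths scale with ``height`` and masses with ``mass`` relative to
    the reference anthropometry table; muscle-tendon lengths scale with height
    and maximal isometric forces with mass.  The HAT segment absorbs the
    rounding residual so the segment masses sum to ``mass`` exactly.
    """
    if mass <= 0 or height <= 0:
        raise ModelValidationError("mass and height must be > 0")
    cfg = _merge(load_default_config(), config or {})
    hs = height / float(cfg["reference"]["height"])
    ms = mass / float(cfg["reference"]["mass"])

    segs: dict[str, SegmentSpec] = {}

    def mk_seg(name: str, key: str, m_kg: float) -> SegmentSpec:
        sc = cfg["segments"][key]
        length = float(sc["length_frac"]) * height
        return SegmentSpec(name=name, mass=m_kg, length=length,
                           com_offset=float(sc["com_frac"]) * length,
                           inertia_zz=m_kg * (float(sc["rog_frac"]) * length) ** 2)

    leg_masses = {k: float(cfg["segments"][k]["mass_frac"]) * mass
                  for k in ("thigh", "shank", "foot")}
    hat_mass = mass - 2.0 * sum(leg_masses.values())
    segs["hat"] = mk_seg("hat", "hat", hat_mass)
    for side in SIDES:
        for key in ("thigh", "shank", "foot"):
            segs[f"{key}_{side}"] = mk_seg(f"{key}_{side}", key, leg_masses[key])

    joints: dict[str, JointSpec] = {}
    parent_of = {"hip": "hat", "knee": "thigh", "ankle": "shank"}
    child_of = {"hip": "thigh", "knee": "shank", "ankle": "foot"}
    for side in SIDES:
        for jname in ("hip", "knee", "ankle"):
            jc = cfg["joints"][jname]
            lo, hi = (float(x) * D2R for x in jc["range_deg"])
            joints[f"{jname}_{side}"] = JointSpec(
                name=f"{jname}_{side}", kind="pin",
                parent=parent_of[jname] if jname == "hip" else f"{parent_of[jname]}_{side}",
                child=f"{child_of[jname]}_{side}",
                range=(lo, hi), passive=_passive_from_cfg(jc["passive"]))

    muscles: list[MuscleSpec] = []
    for side in SIDES:
        for mname, mc in cfg["muscles"].items():
            params = MuscleTendonParams(
                f_max_iso=float(mc["f_max_iso"]) * ms,
                l_opt=float(mc["l_opt"]) * hs,
                l_ts=float(mc["l_ts"]) * hs,
                alpha_opt=float(mc["alpha_opt_deg"]) * D2R,
                v_max=float(mc["v_max"]))
            arms = {f"{j}_{side}": (float(a[0]) * hs, float(a[1]) * hs)
                    for j, a in mc["arms"].items()}
            l_ref = params.l_ts + params.l_opt * math.cos(params.alpha_opt)
            muscles.append(MuscleSpec(name=f"{mname}_{side}", params=params,
                                      arms=arms, l_ref=l_ref))

    contacts: list[ContactSphereSpec] = []
    for side in SIDES:
        for cc in cfg["contacts"].values():
            contacts.append(ContactSphereSpec(
                segment=f"foot_{side}",
                location=(float(cc["location"][0]) * hs, float(cc["location"][1]) * hs),
                radius=float(cc["radius"]), stiffness=float(cc["stiffness"]),
                dissipation=float(cc["dissipation"]), mu=float(cc["mu"]),
                v_t=float(cc["v_t"])))

    tilt = tuple(float(x) * D2R for x in cfg["pelvis"]["tilt_range_deg"])
    model = ModelSpec(segments=segs, joints=joints, muscles=muscles,
                      contacts=contacts, variant="healthy", body_mass=mass,
                      height=height, gravity=float(cfg["gravity"]),
                      pelvis_ty_range=tuple(float(x) for x in cfg["pelvis"]["ty_range"]),
                      pelvis_tilt_range=tilt)
    model.validate()
    return model


def prosthesis_from_config(model: ModelSpec, config: Optional[dict] = None,
                           d_mpk: Optional[float] = None) -> ProsthesisSpec:
    """Default prosthesis sized against ``model``'s intact IL segments."""
    cfg = _merge(load_default_config(), config or {})["prosthesis"]
    ratio = float(cfg["mass_ratio"])
    return ProsthesisSpec(
        d_mpk=float(d_mpk if d_mpk is not None else cfg["d_mpk"]),
        mpk_passive=_passive_from_cfg(cfg["mpk_passive"]),
        tau_mpk=float(cfg["tau_mpk"]),
        esr_passive=_passive_from_cfg(cfg["esr_passive"]),
        shank_mass=ratio * model.segments["shank_il"].mass,
        foot_mass=ratio * model.segments["foot_il"].mass)


def apply_amputation(model: ModelSpec, prosthesis: ProsthesisSpec) -> ModelSpec:
    """Knee-disarticulation on the IL side.

    The IL knee becomes the MPK degree of freedom, the IL ankle becomes the
    passive ESR foot, IL shank/foot masses are replaced by the prosthetic
    component masses, and only the hip-spanning IL muscles are retained (their
    path geometry truncated at the hip, since the anatomical knee is gone).
    """
    if model.variant != "healthy":
        raise ModelValidationError("apply_amputation requires a healthy model")
    if prosthesis is None:
        raise ModelValidationError("apply_amputation requires a prosthesis")
    out = copy.deepcopy(model)
    out.variant = "amputee"
    out.prosthesis = copy.deepcopy(prosthesis)

    for seg, m_new in (("shank_il", prosthesis.shank_mass),
                       ("foot_il", prosthesis.foot_mass)):
        s = out.segments[seg]
        scale = m_new / s.mass if s.mass > 0 else 1.0
        s.mass = m_new
        s.inertia_zz *= scale
    out.body_mass = out.total_segment_mass()

    out.joints["knee_il"].passive = copy.deepcopy(prosthesis.mpk_passive)
    out.joints["ankle_il"].passive = copy.deepcopy(prosthesis.esr_passive)

    kept: list[MuscleSpec] = []
    for m in out.muscles:
        if not m.name.endswith("_il"):
            kept.append(m)
            continue
        if "hip_il" not in m.arms:
            continue
        m2 = copy.deepcopy(m)
        m2.arms = {"hip_il": m.arms["hip_il"]}
        kept.append(m2)
    out.muscles = kept
    out.validate()
    return out


def mirror_to_hypothetical_healthy(model: ModelSpec, healthy_mass: float) -> ModelSpec:
    """Mirror the CL side over the IL side of an amputee model.

    Produces the hypothetical unimpaired twin: bilaterally symmetric, no
    prosthesis, total mass set to ``healthy_mass`` by uniform mass scaling
    (the intact limbs outweigh the prosthesis, so the mass goes up).
    """
    if model.variant != "amputee":
        raise ModelValidationError("mirroring requires an amputee model")
    if healthy_mass <= model.body_mass:
        warnings.warn("healthy_mass <= amputee mass: intact limbs normally "
                      "weigh more than the prosthesis", stacklevel=2)
    out = copy.deepcopy(model)
    out.variant = "hypothetical_healthy"
    out.prosthesis = None

    for key in ("thigh", "shank", "foot"):
        out.segments[f"{key}_il"] = copy.deepcopy(out.segments[f"{key}_cl"])
        out.segments[f"{key}_il"].name = f"{key}_il"
    for jname in ("hip", "knee", "ankle"):
        cl = out.joints[f"{jname}_cl"]
        out.joints[f"{jname}_il"] = JointSpec(
            name=f"{jname}_il", kind=cl.kind, parent=cl.parent.replace("_cl", "_il"),
            child=cl.child.replace("_cl", "_il"), range=cl.range, locked=cl.locked,
            passive=copy.deepcopy(cl.passive))
    out.muscles = [m for m in out.muscles if not m.name.endswith("_il")]
    for m in model.muscles_on("cl"):
        m2 = copy.deepcopy(m)
        m2.name = m.name[:-3] + "_il"
        m2.arms = {j.replace("_cl", "_il"): a for j, a in m.arms.items()}
        out.muscles.append(m2)
    out.contacts = [c for c in out.contacts if c.segment.endswith("_cl")]
    for c in model.contacts:
        if c.segment.endswith("_cl"):
            c2 = copy.deepcopy(c)
            c2.segment = c.segment.replace("_cl", "_il")
            out.contacts.append(c2)

    scale = healthy_mass / out.total_segment_mass()
    for s in out.segments.values():
        s.mass *= scale
        s.inertia_zz *= scale
    out.body_mass = healthy_mass
    # absorb floating-point residue in the HAT segment
    out.segments["hat"].mass += healthy_mass - out.total_segment_mass()
    out.validate()
    return out


def apply_skg_condition(model: ModelSpec, limit_deg: float) -> ModelSpec:
    """Restrict the IL knee (or MPK) passive flexion limit to ``limit_deg``."""
    if not 0.0 < limit_deg <= 137.5:
        raise ModelValidationError("SKG limit must lie in (0, 137.5] degrees")
    out = copy.deepcopy(model)
    p = out.joints["knee_il"].passive
    if p is None:
        raise ModelValidationError("IL knee has no passive moment to restrict")
    out.joints["knee_il"].passive = replace(p, q_upper=limit_deg * D2R)
    if out.prosthesis is not None:
        out.prosthesis.mpk_passive = replace(out.prosthesis.mpk_passive,
                                             q_upper=limit_deg * D2R)
    out.validate()
    return out


def apply_orthosis(model: ModelSpec, limit_deg: float,
                   thigh_mass_add: float, shank_mass_add: float) -> ModelSpec:
    """Flexion-limiting knee orthosis on the IL side of a healthy model."""
    if model.variant != "healthy":
        raise ModelValidationError("apply_orthosis requires a healthy model")
    if thigh_mass_add < 0 or shank_mass_add < 0:
        raise ModelValidationError("orthosis masses must be >= 0")
    out = apply_skg_condition(model, limit_deg)
    out.variant = "orthosis" if (thigh_mass_add or shank_mass_add
                                 or limit_deg < 137.5) else model.variant
    out.segments["thigh_il"].mass += thigh_mass_add
    out.segments["shank_il"].mass += shank_mass_add
    out.body_mass = out.total_segment_mass()
    out.validate()
    return out


def build_amputee_model(mass: float, height: float,
                        config: Optional[dict] = None,
                        d_mpk: Optional[float] = None) -> ModelSpec:
    """Build the knee-disarticulation model at a target total mass.

    ``mass`` is the mass of the amputee wearing the prosthesis; the intact
    base mass is back-computed from the prosthetic mass ratio so the amputee
    model hits ``mass`` exactly.
    """
    cfg = _merge(load_default_config(), config or {})
    ratio = float(cfg["prosthesis"]["mass_ratio"])
    repl = sum(float(cfg["segments"][k]["mass_frac"]) for k in ("shank", "foot"))
    base_mass = mass / (1.0 - (1.0 - ratio) * repl)
    healthy = build_reference_model(base_mass, height, config)
    pros = prosthesis_from_config(healthy, config, d_mpk=d_mpk)
    out = apply_amputation(healthy, pros)
    return out
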