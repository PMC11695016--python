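# gaitopt

Predictive simulation of prosthetic and stiff-knee gait on a planar
musculoskeletal model, with the muscle-tendon parameter estimation and the
gait-curve statistics that surround it.

`gaitopt` is aimed at biomechanics researchers who want a self-contained,
fully inspectable pipeline for *predictive* (non-tracking) gait: given only a
model and a target walking speed, it generates periodic gait by optimal
control, and then asks how that gait changes when the model changes — a
variable-damping microprocessor prosthetic knee (MPK) set to a different
damping, or a passive flexion limit that induces stiff-knee gait (SKG).

## What it computes

**Predictive gait (optimal control).** The model is a bilateral
sagittal-plane linkage (pelvis x/y + trunk tilt, hip/knee/ankle per leg, nine
Hill-type muscles per leg; for the knee-disarticulation variant the
prosthetic side keeps only its hip muscles and carries an MPK with damper
moment `T_MPK = a_MPK · D_MPK · q̇` plus an elastic energy-storage-and-return
foot). The program finds periodic state/control trajectories minimizing

    J = (1/Dist) ∫ [ w₁ Σa² + w₂ Ė² + w₃ Σq̈² + w₄ Σ(ȧ² + Ḟ̃²) + w₅ e²_MPK ] dt

subject to implicit Hill muscle-tendon dynamics, activation dynamics,
Hunt–Crossley foot-ground contact inside the equations of motion, periodicity
of all states except the pelvis forward position, and an imposed average
speed `Dist = v·T` with the cycle time `T` free. Transcription is third-order
Radau direct collocation; the resulting sparse NLP is solved by an
augmented-Lagrangian method with exact AD Jacobians and direct sparse Newton
steps (see `docs/methods.md`).

**Muscle-tendon personalization.** A muscle-redundancy optimal-control
problem reproduces hip joint moments exactly while scaling each hip muscle's
maximal isometric force, optimal fiber length and tendon slack length within
[50%, 200%] of generic values, minimizing
`∫ Σ(w_E1 a² + w_E2 L_opt + w_E3 Re² + w_E4 (ȧ² + Ḟ̃²)) dt`
with reserve actuators `Re` as heavily penalized slack.

**Statistics.** Nonparametric (sign-flip permutation) 1D SPM paired t-tests
over whole 101-sample gait curves with family-wise control via the
permutation distribution of max|t|; dynamic-time-warping similarity scores
with a 5% Sakoe–Chiba band on curves normalized to [−1, 1]; gait-cycle
normalization from vertical-GRF heel strikes; peak metrics.

**Synthetic data.** Everything the pipeline needs is generated on the fly
with stored ground truth: repeated gait-like trials with controlled
variability, nominal kinematics for initial guesses, and exactly-achievable
joint-moment datasets for estimation recovery tests.

## Worked example

```python
from gaitopt import model, ocp

# knee-disarticulation model at the measured 68.5 kg, 1.78 m
amputee = model.build_amputee_model(68.5, 1.78)           # REF damping 1.0
dact    = model.build_amputee_model(68.5, 1.78, d_mpk=0.75)

spec = ocp.PredictionProblemSpec(target_speed=1.48,
                                 grid=ocp.CollocationGrid(8))
ref  = ocp.predict_gait(spec, amputee)
alt  = ocp.predict_gait(spec, dact, warm_from=ref)        # same basin

for name, r in (("REF", ref), ("DACT", alt)):
    knee = r.gait_curves()["knee_il"]
    print(f"{name}: T={r.T:.3f} s  speed={r.dist/r.T:.4f} m/s  "
          f"swing knee peak={knee[40:].max():.1f} deg")
```

prints (8 mesh intervals, exact numbers depend on the mesh):

```
REF: T=0.876 s  speed=1.4800 m/s  swing knee peak=72.7 deg
DACT: T=0.894 s  speed=1.4800 m/s  swing knee peak=75.2 deg
```

Both solutions walk at exactly the imposed 1.48 m/s (it is a hard constraint;
the cycle time is free), and lowering the knee damper from 1.0 to
0.75 N·m·s/rad lets the prosthetic knee swing ≈2.5° further — the
deactivated-prosthesis effect. Applying `model.apply_skg_condition(amputee,
14.9)` instead caps the passive flexion limit and the predicted swing peak
collapses (≈36° at this mesh), the induced stiff-knee gait.

The same models feed the statistics: `synthetic.generate_trials` produces
repeated noisy condition trials, `analysis.spm_paired_nonparametric` locates
the significantly different cycle regions, and `analysis.dtw_matrix` scores
curve similarity per muscle with NaN for muscles missing on the amputated
side.

A `gaitopt` command-line tool wraps the stages
(`synth`, `estimate-params`, `predict`, `analyze-spm`, `analyze-dtw`, `run`),
writing every artifact plus a manifest with the config hash and seed into a
run directory.

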