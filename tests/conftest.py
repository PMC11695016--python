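"""Shared fixtures.

The predictive-gait solves are by far the most expensive objects in the
suite, so they are computed once per session at a small mesh and shared:
the reference amputee prediction is solved cold (with contact continuation),
and the condition variants (altered damping, stiff-knee limits) are re-solved
warm-started from it, which both saves time and keeps the comparisons within
one optimization basin.
"""
import numpy as np
import pytest

from gaitopt import model as gmodel, ocp, synthetic as syn

MESH = 8
SPEED = 1.48


@pytest.fixture(scope="session")
def healthy_model():
    return gmodel.build_reference_model(77.8, 1.81)


@pytest.fixture(scope="session")
def amputee_model():
    return gmodel.build_amputee_model(68.5, 1.78)


@pytest.fixture(scope="session")
def prediction_spec():
    return ocp.PredictionProblemSpec(
        target_speed=SPEED, grid=ocp.CollocationGrid(MESH),
        inner_maxiter=25, max_outer=20)


@pytest.fixture(scope="session")
def ref_prediction(amputee_model, prediction_spec):
    return ocp.predict_gait(prediction_spec, amputee_model)


@pytest.fixture(scope="session")
def dact_prediction(ref_prediction, prediction_spec):
    model = gmodel.build_amputee_model(68.5, 1.78, d_mpk=0.75)
    return ocp.predict_gait(prediction_spec, model, warm_from=ref_prediction)


@pytest.fixture(scope="session")
def skg_predictions(amputee_model, ref_prediction, prediction_spec):
    """SKG35 then SKG15, warm-started along the tightening limit."""
    out = {}
    prior = ref_prediction
    for name, limit in (("SKG35", 35.0), ("SKG15", 14.9)):
        model = gmodel.apply_skg_condition(amputee_model, limit)
        prior = ocp.predict_gait(prediction_spec, model, warm_from=prior)
        out[name] = prior
    return out


@pytest.fixture(scope="session")
def estimation_dataset(amputee_model):
    """Known-truth dataset: one muscle's maximal isometric force at 150%."""
    truth = {"iliopsoas_il": {"f_max_iso": 1.5}}
    t, q, qd, moments, stored = syn.generate_estimation_dataset(
        amputee_model, truth, seed=0, drive_peak=0.9)
    return {"times": t, "q": q, "qdot": qd, "moments": moments["hip_il"],
            "truth": truth, "stored": stored}


@pytest.fixture(scope="session")
def estimation_results(amputee_model, estimation_dataset):
    d = estimation_dataset
    free_spec = ocp.EstimationProblemSpec(
        times=d["times"], q=d["q"], qdot=d["qdot"], moments=d["moments"],
        grid=ocp.CollocationGrid(12, t_f=1.1))
    fixed_spec = ocp.EstimationProblemSpec(
        times=d["times"], q=d["q"], qdot=d["qdot"], moments=d["moments"],
        grid=ocp.CollocationGrid(12, t_f=1.1), fix_params=True)
    return {"free": ocp.estimate_parameters(free_spec, amputee_model),
            "fixed": ocp.estimate_parameters(fixed_spec, amputee_model)}


def swing_knee_peak(result):
    curves = result.gait_curves()
    return float(np.max(curves["knee_il"][40:]))
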