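"""Synthetic gait data generator: determinism, periodicity, stored truth."""
import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from gaitopt import dynamics as dyn
from gaitopt import synthetic as syn
from gaitopt.model import MuscleTendonParams


class TestGenerateTrials:
    def test_zero_variability_gives_identical_trials(self):
        cfg = syn.SyntheticGaitConfig(n_trials=4, seed=7, amplitude_sd=0.0,
                                      timing_jitter_sd=0.0)
        curves, _ = syn.generate_trials(cfg)
        for cs in curves.values():
            assert np.allclose(cs.trials, cs.trials[0][None, :])

    def test_same_seed_reproduces_exactly(self):
        cfg = syn.SyntheticGaitConfig(n_trials=5, seed=42)
        a, _ = syn.generate_trials(cfg)
        b, _ = syn.generate_trials(cfg)
        for k in a:
            assert np.array_equal(a[k].trials, b[k].trials)

    def test_curves_are_periodic_and_smooth_at_wrap(self):
        cfg = syn.SyntheticGaitConfig(n_trials=3, seed=1)
        curves, _ = syn.generate_trials(cfg)
        for cs in curves.values():
            assert np.array_equal(cs.trials[:, 0], cs.trials[:, -1])
            # first-difference continuity across the wrap point
            d_end = cs.trials[:, -1] - cs.trials[:, -2]
            d_start = cs.trials[:, 1] - cs.trials[:, 0]
            scale = np.abs(cs.trials).max() + 1e-9
            assert np.all(np.abs(d_end - d_start) / scale < 0.05)

    def test_swing_peak_sampling_distribution(self):
        """With 5% amplitude SD, the mean of trial knee swing peaks over many
        trials matches the template peak within three standard errors."""
        cfg = syn.SyntheticGaitConfig(n_trials=200, seed=3, amplitude_sd=0.05,
                                      timing_jitter_sd=0.0)
        curves, _ = syn.generate_trials(cfg, variables=["angle_knee"])
        template_peak = float(np.max(syn.template_curve(
            syn.ANGLE_TEMPLATES_DEG["knee"])))
        peaks = curves["angle_knee"].trials.max(axis=1)
        se = peaks.std(ddof=1) / np.sqrt(peaks.size)
        assert abs(peaks.mean() - template_peak) < 3.0 * se

    def test_grf_has_double_bump_and_emg_bursts(self):
        cfg = syn.SyntheticGaitConfig(n_trials=1, seed=0, amplitude_sd=0.0,
                                      timing_jitter_sd=0.0)
        curves, _ = syn.generate_trials(cfg)
        grf = curves["grf_vertical"].trials[0]
        stance = grf[:60]
        # two local maxima separated by a valley
        peaks = [i for i in range(1, 59)
                 if stance[i] > stance[i - 1] and stance[i] > stance[i + 1]
                 and stance[i] > 0.5 * stance.max()]
        assert len(peaks) == 2
        sol = curves["emg_soleus"].trials[0]
        assert sol.max() > 5.0 * np.median(sol)

    def test_effect_injection_is_confined_to_window(self):
        """Pointwise mean difference outside the effect window vanishes over
        many seeds."""
        diffs = []
        for seed in range(25):
            cfg0 = syn.SyntheticGaitConfig(n_trials=5, seed=seed)
            cfg1 = syn.SyntheticGaitConfig(
                n_trials=5, seed=seed,
                effect={"variable": "angle_knee", "window": (40.0, 60.0),
                        "offset": 10.0})
            a, _ = syn.generate_trials(cfg0, variables=["angle_knee"])
            b, _ = syn.generate_trials(cfg1, variables=["angle_knee"])
            diffs.append(b["angle_knee"].trials.mean(0)
                         - a["angle_knee"].trials.mean(0))
        diffs = np.array(diffs)
        inside = (syn.PCT >= 40) & (syn.PCT <= 60)
        assert np.allclose(diffs[:, ~inside], 0.0, atol=1e-9)
        assert np.all(diffs[:, inside].mean(axis=0) > 9.0)


class TestInjectSKG:
    def make(self, seed=0):
        cfg = syn.SyntheticGaitConfig(n_trials=4, seed=seed)
        curves, _ = syn.generate_trials(cfg, variables=["angle_knee"])
        return curves["angle_knee"]

    def test_limit_caps_curve_with_small_margin(self):
        out = syn.inject_skg_effect(self.make(), 20.0)
        assert out.trials.max() <= 21.0

    def test_limit_above_peak_is_noop(self):
        curves = self.make()
        out = syn.inject_skg_effect(curves, 130.0)
        assert np.allclose(out.trials, curves.trials, atol=1e-4)

    def test_idempotent_within_smoothing_margin(self):
        # the saturation is smooth, so re-application only moves samples
        # inside the ~0.4 deg blending band below the limit
        once = syn.inject_skg_effect(self.make(), 25.0)
        twice = syn.inject_skg_effect(once, 25.0)
        assert np.allclose(twice.trials, once.trials, atol=0.45)
        far = once.trials < 20.0
        assert np.allclose(twice.trials[far], once.trials[far], atol=1e-6)

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            syn.inject_skg_effect(self.make(), 0.0)

    def test_contralateral_moment_coupling(self):
        cfg = syn.SyntheticGaitConfig(n_trials=3, seed=2)
        curves, _ = syn.generate_trials(cfg, variables=["moment_knee"])
        cl = curves["moment_knee"]
        before = cl.trials.copy()
        syn.inject_skg_effect(self.make(), 15.0,
                              coupled={"moment_knee_cl": cl})
        early = (syn.PCT >= 5) & (syn.PCT <= 25)
        assert np.all((cl.trials - before)[:, early].mean() > 0.0)


class TestEstimationDataset:
    def test_identity_multipliers_keep_generic_model_feasible(
            self, amputee_model):
        t, q, qd, moments, truth = syn.generate_estimation_dataset(
            amputee_model, {}, seed=0)
        assert truth.multipliers == {}
        assert np.all(truth.activations >= 0.0)
        assert np.all(truth.activations <= 1.0)

    def test_moments_recomputed_from_stored_truth(self, amputee_model,
                                                  estimation_dataset):
        d = estimation_dataset
        muscles = [m for m in amputee_model.muscles_on("il")
                   if "hip_il" in m.arms]
        rec = np.zeros_like(d["times"])
        for k, m in enumerate(muscles):
            r0, r1 = m.arms["hip_il"]
            mult = d["truth"].get(m.name, {})
            fmax = m.params.f_max_iso * mult.get("f_max_iso", 1.0)
            rec += (r0 + r1 * d["q"]) * d["stored"].tendon_forces[k] * fmax
        assert np.max(np.abs(rec - d["moments"])) < 1e-9

    def test_stored_truth_satisfies_implicit_hill_dynamics(
            self, amputee_model, estimation_dataset):
        d = estimation_dataset
        muscles = [m for m in amputee_model.muscles_on("il")
                   if "hip_il" in m.arms]
        cycle = 1.1
        worst = 0.0
        for k, m in enumerate(muscles):
            mult = d["truth"].get(m.name, {})
            p = MuscleTendonParams(
                f_max_iso=m.params.f_max_iso * mult.get("f_max_iso", 1.0),
                l_opt=m.params.l_opt, l_ts=m.params.l_ts,
                alpha_opt=m.params.alpha_opt, v_max=m.params.v_max)
            r0, r1 = m.arms["hip_il"]
            lmt = m.l_ref - (r0 * d["q"] + 0.5 * r1 * d["q"] ** 2)
            vmt = -(r0 + r1 * d["q"]) * d["qdot"]
            ft = d["stored"].tendon_forces[k]
            spl = CubicSpline(np.concatenate([d["times"], [cycle]]),
                              np.concatenate([ft, [ft[0]]]),
                              bc_type="periodic")
            res = dyn.hill_equilibrium_residual(
                d["stored"].activations[k], ft, spl(d["times"], 1), lmt, vmt,
                p)
            worst = max(worst, float(np.max(np.abs(res))))
        assert worst < 1e-9

    def test_strength_multiplier_scales_moment_linearly(self, amputee_model):
        """At fixed tendon-force trajectories, a muscle's moment contribution
        is linear in its maximal isometric force."""
        m = next(mm for mm in amputee_model.muscles_on("il")
                 if mm.name.startswith("iliopsoas"))
        r0, r1 = m.arms["hip_il"]
        q = 0.3
        ft = 0.4
        base = (r0 + r1 * q) * ft * m.params.f_max_iso
        scaled = (r0 + r1 * q) * ft * (1.5 * m.params.f_max_iso)
        assert scaled == pytest.approx(1.5 * base, rel=1e-14)
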