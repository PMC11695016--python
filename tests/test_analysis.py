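"""Gait-curve statistics: cycle cutting, permutation SPM, DTW, peaks."""
import itertools

import numpy as np
import pytest

from gaitopt import analysis as ana
from gaitopt import synthetic as syn


def make_set(trials):
    return ana.GaitCurveSet(label="x", trials=np.asarray(trials, float))


# ---------------------------------------------------------------------------
# gait-cycle normalization
# ---------------------------------------------------------------------------

class TestNormalizeGaitCycle:
    def test_constructed_crossing_detected_within_one_sample(self):
        t = np.linspace(0.0, 1.0, 1001)
        grf = np.zeros_like(t)
        ramp = (t >= 0.217) & (t <= 0.317)
        grf[ramp] = (t[ramp] - 0.217) * 1000.0    # crosses 20 N at t=0.237
        grf[t > 0.317] = 100.0
        events = ana.detect_heel_strikes(t, grf, threshold=20.0)
        assert abs(events[0] - 0.237) <= 1e-3

    def test_constant_signal_stays_constant(self):
        t = np.linspace(0.0, 3.0, 3001)
        grf = 400.0 * np.clip(np.sin(2 * np.pi * t), 0.0, None)
        out = ana.normalize_gait_cycle(t, {"c": np.full_like(t, 4.2)}, grf)
        assert np.allclose(out["c"].trials, 4.2, atol=1e-9)

    def test_cycles_resampled_to_101_points(self):
        t = np.linspace(0.0, 2.5, 2500)
        grf = 400.0 * np.clip(np.sin(2 * np.pi * t), 0.0, None)
        sig = np.cos(2 * np.pi * t)
        out = ana.normalize_gait_cycle(t, {"s": sig}, grf)
        assert out["s"].trials.shape[1] == 101
        assert out["s"].n_trials >= 1

    def test_missing_crossing_is_reported(self):
        t = np.linspace(0.0, 1.0, 100)
        with pytest.raises(ValueError, match="heel-strike"):
            ana.normalize_gait_cycle(t, {"s": t}, np.zeros_like(t))


# ---------------------------------------------------------------------------
# SPM
# ---------------------------------------------------------------------------

def brute_force_spm_threshold(diffs, alpha):
    """Exhaustive sign-flip enumeration, written independently of the
    implementation (explicit loops)."""
    n = diffs.shape[0]
    maxima = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        d = np.array(signs)[:, None] * diffs
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t[~np.isfinite(t)] = 0.0
        maxima.append(np.max(np.abs(t)))
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


class TestSPM:
    def test_identical_sets_never_reject(self):
        a = make_set(np.random.default_rng(0).normal(size=(5, 101)))
        res = ana.spm_paired_nonparametric(a, a)
        assert np.allclose(res.t_curve, 0.0)
        assert res.clusters == []

    def test_exhaustive_enumeration_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        a = make_set(rng.normal(size=(3, 101)))
        b = make_set(rng.normal(size=(3, 101)))
        res = ana.spm_paired_nonparametric(a, b, alpha=0.25)
        oracle = brute_force_spm_threshold(a.trials - b.trials, 0.25)
        assert res.t_crit == pytest.approx(oracle, rel=1e-12)
        assert res.n_perm == 8

    def test_relabeling_negates_t_and_keeps_threshold(self):
        rng = np.random.default_rng(6)
        a = make_set(rng.normal(size=(6, 101)))
        b = make_set(rng.normal(size=(6, 101)))
        r_ab = ana.spm_paired_nonparametric(a, b)
        r_ba = ana.spm_paired_nonparametric(b, a)
        assert np.allclose(r_ab.t_curve, -r_ba.t_curve)
        assert r_ab.t_crit == pytest.approx(r_ba.t_crit, rel=1e-12)

    def test_unequal_trial_counts_rejected(self):
        a = make_set(np.zeros((4, 101)))
        b = make_set(np.zeros((5, 101)))
        with pytest.raises(ValueError):
            ana.spm_paired_nonparametric(a, b)

    def test_resolution_limit_warns(self):
        a = make_set(np.random.default_rng(0).normal(size=(3, 101)))
        b = make_set(np.random.default_rng(1).normal(size=(3, 101)))
        with pytest.warns(UserWarning, match="cannot"):
            ana.spm_paired_nonparametric(a, b, alpha=0.05)

    def test_injected_offset_is_detected_reliably(self):
        """A constant offset of 3x the pointwise noise SD over 20% of the
        cycle yields a cluster overlapping the window in nearly every
        repetition at n = 7."""
        base_cfg = syn.SyntheticGaitConfig(n_trials=7, seed=0)
        curves, _ = syn.generate_trials(base_cfg, variables=["angle_knee"])
        sd = float(curves["angle_knee"].trials.std(axis=0).mean())
        hits = 0
        reps = 25
        for i in range(reps):
            cfg_a = syn.SyntheticGaitConfig(n_trials=7, seed=100 + 2 * i)
            cfg_b = syn.SyntheticGaitConfig(
                n_trials=7, seed=101 + 2 * i,
                effect={"variable": "angle_knee", "window": (30.0, 50.0),
                        "offset": 3.0 * sd})
            a, _ = syn.generate_trials(cfg_a, variables=["angle_knee"])
            b, _ = syn.generate_trials(cfg_b, variables=["angle_knee"])
            res = ana.spm_paired_nonparametric(a["angle_knee"],
                                               b["angle_knee"])
            hits += any(lo <= 50.0 and hi >= 30.0
                        for lo, hi in res.clusters)
        assert hits / reps >= 0.9


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

def unbanded_dtw_oracle(x, y):
    """Plain full-window dynamic program, loops only."""
    n = len(x)
    acc = np.full((n, n), np.inf)
    acc[0, 0] = abs(x[0] - y[0])
    for i in range(n):
        for j in range(n):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = abs(x[i] - y[j]) + best
    return acc[-1, -1]


class TestDTW:
    def test_identical_curves_score_exactly_zero(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 101))
        assert ana.dtw_score(x, x).score == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 101))
        assert ana.dtw_score(x, y).score == pytest.approx(
            ana.dtw_score(y, x).score, rel=1e-12)

    def test_small_monotone_retiming_matches_unbanded_oracle(self):
        # bump with a flat top: duplicating one sample and deleting one
        # plateau sample is a zero-cost monotone re-timing within the band
        x = np.minimum(np.sin(np.linspace(0, np.pi, 101)) ** 2, 0.8)
        assert x[52] == x[53]               # on the plateau
        y = np.concatenate([x[:20], [x[20]], x[20:52], x[53:]])
        assert y.size == x.size
        banded = ana.dtw_score(x, y, window_frac=0.05).score
        oracle = unbanded_dtw_oracle(x, y)
        assert banded == pytest.approx(oracle, abs=1e-12)
        assert banded == pytest.approx(0.0, abs=1e-12)

    def test_score_nonincreasing_in_window(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 60))
        scores = [ana.dtw_score(x, y, w).score
                  for w in (0.02, 0.05, 0.2, 1.0)]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_band_restricts_alignment(self):
        x = np.zeros(101)
        x[20] = 1.0
        y = np.zeros(101)
        y[40] = 1.0                          # 20% shift: outside the 5% band
        narrow = ana.dtw_score(x, y, window_frac=0.05).score
        wide = ana.dtw_score(x, y, window_frac=0.5).score
        assert narrow > wide

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ana.dtw_score(np.zeros(101), np.zeros(100))


class TestDTWNormalization:
    def test_division_by_set_absolute_maximum(self):
        curves = [np.array([40.0, -80.0, 10.0]), np.array([5.0, 0.0, 2.0])]
        normed, const = ana.normalize_curves_for_dtw(curves)
        assert const == 80.0
        assert normed[0][0] == pytest.approx(0.5)
        for c in normed:
            assert np.all(np.abs(c) <= 1.0)

    def test_idempotent(self):
        curves = [np.array([1.0, -2.0]), np.array([0.5, 0.25])]
        once, _ = ana.normalize_curves_for_dtw(curves)
        twice, const2 = ana.normalize_curves_for_dtw(once)
        assert const2 == pytest.approx(1.0)
        assert all(np.allclose(a, b) for a, b in zip(once, twice))

    def test_all_zero_set_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            normed, const = ana.normalize_curves_for_dtw([np.zeros(5)])
        assert const == 1.0


class TestDTWMatrix:
    def test_self_comparison_is_zero_and_missing_is_nan(self):
        rng = np.random.default_rng(11)
        c = rng.normal(size=101)
        sets = {"vasti": {"A": c, "B": c},
                "gastrocnemius": {"A": None, "B": c}}
        df = ana.dtw_matrix(sets, [("A", "B", "A_vs_B")])
        assert df.loc["vasti", "A_vs_B"] == 0.0
        assert np.isnan(df.loc["gastrocnemius", "A_vs_B"])

    def test_grouped_curve_dominates_components(self):
        rng = np.random.default_rng(12)
        long_head = rng.uniform(0, 1, 101)
        short_head = rng.uniform(0, 1, 101)
        grouped = ana.grouped_curve([long_head, short_head])
        assert np.all(grouped >= long_head)
        assert np.all(grouped >= short_head)
        assert np.all((grouped == long_head) | (grouped == short_head))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ana.dtw_matrix({}, [("A", "B", "x")])


# ---------------------------------------------------------------------------
# peak metrics
# ---------------------------------------------------------------------------

class TestPeakMetrics:
    def test_triangular_bump(self):
        curve = np.zeros(101)
        curve[60:81] = np.concatenate([np.linspace(0, 5, 11)[:-1],
                                       np.linspace(5, 0, 11)])
        value, timing = ana.peak_metrics(curve)
        assert value == pytest.approx(5.0, abs=1e-9)
        assert timing == pytest.approx(70.0, abs=1e-9)

    def test_constant_curve_ties_break_to_window_start(self):
        value, timing = ana.peak_metrics(np.full(101, 2.5), window=(20, 80))
        assert value == 2.5
        assert timing == 20.0

    def test_refined_peak_matches_dense_resampling_oracle(self):
        from scipy.interpolate import CubicSpline
        s = np.arange(101.0)
        curve = np.sin(2 * np.pi * (s - 13.37) / 101.0)
        value, timing = ana.peak_metrics(curve)
        dense = np.linspace(0, 100, 100001)
        oracle_t = dense[np.argmax(CubicSpline(s, curve)(dense))]
        assert abs(timing - oracle_t) < 0.5

    def test_empty_or_bad_window_rejected(self):
        with pytest.raises(ValueError):
            ana.peak_metrics(np.zeros(101), window=(80, 20))
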