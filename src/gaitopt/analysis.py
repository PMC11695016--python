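"""Gait-curve statistics: cycle normalization, 1D SPM, DTW, peak metrics.

Curves live on the canonical 0-100% gait-cycle grid (101 samples, heel strike
at 0%).  Between-condition differences of repeated trials are tested with a
nonparametric (sign-flip permutation) paired t statistic over the whole
curve, controlling the family-wise error through the permutation distribution
of the curve maximum of |t|.  Single predicted curves are compared with a
dynamic-time-warping score under a Sakoe-Chiba band (default 5% of the
cycle), computed on curves jointly normalized to [-1, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

N_SAMPLES = 101
PCT = np.arange(N_SAMPLES, dtype=float)


@dataclass
class GaitCurveSet:
    """Repeated trials of one gait variable on the 0-100% cycle grid."""
    label: str
    trials: np.ndarray          # (n_trials, 101)
    units: str = ""

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[1] != N_SAMPLES:
            raise ValueError(f"{self.label}: expected {N_SAMPLES} samples per "
                             f"trial, got {self.trials.shape[1]}")
        if self.trials.shape[0] < 1:
            raise ValueError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)


@dataclass
class SPMResult:
    t_curve: np.ndarray                 # 101 paired t statistics
    t_crit: float
    clusters: list[tuple[float, float]]  # [start%, end%] suprathreshold runs
    alpha: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


@dataclass
class DTWResult:
    score: float
    window_frac: float
    normalization: float     # constant the curves were divided by (1 if none)


# ---------------------------------------------------------------------------
# gait-cycle normalization
# ---------------------------------------------------------------------------

def detect_heel_strikes(time: np.ndarray, grf_vertical: np.ndarray,
                        threshold: float = 20.0) -> np.ndarray:
    """Times of upward crossings of the vertical GRF through ``threshold``."""
    time = np.asarray(time, float)
    f = np.asarray(grf_vertical, float)
    below = f[:-1] < threshold
    above = f[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        raise ValueError("no heel-strike crossing found in vertical GRF channel")
    frac = (threshold - f[idx]) / (f[idx + 1] - f[idx])
    return time[idx] + frac * (time[idx + 1] - time[idx])


def normalize_gait_cycle(time: np.ndarray, signals: Mapping[str, np.ndarray],
                         grf_vertical: np.ndarray, threshold: float = 20.0,
                         units: Optional[Mapping[str, str]] = None
                         ) -> dict[str, GaitCurveSet]:
    """Cut signals into gait cycles at heel strike and resample to 101 points.

    Heel strike is the upward crossing of the vertical GRF through
    ``threshold`` (N).  Each cycle between successive strikes is resampled by
    cubic interpolation onto 0..100% of the cycle.
    """
    time = np.asarray(time, float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    events = detect_heel_strikes(time, grf_vertical, threshold)
    if events.size < 2:
        raise ValueError("need at least two heel strikes to form a gait cycle")
    out: dict[str, GaitCurveSet] = {}
    for name, sig in signals.items():
        sig = np.asarray(sig, float)
        spline = CubicSpline(time, sig)
        cycles = []
        for t0, t1 in zip(events[:-1], events[1:]):
            ts = t0 + (t1 - t0) * PCT / 100.0
            cycles.append(spline(ts))
        out[name] = GaitCurveSet(label=name, trials=np.vstack(cycles),
                                 units=(units or {}).get(name, ""))
    return out


# ---------------------------------------------------------------------------
# nonparametric 1D SPM (paired)
# ---------------------------------------------------------------------------

def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Pointwise paired t; nodes where every difference is zero get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[float, float]]:
    edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    return [(float(s), float(e)) for s, e in zip(starts, ends)]


def spm_paired_nonparametric(set_a: GaitCurveSet, set_b: GaitCurveSet,
                             alpha: float = 0.05, n_perm_cap: int = 10_000,
                             seed: int = 0) -> SPMResult:
    """Permutation-based paired t test over the whole gait curve.

    The null distribution of the curve maximum of |t| is built from sign
    flips of the trial differences: exhaustively (all 2^n) when feasible,
    otherwise from a seeded random subsample of ``n_perm_cap`` sign patterns
    that always includes the identity.  The critical threshold is the
    (1 - alpha) quantile; clusters are the maximal runs where |t| exceeds it.
    Two-tailed by construction (the statistic is |t|).
    """
    if set_a.n_trials != set_b.n_trials:
        raise ValueError("paired test requires equal trial counts")
    n = set_a.n_trials
    if n < 2:
        raise ValueError("paired test requires at least 2 trials")
    diffs = set_a.trials - set_b.trials
    t_obs = _paired_t(diffs)

    if 2.0 ** n * alpha < 1.0:
        warnings.warn(f"2^{n} permutations cannot resolve alpha={alpha}: "
                      "the test can never reject", stacklevel=2)
    if 2 ** n <= n_perm_cap:
        bits = np.arange(2 ** n, dtype=np.uint32)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm_cap - 1, n))
        signs = np.vstack([np.ones(n), signs])
    n_perm = signs.shape[0]

    # |t| is invariant to a global sign flip and d_i^2 is sign-invariant,
    # so only the signed mean varies across permutations.
    sum_sq = np.sum(diffs ** 2, axis=0)
    means = signs @ diffs / n
    var = (sum_sq - n * means ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm[~np.isfinite(t_perm)] = 0.0
    maxima = np.max(np.abs(t_perm), axis=1)
    t_crit = float(np.quantile(maxima, 1.0 - alpha, method="higher"))

    mask = np.abs(t_obs) > t_crit
    return SPMResult(t_curve=t_obs, t_crit=t_crit,
                     clusters=_clusters_from_mask(mask),
                     alpha=alpha, n_perm=n_perm)


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def normalize_curves_for_dtw(curves: Sequence[np.ndarray]
                             ) -> tuple[list[np.ndarray], float]:
    """Divide every curve by the single max |value| over the whole set.

    Returns the normalized curves (values in [-1, 1]) and the constant used.
    An all-zero set is returned unchanged with a warning.
    """
    curves = [np.asarray(c, float) for c in curves]
    peak = max((np.max(np.abs(c)) for c in curves), default=0.0)
    if peak == 0.0:
        warnings.warn("all-zero curve set: skipping DTW normalization",
                      stacklevel=2)
        return [c.copy() for c in curves], 1.0
    return [c / peak for c in curves], float(peak)


def dtw_score(x: np.ndarray, y: np.ndarray, window_frac: float = 0.05,
              normalization: float = 1.0) -> DTWResult:
    """Banded DTW alignment cost between two equal-length curves.

    Dynamic programming with a Sakoe-Chiba band of half-width
    ``ceil(window_frac * N)`` (temporal shifting restricted to that fraction
    of the series), endpoints pinned, cost = accumulated |x_i - y_j| over the
    optimal path.  Zero iff the curves are identical.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dtw_score requires two equal-length 1D curves")
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must lie in (0, 1]")
    n = x.size
    w = max(1, int(np.ceil(window_frac * n)))
    big = np.inf
    acc = np.full((n, n), big)
    dist = np.abs(x[:, None] - y[None, :])
    acc[0, 0] = dist[0, 0]
    for i in range(n):
        jlo, jhi = max(0, i - w), min(n - 1, i + w)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            best = big
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = dist[i, j] + best
    return DTWResult(score=float(acc[n - 1, n - 1]), window_frac=window_frac,
                     normalization=normalization)


def grouped_curve(components: Sequence[np.ndarray]) -> np.ndarray:
    """Grouped-muscle curve: pointwise maximum over the component curves."""
    return np.max(np.vstack([np.asarray(c, float) for c in components]), axis=0)


def dtw_matrix(activation_sets: Mapping[str, Mapping[str, Optional[np.ndarray]]],
               comparisons: Sequence[tuple[str, str, str]],
               window_frac: float = 0.05) -> pd.DataFrame:
    """DTW scores per (muscle, comparison) as a muscles x comparisons table.

    ``activation_sets[muscle][label]`` is a 101-sample activation curve or
    ``None`` when the muscle does not exist in that model (e.g. on the
    amputated side); such entries become NaN.  Each comparison's two curves
    are jointly normalized to [-1, 1] before scoring.
    """
    if not activation_sets:
        raise ValueError("empty activation set")
    rows = {}
    for muscle, curves in activation_sets.items():
        row = {}
        for la, lb, name in comparisons:
            ca = curves.get(la)
            cb = curves.get(lb)
            if ca is None or cb is None:
                row[name] = np.nan
                continue
            (na, nb), const = normalize_curves_for_dtw([ca, cb])
            row[name] = dtw_score(na, nb, window_frac, const).score
        rows[muscle] = row
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[c[2] for c in comparisons])


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def peak_metrics(curve: np.ndarray, window: tuple[float, float] = (0.0, 100.0)
                 ) -> tuple[float, float]:
    """(peak value, peak timing in % cycle) over a phase window.

    The discrete maximum is refined by a parabola through its neighbors; ties
    break toward the earlier sample.
    """
    curve = np.asarray(curve, float)
    lo, hi = window
    if not (0 <= lo <= 100 and 0 <= hi <= 100 and lo < hi):
        raise ValueError("window must be a nonempty subinterval of [0, 100]")
    i0, i1 = int(np.ceil(lo)), int(np.floor(hi))
    seg = curve[i0:i1 + 1]
    if seg.size == 0:
        raise ValueError("empty window")
    k = int(np.argmax(seg)) + i0       # argmax takes the first maximum
    if 0 < k < curve.size - 1:
        y0, y1, y2 = curve[k - 1], curve[k], curve[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:                   # strict local max: refine
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                return (float(y1 - 0.25 * (y0 - y2) * delta), float(k + delta))
    return float(curve[k]), float(k)
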