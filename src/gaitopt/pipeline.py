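"""End-to-end pipeline: synthetic data -> estimation -> prediction -> analysis.

Each stage writes plain-text artifacts into the run directory and registers
them in ``manifest.json`` together with the config hash, the seed and solver
statistics, so a run is reproducible from its manifest alone.
"""
from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__, analysis, model as gmodel, ocp, synthetic as syn
from .io import RunConfig, TimeSeriesTable, write_storage

STAGES = ("synth", "estimate", "predict", "analyze")


class StageDependencyError(RuntimeError):
    pass


def _curves_to_csv(curves: analysis.GaitCurveSet, path: Path) -> None:
    df = pd.DataFrame(curves.trials.T,
                      columns=[f"trial_{i}" for i in range(curves.n_trials)])
    df.insert(0, "percent_cycle", analysis.PCT)
    df.to_csv(path, index=False)


def _load_curves_csv(path: Path) -> analysis.GaitCurveSet:
    df = pd.read_csv(path)
    trials = df.drop(columns=["percent_cycle"]).to_numpy().T
    return analysis.GaitCurveSet(label=path.stem, trials=trials)


def run_pipeline(config: RunConfig, stages: Optional[Iterable[str]] = None
                 ) -> Path:
    """Execute the requested stages in dependency order; returns the run
    directory (created under ``config.output_dir``)."""
    stages = list(stages) if stages is not None else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    manifest.update({"config_digest": config.digest(),
                     "seed": config.seed,
                     "version": __version__,
                     "config": config.to_dict()})
    manifest.setdefault("stages", {})

    scfg = config.synthetic
    mass = float(config.model.get("mass", 68.5))
    height = float(config.model.get("height", 1.78))
    speed = float(config.condition.get("speed", 1.48))

    if "synth" in stages:
        sdir = out / "synth"
        sdir.mkdir(exist_ok=True)
        files = []
        for label, limit in (("REF", None),
                             ("SKG", float(scfg.get("knee_limit_deg", 20.0)))):
            cfg = syn.SyntheticGaitConfig(
                n_trials=int(scfg.get("n_trials", 5)),
                seed=int(config.seed),
                amplitude_sd=float(scfg.get("amplitude_sd", 0.05)),
                timing_jitter_sd=float(scfg.get("timing_jitter_sd", 1.0)),
                knee_limit_deg=limit, body_mass=mass, speed=speed)
            curves, _ = syn.generate_trials(cfg)
            for name, cs in curves.items():
                p = sdir / f"{label}_{name}.csv"
                _curves_to_csv(cs, p)
                files.append(str(p.relative_to(out)))
        manifest["stages"]["synth"] = {"files": files}

    if "estimate" in stages:
        edir = out / "estimate"
        edir.mkdir(exist_ok=True)
        am = gmodel.build_amputee_model(mass, height)
        mults = {k: dict(v) for k, v in
                 scfg.get("truth_multipliers",
                          {"iliopsoas_il": {"f_max_iso": 1.5}}).items()}
        t, q, qd, moments, truth = syn.generate_estimation_dataset(
            am, mults, seed=config.seed,
            drive_peak=float(scfg.get("drive_peak", 0.9)))
        espec = ocp.EstimationProblemSpec(
            times=t, q=q, qdot=qd, moments=moments["hip_il"],
            grid=ocp.CollocationGrid(int(config.ocp.get("estimation_mesh", 12)),
                                     t_f=1.1))
        res = ocp.estimate_parameters(espec, am)
        (edir / "parameters.json").write_text(json.dumps({
            "multipliers": {k: {kk: float(x) for kk, x in v.items()}
                            for k, v in res.multipliers.items()},
            "truth": mults,
            "reserve_rms": res.reserve_rms,
            "objective": res.objective,
            "converged": res.converged}, indent=2))
        manifest["stages"]["estimate"] = {
            "converged": res.converged,
            "reserve_rms": res.reserve_rms,
            "outer_iterations": res.solver_stats.n_outer}

    if "predict" in stages:
        pdir = out / "predict"
        pdir.mkdir(exist_ok=True)
        n_mesh = int(config.ocp.get("prediction_mesh", 8))
        conditions = list(config.condition.get(
            "roster", ["REF", "DACT", "SKG15", "SKG30", "SKG35"]))
        spec = ocp.PredictionProblemSpec(
            target_speed=speed, grid=ocp.CollocationGrid(n_mesh),
            max_outer=int(config.ocp.get("max_outer", 20)),
            inner_maxiter=int(config.ocp.get("inner_maxiter", 25)))
        base = gmodel.build_amputee_model(mass, height)
        results = {}
        prior = None
        for cond in conditions:
            if cond == "REF":
                m = base
            elif cond == "DACT":
                m = gmodel.build_amputee_model(mass, height, d_mpk=0.75)
            elif cond.startswith("SKG"):
                limit = {"SKG15": 14.9, "SKG30": 30.0, "SKG35": 35.0}[cond]
                m = gmodel.apply_skg_condition(base, limit)
            else:
                raise ValueError(f"unknown condition {cond!r}")
            res = ocp.predict_gait(spec, m, warm_from=prior)
            prior = prior or res
            results[cond] = res
            curves = res.gait_curves()
            df = pd.DataFrame({"time": np.linspace(0, res.T, 101)})
            for name, vals in curves.items():
                df[name] = vals
            write_storage(TimeSeriesTable(data=df, name=f"P-KD_{cond}"),
                          pdir / f"P-KD_{cond}_states.sto")
        manifest["stages"]["predict"] = {
            cond: {"converged": r.converged, "T": r.T, "dist": r.dist,
                   "speed": r.dist / r.T,
                   "objective": r.objective,
                   "feasibility": r.solver_stats.feas_inf,
                   "outer_iterations": r.solver_stats.n_outer}
            for cond, r in results.items()}

    if "analyze" in stages:
        adir = out / "analyze"
        adir.mkdir(exist_ok=True)
        sdir = out / "synth"
        if not sdir.exists():
            raise StageDependencyError("analyze requires the synth stage: "
                                       "run stages=['synth'] first")
        alpha = float(config.analysis.get("alpha", 0.05))
        spm_rows = []
        for var in ("angle_knee", "moment_knee", "emg_rectus_femoris"):
            a = _load_curves_csv(sdir / f"REF_{var}.csv")
            b = _load_curves_csv(sdir / f"SKG_{var}.csv")
            res = analysis.spm_paired_nonparametric(a, b, alpha=alpha,
                                                    seed=config.seed)
            spm_rows.append({"variable": var, "t_crit": res.t_crit,
                             "n_clusters": len(res.clusters),
                             "clusters": json.dumps(res.clusters),
                             "n_perm": res.n_perm})
        pd.DataFrame(spm_rows).to_csv(adir / "spm_ref_vs_skg.csv", index=False)

        # DTW similarity of REF vs SKG mean curves per variable
        rows = {}
        for var in ("angle_knee", "angle_hip", "angle_ankle"):
            a = _load_curves_csv(sdir / f"REF_{var}.csv").mean()
            b = _load_curves_csv(sdir / f"SKG_{var}.csv").mean()
            (na, nb), const = analysis.normalize_curves_for_dtw([a, b])
            rows[var] = {"REF_vs_SKG": analysis.dtw_score(na, nb).score}
        pd.DataFrame(rows).T.to_csv(adir / "dtw_ref_vs_skg.csv")
        manifest["stages"]["analyze"] = {
            "spm": str((adir / "spm_ref_vs_skg.csv").relative_to(out)),
            "dtw": str((adir / "dtw_ref_vs_skg.csv").relative_to(out))}

    manifest["completed_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    return out
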