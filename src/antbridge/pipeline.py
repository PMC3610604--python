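"""End-to-end recipe runner: synth -> fit -> calibrate -> sweeps -> analysis.

Each stage is a named function writing its outputs under the run
directory; a recipe is an ordered list of stage names.  Stages share one
master seed (each stage derives its own stream from it), never mutate
their inputs, and can be resumed: with ``resume=True`` a stage whose
outputs already exist is skipped.  A stage failure halts the pipeline
with the failing stage named.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .io import write_table, write_trace

__all__ = ["run_pipeline", "STAGES"]


def _stage_seed(seed: int, stage: str) -> int:
    # stable per-stage stream derived from the master seed
    h = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % 2**31])
    return int(h.generate_state(1)[0] % 2**31)


def _synth(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .synthetic import (generate_perturbation_trace,
                            generate_removal_experiment, generate_trail_trace)
    joins, residence, sizes = generate_removal_experiment(
        params=cfg["params"], gap_length=cfg["simulation"]["gap_length"],
        lambda_range=(0.25, 4.0), n_events=2000, seed=seed)
    trace = generate_trail_trace(seed=seed)
    series, initial_n = generate_perturbation_trace(
        params=cfg["params"], gap_length=cfg["simulation"]["gap_length"],
        seed=seed)
    paths = [out / "join_events.csv", out / "residence.csv",
             out / "bridge_size.csv", out / "trail_trace.csv",
             out / "perturbation.csv"]
    write_table(joins, paths[0])
    write_table(residence, paths[1])
    write_table(sizes, paths[2])
    write_trace(trace, paths[3])
    pert = pd.DataFrame({"time": np.arange(len(series)), "value": series})
    pert.attrs = {"initial_n": initial_n}
    write_table(pert, paths[4])
    return paths


def _fit(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .io import read_table
    from .model_core import fit_join_sigmoid, fit_residence_exponential
    joins = read_table(out / "join_events.csv")
    residence = read_table(out / "residence.csv")
    jf = fit_join_sigmoid(joins, seed=seed)
    rf = fit_residence_exponential(residence)
    path = out / "fits.json"
    path.write_text(json.dumps({
        "join": {"alpha": jf.alpha, "beta": jf.beta, "gamma": jf.gamma,
                 "theta": jf.theta, "residual": jf.residual},
        "residence": {"rho": rf.rho, "sigma": rf.sigma,
                      "residual": rf.residual},
        "seed": seed,
    }, indent=2) + "\n")
    return [path]


def _calibrate(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .io import read_table
    from .model_core import calibrate_share_params
    sizes = read_table(out / "bridge_size.csv")
    target = sizes.groupby("time")["bridge_size"].mean().to_numpy()
    res = calibrate_share_params(
        target, gap_length=cfg["simulation"]["gap_length"],
        params=cfg["params"], reps=50, seed=seed,
        phi_grid=np.linspace(-2.0, 0.0, 5),
        psi_grid=np.linspace(0.5, 5.0, 5),
        omega_grid=np.linspace(0.5, 4.0, 5))
    path = out / "calibration.json"
    path.write_text(json.dumps({
        "phi": res.phi, "psi": res.psi, "omega": res.omega,
        "mse_ants2": res.mse, "rmse_ants": res.rmse, "seed": seed,
    }, indent=2) + "\n")
    return [path]


def _sweep_poisson(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .simulator import poisson_sweep
    table = poisson_sweep(
        lambdas=np.round(np.arange(0.1, 4.0 + 1e-9, 0.1), 3),
        reps=min(int(cfg["simulation"]["reps"]), 200),
        duration=int(cfg["simulation"]["duration"]),
        gap_length=cfg["simulation"]["gap_length"],
        params=cfg["params"], seed=seed)
    path = out / "poisson_sweep.csv"
    write_table(table, path)
    return [path]


def _sweep_oscillation(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .simulator import oscillation_sweep
    res = oscillation_sweep(
        periods=np.arange(1, 21), intensities=[0.5, 1.0],
        reps=min(int(cfg["simulation"]["reps"]), 200),
        gap_length=cfg["simulation"]["gap_length"],
        max_rate=cfg["simulation"]["max_rate"],
        params=cfg["params"], seed=seed)
    res.table.attrs = {"argmax_period": res.argmax_period}
    paths = [out / "oscillation_sweep.csv", out / "oscillation_matrix.csv"]
    write_table(res.table, paths[0])
    res.matrix.to_csv(paths[1])
    return paths


def _analysis(cfg: dict, out: Path, seed: int) -> list[Path]:
    from .io import read_table, read_trace
    from .signal_analysis import block_cross_correlation, lomb_scargle
    from .simulator import replay_perturbation
    trace = read_trace(out / "trail_trace.csv")
    pcfg = cfg["periodogram"]
    pg = lomb_scargle(trace, fmin=pcfg["fmin"], fmax=pcfg["fmax"],
                      oversample=int(pcfg["oversample"]),
                      fap_threshold=pcfg["fap_threshold"])
    pert = read_table(out / "perturbation.csv")
    series = pert["value"].to_numpy()
    initial_n = int(pert.attrs.get("initial_n", 0))
    sizes = replay_perturbation(series, initial_n,
                                gap_length=cfg["simulation"]["gap_length"],
                                params=cfg["params"], reps=100, seed=seed)
    lc = block_cross_correlation(series, sizes.mean(axis=0),
                                 block=int(cfg["xcorr"]["block"]))
    path = out / "analysis.json"
    path.write_text(json.dumps({
        "dominant_period": pg.dominant_period,
        "dominant_frequency": pg.dominant_frequency,
        "replay_max_r": lc.max_r,
        "replay_argmax_lag": lc.argmax_lag,
        "seed": seed,
    }, indent=2) + "\n")
    return [path]


STAGES: dict[str, Callable[[dict, Path, int], list[Path]]] = {
    "synth": _synth,
    "fit": _fit,
    "calibrate": _calibrate,
    "sweep-poisson": _sweep_poisson,
    "sweep-oscillation": _sweep_oscillation,
    "analysis": _analysis,
}


def run_pipeline(
    stages: list[str],
    cfg: dict,
    out_dir: Path,
    seed: int = 0,
    resume: bool = False,
) -> dict[str, list[Path]]:
    """Execute the named stages in order under ``out_dir``.

    Returns stage -> written paths.  Raises ``RuntimeError`` naming the
    failing stage on error; unknown stage names fail before anything runs.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {unknown}; "
                         f"available: {sorted(STAGES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[Path]] = {}
    for stage in stages:
        marker = out_dir / f".{stage}.done"
        if resume and marker.exists():
            outputs[stage] = [Path(p) for p in
                              marker.read_text().strip().splitlines()]
            continue
        try:
            paths = STAGES[stage](cfg, out_dir, _stage_seed(seed, stage))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        marker.write_text("\n".join(str(p) for p in paths) + "\n")
        outputs[stage] = paths
    return outputs
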