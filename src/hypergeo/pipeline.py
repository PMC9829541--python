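"""Session I/O and end-to-end orchestration on synthetic data.

File formats: spike trains as CSV with columns ``neuron_id,time_s``;
trajectories as CSV with columns ``t_s,x_cm[,y_cm]``.  Both can also be
written to / read from HDF5 with identical field names.

:func:`run_pipeline` wires the stages together in the analysis order —
synthesize a session, build the correlation matrix, compute Betti
curves, fit the hyperbolic radius, detect place fields and estimate
curvature, decode position — with one global seed fanned out to
deterministic per-stage seeds, so every stage is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import correlation, curvature, decode, fields, geomfit, synth, topology

__all__ = ["load_session", "save_session", "load_session_hdf5",
           "save_session_hdf5", "default_config", "run_pipeline"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- I/O

def save_session(spikes: synth.SpikeTrainSet, trajectory: synth.Trajectory,
                 spikes_path, trajectory_path) -> None:
    """Write a session to the two CSV files."""
    rows = [(int(i), float(t)) for i, train in enumerate(spikes.spike_times)
            for t in train]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(
        spikes_path, index=False)
    cols = {"t_s": trajectory.times, "x_cm": trajectory.positions[:, 0]}
    if trajectory.ndim == 2:
        cols["y_cm"] = trajectory.positions[:, 1]
    pd.DataFrame(cols).to_csv(trajectory_path, index=False)


def load_session(spikes_path, trajectory_path, arena_cm: float | None = None,
                 duration: float | None = None):
    """Read and validate a session from the two CSV files.

    Unsorted spike times are sorted with a warning; negative times are
    an error.  The session duration defaults to the trajectory extent.
    """
    sp = pd.read_csv(spikes_path)
    if sp.empty:
        raise ValueError(f"{spikes_path}: no spikes")
    missing = {"neuron_id", "time_s"} - set(sp.columns)
    if missing:
        raise ValueError(f"{spikes_path}: missing columns {sorted(missing)}")
    bad = sp.index[sp["time_s"] < 0]
    if len(bad):
        raise ValueError(f"{spikes_path}: negative spike time at row "
                         f"{int(bad[0]) + 2}")  # 1-based + header
    tr = pd.read_csv(trajectory_path)
    if tr.empty:
        raise ValueError(f"{trajectory_path}: no samples")
    if "t_s" not in tr.columns or "x_cm" not in tr.columns:
        raise ValueError(f"{trajectory_path}: need columns t_s,x_cm[,y_cm]")
    pos_cols = ["x_cm"] + (["y_cm"] if "y_cm" in tr.columns else [])
    if tr[pos_cols].isna().any().any():
        first = int(tr[pos_cols].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{trajectory_path}: malformed row {first} "
                         "(mixed 1-D/2-D positions)")
    positions = tr[pos_cols].to_numpy(dtype=float)
    if arena_cm is None:
        arena_cm = float(np.ceil(positions.max()))
    trajectory = synth.Trajectory(tr["t_s"].to_numpy(dtype=float), positions,
                                  arena_cm)
    n_neurons = int(sp["neuron_id"].max()) + 1
    trains = [np.array([], dtype=float) for _ in range(n_neurons)]
    for nid, grp in sp.groupby("neuron_id"):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            logger.warning("%s: spike times of neuron %d unsorted; sorting",
                           spikes_path, nid)
            t = np.sort(t)
        trains[int(nid)] = t
    if duration is None:
        duration = max(trajectory.duration,
                       max((t[-1] for t in trains if t.size), default=0.0))
    return synth.SpikeTrainSet(trains, duration), trajectory


def save_session_hdf5(spikes: synth.SpikeTrainSet,
                      trajectory: synth.Trajectory, path) -> None:
    """Single-file HDF5 container with the same field names as the CSVs."""
    import h5py

    with h5py.File(path, "w") as f:
        rows = np.concatenate([np.full(t.size, i)
                               for i, t in enumerate(spikes.spike_times)]
                              ) if spikes.n_neurons else np.zeros(0)
        times = (np.concatenate(spikes.spike_times)
                 if spikes.n_neurons else np.zeros(0))
        f.create_dataset("spikes/neuron_id", data=rows.astype(np.int64))
        f.create_dataset("spikes/time_s", data=times)
        f.attrs["duration_s"] = spikes.duration
        f.attrs["arena_cm"] = trajectory.arena_cm
        f.create_dataset("trajectory/t_s", data=trajectory.times)
        f.create_dataset("trajectory/x_cm", data=trajectory.positions[:, 0])
        if trajectory.ndim == 2:
            f.create_dataset("trajectory/y_cm", data=trajectory.positions[:, 1])


def load_session_hdf5(path):
    import h5py

    with h5py.File(path, "r") as f:
        nid = f["spikes/neuron_id"][:]
        times = f["spikes/time_s"][:]
        duration = float(f.attrs["duration_s"])
        arena = float(f.attrs["arena_cm"])
        t = f["trajectory/t_s"][:]
        x = f["trajectory/x_cm"][:]
        pos = (np.column_stack([x, f["trajectory/y_cm"][:]])
               if "trajectory/y_cm" in f else x[:, None])
    n_neurons = int(nid.max()) + 1 if nid.size else 0
    trains = [np.sort(times[nid == i]) for i in range(n_neurons)]
    return (synth.SpikeTrainSet(trains, duration),
            synth.Trajectory(t, pos, arena))


# ------------------------------------------------------- orchestration

_KNOWN_KEYS = {
    "seed", "n_neurons", "arena_cm", "duration_s", "dt_s", "speed_mean",
    "zeta", "field_count_mean", "field_count_sd", "tau_max", "rate_band",
    "last_fraction", "rmax_grid", "ensemble_reps", "fit_dim", "noise_eps",
    "max_betti_dim", "decode", "curvature_window",
}


def default_config(**overrides) -> dict:
    """Demo configuration: 50 cells, 20 min in a 180-cm square box."""
    cfg = {
        "seed": 0,
        "n_neurons": 50,
        "arena_cm": 180.0,
        "duration_s": 1200.0,
        "dt_s": 0.025,
        "speed_mean": 12.0,
        "zeta": 0.05,
        "field_count_mean": 1.5,
        "field_count_sd": 1.2,
        "tau_max": 1.0,
        "rate_band": (0.1, 7.0),
        "last_fraction": None,
        "rmax_grid": np.arange(5.0, 16.01, 1.0),
        "ensemble_reps": 50,
        "fit_dim": 3,
        "noise_eps": 0.05,
        "max_betti_dim": 2,
        "decode": False,
        "curvature_window": (4.0, 400.0),
    }
    unknown = set(overrides) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides)
    return cfg


def run_pipeline(config: dict | None = None, **overrides) -> dict:
    """Synthetic session -> correlation -> topology -> geometry fit
    (-> fields & curvature, optionally decoding).

    Deterministic for a fixed seed; the report carries the config, the
    per-stage seeds and all fit statistics.
    """
    cfg = default_config(**(config or {}), **overrides)
    ss = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: seed for name, seed in
                   zip(["trajectory", "population", "spikes", "fit",
                        "decode"], ss.spawn(5))}
    report = {"config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in cfg.items()},
              "stage_seeds": {k: int(v.generate_state(1)[0])
                              for k, v in stage_seeds.items()}}

    traj = synth.simulate_trajectory(cfg["arena_cm"], cfg["duration_s"],
                                     cfg["dt_s"], cfg["speed_mean"],
                                     seed=stage_seeds["trajectory"])
    pop = synth.generate_population(cfg["n_neurons"], zeta=cfg["zeta"],
                                    field_count_mean=cfg["field_count_mean"],
                                    field_count_sd=cfg["field_count_sd"],
                                    arena_cm=cfg["arena_cm"],
                                    seed=stage_seeds["population"])
    spikes = synth.simulate_spikes(pop, traj, seed=stage_seeds["spikes"])
    report["n_spikes"] = int(sum(t.size for t in spikes.spike_times))

    C = correlation.correlation_matrix(spikes, tau_max=cfg["tau_max"],
                                       rate_band=cfg["rate_band"],
                                       last_fraction=cfg["last_fraction"])
    report["n_eligible_neurons"] = C.n_neurons

    bc = topology.betti_curves(C.values, max_dim=cfg["max_betti_dim"])
    report["integrated_betti"] = {
        m: topology.integrated_betti(bc.curve(m))
        for m in range(1, cfg["max_betti_dim"] + 1)}

    fit = geomfit.optimal_rmax(
        C, dim=cfg["fit_dim"], grid=cfg["rmax_grid"],
        n_reps=cfg["ensemble_reps"], eps=cfg["noise_eps"],
        seed=int(stage_seeds["fit"].generate_state(1)[0] % (2 ** 31)))
    report["geometry_fit"] = {"r_max": fit.r_max,
                              "p_int": fit.p_int, "p_l1": fit.p_l1,
                              "p_products": fit.p_products.tolist(),
                              "inconclusive": fit.inconclusive}

    sizes = []
    for train in spikes.spike_times:
        rm = fields.compute_rate_map(train, traj, bin_cm=2.0)
        for f in fields.detect_place_fields_2d(rm):
            sizes.append(f.equivalent_diameter())
    report["n_fields"] = len(sizes)
    lo, hi = cfg["curvature_window"]
    usable = [s for s in sizes if lo < s < hi]
    if len(usable) >= 5:
        post = curvature.fit_curvature_bayes(
            usable, curvature.TruncationWindow(lo, hi))
        report["curvature"] = {"zeta_map": post.zeta_map, "ci95": post.ci95,
                               "n_sizes": len(usable)}
    else:
        report["curvature"] = None

    if cfg["decode"]:
        maps = [fields.compute_rate_map(t, traj, bin_cm=5.0)
                for t in spikes.spike_times]
        run = decode.bayes_decode(spikes, maps, traj)
        report["decoding"] = {"median_error_cm": run.median_error,
                              "n_windows": int(run.errors.size)}
    return report
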