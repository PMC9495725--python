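"""Full in-silico experiment: trajectories, spectra, offline and OTR tables.

Randomness policy: one root seed; every well draws from its own stream
derived by stable hashing of ``(seed, plate, well)`` so that layout edits
do not reshuffle unrelated wells.  Offline assay noise uses a per-condition
stream derived the same way.  Identical seeds give bit-identical outputs.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..data import (
    MeasurementSchedule,
    SpectraDataset,
    WellCondition,
    default_em_grid,
    default_ex_grid,
)
from ..errors import ScheduleError
from ..layout import LayoutSpec
from .kinetics import CultivationTrajectory, KineticParams, simulate_batch_kinetics
from .spectra import ModelCache, SpectralModel, StatePoint, default_spectral_model, render_spectrum

__all__ = ["OfflineNoise", "sample_offline", "generate_experiment", "stream_rng"]


def stream_rng(seed: int, *key: object) -> np.random.Generator:
    """Deterministic per-entity random stream from a root seed and a key."""
    digest = hashlib.blake2b(
        ("|".join([str(seed), *map(str, key)])).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


@dataclass(frozen=True)
class OfflineNoise:
    """Assay noise standard deviations for the destructive offline samples."""

    glycerol: float = 0.10  # g/L
    cdw: float = 0.03  # g/L
    ph: float = 0.008

    def __post_init__(self) -> None:
        if min(self.glycerol, self.cdw, self.ph) < 0:
            raise ValueError("offline noise sds must be >= 0")


def sample_offline(
    traj: CultivationTrajectory,
    times: np.ndarray,
    noise: OfflineNoise | None = None,
    rng: np.random.Generator | None = None,
    condition_id: str = "",
    replicate: int = 1,
) -> pd.DataFrame:
    """Destructive offline samples: trajectory value plus Gaussian assay noise.

    The glycerol assay cannot report negative concentrations, so noisy
    glycerol values are floored at zero.
    """
    times = np.asarray(times, float)
    if times.size and (times.min() < traj.times.min() - 1e-9 or times.max() > traj.times.max() + 1e-9):
        raise ScheduleError(
            f"sampling times [{times.min()}, {times.max()}] outside trajectory span "
            f"[{traj.times.min()}, {traj.times.max()}]"
        )
    gly = np.interp(times, traj.times, traj.S)
    cdw = np.interp(times, traj.times, traj.X)
    ph = np.interp(times, traj.times, traj.pH)
    if noise is not None and rng is not None:
        gly = gly + noise.glycerol * rng.standard_normal(times.size)
        cdw = cdw + noise.cdw * rng.standard_normal(times.size)
        ph = ph + noise.ph * rng.standard_normal(times.size)
    return pd.DataFrame(
        {
            "condition_id": condition_id,
            "replicate": replicate,
            "time_h": times,
            "glycerol_g_L": np.maximum(gly, 0.0),
            "cdw_g_L": np.maximum(cdw, 0.0),
            "pH": ph,
        }
    )


def generate_experiment(
    layout: LayoutSpec,
    params: KineticParams | None = None,
    model: SpectralModel | None = None,
    sched: MeasurementSchedule | None = None,
    seed: int = 0,
    em_step: float = 2.0,
    offline_noise: OfflineNoise | None = OfflineNoise(),
    spectral_noise: bool = True,
) -> tuple[SpectraDataset, pd.DataFrame, pd.DataFrame]:
    """Simulate the campaign described by `layout`.

    Returns ``(spectra, offline_table, otr_table)``.  One Spectrum2D is
    rendered per monitored well per cycle (wells in mode ``until_sampled``
    stop at their scheduled destructive sampling time).  Offline samples
    follow the layout's per-condition schedule; replicate wells of a
    condition share the condition's noise-free reference trajectory, so
    the offline table is condition-level (replicate column = 1).
    """
    params = params or KineticParams()
    model = model or default_spectral_model()
    sched = sched or MeasurementSchedule()
    ex_grid = default_ex_grid()
    em_grid = default_em_grid(em_step)
    cache = ModelCache(model, ex_grid, em_grid)
    spectral_times = sched.spectral_times()

    well_conditions = layout.well_conditions()
    ds = SpectraDataset(conditions=well_conditions, schedule=sched)

    # one noise-free trajectory per condition, shared by replicates
    trajectories: dict[str, CultivationTrajectory] = {}
    offline_times = [t for v in layout.offline_schedule.values() for t in v]
    traj_grid = np.unique(
        np.concatenate([[0.0], spectral_times, offline_times, [sched.horizon]])
    )
    for cid, (S0, X0) in layout.conditions.items():
        cond = WellCondition(cid, S0, X0)
        trajectories[cid] = simulate_batch_kinetics(cond, params, traj_grid)

    sample_time_by_well = {
        f"{plate_id}/{w.well}": w.sample_time_h for plate_id, w in layout.monitored_wells()
    }
    mode_by_well = {f"{plate_id}/{w.well}": w.mode for plate_id, w in layout.monitored_wells()}

    for well_key in sorted(well_conditions):
        cond = well_conditions[well_key]
        traj = trajectories[cond.condition_id]
        rng = stream_rng(seed, "well", well_key) if spectral_noise else None
        if spectral_noise and model.well_gain_sd > 0:
            gain_rng = stream_rng(seed, "gain", well_key)
            gain = float(np.exp(model.well_gain_sd * gain_rng.standard_normal()))
        else:
            gain = 1.0
        t_stop = sched.horizon
        if mode_by_well[well_key] == "until_sampled":
            t_sample = sample_time_by_well.get(well_key)
            if t_sample is None:
                raise ScheduleError(f"well {well_key}: mode until_sampled without sample time")
            t_stop = t_sample
        decay = traj.scatter_decay()
        for cycle, t in enumerate(spectral_times):
            if t > t_stop + 1e-9:
                break
            i = int(np.searchsorted(traj.times, t))
            state = StatePoint(
                time_h=float(t),
                X=float(traj.X[i]),
                G=float(traj.G[i]),
                scatter_decay=float(decay[i]),
            )
            spec = render_spectrum(
                state, model, ex_grid, em_grid, rng=rng, well_gain=gain,
                well_id=well_key, meta={"cycle": cycle}, cache=cache,
            )
            ds.add(spec, cycle)

    offline_frames = []
    for cid in sorted(layout.offline_schedule):
        times = np.asarray(sorted(layout.offline_schedule[cid]), float)
        if np.unique(times).size != times.size:
            raise ScheduleError(f"condition {cid}: duplicate destructive sampling time")
        rng = stream_rng(seed, "offline", cid) if offline_noise is not None else None
        offline_frames.append(
            sample_offline(trajectories[cid], times, offline_noise, rng, cid, 1)
        )
    offline = (
        pd.concat(offline_frames, ignore_index=True)
        if offline_frames
        else pd.DataFrame(
            columns=["condition_id", "replicate", "time_h", "glycerol_g_L", "cdw_g_L", "pH"]
        )
    )

    otr_frames = [
        pd.DataFrame(
            {
                "condition_id": cid,
                "replicate": 1,
                "time_h": trajectories[cid].times,
                "otr_mmol_L_h": trajectories[cid].OTR,
            }
        )
        for cid in sorted(trajectories)
    ]
    otr = pd.concat(otr_frames, ignore_index=True)
    return ds, offline, otr
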