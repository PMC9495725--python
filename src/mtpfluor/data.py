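"""Dataset containers and file I/O.

The canonical acquisition geometry is an excitation grid of 280-700 nm in
10 nm steps (43 wavelengths) and an emission grid of 278-720 nm in 0.45 nm
steps (983 wavelengths).  A coarser 2 nm emission grid is provided for
desk-scale pipeline runs; all downstream code is grid-agnostic.

Two on-disk dialects are supported for spectra collections:

* long CSV (``well_id, cycle, time_h, ex_nm, em_nm, intensity``) with a
  JSON sidecar (``<path>.meta.json``) carrying grids, conditions, schedule
  and per-spectrum metadata;
* an HDF5 container with one ``(cycle, ex, em)`` array per well.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, GridError

__all__ = [
    "WellCondition",
    "MeasurementSchedule",
    "Spectrum2D",
    "SpectraDataset",
    "ExtractedSignal",
    "default_ex_grid",
    "default_em_grid",
    "write_spectra",
    "read_spectra",
    "extract_signal",
    "mean_over_replicates",
    "mean_spectra_over_replicates",
    "validate_offline_table",
]

OFFLINE_COLUMNS = ["condition_id", "replicate", "time_h", "glycerol_g_L", "cdw_g_L", "pH"]
OTR_COLUMNS = ["condition_id", "replicate", "time_h", "otr_mmol_L_h"]


def default_ex_grid() -> np.ndarray:
    """Excitation grid: 280-700 nm, 10 nm step (43 values)."""
    return 280.0 + 10.0 * np.arange(43)


def default_em_grid(step: float = 0.45) -> np.ndarray:
    """Emission grid: 278 nm up to at most 720 nm in `step` nm increments."""
    if step <= 0:
        raise GridError(f"emission step must be positive, got {step}")
    n = int(math.floor((720.0 - 278.0) / step + 1e-9)) + 1
    return 278.0 + step * np.arange(n)


@dataclass(frozen=True)
class WellCondition:
    """Initial condition of one well (blank wells have X0 == 0)."""

    condition_id: str
    S0: float  # initial glycerol, g/L
    X0: float  # initial cell dry weight, g/L
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError(f"S0 must be >= 0, got {self.S0}")
        if self.X0 < 0:
            raise ValueError(f"X0 must be >= 0, got {self.X0}")


def _grid_1p5h(horizon: float) -> list[float]:
    """t=0 plus every 1.5 h after the first 6 h, up to `horizon`."""
    times = [0.0, 6.0]
    t = 7.5
    while t <= horizon + 1e-9:
        times.append(round(t, 6))
        t += 1.5
    return [t for t in times if t <= horizon + 1e-9]


def _grid_6h(horizon: float) -> list[float]:
    return [float(6 * k) for k in range(int(horizon // 6) + 1)]


@dataclass(frozen=True)
class MeasurementSchedule:
    """Online spectral cycle plus the destructive offline sampling grids."""

    cycle_period: float = 0.5  # h
    horizon: float = 32.0  # h
    t_first: float = 0.1  # h, first spectral cycle
    offline_horizon: float = 30.0  # last offline sample, h

    def __post_init__(self) -> None:
        if self.cycle_period <= 0 or self.horizon <= 0:
            raise ValueError("cycle_period and horizon must be positive")
        if self.t_first < 0 or self.t_first > self.horizon:
            raise ValueError("t_first must lie within [0, horizon]")

    def spectral_times(self) -> np.ndarray:
        n = int(math.floor((self.horizon - self.t_first) / self.cycle_period + 1e-9)) + 1
        return self.t_first + self.cycle_period * np.arange(n)

    def offline_times_1p5h(self) -> list[float]:
        return _grid_1p5h(min(self.offline_horizon, self.horizon))

    def offline_times_6h(self) -> list[float]:
        return _grid_6h(min(self.offline_horizon, self.horizon))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementSchedule":
        return cls(**d)


@dataclass
class Spectrum2D:
    """One excitation x emission intensity matrix for one well at one time."""

    well_id: str
    time_h: float
    ex_grid: np.ndarray
    em_grid: np.ndarray
    intensities: np.ndarray  # shape (len(ex_grid), len(em_grid))
    meta: dict = field(default_factory=dict)

    def validate(self) -> "Spectrum2D":
        ex = np.asarray(self.ex_grid, float)
        em = np.asarray(self.em_grid, float)
        inten = np.asarray(self.intensities, float)
        if inten.shape != (ex.size, em.size):
            raise GridError(
                f"well {self.well_id!r} t={self.time_h}: intensity shape "
                f"{inten.shape} does not match grids ({ex.size}, {em.size})"
            )
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise GridError(f"well {self.well_id!r}: grids must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            bad = np.argwhere(~np.isfinite(inten))[0]
            raise FormatError(
                f"well {self.well_id!r} t={self.time_h}: non-finite intensity at "
                f"ex={ex[bad[0]]} nm, em={em[bad[1]]} nm"
            )
        return self


class SpectraDataset:
    """Collection of Spectrum2D keyed by (well_id, cycle) plus well conditions."""

    def __init__(
        self,
        conditions: dict[str, WellCondition] | None = None,
        schedule: MeasurementSchedule | None = None,
    ) -> None:
        self.spectra: dict[tuple[str, int], Spectrum2D] = {}
        self.conditions: dict[str, WellCondition] = dict(conditions or {})
        self.schedule = schedule

    def add(self, spec: Spectrum2D, cycle: int) -> None:
        if spec.well_id not in self.conditions:
            raise FormatError(f"no condition registered for well {spec.well_id!r}")
        spec.validate()
        first = next(iter(self.spectra.values()), None)
        if first is not None and (
            not np.array_equal(first.ex_grid, spec.ex_grid)
            or not np.array_equal(first.em_grid, spec.em_grid)
        ):
            raise GridError(f"well {spec.well_id!r} cycle {cycle}: grid differs from dataset grid")
        self.spectra[(spec.well_id, cycle)] = spec

    def wells(self) -> list[str]:
        return sorted({w for w, _ in self.spectra})

    def cycles(self, well_id: str) -> list[int]:
        return sorted(c for w, c in self.spectra if w == well_id)

    def iter_well(self, well_id: str) -> Iterator[tuple[int, Spectrum2D]]:
        for c in self.cycles(well_id):
            yield c, self.spectra[(well_id, c)]

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def ex_grid(self) -> np.ndarray:
        return next(iter(self.spectra.values())).ex_grid

    @property
    def em_grid(self) -> np.ndarray:
        return next(iter(self.spectra.values())).em_grid


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _conditions_to_json(conds: dict[str, WellCondition]) -> dict:
    return {w: asdict(c) for w, c in conds.items()}


def _conditions_from_json(d: dict) -> dict[str, WellCondition]:
    return {w: WellCondition(**c) for w, c in d.items()}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_spectra_csv(ds: SpectraDataset, path: str | Path) -> None:
    path = Path(path)
    rows = []
    meta: dict[str, dict] = {}
    ex0 = em0 = None
    for (well, cycle), spec in sorted(ds.spectra.items()):
        spec.validate()
        ex0, em0 = spec.ex_grid, spec.em_grid
        n_ex, n_em = spec.intensities.shape
        rows.append(
            pd.DataFrame(
                {
                    "well_id": well,
                    "cycle": cycle,
                    "time_h": spec.time_h,
                    "ex_nm": np.repeat(spec.ex_grid, n_em),
                    "em_nm": np.tile(spec.em_grid, n_ex),
                    "intensity": spec.intensities.ravel(),
                }
            )
        )
        meta[f"{well}|{cycle}"] = spec.meta
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["well_id", "cycle", "time_h", "ex_nm", "em_nm", "intensity"])
    )
    frame.to_csv(path, index=False)
    sidecar = {
        "format": "mtpfluor-spectra-csv/1",
        "ex_grid": None if ex0 is None else list(map(float, ex0)),
        "em_grid": None if em0 is None else list(map(float, em0)),
        "conditions": _conditions_to_json(ds.conditions),
        "schedule": None if ds.schedule is None else ds.schedule.to_dict(),
        "spectrum_meta": meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_spectra_csv(path: str | Path) -> SpectraDataset:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    schedule = (
        MeasurementSchedule.from_dict(sidecar["schedule"]) if sidecar.get("schedule") else None
    )
    ds = SpectraDataset(_conditions_from_json(sidecar.get("conditions", {})), schedule)
    frame = pd.read_csv(path)
    expected = {"well_id", "cycle", "time_h", "ex_nm", "em_nm", "intensity"}
    if not expected.issubset(frame.columns):
        raise FormatError(f"{path}: malformed header, expected columns {sorted(expected)}")
    if frame.empty:
        return ds
    ex_grid = np.asarray(sidecar["ex_grid"], float)
    em_grid = np.asarray(sidecar["em_grid"], float)
    for (well, cycle), g in frame.groupby(["well_id", "cycle"], sort=True):
        if len(g) != ex_grid.size * em_grid.size:
            raise FormatError(
                f"{path}: record well={well!r} cycle={cycle} has {len(g)} cells, "
                f"expected {ex_grid.size * em_grid.size}"
            )
        inten = g["intensity"].to_numpy(float).reshape(ex_grid.size, em_grid.size)
        spec = Spectrum2D(
            well_id=str(well),
            time_h=float(g["time_h"].iloc[0]),
            ex_grid=ex_grid,
            em_grid=em_grid,
            intensities=inten,
            meta=sidecar.get("spectrum_meta", {}).get(f"{well}|{cycle}", {}),
        )
        try:
            ds.add(spec, int(cycle))
        except FormatError as exc:
            raise FormatError(f"{path}: record well={well!r} cycle={cycle}: {exc}") from exc
    return ds


def write_spectra_hdf5(ds: SpectraDataset, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "mtpfluor-spectra-hdf5/1"
        f.attrs["conditions"] = json.dumps(_conditions_to_json(ds.conditions))
        f.attrs["schedule"] = json.dumps(
            None if ds.schedule is None else ds.schedule.to_dict()
        )
        if len(ds):
            f.create_dataset("ex_grid", data=ds.ex_grid)
            f.create_dataset("em_grid", data=ds.em_grid)
        for i, well in enumerate(ds.wells()):
            cycles = ds.cycles(well)
            grp = f.create_group(f"wells/w{i:04d}")  # well ids may contain '/'
            grp.attrs["well_id"] = well
            stack = np.stack([ds.spectra[(well, c)].intensities for c in cycles])
            grp.create_dataset("intensities", data=stack)
            grp.create_dataset("cycles", data=np.asarray(cycles, int))
            grp.create_dataset(
                "times", data=np.asarray([ds.spectra[(well, c)].time_h for c in cycles])
            )
            grp.attrs["meta"] = json.dumps(
                {str(c): ds.spectra[(well, c)].meta for c in cycles}
            )


def read_spectra_hdf5(path: str | Path) -> SpectraDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        schedule_d = json.loads(f.attrs["schedule"])
        ds = SpectraDataset(
            _conditions_from_json(json.loads(f.attrs["conditions"])),
            MeasurementSchedule.from_dict(schedule_d) if schedule_d else None,
        )
        if "wells" not in f:
            return ds
        ex_grid = f["ex_grid"][()]
        em_grid = f["em_grid"][()]
        for key in f["wells"]:
            grp = f[f"wells/{key}"]
            well = grp.attrs["well_id"]
            meta = json.loads(grp.attrs["meta"])
            cycles = grp["cycles"][()]
            times = grp["times"][()]
            stack = grp["intensities"][()]
            for i, c in enumerate(cycles):
                spec = Spectrum2D(
                    well_id=str(well),
                    time_h=float(times[i]),
                    ex_grid=ex_grid,
                    em_grid=em_grid,
                    intensities=stack[i],
                    meta=meta.get(str(int(c)), {}),
                )
                ds.add(spec, int(c))
    return ds


def write_spectra(ds: SpectraDataset, path: str | Path) -> None:
    """Dispatch on extension: ``.csv`` for the long dialect, else HDF5."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        write_spectra_csv(ds, path)
    else:
        write_spectra_hdf5(ds, path)


def read_spectra(path: str | Path) -> SpectraDataset:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_spectra_csv(path)
    return read_spectra_hdf5(path)


def validate_offline_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the offline-table invariants; returns the frame unchanged."""
    missing = [c for c in OFFLINE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"offline table missing columns {missing}")
    if (df["glycerol_g_L"] < 0).any():
        raise FormatError("offline table contains negative glycerol")
    if (df["cdw_g_L"] < 0).any():
        raise FormatError("offline table contains negative CDW")
    if ((df["pH"] <= 2) | (df["pH"] >= 9)).any():
        raise FormatError("offline table contains pH outside (2, 9)")
    dup = df.duplicated(subset=["condition_id", "replicate", "time_h"])
    if dup.any():
        raise FormatError("offline table has duplicate (condition, replicate, time) rows")
    return df


# ---------------------------------------------------------------------------
# signal extraction and replicate statistics
# ---------------------------------------------------------------------------

@dataclass
class ExtractedSignal:
    """Per-well time series of one wavelength combination.

    ``ex_nm``/``em_nm`` are the grid points actually used (nearest-neighbour
    snap of the request, which is retained for provenance).
    """

    ex_requested: float
    em_requested: float
    ex_nm: float
    em_nm: float
    frame: pd.DataFrame  # columns: well_id, condition_id, cycle, time_h, intensity

    @property
    def snapped(self) -> bool:
        return self.ex_nm != self.ex_requested or self.em_nm != self.em_requested


def _snap(grid: np.ndarray, value: float, axis: str) -> tuple[int, float]:
    if value < grid[0] or value > grid[-1]:
        raise GridError(
            f"{axis} wavelength {value} nm outside grid span [{grid[0]}, {grid[-1]}]"
        )
    idx = int(np.argmin(np.abs(grid - value)))
    return idx, float(grid[idx])


def extract_signal(ds: SpectraDataset, ex: float, em: float) -> ExtractedSignal:
    """Time series of intensity at the grid points nearest (ex, em)."""
    if not len(ds):
        raise FormatError("empty dataset")
    i_ex, ex_nm = _snap(ds.ex_grid, ex, "excitation")
    i_em, em_nm = _snap(ds.em_grid, em, "emission")
    rows = []
    for well in ds.wells():
        cond = ds.conditions[well]
        for cycle, spec in ds.iter_well(well):
            rows.append(
                (well, cond.condition_id, cond.replicate_index, cycle, spec.time_h,
                 float(spec.intensities[i_ex, i_em]))
            )
    frame = pd.DataFrame(
        rows, columns=["well_id", "condition_id", "replicate", "cycle", "time_h", "intensity"]
    ).sort_values(["well_id", "time_h"], ignore_index=True)
    return ExtractedSignal(ex, em, ex_nm, em_nm, frame)


def mean_over_replicates(
    frame: pd.DataFrame, value_col: str = "intensity", group: str = "condition_id"
) -> pd.DataFrame:
    """Mean and sample sd (n-1 denominator; sd = 0 for n = 1) per time point.

    Raises AlignmentError when replicates within a group do not share a
    common cycle base.
    """
    for gid, g in frame.groupby(group):
        per_well = g.groupby("well_id")["cycle"].apply(lambda s: tuple(sorted(s)))
        if per_well.nunique() > 1:
            raise AlignmentError(f"group {gid!r}: replicates have mismatched cycle counts")
    out = (
        frame.groupby([group, "cycle"], sort=True)
        .agg(
            time_h=("time_h", "mean"),
            mean=(value_col, "mean"),
            sd=(value_col, lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            n=(value_col, "size"),
        )
        .reset_index()
    )
    return out


def mean_spectra_over_replicates(ds: SpectraDataset, min_replicates: int = 2) -> SpectraDataset:
    """Average Spectrum2D intensities over replicate wells per (condition, cycle).

    The averaged dataset contains one pseudo-well ``avg:<condition>`` per
    condition with replicate_index 1.
    """
    by_cond: dict[str, list[str]] = {}
    for well in ds.wells():
        by_cond.setdefault(ds.conditions[well].condition_id, []).append(well)
    out = SpectraDataset(schedule=ds.schedule)
    for cond_id, wells in sorted(by_cond.items()):
        if len(wells) < min_replicates:
            raise AlignmentError(
                f"condition {cond_id!r}: {len(wells)} replicate(s), need >= {min_replicates}"
            )
        cycle_sets = {tuple(ds.cycles(w)) for w in wells}
        if len(cycle_sets) > 1:
            raise AlignmentError(f"condition {cond_id!r}: replicates have mismatched cycles")
        base = ds.conditions[wells[0]]
        avg_well = f"avg:{cond_id}"
        out.conditions[avg_well] = WellCondition(cond_id, base.S0, base.X0, 1)
        for cycle in ds.cycles(wells[0]):
            stack = np.stack([ds.spectra[(w, cycle)].intensities for w in wells])
            ref = ds.spectra[(wells[0], cycle)]
            out.add(
                Spectrum2D(
                    well_id=avg_well,
                    time_h=ref.time_h,
                    ex_grid=ref.ex_grid,
                    em_grid=ref.em_grid,
                    intensities=stack.mean(axis=0),
                    meta={"n_averaged": len(wells)},
                ),
                cycle,
            )
    return out
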