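"""Experimental plate layouts and sampling/throughput arithmetic.

Two layouts are packaged:

* the *original* multi-plate campaign: eight initial conditions across one
  OTR plate (triplicates), one spectral plate (six replicates per
  condition) and three destructive-sampling plates totalling 120 scheduled
  offline samples with at most 16 per condition;
* the *revised* single-plate layout: two calibration conditions (two fully
  monitored wells plus four in-cultivation sampling wells each) and twelve
  prediction conditions in triplicate, 48 wells and 48 scheduled samples
  in total.

The 120-sample interior allocation of the original campaign is
under-determined; the packaged schedule (16 samples for each of the two
intensively sampled calibration conditions, 15 or 14 for the rest) is a
declared assumption — only the total of 120 and the per-condition cap of
16 are contract.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .data import WellCondition, _grid_1p5h
from .errors import ConfigError, ScheduleError

__all__ = [
    "WellAssignment",
    "PlateSpec",
    "LayoutSpec",
    "ORIGINAL_CONDITIONS",
    "CALIBRATION_CONDITION_IDS",
    "build_original_layout",
    "build_revised_layout",
    "build_monitoring_layout",
    "layout_metrics",
]

MODES = ("full", "until_sampled", "unmonitored", "blank", "unused")
ROLES = ("otr", "spectral", "sampling", "combined")

#: the eight initial conditions of the original campaign:
#: I-III vary initial CDW at 9 g/L glycerol, IV-VIII vary glycerol at 0.03 g/L CDW.
ORIGINAL_CONDITIONS: dict[str, tuple[float, float]] = {
    "I": (9.0, 0.13),
    "II": (9.0, 0.07),
    "III": (9.0, 0.03),
    "IV": (7.0, 0.03),
    "V": (5.0, 0.03),
    "VI": (3.5, 0.03),
    "VII": (2.0, 0.03),
    "VIII": (0.0, 0.03),
}

#: conditions used to fit the regression models (9 g/L / 0.07 g/L CDW and
#: 2 g/L / 0.03 g/L CDW)
CALIBRATION_CONDITION_IDS = ("II", "VII")


@dataclass(frozen=True)
class WellAssignment:
    well: str  # e.g. "A1"
    condition_id: str | None
    mode: str  # one of MODES
    replicate_index: int = 1
    sample_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"well {self.well}: unknown mode {self.mode!r}")
        if self.mode in ("blank", "unused") and self.sample_time_h is not None:
            raise ConfigError(f"well {self.well}: {self.mode} wells cannot be sampled")


@dataclass
class PlateSpec:
    plate_id: str
    role: str  # one of ROLES
    wells: list[WellAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"plate {self.plate_id}: unknown role {self.role!r}")
        if len(self.wells) > 48:
            raise ConfigError(f"plate {self.plate_id}: {len(self.wells)} wells exceed 48")
        seen: dict[str, WellAssignment] = {}
        for w in self.wells:
            if w.well in seen:
                raise ScheduleError(f"plate {self.plate_id}: well {w.well} assigned twice")
            seen[w.well] = w


@dataclass
class LayoutSpec:
    plates: list[PlateSpec]
    conditions: dict[str, tuple[float, float]]  # condition_id -> (S0, X0)
    offline_schedule: dict[str, list[float]]  # condition_id -> sampling times, h
    spectral_cycle_h: float = 0.5
    practical_offline_interval_h: float = 6.0
    name: str = "layout"

    def __post_init__(self) -> None:
        referenced = {
            w.condition_id
            for p in self.plates
            for w in p.wells
            if w.condition_id is not None and w.mode not in ("blank", "unused")
        }
        for cid in self.conditions:
            if cid not in referenced:
                raise ConfigError(f"condition {cid!r} referenced by no well")
        for cid in self.offline_schedule:
            if cid not in self.conditions:
                raise ConfigError(f"offline schedule for unknown condition {cid!r}")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def total_samples(self) -> int:
        return sum(len(v) for v in self.offline_schedule.values())

    @property
    def max_samples_per_condition(self) -> int:
        return max((len(v) for v in self.offline_schedule.values()), default=0)

    def monitored_wells(self) -> list[tuple[str, WellAssignment]]:
        """(plate_id, assignment) for every spectrally monitored culture well."""
        out = []
        for p in self.plates:
            if p.role not in ("spectral", "combined"):
                continue
            for w in p.wells:
                if w.mode in ("full", "until_sampled", "blank") and w.condition_id:
                    out.append((p.plate_id, w))
        return out

    def well_conditions(self) -> dict[str, WellCondition]:
        """Map monitored well key 'plate/well' to its WellCondition."""
        out = {}
        for plate_id, w in self.monitored_wells():
            S0, X0 = self.conditions[w.condition_id]
            out[f"{plate_id}/{w.well}"] = WellCondition(
                w.condition_id, S0, X0 if w.mode != "blank" else 0.0, w.replicate_index
            )
        return out

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "spectral_cycle_h": self.spectral_cycle_h,
            "practical_offline_interval_h": self.practical_offline_interval_h,
            "conditions": {k: list(v) for k, v in self.conditions.items()},
            "offline_schedule": self.offline_schedule,
            "plates": [
                {"plate_id": p.plate_id, "role": p.role, "wells": [asdict(w) for w in p.wells]}
                for p in self.plates
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "LayoutSpec":
        plates = [
            PlateSpec(p["plate_id"], p["role"], [WellAssignment(**w) for w in p["wells"]])
            for p in d["plates"]
        ]
        return cls(
            plates=plates,
            conditions={k: tuple(v) for k, v in d["conditions"].items()},
            offline_schedule={k: list(map(float, v)) for k, v in d["offline_schedule"].items()},
            spectral_cycle_h=d["spectral_cycle_h"],
            practical_offline_interval_h=d["practical_offline_interval_h"],
            name=d.get("name", "layout"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LayoutSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def plate_map(self) -> pd.DataFrame:
        """Flat plate-map table (for wet-lab use): one row per well."""
        rows = [
            {
                "plate_id": p.plate_id,
                "role": p.role,
                "well": w.well,
                "row": w.well[0],
                "col": int(w.well[1:]),
                "condition_id": w.condition_id or "",
                "mode": w.mode,
                "replicate": w.replicate_index,
                "sample_time_h": "" if w.sample_time_h is None else w.sample_time_h,
            }
            for p in self.plates
            for w in p.wells
        ]
        return pd.DataFrame(rows)


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in "ABCDEF" for c in range(1, 9)]


def build_original_layout() -> LayoutSpec:
    """Five-plate campaign: OTR triplicates, six spectral replicates per
    condition, and 120 destructive samples over three sampling plates."""
    conds = list(ORIGINAL_CONDITIONS)
    names = _well_names()

    otr_wells = []
    i = 0
    for cid in conds:
        for rep in range(1, 4):
            otr_wells.append(WellAssignment(names[i], cid, "full", rep))
            i += 1
    otr_plate = PlateSpec("P1-otr", "otr", otr_wells)

    spectral_wells = []
    i = 0
    for cid in conds:
        for rep in range(1, 7):
            spectral_wells.append(WellAssignment(names[i], cid, "full", rep))
            i += 1
    spectral_plate = PlateSpec("P2-spectral", "spectral", spectral_wells)

    # sampling allocation: 2 x 16 + 4 x 15 + 2 x 14 = 120 (cap 16/condition);
    # all grids start with the t=0 master-mix sample, then 6 h, then 1.5 h steps.
    n_samples = {"I": 15, "II": 16, "III": 15, "IV": 15, "V": 15, "VI": 14, "VII": 16, "VIII": 14}
    schedule: dict[str, list[float]] = {}
    for cid, n in n_samples.items():
        grid = _grid_1p5h(horizon=30.0)
        schedule[cid] = grid[:n]

    sampling_plates = []
    pending: list[tuple[str, int, float]] = []  # (condition, replicate, time) for t > 0
    for cid in conds:
        for k, t in enumerate(schedule[cid]):
            if t > 0:  # t=0 comes from the master mix, not a well
                pending.append((cid, k, t))
    for pi in range(3):
        chunk = pending[pi * 48 : (pi + 1) * 48]
        wells = [
            WellAssignment(names[j], cid, "unmonitored", rep, t)
            for j, (cid, rep, t) in enumerate(chunk)
        ]
        sampling_plates.append(PlateSpec(f"P{3 + pi}-sampling", "sampling", wells))

    return LayoutSpec(
        plates=[otr_plate, spectral_plate, *sampling_plates],
        conditions=dict(ORIGINAL_CONDITIONS),
        offline_schedule=schedule,
        name="original",
    )


def _revised_conditions(n_prediction: int) -> dict[str, tuple[float, float]]:
    roman = ["III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII", "XIII", "XIV",
             "XV", "XVI"]
    conds: dict[str, tuple[float, float]] = {
        "I": ORIGINAL_CONDITIONS["II"],   # 9.0 g/L, 0.07 g/L CDW
        "II": ORIGINAL_CONDITIONS["VII"],  # 2.0 g/L, 0.03 g/L CDW
    }
    s0_grid = [9.0, 9.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.5, 1.5, 1.0, 0.5, 0.0, 8.0, 6.5]
    x0_grid = [0.13, 0.03, 0.03, 0.05, 0.03, 0.07, 0.03, 0.05, 0.03, 0.07, 0.03, 0.03,
               0.09, 0.11]
    for k in range(n_prediction):
        conds[roman[k]] = (s0_grid[k], x0_grid[k])
    return conds


def build_revised_layout(
    n_prediction: int = 12, mid_sample_time_h: float = 12.0
) -> LayoutSpec:
    """Single 48-well plate: calibration conditions I-II with two fully
    monitored wells plus four in-cultivation sampling wells (default
    sampling times 6/12/18/24 h), prediction conditions in triplicate with
    an initial, one mid-run and a final sample."""
    n_wells = 2 * 6 + 3 * n_prediction
    if n_wells > 48:
        raise ConfigError(
            f"revised layout needs {n_wells} wells for {n_prediction} prediction "
            "conditions; 48-well capacity exceeded"
        )
    conds = _revised_conditions(n_prediction)
    names = _well_names()
    t_end = 30.0
    cal_times = [6.0, 12.0, 18.0, 24.0]

    wells: list[WellAssignment] = []
    schedule: dict[str, list[float]] = {}
    i = 0
    for cid in ("I", "II"):
        wells.append(WellAssignment(names[i], cid, "full", 1, sample_time_h=t_end))
        i += 1
        wells.append(WellAssignment(names[i], cid, "full", 2))
        i += 1
        for k, t in enumerate(cal_times, start=3):
            wells.append(WellAssignment(names[i], cid, "until_sampled", k, sample_time_h=t))
            i += 1
        schedule[cid] = [0.0, *cal_times, t_end]  # t=0 from master mix, final from monitored well
    for cid in list(conds)[2:]:
        wells.append(WellAssignment(names[i], cid, "full", 1, sample_time_h=t_end))
        i += 1
        wells.append(WellAssignment(names[i], cid, "full", 2))
        i += 1
        wells.append(
            WellAssignment(names[i], cid, "until_sampled", 3, sample_time_h=mid_sample_time_h)
        )
        i += 1
        schedule[cid] = [0.0, mid_sample_time_h, t_end]

    plate = PlateSpec("P1-combined", "combined", wells)
    return LayoutSpec(
        plates=[plate],
        conditions=conds,
        offline_schedule=schedule,
        name="revised",
    )


def build_monitoring_layout(
    conditions: dict[str, tuple[float, float]] | None = None,
    n_replicates: int = 2,
    offline_horizon: float = 30.0,
    name: str = "monitoring",
) -> LayoutSpec:
    """Desk-scale layout: one spectral plate with `n_replicates` fully
    monitored wells per condition and a shared 1.5-h offline grid
    (t=0, 6 h, then every 1.5 h) per condition."""
    conditions = dict(conditions or ORIGINAL_CONDITIONS)
    names = _well_names()
    n_wells = len(conditions) * n_replicates
    if n_wells > 48:
        raise ConfigError(f"monitoring layout needs {n_wells} wells; 48-well capacity exceeded")
    wells = []
    i = 0
    for cid in conditions:
        for rep in range(1, n_replicates + 1):
            wells.append(WellAssignment(names[i], cid, "full", rep))
            i += 1
    grid = _grid_1p5h(offline_horizon)
    schedule = {cid: list(grid) for cid in conditions}
    return LayoutSpec(
        plates=[PlateSpec("P1-spectral", "spectral", wells)],
        conditions=conditions,
        offline_schedule=schedule,
        name=name,
    )


def layout_metrics(a: LayoutSpec, b: LayoutSpec) -> dict:
    """Sampling/throughput comparison of two layouts (a = baseline)."""
    for lay in (a, b):
        if lay.spectral_cycle_h <= 0:
            raise ConfigError(f"layout {lay.name!r}: spectral cycle must be positive")
        if b.total_samples == 0 or a.n_conditions == 0:
            raise ConfigError("zero denominator in layout metrics")
    return {
        "a": {"name": a.name, "conditions": a.n_conditions, "samples": a.total_samples,
              "max_samples_per_condition": a.max_samples_per_condition},
        "b": {"name": b.name, "conditions": b.n_conditions, "samples": b.total_samples,
              "max_samples_per_condition": b.max_samples_per_condition},
        "sample_reduction_fold": a.total_samples / b.total_samples,
        "condition_increase_fold": b.n_conditions / a.n_conditions,
        "resolution_ratio": a.practical_offline_interval_h / a.spectral_cycle_h,
    }
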