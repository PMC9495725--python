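"""Temporal alignment of offline samples to spectral timestamps.

Offline parameters are piecewise-linearly interpolated between sampling
points and evaluated at each spectral measurement time.  Query times
outside the sampled span use constant extrapolation of the nearest sample
(with a warning).  Reference curves are built per condition from that
condition's own samples; replicate wells share one curve because the
destructive offline sampling is not replicate-resolved.

Glycerol can be transformed to *consumed* glycerol (S0 - residual) for
model fitting and back; the inverse is exact and residual outputs are
deliberately not clipped at zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .preprocess import FeatureMatrix

__all__ = [
    "PARAMETERS",
    "AlignedDataset",
    "interpolate_offline",
    "truncate_horizon",
    "glycerol_to_consumed",
    "consumed_to_residual",
    "offline_on_grid",
    "align_offline",
]

#: offline parameters and their table columns
PARAMETERS = {"glycerol": "glycerol_g_L", "cdw": "cdw_g_L", "ph": "pH"}

#: sampling-interval labels -> selector for grid times
INTERVALS = ("6h", "1.5h")

_TOL = 1e-6


def interpolate_offline(sample_times, sample_values, t) -> np.ndarray:
    """Exact piecewise-linear interpolation of offline samples at times t.

    Outside the sampled span the nearest sample value is used (constant
    extrapolation) and a warning is emitted.
    """
    st = np.asarray(sample_times, float)
    sv = np.asarray(sample_values, float)
    if st.size < 2:
        raise AlignmentError(f"need >= 2 samples to interpolate, got {st.size}")
    order = np.argsort(st)
    st, sv = st[order], sv[order]
    t = np.asarray(t, float)
    if np.any(t < st[0] - _TOL) or np.any(t > st[-1] + _TOL):
        warnings.warn(
            "query time outside offline sample span; using constant extrapolation",
            stacklevel=2,
        )
    return np.interp(t, st, sv)


def truncate_horizon(fm: FeatureMatrix, horizon: float = 25.0) -> FeatureMatrix:
    """Keep feature rows with time <= horizon (inclusive bound)."""
    mask = fm.row_meta["time_h"].to_numpy() <= horizon + _TOL
    if not mask.any():
        raise AlignmentError(f"no rows within horizon {horizon} h")
    return fm.select(mask)


def glycerol_to_consumed(residual, S0: float):
    """Consumed glycerol = S0 - residual."""
    return S0 - np.asarray(residual, float)


def consumed_to_residual(consumed, S0: float):
    """Inverse transform; not clipped, so negative residuals are possible."""
    return S0 - np.asarray(consumed, float)


def offline_on_grid(offline: pd.DataFrame, condition_id: str, interval: str) -> pd.DataFrame:
    """Offline rows of one condition restricted to one sampling interval.

    The 6-h grid keeps samples at multiples of 6 h (t=0 included); the
    1.5-h grid keeps every sample (t=0, 6 h, then 1.5-h steps).
    """
    if interval not in INTERVALS:
        raise ConfigError(f"unknown interval {interval!r}, expected one of {INTERVALS}")
    sub = offline[offline["condition_id"] == condition_id]
    if sub.empty:
        raise AlignmentError(f"no offline samples for condition {condition_id!r}")
    if interval == "6h":
        t = sub["time_h"].to_numpy(float)
        sub = sub[np.abs(t / 6.0 - np.round(t / 6.0)) < 1e-9]
    return sub.sort_values("time_h")


@dataclass
class AlignedDataset:
    """Feature rows with interpolated offline reference values.

    ``y`` maps (parameter, interval) -> reference value per row; glycerol
    references are stored in *consumed* space alongside per-row S0 so the
    residual representation is recoverable exactly.
    """

    X: FeatureMatrix
    y: dict[tuple[str, str], np.ndarray]
    S0: np.ndarray  # initial glycerol per row (for the consumed transform)
    horizon: float
    out_of_span: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def times(self) -> np.ndarray:
        return self.X.row_meta["time_h"].to_numpy(float)

    def y_ref(self, parameter: str, interval: str) -> np.ndarray:
        return self.y[(parameter, interval)]


def align_offline(
    fm: FeatureMatrix,
    offline: pd.DataFrame,
    conditions_S0: dict[str, float],
    horizon: float = 25.0,
    intervals: tuple[str, ...] = INTERVALS,
) -> AlignedDataset:
    """Truncate to `horizon` and interpolate every offline parameter at each
    spectral timestamp, once per sampling interval."""
    fm = truncate_horizon(fm, horizon)
    times = fm.row_meta["time_h"].to_numpy(float)
    cond_ids = fm.row_meta["condition_id"].to_numpy()
    missing = [c for c in np.unique(cond_ids) if c not in conditions_S0]
    if missing:
        raise AlignmentError(f"missing S0 for conditions {missing}")
    S0 = np.asarray([conditions_S0[c] for c in cond_ids], float)

    y: dict[tuple[str, str], np.ndarray] = {}
    out_of_span = np.zeros(times.size, bool)
    for interval in intervals:
        per_param = {p: np.empty(times.size) for p in PARAMETERS}
        for cid in np.unique(cond_ids):
            sub = offline_on_grid(offline, cid, interval)
            sel = cond_ids == cid
            st = sub["time_h"].to_numpy(float)
            out_of_span[sel] |= (times[sel] < st.min() - _TOL) | (times[sel] > st.max() + _TOL)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for param, col in PARAMETERS.items():
                    per_param[param][sel] = interpolate_offline(
                        st, sub[col].to_numpy(float), times[sel]
                    )
        for param in PARAMETERS:
            vals = per_param[param]
            if param == "glycerol":
                vals = glycerol_to_consumed(vals, S0)  # store in consumed space
            y[(param, interval)] = vals
    if any(not np.all(np.isfinite(v)) for v in y.values()):
        raise AlignmentError("non-finite interpolated reference value")
    return AlignedDataset(X=fm, y=y, S0=S0, horizon=horizon, out_of_span=out_of_span)
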