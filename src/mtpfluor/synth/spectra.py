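"""Forward model turning cultivation state into 2D fluorescence spectra.

A spectrum is the sum of Gaussian excitation x emission bands (each tied
to one state variable), a scattered-light ridge along the Em = Ex
bisecting line, an early-cultivation optical artifact, and measurement
noise.  Fluorescence bands obey the Stokes shift (emission strictly above
excitation); the scattered-light ridge saturates in biomass and declines
phenomenologically after substrate depletion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import Spectrum2D
from ..errors import ConfigError

__all__ = ["Band", "SpectralModel", "StatePoint", "render_spectrum", "default_spectral_model"]


@dataclass(frozen=True)
class Band:
    """One Gaussian fluorophore band; amplitude scales with `driver`."""

    name: str
    ex_center: float
    ex_width: float
    em_center: float
    em_width: float
    amplitude: float
    driver: str  # 'X' | 'G' | 'const'

    def __post_init__(self) -> None:
        if self.ex_width <= 0 or self.em_width <= 0:
            raise ValueError(f"band {self.name!r}: widths must be positive")
        if self.driver not in ("X", "G", "const"):
            raise ValueError(f"band {self.name!r}: unknown driver {self.driver!r}")
        if self.em_center < self.ex_center:
            raise ValueError(f"band {self.name!r}: Stokes shift requires em_center >= ex_center")


@dataclass(frozen=True)
class SpectralModel:
    components: tuple[Band, ...]
    scatter_gain: float = 6200.0    # a.u. per g/L CDW (before saturation)
    scatter_sat: float = 15.0       # g/L saturation constant
    scatter_width: float = 6.0      # nm, ridge width in (em - ex)
    noise_add_sd: float = 15.0      # a.u.
    noise_mult_sd: float = 0.005    # fraction
    well_gain_sd: float = 0.02      # fraction, per-well static gain
    early_artifact_amp: float = 60.0  # a.u., low-turbidity artifact for t < 6 h

    def __post_init__(self) -> None:
        for sd in (self.noise_add_sd, self.noise_mult_sd, self.well_gain_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.scatter_sat <= 0 or self.scatter_width <= 0:
            raise ValueError("scatter_sat and scatter_width must be positive")


def default_spectral_model(**overrides) -> SpectralModel:
    """Band placements follow the observed spectral areas: the main
    fluorophore band around Ex 440-550 / Em 470-600 nm (driver G), a flavin
    band below Ex 440 nm (driver X), a secondary band near Ex 300-330 nm,
    and a constant plate-bottom band at Ex 280-350 / Em 290-360 nm."""
    bands = (
        Band("gfp", 495.0, 30.0, 535.0, 35.0, 1.0, "G"),
        Band("flavin", 410.0, 28.0, 515.0, 32.0, 950.0, "X"),
        Band("uv_secondary", 315.0, 12.0, 510.0, 28.0, 0.12, "G"),
        Band("plate_bottom", 310.0, 16.0, 325.0, 18.0, 4000.0, "const"),
    )
    return SpectralModel(components=bands, **overrides)


@dataclass(frozen=True)
class StatePoint:
    """Trajectory point handed to the renderer."""

    time_h: float
    X: float
    G: float
    scatter_decay: float = 1.0


class _ModelCache:
    """Pre-evaluated band profiles for one (model, grids) pair."""

    def __init__(self, model: SpectralModel, ex_grid: np.ndarray, em_grid: np.ndarray):
        self.model = model
        self.ex_grid = np.asarray(ex_grid, float)
        self.em_grid = np.asarray(em_grid, float)
        ex = self.ex_grid[:, None]
        em = self.em_grid[None, :]
        stokes = em > ex
        self.profiles: dict[str, np.ndarray] = {}
        for b in model.components:
            prof = (
                b.amplitude
                * np.exp(-0.5 * ((ex - b.ex_center) / b.ex_width) ** 2)
                * np.exp(-0.5 * ((em - b.em_center) / b.em_width) ** 2)
            )
            self.profiles[b.name] = np.where(stokes, prof, 0.0)
        self.ridge = np.exp(-0.5 * ((em - ex) / model.scatter_width) ** 2)

    def matches(self, model: SpectralModel, ex_grid: np.ndarray, em_grid: np.ndarray) -> bool:
        return (
            self.model == model
            and np.array_equal(self.ex_grid, ex_grid)
            and np.array_equal(self.em_grid, em_grid)
        )


ModelCache = _ModelCache  # public alias

_cache: _ModelCache | None = None


def _get_cache(model: SpectralModel, ex_grid: np.ndarray, em_grid: np.ndarray) -> _ModelCache:
    global _cache
    if _cache is None or not _cache.matches(model, ex_grid, em_grid):
        _cache = _ModelCache(model, ex_grid, em_grid)
    return _cache


def _driver_value(driver: str, state: StatePoint) -> float:
    if driver == "X":
        return state.X
    if driver == "G":
        return state.G
    return 1.0


def scatter_amplitude(model: SpectralModel, X: float, decay: float = 1.0) -> float:
    """Saturating biomass law for the scattered-light ridge."""
    return model.scatter_gain * X / (1.0 + X / model.scatter_sat) * decay


def early_artifact(model: SpectralModel, t: float) -> float:
    """Decaying non-negative oscillation on the ridge for t < 6 h."""
    if t >= 6.0 or model.early_artifact_amp == 0.0:
        return 0.0
    return model.early_artifact_amp * np.exp(-t / 2.0) * 0.5 * (1.0 + np.cos(2 * np.pi * t / 1.5))


def render_spectrum(
    state: StatePoint,
    model: SpectralModel,
    ex_grid: np.ndarray,
    em_grid: np.ndarray,
    rng: np.random.Generator | None = None,
    well_gain: float = 1.0,
    well_id: str = "",
    meta: dict | None = None,
    cache: _ModelCache | None = None,
) -> Spectrum2D:
    """Render one noise-free or noisy spectrum for a trajectory point.

    Noise is applied only when `rng` is given: multiplicative first, then
    additive, after scaling by the per-well static gain.  Passing an
    explicit `cache` built for different grids or a different model is a
    configuration error.
    """
    if not all(np.isfinite(v) for v in (state.time_h, state.X, state.G, state.scatter_decay)):
        raise ConfigError(f"non-finite state at t={state.time_h}")
    ex_grid = np.asarray(ex_grid, float)
    em_grid = np.asarray(em_grid, float)
    if cache is not None:
        if not cache.matches(model, ex_grid, em_grid):
            raise ConfigError("model cache was built for different grids or model")
    else:
        cache = _get_cache(model, ex_grid, em_grid)
    inten = np.zeros((cache.ex_grid.size, cache.em_grid.size))
    for b in model.components:
        inten += _driver_value(b.driver, state) * cache.profiles[b.name]
    ridge_amp = scatter_amplitude(model, state.X, state.scatter_decay)
    ridge_amp += early_artifact(model, state.time_h)
    inten += ridge_amp * cache.ridge
    inten *= well_gain
    if rng is not None:
        if model.noise_mult_sd > 0:
            inten *= 1.0 + model.noise_mult_sd * rng.standard_normal(inten.shape)
        if model.noise_add_sd > 0:
            inten += model.noise_add_sd * rng.standard_normal(inten.shape)
    base_meta = {"integration_time_ms": 30}
    if meta:
        base_meta.update(meta)
    return Spectrum2D(
        well_id=well_id,
        time_h=float(state.time_h),
        ex_grid=cache.ex_grid,
        em_grid=cache.em_grid,
        intensities=inten,
        meta=base_meta,
    )
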