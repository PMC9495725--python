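"""Single-response partial least-squares regression (SIMPLS) and metrics.

The SIMPLS procedure iterates on the covariance vector s = Xc' yc: each
latent variable takes its weight vector from s, forms a unit-norm score
t = Xc r / ||Xc r||, computes loadings p = Xc' t and q = yc' t, and then
deflates s by projecting out the orthonormalised loading basis.  Data are
mean-centred only (no autoscaling of features; switchable by callers
scaling beforehand).  Scores use the unit-norm convention — coefficient
vectors, though not predictions, depend on this choice.

For a univariate response the coefficient vector coincides with NIPALS
PLS1 at the same number of latent variables, and at full rank with the
minimum-norm least-squares solution.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = ["PLSModel", "fit_simpls", "predict", "rmse", "relative_rmse", "r_squared"]


@dataclass
class PLSModel:
    n_lv: int
    x_center: np.ndarray
    y_center: float
    weights: np.ndarray  # (n_lv, n_features)
    x_loadings: np.ndarray  # (n_lv, n_features)
    y_loadings: np.ndarray  # (n_lv,)
    coefficients: np.ndarray  # (n_features,)
    parameter_name: str = ""

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_lv": self.n_lv,
            "parameter_name": self.parameter_name,
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_lv=d["n_lv"],
            x_center=np.asarray(d["x_center"]),
            y_center=d["y_center"],
            weights=np.asarray(d["weights"]),
            x_loadings=np.asarray(d["x_loadings"]),
            y_loadings=np.asarray(d["y_loadings"]),
            coefficients=np.asarray(d["coefficients"]),
            parameter_name=d.get("parameter_name", ""),
        )


def fit_simpls(X: np.ndarray, y: np.ndarray, n_lv: int, parameter_name: str = "") -> PLSModel:
    """Fit a single-response SIMPLS model with `n_lv` latent variables."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ConfigError(f"X has {n} rows but y has {y.size}")
    if n_lv < 1:
        raise ConfigError(f"n_lv must be >= 1, got {n_lv}")
    if np.std(y) == 0:
        raise ConfigError("zero-variance response")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    Xc = X - x_center
    yc = y - y_center
    scale = float(np.linalg.norm(Xc)) * float(np.linalg.norm(yc))
    tol = 1e-12 * max(scale, 1.0)

    s = Xc.T @ yc
    R = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    q = np.zeros(n_lv)
    V = np.zeros((n_lv, p))  # orthonormalised loading basis
    for a in range(n_lv):
        r = s.copy()
        t = Xc @ r
        t_norm = float(np.linalg.norm(t))
        if t_norm <= tol:
            raise ConfigError(
                f"n_lv={n_lv} exceeds the rank of the centred data "
                f"(score collapsed at LV {a + 1})"
            )
        t /= t_norm
        r /= t_norm
        pvec = Xc.T @ t
        q[a] = float(yc @ t)
        v = pvec.copy()
        for b in range(a):
            v -= V[b] * (V[b] @ pvec)
        v_norm = float(np.linalg.norm(v))
        if v_norm <= tol:
            raise ConfigError(f"n_lv={n_lv} exceeds the rank of the centred data")
        v /= v_norm
        s = s - v * (v @ s)
        R[a], P[a] = r, pvec
        V[a] = v

    coefficients = R.T @ q
    return PLSModel(
        n_lv=n_lv,
        x_center=x_center,
        y_center=y_center,
        weights=R,
        x_loadings=P,
        y_loadings=q,
        coefficients=coefficients,
        parameter_name=parameter_name,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """y_hat = (X - x_center) @ coefficients + y_center."""
    X = np.asarray(X, float)
    if X.shape[-1] != model.coefficients.size:
        raise ConfigError(
            f"feature count {X.shape[-1]} does not match model ({model.coefficients.size})"
        )
    return (X - model.x_center) @ model.coefficients + model.y_center


def rmse(y_hat, y_ref) -> float:
    """Root-mean-square error."""
    y_hat = np.asarray(y_hat, float).ravel()
    y_ref = np.asarray(y_ref, float).ravel()
    if y_hat.size == 0 or y_hat.size != y_ref.size:
        raise ConfigError("rmse inputs must be non-empty and of equal length")
    return float(np.sqrt(np.mean((y_hat - y_ref) ** 2)))


def relative_rmse(value: float, value_range: float) -> float:
    """RMSE as a percentage of the offline-parameter range."""
    if value_range <= 0:
        raise ConfigError(f"range must be positive, got {value_range}")
    return 100.0 * value / value_range


def r_squared(y_hat, y_ref) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of parity pairs."""
    y_hat = np.asarray(y_hat, float).ravel()
    y_ref = np.asarray(y_ref, float).ravel()
    if y_hat.size == 0 or y_hat.size != y_ref.size:
        raise ConfigError("r_squared inputs must be non-empty and of equal length")
    ss_res = float(np.sum((y_ref - y_hat) ** 2))
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if ss_tot == 0:
        raise ConfigError("constant reference values: R^2 undefined")
    return 1.0 - ss_res / ss_tot
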