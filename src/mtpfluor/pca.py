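"""Principal component analysis of the feature matrix.

Mean-centring only (no variance scaling — unit-variance scaling would
inflate empty spectral regions); the decomposition is the truncated SVD of
the centred matrix.  Component signs are fixed so that the
largest-magnitude loading element is positive, making results reproducible
across runs and libraries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import mean_over_replicates
from .errors import ConfigError
from .preprocess import FeatureMatrix

__all__ = ["PCAResult", "fit_pca", "scores_over_time", "score_plot"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # (n_pc, n_features)
    scores: np.ndarray  # (n_rows, n_pc)
    explained_pct: np.ndarray  # percentage of total variance per PC
    center: np.ndarray  # per-feature mean
    row_meta: pd.DataFrame | None = None

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.center + self.scores @ self.loadings


def fit_pca(fm: FeatureMatrix | np.ndarray, n_pc: int) -> PCAResult:
    """SVD-based PCA; explained percentage is sigma_k^2 over total variance."""
    if isinstance(fm, FeatureMatrix):
        X, row_meta = fm.values, fm.row_meta
    else:
        X, row_meta = np.asarray(fm, float), None
    n, p = X.shape
    if n < 2:
        raise ConfigError(f"need >= 2 rows, got {n}")
    if not (1 <= n_pc <= min(n - 1, p)):
        raise ConfigError(f"n_pc={n_pc} outside [1, {min(n - 1, p)}]")
    center = X.mean(axis=0)
    Xc = X - center
    total = float(np.sum(Xc**2))
    if total <= 0:
        raise ConfigError("zero-variance matrix: nothing to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| element positive per component
    for k in range(min(n_pc, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    loadings = Vt[:n_pc]
    scores = U[:, :n_pc] * s[:n_pc]
    explained = 100.0 * s[:n_pc] ** 2 / total
    return PCAResult(loadings, scores, explained, center, row_meta)


def scores_over_time(res: PCAResult, pc: int) -> pd.DataFrame:
    """Per-condition mean and sample sd of one PC's scores over time."""
    if res.row_meta is None:
        raise ConfigError("PCAResult carries no row metadata")
    if not (0 <= pc < res.n_pc):
        raise ConfigError(f"unknown pc index {pc}")
    frame = res.row_meta.copy()
    frame["score"] = res.scores[:, pc]
    return mean_over_replicates(frame, value_col="score")


def score_plot(res: PCAResult, pc_x: int = 0, pc_y: int = 1) -> pd.DataFrame:
    """Ordered (score_x, score_y) trajectory table per well."""
    if res.row_meta is None:
        raise ConfigError("PCAResult carries no row metadata")
    for pc in (pc_x, pc_y):
        if not (0 <= pc < res.n_pc):
            raise ConfigError(f"unknown pc index {pc}")
    frame = res.row_meta.copy()
    frame["score_x"] = res.scores[:, pc_x]
    frame["score_y"] = res.scores[:, pc_y]
    return frame.sort_values(["well_id", "time_h"], ignore_index=True)
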