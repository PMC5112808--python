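"""PCA fusion of concatenated texture features.

Features are centred on the training mean and projected onto the leading
eigenvectors of the sample covariance (unbiased 1/(n-1) scaling).  The
retained dimension D is either given explicitly or chosen as the smallest D
whose cumulative eigenvalue fraction reaches ``variance_fraction``; D is
always capped at min(L-1, n-1) so the projection is a strict reduction.
Each basis column's largest-magnitude entry is made positive so fitted
models are deterministic run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import ConfigError

__all__ = ["FusionModel", "fit_pca", "project"]


@dataclass
class FusionModel:
    mean_vector: np.ndarray  # (L,)
    basis: np.ndarray  # (L, D), orthonormal columns
    eigenvalues: np.ndarray  # descending, length >= D
    D: int

    @property
    def input_dim(self) -> int:
        return self.mean_vector.shape[0]


def fit_pca(feature_table: np.ndarray, variance_fraction: float = 0.95, D: int | None = None) -> FusionModel:
    """Fit the PCA fusion model on a (n_samples, L) feature table."""
    F = np.asarray(feature_table, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 2 or F.shape[1] < 2:
        raise ConfigError("feature table must be (n >= 2, L >= 2)")
    n, L = F.shape
    if np.allclose(F.std(axis=0), 0.0):
        raise ConfigError("constant feature table: covariance is zero")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(F)
    eigenvalues = pca.explained_variance_.copy()
    cap = min(L - 1, n - 1)
    if D is not None:
        if D < 1:
            raise ConfigError("D must be >= 1")
        D_eff = min(D, cap, eigenvalues.shape[0])
    else:
        if not 0 < variance_fraction <= 1:
            raise ConfigError("variance_fraction must be in (0, 1]")
        frac = np.cumsum(eigenvalues) / eigenvalues.sum()
        D_eff = int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)
        D_eff = min(D_eff, cap)
    basis = pca.components_[:D_eff].T.copy()  # (L, D)
    # deterministic sign: largest-|entry| of each column positive
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(D_eff)])
    signs[signs == 0] = 1.0
    basis *= signs
    return FusionModel(
        mean_vector=pca.mean_.copy(),
        basis=basis,
        eigenvalues=eigenvalues,
        D=D_eff,
    )


def project(model: FusionModel, feature_vector: np.ndarray) -> np.ndarray:
    """Project centred features onto the retained basis: y = U_D^T (f - mean).

    Accepts a single vector (L,) or a batch (n, L).
    """
    f = np.asarray(feature_vector, dtype=np.float64)
    single = f.ndim == 1
    if single:
        f = f[None, :]
    if f.shape[1] != model.input_dim:
        raise ConfigError(
            f"feature length {f.shape[1]} does not match model dimension {model.input_dim}"
        )
    y = (f - model.mean_vector) @ model.basis
    return y[0] if single else y
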