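"""Standardization, PCA feature extraction, and the systematic 7:3 split.

Standardization is the per-variable z-score S = (x - mu) / sigma with the
population standard deviation (divide by n), matching the StandardScaler
convention.  PCA follows the bilinear decomposition X = T P^T + E with scores
T (n x k), orthonormal loadings P (m x k) ordered by explained variance, and
residual E.  The train/test split is a deterministic systematic (interleaved)
sample within each stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from swirclass.spectra_io import SpectraDataset, Spectrum


@dataclass
class StandardizerParams:
    """Fitted per-variable mean and population standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have the same length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be non-negative")


@dataclass
class PCAModel:
    """Fitted PCA: centering mean, loading matrix P (m x k), variances."""

    mean: np.ndarray
    loadings: np.ndarray  # (m, k), orthonormal columns
    explained_variance: np.ndarray
    k: int


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic systematic train/test split specification.

    Within each stratum, row indices are taken in file order and walked in
    blocks of 10: with train_fraction f, the first round(10 f) indices of each
    block go to the training set and the rest to the test set.  At f = 0.7
    this sends index i to the test set iff (i mod 10) >= 7.
    """

    train_fraction: float = 0.7
    stratify_by: tuple[str, ...] = ("product_class", "physical_state")
    ordering: str = "file"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def fit_standardizer(train: SpectraDataset) -> StandardizerParams:
    """Per-variable mean and population std over the training spectra."""
    if len(train) == 0:
        raise ValueError("cannot fit a standardizer on an empty dataset")
    X = train.X
    return StandardizerParams(mu=X.mean(axis=0), sigma=X.std(axis=0, ddof=0))


def apply_standardizer(ds: SpectraDataset, p: StandardizerParams) -> SpectraDataset:
    """z-score each variable; variables with sigma == 0 map to 0."""
    if ds.grid.n_points != p.mu.shape[0]:
        raise ValueError(
            f"dataset has {ds.grid.n_points} variables but params expect {p.mu.shape[0]}"
        )
    safe_sigma = np.where(p.sigma == 0, 1.0, p.sigma)
    Xs = (ds.X - p.mu) / safe_sigma
    Xs[:, p.sigma == 0] = 0.0
    spectra = [Spectrum(s.meta, row) for s, row in zip(ds.spectra, Xs)]
    return SpectraDataset(ds.grid, spectra)


def standardize_matrix(X: np.ndarray, p: StandardizerParams) -> np.ndarray:
    """Matrix form of :func:`apply_standardizer` for feature tables."""
    safe_sigma = np.where(p.sigma == 0, 1.0, p.sigma)
    Xs = (np.asarray(X, dtype=float) - p.mu) / safe_sigma
    Xs[:, p.sigma == 0] = 0.0
    return Xs


def fit_pca(train: SpectraDataset, k: int) -> PCAModel:
    """Top-k principal axes of the centered training matrix.

    Components are ordered by explained variance, descending.  ``k`` must not
    exceed min(n - 1, m).
    """
    if len(train) == 0:
        raise ValueError("cannot fit PCA on an empty dataset")
    X = train.X
    n, m = X.shape
    bound = min(n - 1, m)
    if k < 1 or k > bound:
        raise ValueError(f"k must satisfy 1 <= k <= min(n-1, m) = {bound}, got {k}")
    pca = _SKPCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        mean=pca.mean_.copy(),
        loadings=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_.copy(),
        k=k,
    )


def apply_pca(ds: SpectraDataset, model: PCAModel) -> np.ndarray:
    """Score matrix T = (X - mean) P, one row per spectrum (n x k)."""
    if ds.grid.n_points != model.mean.shape[0]:
        raise ValueError(
            f"dataset has {ds.grid.n_points} variables but model expects {model.mean.shape[0]}"
        )
    return (ds.X - model.mean) @ model.loadings


def transform_pca(X: np.ndarray, model: PCAModel) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError("feature width does not match the PCA model")
    return (X - model.mean) @ model.loadings


def reconstruct_pca(T: np.ndarray, model: PCAModel) -> np.ndarray:
    """Inverse map T -> T P^T + mean (residual E discarded)."""
    return np.asarray(T) @ model.loadings.T + model.mean


def _systematic_indices(n: int, train_fraction: float) -> tuple[list[int], list[int]]:
    n_train_per_block = int(round(10 * train_fraction))
    train_idx, test_idx = [], []
    for i in range(n):
        (train_idx if (i % 10) < n_train_per_block else test_idx).append(i)
    return train_idx, test_idx


def systematic_split(
    ds: SpectraDataset, spec: SplitSpec = SplitSpec()
) -> tuple[SpectraDataset, SpectraDataset]:
    """Deterministic stratified systematic split into (train, test).

    Strata are the distinct combinations of ``spec.stratify_by`` metadata
    fields; within each stratum the interleaving rule of :class:`SplitSpec`
    applies.  Every stratum must have at least 2 members.
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    meta = ds.meta_frame()
    for f in spec.stratify_by:
        if f not in meta.columns:
            raise ValueError(f"unknown stratification field {f!r}")
    keys = list(zip(*(meta[f] for f in spec.stratify_by))) if spec.stratify_by else [()] * len(ds)
    strata: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        strata.setdefault(key, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for key, rows in strata.items():
        if len(rows) < 2:
            raise ValueError(
                f"stratum {key} has {len(rows)} member(s); need at least 2 to split"
            )
        tr, te = _systematic_indices(len(rows), spec.train_fraction)
        if not tr or not te:
            raise ValueError(f"stratum {key} too small to populate both split sides")
        train_idx.extend(rows[i] for i in tr)
        test_idx.extend(rows[i] for i in te)
    train_idx.sort()
    test_idx.sort()
    return ds.select(train_idx), ds.select(test_idx)


def save_transforms(
    path: str | Path,
    standardizer: StandardizerParams | None = None,
    pca: PCAModel | None = None,
) -> Path:
    """Persist fitted transforms to a .npz container."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    if standardizer is not None:
        arrays["standardizer_mu"] = standardizer.mu
        arrays["standardizer_sigma"] = standardizer.sigma
    if pca is not None:
        arrays["pca_mean"] = pca.mean
        arrays["pca_loadings"] = pca.loadings
        arrays["pca_explained_variance"] = pca.explained_variance
    np.savez(path, **arrays)
    return path


def load_transforms(path: str | Path) -> tuple[StandardizerParams | None, PCAModel | None]:
    data = np.load(Path(path))
    std = None
    pca = None
    if "standardizer_mu" in data:
        std = StandardizerParams(data["standardizer_mu"], data["standardizer_sigma"])
    if "pca_mean" in data:
        pca = PCAModel(
            mean=data["pca_mean"],
            loadings=data["pca_loadings"],
            explained_variance=data["pca_explained_variance"],
            k=data["pca_loadings"].shape[1],
        )
    return std, pca
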