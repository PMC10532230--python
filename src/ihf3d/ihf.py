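"""Intensity Histogram Features (IHF) out-of-distribution detector.

The method scores a 3D scan against a reference cohort using nothing but its
intensity distribution:

*Step 1* — after standardization to [0, 1], compute the probability density
function of the voxel intensities over ``m`` equal bins, giving an embedding
``e(x)`` in R^m.

*Step 2* — optionally reduce the embeddings with PCA fitted once on the
training cohort, keeping the smallest number of components whose cumulative
explained-variance ratio reaches ``v`` (default 99.99%).  This guards the
covariance estimate against ill-conditioning in high dimension.

*Step 3* — score a test embedding ``ẽ(x)`` by either the Mahalanobis distance

    S_Mah(x) = sqrt( (ẽ(x) − μ̂)ᵀ Σ̂⁻¹ (ẽ(x) − μ̂) )

with μ̂, Σ̂ the training mean and (population, divisor-n) covariance, or the
Euclidean distance to the nearest training embedding (min-distance),

    S_NN(x) = min over training x' of ‖ẽ(x) − ẽ(x')‖₂.

Higher scores mean a higher outlier likelihood.  The fit and scoring paths
are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .preprocess import PreprocessConfig, preprocess
from .volume_io import Volume

__all__ = [
    "HistogramEmbedding",
    "PCAReducer",
    "IHFConfig",
    "IHFReference",
    "compute_histogram",
    "fit_reducer",
    "reduce_embedding",
    "fit_reference",
    "score_mahalanobis",
    "score_nn",
    "score",
    "save_reference",
    "load_reference",
]

#: ridge factor applied to the covariance before factorization
COV_RIDGE = 1e-6


@dataclass
class HistogramEmbedding:
    """Density-normalized intensity histogram: m bins partitioning [0, 1]."""

    values: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.m,):
            raise ValueError(f"expected {self.m} bin values, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("histogram densities must be nonnegative")


@dataclass
class PCAReducer:
    """Linear reducer e -> basisᵀ(e − center) with orthonormal basis columns."""

    center: np.ndarray
    basis: np.ndarray  # (m, k), orthonormal columns
    explained_variance_ratio: float

    @property
    def k(self) -> int:
        return self.basis.shape[1]


@dataclass
class IHFConfig:
    """Detector hyperparameters: bin count m, PCA variance target v, scorer."""

    m: int = 150
    v: float = 0.9999
    use_pca: bool = True
    scorer: str = "mahalanobis"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if not 0 < self.v <= 1:
            raise ValueError(f"v must be in (0, 1], got {self.v}")
        if self.scorer not in ("mahalanobis", "nn"):
            raise ValueError(f"scorer must be 'mahalanobis' or 'nn', got {self.scorer!r}")


@dataclass
class IHFReference:
    """Fitted detector state: reducer, reduced training embeddings, μ̂, Σ̂."""

    reducer: PCAReducer | None
    train_reduced: np.ndarray  # (n, k)
    mean: np.ndarray  # (k,)
    covariance: np.ndarray  # (k, k), ridge-regularized
    config: IHFConfig
    solve_handle: tuple = field(default=None, repr=False)  # cho_factor output

    def __post_init__(self) -> None:
        if self.solve_handle is None:
            self.solve_handle = linalg.cho_factor(self.covariance, lower=True)


def compute_histogram(v: Volume | np.ndarray, m: int) -> HistogramEmbedding:
    """Probability density function of the intensities of a preprocessed volume.

    Bin i covers [i/m, (i+1)/m), the last bin is closed at 1; the returned
    values are densities count_i * m / N, so sum(values)/m == 1.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("intensities must lie in [0, 1]; run preprocessing first")
    densities, _ = np.histogram(data, bins=m, range=(0.0, 1.0), density=True)
    return HistogramEmbedding(values=densities, m=m)


def fit_reducer(train_embeddings: np.ndarray, v: float) -> PCAReducer:
    """Fit PCA_v on an (n, m) matrix of training embeddings.

    Keeps the smallest k whose cumulative explained-variance ratio is >= v,
    capped at min(n − 1, m); v = 1.0 keeps the full rank of the centered data.
    """
    E = np.asarray(train_embeddings, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("need at least 2 training embeddings in an (n, m) matrix")
    n, m = E.shape
    center = E.mean(axis=0)
    X = E - center
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    cap = min(n - 1, m)
    if total <= 0:
        # zero-variance cohort: keep a single (arbitrary orthonormal) direction
        return PCAReducer(center=center, basis=Vt[:1].T.copy(), explained_variance_ratio=1.0)
    ratios = s**2 / total
    cum = np.cumsum(ratios)
    if v >= 1.0:
        tol = s[0] * max(n, m) * np.finfo(np.float64).eps
        k = int(np.sum(s > tol))  # numerical rank of centered data
    else:
        k = int(np.searchsorted(cum, v - 1e-12) + 1)
    k = max(1, min(k, cap))
    return PCAReducer(center=center, basis=Vt[:k].T.copy(), explained_variance_ratio=float(cum[k - 1]))


def reduce_embedding(reducer: PCAReducer | None, e: HistogramEmbedding | np.ndarray) -> np.ndarray:
    """Project an embedding into the reduced space; identity when no reducer is set."""
    vec = e.values if isinstance(e, HistogramEmbedding) else np.asarray(e, dtype=np.float64)
    if reducer is None:
        return vec.copy()
    if vec.shape != reducer.center.shape:
        raise ValueError(f"embedding length {vec.shape} does not match reducer ({reducer.center.shape})")
    return reducer.basis.T @ (vec - reducer.center)


def _embed(v: Volume, config: IHFConfig, pre: PreprocessConfig) -> np.ndarray:
    return compute_histogram(preprocess(v, pre), config.m).values


def fit_reference(
    train_volumes: list[Volume],
    config: IHFConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> IHFReference:
    """Fit the detector on a training cohort of raw volumes.

    Runs preprocess -> histogram -> (optional) PCA on every volume, then
    estimates μ̂ and the population covariance Σ̂ (divisor n) in the reduced
    space.  Σ̂ receives a small trace-scaled ridge before factorization so the
    Mahalanobis solve is always well posed.
    """
    config = config or IHFConfig()
    preprocess_config = preprocess_config or PreprocessConfig()
    if len(train_volumes) < 2:
        raise ValueError("need at least 2 training volumes")
    E = np.stack([_embed(v, config, preprocess_config) for v in train_volumes])
    reducer = fit_reducer(E, config.v) if config.use_pca else None
    X = np.stack([reduce_embedding(reducer, e) for e in E])
    n, k = X.shape
    mean = X.mean(axis=0)
    D = X - mean
    cov = (D.T @ D) / n
    scale = float(np.trace(cov)) / k
    if scale <= 0:
        scale = 1.0  # zero-variance cohort: pure ridge
    cov = cov + COV_RIDGE * scale * np.eye(k)
    return IHFReference(reducer=reducer, train_reduced=X, mean=mean, covariance=cov, config=config)


def score_mahalanobis(ref: IHFReference, e_reduced: np.ndarray) -> float:
    """Mahalanobis distance of a reduced embedding from the training cohort."""
    e_reduced = np.asarray(e_reduced, dtype=np.float64)
    if e_reduced.shape != ref.mean.shape:
        raise ValueError(f"vector length {e_reduced.shape} does not match reference ({ref.mean.shape})")
    d = e_reduced - ref.mean
    # symmetric factorization solve; never forms Σ̂⁻¹ explicitly
    q = float(d @ linalg.cho_solve(ref.solve_handle, d))
    return float(np.sqrt(max(q, 0.0)))


def score_nn(ref: IHFReference, e_reduced: np.ndarray) -> float:
    """Euclidean distance to the nearest training embedding (min-distance)."""
    e_reduced = np.asarray(e_reduced, dtype=np.float64)
    if ref.train_reduced.size == 0:
        raise ValueError("reference has no training embeddings")
    if e_reduced.shape[0] != ref.train_reduced.shape[1]:
        raise ValueError("vector length does not match reference embeddings")
    d2 = np.sum((ref.train_reduced - e_reduced) ** 2, axis=1)
    return float(np.sqrt(d2.min()))


def score(
    ref: IHFReference,
    v: Volume,
    config: IHFConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> float:
    """OOD score of a raw volume: full preprocess -> histogram -> reduce -> scorer pipeline."""
    config = config or ref.config
    preprocess_config = preprocess_config or PreprocessConfig()
    e = _embed(v, config, preprocess_config)
    e_red = reduce_embedding(ref.reducer, e)
    if config.scorer == "nn":
        return score_nn(ref, e_red)
    return score_mahalanobis(ref, e_red)


FORMAT_VERSION = 1


def save_reference(ref: IHFReference, path: str | Path) -> None:
    """Serialize a fitted reference (arrays + config + format version) to one .npz archive."""
    payload: dict[str, np.ndarray] = {
        "format_version": np.array(FORMAT_VERSION),
        "train_reduced": ref.train_reduced,
        "mean": ref.mean,
        "covariance": ref.covariance,
        "m": np.array(ref.config.m),
        "v": np.array(ref.config.v),
        "use_pca": np.array(ref.config.use_pca),
        "scorer": np.array(ref.config.scorer),
    }
    if ref.reducer is not None:
        payload["pca_center"] = ref.reducer.center
        payload["pca_basis"] = ref.reducer.basis
        payload["pca_evr"] = np.array(ref.reducer.explained_variance_ratio)
    np.savez(path, **payload)


def load_reference(path: str | Path) -> IHFReference:
    with np.load(path, allow_pickle=False) as z:
        if int(z["format_version"]) != FORMAT_VERSION:
            raise ValueError(f"unsupported reference format version {int(z['format_version'])}")
        config = IHFConfig(m=int(z["m"]), v=float(z["v"]), use_pca=bool(z["use_pca"]), scorer=str(z["scorer"]))
        reducer = None
        if "pca_basis" in z:
            reducer = PCAReducer(
                center=z["pca_center"], basis=z["pca_basis"], explained_variance_ratio=float(z["pca_evr"])
            )
        return IHFReference(
            reducer=reducer,
            train_reduced=z["train_reduced"],
            mean=z["mean"],
            covariance=z["covariance"],
            config=config,
        )
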