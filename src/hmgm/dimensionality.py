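"""Standardization, Horn's parallel analysis, projection and back-projection.

The reduced model lives in the span of the first ``d`` principal eigenvectors
of the pooled correlation matrix (series are standardized per region, so
covariance and correlation coincide). A single eigenmatrix ``A`` (D x d) is
shared across subjects; fitted state means and covariances are mapped back to
region space as ``mu = mu* A^T`` and ``Sigma = A Sigma* A^T``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hmgm.containers import SubjectSeries, check_psd


@dataclass
class Eigenmatrix:
    """First ``d`` principal eigenvectors of the pooled correlation matrix.

    Columns are orthonormal; the sign of each column is fixed so that its
    largest-magnitude entry is positive, making the decomposition
    deterministic.
    """

    A: np.ndarray  # (D, d)
    explained_variance_fraction: float
    d: int
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be a D x d matrix")
        D, d = self.A.shape
        if not (1 <= d <= D):
            raise ValueError(f"need 1 <= d <= D, got d={d}, D={D}")
        if self.d != d:
            raise ValueError("d field does not match A's column count")
        gram = self.A.T @ self.A
        if not np.allclose(gram, np.eye(d), atol=1e-8):
            raise ValueError("columns of A are not orthonormal")
        if not (0.0 <= self.explained_variance_fraction <= 1.0 + 1e-12):
            raise ValueError("explained_variance_fraction must lie in [0, 1]")


def standardize(series: SubjectSeries | np.ndarray, subject_id: str = "subject") -> SubjectSeries:
    """Subtract each region's temporal mean and divide by its sample SD.

    Raises if any region is constant in time (its SD is zero and the region
    carries no usable signal), naming the offending region.
    """
    if isinstance(series, SubjectSeries):
        data, names, subject_id = series.data, series.region_names, series.subject_id
    else:
        data = np.asarray(series, dtype=float)
        names = [f"roi_{i:03d}" for i in range(data.shape[1])]
    if data.shape[0] < 2:
        raise ValueError("need at least 2 time points to standardize")
    sd = data.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant region(s) cannot be standardized: {[names[i] for i in zero]}")
    out = (data - data.mean(axis=0)) / sd
    return SubjectSeries(subject_id=subject_id, data=out, region_names=list(names))


def _correlation_eigvals(X: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the correlation matrix of ``X`` (rows = samples)."""
    R = np.corrcoef(X, rowvar=False)
    return np.linalg.eigvalsh(R)[::-1]


def parallel_analysis(
    pooled: np.ndarray,
    n_null: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis on the pooled (all subjects stacked) matrix.

    Observed correlation-matrix eigenvalues are compared, rank by rank,
    against the stated percentile of eigenvalues from ``n_null`` i.i.d.
    standard-normal datasets of identical shape. ``d`` is the number of
    leading eigenvalues exceeding their null percentile, stopping at the
    first failure; at least 1 component is always retained.
    """
    pooled = np.asarray(pooled, dtype=float)
    if n_null < 50:
        raise ValueError("n_null must be at least 50 for a stable percentile")
    n, D = pooled.shape
    if D > n:
        warnings.warn("more regions than pooled samples: correlation spectrum is rank-deficient")
    observed = _correlation_eigvals(pooled)
    rng = np.random.default_rng(seed)
    null = np.empty((n_null, D))
    for i in range(n_null):
        null[i] = _correlation_eigvals(rng.standard_normal((n, D)))
    threshold = np.percentile(null, percentile, axis=0)
    d = 0
    for lam, thr in zip(observed, threshold):
        if lam > thr:
            d += 1
        else:
            break
    return max(d, 1)


def fit_eigenmatrix(pooled: np.ndarray, d: int, region_names: list[str] | None = None) -> Eigenmatrix:
    """Leading ``d`` eigenvectors of the pooled correlation matrix."""
    pooled = np.asarray(pooled, dtype=float)
    D = pooled.shape[1]
    if not (1 <= d <= D):
        raise ValueError(f"need 1 <= d <= D, got d={d}")
    R = np.corrcoef(pooled, rowvar=False)
    w, v = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    A = v[:, :d].copy()
    # deterministic sign: largest-magnitude entry of each column positive
    flip = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    A *= flip
    evf = float(np.clip(w[:d].sum() / w.sum(), 0.0, 1.0))
    return Eigenmatrix(A=A, explained_variance_fraction=evf, d=d, region_names=region_names)


def reduce_series(series: SubjectSeries | np.ndarray, A: Eigenmatrix) -> np.ndarray:
    """Project a standardized T x D series onto the d leading components."""
    data = series.data if isinstance(series, SubjectSeries) else np.asarray(series, dtype=float)
    if data.shape[1] != A.A.shape[0]:
        raise ValueError(f"series has {data.shape[1]} regions but A expects {A.A.shape[0]}")
    return data @ A.A


def backproject(mu_star: np.ndarray, sigma_star: np.ndarray, A: Eigenmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Map reduced state parameters back to region space.

    ``Sigma = A Sigma* A^T`` and ``mu = mu* A^T``; for orthonormal ``A`` the
    spectrum of Sigma equals that of Sigma* padded with D - d zeros, so the
    back-projected covariance has rank at most d.
    """
    mu_star = np.asarray(mu_star, dtype=float).ravel()
    sigma_star = check_psd(np.asarray(sigma_star, dtype=float), name="sigma_star")
    if mu_star.size != A.d or sigma_star.shape[0] != A.d:
        raise ValueError("reduced parameters do not match eigenmatrix dimension d")
    mu = A.A @ mu_star
    sigma = A.A @ sigma_star @ A.A.T
    sigma = (sigma + sigma.T) / 2.0
    return mu, sigma


def write_eigenmatrix(A: Eigenmatrix, prefix: str | Path) -> None:
    """Write A as delimited text with region row labels plus a JSON sidecar."""
    prefix = Path(prefix)
    names = A.region_names or [f"roi_{i:03d}" for i in range(A.A.shape[0])]
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write("region\t" + "\t".join(f"pc{j+1}" for j in range(A.d)) + "\n")
        for name, row in zip(names, A.A):
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
    prefix.with_suffix(".json").write_text(
        json.dumps({"d": A.d, "explained_variance_fraction": A.explained_variance_fraction})
    )
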