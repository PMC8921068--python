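"""Shared containers and validation helpers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectSeries:
    """One subject's T x D regional activity matrix.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject (used to label occupancy rows).
    data : ndarray of shape (T, D)
        Regional signals, one column per region of interest.
    region_names : list of str
        Column labels; generated as ``roi_000 ...`` when absent.
    """

    subject_id: str
    data: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("subject series must be a 2-D (T x D) array")
        if not self.region_names:
            self.region_names = [f"roi_{i:03d}" for i in range(self.data.shape[1])]
        if len(self.region_names) != self.data.shape[1]:
            raise ValueError("region_names length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def check_row_stochastic(P: np.ndarray, *, tol: float = 1e-10, name: str = "P") -> np.ndarray:
    """Validate that ``P`` is a nonnegative matrix with rows summing to one."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {P.shape}")
    if np.any(P < -tol):
        raise ValueError(f"{name} has negative entries")
    rows = P.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > max(tol, 1e-8)):
        raise ValueError(f"rows of {name} do not sum to 1 (max deviation {np.abs(rows - 1).max():.3g})")
    return P


def check_psd(sigma: np.ndarray, *, tol: float = 1e-10, name: str = "sigma") -> np.ndarray:
    """Validate symmetry and positive semi-definiteness of a covariance matrix."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{name} must be square, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh((sigma + sigma.T) / 2.0)
    if w.min() < -max(tol, 1e-8 * max(w.max(), 1.0)):
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})")
    return sigma


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a derived seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))
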