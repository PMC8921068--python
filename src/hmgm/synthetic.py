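"""Ground-truthed synthetic inputs for every stage of the pipeline.

Three generators cover the three kinds of structure the pipeline is meant to
recover: a multi-subject hidden-Markov time-series generator (shared K-state
chain, multivariate-normal emissions per state), a planted-partition weighted
graph generator for community-detection validation, and a "planted coherent
state" builder that embeds a community whose mean activity aligns with its
covariance, giving a known functional-homogeneity signal.

All randomness is routed through one ``numpy.random.Generator`` seeded per
call; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hmgm.containers import SubjectSeries, check_psd, check_row_stochastic


@dataclass
class GeneratorSpec:
    """Parameters of the multi-subject HMM data generator.

    ``transition_matrix`` must be row-stochastic and every state covariance
    symmetric PSD; both are validated on construction. The initial state of
    each subject is drawn uniformly over states (the chain's initial law is a
    free choice of the generator; see docs/methods.md).
    """

    n_subjects: int
    n_timepoints: int
    n_regions: int
    n_states: int
    transition_matrix: np.ndarray
    state_means: np.ndarray
    state_covariances: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_timepoints", "n_regions", "n_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        self.transition_matrix = check_row_stochastic(
            np.asarray(self.transition_matrix, dtype=float), tol=1e-12, name="transition_matrix"
        )
        if self.transition_matrix.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix shape must be (n_states, n_states)")
        self.state_means = np.asarray(self.state_means, dtype=float)
        if self.state_means.shape != (self.n_states, self.n_regions):
            raise ValueError("state_means shape must be (n_states, n_regions)")
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        if self.state_covariances.shape != (self.n_states, self.n_regions, self.n_regions):
            raise ValueError("state_covariances shape must be (n_states, n_regions, n_regions)")
        for s in range(self.n_states):
            check_psd(self.state_covariances[s], tol=1e-10, name=f"state_covariances[{s}]")


@dataclass
class GroundTruth:
    """Latent structure behind a synthetic dataset (1-based state labels)."""

    state_paths: np.ndarray  # (n_subjects, T) of values in {1..K_true}
    temporal_labels: np.ndarray | None = None  # community label per state
    spatial_labels: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_paths = np.asarray(self.state_paths, dtype=int)
        if self.state_paths.min() < 1:
            raise ValueError("state_paths must use 1-based state labels")


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """Square root factor L with L @ L.T = sigma, valid for singular PSD input."""
    w, v = np.linalg.eigh((sigma + sigma.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def generate_hmm_dataset(spec: GeneratorSpec) -> tuple[list[SubjectSeries], GroundTruth]:
    """Simulate N independent subjects from one shared K-state Markov chain.

    Each subject starts in a uniformly drawn state; subsequent states follow
    the rows of ``spec.transition_matrix``; the observation at time t is drawn
    from the multivariate normal of the current state.

    Returns the subject series (unstandardized) and the true state paths.
    """
    rng = np.random.default_rng(spec.seed)
    K, T, D = spec.n_states, spec.n_timepoints, spec.n_regions
    factors = np.stack([_psd_factor(spec.state_covariances[s]) for s in range(K)])
    # Inverse-CDF sampling from precomputed row CDFs keeps the T-loop cheap.
    cdf = np.cumsum(spec.transition_matrix, axis=1)
    cdf[:, -1] = 1.0

    series: list[SubjectSeries] = []
    paths = np.empty((spec.n_subjects, T), dtype=int)
    names = [f"roi_{i:03d}" for i in range(D)]
    for n in range(spec.n_subjects):
        states = np.empty(T, dtype=int)
        states[0] = rng.integers(0, K)
        u = rng.random(T)
        for t in range(1, T):
            states[t] = np.searchsorted(cdf[states[t - 1]], u[t], side="right")
        z = rng.standard_normal((T, D))
        X = spec.state_means[states].copy()
        for s in range(K):
            mask = states == s
            if mask.any():
                X[mask] += z[mask] @ factors[s].T
        series.append(SubjectSeries(subject_id=f"sub-{n:02d}", data=X, region_names=list(names)))
        paths[n] = states + 1
    return series, GroundTruth(state_paths=paths)


def generate_planted_partition_graph(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    weight_scale: float = 1.0,
    directed: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted planted-partition graph with known community labels.

    Edges appear with probability ``p_in`` within blocks and ``p_out``
    between; weights are drawn uniform(0.5, 1.5) * ``weight_scale`` so that
    weighted and unweighted community structure coincide. Returns the dense
    weight matrix (symmetric unless ``directed``) and the 0-based labels.
    """
    if not block_sizes or any(b < 1 for b in block_sizes):
        raise ValueError("every block must contain at least one node")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("require 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    n = labels.size
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, p_in, p_out)
    present = rng.random((n, n)) < prob
    weights = (0.5 + rng.random((n, n))) * weight_scale
    W = np.where(present, weights, 0.0)
    np.fill_diagonal(W, 0.0)
    if not directed:
        W = np.triu(W, 1)
        W = W + W.T
    return W, labels


def plant_coherent_state(
    n_regions: int,
    community: list[int],
    mean_level: float,
    within_corr: float,
    seed: int = 0,
    background_sd: float = 1.0,
    background_corr: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a state (mu, Sigma) with one functionally coherent community.

    Regions inside ``community`` get mean ``mean_level``, unit variance and
    pairwise covariance ``within_corr``; all other regions are zero-mean with
    variance ``background_sd**2`` and pairwise correlation ``background_corr``
    (0 by default, i.e. independent noise; a small positive value makes the
    state's information graph walkable outside the planted block, which the
    random-walk null sampler needs). The planted community has functional
    homogeneity ``mean_level**2 * (|C| + |C|(|C|-1)*within_corr)``, strictly
    larger than matched background sets whenever mean_level and within_corr
    are positive.
    """
    community = np.asarray(sorted(set(int(c) for c in community)), dtype=int)
    if community.size < 2:
        raise ValueError("community must contain at least 2 regions")
    if community.min() < 0 or community.max() >= n_regions:
        raise ValueError("community indices out of range")
    if not (0.0 < within_corr < 1.0):
        raise ValueError("within_corr must lie in (0, 1)")
    if not (0.0 <= background_corr < 1.0):
        raise ValueError("background_corr must lie in [0, 1)")
    mu = np.zeros(n_regions)
    mu[community] = mean_level
    sigma = np.full((n_regions, n_regions), background_corr) * background_sd**2
    np.fill_diagonal(sigma, background_sd**2)
    block = np.full((community.size, community.size), within_corr)
    np.fill_diagonal(block, 1.0)
    sigma[np.ix_(community, community)] = block
    check_psd(sigma, name="planted sigma")
    return mu, sigma, community


def write_dataset(series: list[SubjectSeries], truth: GroundTruth, out_dir: str | Path) -> None:
    """Write one delimited text file per subject plus the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in series:
        header = "\t".join(s.region_names)
        np.savetxt(out / f"{s.subject_id}.tsv", s.data, delimiter="\t", header=header, comments="")
    payload = {"state_paths": truth.state_paths.tolist()}
    if truth.temporal_labels is not None:
        payload["temporal_labels"] = np.asarray(truth.temporal_labels).tolist()
    if truth.spatial_labels:
        payload["spatial_labels"] = {str(k): np.asarray(v).tolist() for k, v in truth.spatial_labels.items()}
    (out / "ground_truth.json").write_text(json.dumps(payload))


def read_dataset(in_dir: str | Path) -> list[SubjectSeries]:
    """Read subject series written by :func:`write_dataset` (or user data laid out the same way)."""
    series = []
    for path in sorted(Path(in_dir).glob("*.tsv")):
        with open(path) as fh:
            names = fh.readline().strip().split("\t")
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        series.append(SubjectSeries(subject_id=path.stem, data=np.atleast_2d(data), region_names=names))
    if not series:
        raise FileNotFoundError(f"no .tsv subject files found in {in_dir}")
    return series
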