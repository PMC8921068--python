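"""Multi-subject Gaussian-observation HMM fitting and occupancy statistics.

Subjects enter as independent trials sharing one set of states: a single
transition matrix P, and per-state multivariate-normal observation models in
the reduced d-dimensional space. Fitting is expectation-maximisation
(Baum-Welch) with full covariances, run from several random restarts; the
forward-backward recursion restarts at each trial boundary. The downstream
pipeline consumes only P, the state parameters and the smoothed posteriors,
so any fitting backend honouring that contract is interchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from hmgm.containers import SubjectSeries, check_psd, check_row_stochastic, spawn_seed
from hmgm.dimensionality import Eigenmatrix, backproject

__all__ = [
    "HMGModel",
    "OccupancyTable",
    "SubjectSeries",
    "fit_hmm",
    "posterior_marginals",
    "fractional_occupancy",
    "stationary_distribution",
]


@dataclass
class HMGModel:
    """A fitted hidden Markov graph model.

    Holds the K x K transition matrix ``P``, reduced state parameters
    (``mu_star``: K x d, ``sigma_star``: K x d x d), the eigenmatrix ``A``
    used for back-projection, and the back-projected region-space parameters
    (``mu``: K x D, ``sigma``: K x D x D). When no eigenmatrix is supplied the
    model lives directly in region space and ``mu``/``sigma`` alias the
    reduced parameters.
    """

    K: int
    P: np.ndarray
    mu_star: np.ndarray
    sigma_star: np.ndarray
    A: Eigenmatrix | None = None
    mu: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma: np.ndarray = field(default=None)  # type: ignore[assignment]
    startprob: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.P = check_row_stochastic(np.asarray(self.P, dtype=float), name="P")
        if self.P.shape[0] != self.K:
            raise ValueError("P dimension does not match K")
        self.mu_star = np.atleast_2d(np.asarray(self.mu_star, dtype=float))
        self.sigma_star = np.asarray(self.sigma_star, dtype=float)
        if self.sigma_star.ndim == 2:
            self.sigma_star = self.sigma_star[None]
        if self.startprob is None:
            self.startprob = np.full(self.K, 1.0 / self.K)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if self.mu is None or self.sigma is None:
            if self.A is not None:
                pairs = [backproject(m, s, self.A) for m, s in zip(self.mu_star, self.sigma_star)]
                self.mu = np.stack([p[0] for p in pairs])
                self.sigma = np.stack([p[1] for p in pairs])
            else:
                self.mu = self.mu_star
                self.sigma = self.sigma_star
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.A is not None:
            for s in range(self.K):
                m, S = backproject(self.mu_star[s], self.sigma_star[s], self.A)
                if np.abs(m - self.mu[s]).max() > 1e-10 or np.abs(S - self.sigma[s]).max() > 1e-10:
                    raise ValueError("mu/sigma inconsistent with back-projection of reduced parameters")

    @property
    def d(self) -> int:
        return self.mu_star.shape[1]

    def _backend(self) -> GaussianHMM:
        model = GaussianHMM(n_components=self.K, covariance_type="full", init_params="", params="")
        model.startprob_ = self.startprob
        model.transmat_ = self.P
        model.means_ = self.mu_star
        model.covars_ = self.sigma_star
        model.n_features = self.d
        return model


@dataclass
class OccupancyTable:
    """Per-subject fractional occupancy: kappa[n, s] = time-averaged posterior of state s."""

    kappa: np.ndarray  # (N, K)
    subject_ids: list[str]
    n_timepoints: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.kappa = np.atleast_2d(np.asarray(self.kappa, dtype=float))
        if np.any(self.kappa < -1e-12) or np.any(self.kappa > 1 + 1e-12):
            raise ValueError("kappa entries must lie in [0, 1]")
        if np.any(np.abs(self.kappa.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("kappa rows must sum to 1")
        if len(self.subject_ids) != self.kappa.shape[0]:
            raise ValueError("subject_ids length does not match kappa rows")
        if self.n_timepoints is None:
            self.n_timepoints = np.zeros(self.kappa.shape[0], dtype=int)
        self.n_timepoints = np.asarray(self.n_timepoints, dtype=int)

    @property
    def n_subjects(self) -> int:
        return self.kappa.shape[0]

    @property
    def n_states(self) -> int:
        return self.kappa.shape[1]


def _ridge_psd(cov: np.ndarray) -> np.ndarray:
    """Add eps = 1e-6 * trace/d to the diagonal only when numerically needed."""
    cov = (cov + cov.swapaxes(-1, -2)) / 2.0
    d = cov.shape[-1]
    out = cov.copy()
    for idx in range(cov.shape[0]):
        w = np.linalg.eigvalsh(cov[idx])
        eps = 1e-6 * np.trace(cov[idx]) / d
        if w.min() < eps * 1e-3:
            out[idx] = cov[idx] + np.eye(d) * max(eps, -w.min() + eps)
    return out


def fit_hmm(
    trials: list[np.ndarray],
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    A: Eigenmatrix | None = None,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> HMGModel:
    """Fit a k-state Gaussian HMM to the concatenated trials by EM.

    Runs ``n_restarts`` independently initialised EM fits and keeps the one
    with the highest training log-likelihood. Deterministic given ``seed``.
    States are reported in decreasing order of pooled fractional occupancy so
    that output ordering is stable across backends and restarts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    trials = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    if any(t.shape[0] < k for t in trials):
        raise ValueError("every trial needs at least k time points")
    X = np.concatenate(trials, axis=0)
    lengths = [t.shape[0] for t in trials]
    rng = np.random.default_rng(seed)

    best: GaussianHMM | None = None
    best_ll = -np.inf
    for _ in range(max(1, n_restarts)):
        model = GaussianHMM(
            n_components=k,
            covariance_type="full",
            min_covar=1e-7,
            covars_prior=0.0,
            covars_weight=0.0,
            n_iter=n_iter,
            tol=tol,
            random_state=spawn_seed(rng),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, lengths)
        hist = np.asarray(model.monitor_.history)
        if hist.size > 1 and np.any(np.diff(hist) < -1e-6 * np.abs(hist[:-1]).max()):
            # EM is monotone in exact arithmetic; a drop marks a numerically
            # degenerate restart (near-singular covariance) — discard it
            warnings.warn("discarding EM restart with non-monotone log-likelihood")
            continue
        ll = float(hist[-1])
        if ll > best_ll:
            best, best_ll = model, ll
    if best is None:
        raise RuntimeError("every EM restart was numerically degenerate")

    means = np.atleast_2d(best.means_)
    covs = _ridge_psd(np.asarray(best.covars_))
    P = np.asarray(best.transmat_)
    start = np.asarray(best.startprob_)
    bad = ~np.all(np.isfinite(means), axis=1) | ~np.all(np.isfinite(covs), axis=(1, 2))
    if bad.any():
        warnings.warn(f"{bad.sum()} state(s) degenerate after fitting; regularised to pooled moments")
        pooled_mu = X.mean(axis=0)
        pooled_cov = np.cov(X.T, bias=True) + np.eye(X.shape[1]) * 1e-6
        means[bad] = pooled_mu
        covs[bad] = pooled_cov
        P[bad] = 1.0 / k
    P = P / P.sum(axis=1, keepdims=True)

    # stable ordering: decreasing pooled occupancy
    interim = HMGModel(K=k, P=P, mu_star=means, sigma_star=covs, A=A, startprob=start / start.sum(), log_likelihood=best_ll)
    marg = [posterior_marginals(interim, t) for t in trials]
    pooled_kappa = np.mean([m.mean(axis=0) for m in marg], axis=0)
    order = np.argsort(-pooled_kappa, kind="stable")
    return HMGModel(
        K=k,
        P=P[np.ix_(order, order)],
        mu_star=means[order],
        sigma_star=covs[order],
        A=A,
        startprob=(start / start.sum())[order],
        log_likelihood=best_ll,
    )


def posterior_marginals(model: HMGModel, trial: np.ndarray) -> np.ndarray:
    """Forward-backward smoothed state probabilities, one row per time point."""
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    if trial.shape[1] != model.d:
        raise ValueError(f"trial has dimension {trial.shape[1]}, model expects {model.d}")
    gamma = model._backend().predict_proba(trial)
    return gamma / gamma.sum(axis=1, keepdims=True)


def fractional_occupancy(
    marginals: list[np.ndarray],
    subject_ids: list[str] | None = None,
) -> OccupancyTable:
    """Average the smoothed posteriors over time, one row per subject."""
    if subject_ids is None:
        subject_ids = [f"sub-{i:02d}" for i in range(len(marginals))]
    kappa = np.stack([np.asarray(m, dtype=float).mean(axis=0) for m in marginals])
    T = np.array([np.asarray(m).shape[0] for m in marginals], dtype=int)
    return OccupancyTable(kappa=kappa, subject_ids=list(subject_ids), n_timepoints=T)


def stationary_distribution(P: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unique stationary distribution pi of a row-stochastic matrix, pi P = pi.

    Raises when the chain has more than one closed communicating class (the
    stationary law is then not unique), identifying the classes. Solved via
    the leading left eigenvector, which also covers periodic irreducible
    chains where plain power iteration would oscillate.
    """
    P = check_row_stochastic(np.asarray(P, dtype=float), name="P")
    K = P.shape[0]
    if K == 1:
        return np.array([1.0])
    closed = _closed_classes(P)
    if len(closed) != 1:
        raise ValueError(f"chain is reducible: closed communicating classes {closed}")
    w, v = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    if np.abs(pi @ P - pi).max() > max(tol, 1e-10):
        raise RuntimeError("stationary distribution did not converge")
    return pi


def _closed_classes(P: np.ndarray, eps: float = 0.0) -> list[list[int]]:
    """Closed communicating classes of the digraph of strictly positive transitions."""
    import networkx as nx

    G = nx.DiGraph()
    K = P.shape[0]
    G.add_nodes_from(range(K))
    for i in range(K):
        for j in range(K):
            if P[i, j] > eps:
                G.add_edge(i, j)
    cond = nx.condensation(G)
    closed = [sorted(cond.nodes[n]["members"]) for n in cond.nodes if cond.out_degree(n) == 0]
    return sorted(closed)
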