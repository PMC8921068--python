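"""Functional homogeneity and random-walk T-score ranking of spatial communities.

Functional homogeneity of a community C in state s is the quadratic form

    FH(s, C) = mu(s)^C' Sigma(s)^C mu(s)^C,

high when the community's mean activity aligns with the directions of strong
within-community covariance. Because raw FH depends on local activity levels,
communities are ranked against a spatiotemporal null: states are drawn from
the stationary distribution pi, and size-matched candidate subgraphs are
sampled by random walks on the drawn state's Markov information graph. The
T-score is the fraction of null pairs whose FH the candidate strictly
exceeds — a number in [0, 1] comparable across communities of one state, but
not across states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hmgm.graph_model import MultiplexModel


@dataclass
class NullSample:
    """Paired null draws (state, region set), all sets of equal size."""

    pairs: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        sizes = {len(c) for _, c in self.pairs}
        if len(sizes) > 1:
            raise ValueError("all null communities must share one size")


@dataclass
class RankedCommunity:
    """A spatial community with its FH, T-score, activity sign and rank."""

    state_id: int
    members: np.ndarray
    fh: float
    t_score: float
    sign: int
    rank: int = 0
    community_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_score <= 1.0):
            raise ValueError("t_score must lie in [0, 1]")
        if self.sign not in (-1, 0, 1):
            raise ValueError("sign must be -1, 0 or +1")
        if self.sign == 0:
            warnings.warn(f"community {self.community_id} in state {self.state_id} has zero mean activity sum")


def functional_homogeneity(mu: np.ndarray, sigma: np.ndarray, C) -> float:
    """FH = quadratic form of the community mean through the community covariance.

    Rows and columns outside C are removed before the product; for PSD sigma
    the result is nonnegative regardless of the sign pattern of the mean.
    """
    C = np.asarray(sorted(set(int(c) for c in np.atleast_1d(C))), dtype=int)
    if C.size == 0:
        raise ValueError("community must be non-empty")
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.asarray(sigma, dtype=float)
    if C.min() < 0 or C.max() >= mu.size:
        raise ValueError("community indices out of range")
    m = mu[C]
    return float(m @ sigma[np.ix_(C, C)] @ m)


def _walk_community(
    cdf: np.ndarray, start: int, size: int, max_steps: int, rng: np.random.Generator
) -> np.ndarray | None:
    """First ``size`` distinct nodes visited by a random walk from ``start``.

    ``cdf`` holds the row-wise cumulative transition probabilities of W.
    """
    visited = [start]
    seen = {start}
    current = start
    u = rng.random(max_steps)
    for step in range(max_steps):
        if len(visited) == size:
            break
        current = int(np.searchsorted(cdf[current], u[step], side="right"))
        if current not in seen:
            seen.add(current)
            visited.append(current)
    if len(visited) < size:
        return None
    return np.asarray(visited, dtype=int)


def sample_null_communities(
    model: MultiplexModel,
    size: int,
    start_pool,
    L: int,
    max_steps: int | None = None,
    seed: int = 0,
) -> NullSample:
    """Draw L (state, region-set) pairs from the random-walk null.

    Each draw samples a state from pi, a start region uniformly from
    ``start_pool``, then walks on that state's W collecting distinct regions
    (start included) until ``size`` are gathered. A walk hitting ``max_steps``
    (default 100 * size) first is abandoned and redrawn; persistent failure
    after 100 redraws raises, pointing at absorbing structure in W.
    """
    start_pool = np.asarray(sorted(set(int(x) for x in np.atleast_1d(start_pool))), dtype=int)
    D = model.state_graphs[0].n_regions
    if not (1 <= size <= D):
        raise ValueError(f"size must lie in [1, {D}]")
    if start_pool.min() < 0 or start_pool.max() >= D:
        raise ValueError("start_pool indices out of range")
    rng = np.random.default_rng(seed)
    pi_cdf = np.cumsum(model.pi)
    pi_cdf[-1] = 1.0
    max_steps = max_steps or 100 * size
    cdf_by_state: dict[int, np.ndarray] = {}
    pairs: list[tuple[int, np.ndarray]] = []
    for _ in range(L):
        for attempt in range(100):
            s = int(np.searchsorted(pi_cdf, rng.random(), side="right"))
            x = int(start_pool[rng.integers(start_pool.size)])
            cdf = cdf_by_state.get(s)
            if cdf is None:
                cdf = np.cumsum(model.state_graphs[s].W, axis=1)
                cdf[:, -1] = 1.0
                cdf_by_state[s] = cdf
            C = _walk_community(cdf, x, size, max_steps, rng)
            if C is not None:
                pairs.append((s, C))
                break
        else:
            raise RuntimeError(
                f"random walk failed to gather {size} distinct regions in "
                f"{max_steps} steps over 100 redraws; W likely has absorbing structure"
            )
    return NullSample(pairs=pairs)


def t_score(
    model: MultiplexModel,
    s: int,
    C,
    L: int = 10_000,
    seed: int = 0,
) -> tuple[float, int]:
    """T(s, C): fraction of null pairs whose FH is strictly below FH(s, C).

    The null uses start_pool = C and scores each sampled pair with its own
    state's parameters. Ties count as not exceeded, so comparing a community
    against copies of itself gives exactly 0. Also returns the community
    sign: the sign of the summed mean activity over C.
    """
    C = np.asarray(sorted(set(int(c) for c in np.atleast_1d(C))), dtype=int)
    if C.size == 0:
        raise ValueError("community must be non-empty")
    if L < 100:
        warnings.warn("L < 100 gives an unstable T-score")
    g = model.state_graphs[s]
    fh_obs = functional_homogeneity(g.a, _graph_sigma(model, s), C)
    null = sample_null_communities(model, C.size, C, L, seed=seed)
    exceeded = 0
    for s_l, C_l in null.pairs:
        g_l = model.state_graphs[s_l]
        if fh_obs > functional_homogeneity(g_l.a, _graph_sigma(model, s_l), C_l):
            exceeded += 1
    sign_sum = float(g.a[C].sum())
    sign = int(np.sign(sign_sum))
    return exceeded / L, sign


def _graph_sigma(model: MultiplexModel, s: int) -> np.ndarray:
    """State covariance used by FH scoring."""
    if model.sigmas is None:
        raise ValueError(
            "multiplex model carries no state covariances; build it with "
            "build_multiplex(fitted_model) or pass sigmas= to MultiplexModel"
        )
    return model.sigmas[s]


def rank_communities(
    model: MultiplexModel,
    s: int,
    partition,
    L: int = 10_000,
    seed: int = 0,
) -> list[RankedCommunity]:
    """Score every community of one state's partition and rank by T-score.

    Ties in T are broken by larger FH, then by lower community id. T-scores
    are comparable within this state only.
    """
    rng = np.random.default_rng(seed)
    g = model.state_graphs[s]
    sigma = _graph_sigma(model, s)
    scored: list[RankedCommunity] = []
    for lab in range(1, partition.n_communities + 1):
        C = partition.members(lab)
        fh = functional_homogeneity(g.a, sigma, C)
        t, sign = t_score(model, s, C, L=L, seed=int(rng.integers(0, 2**31 - 1)))
        scored.append(
            RankedCommunity(state_id=s, members=C, fh=fh, t_score=t, sign=sign, community_id=lab)
        )
    scored.sort(key=lambda r: (-r.t_score, -r.fh, r.community_id))
    for rank, r in enumerate(scored, start=1):
        r.rank = rank
    return scored
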