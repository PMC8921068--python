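import numpy as np
import pytest

from hmgm import (
    GeneratorSpec,
    MultiplexModel,
    generate_hmm_dataset,
    markov_information_graph,
    plant_coherent_state,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd(rng: np.random.Generator, d: int, ridge: float = 0.5) -> np.ndarray:
    """A well-conditioned random covariance matrix."""
    M = rng.standard_normal((d, d))
    return M @ M.T / d + ridge * np.eye(d)


def separated_hmm_spec(
    n_subjects: int = 6,
    n_timepoints: int = 300,
    d: int = 4,
    k_true: int = 3,
    separation: float = 5.0,
    stay: float = 0.8,
    seed: int = 0,
) -> GeneratorSpec:
    """Ground-truth HMM with well-separated state means on orthogonal axes."""
    means = np.zeros((k_true, d))
    for s in range(k_true):
        means[s, s % d] = separation * (1 if s < d else -1)
    P = np.full((k_true, k_true), (1 - stay) / max(k_true - 1, 1))
    np.fill_diagonal(P, stay if k_true > 1 else 1.0)
    return GeneratorSpec(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        n_regions=d,
        n_states=k_true,
        transition_matrix=P,
        state_means=means,
        state_covariances=np.stack([np.eye(d)] * k_true),
        seed=seed,
    )


@pytest.fixture
def separated_dataset():
    spec = separated_hmm_spec(seed=2)
    series, truth = generate_hmm_dataset(spec)
    return spec, series, truth


def random_multiplex(
    K: int = 5, D: int = 12, seed: int = 7, mean_scale: float = 0.5
) -> MultiplexModel:
    """A multiplex model with continuous means everywhere (no FH ties)."""
    rng = np.random.default_rng(seed)
    graphs, sigmas = [], []
    for s in range(K):
        S = random_psd(rng, D)
        mu = rng.standard_normal(D) * mean_scale
        graphs.append(markov_information_graph(mu, S, state_id=s))
        sigmas.append(S)
    return MultiplexModel(
        state_graphs=graphs,
        P=np.full((K, K), 1.0 / K),
        pi=np.full(K, 1.0 / K),
        sigmas=np.stack(sigmas),
    )


def planted_multiplex(
    K: int = 5, D: int = 12, community=(0, 1, 2, 3), seed: int = 7
) -> tuple[MultiplexModel, np.ndarray]:
    """One coherent planted state among zero-mean random-covariance background states."""
    rng = np.random.default_rng(seed)
    mu0, sig0, C = plant_coherent_state(D, list(community), 1.0, 0.8, background_corr=0.2)
    graphs = [markov_information_graph(mu0, sig0, state_id=0)]
    sigmas = [sig0]
    for s in range(1, K):
        S = random_psd(rng, D)
        graphs.append(markov_information_graph(np.zeros(D), S, state_id=s))
        sigmas.append(S)
    model = MultiplexModel(
        state_graphs=graphs,
        P=np.full((K, K), 1.0 / K),
        pi=np.full(K, 1.0 / K),
        sigmas=np.stack(sigmas),
    )
    return model, C
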