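"""Choosing the number of hidden states by cross-validated occupancy entropy.

For each candidate k and each held-out subject, a k-state model is trained on
all remaining subjects; the held-out subject's fractional occupancy under that
model contributes -sum_s kappa log kappa to the pooled objective

    H(k) = - sum_n sum_s kappa(s, n | M(n,k), X_n) log kappa(s, n | M(n,k), X_n)

and K is chosen as argmax_k H(k) (ties broken toward the smallest k). The
held-out log-likelihood is recorded per k as an independent check: on
recoverable data the entropy maximum and the cross-validated likelihood
maximum coincide.

After fitting at the selected K, states occupied by too few subjects can be
pruned and the surviving transition rows renormalised, reducing the risk of
overfitting to idiosyncratic subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from hmgm.containers import spawn_seed
from hmgm.hmm_core import HMGModel, OccupancyTable, fit_hmm, posterior_marginals


@dataclass
class SelectionCurve:
    """Cross-validated entropy and log-likelihood per candidate state count."""

    k_values: list[int]
    cv_entropy: np.ndarray
    cv_loglik: np.ndarray
    selected_k: int = field(default=None)  # type: ignore[assignment]
    flagged_k: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cv_entropy = np.asarray(self.cv_entropy, dtype=float)
        self.cv_loglik = np.asarray(self.cv_loglik, dtype=float)
        if np.any(self.cv_entropy < -1e-9):
            raise ValueError("cross-validated entropy cannot be negative")
        if self.selected_k is None:
            self.selected_k = self.argmax_entropy()

    def argmax_entropy(self) -> int:
        best = np.nanmax(self.cv_entropy)
        for k, h in zip(self.k_values, self.cv_entropy):  # ties -> smallest k
            if h >= best - 1e-12:
                return k
        raise RuntimeError("empty selection curve")

    def argmax_loglik(self) -> int:
        best = np.nanmax(self.cv_loglik)
        for k, ll in zip(self.k_values, self.cv_loglik):
            if ll >= best - 1e-9:
                return k
        raise RuntimeError("empty selection curve")

    def to_table(self) -> str:
        lines = ["k\tcv_entropy\tcv_loglik"]
        for k, h, ll in zip(self.k_values, self.cv_entropy, self.cv_loglik):
            lines.append(f"{k}\t{h:.10g}\t{ll:.10g}")
        return "\n".join(lines) + "\n"


def _entropy(kappa_row: np.ndarray) -> float:
    """-sum kappa log kappa with the 0 log 0 := 0 convention."""
    p = np.asarray(kappa_row, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def cv_entropy(
    trials: list[np.ndarray],
    k_range: list[int],
    seed: int = 0,
    n_restarts: int = 2,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> SelectionCurve:
    """Leave-one-subject-out cross-validated entropy of fractional occupancy.

    Every (k, fold) fit uses a seed derived deterministically from ``seed``;
    a fold whose fit fails is skipped with a warning and its k flagged. Fold
    fits use the same EM convergence settings as final fits: a capped
    iteration budget leaves small-k fits short of convergence and biases the
    held-out log-likelihood comparison across k.
    """
    trials = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    N = len(trials)
    if N < 3:
        raise ValueError("need at least 3 subjects for leave-one-subject-out selection")
    k_range = sorted(int(k) for k in k_range)
    min_len = min(t.shape[0] for t in trials)
    if max(k_range) >= min_len:
        raise ValueError("every candidate k must be smaller than the shortest trial")

    rng = np.random.default_rng(seed)
    fold_seeds = {(k, n): spawn_seed(rng) for k in k_range for n in range(N)}
    H = np.zeros(len(k_range))
    LL = np.zeros(len(k_range))
    flagged: list[int] = []
    for i, k in enumerate(k_range):
        for n in range(N):
            train = [t for m, t in enumerate(trials) if m != n]
            try:
                model = fit_hmm(train, k, seed=fold_seeds[(k, n)], n_restarts=n_restarts,
                                n_iter=n_iter, tol=tol)
                gamma = posterior_marginals(model, trials[n])
                H[i] += _entropy(gamma.mean(axis=0))
                LL[i] += float(model._backend().score(trials[n]))
            except Exception as exc:  # noqa: BLE001 - fold failure is survivable
                warnings.warn(f"fold (k={k}, held-out subject {n}) failed: {exc}")
                if k not in flagged:
                    flagged.append(k)
    return SelectionCurve(k_values=k_range, cv_entropy=H, cv_loglik=LL, flagged_k=flagged)


def prune_states(model: HMGModel, kappa: OccupancyTable, threshold: float = 0.25) -> HMGModel:
    """Drop states occupied in fewer than ``threshold`` of subjects, renormalise P.

    A state "occurs" in a subject when its fractional occupancy exceeds 1/T
    for that subject — more than one expected time point in the state. The
    surviving transition submatrix has its rows renormalised to sum to one and
    state parameters are re-indexed.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if kappa.n_states != model.K:
        raise ValueError("occupancy table does not match model state count")
    T = kappa.n_timepoints.astype(float)
    if np.any(T <= 0):
        raise ValueError("occupancy table lacks per-subject trial lengths")
    occurs = kappa.kappa > (1.0 / T)[:, None]
    n_occupied = occurs.sum(axis=0)
    keep = np.flatnonzero(n_occupied >= threshold * kappa.n_subjects)
    if keep.size == 0:
        raise ValueError("pruning removed every state; lower the threshold")
    if keep.size == model.K:
        return model
    P = model.P[np.ix_(keep, keep)]
    P = P / P.sum(axis=1, keepdims=True)
    start = model.startprob[keep]
    return HMGModel(
        K=keep.size,
        P=P,
        mu_star=model.mu_star[keep],
        sigma_star=model.sigma_star[keep],
        A=model.A,
        startprob=start / start.sum(),
        log_likelihood=model.log_likelihood,
    )
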