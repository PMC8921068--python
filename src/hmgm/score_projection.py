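"""One-step-ahead propagation of per-state term scores through P.

A term-score table theta assigns each state a score in [-1, 1] for each of M
terms (e.g. meta-analytic associations of the state's activity map with
labels such as "default mode" or "visual"). Because the states evolve as a
Markov chain, the expected score one step after leaving state s is the
P-weighted average

    E_{t+1}[theta_{i,s}] = sum_{s'} P_{s,s'} theta_{i,s'},

a convex combination that stays inside [-1, 1]. Correlating, across states,
every current-term column with every projected-term column (Pearson, t-test,
Benjamini-Hochberg correction over all M^2 pairs) summarises which global
activity patterns tend to follow which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hmgm.containers import check_row_stochastic


@dataclass
class TermScoreTable:
    """K x M table of per-state term scores in [-1, 1]."""

    theta: np.ndarray
    term_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if np.any(np.abs(self.theta) > 1 + 1e-12):
            raise ValueError("term scores must lie in [-1, 1]")
        if not self.term_names:
            self.term_names = [f"term_{j}" for j in range(self.theta.shape[1])]
        if len(self.term_names) != self.theta.shape[1]:
            raise ValueError("term_names length does not match columns of theta")

    @property
    def n_states(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def read(cls, path: str | Path) -> "TermScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(theta=df.to_numpy(dtype=float), term_names=list(df.columns))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            self.theta,
            index=[f"state_{s}" for s in range(self.n_states)],
            columns=self.term_names,
        ).to_csv(path, sep="\t")


def one_step_projected_score(P: np.ndarray, theta: TermScoreTable) -> TermScoreTable:
    """Expected term scores one transition ahead: projected = P . theta."""
    P = check_row_stochastic(np.asarray(P, dtype=float), name="P")
    if P.shape[0] != theta.n_states:
        raise ValueError("P dimension does not match number of states in theta")
    projected = P @ theta.theta
    return TermScoreTable(theta=np.clip(projected, -1.0, 1.0), term_names=list(theta.term_names))


def term_dynamics_correlation(
    theta: TermScoreTable,
    projected: TermScoreTable,
    alpha_tiers: tuple[float, float, float] = (0.01, 0.05, 0.1),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correlate current-term columns with projected-term columns across states.

    Returns (correlations, BH-adjusted p-values, significance marks). Marks
    follow the **/*/(*) convention at the three tiers. Pairs involving a
    zero-variance column are reported as missing (NaN correlation, mark "").
    """
    K, M = theta.theta.shape
    if K < 3:
        raise ValueError("need at least 3 states for a correlation t-test (df = K - 2)")
    if projected.theta.shape != (K, M):
        raise ValueError("theta and projected must share shape")
    corr = np.full((M, M), np.nan)
    pval = np.full((M, M), np.nan)
    for i in range(M):  # projected term (rows, "_{t+1}")
        y = projected.theta[:, i]
        for j in range(M):  # current term (columns)
            x = theta.theta[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            corr[i, j] = r
            if abs(r) >= 1.0:
                pval[i, j] = 0.0
            else:
                t = r * np.sqrt((K - 2) / (1 - r**2))
                pval[i, j] = 2 * stats.t.sf(abs(t), df=K - 2)
    flat = pval.ravel()
    ok = np.isfinite(flat)
    adj = np.full(flat.shape, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    padj = adj.reshape(pval.shape)

    t1, t2, t3 = alpha_tiers
    marks = np.full((M, M), "", dtype=object)
    marks[padj < t3] = "(*)"
    marks[padj < t2] = "*"
    marks[padj < t1] = "**"
    rows = [f"{name}_t+1" for name in projected.term_names]
    cols = list(theta.term_names)
    return (
        pd.DataFrame(corr, index=rows, columns=cols),
        pd.DataFrame(padj, index=rows, columns=cols),
        pd.DataFrame(marks, index=rows, columns=cols),
    )
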