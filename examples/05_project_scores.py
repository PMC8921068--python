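"""Propagate per-state term scores one transition ahead and correlate.

Six states form two metastable blocks; states in block one score high on a
"rest"-like term and low on a "sensory"-like term, and vice versa. Because
transitions stay within blocks, the projected (one-step-ahead) scores stay
correlated with the current ones within a pattern and anticorrelated across
patterns — the signature of spatiotemporally exclusive activity modes.
"""

import numpy as np

from hmgm import TermScoreTable, one_step_projected_score, term_dynamics_correlation

K = 6
P = np.full((K, K), 0.04 / 3)
P[:3, :3] = 0.96 / 3
P[3:, 3:] = 0.96 / 3
P /= P.sum(axis=1, keepdims=True)

rng = np.random.default_rng(1)
base = np.array([0.8, 0.8, 0.8, -0.8, -0.8, -0.8])
theta = TermScoreTable(
    theta=np.column_stack([
        np.clip(base + rng.normal(0, 0.05, K), -1, 1),
        np.clip(-base + rng.normal(0, 0.05, K), -1, 1),
    ]),
    term_names=["rest", "sensory"],
)

projected = one_step_projected_score(P, theta)
corr, padj, marks = term_dynamics_correlation(theta, projected)
print("correlation of current term scores (columns) with one-step-ahead scores (rows):")
print(corr.round(3).to_string())
print("\nBH-adjusted p-values:")
print(padj.round(4).to_string())
print("\nsignificance marks (** p<0.01, * p<0.05, (*) p<0.1):")
print(marks.to_string())
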