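# Methods

This note documents the statistical model behind `hmgm`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer would want
written down.

## Model and assumptions

Subjects are modelled as independent realisations of one shared K-state
Markov chain; each state s emits multivariate-normal observations
MVN(mu*(s), Sigma*(s)) in a reduced d-dimensional space. The assumptions
this buys and their costs:

- **Weak stationarity within state**: activity statistics are constant while
  a state is occupied. Slow drifts within a visit are absorbed into the
  covariance.
- **Shared parameters across subjects**: one P and one set of state models
  for everyone; inter-subject variation is expressed only through different
  state paths (and hence occupancies).
- **Geometric dwell times**: a plain Markov chain implies geometrically
  distributed visit lengths; no semi-Markov durations are modelled.
- **Gaussian emissions, full covariance**: the covariance *is* the object of
  interest downstream (it becomes the state's connectivity graph), so no
  diagonal approximation is used.

Fitting is expectation-maximisation (Baum–Welch) over the concatenated
trials with the forward–backward pass restarting at each subject boundary,
run from `n_restarts = 5` random initialisations and keeping the best
training log-likelihood. The pipeline consumes only P, the state parameters
and smoothed posteriors, so the fitter is a replaceable backend; a
variational-Bayes fitter honouring the same contract would slot in
unchanged. EM restarts whose log-likelihood is not monotone (a numerical
symptom of covariance collapse) are discarded.

## Dimensionality reduction

Series are standardized per region (mean 0, sample SD 1), pooled across
subjects, and decomposed by PCA on the correlation matrix (equal to the
covariance after standardization). One shared eigenmatrix A is used for all
subjects. The retained dimension d comes from Horn's parallel analysis:
observed eigenvalues are kept while they exceed the 95th percentile
(`percentile`, configurable; `n_null = 100` draws) of eigenvalues from
size-matched i.i.d. normal data, stopping at the first failure; at least one
component is always kept. The 95th percentile is the conventional
conservative choice; a mean-criterion variant is available through the
`percentile` argument. Eigenvector signs are fixed (largest-magnitude entry
positive) so repeated runs are bit-identical.

## Choosing K, and what the entropy criterion can and cannot do

For each candidate k and each held-out subject, a model is fitted to the
remaining subjects and the held-out subject's fractional occupancy
contributes −Σ_s κ log κ to the pooled objective H(k); the held-out
log-likelihood is recorded alongside. K = argmax H(k), smallest k on ties.

A caveat established by this package's own simulations: when subjects are
*exchangeable* draws from the same chain — exactly what the synthetic
generator produces — H(k) keeps increasing past the true state count.
The mechanism is that at k > K_true the fitter splits one true state into
two near-duplicates; a held-out subject's posterior mass divides between
the duplicates, adding roughly κ_split·ln 2 per subject to the entropy, so
the curve cannot peak. The criterion is informative when surplus states are
subject-idiosyncratic and fail to generalise (heterogeneous real cohorts),
which is why the cross-validated log-likelihood — whose gain per added state
collapses at the true count on synthetic data — is always reported next to
H(k). CV fold fits use the same EM convergence settings as final fits
(tolerance 1e-4, up to 200 iterations): capping the iteration budget leaves
small-k fits short of convergence and distorts the between-k comparison.

After fitting at the selected K, states occupied in fewer than
`prune_threshold = 0.25` of subjects are removed and the remaining rows of P
renormalised. "Occupied" means κ(s, n) > 1/T — more than one expected time
point — since occupancy is continuous and never exactly zero; a
Viterbi-path presence rule would be the natural alternative and the
threshold semantics are documented here precisely because the choice is a
convention.

## Graphs, communities, hubs

Each state's information graph uses edge weights
W^{x,y} = |ρ^{x,y}| / Σ_z |ρ^{x,z}| with the diagonal included, so every
node keeps a self-loop of weight 1/row-sum and W is a proper random-walk
transition matrix over regions. Back-projected covariances have rank ≤ d;
their correlation matrices are computed after a 1e-10 diagonal ridge with a
warning. Matrix "energy" in the symmetry measure Sym(W) is the squared
Frobenius norm, under which symmetric and antisymmetric fractions add to
one exactly.

Community detection is the hybrid the directed-modularity literature calls
pragmatic: greedy Louvain runs on (W + Wᵀ)/2 with shuffled node orders
(`n_runs`, default 10), every candidate scored with the Leicht–Newman
directed Q on the original W, best candidate returned. Self-loops count once
in the total weight and in both strengths. This hybrid is near-optimal on
near-symmetric graphs — which all of the package's graphs are (row-normalised
|correlation| layers; fitted P empirically has Sym > 0.99) — and that is the
regime in which the exhaustive-enumeration oracle in the test suite checks
it; on strongly asymmetric graphs no symmetrised optimiser can track the
directed optimum, a known limitation of the scheme.

The temporal resolution γ is selected by minimising the mean pairwise
Variation of Information across repeated Louvain runs over a grid
(0.1–2.0, step 0.02 by default). One refinement: resolutions whose runs
collapse to a single community in the majority of runs are excluded from the
minimisation, because the all-merge partition is perfectly reproducible at
small γ on any connected graph and would otherwise always win on the
ties-to-smallest rule while carrying no structure. Spatial (within-state)
community detection uses fixed γ = 2, which yields community sizes small
enough for the random-walk null to sample efficiently (median around four
regions on realistic graphs).

Partition significance: the observed label vector is shuffled uniformly
(community sizes preserved) `n_perm = 10,000` times and
p = (1 + #{Q_perm ≥ Q_obs}) / (1 + n_perm). Note the test is tie-limited on
very small graphs: with four states and a 2+2 partition only six distinct
labelings exist, so p cannot fall below roughly 1/6 regardless of how strong
the structure is.

Hubs: within each community U, node strength k_i sums in- and out-weights to
members of U; z_i standardises k within U (z = 0 throughout if the community
is degree-regular); the hub is the argmax, ties to the lower index. Ward
trees over subjects and states use 1 − Pearson correlation of occupancy
rows/columns and are serialised as Newick.

## Community ranking

FH(s, C) is the quadratic form of the community mean through the community
covariance — nonnegative for PSD Sigma, large when mean activity aligns with
dominant covariance directions. The null draws L = 10,000 pairs: a state
from π, a start region uniform from C, then a random walk on the drawn
state's W collecting *distinct* regions until |C| are gathered (the
distinct-node reading makes the null subgraph a size-matched set of regions,
directly comparable to C; walks hitting `max_steps = 100·|C|` are redrawn,
and 100 consecutive failures raise an error naming the absorbing
structure). Each null pair is scored with its own state's parameters. The
T-score is the fraction *strictly* exceeded; ties count against the
candidate, which makes the single-state whole-graph case exactly zero and
the score conservative in the presence of FH ties (e.g. exactly zero-mean
states). T-scores order communities within a state only; they are not
comparable across states. Community sign is the sign of Σ_{x∈C} mu(s)^x,
reported separately (zero sums are flagged).

Monte-Carlo precision: T is a binomial proportion, so its seed-to-seed SD is
bounded by 1/(2√L) ≈ 0.005 at the default L.

## Score projection

Projected scores Pθ stay within the convex hull of the input columns.
The correlation analysis uses Pearson correlation across states between
every current-term and projected-term column, a two-sided t-test with
df = K − 2, and Benjamini–Hochberg correction across all M² pairs, with
significance tiers 0.01 / 0.05 / 0.1. Zero-variance columns yield missing
entries rather than errors.

## Synthetic data: what it does and does not emulate

The generator produces exactly the model's assumptions: a shared chain
(uniform initial state — the initial law is otherwise unconstrained and
configurable), per-state Gaussian emissions, independent subjects. It does
*not* emulate haemodynamic smoothing, temporal autocorrelation within
states, scanner artefacts, inter-subject parameter variability, or
non-geometric dwell times. Consequently, passing tests demonstrate that the
algorithms recover planted structure under the model's own assumptions — a
correctness statement, not a claim that real fMRI satisfies those
assumptions. The exchangeable-subjects property is also why the entropy
selection criterion cannot peak on generated data (see above).

Planted-partition graphs draw edge weights uniform(0.5, 1.5)·scale so
weighted and unweighted structure coincide; `plant_coherent_state` can add a
small background correlation (`background_corr`) so the resulting
information graph is walkable outside the planted block, which the
random-walk null requires.

## Numerical choices

- Covariance PSD repair: ridge ε = 1e-6 · trace/d added only when the
  smallest eigenvalue falls below ε/1000, so well-conditioned ML estimates
  are bit-exact.
- Stationary distributions via the leading left eigenvector plus a
  closed-class check (error lists the closed communicating classes when the
  chain is reducible); this also handles periodic irreducible chains, where
  power iteration would oscillate.
- All randomness flows through per-call `numpy` generators seeded
  explicitly; the pipeline derives one seed per stage from `master_seed` in
  a fixed order, so reruns are bit-identical and the manifest suffices to
  reproduce a run.
- Tie-breaks are deterministic everywhere: smallest k for selection, lower
  community id then larger FH for ranking, lower node index for hubs,
  smallest γ for resolution.

## Problem sizes used in the test suite

Simulation-based checks run at desk scale chosen to keep each property
clearly resolved: model-selection replicates use 8 subjects × 200 time
points × 4 dimensions with 4 true states over 10 seeds; the κ → π limit
uses a single 100,000-point trial; permutation calibration uses 20-node
graphs with the full 10,000 permutations; T-score calibration uses 12-region
5-state models with L = 10,000 for point checks and L = 1,000 for averages
over 30 self-sampled communities.

## Known limitations

- The entropy-based K selection is uninformative on exchangeable subjects
  (documented above); use the reported cross-validated log-likelihood
  alongside it.
- Louvain on the symmetrised graph cannot exploit strong edge asymmetry;
  the directed Q is used for scoring only.
- The permutation test is tie-limited for small K.
- No autoregressive observation models; no multilayer (interlayer-coupled)
  community detection — the transition matrix is used only to sample states
  in the ranking null and to define temporal communities.
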