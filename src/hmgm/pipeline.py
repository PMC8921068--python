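"""End-to-end orchestration: series in, ranked spatiotemporal communities out.

The flow mirrors the analysis pipeline: standardize each subject's series,
choose the reduced dimension d (Horn's parallel analysis) and project, select
the number of states K by leave-one-subject-out cross-validated occupancy
entropy, fit the HMM, prune rarely occupied states and renormalise P, build
the per-state Markov information graphs and the multiplex model, detect
temporal communities on P (resolution by Variation-of-Information
minimisation, significance by label permutation), pick hub states by the
community-centrality z-score, detect and rank spatial communities inside each
hub state by the random-walk T-score, and — when a term-score table is
supplied — project scores one step ahead and correlate.

Every stage draws its seed deterministically from ``master_seed``; rerunning
with the same config and inputs is bit-identical, and the manifest written to
the run directory records everything needed to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hmgm.community import (
    community_zscore,
    linkage_to_newick,
    louvain,
    modularity_significance,
    select_hubs,
    select_resolution_vi,
    ward_cluster_occupancy,
)
from hmgm.dimensionality import fit_eigenmatrix, parallel_analysis, reduce_series, standardize, write_eigenmatrix
from hmgm.graph_model import build_multiplex, symmetry_fraction, write_multiplex
from hmgm.hmm_core import fit_hmm, fractional_occupancy, posterior_marginals
from hmgm.model_selection import cv_entropy, prune_states
from hmgm.ranking import rank_communities
from hmgm.score_projection import TermScoreTable, one_step_projected_score, term_dynamics_correlation
from hmgm.synthetic import read_dataset

log = logging.getLogger("hmgm")
_T0 = time.perf_counter()


@dataclass
class PipelineConfig:
    """Configuration of a full run; see docs/methods.md for parameter rationale."""

    input_dir: str
    output_dir: str
    d_selection: str | int = "auto"  # "auto" (parallel analysis) or a fixed d
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    prune_threshold: float = 0.25
    gamma_temporal: str | float = "auto"  # "auto" (VI minimisation) or a value
    gamma_spatial: float = 2.0
    n_perm: int = 10_000
    L: int = 10_000
    n_restarts: int = 5
    cv_restarts: int = 2
    master_seed: int = 0
    theta_path: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prune_threshold < 1.0):
            raise ValueError("prune_threshold must lie in (0, 1)")
        if self.n_perm < 100 or self.L < 1:
            raise ValueError("n_perm must be >= 100 and L >= 1")
        if not self.k_range or any(k < 1 for k in self.k_range):
            raise ValueError("k_range must contain positive counts")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str) -> None:
    log.info("stage %s (t=%.1fs)", name, time.perf_counter() - _T0)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory. Halts naming the failing stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.master_seed)
    seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("parallel_analysis", "cv", "fit", "gamma", "louvain_temporal", "perm", "spatial", "rank")
    }
    manifest: dict = {"config": asdict(config), "seeds": seeds, "version": _pkg_version(), "stages": []}
    stage = "load"
    try:
        _stage(stage)
        series = read_dataset(config.input_dir)
        manifest["stages"].append(stage)

        stage = "standardize"
        _stage(stage)
        std = [standardize(s) for s in series]
        pooled = np.concatenate([s.data for s in std], axis=0)

        stage = "dimensionality"
        _stage(stage)
        if config.d_selection == "auto":
            d = parallel_analysis(pooled, seed=seeds["parallel_analysis"])
        else:
            d = int(config.d_selection)
        A = fit_eigenmatrix(pooled, d, region_names=std[0].region_names)
        write_eigenmatrix(A, out / "eigenmatrix")
        trials = [reduce_series(s, A) for s in std]
        manifest["d"] = d
        manifest["explained_variance_fraction"] = A.explained_variance_fraction

        stage = "select_k"
        _stage(stage)
        if len(config.k_range) > 1:
            curve = cv_entropy(trials, config.k_range, seed=seeds["cv"], n_restarts=config.cv_restarts)
            (out / "selection_curve.tsv").write_text(curve.to_table())
            K = curve.selected_k
        else:
            K = config.k_range[0]
        manifest["selected_k"] = K

        stage = "fit"
        _stage(stage)
        model = fit_hmm(trials, K, seed=seeds["fit"], n_restarts=config.n_restarts, A=A)
        marginals = [posterior_marginals(model, t) for t in trials]
        kappa = fractional_occupancy(marginals, [s.subject_id for s in std])

        stage = "prune"
        _stage(stage)
        model = prune_states(model, kappa, config.prune_threshold)
        if model.K != K:
            marginals = [posterior_marginals(model, t) for t in trials]
            kappa = fractional_occupancy(marginals, [s.subject_id for s in std])
        manifest["pruned_k"] = model.K
        np.savetxt(out / "occupancy.tsv", kappa.kappa, delimiter="\t")

        stage = "graphs"
        _stage(stage)
        multiplex = build_multiplex(model, nodes=std[0].region_names)
        write_multiplex(multiplex, out / "multiplex")
        manifest["sym_P"] = symmetry_fraction(model.P)

        stage = "temporal_communities"
        _stage(stage)
        temporal = None
        hubs = None
        if model.K >= 2:
            if config.gamma_temporal == "auto":
                gamma_t, _ = select_resolution_vi(model.P, seed=seeds["gamma"])
            else:
                gamma_t = float(config.gamma_temporal)
            temporal = louvain(model.P, gamma=gamma_t, seed=seeds["louvain_temporal"])
            p_val = modularity_significance(model.P, temporal, n_perm=config.n_perm, seed=seeds["perm"])
            manifest["gamma_temporal"] = gamma_t
            manifest["temporal_Q"] = temporal.Q
            manifest["temporal_p"] = p_val
            with open(out / "temporal_partition.tsv", "w") as fh:
                fh.write("state\tcommunity\n")
                for s_idx, lab in enumerate(temporal.labels):
                    fh.write(f"{s_idx}\t{lab}\n")
            z = community_zscore(model.P, temporal)
            hubs = select_hubs(z, temporal)
            manifest["hubs"] = {str(u): h for u, h in hubs.hubs.items()}
            Z_sub, Z_state = ward_cluster_occupancy(kappa)
            (out / "subject_tree.nwk").write_text(linkage_to_newick(Z_sub, kappa.subject_ids))
            (out / "state_tree.nwk").write_text(
                linkage_to_newick(Z_state, [f"state_{s}" for s in range(model.K)])
            )
        else:
            manifest["gamma_temporal"] = None
            manifest["hubs"] = {}

        stage = "rank"
        _stage(stage)
        rank_rng = np.random.default_rng(seeds["rank"])
        hub_states = sorted(set(hubs.hubs.values())) if hubs else [0]
        with open(out / "ranked_communities.tsv", "w") as fh:
            fh.write("state\tcommunity\tmembers\tfh\tt_score\tsign\trank\n")
            for s_idx in hub_states:
                spatial = louvain(
                    multiplex.state_graphs[s_idx].W,
                    gamma=config.gamma_spatial,
                    seed=seeds["spatial"] + s_idx,
                )
                ranked = rank_communities(
                    multiplex, s_idx, spatial, L=config.L, seed=int(rank_rng.integers(0, 2**31 - 1))
                )
                for r in ranked:
                    members = ",".join(multiplex.state_graphs[s_idx].nodes[i] for i in r.members)
                    fh.write(
                        f"{r.state_id}\t{r.community_id}\t{members}\t{r.fh:.10g}\t"
                        f"{r.t_score:.10g}\t{r.sign}\t{r.rank}\n"
                    )

        stage = "project"
        _stage(stage)
        if config.theta_path:
            theta = TermScoreTable.read(config.theta_path)
            projected = one_step_projected_score(model.P, theta)
            projected.write(out / "projected_scores.tsv")
            corr, padj, marks = term_dynamics_correlation(theta, projected)
            corr.to_csv(out / "term_correlations.tsv", sep="\t")
            padj.to_csv(out / "term_correlations_padj.tsv", sep="\t")
            marks.to_csv(out / "term_correlations_marks.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("hmgm")
    except PackageNotFoundError:
        return "unknown"
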