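"""Reusable simulation experiments over the pipeline.

Each function runs a complete, self-contained experiment on synthetic
cohorts — the cluster-lack design, null calibrations, planted-bias
detection — and returns plain numbers, so drivers (analysis scripts,
acceptance checks) stay thin.
"""

from __future__ import annotations

import numpy as np

from . import clustering, compare, simulate, vj_usage
from .io import EmptyRepertoireError, Repertoire, clone_frequencies, filter_repertoire
from .pipeline import depth_match
from .simulate import SimulationConfig

__all__ = [
    "calibration_config",
    "prepare_samples",
    "cluster_lack_experiment",
    "wilcoxon_null_pvalues",
    "manova_null_pvalues",
    "vj_bias_pvalue",
    "exclusive_asymmetry_rate",
]


def calibration_config() -> SimulationConfig:
    """Null-calibration conditions: 10 + 10 samples at the small preset.

    Two deliberate choices isolate the tests being calibrated: the first
    planted cluster has prevalence 1.0, so its per-sample frequencies are
    positive and tie-free (the exact rank-sum path is exercised), and
    clone sizes are geometric — finite variance — because the Pillai
    F-approximation is only asymptotically calibrated under finite second
    moments; under the heavy-tailed power-law default it is conservative.
    """
    from dataclasses import replace

    cfg = simulate.tiny_config(n_samples_per_cohort=10,
                               clone_size_distribution=("geometric", 0.98))
    planted = list(cfg.planted_clusters)
    planted[0] = replace(planted[0], prevalence=1.0)
    return replace(cfg, planted_clusters=tuple(planted))


def prepare_samples(reps: list[Repertoire], min_count: int = 2,
                    match_depth: bool = True, seed: int = 0) -> list[Repertoire]:
    """Standard pre-processing: productive/count filter, then depth match."""
    reps = [filter_repertoire(r, min_count=min_count) for r in reps]
    return depth_match(reps, seed) if match_depth else reps


def cluster_lack_experiment(config: SimulationConfig, seed: int,
                            min_individuals: int = 3,
                            ref_multiplier: int = 10) -> dict:
    """One replicate of the cluster-lack design, end to end.

    Simulates the two-cohort design (second cohort missing 60% of the
    planted clusters), runs filtering, depth matching, specificity
    clustering and the cohort comparison, and scores the output against
    ground truth.
    """
    reps, sheet, gt = simulate.simulate_cohorts(config, seed=seed)
    cohort_a, cohort_b = sheet["cohort"].unique()[:2]
    reps = prepare_samples(reps, seed=seed)
    clusters, motifs = clustering.find_specificity_clusters(
        reps, seed=seed, ref_multiplier=ref_multiplier)
    sample_cohorts = {r.sample_id: r.cohort for r in reps}
    table = compare.cluster_cohort_table(clusters, sample_cohorts, cohort_a, cohort_b,
                                         min_individuals=min_individuals)
    comps = compare.compare_clusters(table)
    n_a, n_b = compare.exclusive_cluster_counts(comps)
    out = simulate.recovery_stats(clusters, gt)
    out.update({
        "cohort_a": cohort_a, "cohort_b": cohort_b,
        "exclusive_a": n_a, "exclusive_b": n_b,
        "n_compared": int(len(comps)),
        "n_enriched_motifs": len(motifs),
        "comparisons": comps,
    })
    return out


def exclusive_asymmetry_rate(config: SimulationConfig, n_replicates: int,
                             seed: int, **kwargs) -> float:
    """Fraction of replicates in which the full-cluster cohort has
    strictly more exclusive clusters than the cluster-lacking cohort."""
    wins = 0
    for i in range(n_replicates):
        res = cluster_lack_experiment(config, seed=seed + i, **kwargs)
        wins += res["exclusive_a"] > res["exclusive_b"]
    return wins / n_replicates


def _planted_cluster_frequency(rep: Repertoire, members: set[str]) -> float:
    ft = clone_frequencies(rep, "cdr3_aa")
    return float(sum(f for aa, f in ft.entries.items() if aa in members))


def wilcoxon_null_pvalues(config: SimulationConfig, n_replicates: int,
                          seed: int, cluster_name: str | None = None) -> np.ndarray:
    """Rank-sum p-values for a planted cluster under identical cohorts.

    Each replicate draws two cohorts from one generator, computes the
    per-sample summed frequency of one planted cluster's members (ground
    truth, so the check isolates the test itself) and applies the same
    two-sided rank-sum test the cluster comparison uses.  Under the null
    the p-values should be uniform.
    """
    ps = []
    for i in range(n_replicates):
        reps, sheet, gt = simulate.null_cohorts(config, seed=seed + i)
        name = cluster_name or sorted(gt.planted)[0]
        members = gt.cluster_members(name)
        by_cohort: dict[str, list[float]] = {}
        for rep in reps:
            try:
                filtered = filter_repertoire(rep)
            except EmptyRepertoireError:
                continue
            by_cohort.setdefault(rep.cohort, []).append(
                _planted_cluster_frequency(filtered, members))
        a, b = (by_cohort[c] for c in sorted(by_cohort))
        ps.append(compare.rank_sum_test(a, b))
    return np.asarray(ps)


def manova_null_pvalues(config: SimulationConfig, n_replicates: int,
                        seed: int) -> np.ndarray:
    """Pillai-trace p-values of VJ-usage PCA under identical cohorts."""
    ps = []
    for i in range(n_replicates):
        reps, sheet, _ = simulate.null_cohorts(config, seed=seed + i)
        reps = [filter_repertoire(r) for r in reps]
        matrix = vj_usage.vj_usage_matrix(reps)
        proj = vj_usage.pca_vj(matrix, n_components=2)
        cohort_of = {r.sample_id: r.cohort for r in reps}
        labels = [cohort_of[s] for s in proj.scores.index]
        ps.append(vj_usage.manova_pillai(proj.scores[["PC1", "PC2"]], labels))
    return np.asarray(ps)


def vj_bias_pvalue(config: SimulationConfig, seed: int,
                   cohorts: tuple[str, str] = ("null-A", "null-B")) -> float:
    """Pillai p-value when the second cohort carries the default planted
    V-gene usage bias."""
    biased = simulate.with_vj_bias(config, cohorts[1])
    reps, _, _ = simulate.null_cohorts(biased, seed=seed, cohorts=cohorts)
    reps = [filter_repertoire(r) for r in reps]
    matrix = vj_usage.vj_usage_matrix(reps)
    proj = vj_usage.pca_vj(matrix, n_components=2)
    cohort_of = {r.sample_id: r.cohort for r in reps}
    labels = [cohort_of[s] for s in proj.scores.index]
    return vj_usage.manova_pillai(proj.scores[["PC1", "PC2"]], labels)
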