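"""Per-cluster cohort comparison: fold changes, exclusivity, rank tests.

For every specificity cluster present in at least ``min_individuals``
individuals, the per-sample cluster frequency (summed member CDR3 aa
frequencies, 0 where no member occurs) is compared between two cohorts:
log2 fold change of cohort mean frequencies, a two-sided Wilcoxon
rank-sum test on the per-sample vectors, and an exclusivity flag for
clusters whose members occur in only one cohort.  Clusters exclusive to
one cohort get a sentinel log2 value of +/-(max finite |log2 fc| +
offset) with an explicit ``artificial`` flag so no statistic consumes
the sentinel silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import SpecificityCluster

__all__ = [
    "cluster_cohort_table",
    "rank_sum_test",
    "compare_clusters",
    "exclusive_cluster_counts",
    "significance_mark",
]


def cluster_cohort_table(clusters: list[SpecificityCluster],
                         sample_cohorts: dict[str, str],
                         cohort_a: str, cohort_b: str,
                         min_individuals: int = 3,
                         patient_ids: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-cluster, per-sample frequency table for a two-cohort comparison.

    ``sample_cohorts`` maps sample_id -> cohort; every sample must belong
    to exactly one of the two cohorts.  Clusters whose members occur in
    fewer than ``min_individuals`` distinct individuals (patient ids,
    falling back to sample ids) across both cohorts are dropped.

    Returns a DataFrame indexed by cluster_id with one column per sample
    (frequency, 0 if absent) plus ``consensus`` and ``n_individuals``;
    cohort assignment is carried in ``DataFrame.attrs``.
    """
    cohorts = set(sample_cohorts.values())
    if not cohorts <= {cohort_a, cohort_b}:
        raise ValueError(f"samples with cohorts outside the comparison: "
                         f"{sorted(cohorts - {cohort_a, cohort_b})}")
    if cohort_a == cohort_b:
        raise ValueError("cohort labels must differ")
    patient_ids = patient_ids or {}
    samples = sorted(sample_cohorts)
    rows = []
    for cl in clusters:
        individuals = {patient_ids.get(s, s) for s in cl.samples_present if s in sample_cohorts}
        if len(individuals) < min_individuals:
            continue
        row = {"cluster_id": cl.cluster_id, "consensus": cl.consensus,
               "n_individuals": len(individuals)}
        for s in samples:
            row[s] = cl.per_sample_frequency.get(s, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["cluster_id", "consensus", "n_individuals"] + samples)
    df = df.set_index("cluster_id")
    df.attrs["cohort_a"] = cohort_a
    df.attrs["cohort_b"] = cohort_b
    df.attrs["samples_a"] = [s for s in samples if sample_cohorts[s] == cohort_a]
    df.attrs["samples_b"] = [s for s in samples if sample_cohorts[s] == cohort_b]
    return df


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the combined sample size is <= 20 and
    the data are tie-free; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_clusters(table: pd.DataFrame, artificial_offset: float = 1.0) -> pd.DataFrame:
    """Cohort comparison of every cluster in ``table``.

    Returns a DataFrame indexed by cluster_id with columns ``consensus``,
    ``n_individuals``, ``mean_freq_a``, ``mean_freq_b``, ``log2_fc``,
    ``artificial``, ``exclusive_to`` and ``p_value``.  Cohort means
    include zero-frequency samples, which makes exclusivity well-defined
    as a zero mean.
    """
    sa, sb = table.attrs["samples_a"], table.attrs["samples_b"]
    A = table[sa].to_numpy(dtype=float)
    B = table[sb].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_fc = np.log2(mean_a / mean_b)
    finite = np.isfinite(raw_fc)
    max_abs = float(np.max(np.abs(raw_fc[finite]))) if finite.any() else 0.0
    sentinel = max_abs + artificial_offset

    log2_fc = np.where(finite, raw_fc, 0.0)
    artificial = ~finite
    exclusive_to = np.full(len(table), "none", dtype=object)
    for i in range(len(table)):
        if not finite[i]:
            if mean_a[i] > 0 and mean_b[i] == 0:
                exclusive_to[i] = "cohort_a"
                log2_fc[i] = sentinel
            elif mean_b[i] > 0 and mean_a[i] == 0:
                exclusive_to[i] = "cohort_b"
                log2_fc[i] = -sentinel
            else:  # both zero: degenerate, keep artificial with fc 0
                log2_fc[i] = 0.0
    p = np.array([rank_sum_test(A[i], B[i]) for i in range(len(table))])
    out = pd.DataFrame({
        "consensus": table["consensus"].to_numpy(),
        "n_individuals": table["n_individuals"].to_numpy(),
        "mean_freq_a": mean_a,
        "mean_freq_b": mean_b,
        "log2_fc": log2_fc,
        "artificial": artificial,
        "exclusive_to": exclusive_to,
        "p_value": p,
    }, index=table.index)
    out.attrs.update(table.attrs)
    return out


def exclusive_cluster_counts(comparisons: pd.DataFrame) -> tuple[int, int]:
    """(clusters exclusive to cohort A, clusters exclusive to cohort B)."""
    ex = comparisons["exclusive_to"]
    return int((ex == "cohort_a").sum()), int((ex == "cohort_b").sum())


def significance_mark(comparisons: pd.DataFrame, alpha: float = 0.05,
                      adjust: bool = False) -> pd.DataFrame:
    """Mark clusters with p <= alpha.

    No multiplicity adjustment by default (matching single-star marking
    at p <= 0.05); ``adjust`` re-marks on Benjamini-Hochberg adjusted
    p-values, which is the recommended mode for discovery claims.
    """
    out = comparisons.copy()
    out.attrs.update(comparisons.attrs)
    if adjust:
        _, p_adj, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["marked"] = out["p_adjusted"] <= alpha
    else:
        out["marked"] = out["p_value"] <= alpha
    return out
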