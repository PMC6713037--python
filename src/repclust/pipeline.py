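"""Pipeline orchestration: ingest -> depth-match -> metrics -> PCA ->
clustering -> comparison, from a single config, with a run manifest.

Stage outputs are plain TSV/JSON, self-describing and re-loadable by the
library without the manifest.  Reruns with the same config and inputs
are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, compare, diversity, physchem, vj_usage
from .io import (Repertoire, clone_frequencies, downsample_reads, filter_repertoire,
                 read_clonotype_table, read_sample_sheet)

log = logging.getLogger(__name__)

STAGES = ("ingest", "depth_match", "metrics", "vj_pca", "clustering", "compare")


@dataclass
class RunConfig:
    sample_sheet: str = ""
    dialect: str = "airr"
    out_dir: str = "results"
    cohort_a: str = ""
    cohort_b: str = ""
    min_count: int = 2
    productive_only: bool = True
    depth_match: bool = True
    min_individuals: int = 3
    k_values: tuple = (2, 3, 4)
    min_fold: float | dict | None = None  # None -> length-graded GLIPH defaults
    max_p: float = 0.001
    n_resamples: int = 1000
    ref_multiplier: int = 10
    min_expected: float = 0.5
    alpha: float = 0.05
    adjust: bool = False
    clonality_guard: float | None = None
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    cfg = RunConfig(**payload)
    cfg.k_values = tuple(cfg.k_values)
    return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Static checks of a run config; never touches data content."""
    problems = []
    if not config.sample_sheet:
        problems.append("sample_sheet path is required")
    elif not Path(config.sample_sheet).exists():
        problems.append(f"sample sheet not found: {config.sample_sheet}")
    else:
        try:
            sheet = read_sample_sheet(config.sample_sheet)
        except Exception as exc:  # surfaced as a config problem, not a crash
            problems.append(f"sample sheet unreadable: {exc}")
            sheet = None
        if sheet is not None:
            cohorts = set(sheet["cohort"])
            for label in (config.cohort_a, config.cohort_b):
                if label and label not in cohorts:
                    problems.append(f"cohort {label!r} not present in the sample sheet")
            for _, row in sheet.iterrows():
                if row["path"] and not Path(row["path"]).exists():
                    problems.append(f"clonotype table not found: {row['path']}")
    if config.dialect not in ("airr", "mixcr"):
        problems.append(f"unknown dialect {config.dialect!r}")
    if config.min_individuals < 2:
        problems.append("warning: min_individuals < 2 makes every cluster 'shared'")
    return problems


# ---------------------------------------------------------------------------
# stages (reused by the CLI subcommands)
# ---------------------------------------------------------------------------

def ingest_samples(config: RunConfig) -> tuple[list[Repertoire], pd.DataFrame]:
    sheet = read_sample_sheet(config.sample_sheet)
    reps = []
    for _, row in sheet.iterrows():
        rep = read_clonotype_table(
            row["path"], dialect=config.dialect, sample_id=row["sample_id"],
            cohort=row["cohort"], locus=row["locus"],
            metadata={k: row.get(k, "") for k in ("patient_id", "age_band", "timepoint")})
        reps.append(filter_repertoire(rep, config.min_count, config.productive_only))
    return reps, sheet


def depth_match(reps: list[Repertoire], seed: int) -> list[Repertoire]:
    """Downsample every repertoire to the minimum post-filter read depth."""
    target = min(rep.total_reads for rep in reps)
    return [downsample_reads(rep, target, seed=seed + i) for i, rep in enumerate(reps)]


def stage_metrics(reps: list[Repertoire], out: Path) -> dict:
    profile_rows, summary_rows = [], []
    for rep in reps:
        ft = clone_frequencies(rep, "cdr3_nt")
        prof = diversity.diversity_profile(ft)
        for a, d in zip(prof.alphas, prof.values):
            profile_rows.append((rep.sample_id, rep.cohort, a, d))
        space = diversity.clonal_space(ft)
        summary_rows.append({
            "sample_id": rep.sample_id, "cohort": rep.cohort,
            "total_reads": rep.total_reads, "richness": prof.richness,
            "shannon_bits": prof.shannon_bits, "evenness": prof.evenness,
            "simpson": prof.simpson, **{f"frac_{k}": v for k, v in space.fractions.items()},
        })
    profiles = pd.DataFrame(profile_rows, columns=["sample_id", "cohort", "alpha", "d_alpha"])
    profiles.to_csv(out / "diversity_profiles.tsv", sep="\t", index=False)
    # cohort curves: mean D_alpha across samples with SD bands
    cohort_curves = (profiles.groupby(["cohort", "alpha"])["d_alpha"]
                     .agg(mean="mean", sd="std").reset_index())
    cohort_curves.to_csv(out / "diversity_cohort_curves.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "diversity_summary.tsv", sep="\t", index=False)

    curves = []
    for cohort in sorted({rep.cohort for rep in reps}):
        curve = physchem.gravy_cumulative_curve([r for r in reps if r.cohort == cohort])
        curve.insert(0, "cohort", cohort)
        curves.append(curve)
    pd.concat(curves).to_csv(out / "gravy_curves.tsv", sep="\t", index=False)

    lengths = []
    for rep in reps:
        h = physchem.cdr3_length_distribution(rep)
        lengths.append(pd.DataFrame({"sample_id": rep.sample_id, "cohort": rep.cohort,
                                     "length_aa": h.index, "share": h.values}))
    pd.concat(lengths).to_csv(out / "cdr3_lengths.tsv", sep="\t", index=False)
    return {"samples": len(reps)}


def stage_vj_pca(reps: list[Repertoire], config: RunConfig, out: Path) -> dict:
    if config.clonality_guard is not None:
        kept = []
        for rep in reps:
            top = max(clone_frequencies(rep, "cdr3_nt").entries.values())
            if top > config.clonality_guard:
                log.warning("excluding %s from VJ PCA: top clone frequency %.3f exceeds "
                            "clonality guard %.3f", rep.sample_id, top, config.clonality_guard)
            else:
                kept.append(rep)
        reps = kept
    matrix = vj_usage.vj_usage_matrix(reps)
    matrix.to_csv(out / "vj_usage.tsv", sep="\t")
    proj = vj_usage.pca_vj(matrix)
    proj.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    proj.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    cohort_of = {rep.sample_id: rep.cohort for rep in reps}
    labels = [cohort_of[s] for s in proj.scores.index]
    p = vj_usage.manova_pillai(proj.scores[["PC1", "PC2"]], labels)
    proj.manova_p = p
    report = {
        "manova_pillai_p": p,
        "explained_variance": proj.explained_variance[:2].tolist(),
        "top_contributors": vj_usage.top_contributors(proj),
        "n_samples": int(matrix.shape[0]), "n_vj_pairs": int(matrix.shape[1]),
    }
    (out / "manova.json").write_text(json.dumps(report, indent=1))
    return {"samples": len(reps), "vj_pairs": int(matrix.shape[1]), "manova_p": p}


def stage_clustering(reps: list[Repertoire], config: RunConfig, out: Path,
                     patient_ids: dict[str, str] | None = None):
    shared = clustering.shared_clones(reps, config.min_individuals, patient_ids)
    shared.freqs.assign(n_individuals=shared.n_individuals).to_csv(
        out / "shared_clones.tsv", sep="\t")
    clusters, motifs = clustering.find_specificity_clusters(
        reps, k_values=config.k_values, min_fold=config.min_fold, max_p=config.max_p,
        n_resamples=config.n_resamples, seed=config.seed,
        ref_multiplier=config.ref_multiplier)
    rows = []
    for cl in clusters:
        for m in cl.members:
            for sid, f in sorted(cl.per_sample_frequency.items()):
                rows.append((cl.cluster_id, cl.consensus, m, sid, f))
    pd.DataFrame(rows, columns=["cluster_id", "consensus", "member", "sample_id",
                                "cluster_frequency"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    edge_rows = [(cl.cluster_id, a, b, kind)
                 for cl in clusters for (a, b), kind in sorted(cl.edges.items())]
    pd.DataFrame(edge_rows, columns=["cluster_id", "member_a", "member_b", "edge_kind"]
                 ).to_csv(out / "cluster_edges.tsv", sep="\t", index=False)
    motif_rows = [(m.motif, m.observed, m.ref_count, m.fold, m.p_value)
                  for m in motifs.values()]
    pd.DataFrame(motif_rows, columns=["motif", "observed", "ref_count", "fold", "p_value"]
                 ).to_csv(out / "enriched_motifs.tsv", sep="\t", index=False)
    return clusters, {"shared_clones": int(shared.freqs.shape[0]),
                      "clusters": len(clusters), "enriched_motifs": len(motifs)}


def stage_compare(clusters, reps: list[Repertoire], config: RunConfig, out: Path,
                  patient_ids: dict[str, str] | None = None) -> dict:
    sample_cohorts = {rep.sample_id: rep.cohort for rep in reps
                      if rep.cohort in (config.cohort_a, config.cohort_b)}
    table = compare.cluster_cohort_table(
        clusters, sample_cohorts, config.cohort_a, config.cohort_b,
        min_individuals=config.min_individuals, patient_ids=patient_ids)
    comps = compare.compare_clusters(table)
    comps = compare.significance_mark(comps, alpha=config.alpha, adjust=config.adjust)
    comps.to_csv(out / "cluster_comparisons.tsv", sep="\t")
    n_a, n_b = compare.exclusive_cluster_counts(comps)
    summary = {
        "cohort_a": config.cohort_a, "cohort_b": config.cohort_b,
        "total_clusters": int(len(comps)),
        "shared_clusters": int((comps["exclusive_to"] == "none").sum()),
        "exclusive_a": n_a, "exclusive_b": n_b,
        "significant": int(comps["marked"].sum()),
    }
    (out / "comparison_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in fixed order; returns the output directory.

    Aborts on the first stage error, naming the stage.  Writes a manifest
    with the config hash, seed, package versions and per-stage counts.
    """
    problems = [p for p in validate_config(config) if not p.startswith("warning")]
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"repclust": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    stage = "ingest"
    try:
        reps, sheet = ingest_samples(config)
        patient_ids = dict(zip(sheet["sample_id"], sheet["patient_id"]))
        manifest["stages"]["ingest"] = {
            "samples": len(reps), "clones": int(sum(len(r) for r in reps))}

        stage = "depth_match"
        if config.depth_match:
            reps = depth_match(reps, config.seed)
        manifest["stages"]["depth_match"] = {
            "enabled": config.depth_match,
            "depth": int(min(r.total_reads for r in reps))}

        stage = "metrics"
        manifest["stages"]["metrics"] = stage_metrics(reps, out)

        stage = "vj_pca"
        manifest["stages"]["vj_pca"] = stage_vj_pca(reps, config, out)

        stage = "clustering"
        clusters, counts = stage_clustering(reps, config, out, patient_ids)
        manifest["stages"]["clustering"] = counts

        stage = "compare"
        if config.cohort_a and config.cohort_b:
            manifest["stages"]["compare"] = stage_compare(
                clusters, reps, config, out, patient_ids)
        else:
            manifest["stages"]["compare"] = {"skipped": "no cohort pair configured"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
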