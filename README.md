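# repclust

Cohort-level analysis of adaptive immune repertoires (TRB / IGH
clonotype tables): diversity profiling, clonal-space homeostasis, CDR3
physico-chemical metrics, VJ-usage ordination, shared-clone analysis,
and GLIPH-style specificity clustering with per-cluster cohort
comparison.  A synthetic repertoire generator with planted ground truth
makes every stage testable without sequencing data.

The scientific question this pipeline serves: do patients with an
immune-mediated condition carry a repertoire signature — and in
particular, do they *lack* the "physiological" T cell specificity
clusters that healthy donors share?  Global metrics (diversity, VJ
usage) are often uninformative for this; clustering TCRβ CDR3s by
predicted antigen specificity and comparing cluster abundance between
cohorts is the sensitive readout.

## What it computes

* **Diversity**: Hill profiles `D_α(f) = (Σ f_i^α)^{1/(1−α)}` for
  α = 0..5 (step 0.2), Shannon `H = −Σ p log₂ p` (bits), evenness
  `H/log₂S`, Simpson `D = Σ f²`; clonal-space partition into
  hyperexpanded (0.01, 1], large (0.001, 0.01], medium (1e-4, 1e-3],
  small (1e-5, 1e-4] and rare (≤ 1e-5) read-mass fractions.
* **Physico-chemistry**: Kyte–Doolittle GRAVY per CDR3 and cohort-level
  cumulative curves (each distinct clone contributing 1/total clones);
  CDR3 length distributions.
* **VJ usage**: per-sample V–J pair frequencies, covariance PCA with
  deterministic sign convention, Pillai–Bartlett MANOVA of PC1/PC2,
  top-contributor ranking.
* **Specificity clusters**: CDR3 aa sequences linked by enriched
  central-region k-mers (k = 2, 3, 4; fold ≥ 1000/100/10 by length,
  resampling p ≤ 0.001) or by single-substitution similarity at equal
  length; connected components with ≥ 2 members, consensus sequences
  with `%` at non-conserved positions.
* **Cohort comparison**: per-sample cluster frequencies, log2 fold
  change of cohort means (artificial sentinel for cohort-exclusive
  clusters, explicitly flagged), two-sided Wilcoxon rank-sum tests,
  exclusive-cluster counts, optional Benjamini–Hochberg marking.

Input is AIRR Rearrangement TSV (canonical) or a MiXCR-style export
(`cloneCount`, `nSeqCDR3`, `aaSeqCDR3`, `allVHitsWithScore`,
`allJHitsWithScore`; first hit, alleles stripped), plus a sample sheet
CSV (`sample_id`, `path`, `cohort`, `locus`, optional `patient_id`,
`age_band`, `timepoint`).

## Worked example

Generate a synthetic two-cohort dataset in which the "AIC-like" cohort
lacks 60% of the planted specificity clusters, then run the pipeline:

```bash
repclust simulate --tiny --seed 3 --out data/
repclust compare --sample-sheet data/sample_sheet.csv \
    --cohort-a HD-like --cohort-b AIC-like --seed 3 --out out/
```

which prints (numbers from this exact invocation):

```
wrote 16 samples to data/
{"cohort_a": "HD-like", "cohort_b": "AIC-like", "total_clusters": 8,
 "shared_clusters": 4, "exclusive_a": 4, "exclusive_b": 0, "significant": 5}
```

Read: 8 specificity clusters occur in ≥ 3 individuals and enter the
comparison; 4 are exclusive to the HD-like cohort and none to the
AIC-like cohort — the planted "lack of physiological clusters"
signature — and 5 differ significantly in abundance (rank-sum
p ≤ 0.05).  `out/` contains the per-cluster table
(`cluster_comparisons.tsv`), the 30 enriched motifs, the shared-clone
matrix and a JSON summary.

The numbered scripts under `analysis/` run the same stages as a
narrative over a default-scale dataset (01 simulate → 02 diversity →
03 physico-chemistry → 04 VJ PCA → 05 clustering → 06 comparison),
writing tables under `results/`.  The full pipeline is also available
as `repclust run --config run.yaml` with a manifest recording config
hash, seed and per-stage counts.

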