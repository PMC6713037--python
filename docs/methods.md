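# Methods

`repclust` implements a cohort-level analysis of adaptive immune
repertoires (TRB or IGH clonotype tables): diversity profiling, clonal
space homeostasis, CDR3 physico-chemical description, VJ-usage
ordination, shared-clone analysis, GLIPH-style specificity clustering
and a per-cluster cohort comparison, together with a synthetic
repertoire generator that plants the structure the analysis is supposed
to find.

## Clone definition and filtering

A clone is a unique CDR3 nucleotide sequence with its V/J call and read
count; rows sharing a CDR3 nt sequence are merged by summing counts
(majority V/J call, ties broken lexicographically).  The standard
inclusion rule — productive sequences with read count >= 2 — is applied
after merging; filtering before merging would make the threshold depend
on how the upstream tool happened to split rows.  Clone identity is
always an explicit parameter: diversity uses the nucleotide level (the
clone definition), sharing and clustering use the amino-acid level
(convergent recombination is the signal there, not noise).

Read-depth matching across samples in a comparison is implemented as a
multivariate-hypergeometric downsample (without replacement) of every
sample to the minimum post-filter depth, with a recorded seed.  This is
conservative and reproducible; no upsampling is ever performed.

## Diversity

The alpha-parameterised (Hill) diversity of a clone frequency vector f
is `D_alpha(f) = (sum_i f_i^alpha)^(1/(1-alpha))`, evaluated on the grid
alpha = 0 to 5 in steps of 0.2 (26 points).  alpha = 0 and alpha = 1 are
computed analytically (richness S and exp of Shannon entropy), never by
grid perturbation.  The named indices are Shannon entropy in bits
(H = -sum p log2 p), evenness H / log2 S (undefined for S = 1, an
explicit error), and Simpson D = sum f^2.  The identities D_2 = 1/D and
D_1 = 2^H hold to 1e-9 and are enforced by tests.

Clonal space homeostasis partitions total read mass by clone frequency:
hyperexpanded (0.01, 1], large (0.001, 0.01], medium (1e-4, 1e-3],
small (1e-5, 1e-4].  These four bins do not cover frequencies <= 1e-5,
so a fifth "rare" bin completes the partition (mass must be conserved);
`merge_rare=True` folds it into "small" for four-bin figure parity.

## Physico-chemical descriptors

GRAVY is the mean Kyte–Doolittle hydropathy over a CDR3 amino-acid
sequence; the scale ships as a versioned data file.  The cohort curve
pools distinct CDR3 aa clones across a cohort's samples, orders them by
ascending GRAVY (ties broken lexicographically by sequence) and plots
the cumulative relative frequency with each clone contributing
1/(total clones); a read-weighted variant exists behind a flag, off by
default.  Pooling within the cohort (rather than averaging per-sample
curves) is the default.

## VJ usage, PCA and MANOVA

Per-sample combinatorial VJ usage is the read-weighted frequency of
each V–J gene pair; columns are the union of observed pairs, rows sum
to 1.  PCA is run on the column-centered matrix without unit-variance
scaling (frequencies share a scale; correlation PCA is a flag), and
component signs are fixed so each component's largest-magnitude loading
is positive.  Cohort separation is tested with the Pillai–Bartlett trace
of a one-way MANOVA on PC1 and PC2 only; using more components is a
documented flag, not the default.  Samples are depth-matched first, and
a clonality guard can exclude samples dominated by a single clone (for
example lymphoma IGH repertoires) from the ordination rather than
silently distorting it.

## Specificity clustering

CDR3 amino-acid sequences are clustered into putative
common-specificity groups by combining two edge kinds:

* **local motif edges** — pairs sharing an enriched k-mer (k = 2, 3, 4)
  from the CDR3 central region, positions 4..length-2 (1-based), which
  trims the conserved C/F flanks;
* **global similarity edges** — pairs of equal length at Hamming
  distance <= 1.

A motif, counted once per distinct CDR3, is enriched when its observed
count is at least `min_fold` times the expected count and its
resampling probability over 1,000 draws of |target| sequences from the
reference (with replacement; per-motif counts are Binomial variates) is
<= 0.001.  `min_fold` is length-graded — 1000, 100, 10 for k = 2, 3, 4
— because short motifs are common by chance; a flat threshold lets
3-mer fragments of genuine 4-mer motifs through, and stray occurrences
of those fragments bridge unrelated clusters.

Two numerical guards matter in sparse regimes.  First, the expected
count in the fold denominator is floored at `min_expected = 0.5`
counts: an empirical reference rate of zero or near zero would
otherwise produce unbounded folds from pure estimation noise.  At
realistic depths (tens of thousands of pooled clones) the expected
count of any 4-mer is well above the floor and the fold is untouched.
Second, a motif must be observed in at least 2 distinct CDR3s
(`min_target_count`), since a single carrier cannot form an edge.

When no external naive reference is supplied, the reference is built
from the analysed sequences themselves: each CDR3's central region is
randomly permuted, `ref_multiplier` (default 10) times, preserving
per-sequence length and residue composition while destroying motif
structure.  This is a standard permutation null and keeps the analysis
self-contained; a file of naive CDR3s can be supplied instead.

Clusters are connected components with >= 2 members over the union of
edge kinds; each is summarised by a position-wise consensus of its
majority length class, writing `%` where no residue exceeds half the
members.  Cluster discovery is separate from cohort filtering: the
"present in >= 3 individuals" rule is applied downstream in the
comparison, so the same clusters can be re-filtered without re-running
discovery.

## Cohort comparison

For each cluster present in >= 3 distinct individuals (patients, not
samples: multiple timepoints count once), the per-sample cluster
frequency is the summed frequency of member CDR3s, zero where no
member occurs; zeros are included in cohort means so exclusivity is
well-defined as a zero mean.  The comparison reports log2 of the ratio
of cohort means, a two-sided Wilcoxon rank-sum test on the per-sample
vectors (exact when the combined n <= 20 and tie-free, normal
approximation with tie correction otherwise), and an exclusivity flag.
Clusters exclusive to one cohort receive a sentinel log2 value of
+/-(max finite |log2 fc| + 1) stored with an explicit `artificial`
flag, so no statistic ever consumes the sentinel silently.  Wilcoxon
p-values are marked at p <= 0.05 without multiplicity adjustment by
default; a Benjamini–Hochberg flag is available and recommended for
discovery claims.  The test uses per-sample frequency vectors rather
than pooled means because a test needs replicates; this is the one
place where "compare the mean frequencies" is ambiguous and the choice
is deliberate.

## Synthetic cohorts and what they do (and do not) show

The generator emits per-sample AIRR tables with: clone-size weights
from a continuous power law (density ~ x^-2.5; a geometric option
exists), a TRB-like CDR3 length distribution (8–20 aa, mode 14),
uniform interior residues over the 19 standard letters excluding
cysteine with fixed C/F flanks, random synonymous codons for the
nucleotide sequence, cohort-specific V/J weight tables, public clones
shared across samples, planted specificity clusters, and an optional
monoclonal spike.  Defaults are 2,500 clones and 50,000 reads per
sample, 10 samples per cohort — the scale of a typical TRB amplicon
cohort; the `tiny` preset (200 clones, 2,000 reads, 8 samples) keeps
continuous-integration runs fast.

A planted cluster is a central 4-mer motif; each carrying sample
(Bernoulli prevalence, default 0.8) contributes 5 carriers embedding
the motif at a random admissible central position (3 in the tiny
preset) plus one single-substitution variant whose substitution hits a
motif position — so both local and global edge machinery is exercised.
Planted carriers, variants and public clones have clone-size weights
floored at 2 so they survive the count filter.  The cluster-lack design
gives the first cohort all planted clusters and drops 60% of them from
the second, creating a ground-truth exclusive-cluster asymmetry; the
null design (`null_cohorts`) drops nothing and drives the calibration
checks.  Per-sample random substreams are spawned from the master seed
keyed by cohort and sample index, so adding samples never perturbs
existing ones.

The generator reproduces the statistical structure the pipeline
consumes, not sequence biology: there is no VDJ recombination model, no
sequencing error, no PCR bias, and real repertoires are far from
uniform in residue usage.  Passing recovery tests therefore shows the
clustering machinery is correct and calibrated under the stated
assumptions, not that it will achieve the same operating point on
sequencing data.  Two quantitative consequences of the synthetic scale
are documented rather than hidden: (1) at desk scales the expected
count of any specific 4-mer among pooled clones is of order 0.1–2, so a
small number of chance motifs and chance Hamming-1 pairs produce
occasional spurious or merged clusters — the false-discovery proportion
is measured against planted truth and stays well under 10% at the
default scale; (2) chance carriers of a dropped motif in the other
cohort dilute strict exclusivity at the default scale, which is why the
exclusivity asymmetry is assessed as a direction over replicates and is
essentially always in the planted direction.

## Calibration choices

The null-calibration configuration uses 10 + 10 samples at the small
preset with two deliberate choices: the calibrated planted cluster has
prevalence 1.0, making its per-sample frequencies positive and tie-free
so the exact rank-sum path is exercised; and clone sizes are geometric
(finite variance) because the Pillai F-approximation is only
asymptotically calibrated under finite second moments — under the
power-law default (tail exponent 2.5, infinite variance) the MANOVA is
conservative, which is a known limitation of applying Gaussian MANOVA
to heavy-tailed usage frequencies, not a defect of the implementation.
The default planted V-usage bias (three TRBV genes up-weighted 6-fold,
renormalised) is sized to emulate the strong preferential V-gene usage
of lymphoma repertoires and is reliably detected at p < 0.01 by the
PC1/PC2 MANOVA at calibration scale.

## Numerical conventions

Frequencies must sum to 1 within 1e-6 on input; derived frequency
tables sum to 1 within 1e-9.  Hill evaluations treat alpha = 0 and 1
analytically.  Hierarchical clustering of shared-clone profiles uses
log10 frequencies with zeros replaced by half the smallest observed
frequency, average linkage, Euclidean distance, and sorts samples
lexicographically first so results are independent of input order.
GRAVY ties, V/J call ties, component ordering and consensus length
ties (shorter length wins) are all broken deterministically.  All
stochastic steps take explicit seeds; the pipeline manifest records the
config hash and seed.

## Problem sizes used in the shipped checks

The planted-recovery check runs the full pipeline at the default scale
(2 x 10 samples, 2,500 clones, 50,000 reads) over 20 seeds; the
asymmetry-direction check runs 100 replicates of the tiny preset; the
rank-sum calibration uses 1,000 null replicates and the MANOVA
calibration 500, both at the calibration configuration.  The
acceptance script reports the same quantities at moderately reduced
replicate counts; all of them are computed from scratch at run time.
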