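"""Synthetic clonotype cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes —
a heavy-tailed clone-size distribution, cohort-specific V/J usage,
public (shared) clones, planted CDR3 specificity clusters and an
optional monoclonal lymphoma spike — so every pipeline stage can be
exercised against known ground truth without sequencing data.

Defaults mirror a typical TRB amplicon cohort (2,500 distinct clones
and 50,000 reads per sample, near the median richness and depth of
published autoimmune-cytopenia cohorts); a ``tiny`` preset (200 clones,
2,000 reads) keeps continuous-integration runs fast.

CDR3 realism is deliberately limited: fixed C...F flanks, a TRB-like
length distribution and uniform interior residues over the 19 standard
letters other than cysteine.  There is no germline VDJ recombination
model — sufficient for the statistics under test, not for sequence-level
biology.

Planted specificity clusters are defined by a shared central 4-mer
motif: each carrying sample contributes ``carriers_per_sample`` CDR3s
embedding the motif at a random central position, plus single-
substitution variants of a carrier (the substitution hits a motif
position), so both local-motif and global-similarity cluster edges are
exercised.

Randomness: every sample draws from its own substream derived from the
master seed via ``SeedSequence(seed, spawn_key=(crc32(cohort), index))``,
so adding a sample or cohort never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_name

from .io import ClonotypeRecord, Repertoire, write_repertoire

__all__ = [
    "PlantedCluster",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "tiny_config",
    "with_vj_bias",
    "simulate_repertoire",
    "simulate_cohorts",
    "null_cohorts",
    "recovery_stats",
    "fit_powerlaw_exponent",
]

#: interior CDR3 alphabet: the 20 standard residues minus cysteine.
ALPHABET = "ADEFGHIKLMNPQRSTVWY"
_ALPHABET_U8 = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

DEFAULT_TRBV = (
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV7-2", "TRBV9",
    "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV14", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28",
)
DEFAULT_TRBJ = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6", "TRBJ2-7",
)

#: TRB-like CDR3 amino-acid length distribution (8..20 aa, mode 14).
DEFAULT_LENGTH_DIST = {
    8: 0.005, 9: 0.015, 10: 0.04, 11: 0.08, 12: 0.12, 13: 0.15, 14: 0.16,
    15: 0.14, 16: 0.11, 17: 0.08, 18: 0.05, 19: 0.03, 20: 0.02,
}

#: planted central 4-mers; pairwise disjoint 3-mer content so clusters
#: cannot merge through shared sub-motifs.
DEFAULT_MOTIFS = ("QRWD", "HNKE", "WEYT", "DKPM", "NHQA", "YRGD",
                  "PQWN", "KDHY", "MNRE", "GQKW", "THDN", "RWEP")

DEFAULT_PUBLIC_CLONES = (
    ("CASSLDRGYEQF", 0.5),
    ("CATSDLNTGELF", 0.5),
    ("CASRQGAYNEQF", 0.5),
    ("CAWSVLAGGTDTQF", 0.5),
    ("CASSPGQGAYEQF", 0.5),
    ("CASSIRSSYEQF", 0.5),
    ("CASMGGASYGYTF", 0.5),
    ("CASSPWGDTEAFF", 0.5),
)


def _rank_weights(names) -> dict[str, float]:
    w = np.array([1.0 / (i + 2) for i in range(len(names))])
    w /= w.sum()
    return dict(zip(names, w))


@dataclass(frozen=True)
class PlantedCluster:
    """One planted specificity cluster.

    ``prevalence`` is the probability that a sample carries the cluster,
    either a scalar (all cohorts) or a per-cohort mapping with an
    optional ``"default"`` key.
    """

    name: str
    motif: str
    prevalence: float | dict = 0.8
    carriers_per_sample: int = 5
    n_variants: int = 1

    def prevalence_in(self, cohort: str) -> float:
        if isinstance(self.prevalence, dict):
            return float(self.prevalence.get(cohort, self.prevalence.get("default", 0.0)))
        return float(self.prevalence)


@dataclass(frozen=True)
class SimulationConfig:
    n_samples_per_cohort: int = 10
    reads_per_sample: int = 50_000
    clones_per_sample: int = 2_500
    clone_size_distribution: tuple = ("power_law", 2.5)
    v_gene_weights: dict = field(default_factory=lambda: {"default": _rank_weights(DEFAULT_TRBV)})
    j_gene_weights: dict = field(default_factory=lambda: {"default": _rank_weights(DEFAULT_TRBJ)})
    cdr3_length_distribution: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    planted_clusters: tuple = field(default_factory=lambda: tuple(
        PlantedCluster(f"planted-{i + 1:02d}", m) for i, m in enumerate(DEFAULT_MOTIFS)))
    public_clones: tuple = DEFAULT_PUBLIC_CLONES
    lymphoma_spike: float | None = None
    nonproductive_fraction: float = 0.02
    locus: str = "TRB"
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        kind, param = self.clone_size_distribution
        if kind not in ("power_law", "geometric"):
            problems.append(f"unknown clone size distribution {kind!r}")
        elif kind == "power_law" and param <= 1:
            problems.append("power-law exponent must exceed 1")
        elif kind == "geometric" and not 0 < param < 1:
            problems.append("geometric ratio must lie in (0, 1)")
        probs = np.array(list(self.cdr3_length_distribution.values()))
        if np.any(probs < 0) or probs.sum() <= 0:
            problems.append("length distribution weights must be non-negative and normalizable")
        for table in (self.v_gene_weights, self.j_gene_weights):
            for cohort, weights in table.items():
                w = np.array(list(weights.values()))
                if np.any(w < 0) or w.sum() <= 0:
                    problems.append(f"gene weights for {cohort!r} not normalizable")
        n_special = sum(pc.carriers_per_sample + pc.n_variants for pc in self.planted_clusters)
        n_special += len(self.public_clones) + (1 if self.lymphoma_spike else 0)
        if n_special > self.clones_per_sample:
            problems.append(
                f"more planted/public clones ({n_special}) than clones_per_sample "
                f"({self.clones_per_sample})")
        for pc in self.planted_clusters:
            prevs = (pc.prevalence.values() if isinstance(pc.prevalence, dict)
                     else [pc.prevalence])
            if any(not 0 <= p <= 1 for p in prevs):
                problems.append(f"prevalence of {pc.name!r} outside [0, 1]")
            if len(pc.motif) + 5 > max(self.cdr3_length_distribution):
                problems.append(f"motif {pc.motif!r} cannot fit any central region")
        if self.lymphoma_spike is not None and not 0 < self.lymphoma_spike < 1:
            problems.append("lymphoma_spike frequency must lie in (0, 1)")
        return problems


def default_config(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def tiny_config(**overrides) -> SimulationConfig:
    """Small preset for fast runs: 200 clones, 2,000 reads, 8 samples per
    cohort, 3 carriers per planted cluster."""
    cfg = SimulationConfig(
        n_samples_per_cohort=8,
        reads_per_sample=2_000,
        clones_per_sample=200,
        planted_clusters=tuple(
            PlantedCluster(f"planted-{i + 1:02d}", m, carriers_per_sample=3)
            for i, m in enumerate(DEFAULT_MOTIFS)),
        public_clones=DEFAULT_PUBLIC_CLONES[:5],
    )
    return replace(cfg, **overrides) if overrides else cfg


DEFAULT_BIAS_GENES = ("TRBV7-2", "TRBV12-3", "TRBV20-1")


def with_vj_bias(config: SimulationConfig, cohort: str,
                 genes: tuple[str, ...] = DEFAULT_BIAS_GENES,
                 factor: float = 6.0) -> SimulationConfig:
    """Return a config in which ``cohort`` over-uses ``genes`` by
    ``factor`` (weights renormalised) — the default planted V-usage
    bias, sized to emulate the strong preferential TRBV usage seen in
    lymphoma repertoires."""
    base = dict(config.v_gene_weights.get("default", {}))
    biased = {g: w * (factor if g in genes else 1.0) for g, w in base.items()}
    total = sum(biased.values())
    biased = {g: w / total for g, w in biased.items()}
    table = dict(config.v_gene_weights)
    table[cohort] = biased
    return replace(config, v_gene_weights=table)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort set.

    ``planted`` maps cluster name -> sample_id -> emitted member CDR3 aa
    sequences; ``public`` maps CDR3 aa -> carrying samples;
    ``spikes`` maps sample_id -> spike clone; ``dropped_clusters`` names
    planted clusters absent by design from the second cohort.
    """

    planted: dict = field(default_factory=dict)
    public: dict = field(default_factory=dict)
    spikes: dict = field(default_factory=dict)
    dropped_clusters: list = field(default_factory=list)

    def cluster_members(self, name: str) -> set[str]:
        return set().union(*self.planted.get(name, {}).values()) if self.planted.get(name) else set()

    def merge(self, other: "GroundTruth") -> None:
        for name, by_sample in other.planted.items():
            self.planted.setdefault(name, {}).update(by_sample)
        for aa, samples in other.public.items():
            self.public.setdefault(aa, []).extend(samples)
        self.spikes.update(other.spikes)

    def to_json(self, path) -> None:
        payload = {
            "planted": {k: {s: sorted(v) for s, v in d.items()} for k, d in self.planted.items()},
            "public": {k: sorted(v) for k, v in self.public.items()},
            "spikes": self.spikes,
            "dropped_clusters": self.dropped_clusters,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted={k: {s: set(v) for s, v in d.items()}
                     for k, d in payload["planted"].items()},
            public={k: list(v) for k, v in payload["public"].items()},
            spikes=dict(payload["spikes"]),
            dropped_clusters=list(payload["dropped_clusters"]),
        )


# ---------------------------------------------------------------------------
# sequence generation machinery
# ---------------------------------------------------------------------------

def _codon_tables():
    table = unambiguous_dna_by_name["Standard"]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(table.stop_codons)
    offsets = np.zeros(256, dtype=np.int64)
    counts = np.zeros(256, dtype=np.int64)
    flat: list[str] = []
    for aa, codons in sorted(by_aa.items()):
        offsets[ord(aa)] = len(flat)
        counts[ord(aa)] = len(codons)
        flat.extend(sorted(codons))
    codon_arr = np.frombuffer("".join(flat).encode(), dtype=np.uint8).reshape(-1, 3)
    return offsets, counts, codon_arr


_CODON_OFFSET, _CODON_COUNT, _CODONS = _codon_tables()


def _random_cdr3_aa(rng, n: int, lengths: np.ndarray) -> list[str]:
    """n CDR3 aa strings with fixed C/F flanks and uniform interior."""
    interior = lengths - 2
    letters = _ALPHABET_U8[rng.integers(0, len(ALPHABET), size=int(interior.sum()))]
    out, pos = [], 0
    for m in interior:
        out.append("C" + letters[pos:pos + m].tobytes().decode() + "F")
        pos += m
    return out


def _nt_for(rng, aa_seqs: list[str]) -> list[str]:
    """Random coding DNA for each aa sequence (uniform synonymous codons)."""
    res = np.frombuffer("".join(aa_seqs).encode(), dtype=np.uint8)
    pick = _CODON_OFFSET[res] + rng.integers(0, _CODON_COUNT[res])
    buf = _CODONS[pick].reshape(-1).tobytes().decode()
    out, pos = [], 0
    for s in aa_seqs:
        out.append(buf[pos:pos + 3 * len(s)])
        pos += 3 * len(s)
    return out


def _clone_weights(rng, n: int, dist: tuple) -> np.ndarray:
    kind, param = dist
    if kind == "power_law":
        # density ~ x^(-param) for x >= 1  ->  Pareto shape param - 1
        return rng.pareto(param - 1.0, size=n) + 1.0
    if kind == "geometric":
        return param ** np.arange(n, dtype=float)
    raise ValueError(f"unknown clone size distribution {kind!r}")


def _sample_lengths(rng, n: int, dist: dict, minimum: int = 0) -> np.ndarray:
    values = np.array(sorted(dist))
    probs = np.array([dist[v] for v in values], dtype=float)
    ok = values >= minimum
    if not ok.any():
        raise ValueError(f"no CDR3 length >= {minimum} has positive probability")
    values, probs = values[ok], probs[ok]
    return rng.choice(values, p=probs / probs.sum(), size=n)


def _carrier_with_motif(rng, motif: str, length_dist: dict) -> str:
    k = len(motif)
    L = int(_sample_lengths(rng, 1, length_dist, minimum=k + 5)[0])
    seq = _random_cdr3_aa(rng, 1, np.array([L]))[0]
    start = int(rng.integers(3, L - k - 1))  # motif inside positions 4..L-2
    return seq[:start] + motif + seq[start + k:]


def _mutate_motif_position(rng, carrier: str, motif: str) -> str:
    start = carrier.find(motif)
    j = start + int(rng.integers(len(motif)))
    alternatives = [a for a in ALPHABET if a != carrier[j]]
    return carrier[:j] + alternatives[int(rng.integers(len(alternatives)))] + carrier[j + 1:]


def _cohort_weights(table: dict, cohort: str) -> tuple[list[str], np.ndarray]:
    weights = table.get(cohort, table.get("default"))
    if weights is None:
        raise ValueError(f"no gene weights for cohort {cohort!r} and no default")
    genes = sorted(weights)
    w = np.array([weights[g] for g in genes], dtype=float)
    return genes, w / w.sum()


def _sample_rng(seed: int, cohort: str, sample_index: int):
    key = zlib.crc32(cohort.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, sample_index)))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_repertoire(config: SimulationConfig, cohort: str, sample_index: int,
                        seed: int | None = None) -> tuple[Repertoire, GroundTruth]:
    """Generate one sample: a :class:`Repertoire` plus its ground-truth slice.

    Deterministic given the config and master seed; planted carriers,
    variants and public clones receive clone-size weights floored at 2 so
    they survive the standard read-count filter with high probability.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid simulation config: " + "; ".join(problems))
    seed = config.seed if seed is None else seed
    rng = _sample_rng(seed, cohort, sample_index)
    sample_id = f"{cohort}-{sample_index + 1:02d}"
    gt = GroundTruth()

    special_aa: list[str] = []
    planted_of: list[tuple[str, int]] = []  # (cluster name, index into special_aa)
    for pc in config.planted_clusters:
        if rng.random() < pc.prevalence_in(cohort):
            members = [_carrier_with_motif(rng, pc.motif, config.cdr3_length_distribution)
                       for _ in range(pc.carriers_per_sample)]
            members += [_mutate_motif_position(rng, members[0], pc.motif)
                        for _ in range(pc.n_variants)]
            for m in members:
                planted_of.append((pc.name, len(special_aa)))
                special_aa.append(m)
    public_idx: list[tuple[str, int]] = []
    for aa, fraction in config.public_clones:
        if rng.random() < fraction:
            public_idx.append((aa, len(special_aa)))
            special_aa.append(aa)
    spike_idx = None
    if config.lymphoma_spike is not None:
        spike_idx = len(special_aa)
        spike_len = _sample_lengths(rng, 1, config.cdr3_length_distribution)
        special_aa.append(_random_cdr3_aa(rng, 1, spike_len)[0])

    n_background = config.clones_per_sample - len(special_aa)
    bg_aa = _random_cdr3_aa(
        rng, n_background,
        _sample_lengths(rng, n_background, config.cdr3_length_distribution))
    n_nonprod = int(round(config.nonproductive_fraction * config.clones_per_sample))
    nonprod_aa = []
    for s in _random_cdr3_aa(rng, n_nonprod,
                             _sample_lengths(rng, n_nonprod, config.cdr3_length_distribution)):
        j = int(rng.integers(1, len(s) - 1))
        nonprod_aa.append(s[:j] + "*" + s[j + 1:])

    all_aa = special_aa + bg_aa + nonprod_aa
    n_total = len(all_aa)
    weights = _clone_weights(rng, n_total, config.clone_size_distribution)
    weights[:len(special_aa)] = np.maximum(weights[:len(special_aa)], 2.0)
    if spike_idx is not None:
        rest = weights.sum() - weights[spike_idx]
        weights[spike_idx] = config.lymphoma_spike / (1.0 - config.lymphoma_spike) * rest
    counts = rng.multinomial(config.reads_per_sample, weights / weights.sum())

    v_genes, v_p = _cohort_weights(config.v_gene_weights, cohort)
    j_genes, j_p = _cohort_weights(config.j_gene_weights, cohort)
    v_calls = rng.choice(v_genes, p=v_p, size=n_total)
    j_calls = rng.choice(j_genes, p=j_p, size=n_total)
    nts = _nt_for(rng, all_aa)

    records: dict[str, ClonotypeRecord] = {}
    emitted = np.zeros(n_total, dtype=bool)
    for i in range(n_total):
        if counts[i] == 0:
            continue
        nt = nts[i]
        productive = "*" not in all_aa[i]
        if nt in records:  # vanishing-probability nt collision: merge counts
            prev = records[nt]
            records[nt] = ClonotypeRecord(nt, prev.cdr3_aa, prev.v_gene, prev.j_gene,
                                          prev.read_count + int(counts[i]),
                                          prev.productive and productive)
        else:
            records[nt] = ClonotypeRecord(nt, all_aa[i], str(v_calls[i]), str(j_calls[i]),
                                          int(counts[i]), productive)
        emitted[i] = True

    for name, idx in planted_of:
        if emitted[idx]:
            gt.planted.setdefault(name, {}).setdefault(sample_id, set()).add(special_aa[idx])
    for aa, idx in public_idx:
        if emitted[idx]:
            gt.public.setdefault(aa, []).append(sample_id)
    if spike_idx is not None and emitted[spike_idx]:
        gt.spikes[sample_id] = special_aa[spike_idx]

    rep = Repertoire(sample_id=sample_id, cohort=cohort, locus=config.locus,
                     records=records, metadata={"sample_index": sample_index})
    return rep, gt


def simulate_cohorts(config: SimulationConfig, seed: int | None = None,
                     cohorts: tuple[str, str] = ("HD-like", "AIC-like"),
                     keep_fraction: float = 0.4,
                     out_dir=None) -> tuple[list[Repertoire], pd.DataFrame, GroundTruth]:
    """Two-cohort "cluster-lack" design with known ground truth.

    The first cohort carries every planted cluster at its configured
    prevalence; the second carries only the first ``keep_fraction`` of
    them (default 40%, the remaining 60% dropped), producing a planted
    exclusive-cluster asymmetry.  Returns ``(repertoires, sample_sheet,
    ground_truth)`` and optionally writes AIRR TSVs, a sample sheet CSV
    and a ground-truth JSON to ``out_dir``.
    """
    seed = config.seed if seed is None else seed
    n_keep = int(np.ceil(keep_fraction * len(config.planted_clusters)))
    adjusted = []
    dropped = []
    for i, pc in enumerate(config.planted_clusters):
        prev_a = pc.prevalence_in(cohorts[0])
        prev_b = pc.prevalence_in(cohorts[1]) if i < n_keep else 0.0
        if i >= n_keep:
            dropped.append(pc.name)
        adjusted.append(replace(pc, prevalence={cohorts[0]: prev_a, cohorts[1]: prev_b}))
    cfg = replace(config, planted_clusters=tuple(adjusted))

    reps: list[Repertoire] = []
    gt = GroundTruth(dropped_clusters=dropped)
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for cohort in cohorts:
        for i in range(config.n_samples_per_cohort):
            rep, slice_gt = simulate_repertoire(cfg, cohort, i, seed)
            gt.merge(slice_gt)
            reps.append(rep)
            path = ""
            if out_dir is not None:
                path = f"{rep.sample_id}.tsv"  # relative to the sample sheet
                write_repertoire(rep, out_dir / path)
            rows.append({"sample_id": rep.sample_id, "path": path, "cohort": cohort,
                         "locus": config.locus, "patient_id": rep.sample_id,
                         "age_band": "", "timepoint": "baseline"})
    sheet = pd.DataFrame(rows)
    if out_dir is not None:
        sheet.to_csv(out_dir / "sample_sheet.csv", index=False)
        gt.to_json(out_dir / "ground_truth.json")
    return reps, sheet, gt


def null_cohorts(config: SimulationConfig, seed: int | None = None,
                 cohorts: tuple[str, str] = ("null-A", "null-B")):
    """Two cohorts from one identical generator (keep_fraction = 1), the
    calibration harness for type-I error and MANOVA-null checks."""
    return simulate_cohorts(config, seed=seed, cohorts=cohorts, keep_fraction=1.0)


def recovery_stats(clusters, ground_truth: GroundTruth,
                   min_overlap: float = 0.8,
                   match_threshold: float = 0.5) -> dict:
    """Score discovered clusters against the planted ground truth.

    A planted cluster is *recovered* when some output cluster contains at
    least ``min_overlap`` of its emitted members; an output cluster is a
    *false discovery* when fewer than ``match_threshold`` of its members
    belong to any single planted cluster.  Planted clusters with fewer
    than two emitted members are excluded from the denominator.
    """
    planted_sets = {name: ground_truth.cluster_members(name)
                    for name in ground_truth.planted}
    planted_sets = {k: v for k, v in planted_sets.items() if len(v) >= 2}
    member_sets = [set(c.members) for c in clusters]
    recovered = 0
    for members in planted_sets.values():
        if any(len(out & members) >= min_overlap * len(members) for out in member_sets):
            recovered += 1
    false = merged = 0
    for out in member_sets:
        best = max((len(out & p) / len(out) for p in planted_sets.values()), default=0.0)
        if best < match_threshold:
            false += 1
        contained = sum(len(out & p) >= min_overlap * len(p) for p in planted_sets.values())
        if contained >= 2:
            merged += 1  # a union of >= 2 planted clusters (bridged component)
    n_planted = len(planted_sets)
    n_out = len(member_sets)
    return {
        "n_planted": n_planted,
        "n_recovered": recovered,
        "recovery_rate": recovered / n_planted if n_planted else float("nan"),
        "n_clusters": n_out,
        "n_false": false,
        "n_merged": merged,
        "fdp": false / n_out if n_out else 0.0,
    }


def fit_powerlaw_exponent(counts, xmin: float) -> float:
    """Continuous maximum-likelihood tail exponent (density ~ x^-alpha)
    of clone read counts at or above ``xmin``."""
    x = np.asarray(counts, dtype=float)
    x = x[x >= xmin]
    if x.size < 10:
        raise ValueError("too few tail observations for a power-law fit")
    return 1.0 + x.size / np.sum(np.log(x / (xmin - 0.5)))
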