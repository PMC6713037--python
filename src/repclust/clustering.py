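"""Shared-clone analysis and GLIPH-style specificity clustering.

TCRs recognising the same antigen tend to share short CDR3 amino-acid
motifs ("paratope hotspots") or to differ by a single substitution.  This
module groups CDR3 aa sequences into putative common-specificity clusters
by combining

* **local edges** — pairs sharing a k-mer (k = 2, 3, 4 by default) from
  the CDR3 central region that is enriched in the analysed sequences
  relative to an unselected reference (fold >= 10 and resampling
  probability <= 0.001 with 1,000 draws, the published GLIPH defaults),
  and
* **global edges** — pairs of equal length at Hamming distance <= 1.

Clusters are the connected components with at least two members; each is
summarised by a consensus sequence with ``%`` at non-conserved positions.

When no external naive reference is supplied, the reference is built from
the analysed sequences themselves by permuting each CDR3's central region
(``ScrambledReference``): a composition- and length-preserving null in
which genuine motifs are destroyed, so enrichment is measured against an
unselected background without external data.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io import Repertoire, clone_frequencies

log = logging.getLogger(__name__)

__all__ = [
    "SharedCloneTable",
    "SpecificityCluster",
    "MotifEnrichment",
    "ScrambledReference",
    "central_region",
    "shared_clones",
    "hierarchical_cluster_samples",
    "enriched_motifs",
    "global_edges",
    "build_clusters",
    "consensus_sequence",
    "find_specificity_clusters",
]

#: conserved flank trimming: the scanned central region is positions
#: 4 .. length-2 (1-based, inclusive), i.e. ``seq[3:-2]``.
CENTRAL_START = 3
CENTRAL_END_TRIM = 2

_K_TAG_SHIFT = np.uint64(34)   # k stored above 4 bytes of packed characters
_SEG_BITS = np.uint64(21)      # up to 2**21 sequences per indexed set
_SEG_MASK = np.uint64((1 << 21) - 1)


def central_region(seq: str) -> str:
    """Central portion of a CDR3 aa sequence (conserved flanks trimmed)."""
    return seq[CENTRAL_START:len(seq) - CENTRAL_END_TRIM]


# ---------------------------------------------------------------------------
# packed k-mer presence counting
# ---------------------------------------------------------------------------

def _central_buffer(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate central regions into one uint8 buffer with segment
    starts/lengths."""
    central = [central_region(s) for s in seqs]
    lens = np.array([len(c) for c in central], dtype=np.int64)
    buf = np.frombuffer("".join(central).encode("ascii"), dtype=np.uint8)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]]) if lens.size else np.zeros(0, np.int64)
    return buf, starts, lens


def _encode_motif(motif: str) -> np.uint64:
    token = np.uint64(0)
    for j, ch in enumerate(motif):
        token |= np.uint64(ord(ch)) << np.uint64(8 * j)
    return token | (np.uint64(len(motif)) << _K_TAG_SHIFT)


def _decode_motif(token: int) -> str:
    token = int(token)
    k = token >> int(_K_TAG_SHIFT)
    return "".join(chr((token >> (8 * j)) & 0xFF) for j in range(k))


class _KmerPresence:
    """Per-sequence presence counts of central-region k-mers.

    A k-mer is counted once per distinct sequence regardless of how many
    times it occurs within it.
    """

    def __init__(self, buf: np.ndarray, starts: np.ndarray, lens: np.ndarray,
                 n_seqs: int, k_values: tuple[int, ...]):
        if n_seqs >= 1 << 21:
            raise ValueError("k-mer index supports at most 2**21 sequences")
        self.n_seqs = n_seqs
        keys = []
        for k in k_values:
            nwin = np.maximum(lens - k + 1, 0)
            total = int(nwin.sum())
            if total == 0:
                continue
            seg = np.repeat(np.arange(lens.size, dtype=np.int64), nwin)
            first = np.repeat(np.cumsum(nwin) - nwin, nwin)
            idx = starts[seg] + (np.arange(total, dtype=np.int64) - first)
            token = np.zeros(idx.size, dtype=np.uint64)
            for j in range(k):
                token |= buf[idx + j].astype(np.uint64) << np.uint64(8 * j)
            token |= np.uint64(k) << _K_TAG_SHIFT
            keys.append((token << _SEG_BITS) | seg.astype(np.uint64))
        if keys:
            # token-major sort, then de-duplicate (seq, kmer) pairs in place
            allk = np.concatenate(keys)
            allk.sort(kind="stable")
            if allk.size:
                keep = np.empty(allk.size, dtype=bool)
                keep[0] = True
                np.not_equal(allk[1:], allk[:-1], out=keep[1:])
                allk = allk[keep]
            pairs = allk
        else:
            pairs = np.zeros(0, dtype=np.uint64)
        self._pair_token = pairs >> _SEG_BITS          # ascending
        self._pair_seg = (pairs & _SEG_MASK).astype(np.int64)
        if pairs.size:
            bounds = np.flatnonzero(np.concatenate(
                ([True], self._pair_token[1:] != self._pair_token[:-1])))
            self.tokens = self._pair_token[bounds]
            self.presence = np.diff(np.append(bounds, pairs.size))
        else:
            self.tokens = np.zeros(0, dtype=np.uint64)
            self.presence = np.zeros(0, dtype=np.int64)

    def counts_for(self, query_tokens: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.tokens, query_tokens)
        pos = np.clip(pos, 0, max(self.tokens.size - 1, 0))
        out = np.zeros(query_tokens.size, dtype=np.int64)
        if self.tokens.size:
            hit = self.tokens[pos] == query_tokens
            out[hit] = self.presence[pos[hit]]
        return out

    def members_of(self, token: np.uint64) -> np.ndarray:
        lo = np.searchsorted(self._pair_token, token, side="left")
        hi = np.searchsorted(self._pair_token, token, side="right")
        return self._pair_seg[lo:hi]


class ScrambledReference:
    """Unselected background built by permuting CDR3 central regions.

    ``multiplier`` independent scrambles of every input sequence are
    pooled, preserving per-sequence length and residue composition while
    destroying motif structure.  Deterministic given ``seed``.
    """

    def __init__(self, seqs: list[str], multiplier: int = 10, seed: int = 0):
        if multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        seqs = sorted(set(seqs))
        buf, starts, lens = _central_buffer(seqs)
        seg_ids = np.repeat(np.arange(lens.size), lens)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x5C,)))
        bufs, all_lens = [], []
        for _ in range(multiplier):
            order = np.lexsort((rng.random(buf.size), seg_ids))
            bufs.append(buf[order])
            all_lens.append(lens)
        self._buf = np.concatenate(bufs) if bufs else buf
        self._lens = np.concatenate(all_lens) if all_lens else lens
        self._starts = (np.concatenate([[0], np.cumsum(self._lens)[:-1]])
                        if self._lens.size else np.zeros(0, np.int64))
        self.n_seqs = len(seqs) * multiplier
        self._cache: dict[tuple[int, ...], _KmerPresence] = {}

    def _presence(self, k_values: tuple[int, ...]) -> _KmerPresence:
        if k_values not in self._cache:
            self._cache[k_values] = _KmerPresence(
                self._buf, self._starts, self._lens, self.n_seqs, k_values)
        return self._cache[k_values]


# ---------------------------------------------------------------------------
# shared clones
# ---------------------------------------------------------------------------

@dataclass
class SharedCloneTable:
    """Public-clone matrix: CDR3 aa x sample within-sample frequencies.

    Retained rows are present in at least ``min_individuals`` distinct
    individuals (samples of one patient count once).
    """

    freqs: pd.DataFrame            # rows cdr3_aa, cols sample_id
    n_individuals: pd.Series       # per retained cdr3_aa
    min_individuals: int


def shared_clones(repertoires: list[Repertoire], min_individuals: int = 3,
                  patient_ids: dict[str, str] | None = None) -> SharedCloneTable:
    """CDR3 aa sequences shared by at least ``min_individuals`` individuals.

    ``patient_ids`` maps sample_id -> patient id so that multiple
    timepoints of one patient count as a single individual.
    """
    if len(repertoires) < min_individuals:
        raise ValueError(
            f"need at least min_individuals={min_individuals} samples, got {len(repertoires)}")
    patient_ids = patient_ids or {}
    cols = {}
    carriers: dict[str, set[str]] = defaultdict(set)
    for rep in repertoires:
        ft = clone_frequencies(rep, "cdr3_aa")
        cols[rep.sample_id] = ft.entries
        patient = patient_ids.get(rep.sample_id, rep.sample_id)
        for aa in ft.entries:
            carriers[aa].add(patient)
    keep = sorted(aa for aa, pats in carriers.items() if len(pats) >= min_individuals)
    df = pd.DataFrame(
        {sid: [cols[sid].get(aa, 0.0) for aa in keep] for sid in sorted(cols)},
        index=pd.Index(keep, name="cdr3_aa"))
    n_ind = pd.Series({aa: len(carriers[aa]) for aa in keep}, name="n_individuals", dtype=int)
    return SharedCloneTable(df, n_ind.reindex(keep), min_individuals)


def hierarchical_cluster_samples(table: SharedCloneTable):
    """Agglomerative clustering of samples on log10 shared-clone frequencies.

    Average linkage on Euclidean distances; zeros are replaced by half
    the smallest observed frequency before the log transform (the usual
    heatmap convention).  Samples are sorted lexicographically first so
    the output is invariant to input order.

    Returns ``(ordered_sample_ids, linkage_matrix)``.
    """
    df = table.freqs.reindex(sorted(table.freqs.columns), axis=1)
    if df.shape[1] < 2:
        raise ValueError("hierarchical clustering needs at least two samples")
    X = df.to_numpy(dtype=float)
    positive = X[X > 0]
    pseudo = positive.min() / 2.0 if positive.size else 1.0
    logX = np.log10(np.where(X > 0, X, pseudo))
    Z = linkage(logX.T, method="average", metric="euclidean")
    order = [df.columns[i] for i in leaves_list(Z)]
    return order, Z


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifEnrichment:
    """Evidence for one enriched central-region k-mer."""

    motif: str
    observed: int          # target sequences containing the motif
    ref_count: int         # reference sequences containing the motif
    fold: float            # observed / expected count (expected floored)
    p_value: float         # resampling probability
    members: tuple[str, ...] = field(repr=False, default=())


#: minimum observed/expected fold per motif length: short motifs are
#: common by chance and must clear a much higher bar.
DEFAULT_MIN_FOLD = {2: 1000.0, 3: 100.0, 4: 10.0}


def enriched_motifs(target: list[str], reference, k_values: tuple[int, ...] = (2, 3, 4),
                    min_fold: float | dict | None = None, max_p: float = 0.001,
                    n_resamples: int = 1000, seed: int = 0,
                    min_target_count: int = 2,
                    min_expected: float = 0.5) -> dict[str, MotifEnrichment]:
    """Central-region k-mers over-represented in ``target`` vs ``reference``.

    A motif (counted once per distinct CDR3) is enriched when its fold
    change over the expected count is >= ``min_fold`` — a scalar or a
    per-length mapping, defaulting to 1000/100/10 for k = 2/3/4 — and its resampling
    probability — the frequency, among ``n_resamples`` draws of |target|
    sequences from the reference (with replacement), of a motif count at
    least as large as observed — is <= ``max_p``.  Per-motif draw counts
    are sampled as Binomial(|target|, ref rate) variates, which is the
    distribution of the motif count in such a draw.

    The expected count is ``|target| * ref_count/|reference|``, floored
    at ``min_expected`` so that motifs absent or nearly absent from the
    reference cannot produce unbounded folds from a noisy near-zero rate
    estimate; at depths where the expected count is well above the floor
    the fold is untouched.

    ``reference`` may be a list of sequences or a :class:`ScrambledReference`.
    Returns a mapping motif -> :class:`MotifEnrichment` (the key set is
    the enriched-motif set).
    """
    target = sorted(set(target))
    if not target:
        raise ValueError("empty target set")
    k_values = tuple(sorted(k_values))
    if isinstance(reference, ScrambledReference):
        ref_presence = reference._presence(k_values)
        n_ref = reference.n_seqs
    else:
        ref_seqs = sorted(set(reference))
        if not ref_seqs:
            raise ValueError("empty reference set")
        buf, starts, lens = _central_buffer(ref_seqs)
        ref_presence = _KmerPresence(buf, starts, lens, len(ref_seqs), k_values)
        n_ref = len(ref_seqs)
    if n_ref < len(target):
        log.warning("reference (%d) smaller than target (%d); enrichment "
                    "p-values will be noisy", n_ref, len(target))

    buf, starts, lens = _central_buffer(target)
    tgt = _KmerPresence(buf, starts, lens, len(target), k_values)
    n_t = len(target)

    obs_ok = tgt.presence >= min_target_count
    tokens = tgt.tokens[obs_ok]
    observed = tgt.presence[obs_ok]
    ref_counts = ref_presence.counts_for(tokens)
    expected = np.maximum(n_t * ref_counts / max(n_ref, 1), min_expected)
    fold = observed / expected
    if min_fold is None:
        min_fold = DEFAULT_MIN_FOLD
    if isinstance(min_fold, dict):
        kk = (tokens >> _K_TAG_SHIFT).astype(np.int64)
        thresholds = np.array([min_fold.get(k, 10.0) for k in range(int(kk.max(initial=0)) + 1)])
        cand = fold >= thresholds[kk]
    else:
        cand = fold >= float(min_fold)
    tokens, observed, ref_counts, fold = tokens[cand], observed[cand], ref_counts[cand], fold[cand]

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x3F,)))
    result: dict[str, MotifEnrichment] = {}
    if tokens.size:
        q = ref_counts / n_ref
        draws = rng.binomial(n_t, q[None, :], size=(n_resamples, q.size))
        p = (draws >= observed[None, :]).mean(axis=0)
        for i in np.argsort(tokens, kind="stable"):
            if p[i] <= max_p:
                motif = _decode_motif(tokens[i])
                members = tuple(target[s] for s in sorted(tgt.members_of(tokens[i])))
                result[motif] = MotifEnrichment(
                    motif, int(observed[i]), int(ref_counts[i]),
                    float(fold[i]), float(p[i]), members)
    return result


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def global_edges(members) -> set[tuple[str, str]]:
    """Pairs of equal-length sequences at Hamming distance <= 1.

    O(n * L): within each length class, sequences sharing a
    position-wildcarded key (computed as a rolling polynomial hash per
    wildcard position) can only differ at the wildcard; hash-collision
    candidates are verified by direct comparison.
    """
    seqs = sorted(set(members))
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        by_len[len(s)].append(i)
    B = np.uint64(1099511628211)
    edges: set[tuple[str, str]] = set()
    for L, idxs in by_len.items():
        n = len(idxs)
        if n < 2 or L == 0:
            continue
        sub = np.frombuffer("".join(seqs[i] for i in idxs).encode("ascii"),
                            dtype=np.uint8).reshape(n, L).astype(np.uint64)
        with np.errstate(over="ignore"):  # hashes live in Z/2^64
            pref = np.zeros((n, L + 1), dtype=np.uint64)
            suf = np.zeros((n, L + 1), dtype=np.uint64)
            for j in range(L):
                pref[:, j + 1] = pref[:, j] * B + sub[:, j]
            for j in range(L - 1, -1, -1):
                suf[:, j] = suf[:, j + 1] * B + sub[:, j]
            powB = np.ones(L + 1, dtype=np.uint64)
            for j in range(L):
                powB[j + 1] = powB[j] * B
            key_matrix = [pref[:, i] * powB[L - 1 - i] + suf[:, i + 1] for i in range(L)]
        for i in range(L):
            keys = key_matrix[i]
            order = np.argsort(keys, kind="stable")
            ks = keys[order]
            eq = np.flatnonzero(ks[1:] == ks[:-1])
            if eq.size == 0:
                continue
            # contiguous equal-key runs; all within-run pairs are candidates
            breaks = np.flatnonzero(np.diff(eq) > 1)
            run_bounds = np.split(eq, breaks + 1)
            for run in run_bounds:
                lo, hi = run[0], run[-1] + 2
                group = order[lo:hi]
                for a_i in range(group.size):
                    for b_i in range(a_i + 1, group.size):
                        ra, rb = group[a_i], group[b_i]
                        if int(np.count_nonzero(sub[ra] != sub[rb])) <= 1:
                            pair = tuple(sorted((seqs[idxs[ra]], seqs[idxs[rb]])))
                            edges.add(pair)
    return edges


@dataclass
class SpecificityCluster:
    """A connected component of CDR3 aa sequences with shared predicted
    specificity."""

    cluster_id: str
    members: tuple[str, ...]
    edges: dict[tuple[str, str], str]      # pair -> "motif" | "global" | "both"
    consensus: str
    samples_present: frozenset[str]
    per_sample_frequency: dict[str, float]
    motifs: tuple[str, ...] = ()


def consensus_sequence(members, conservation_threshold: float = 0.5) -> str:
    """Position-wise consensus of the majority length class.

    A residue is written when it exceeds ``conservation_threshold`` of the
    majority-length members at that position; otherwise ``%``.  Ties in
    the length vote resolve to the shorter length.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("consensus needs at least two members")
    by_len: dict[int, list[str]] = defaultdict(list)
    for m in members:
        by_len[len(m)].append(m)
    length = min(sorted(by_len), key=lambda L: (-len(by_len[L]), L))
    group = by_len[length]
    out = []
    for i in range(length):
        counts: dict[str, int] = defaultdict(int)
        for m in group:
            counts[m[i]] += 1
        letter, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        out.append(letter if n / len(group) > conservation_threshold else "%")
    return "".join(out)


def build_clusters(universe: dict[str, dict[str, float]],
                   motifs: dict[str, MotifEnrichment],
                   edges: set[tuple[str, str]] | None = None,
                   min_members: int = 2,
                   conservation_threshold: float = 0.5) -> list[SpecificityCluster]:
    """Connected components over the CDR3 aa universe.

    ``universe`` maps each sequence to its per-sample frequency.  Edges
    are the union of global (Hamming <= 1, equal length) pairs and pairs
    sharing at least one enriched motif.  Components with fewer than
    ``min_members`` members are discarded.  Output order and cluster ids
    are deterministic (sorted by first member).
    """
    if edges is None:
        edges = global_edges(universe.keys())
    G: nx.Graph = nx.Graph()
    G.add_nodes_from(universe)
    for a, b in edges:
        if a in universe and b in universe:
            G.add_edge(a, b)
    motif_of_seq: dict[str, set[str]] = defaultdict(set)
    for motif, enr in motifs.items():
        present = [m for m in enr.members if m in universe]
        for m in present:
            motif_of_seq[m].add(motif)
        for i in range(1, len(present)):
            G.add_edge(present[0], present[i])

    components = sorted(
        (sorted(c) for c in nx.connected_components(G) if len(c) >= min_members),
        key=lambda c: c[0])
    global_set = {tuple(sorted(e)) for e in edges}
    clusters = []
    for ci, comp in enumerate(components):
        comp_set = set(comp)
        edge_kinds: dict[tuple[str, str], str] = {}
        for a_i in range(len(comp)):
            for b_i in range(a_i + 1, len(comp)):
                a, b = comp[a_i], comp[b_i]
                is_motif = bool(motif_of_seq[a] & motif_of_seq[b])
                is_global = (a, b) in global_set
                if is_motif and is_global:
                    edge_kinds[(a, b)] = "both"
                elif is_motif:
                    edge_kinds[(a, b)] = "motif"
                elif is_global:
                    edge_kinds[(a, b)] = "global"
        per_sample: dict[str, float] = defaultdict(float)
        for m in comp:
            for sid, f in universe[m].items():
                if f > 0:
                    per_sample[sid] += f
        cluster_motifs = tuple(sorted(set().union(*(motif_of_seq[m] for m in comp))))
        clusters.append(SpecificityCluster(
            cluster_id=f"C{ci + 1:04d}",
            members=tuple(comp),
            edges=edge_kinds,
            consensus=consensus_sequence(comp, conservation_threshold),
            samples_present=frozenset(per_sample),
            per_sample_frequency=dict(per_sample),
            motifs=cluster_motifs,
        ))
    return clusters


def find_specificity_clusters(repertoires: list[Repertoire],
                              k_values: tuple[int, ...] = (2, 3, 4),
                              min_fold: float | dict | None = None, max_p: float = 0.001,
                              n_resamples: int = 1000, seed: int = 0,
                              ref_multiplier: int = 10,
                              reference: list[str] | None = None,
                              min_members: int = 2):
    """End-to-end clustering of a set of samples.

    Pools distinct CDR3 aa sequences across the repertoires, scores motif
    enrichment against ``reference`` (default: a :class:`ScrambledReference`
    built from the pooled sequences), computes global edges and returns
    ``(clusters, motifs)``.
    """
    universe: dict[str, dict[str, float]] = defaultdict(dict)
    for rep in repertoires:
        ft = clone_frequencies(rep, "cdr3_aa")
        for aa, f in ft.entries.items():
            universe[aa][rep.sample_id] = f
    seqs = sorted(universe)
    if reference is None:
        ref = ScrambledReference(seqs, multiplier=ref_multiplier, seed=seed)
    else:
        ref = reference
    motifs = enriched_motifs(seqs, ref, k_values=k_values, min_fold=min_fold,
                             max_p=max_p, n_resamples=n_resamples, seed=seed)
    edges = global_edges(seqs)
    clusters = build_clusters(dict(universe), motifs, edges, min_members=min_members)
    return clusters, motifs
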