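import itertools

import numpy as np
import pytest
from scipy import stats

from repclust import clustering
from repclust.clustering import (ScrambledReference, build_clusters, central_region,
                                 consensus_sequence, enriched_motifs, global_edges,
                                 hierarchical_cluster_samples, shared_clones)

from conftest import make_repertoire


def rep_with_aa(sample_id, aa_counts, cohort="A"):
    nt_counts, aa_map = {}, {}
    for i, (aa, n) in enumerate(aa_counts.items()):
        nt = "TGT" + "GCA" * (i + 1) + "TTT"
        nt_counts[nt] = n
        aa_map[nt] = aa
    return make_repertoire(nt_counts, sample_id=sample_id, cohort=cohort, aa=aa_map)


class TestSharedClones:
    def _samples(self):
        return [
            rep_with_aa("s1", {"CASSAF": 4, "CAQQF": 2}),
            rep_with_aa("s2", {"CASSAF": 2, "CAWWF": 2}),
            rep_with_aa("s3", {"CASSAF": 2, "CAQQF": 2}),
            rep_with_aa("s4", {"CAYYYF": 2}),
        ]

    def test_min_three_individuals_rule(self):
        table = shared_clones(self._samples(), min_individuals=3)
        assert list(table.freqs.index) == ["CASSAF"]  # 3 of 4 samples
        assert table.n_individuals["CASSAF"] == 3

    def test_clone_in_two_samples_dropped(self):
        table = shared_clones(self._samples(), min_individuals=3)
        assert "CAQQF" not in table.freqs.index

    def test_clone_in_all_samples_retained(self):
        samples = [rep_with_aa(f"s{i}", {"CASSAF": 2, f"CA{'Q' * (i + 1)}F": 2})
                   for i in range(4)]
        table = shared_clones(samples, min_individuals=3)
        assert "CASSAF" in table.freqs.index

    def test_timepoints_of_one_patient_count_once(self):
        samples = self._samples()
        patient = {"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p3"}
        table = shared_clones(samples, min_individuals=3, patient_ids=patient)
        assert "CASSAF" not in table.freqs.index  # only 2 distinct individuals


class TestHierarchicalClustering:
    def test_identical_samples_merge_at_distance_zero(self):
        samples = [rep_with_aa("s1", {"CASSAF": 2, "CAQQF": 2}),
                   rep_with_aa("s2", {"CASSAF": 2, "CAQQF": 2}),
                   rep_with_aa("s3", {"CASSAF": 2, "CAQQF": 6})]
        table = shared_clones(samples, min_individuals=2)
        order, Z = hierarchical_cluster_samples(table)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_ordering_invariant_to_input_order(self):
        samples = [rep_with_aa("s1", {"CASSAF": 4, "CAQQF": 2}),
                   rep_with_aa("s2", {"CASSAF": 2, "CAQQF": 8}),
                   rep_with_aa("s3", {"CASSAF": 2, "CAQQF": 2})]
        table_fwd = shared_clones(samples, min_individuals=2)
        table_rev = shared_clones(samples[::-1], min_individuals=2)
        assert hierarchical_cluster_samples(table_fwd)[0] == \
               hierarchical_cluster_samples(table_rev)[0]

    def test_outlier_merges_last(self):
        # s3's profile is far from s1/s2 in log10 space: it must join last
        samples = [rep_with_aa("s1", {"CASSAF": 50, "CAQQF": 50}),
                   rep_with_aa("s2", {"CASSAF": 49, "CAQQF": 51}),
                   rep_with_aa("s3", {"CASSAF": 1, "CAQQF": 999})]
        table = shared_clones(samples, min_individuals=2)
        order, Z = hierarchical_cluster_samples(table)
        # first merge joins s1 and s2 (leaves 0 and 1), the outlier joins after
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_single_sample_rejected(self):
        table = shared_clones([rep_with_aa("s1", {"CASSAF": 2}),
                               rep_with_aa("s2", {"CASSAF": 2})], min_individuals=2)
        table.freqs = table.freqs[["s1"]]
        with pytest.raises(ValueError):
            hierarchical_cluster_samples(table)


def seq_with_motif(motif, flank="ADE", tail="GH"):
    # motif inside the central region (positions 4..len-2)
    return "C" + flank + motif + tail + "F"


class TestEnrichedMotifs:
    def test_motif_absent_from_reference_is_enriched_with_p_zero(self, rng):
        target = [seq_with_motif("QRWD", flank=f, tail=t)
                  for f, t in zip(["ADE", "AGH", "IKL", "MNP", "QST", "VWY",
                                   "AAD", "EEG", "HIK", "LMN"],
                                  ["GH"] * 10)]
        target += ["C" + "".join(rng.choice(list("ADEGHIKLMN"), 8)) + "F" for _ in range(40)]
        reference = ["C" + "".join(rng.choice(list("ADEGHIKLMN"), 8)) + "F"
                     for _ in range(10000)]
        reference = [r for r in reference if "QRWD" not in central_region(r)]
        res = enriched_motifs(sorted(set(target)), reference, k_values=(4,), seed=0)
        assert "QRWD" in res
        assert res["QRWD"].p_value == 0.0

    def test_identical_rates_not_enriched(self):
        seqs = [seq_with_motif("QRWD", flank=f) for f in ["ADE", "AGH", "IKL", "MNP"]]
        res = enriched_motifs(seqs, seqs, k_values=(4,), seed=0)
        assert res == {}

    def test_reference_equal_to_target_yields_empty_set(self, rng):
        seqs = sorted({"C" + "".join(rng.choice(list("ADEGHIKLMNPQ"), 9)) + "F"
                       for _ in range(200)})
        assert enriched_motifs(seqs, seqs, seed=0) == {}

    def test_planted_motif_reliably_enriched_across_seeds(self, rng):
        # 20% target prevalence vs ~0.1% reference prevalence of a 4-mer
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            target = [seq_with_motif("HNKE",
                                     flank="".join(r.choice(list("ADEGILM"), 3)),
                                     tail="".join(r.choice(list("ADEGILM"), 2)))
                      for _ in range(10)]
            target += ["C" + "".join(r.choice(list("ADEGHIKLMNPQRSTVWY"), 9)) + "F"
                       for _ in range(40)]
            reference = ["C" + "".join(r.choice(list("ADEGHIKLMNPQRSTVWY"), 9)) + "F"
                         for _ in range(5000)]
            res = enriched_motifs(sorted(set(target)), reference, k_values=(4,), seed=seed)
            hits += "HNKE" in res
        assert hits == 20

    def test_motif_counted_once_per_distinct_cdr3(self, rng):
        # a sequence containing the motif twice still counts as one observation
        seqs = ["CADEQRWDQRWDGHF"] + [
            seq_with_motif("QRWD", flank=f) for f in
            ["ADE", "AGH", "IKL", "MNP", "QST"]]
        ref = list({"C" + "".join(rng.choice(list("ADEGHIKLMN"), 11)) + "F"
                    for _ in range(500)})
        res = enriched_motifs(seqs, ref, k_values=(4,), seed=0)
        assert res["QRWD"].observed == len(seqs)

    def test_central_region_trimming(self):
        # motif straddling the conserved flank is not scanned
        assert central_region("CASSLGETQYF") == "SLGETQ"
        seqs = ["CQRWDAAAAF", "CQRWDGGGGF"]  # QRWD starts at position 2
        res = enriched_motifs(seqs, ["CAAAAAAAAF"] * 50, k_values=(4,), seed=0)
        assert "QRWD" not in res

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            enriched_motifs([], ["CAAAAF"], seed=0)


class TestScrambledReference:
    def test_preserves_length_and_composition(self):
        seqs = ["CADEQRWDGHF", "CIKLMNPSTF"]
        ref = ScrambledReference(seqs, multiplier=3, seed=1)
        assert ref.n_seqs == 6
        # composition-preserving: 1-mer counts identical to target's
        t = enriched_motifs(seqs, ref, k_values=(2,), min_fold=1.0, max_p=1.1,
                            n_resamples=10, seed=0)
        # no 2-mer can be more than mildly enriched against its own scramble
        assert all(e.fold < 10 for e in t.values())

    def test_deterministic_given_seed(self):
        seqs = ["CADEQRWDGHF", "CIKLMNPQSTF", "CDEFGHIKLMF"]
        r1 = ScrambledReference(seqs, multiplier=2, seed=7)
        r2 = ScrambledReference(seqs, multiplier=2, seed=7)
        assert np.array_equal(r1._buf, r2._buf)


class TestGlobalEdges:
    def test_single_substitution_pair(self):
        assert global_edges(["CASSLGETQYF", "CASSLGATQYF"]) == \
               {("CASSLGATQYF", "CASSLGETQYF")}

    def test_no_self_edges_and_no_cross_length_edges(self):
        assert global_edges(["CASSF", "CASSF"]) == set()
        assert global_edges(["CASSF", "CASSAF"]) == set()

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            seqs = list({"C" + "".join(rng.choice(list("ADE"), int(rng.integers(3, 6)))) + "F"
                         for _ in range(15)})
            brute = {tuple(sorted(p)) for p in itertools.combinations(sorted(seqs), 2)
                     if len(p[0]) == len(p[1])
                     and sum(a != b for a, b in zip(*p)) <= 1}
            assert global_edges(seqs) == brute


class TestBuildClusters:
    def _universe(self, seqs):
        return {s: {"s1": 0.1} for s in seqs}

    def test_two_members_sharing_motif_form_cluster(self):
        a, b = seq_with_motif("QRWD", "ADE"), seq_with_motif("QRWD", "GHI")
        motifs = {"QRWD": clustering.MotifEnrichment("QRWD", 2, 0, 20.0, 0.0, (a, b))}
        clusters = build_clusters(self._universe([a, b]), motifs, set())
        assert len(clusters) == 1 and set(clusters[0].members) == {a, b}
        assert all(k == "motif" for k in clusters[0].edges.values())

    def test_motif_and_global_edges_chain_transitively(self):
        a, b = seq_with_motif("QRWD", "ADE"), seq_with_motif("QRWD", "GHI")
        c = b[:2] + "X" + b[3:]  # Hamming 1 from b, no motif edge
        motifs = {"QRWD": clustering.MotifEnrichment("QRWD", 2, 0, 20.0, 0.0, (a, b))}
        clusters = build_clusters(self._universe([a, b, c]), motifs,
                                  global_edges([a, b, c]))
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_components_match_brute_force_transitive_closure(self, rng):
        for trial in range(10):
            seqs = list({"C" + "".join(rng.choice(list("ADEG"), 4)) + "F"
                         for _ in range(20)})
            edges = global_edges(seqs)
            clusters = build_clusters(self._universe(seqs), {}, edges)
            # brute force: repeated expansion over the edge relation
            comp = {s: {s} for s in seqs}
            changed = True
            while changed:
                changed = False
                for a, b in edges:
                    merged = comp[a] | comp[b]
                    if merged != comp[a] or merged != comp[b]:
                        for m in merged:
                            comp[m] = merged
                        changed = True
            brute = {frozenset(c) for c in comp.values() if len(c) >= 2}
            assert {frozenset(c.members) for c in clusters} == brute

    def test_every_clustered_member_in_exactly_one_cluster(self, rng):
        seqs = list({"C" + "".join(rng.choice(list("ADEG"), 4)) + "F" for _ in range(30)})
        clusters = build_clusters(self._universe(seqs), {}, global_edges(seqs))
        seen = [m for c in clusters for m in c.members]
        assert len(seen) == len(set(seen))

    def test_per_sample_frequency_sums_member_frequencies(self):
        a, b = seq_with_motif("QRWD", "ADE"), seq_with_motif("QRWD", "GHI")
        universe = {a: {"s1": 0.1, "s2": 0.05}, b: {"s1": 0.2}}
        motifs = {"QRWD": clustering.MotifEnrichment("QRWD", 2, 0, 20.0, 0.0, (a, b))}
        (cluster,) = build_clusters(universe, motifs, set())
        assert cluster.per_sample_frequency == pytest.approx({"s1": 0.3, "s2": 0.05})
        assert cluster.samples_present == {"s1", "s2"}


class TestConsensus:
    def test_identical_members(self):
        assert consensus_sequence(["CASSF", "CASSF"]) == "CASSF"

    def test_half_agreement_is_not_conserved(self):
        assert consensus_sequence(["CASSF", "CASTF"]) == "CAS%F"

    def test_three_members_one_wildcard(self):
        assert consensus_sequence(["CASSF", "CASSF", "CASTF"]) == "CASSF"
        assert consensus_sequence(["CASAF", "CASSF", "CASTF"]) == "CAS%F"

    def test_majority_length_class_wins(self):
        assert consensus_sequence(["CASSF", "CASSF", "CASSAF"]) == "CASSF"


def test_clustering_invariant_to_input_order(rng):
    reps = []
    for i in range(4):
        aa_counts = {seq_with_motif("QRWD", "".join(rng.choice(list("ADEGIL"), 3))): 3
                     for _ in range(3)}
        aa_counts.update({"C" + "".join(rng.choice(list("ADEGHIKLMNPQ"), 9)) + "F": 2
                          for _ in range(20)})
        reps.append(rep_with_aa(f"s{i}", aa_counts))
    c_fwd, _ = clustering.find_specificity_clusters(reps, seed=3)
    c_rev, _ = clustering.find_specificity_clusters(reps[::-1], seed=3)
    assert [c.members for c in c_fwd] == [c.members for c in c_rev]
    assert [c.consensus for c in c_fwd] == [c.consensus for c in c_rev]
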