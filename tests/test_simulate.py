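import filecmp
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from repclust import simulate
from repclust.diversity import clonal_space
from repclust.io import clone_frequencies, filter_repertoire
from repclust.simulate import (ALPHABET, GroundTruth, PlantedCluster, default_config,
                               fit_powerlaw_exponent, null_cohorts, recovery_stats,
                               simulate_cohorts, simulate_repertoire, tiny_config)


class TestSingleRepertoire:
    def test_same_seed_identical_output(self):
        cfg = tiny_config()
        r1, g1 = simulate_repertoire(cfg, "HD-like", 0, seed=5)
        r2, g2 = simulate_repertoire(cfg, "HD-like", 0, seed=5)
        assert r1.records == r2.records
        assert g1.planted == g2.planted

    def test_adding_a_sample_never_perturbs_existing_ones(self):
        cfg = tiny_config()
        alone, _ = simulate_repertoire(cfg, "HD-like", 0, seed=5)
        other, _ = simulate_repertoire(cfg, "HD-like", 7, seed=5)
        again, _ = simulate_repertoire(cfg, "HD-like", 0, seed=5)
        assert alone.records == again.records
        assert alone.records != other.records

    def test_richness_close_to_configured_clone_number(self):
        cfg = default_config()
        rep, _ = simulate_repertoire(cfg, "HD-like", 0, seed=2)
        productive = [r for r in rep.records.values() if r.productive]
        assert len(productive) >= 0.95 * cfg.clones_per_sample

    def test_lymphoma_spike_dominates_clonal_space(self):
        cfg = tiny_config(lymphoma_spike=0.4, reads_per_sample=20000)
        rep, gt = simulate_repertoire(cfg, "CLL-like", 0, seed=3)
        rep = filter_repertoire(rep)
        ft = clone_frequencies(rep, "cdr3_nt")
        assert max(ft.entries.values()) == pytest.approx(0.4, abs=0.03)
        assert clonal_space(ft).fractions["hyperexpanded"] >= 0.39

    def test_cdr3_alphabet_and_flanks(self):
        rep, _ = simulate_repertoire(tiny_config(), "HD-like", 1, seed=1)
        for r in rep.records.values():
            if r.productive:
                assert r.cdr3_aa[0] == "C" and r.cdr3_aa[-1] == "F"
                assert set(r.cdr3_aa[1:-1]) <= set(ALPHABET)
                assert len(r.cdr3_nt) == 3 * len(r.cdr3_aa)

    def test_nt_translates_to_aa(self):
        from Bio.Seq import Seq
        rep, _ = simulate_repertoire(tiny_config(), "HD-like", 2, seed=9)
        for r in list(rep.records.values())[:50]:
            assert str(Seq(r.cdr3_nt).translate()) == r.cdr3_aa

    def test_infeasible_config_rejected(self):
        cfg = tiny_config(clones_per_sample=10)
        with pytest.raises(ValueError, match="planted"):
            simulate_repertoire(cfg, "HD-like", 0, seed=0)


class TestCohorts:
    def test_dropped_clusters_absent_from_second_cohort(self):
        cfg = tiny_config()
        reps, sheet, gt = simulate_cohorts(cfg, seed=4)
        assert len(gt.dropped_clusters) == 7  # 60% of 12, ceil(0.4*12)=5 kept
        aic_samples = set(sheet[sheet["cohort"] == "AIC-like"]["sample_id"])
        for name in gt.dropped_clusters:
            samples = set(gt.planted.get(name, {}))
            assert not samples & aic_samples

    def test_prevalence_one_cluster_present_in_every_first_cohort_sample(self):
        pcs = (PlantedCluster("always", "QRWD", prevalence=1.0, carriers_per_sample=3),)
        cfg = tiny_config(planted_clusters=pcs)
        reps, sheet, gt = simulate_cohorts(cfg, seed=6)
        hd = set(sheet[sheet["cohort"] == "HD-like"]["sample_id"])
        assert hd <= set(gt.planted["always"])

    def test_ground_truth_sequences_exist_in_their_samples(self):
        reps, _, gt = simulate_cohorts(tiny_config(), seed=8)
        by_id = {r.sample_id: r for r in reps}
        for name, by_sample in gt.planted.items():
            for sid, members in by_sample.items():
                aa_present = {rec.cdr3_aa for rec in by_id[sid].records.values()}
                assert members <= aa_present

    def test_written_files_byte_identical_across_runs(self, tmp_path):
        cfg = tiny_config(n_samples_per_cohort=2)
        simulate_cohorts(cfg, seed=11, out_dir=tmp_path / "a")
        simulate_cohorts(cfg, seed=11, out_dir=tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b",
                                                   names, shallow=False)
        assert not mismatch and not errors

    def test_null_cohorts_drop_nothing(self):
        _, _, gt = null_cohorts(tiny_config(), seed=2)
        assert gt.dropped_clusters == []


class TestMarginals:
    def test_powerlaw_tail_exponent_recovered(self):
        cfg = default_config()
        exponent = cfg.clone_size_distribution[1]
        fits = []
        for i in range(20):
            rep, _ = simulate_repertoire(cfg, "HD-like", i, seed=21)
            counts = [r.read_count for r in rep.records.values()]
            fits.append(fit_powerlaw_exponent(counts, xmin=3 * np.mean(counts)))
        assert abs(np.mean(fits) - exponent) <= 0.3

    def test_v_gene_usage_matches_configured_weights(self):
        cfg = default_config()
        weights = cfg.v_gene_weights["default"]
        genes = sorted(weights)
        p = np.array([weights[g] for g in genes])
        p = p / p.sum()
        ok = 0
        n_reps = 20
        for i in range(n_reps):
            rep, _ = simulate_repertoire(cfg, "HD-like", i, seed=33)
            counts = np.zeros(len(genes))
            idx = {g: k for k, g in enumerate(genes)}
            for r in rep.records.values():
                counts[idx[r.v_gene]] += 1  # clone-level V assignment
            ok += stats.chisquare(counts, p * counts.sum()).pvalue > 0.01
        assert ok >= 0.95 * n_reps

    def test_geometric_clone_sizes_supported(self):
        cfg = tiny_config(clone_size_distribution=("geometric", 0.95))
        rep, _ = simulate_repertoire(cfg, "HD-like", 0, seed=1)
        assert rep.total_reads == cfg.reads_per_sample


class TestRecoveryStats:
    def test_perfect_recovery_and_no_false_discoveries(self):
        gt = GroundTruth(planted={"p1": {"s1": {"CAAAF", "CAASF"}}})
        clusters = [type("C", (), {"members": ("CAAAF", "CAASF")})]
        st = recovery_stats(clusters, gt)
        assert st["recovery_rate"] == 1.0 and st["fdp"] == 0.0

    def test_unmatched_cluster_counts_as_false(self):
        gt = GroundTruth(planted={"p1": {"s1": {"CAAAF", "CAASF"}}})
        clusters = [type("C", (), {"members": ("CWWWF", "CWWAF")})]
        st = recovery_stats(clusters, gt)
        assert st["recovery_rate"] == 0.0 and st["fdp"] == 1.0


def test_config_validation_reports_problems():
    bad = replace(tiny_config(), clone_size_distribution=("power_law", 0.5),
                  lymphoma_spike=1.5)
    problems = bad.validate()
    assert any("exponent" in p for p in problems)
    assert any("spike" in p for p in problems)
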