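import numpy as np
import pandas as pd
import pytest

from repclust import vj_usage
from repclust.io import ClonotypeRecord, Repertoire
from repclust.simulate import tiny_config, simulate_repertoire
from repclust.io import filter_repertoire
from dataclasses import replace


def rep_with_pairs(sample_id, pair_counts, cohort="A", locus="TRB"):
    records = {}
    for i, ((v, j), n) in enumerate(pair_counts.items()):
        nt = "TGT" + "GCA" * (i + 1) + "TTT"  # unique per pair
        records[nt] = ClonotypeRecord(nt, "CAAF", v, j, n, True)
    return Repertoire(sample_id, cohort, locus, records)


class TestUsageMatrix:
    def test_single_pair_sample_row(self):
        r1 = rep_with_pairs("s1", {("TRBV7", "TRBJ2-1"): 10})
        r2 = rep_with_pairs("s2", {("TRBV7", "TRBJ2-1"): 5, ("TRBV9", "TRBJ1-1"): 5})
        m = vj_usage.vj_usage_matrix([r1, r2])
        assert m.loc["s1", "TRBV7|TRBJ2-1"] == 1.0
        assert m.loc["s1"].drop("TRBV7|TRBJ2-1").eq(0).all()

    def test_rows_sum_to_one_and_columns_sorted(self):
        r1 = rep_with_pairs("s1", {("TRBV9", "TRBJ1-1"): 3, ("TRBV2", "TRBJ2-7"): 1})
        r2 = rep_with_pairs("s2", {("TRBV2", "TRBJ2-7"): 4})
        m = vj_usage.vj_usage_matrix([r1, r2])
        assert np.allclose(m.sum(axis=1), 1.0)
        assert list(m.columns) == sorted(m.columns)

    def test_unobserved_pair_is_not_a_column(self):
        m = vj_usage.vj_usage_matrix([
            rep_with_pairs("s1", {("TRBV7", "TRBJ2-1"): 1}),
            rep_with_pairs("s2", {("TRBV7", "TRBJ2-1"): 1})])
        assert list(m.columns) == ["TRBV7|TRBJ2-1"]

    def test_mixed_loci_rejected(self):
        r1 = rep_with_pairs("s1", {("TRBV7", "TRBJ2-1"): 1})
        r2 = rep_with_pairs("s2", {("IGHV1-2", "IGHJ4"): 1}, locus="IGH")
        with pytest.raises(ValueError, match="loci"):
            vj_usage.vj_usage_matrix([r1, r2])


class TestPca:
    def _matrix(self, rng, n=8, p=12):
        X = rng.dirichlet(np.ones(p), size=n)
        return pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                            columns=[f"TRBV{i}|TRBJ1-1" for i in range(p)])

    def test_duplicated_rows_have_identical_scores(self, rng):
        m = self._matrix(rng, n=4)
        m = pd.concat([m, m.rename(index=lambda s: s + "b")])
        proj = vj_usage.pca_vj(m)
        assert np.allclose(proj.scores.loc["s0"], proj.scores.loc["s0b"], atol=1e-10)

    def test_explained_variance_valid(self, rng):
        proj = vj_usage.pca_vj(self._matrix(rng))
        ev = proj.explained_variance
        assert np.all(ev >= 0) and np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9

    def test_scores_centered_and_reconstruction(self, rng):
        m = self._matrix(rng, n=10, p=6)
        proj = vj_usage.pca_vj(m)
        assert np.allclose(proj.scores.mean(axis=0), 0, atol=1e-10)
        X = m.to_numpy()
        recon = proj.scores.to_numpy() @ proj.loadings.to_numpy().T + X.mean(axis=0)
        assert np.abs(recon - X).max() < 1e-8

    def test_sign_convention_deterministic(self, rng):
        proj = vj_usage.pca_vj(self._matrix(rng))
        for c in proj.loadings.columns:
            col = proj.loadings[c]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            vj_usage.pca_vj(self._matrix(rng, n=2))

    def test_disjoint_cohort_usage_separates_on_pc1(self):
        # cohort A draws V genes from one half of the gene list, cohort B
        # from the other: PC1 scores must separate with no overlap
        cfg = tiny_config(n_samples_per_cohort=6, planted_clusters=(), public_clones=())
        base = cfg.v_gene_weights["default"]
        genes = sorted(base)
        half = len(genes) // 2
        wa = {g: (1.0 if i < half else 0.0) for i, g in enumerate(genes)}
        wb = {g: (0.0 if i < half else 1.0) for i, g in enumerate(genes)}
        cfg = replace(cfg, v_gene_weights={"A": wa, "B": wb})
        reps = []
        for cohort in ("A", "B"):
            for i in range(6):
                rep, _ = simulate_repertoire(cfg, cohort, i, seed=5)
                reps.append(filter_repertoire(rep))
        m = vj_usage.vj_usage_matrix(reps)
        proj = vj_usage.pca_vj(m)
        a = proj.scores.loc[[s for s in proj.scores.index if s.startswith("A")], "PC1"]
        b = proj.scores.loc[[s for s in proj.scores.index if s.startswith("B")], "PC1"]
        assert a.max() < b.min() or b.max() < a.min()


class TestManova:
    def test_no_effect_limit_p_near_one(self, rng):
        half = pd.DataFrame(rng.normal(size=(6, 2)), columns=["PC1", "PC2"])
        scores = pd.concat([half, half], ignore_index=True)
        p = vj_usage.manova_pillai(scores, ["A"] * 6 + ["B"] * 6)
        assert p > 0.99

    def test_large_offset_significant(self, rng):
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(10, 2)) + 10.0  # 10 within-group SDs apart
        scores = pd.DataFrame(np.vstack([a, b]), columns=["PC1", "PC2"])
        assert vj_usage.manova_pillai(scores, ["A"] * 10 + ["B"] * 10) < 1e-6

    def test_group_with_single_sample_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 2)), columns=["PC1", "PC2"])
        with pytest.raises(ValueError):
            vj_usage.manova_pillai(scores, ["A"] * 4 + ["B"])

    def test_requires_two_response_columns(self, rng):
        scores = pd.DataFrame(rng.normal(size=(6, 3)), columns=["PC1", "PC2", "PC3"])
        with pytest.raises(ValueError):
            vj_usage.manova_pillai(scores, ["A"] * 3 + ["B"] * 3)


class TestTopContributors:
    def test_ranking_by_absolute_loading_with_ties_lexicographic(self, rng):
        load = pd.DataFrame({"PC1": [0.5, -0.9, 0.5, 0.1], "PC2": [0.1, 0.2, 0.3, 0.4]},
                            index=["b", "a", "aa", "c"])
        proj = vj_usage.PcaProjection(scores=pd.DataFrame(), loadings=load,
                                      explained_variance=np.array([0.5, 0.3]))
        top = vj_usage.top_contributors(proj, n=3)
        assert top["PC1"] == ["a", "aa", "b"]

    def test_n_larger_than_variable_count_returns_all(self, rng):
        load = pd.DataFrame({"PC1": [0.2, 0.1], "PC2": [0.1, 0.2]}, index=["x", "y"])
        proj = vj_usage.PcaProjection(pd.DataFrame(), load, np.array([0.6, 0.4]))
        assert len(vj_usage.top_contributors(proj, n=10)["PC1"]) == 2
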