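"""Combinatorial VJ gene-usage matrices, PCA and Pillai-Bartlett MANOVA.

Per-sample VJ usage (read-weighted frequency of each observed V-J gene
pair) is projected onto principal components; cohort separation on the
first two components is tested with the Pillai-Bartlett trace of a
one-way MANOVA, the test used for repertoire ordination figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.multivariate.manova import MANOVA

from .io import Repertoire, clone_frequencies

__all__ = ["PcaProjection", "vj_usage_matrix", "pca_vj", "manova_pillai", "top_contributors"]


@dataclass
class PcaProjection:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components
    explained_variance: np.ndarray  # fraction per component
    manova_p: float | None = None


def vj_usage_matrix(repertoires: list[Repertoire]) -> pd.DataFrame:
    """Samples x VJ-pair matrix of read-weighted pair frequencies.

    Columns are the union of pairs observed in any sample (lexicographic
    by V then J, labelled "V|J"); absent pairs are 0 and each row sums
    to 1.  All repertoires must share a locus.
    """
    if len(repertoires) < 2:
        raise ValueError("need at least two samples")
    loci = {rep.locus for rep in repertoires}
    if len(loci) > 1:
        raise ValueError(f"mixed loci in VJ usage matrix: {sorted(loci)}")
    rows = {}
    for rep in repertoires:
        ft = clone_frequencies(rep, "vj_pair")
        rows[rep.sample_id] = {f"{v}|{j}": f for (v, j), f in ft.entries.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return df.reindex(sorted(df.columns), axis=1)


def pca_vj(matrix: pd.DataFrame, scale: bool = False, n_components: int | None = None) -> PcaProjection:
    """PCA of the column-centered usage matrix.

    Covariance PCA by default: VJ frequencies share a common scale, so no
    unit-variance scaling (``scale=True`` switches to correlation PCA).
    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making runs reproducible.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = matrix.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if scale:
        X = X.copy()
        X[:, keep] = X[:, keep] / X[:, keep].std(axis=0)
    if keep.sum() < 2:
        raise ValueError("need at least 2 variables with nonzero variance")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    load = pca.components_.T  # variables x components
    for c in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, c])), c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    names = [f"PC{i + 1}" for i in range(load.shape[1])]
    return PcaProjection(
        scores=pd.DataFrame(scores, index=matrix.index, columns=names),
        loadings=pd.DataFrame(load, index=matrix.columns, columns=names),
        explained_variance=pca.explained_variance_ratio_,
    )


def manova_pillai(scores: pd.DataFrame, labels) -> float:
    """Pillai-Bartlett trace p-value for cohort separation on PC1/PC2.

    One-way MANOVA with the two score columns as responses; returns the
    p-value of the Pillai trace F approximation for the group effect.
    """
    if scores.shape[1] != 2:
        raise ValueError("MANOVA runs on exactly two response columns (PC1, PC2)")
    labels = pd.Series(np.asarray(labels, dtype=object), index=scores.index, name="group")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"each group needs >= 2 samples; too small: {small}")
    df = pd.DataFrame({"y1": scores.iloc[:, 0], "y2": scores.iloc[:, 1], "group": labels})
    means = df.groupby("group")[["y1", "y2"]].mean()
    if np.allclose(means.to_numpy() - means.to_numpy().mean(axis=0), 0, atol=1e-12):
        return 1.0  # zero between-group variation: degenerate for the F fit
    mv = MANOVA.from_formula("y1 + y2 ~ group", data=df)
    stat = mv.mv_test().results["group"]["stat"]
    return float(stat.loc["Pillai's trace", "Pr > F"])


def top_contributors(pca: PcaProjection, n: int = 10,
                     components: tuple[str, ...] = ("PC1", "PC2")) -> dict[str, list[str]]:
    """Variables ranked by absolute loading per component (descending),
    ties broken lexicographically; at most ``n`` per component."""
    out = {}
    for comp in components:
        col = pca.loadings[comp]
        order = sorted(col.index, key=lambda v: (-abs(col[v]), v))
        out[comp] = order[:n]
    return out
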