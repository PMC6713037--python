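"""CDR3 physico-chemical descriptors: GRAVY and length distributions.

GRAVY (grand average of hydropathy) is the mean Kyte-Doolittle hydropathy
over a peptide's residues.  Cohort-level hydrophobicity is summarised as a
cumulative curve: all distinct CDR3 amino-acid clones pooled within a
cohort, ordered by ascending GRAVY, each contributing 1/(total clones) to
the cumulative relative frequency.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .io import EmptyRepertoireError, Repertoire, clone_frequencies

__all__ = ["KYTE_DOOLITTLE", "gravy", "gravy_cumulative_curve", "cdr3_length_distribution"]


def _load_scale() -> dict[str, float]:
    with resources.files("repclust.data").joinpath("kyte_doolittle.json").open() as fh:
        return {k: float(v) for k, v in json.load(fh)["values"].items()}


#: Kyte-Doolittle hydropathy values for the 20 standard residues.
KYTE_DOOLITTLE: dict[str, float] = _load_scale()


def gravy(cdr3_aa: str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy of an amino-acid sequence.

    Raises on an empty string or a letter outside the scale, naming the
    offending 1-based position.
    """
    scale = KYTE_DOOLITTLE if scale is None else scale
    if not cdr3_aa:
        raise ValueError("cannot compute GRAVY of an empty sequence")
    total = 0.0
    for i, letter in enumerate(cdr3_aa):
        try:
            total += scale[letter]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid letter {letter!r} at position {i + 1} in {cdr3_aa!r}"
            ) from None
    return total / len(cdr3_aa)


def gravy_cumulative_curve(repertoires: list[Repertoire],
                           read_weighted: bool = False) -> pd.DataFrame:
    """Cohort cumulative GRAVY curve.

    Distinct CDR3 aa clones are pooled across the given repertoires (one
    cohort).  By default every clone contributes 1/(total distinct clones)
    to the cumulative relative frequency; ``read_weighted`` uses pooled
    read shares instead.  GRAVY ties are ordered lexicographically by
    sequence so output is deterministic.

    Returns a DataFrame with columns ``cdr3_aa``, ``gravy``,
    ``cumulative_fraction`` (last value exactly 1).
    """
    if not repertoires:
        raise ValueError("need at least one repertoire")
    weights: dict[str, float] = {}
    for rep in repertoires:
        for r in rep.records.values():
            weights[r.cdr3_aa] = weights.get(r.cdr3_aa, 0.0) + float(r.read_count)
    if not weights:
        raise EmptyRepertoireError("no clones in cohort")
    seqs = sorted(weights)
    if read_weighted:
        total = sum(weights.values())
        w = np.array([weights[s] / total for s in seqs])
    else:
        w = np.full(len(seqs), 1.0 / len(seqs))
    g = np.array([gravy(s) for s in seqs])
    order = np.lexsort((np.array(seqs, dtype=object), g))  # gravy asc, sequence asc
    cum = np.cumsum(w[order])
    cum[-1] = 1.0  # clamp float drift; curve ends at exactly 1
    return pd.DataFrame({
        "cdr3_aa": np.array(seqs, dtype=object)[order],
        "gravy": g[order],
        "cumulative_fraction": cum,
    })


def cdr3_length_distribution(rep: Repertoire, weighting: str = "clone") -> pd.Series:
    """CDR3 amino-acid length histogram for one sample.

    ``weighting="clone"`` counts each distinct aa clone once;
    ``weighting="read"`` weights by read share.  Shares sum to 1.
    """
    if not rep.records:
        raise EmptyRepertoireError(f"sample {rep.sample_id!r} has no records")
    if weighting not in ("clone", "read"):
        raise ValueError(f"unknown weighting {weighting!r}")
    freqs = clone_frequencies(rep, "cdr3_aa")
    lengths: dict[int, float] = {}
    n = len(freqs.entries)
    for aa, f in freqs.entries.items():
        w = f if weighting == "read" else 1.0 / n
        lengths[len(aa)] = lengths.get(len(aa), 0.0) + w
    return pd.Series(lengths, name="share").sort_index()
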