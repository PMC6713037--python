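"""Clonotype table I/O, filtering, frequencies and read-depth matching.

A *clone* is a unique CDR3 nucleotide sequence together with its V/J call
and read count.  Tables are read from AIRR Rearrangement TSV (canonical)
or a MiXCR-style export dialect; rows with identical CDR3 nucleotide
sequences are merged by summing read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ClonotypeRecord",
    "Repertoire",
    "FrequencyTable",
    "FormatError",
    "EmptyRepertoireError",
    "read_clonotype_table",
    "write_repertoire",
    "filter_repertoire",
    "clone_frequencies",
    "downsample_reads",
    "read_sample_sheet",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# Required columns per dialect and their mapping onto ClonotypeRecord fields.
_AIRR_REQUIRED = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]
_MIXCR_REQUIRED = ["cloneCount", "nSeqCDR3", "aaSeqCDR3", "allVHitsWithScore", "allJHitsWithScore"]


class FormatError(ValueError):
    """A clonotype table does not conform to the declared dialect."""


class EmptyRepertoireError(ValueError):
    """An operation produced or received a repertoire with no records."""


@dataclass(frozen=True, slots=True)
class ClonotypeRecord:
    """One clonotype row: CDR3 at nt and aa level, V/J call, read count."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    read_count: int
    productive: bool

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise ValueError("cdr3_nt must be non-empty")
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")


@dataclass
class Repertoire:
    """A sample's clonotype set, keyed by CDR3 nucleotide sequence."""

    sample_id: str
    cohort: str
    locus: str = "TRB"
    records: dict[str, ClonotypeRecord] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(r.read_count for r in self.records.values())

    @property
    def n_clones(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FrequencyTable:
    """Relative read-count shares at a chosen clone-identity level.

    ``identity_level`` is one of ``cdr3_nt`` (the clone definition used for
    diversity), ``cdr3_aa`` (used for sharing/clustering) or ``vj_pair``.
    """

    identity_level: str
    entries: dict = field(default_factory=dict)

    def values(self) -> np.ndarray:
        return np.asarray(list(self.entries.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def _strip_allele(call: str) -> str:
    """First hit of a MiXCR gene-call field, trimmed to gene level."""
    first = call.split(",")[0].strip()
    first = first.split("(")[0]
    return first.split("*")[0]


def _derive_productive(cdr3_nt: str, cdr3_aa: str) -> bool:
    return ("*" not in cdr3_aa) and ("_" not in cdr3_aa) and len(cdr3_nt) % 3 == 0


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().upper() in {"T", "TRUE", "1", "YES"}


def read_clonotype_table(path, dialect: str = "airr", sample_id: str = "",
                         cohort: str = "", locus: str = "TRB",
                         metadata: dict | None = None) -> Repertoire:
    """Read one clonotype table into a :class:`Repertoire`.

    Rows with identical ``cdr3_nt`` are merged by summing read counts; the
    V/J call of the highest-count row wins, ties broken lexicographically.

    Parameters
    ----------
    dialect
        ``"airr"`` for AIRR Rearrangement TSV, ``"mixcr"`` for a MiXCR-style
        export (``cloneCount``/``nSeqCDR3``/``aaSeqCDR3``/``allVHitsWithScore``
        /``allJHitsWithScore``; allele suffixes are stripped to gene level).
    """
    if dialect not in ("airr", "mixcr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = _AIRR_REQUIRED if dialect == "airr" else _MIXCR_REQUIRED
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} for dialect {dialect!r}")

    rows = []
    for idx, row in enumerate(df.itertuples(index=False)):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        if dialect == "airr":
            nt, aa = r["junction"], r["junction_aa"]
            v, j = r["v_call"].split("*")[0], r["j_call"].split("*")[0]
            raw_count = r["duplicate_count"]
        else:
            nt, aa = r["nSeqCDR3"], r["aaSeqCDR3"]
            v, j = _strip_allele(r["allVHitsWithScore"]), _strip_allele(r["allJHitsWithScore"])
            raw_count = r["cloneCount"]
        try:
            count = int(float(raw_count))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable read count {raw_count!r} at row {idx}") from exc
        if dialect == "airr" and "productive" in df.columns and pd.notna(r.get("productive")):
            productive = _parse_bool(r["productive"])
        else:
            productive = _derive_productive(nt, aa)
        rows.append((nt, aa, v, j, count, productive))

    # merge identical cdr3_nt: sum counts, majority V/J (count, then lexicographic)
    merged: dict[str, list] = {}
    for nt, aa, v, j, count, productive in rows:
        if nt not in merged:
            merged[nt] = [aa, count, productive, {(v, j): count}]
        else:
            m = merged[nt]
            m[1] += count
            m[2] = m[2] and productive
            m[3][(v, j)] = m[3].get((v, j), 0) + count
    records = {}
    for nt, (aa, count, productive, vj_counts) in merged.items():
        (v, j), _ = min(vj_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        records[nt] = ClonotypeRecord(nt, aa, v, j, count, productive)

    return Repertoire(sample_id=sample_id, cohort=cohort, locus=locus,
                      records=records, metadata=dict(metadata or {}))


def write_repertoire(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV (round-trips with
    :func:`read_clonotype_table` in the ``airr`` dialect)."""
    cols = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count", "productive"]
    data = [
        (r.cdr3_nt, r.cdr3_aa, r.v_gene, r.j_gene, r.read_count, "T" if r.productive else "F")
        for r in rep.records.values()
    ]
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False)


def filter_repertoire(rep: Repertoire, min_count: int = 2,
                      productive_only: bool = True) -> Repertoire:
    """Keep productive clones with read count >= ``min_count``.

    The defaults mirror the standard inclusion rule for amplicon
    immunosequencing: only productive sequences with a read count of at
    least 2 enter the analysis.  Raises :class:`EmptyRepertoireError` if
    nothing survives (downstream metrics would be undefined).
    """
    kept = {
        nt: r for nt, r in rep.records.items()
        if r.read_count >= min_count and (r.productive or not productive_only)
    }
    log.info("filter_repertoire(%s): %d -> %d clones", rep.sample_id, len(rep.records), len(kept))
    if not kept:
        raise EmptyRepertoireError(
            f"sample {rep.sample_id!r}: empty repertoire after filtering "
            f"(min_count={min_count}, productive_only={productive_only})")
    return replace(rep, records=kept, metadata=dict(rep.metadata))


def clone_frequencies(rep: Repertoire, identity_level: str = "cdr3_nt") -> FrequencyTable:
    """Relative clone frequencies p = n/N at the requested identity level.

    At ``cdr3_aa`` or ``vj_pair`` level, read counts of records mapping to
    the same key are summed before normalisation.
    """
    if not rep.records:
        raise EmptyRepertoireError(f"sample {rep.sample_id!r} has no records")
    counts: dict = {}
    for r in rep.records.values():
        if identity_level == "cdr3_nt":
            key = r.cdr3_nt
        elif identity_level == "cdr3_aa":
            key = r.cdr3_aa
        elif identity_level == "vj_pair":
            key = (r.v_gene, r.j_gene)
        else:
            raise ValueError(f"unknown identity level {identity_level!r}")
        counts[key] = counts.get(key, 0) + r.read_count
    total = sum(counts.values())
    return FrequencyTable(identity_level, {k: n / total for k, n in counts.items()})


def downsample_reads(rep: Repertoire, target_depth: int, seed: int) -> Repertoire:
    """Depth-match by drawing ``target_depth`` reads without replacement.

    A multivariate-hypergeometric draw across clones; clones drawn zero
    times are dropped.  Used to match sequencing depth across samples
    before cross-cohort comparisons (every sample is downsampled to the
    minimum post-filter depth).  No upsampling: ``target_depth`` may not
    exceed the repertoire's total reads.
    """
    counts = np.array([r.read_count for r in rep.records.values()], dtype=np.int64)
    total = int(counts.sum())
    if target_depth > total:
        raise ValueError(f"target_depth {target_depth} exceeds total reads {total}")
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(counts, target_depth)
    records = {}
    for r, n in zip(rep.records.values(), drawn):
        if n > 0:
            records[r.cdr3_nt] = replace(r, read_count=int(n))
    return replace(rep, records=records, metadata=dict(rep.metadata))


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV.

    Required columns: ``sample_id``, ``path``, ``cohort``, ``locus``.
    Optional: ``patient_id`` (defaults to ``sample_id``; multiple
    timepoints of one patient share a patient_id and count as one
    individual in sharing filters), ``age_band``, ``timepoint``.
    Relative clonotype-table paths are resolved against the sheet's own
    directory, so generated datasets are relocatable.
    """
    from pathlib import Path

    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "path", "cohort", "locus"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing required column {col!r}")
    if "patient_id" not in df.columns:
        df["patient_id"] = df["sample_id"]
    df["patient_id"] = df["patient_id"].fillna(df["sample_id"])
    base = Path(path).resolve().parent
    df["path"] = [p if not p or Path(p).is_absolute() else str(base / p)
                  for p in df["path"].fillna("")]
    return df
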