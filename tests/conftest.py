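import numpy as np
import pytest

from repclust.io import ClonotypeRecord, Repertoire


def make_repertoire(counts: dict[str, int], sample_id="s1", cohort="A",
                    productive=True, aa=None, v="TRBV2", j="TRBJ1-1") -> Repertoire:
    """Repertoire from {cdr3_nt: count}; aa defaults to a translation-length
    placeholder derived from nt length."""
    records = {}
    for nt, n in counts.items():
        cdr3_aa = (aa or {}).get(nt) if aa else None
        if cdr3_aa is None:
            cdr3_aa = "C" + "A" * (len(nt) // 3 - 2) + "F"
        records[nt] = ClonotypeRecord(nt, cdr3_aa, v, j, n, productive)
    return Repertoire(sample_id=sample_id, cohort=cohort, records=records)


@pytest.fixture
def toy_repertoire():
    return make_repertoire({"TGTGCAGCATTT": 3, "TGTGCAGCCTTT": 1})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
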