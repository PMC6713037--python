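#!/usr/bin/env python
"""CDR3 physico-chemical characterisation: GRAVY curves, lengths.

Pools distinct CDR3 aa clones per cohort, orders them by ascending
grand-average hydropathy and writes the cumulative curves plus
per-sample length distributions under results/.
"""

import argparse
from pathlib import Path

import numpy as np

from repclust.physchem import gravy_cumulative_curve
from repclust.pipeline import RunConfig, ingest_samples

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "synthetic_cohorts")
    args = ap.parse_args()

    cfg = RunConfig(sample_sheet=str(args.data / "sample_sheet.csv"))
    reps, _ = ingest_samples(cfg)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    curves = []
    for cohort in sorted({r.cohort for r in reps}):
        curve = gravy_cumulative_curve([r for r in reps if r.cohort == cohort])
        median_gravy = float(np.interp(0.5, curve["cumulative_fraction"], curve["gravy"]))
        print(f"{cohort}: {len(curve)} distinct CDR3 aa clones, "
              f"median GRAVY {median_gravy:+.3f}")
        curve.insert(0, "cohort", cohort)
        curves.append(curve)
    import pandas as pd
    pd.concat(curves).to_csv(out / "gravy_curves.tsv", sep="\t", index=False)
    print("cohort curves should coincide: the generator draws CDR3 "
          "composition identically for both cohorts.")


if __name__ == "__main__":
    main()
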