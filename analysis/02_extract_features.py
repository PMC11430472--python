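#!/usr/bin/env python
"""Extract the 324-feature vectors for every scan of every simulated cohort.

Reads the cohorts written by 01_simulate_cohorts.py, computes both
connectivity variants, the binary-graph metrics and the aligned cortical
gradients, and writes one features.tsv per cohort (scratch/) plus the
per-family feature counts (results/feature_counts.tsv).
"""

import argparse
from pathlib import Path

import pandas as pd

import connstates as cs
from connstates import io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", type=Path, default=Path("scratch/cohorts"))
    ap.add_argument("--out", type=Path, default=Path("scratch/features"))
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    counts = None
    for cohort_dir in sorted(args.cohorts.iterdir()):
        if not (cohort_dir / "cohort.json").exists():
            continue
        cohort = io.read_cohort(cohort_dir)
        features, meta, ref = cs.extract_cohort_features(cohort)
        io.write_features(args.out / f"{cohort.condition}.tsv", features, meta)
        io.write_reference(args.out / f"{cohort.condition}_reference.tsv", ref)
        fams = {fam: len(cols) for fam, cols in cs.family_columns(features).items()}
        fams["total"] = features.shape[1]
        counts = pd.Series(fams, name="n_features")
        print(f"{cohort.condition}: {features.shape[0]} scans x {features.shape[1]} features")

    if counts is not None:
        Path("results").mkdir(exist_ok=True)
        counts.rename_axis("family").to_frame().to_csv(
            "results/feature_counts.tsv", sep="\t")
        print(counts)


if __name__ == "__main__":
    main()
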