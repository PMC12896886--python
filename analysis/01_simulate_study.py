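#!/usr/bin/env python
"""Simulate the multi-platform discovery study.

Generates the default study conditions: 2,000 genes across seven tissue
classes (8 sCSC, 8 dCSC, 10 normal, 4 LCM normal, 10 tumor, 4 LCM tumor,
8 cell lines) on two array platforms with per-platform batch effects,
25 planted CSC-enriched membrane targets and 25 tumor-shared membrane
decoys.  Writes the matrix, sample sheet, annotation and truth tables.
"""

from pathlib import Path

import pandas as pd

from csctargets import StudyConfig, gen_expression_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 20260926


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = StudyConfig(seed=SEED, n_planted_targets=25, n_planted_decoys=25)
    study, annotation, truth = gen_expression_study(config)
    study.to_tsv(OUT / "matrix.tsv", OUT / "samples.tsv")
    annotation.to_csv(OUT / "annotation.tsv", sep="\t")
    pd.DataFrame(
        {
            "gene": truth.planted_target_ids + truth.planted_decoy_ids,
            "role": ["target"] * len(truth.planted_target_ids)
            + ["decoy"] * len(truth.planted_decoy_ids),
        }
    ).to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(
        f"simulated {study.values.shape[0]} genes × {study.n_samples} samples "
        f"({study.sample_sheet['platform'].nunique()} platforms), "
        f"{len(truth.planted_target_ids)} planted targets, "
        f"{len(truth.planted_decoy_ids)} decoys -> {OUT}"
    )


if __name__ == "__main__":
    main()
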