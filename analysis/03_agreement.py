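#!/usr/bin/env python
"""Step 3 — pairwise model agreement on AUROC.

For each evaluation level, computes the Spearman rank-correlation matrix
between models' AUROC lists: the lower triangle compares per-group
(superfamily / fold) mean AUROC, the upper triangle per-query AUROC.  High
agreement means two models find the same groups easy or hard, regardless of
their average performance.  Outputs go to results/study/.
"""

from pathlib import Path

import pandas as pd

from remhom import EvalLevel, agreement_matrix

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
EVAL = ROOT / "scratch" / "study_eval"
MODELS = ("plm_strong", "plm_weak", "fold_only", "random")


def main() -> None:
    for level in (EvalLevel.SUPERFAMILY, EvalLevel.FOLD):
        frames = {
            model: pd.read_csv(
                EVAL / f"perquery_th30_{level.value}_{model}.tsv", sep="\t"
            )
            for model in MODELS
        }
        result = agreement_matrix(frames, level)
        out = STUDY / f"agreement_{level.value}.tsv"
        result.values.to_csv(out, sep="\t", float_format="%.4f")
        print(f"{level.value} agreement (lower=per-group, upper=per-query):")
        print(result.values.round(3).to_string())
        print(f"-> {out}\n")


if __name__ == "__main__":
    main()
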