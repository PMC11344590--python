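#!/usr/bin/env python
"""Step 4 — report tables: best/worst superfamilies and model deltas.

Emits (a) the top/bottom superfamilies by mean AUROC for the strong model,
with the mean number of true labels per query and the query count per
superfamily, and (b) the superfamilies with the largest AUROC differences
between the strong model and the random baseline, in both directions.
Outputs go to results/study/tables/.
"""

from pathlib import Path

import pandas as pd

from remhom import model_delta_table, top_bottom_groups

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
EVAL = ROOT / "scratch" / "study_eval"


def main() -> None:
    tables = STUDY / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    strong = pd.read_csv(EVAL / "perquery_th30_superfamily_plm_strong.tsv", sep="\t")
    weak = pd.read_csv(EVAL / "perquery_th30_superfamily_plm_weak.tsv", sep="\t")

    top_bottom = top_bottom_groups(strong, n=3, min_queries=5)
    top_bottom.to_csv(tables / "top_bottom_superfamilies.tsv", sep="\t", index=False,
                      float_format="%.4f")
    print("plm_strong: top/bottom superfamilies by mean AUROC")
    print(top_bottom.to_string(index=False), "\n")

    delta = model_delta_table(strong, weak, n=3, names=("plm_strong", "plm_weak"))
    delta.to_csv(tables / "model_delta_superfamilies.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print("largest per-superfamily AUROC differences (strong vs weak):")
    print(delta.to_string(index=False))
    print(f"\ntables -> {tables}")


if __name__ == "__main__":
    main()
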