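#!/usr/bin/env python
"""Step 2 — run the retrieval evaluation for every model at both levels.

Each of the 80 domains queries the other 79; same-family (superfamily
level) or same-superfamily (fold level) candidates are excluded, cosine
similarity ranks the rest, and per-query AUROC/AUPRC/Hit@1/Hit@10 are
aggregated per superfamily / per fold (weighted) and over all queries
(unweighted).  Full per-query and per-group tables go to scratch/study_eval/
(regenerable); the compact overall summary goes to
results/study/overall_metrics.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from remhom import EvalLevel, RunConfig, run_evaluation
from remhom.runner import DatabaseSpec, ModelSpec

ROOT = Path(__file__).resolve().parents[1]
EVAL = ROOT / "scratch" / "study_eval"
MODELS = ("plm_strong", "plm_weak", "fold_only", "random")


def main() -> None:
    inputs = ROOT / "scratch" / "study_inputs"
    config = RunConfig(
        databases=(DatabaseSpec(str(inputs / "database.tsv"), "tsv", 0.3),),
        models=tuple(ModelSpec(m, store=str(inputs / f"{m}.h5")) for m in MODELS),
        levels=(EvalLevel.SUPERFAMILY, EvalLevel.FOLD),
        output_dir=str(EVAL),
        seed=2024,
    )
    report = run_evaluation(config)
    assert report.exit_code == 0, "some combinations failed"

    rows = []
    for level in ("superfamily", "fold"):
        for model in MODELS:
            for scheme in ("weighted", "unweighted"):
                data = json.loads(
                    (EVAL / f"aggregate_th30_{level}_{model}_{scheme}.json").read_text()
                )
                rows.append({"level": level, "model": model, "scheme": scheme,
                             "n_queries": data["n_queries"], **data["overall"]})
    summary = pd.DataFrame(rows)
    out = ROOT / "results" / "study" / "overall_metrics.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print("weighted overall AUROC:")
    weighted = summary[summary["scheme"] == "weighted"]
    for row in weighted.itertuples(index=False):
        print(f"  {row.level:12s} {row.model:11s} auroc={row.auroc:.3f} "
              f"auprc={row.auprc:.3f} hit1={row.hit1:.3f} ({row.n_queries} queries)")
    print(f"summary -> {out}; full tables -> {EVAL}")


if __name__ == "__main__":
    main()
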