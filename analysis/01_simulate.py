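#!/usr/bin/env python
"""Step 1 — generate the synthetic study inputs.

Builds a balanced SCOP-like database (4 folds x 2 superfamilies x 2 families
x 5 domains = 80 domains) and four representation stores over it:

* ``plm_strong``  — clear superfamily-level signal (weight 1.0, noise 0.6),
  standing in for a high-performing embedding model (near-perfect but not
  degenerate: per-query AUROC must vary for rank-agreement analysis);
* ``plm_weak``    — weak signal (weight 0.5, noise 1.0), a smaller model;
* ``fold_only``   — signal only at the fold level (weight 1.0, noise 1.0), to probe level separation;
* ``random``      — the uniform-[0,1) length-150 null baseline.

Stores and the database are intermediate artefacts and go to scratch/study_inputs/;
later steps write their tables under results/study/.
"""

from pathlib import Path

from remhom import (
    HierarchySpec,
    SignalSpec,
    generate_embeddings,
    generate_hierarchy,
    generate_random_representations,
    save_representation_store,
    write_annotation_table,
)

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "scratch" / "study_inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    db = generate_hierarchy(HierarchySpec(4, 2, 2, 5, seed=SEED))
    write_annotation_table(db, OUT / "database.tsv")

    specs = {
        "plm_strong": SignalSpec(dim=32, superfamily_weight=1.0, noise_sd=0.6,
                                 seed=SEED + 1),
        "plm_weak": SignalSpec(dim=32, superfamily_weight=0.5, noise_sd=1.0,
                               seed=SEED + 2),
        "fold_only": SignalSpec(dim=32, fold_weight=1.0, noise_sd=1.0,
                                seed=SEED + 3),
    }
    for name, spec in specs.items():
        save_representation_store(generate_embeddings(db, spec), OUT / f"{name}.h5")
    save_representation_store(
        generate_random_representations(db.ids, length=150, seed=SEED + 4),
        OUT / "random.h5",
    )
    n_sfs = len({r.classification.superfamily_id for r in db})
    print(f"wrote {len(db)} domains across {n_sfs} superfamilies, "
          f"4 model stores -> {OUT}")


if __name__ == "__main__":
    main()
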