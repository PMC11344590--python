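# Methods

## Task model

The unit of evaluation is a classified protein domain database: every
domain carries a depth-4 SCOP concise classification string
(class.fold.superfamily.family, e.g. `a.38.1.2`) and a sequence. Remote
homology is defined relative to a level of the hierarchy:

* **Superfamily level** — domains *i, j* are remote homologs iff
  SF_i = SF_j and F_i ≠ F_j;
* **Fold level** — iff Fold_i = Fold_j and SF_i ≠ SF_j.

Each domain in turn is a query against all others. Candidates in the
query's own Family (Superfamily level) or Superfamily (Fold level) are
excluded from the candidate set entirely, so the task is remote homology
versus non-homology rather than versus "everything else"; the query itself
is always excluded (its self-similarity of 1 would trivialise Hit@1).
Queries with zero positives are dropped and counted. For every retained
query, positives + negatives + excluded + 1 = N holds exactly, and the
suite property-tests this over randomized hierarchies.

The hardened definition adds a sequence-identity clause: a pair only counts
as remote-homologous when seqident(i, j) ≤ th. This clause is enforced at
the dataset level — each evaluated database is a pre-filtered subset (e.g.
an Astral identity subset) in which no pair exceeds *th* — and *th* is
carried as provenance metadata (`identity_threshold_label`), not applied at
run time. Consequently the labeller implements only the hierarchy clauses.

A deliberate consequence of the labeling rules: at the Superfamily level,
same-Fold/different-SF domains (Fold-level homologs) remain in the
*negative* pool. This follows the task definition literally, but it couples
the two levels: any model whose similarity reflects fold membership gains
Superfamily-level AUROC through its cross-fold negatives. Quantitatively,
with per-pair discriminations d ≈ 0.5 against same-fold negatives and
d ≈ AUROC_fold against cross-fold ones, the Superfamily AUROC of a
fold-only model is approximately w·0.5 + (1−w)·AUROC_fold, where w is the
same-fold fraction of the negative pool (on the default 4×2×2×5 toy
database, w = 10/70, predicting ≈ 0.93 — which the tests confirm). A
fold-only signal therefore does *not* reduce Superfamily-level AUROC to
chance on any multi-fold database; chance would require w → 1, i.e. a
database that is essentially one fold, which in turn destroys the
Fold-level task. One acceptance-style check encoding the "chance" reading
is retained and fails by design; the module test asserts the mixture
relation above instead.

## Representations and scoring

Per-residue matrices s ∈ R^(l×D) are mean-pooled over the residue axis in
double precision; the store contract requires exporters to strip
special/padding token rows so pooling runs over exactly the l residues.
Pairs are scored with cosine similarity. Zero-norm vectors are treated as
corrupt input: a zero-norm query is an error, a zero-norm candidate is
dropped with a logged count — never silently scored 0, which would bias
rankings. Candidate ranking is descending by score with exact ties broken
by ascending domain id, making every ranking byte-reproducible; the
statistically meaningful tie handling lives in the metrics (midranks).

External scorers enter as pairwise score matrices (long or square TSV) with
an orientation flag (`higher_is_better`); lower-is-better scores are
negated. Missing pairs and non-finite scores are errors, so external
baselines pass through exactly the same metric path as embedding models.

## Metrics

* **AUROC** — Mann–Whitney midrank form: the probability a uniformly chosen
  positive outscores a uniformly chosen negative, ties credited ½;
  equivalent to the trapezoidal area under the ROC swept over score
  thresholds with the standard orientation (predict positive for scores ≥
  threshold). Verified against an exhaustive pair-count oracle and
  scikit-learn on random instances.
* **AUPRC** — average precision: the mean of precision@k over the ranks k
  occupied by positives, under the deterministic tie-break. AP = 1 iff all
  positives precede all negatives. Under a null (random-score) ranking the
  mean AP exceeds the positive prevalence by O(log n_pos / n_pos), so
  "AP ≈ prevalence" is asserted only in the many-positives regime; the null
  AUROC calibration (0.5) has no such bias.
* **Hit@k** — 1 iff any of the top min(k, list length) candidates is
  positive; k ∈ {1, 10} are reported.
* Queries with zero negatives (possible in tiny toy databases) are dropped
  from metric computation with a logged count, since AUROC is undefined
  there.

**Aggregation.** *Weighted*: mean per Superfamily (or Fold), then the plain
mean of group means, so small groups influence the headline number as much
as large ones. *Unweighted*: plain mean over queries. The two coincide
exactly when all groups have equal query counts.

**Agreement.** Spearman's ρ between two models' AUROC lists — per group
(which Superfamilies/Folds are easy or hard) and per query (paired by query
id) — computed as the Pearson correlation of midrank vectors, which reduces
to 1 − 6Σd²/(n(n²−1)) on tie-free lists. Models are aligned on the
intersection of their groups/queries; constant lists (e.g. a model with
AUROC exactly 1 everywhere) have zero rank variance and raise an
undefined-metric error rather than returning an arbitrary value — agreement
analyses should use operating points where performance varies.

## Synthetic data generator

The generator emulates the *structure* of a SCOP-style benchmark, not its
content. A balanced hierarchy (n_folds × superfamilies_per_fold ×
families_per_superfamily × domains_per_family) is enumerated
systematically; sequences are uniform random strings over the 20-letter
alphabet, lengths uniform in [50, 200] by default — plausible domain sizes
— and carry no signal unless `family_sequence_similarity` is set (then
family members are point mutations of a family template, used to exercise
the toy identity filter).

Embeddings follow an additive hierarchical Gaussian model: one independent
standard-normal centroid in R^D per fold, superfamily and family, and

    p = w_fold·c_fold + w_sf·c_SF + w_fam·c_F + ε,   ε ~ N(0, σ² I).

Centroids are drawn before per-domain noise and in sorted key order, so
configurations differing only in weights share their randomness for a given
seed. This is the simplest model in which cosine proximity encodes each
hierarchy level with tunable strength — exactly the assumption zero-shot
retrieval probes. The uniform-random baseline draws one length-150 vector
of i.i.d. U[0,1) entries per domain; any fixed bounded support is
equivalent under rank metrics, and 150 is the conventional length for this
baseline. Per-residue matrices broadcast the pooled target over the
sequence length plus i.i.d. per-residue noise, so pooling recovers the
target at rate 1/√l (tested at l ∈ {10, 1000}).

What the generator does **not** emulate: realistic sequence evolution,
SCOPe's skewed group-size distributions, anisotropic or non-Gaussian
embedding geometry, and any correlation between sequence content and
embedding signal. Passing tests therefore demonstrate the correctness of
the task construction, metrics and plumbing under controlled signal — not
that any particular real embedding model detects remote homology.

## Preprocessing and the toy identity filter

Dataset preprocessing supports an excluded-fold list (supplied as
configuration — e.g. Rossmann-like folds and 4–8-bladed β-propellers in
curated setups, whose exact identifiers depend on the database release) and
a single-continuous-span rule (Astral region descriptors with commas denote
multi-span sequences). Classification strings with more than four
components (sub-domain annotations) fail parsing and are collected as
record-level read errors. Filters report removed counts per rule and
conserve records exactly.

Production-scale identity subsets should come from dedicated clustering
tools; the built-in `greedy_identity_filter` is a toy-scale stand-in for
testing. It computes global percent identity as identical positions over
alignment length (gap columns included) under a stated scheme — match 1,
mismatch 0, linear gap −1 — retains greedily longest-first (ties by
ascending id), and guards against quadratic blow-up with a 2000-residue
cap. Non-standard residue codes (X/B/Z/U) are retained in sequences and
count as mismatches here; nothing else computes on sequence content.

## Numerical and design choices

* Pooling accumulates in float64 regardless of stored precision; stores are
  written as float64.
* All tie-breaking is deterministic (ascending id in rankings; midranks in
  AUROC and Spearman), and every generator is a pure function of its seed,
  so an entire run is byte-reproducible from its config — the suite
  compares files across reruns byte for byte.
* Identity thresholds are dataset labels (one database per threshold), not
  runtime filters; a run iterates databases × levels × models, isolates
  failures per combination, and exits 0/1/2 for ok / partial / total
  failure.
* Report tables follow the standard layout: top/bottom groups by mean AUROC
  among groups with more than `min_queries` queries (default 5), with the
  mean number of true labels per query and the query count; model-delta
  tables emit both difference directions over the group intersection.

## Problem sizes

The default study and test conditions use an 80-domain database (4 folds ×
2 SFs × 2 families × 5 domains; superfamily-level tasks then have 5
positives / 70 negatives / 4 exclusions per query), 560 null-model query
evaluations (7 independent random-baseline replicates, chosen to put the
null calibration beyond 500 observations while keeping the stated database
shape), 10,000 random instances for the metric-oracle equivalence check,
and 1,000 randomized hierarchies for the exclusion-invariant sweep. These
sizes give tight Monte-Carlo error (e.g. SEM of the null mean AUROC
≈ 0.006) at desk-scale cost.

## Known limitations

* The exclusion rules assume a strict tree: every family id determines its
  superfamily and fold. SCOP variants with cross-listed domains would need
  id disambiguation upstream.
* `DomainDatabase` is an in-memory tuple; databases of tens of thousands of
  domains are fine, millions are not the target.
* Task construction is O(N²) in labels and the toy identity filter is
  O(N²) alignments; both are intended for the ≤ tens-of-thousands regime
  (the filter far below that).
* AUPRC uses average precision; trapezoidal PR interpolation would give
  slightly different values and is deliberately not offered, to keep
  reported numbers unambiguous.
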