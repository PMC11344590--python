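"""Remote-homology task construction and cosine-ranked retrieval.

Remote homologs are defined at two levels of the SCOP hierarchy:

* superfamily level — a pair is positive when both domains share a
  Superfamily but belong to different Families;
* fold level — positive when both share a Fold but belong to different
  Superfamilies.

Every domain in the database serves as an independent query against all
other domains.  Candidates from the query's own Family (superfamily level)
or Superfamily (fold level) are *excluded* — they are sequence homologs, not
remote ones — so each task is remote homology versus non-homology.  Queries
with zero positive candidates are dropped and counted.  The sequence-identity
clause of the hardened definition is satisfied at the dataset level: the
database is a pre-filtered subset whose maximum pairwise identity is the
task's ``threshold_label``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import (
    ClassificationDepthError,
    DegenerateRepresentationError,
    MissingRepresentationError,
    MissingScoreError,
    SchemaError,
)
from .representations import RepresentationStore
from .scop import ClassificationPath, DomainDatabase

logger = logging.getLogger(__name__)

#: ranked lists break exact score ties by ascending candidate id
TIE_POLICY = "score_desc_then_id_asc"


class EvalLevel(str, Enum):
    """Evaluation level; fixes the positive group and the exclusion key."""

    SUPERFAMILY = "superfamily"
    FOLD = "fold"

    @property
    def group_attr(self) -> str:
        return "superfamily_id" if self is EvalLevel.SUPERFAMILY else "fold_id"

    @property
    def exclusion_attr(self) -> str:
        return "family_id" if self is EvalLevel.SUPERFAMILY else "superfamily_id"


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


def label_pair(a: ClassificationPath, b: ClassificationPath, level: EvalLevel) -> Label:
    """Label a candidate pair as positive / negative / excluded.

    Superfamily level: same Family -> excluded; same Superfamily, different
    Family -> positive; different Superfamily -> negative.  Fold level: same
    Superfamily -> excluded; same Fold, different Superfamily -> positive;
    different Fold -> negative.  Symmetric in its arguments.
    """
    level = EvalLevel(level)
    if a.depth != 4 or b.depth != 4:
        raise ClassificationDepthError(
            f"label_pair requires depth-4 paths, got {a.sccs!r} and {b.sccs!r}"
        )
    if getattr(a, level.exclusion_attr) == getattr(b, level.exclusion_attr):
        return Label.EXCLUDED
    if getattr(a, level.group_attr) == getattr(b, level.group_attr):
        return Label.POSITIVE
    return Label.NEGATIVE


@dataclass(frozen=True)
class QueryTask:
    """One query with its candidate database, labels and exclusion counts."""

    query_id: str
    candidate_ids: tuple[str, ...]
    labels: np.ndarray  # 1 = remote homolog, 0 = non-homolog, per candidate
    level: EvalLevel
    n_excluded: int
    threshold_label: float | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "candidate_ids", tuple(self.candidate_ids))
        if self.query_id in self.candidate_ids:
            raise SchemaError(f"query {self.query_id!r} appears among its candidates")
        if labels.shape != (len(self.candidate_ids),):
            raise SchemaError("labels and candidate_ids lengths differ")
        if labels.sum() < 1:
            raise SchemaError(
                f"query {self.query_id!r}: tasks require at least one positive"
            )

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.candidate_ids) - self.labels.sum())


@dataclass
class TaskBuildReport:
    """Bookkeeping for dropped queries during task construction."""

    n_domains: int = 0
    n_tasks: int = 0
    dropped_zero_positive: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_zero_positive)


def build_query_tasks(
    db: DomainDatabase, level: EvalLevel
) -> tuple[list[QueryTask], TaskBuildReport]:
    """Build one retrieval task per retained query domain.

    Every other domain in the database is labelled by :func:`label_pair`;
    excluded domains are absent from the candidate list, and queries with
    zero positives are dropped (and listed in the report).  For every
    retained query, positives + negatives + excluded + 1 = N.
    """
    level = EvalLevel(level)
    if len(db) == 0:
        raise SchemaError("cannot build tasks from an empty database")
    ids = np.array(db.ids)
    group = np.array([getattr(r.classification, level.group_attr) for r in db])
    excl = np.array([getattr(r.classification, level.exclusion_attr) for r in db])
    tasks: list[QueryTask] = []
    report = TaskBuildReport(n_domains=len(db))
    for i in range(len(db)):
        same_excl = excl == excl[i]
        positive = (group == group[i]) & ~same_excl
        if not positive.any():
            report.dropped_zero_positive.append(ids[i])
            continue
        candidate = ~same_excl  # positives and negatives; drops query + exclusions
        tasks.append(
            QueryTask(
                query_id=str(ids[i]),
                candidate_ids=tuple(ids[candidate]),
                labels=positive[candidate].astype(np.int8),
                level=level,
                n_excluded=int(same_excl.sum()) - 1,
                threshold_label=db.identity_threshold_label,
            )
        )
    report.n_tasks = len(tasks)
    if not tasks:
        warnings.warn(
            f"no retrievable queries at {level.value} level "
            "(no query has a remote homolog)",
            stacklevel=2,
        )
    return tasks, report


@dataclass(frozen=True)
class RankedList:
    """Candidates of one task in descending score order."""

    query_id: str
    candidate_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    tie_policy_tag: str = TIE_POLICY

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if np.any(np.diff(scores) > 0):
            raise SchemaError("ranked scores must be non-increasing")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


def _sorted_ranked(task: QueryTask, candidate_ids, scores, labels) -> RankedList:
    candidate_ids = np.asarray(candidate_ids)
    order = np.lexsort((candidate_ids, -np.asarray(scores)))
    return RankedList(
        query_id=task.query_id,
        candidate_ids=tuple(candidate_ids[order]),
        scores=np.asarray(scores, dtype=float)[order],
        labels=np.asarray(labels, dtype=np.int8)[order],
    )


def rank_candidates(task: QueryTask, store: RepresentationStore) -> RankedList:
    """Rank a task's candidates by cosine similarity to the query.

    Exact score ties are broken by ascending candidate id.  Zero-norm
    candidate representations are dropped with a log entry; a zero-norm
    query is an error.
    """
    missing = [i for i in (task.query_id, *task.candidate_ids) if i not in store]
    if missing:
        raise MissingRepresentationError(
            f"store {store.model_name!r} lacks representations for {missing[:10]}"
        )
    q = store[task.query_id]
    q_norm = np.linalg.norm(q)
    if q_norm == 0.0:
        raise DegenerateRepresentationError(
            f"query {task.query_id!r} has a zero-norm representation"
        )
    cand = store.matrix(task.candidate_ids)
    norms = np.linalg.norm(cand, axis=1)
    degenerate = norms == 0.0
    if degenerate.any():
        dropped = [c for c, bad in zip(task.candidate_ids, degenerate) if bad]
        logger.warning(
            "query %s: dropping %d zero-norm candidates: %s",
            task.query_id, len(dropped), dropped[:10],
        )
    keep = ~degenerate
    ids = np.asarray(task.candidate_ids)[keep]
    scores = (cand[keep] @ q) / (norms[keep] * q_norm)
    return _sorted_ranked(task, ids, scores, task.labels[keep])


def rank_candidates_from_matrix(
    task: QueryTask, scores: pd.DataFrame, higher_is_better: bool = True
) -> RankedList:
    """Rank candidates using externally supplied pairwise match scores.

    ``scores`` is a query-by-candidate DataFrame (see
    :func:`read_score_matrix`).  Scores where higher means more similar are
    the native orientation; with ``higher_is_better=False`` scores are
    negated before ranking.  Missing or non-finite entries are errors, so
    external baselines flow through exactly the same metric path as
    embedding models.
    """
    if task.query_id not in scores.index:
        raise MissingScoreError(f"no score row for query {task.query_id!r}")
    row = scores.loc[task.query_id]
    missing = [c for c in task.candidate_ids if c not in row.index]
    if missing:
        raise MissingScoreError(
            f"missing score pairs for query {task.query_id!r}: {missing[:10]}"
        )
    values = row.loc[list(task.candidate_ids)].to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        bad = [c for c, v in zip(task.candidate_ids, values) if np.isnan(v)]
        raise MissingScoreError(
            f"missing score pairs for query {task.query_id!r}: {bad[:10]}"
        )
    if not np.all(np.isfinite(values)):
        bad = [c for c, v in zip(task.candidate_ids, values) if not np.isfinite(v)]
        raise SchemaError(
            f"non-finite scores for query {task.query_id!r}: {bad[:10]}"
        )
    if not higher_is_better:
        values = -values
    return _sorted_ranked(task, task.candidate_ids, values, task.labels)


def read_score_matrix(path, layout: str = "long") -> pd.DataFrame:
    """Read a pairwise score matrix from TSV.

    ``layout="long"`` expects columns ``query_id``, ``candidate_id``,
    ``score``; ``layout="square"`` expects a square table with the id index
    in the first column.  Pairs absent from the long form are NaN in the
    resulting frame and trigger errors when ranked.
    """
    if layout == "long":
        frame = pd.read_csv(path, sep="\t", dtype={"query_id": str, "candidate_id": str})
        required = {"query_id", "candidate_id", "score"}
        if not required.issubset(frame.columns):
            raise SchemaError(f"{path}: long score table requires columns {sorted(required)}")
        return frame.pivot(index="query_id", columns="candidate_id", values="score")
    if layout == "square":
        return pd.read_csv(path, sep="\t", index_col=0).rename(columns=str, index=str)
    raise SchemaError(f"unknown score-matrix layout {layout!r}")
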