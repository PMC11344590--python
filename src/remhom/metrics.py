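"""Per-query ranking metrics, weighted aggregation and model agreement.

Per query we compute AUROC, AUPRC, Hit@1 and Hit@10 over the ranked
candidate list.  AUROC uses the Mann-Whitney midrank convention: it equals
the probability that a uniformly chosen positive outscores a uniformly
chosen negative, with exact score ties credited 1/2 — equivalent to the
trapezoidal area under the ROC curve swept over score thresholds (the
standard direction: predict positive for scores at or above the threshold).
AUPRC uses the average-precision convention, the mean of precision@k over
the ranks k at which positives sit, under the ranked list's deterministic
tie-break.

Aggregation follows two schemes: *weighted* first averages per Superfamily
(or Fold) and then across groups, so small groups count as much as large
ones; *unweighted* averages over all queries.  Model agreement is Spearman's
rank correlation between two models' AUROC lists — per group or per query —
``rho = 1 - 6 * sum d_k^2 / (n (n^2 - 1))`` for tie-free ranks, computed in
general as the linear correlation of midrank vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError, SchemaError, UndefinedMetricError
from .retrieval import EvalLevel, RankedList

METRIC_COLUMNS = ("auroc", "auprc", "hit1", "hit10")


def auroc_from_scores(labels, scores) -> float:
    """Midrank AUROC from raw label/score arrays (any order)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC undefined with {n_pos} positives and {n_neg} negatives"
        )
    ranks = rankdata(scores)  # midranks for ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc(ranked: RankedList) -> float:
    """AUROC of a ranked list (>= 1 positive and >= 1 negative required)."""
    return auroc_from_scores(ranked.labels, ranked.scores)


def average_precision_from_order(labels_in_rank_order) -> float:
    """Average precision from labels already in (deterministic) rank order."""
    labels = np.asarray(labels_in_rank_order)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    precision_at = np.cumsum(labels) / np.arange(1, labels.size + 1)
    return float(precision_at[labels == 1].sum() / n_pos)


def auprc(ranked: RankedList) -> float:
    """Average-precision AUPRC of a ranked list."""
    return average_precision_from_order(ranked.labels)


def hit_at_k(ranked: RankedList, k: int) -> int:
    """1 iff any of the top ``min(k, len)`` candidates is a remote homolog."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return int(bool(ranked.labels[:k].any()))


@dataclass(frozen=True)
class QueryMetricRecord:
    """Per-query metrics plus the grouping keys used for aggregation."""

    query_id: str
    superfamily_id: str
    fold_id: str
    auroc: float
    auprc: float
    hit1: int
    hit10: int
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise SchemaError("metric records require n_pos >= 1")
        if self.hit10 < self.hit1:
            raise SchemaError("hit10 >= hit1 must hold")
        for name in ("auroc", "auprc"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SchemaError(f"{name}={value} outside [0, 1]")


def score_ranked_list(
    ranked: RankedList, superfamily_id: str, fold_id: str
) -> QueryMetricRecord:
    """Compute all per-query metrics for one ranked list."""
    return QueryMetricRecord(
        query_id=ranked.query_id,
        superfamily_id=superfamily_id,
        fold_id=fold_id,
        auroc=auroc(ranked),
        auprc=auprc(ranked),
        hit1=hit_at_k(ranked, 1),
        hit10=hit_at_k(ranked, 10),
        n_pos=ranked.n_pos,
        n_neg=ranked.n_neg,
    )


def records_frame(records) -> pd.DataFrame:
    """Materialise :class:`QueryMetricRecord` objects as a DataFrame."""
    return pd.DataFrame([vars(r) for r in records])


@dataclass(frozen=True)
class AggregateResult:
    """Per-group and overall mean metrics under one aggregation scheme."""

    scheme: str
    level: EvalLevel
    per_group: pd.DataFrame  # one row per group: means + n_queries
    overall: pd.Series  # mean of METRIC_COLUMNS
    n_queries: int


def aggregate(records, scheme: str, level: EvalLevel) -> AggregateResult:
    """Aggregate per-query metrics.

    ``weighted``: mean within each Superfamily (or Fold), then the plain mean
    of the group means.  ``unweighted``: the plain mean over all queries.
    """
    level = EvalLevel(level)
    if scheme not in ("weighted", "unweighted"):
        raise ParameterError(f"unknown aggregation scheme {scheme!r}")
    frame = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if frame.empty:
        raise SchemaError("cannot aggregate zero metric records")
    key = level.group_attr
    grouped = frame.groupby(key)[list(METRIC_COLUMNS)].mean()
    grouped["n_queries"] = frame.groupby(key).size()
    grouped = grouped.sort_index()
    if scheme == "weighted":
        overall = grouped[list(METRIC_COLUMNS)].mean()
    else:
        overall = frame[list(METRIC_COLUMNS)].mean()
    return AggregateResult(
        scheme=scheme,
        level=level,
        per_group=grouped.reset_index().rename(columns={key: "group_id"}),
        overall=overall,
        n_queries=len(frame),
    )


def spearman(x, y) -> float:
    """Spearman rank correlation with midranks for ties.

    Equals ``1 - 6 * sum d^2 / (n (n^2 - 1))`` on tie-free lists and the
    Pearson correlation of rank vectors in general.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("spearman requires two equal-length 1-D lists")
    if x.size < 2:
        raise UndefinedMetricError("spearman undefined for n < 2")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0.0 or ry.std() == 0.0:
        raise UndefinedMetricError("spearman undefined with zero rank variance")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass(frozen=True)
class AgreementMatrix:
    """Pairwise model agreement on AUROC.

    Lower triangle: Spearman rho between per-group mean AUROC lists; upper
    triangle: rho between per-query AUROC lists; diagonal 1 by convention.
    ``n`` holds the number of paired observations behind each cell.
    """

    model_names: tuple[str, ...]
    values: pd.DataFrame
    n: pd.DataFrame
    level: EvalLevel


def agreement_matrix(per_model_records, level: EvalLevel) -> AgreementMatrix:
    """Compute the pairwise Spearman agreement matrix across models.

    ``per_model_records`` maps model name to that model's per-query metric
    DataFrame.  Models are aligned on the intersection of their queries
    (upper triangle) or groups (lower triangle); an empty intersection is an
    error.
    """
    level = EvalLevel(level)
    if len(per_model_records) < 2:
        raise ParameterError("agreement requires at least two models")
    names = tuple(per_model_records)
    frames = {
        name: (rec if isinstance(rec, pd.DataFrame) else records_frame(rec))
        for name, rec in per_model_records.items()
    }
    key = level.group_attr
    per_query = {
        name: frame.set_index("query_id")["auroc"] for name, frame in frames.items()
    }
    per_group = {
        name: frame.groupby(key)["auroc"].mean() for name, frame in frames.items()
    }
    values = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        counts.loc[name, name] = len(per_query[name])
    for a, b in combinations(names, 2):
        qa, qb = per_query[a].align(per_query[b], join="inner")
        if qa.empty:
            raise SchemaError(f"models {a!r} and {b!r} share no queries")
        values.loc[a, b] = spearman(qa.to_numpy(), qb.to_numpy())
        counts.loc[a, b] = qa.size
        ga, gb = per_group[a].align(per_group[b], join="inner")
        if ga.empty:
            raise SchemaError(f"models {a!r} and {b!r} share no groups")
        values.loc[b, a] = spearman(ga.to_numpy(), gb.to_numpy())
        counts.loc[b, a] = ga.size
    return AgreementMatrix(model_names=names, values=values, n=counts, level=level)
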