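"""End-to-end evaluation runs: dataset -> tasks -> rankings -> metrics -> reports.

A run is described by a :class:`RunConfig` (YAML or JSON): one database per
identity threshold, one representation store and/or score matrix per model,
the evaluation levels and aggregation schemes, an output directory and a
seed.  Each (database, level, model) combination is evaluated independently;
a failure in one combination is recorded and the run continues.  All outputs
are plain TSV/JSON written deterministically, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import metrics as _metrics
from . import retrieval as _retrieval
from .errors import ParameterError, SchemaError
from .representations import load_representation_store
from .retrieval import EvalLevel
from .scop import (
    DomainDatabase,
    apply_preprocessing_filters,
    read_annotation_table,
    read_astral_fasta,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class DatabaseSpec:
    path: str
    format: str = "tsv"  # "tsv" or "fasta"
    threshold_label: float | None = None

    @property
    def label(self) -> str:
        if self.threshold_label is None:
            return "all"
        return f"th{int(round(self.threshold_label * 100)):02d}"


@dataclass(frozen=True)
class ModelSpec:
    name: str
    store: str | None = None
    score_matrix: str | None = None
    score_layout: str = "long"
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if (self.store is None) == (self.score_matrix is None):
            raise ParameterError(
                f"model {self.name!r}: provide exactly one of store / score_matrix"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one evaluation run."""

    databases: tuple[DatabaseSpec, ...]
    models: tuple[ModelSpec, ...]
    levels: tuple[EvalLevel, ...]
    output_dir: str
    schemes: tuple[str, ...] = ("weighted", "unweighted")
    seed: int = 0
    excluded_fold_ids: frozenset[str] = frozenset()
    require_single_span: bool = False

    def __post_init__(self) -> None:
        if not self.databases:
            raise ParameterError("config requires at least one database")
        if not self.models:
            raise ParameterError("config requires at least one model source")
        labels = [d.threshold_label for d in self.databases if d.threshold_label is not None]
        if labels != sorted(labels):
            raise ParameterError("database threshold labels must be sorted ascending")
        object.__setattr__(self, "levels", tuple(EvalLevel(l) for l in self.levels))
        for scheme in self.schemes:
            if scheme not in ("weighted", "unweighted"):
                raise ParameterError(f"unknown aggregation scheme {scheme!r}")
        missing = [
            p for p in (
                [d.path for d in self.databases]
                + [m.store or m.score_matrix for m in self.models]
            )
            if not Path(p).exists()
        ]
        if missing:
            raise ParameterError(f"configured paths do not exist: {missing}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        filters = data.get("filters", {})
        return cls(
            databases=tuple(DatabaseSpec(**d) for d in data["databases"]),
            models=tuple(ModelSpec(**m) for m in data["models"]),
            levels=tuple(data.get("levels", ["superfamily"])),
            schemes=tuple(data.get("schemes", ["weighted", "unweighted"])),
            output_dir=data["output_dir"],
            seed=int(data.get("seed", 0)),
            excluded_fold_ids=frozenset(filters.get("excluded_fold_ids", [])),
            require_single_span=bool(filters.get("require_single_span", False)),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_mapping(data)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded as provenance."""
        canon = json.dumps(
            {
                "databases": [vars(d) for d in self.databases],
                "models": [vars(m) for m in self.models],
                "levels": [l.value for l in self.levels],
                "schemes": list(self.schemes),
                "seed": self.seed,
                "excluded_fold_ids": sorted(self.excluded_fold_ids),
                "require_single_span": self.require_single_span,
            },
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Outcome of a run: one entry per (database, level, model) combination."""

    config_digest: str
    seed: int
    combinations: list[dict] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return sum(1 for c in self.combinations if c["status"] == "failed")

    @property
    def exit_code(self) -> int:
        """0 all ok, 1 partial failure, 2 total failure."""
        if not self.combinations or self.n_failed == len(self.combinations):
            return 2
        return 1 if self.n_failed else 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "seed": self.seed,
                "combinations": self.combinations,
            },
            indent=2,
            sort_keys=True,
        )


def _read_database(spec: DatabaseSpec) -> DomainDatabase:
    if spec.format == "tsv":
        db, _ = read_annotation_table(spec.path)
    elif spec.format == "fasta":
        db, _ = read_astral_fasta(spec.path)
    else:
        raise SchemaError(f"unknown database format {spec.format!r}")
    if spec.threshold_label is not None:
        db = DomainDatabase(db.records, identity_threshold_label=spec.threshold_label)
    return db


def evaluate_store(db: DomainDatabase, tasks, store) -> pd.DataFrame:
    """Per-query metrics for every task under one representation store."""
    return _evaluate(db, tasks, lambda task: _retrieval.rank_candidates(task, store))


def evaluate_score_matrix(
    db: DomainDatabase, tasks, scores: pd.DataFrame, higher_is_better: bool = True
) -> pd.DataFrame:
    """Per-query metrics using an external pairwise score matrix."""
    return _evaluate(
        db,
        tasks,
        lambda task: _retrieval.rank_candidates_from_matrix(task, scores, higher_is_better),
    )


def _evaluate(db: DomainDatabase, tasks, rank_fn) -> pd.DataFrame:
    lookup = {r.domain_id: r.classification for r in db}
    records = []
    n_zero_negative = 0
    for task in tasks:
        ranked = rank_fn(task)
        if ranked.n_neg == 0:
            n_zero_negative += 1
            continue
        cls = lookup[task.query_id]
        records.append(
            _metrics.score_ranked_list(ranked, cls.superfamily_id, cls.fold_id)
        )
    if n_zero_negative:
        logger.warning("dropped %d queries with zero negatives", n_zero_negative)
    if not records:
        raise SchemaError("no scorable queries (all dropped)")
    frame = _metrics.records_frame(records)
    frame.attrs["n_zero_negative"] = n_zero_negative
    return frame


def run_evaluation(config: RunConfig) -> RunReport:
    """Execute a full evaluation run and write its TSV/JSON outputs.

    Output files per combination, under ``output_dir``:
    ``perquery_<db>_<level>_<model>.tsv`` and, per aggregation scheme,
    ``aggregate_<db>_<level>_<model>_<scheme>.{tsv,json}``; plus a global
    ``run_report.json``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=config.digest(), seed=config.seed)
    for db_spec in config.databases:
        try:
            db = _read_database(db_spec)
            db, filter_report = apply_preprocessing_filters(
                db, config.excluded_fold_ids, config.require_single_span
            )
        except Exception as exc:  # noqa: BLE001 - per-combination error capture
            for level in config.levels:
                for model in config.models:
                    report.combinations.append(_failed(db_spec, level, model, exc))
            continue
        for level in config.levels:
            tasks, task_report = _retrieval.build_query_tasks(db, level)
            for model in config.models:
                entry = {
                    "database": db_spec.label,
                    "level": level.value,
                    "model": model.name,
                    "n_domains": len(db),
                    "n_removed_by_filters": sum(filter_report.removed_by_rule.values()),
                    "n_tasks": task_report.n_tasks,
                    "n_dropped_zero_positive": task_report.n_dropped,
                }
                try:
                    frame = _evaluate_model(db, tasks, model)
                    stem = f"{db_spec.label}_{level.value}_{model.name}"
                    frame.to_csv(
                        out_dir / f"perquery_{stem}.tsv",
                        sep="\t", index=False, float_format=FLOAT_FORMAT,
                    )
                    entry["outputs"] = [f"perquery_{stem}.tsv"]
                    for scheme in config.schemes:
                        agg = _metrics.aggregate(frame, scheme, level)
                        agg.per_group.to_csv(
                            out_dir / f"aggregate_{stem}_{scheme}.tsv",
                            sep="\t", index=False, float_format=FLOAT_FORMAT,
                        )
                        (out_dir / f"aggregate_{stem}_{scheme}.json").write_text(
                            json.dumps(
                                {
                                    "overall": {
                                        k: round(float(v), 10)
                                        for k, v in agg.overall.items()
                                    },
                                    "n_queries": agg.n_queries,
                                    "n_groups": len(agg.per_group),
                                    "scheme": scheme,
                                    "level": level.value,
                                },
                                indent=2, sort_keys=True,
                            )
                        )
                        entry["outputs"] += [
                            f"aggregate_{stem}_{scheme}.tsv",
                            f"aggregate_{stem}_{scheme}.json",
                        ]
                    entry["status"] = "ok"
                    entry["n_queries_scored"] = len(frame)
                    entry["n_dropped_zero_negative"] = frame.attrs["n_zero_negative"]
                except Exception as exc:  # noqa: BLE001
                    logger.error(
                        "combination %s/%s/%s failed: %s",
                        db_spec.label, level.value, model.name, exc,
                    )
                    entry["status"] = "failed"
                    entry["error"] = str(exc)
                report.combinations.append(entry)
    (out_dir / "run_report.json").write_text(report.to_json())
    return report


def _evaluate_model(db, tasks, model: ModelSpec) -> pd.DataFrame:
    if model.store is not None:
        store = load_representation_store(model.store, pool_if_needed=True)
        return evaluate_store(db, tasks, store)
    scores = _retrieval.read_score_matrix(model.score_matrix, model.score_layout)
    return evaluate_score_matrix(db, tasks, scores, model.higher_is_better)


def _failed(db_spec, level, model, exc) -> dict:
    return {
        "database": db_spec.label,
        "level": EvalLevel(level).value,
        "model": model.name,
        "status": "failed",
        "error": str(exc),
    }


def top_bottom_groups(
    records: pd.DataFrame,
    n: int = 5,
    min_queries: int = 5,
    level: EvalLevel = EvalLevel.SUPERFAMILY,
) -> pd.DataFrame:
    """Best and worst groups by mean AUROC, among groups with enough queries.

    Columns mirror the standard report: group id, mean AUROC, mean number of
    true (positive) labels per query, and the number of available queries.
    Only groups with strictly more than ``min_queries`` queries are shown;
    ties are broken by group id.
    """
    level = EvalLevel(level)
    key = level.group_attr
    grouped = records.groupby(key).agg(
        auroc=("auroc", "mean"),
        mean_true_per_query=("n_pos", "mean"),
        n_queries=("query_id", "size"),
    )
    eligible = grouped[grouped["n_queries"] > min_queries].reset_index()
    eligible = eligible.rename(columns={key: "group_id"})
    if eligible.empty:
        logger.warning("no groups with more than %d queries", min_queries)
        return pd.DataFrame(
            columns=["group_id", "auroc", "mean_true_per_query", "n_queries", "panel"]
        )
    top = eligible.sort_values(["auroc", "group_id"], ascending=[False, True]).head(n)
    bottom = eligible.sort_values(["auroc", "group_id"], ascending=[True, True]).head(n)
    top = top.assign(panel="top")
    bottom = bottom.assign(panel="bottom").sort_values(
        ["auroc", "group_id"], ascending=[True, True]
    )
    return pd.concat([top, bottom], ignore_index=True)


def model_delta_table(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    n: int = 10,
    level: EvalLevel = EvalLevel.SUPERFAMILY,
    names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Groups with the largest per-group AUROC differences between two models.

    Emits both directions (``a_minus_b`` and ``b_minus_a`` panels) over the
    intersection of groups; groups present in only one model are omitted and
    the count is logged.
    """
    level = EvalLevel(level)
    key = level.group_attr
    mean_a = records_a.groupby(key)["auroc"].mean()
    mean_b = records_b.groupby(key)["auroc"].mean()
    shared = mean_a.index.intersection(mean_b.index)
    if shared.empty:
        raise SchemaError("models share no groups")
    omitted = len(mean_a.index.union(mean_b.index)) - len(shared)
    if omitted:
        logger.info("omitting %d groups present in only one model", omitted)
    frame = pd.DataFrame(
        {
            "group_id": shared,
            f"auroc_{names[0]}": mean_a.loc[shared].to_numpy(),
            f"auroc_{names[1]}": mean_b.loc[shared].to_numpy(),
        }
    )
    frame["delta"] = frame[f"auroc_{names[0]}"] - frame[f"auroc_{names[1]}"]
    fwd = frame.sort_values(["delta", "group_id"], ascending=[False, True]).head(n)
    rev = frame.assign(delta=-frame["delta"]).sort_values(
        ["delta", "group_id"], ascending=[False, True]
    ).head(n)
    fwd = fwd.assign(panel=f"{names[0]}_minus_{names[1]}")
    rev = rev.assign(panel=f"{names[1]}_minus_{names[0]}")
    return pd.concat([fwd, rev], ignore_index=True)
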