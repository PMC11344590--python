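"""SCOP/SCOPe-style domain data: classification strings, readers, filters.

The SCOP hierarchy classifies protein domains as Class -> Fold -> Superfamily
-> Family, encoded in a concise classification string (sccs) such as
``a.38.1.2``: class ``a``, fold ``a.38``, superfamily ``a.38.1`` and family
``a.38.1.2``.  Domain-level records require the full depth-4 path; reporting
keys (e.g. table rows per superfamily) use the depth-3 prefix.

Two on-disk dialects are supported: Astral-style FASTA, where each header
carries the domain id, the sccs token and a parenthesised region descriptor,
and a plain TSV annotation table (``domain_id``, ``sccs``, ``sequence``).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import (
    DuplicateIdError,
    ParameterError,
    SccsParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: the 20 standard residues plus the ambiguity/rare codes seen in SCOP data
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")

_REGION_RE = re.compile(r"\(([^)]*)\)")


@dataclass(frozen=True)
class ClassificationPath:
    """A depth-2..4 prefix path through the SCOP hierarchy.

    Each deeper identifier extends its parent by one dot-separated integer
    component; ``superfamily_id`` must be present whenever ``family_id`` is.
    """

    class_id: str
    fold_id: str
    superfamily_id: str | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.class_id) != 1 or not self.class_id.isalpha():
            raise SccsParseError(
                f"class identifier must be a single letter, got {self.class_id!r}"
            )
        _check_extends(self.fold_id, self.class_id, "fold")
        if self.family_id is not None and self.superfamily_id is None:
            raise SccsParseError("family_id present without superfamily_id")
        if self.superfamily_id is not None:
            _check_extends(self.superfamily_id, self.fold_id, "superfamily")
        if self.family_id is not None:
            _check_extends(self.family_id, self.superfamily_id, "family")

    @property
    def depth(self) -> int:
        return 2 + (self.superfamily_id is not None) + (self.family_id is not None)

    @property
    def sccs(self) -> str:
        return self.family_id or self.superfamily_id or self.fold_id

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sccs


def _check_extends(child: str | None, parent: str | None, name: str) -> None:
    if child is None or parent is None:
        raise SccsParseError(f"{name} identifier missing")
    prefix, _, tail = child.rpartition(".")
    if prefix != parent or not tail.isdigit() or int(tail) <= 0:
        raise SccsParseError(
            f"{name} id {child!r} does not extend {parent!r} by one integer component"
        )


def parse_sccs(text: str) -> ClassificationPath:
    """Parse a concise classification string into a :class:`ClassificationPath`.

    Accepts 2-4 dot-separated components: a single-letter class followed by
    positive-integer fold / superfamily / family numbers.

    >>> parse_sccs("a.38.1").superfamily_id
    'a.38.1'
    """
    parts = text.strip().split(".")
    if not 2 <= len(parts) <= 4:
        raise SccsParseError(
            f"sccs {text!r} has {len(parts)} components; expected 2-4"
        )
    cls = parts[0]
    if len(cls) != 1 or not cls.isalpha():
        raise SccsParseError(f"sccs {text!r}: class component {cls!r} is not a single letter")
    for comp in parts[1:]:
        if not comp.isdigit() or int(comp) <= 0:
            raise SccsParseError(
                f"sccs {text!r}: component {comp!r} is not a positive integer"
            )
    ids = [".".join(parts[: i + 1]) for i in range(len(parts))]
    return ClassificationPath(
        class_id=cls,
        fold_id=ids[1],
        superfamily_id=ids[2] if len(ids) > 2 else None,
        family_id=ids[3] if len(ids) > 3 else None,
    )


def format_sccs(path: ClassificationPath) -> str:
    """Inverse of :func:`parse_sccs` on valid paths."""
    return path.sccs


@dataclass(frozen=True)
class DomainRecord:
    """One classified protein domain.

    ``span_count`` is the number of discontinuous structural spans the
    sequence represents (Astral region descriptors with commas denote more
    than one span).
    """

    domain_id: str
    classification: ClassificationPath
    sequence: str
    description: str = ""
    span_count: int = 1

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise SchemaError("domain_id must be non-empty")
        if self.classification.depth != 4:
            raise SchemaError(
                f"domain {self.domain_id!r}: classification must be depth 4, "
                f"got depth {self.classification.depth} ({self.classification.sccs})"
            )
        if not self.sequence:
            raise SchemaError(f"domain {self.domain_id!r}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise SchemaError(
                f"domain {self.domain_id!r}: invalid residue codes {sorted(bad)}"
            )
        if self.span_count < 1:
            raise SchemaError(f"domain {self.domain_id!r}: span_count must be >= 1")


@dataclass(frozen=True)
class DomainDatabase:
    """An ordered collection of depth-4 classified domains with unique ids.

    ``identity_threshold_label`` records, as provenance metadata, the maximum
    pairwise sequence identity of a pre-filtered subset (e.g. 0.30 for an
    Astral 30% subset); it is a label, not a runtime filter.
    """

    records: tuple[DomainRecord, ...]
    identity_threshold_label: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.domain_id in seen:
                raise DuplicateIdError(f"duplicate domain_id {rec.domain_id!r}")
            seen.add(rec.domain_id)
        th = self.identity_threshold_label
        if th is not None and not 0.0 < th <= 1.0:
            raise ParameterError(f"identity_threshold_label {th} outside (0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.domain_id for r in self.records)

    def get(self, domain_id: str) -> DomainRecord:
        for rec in self.records:
            if rec.domain_id == domain_id:
                return rec
        raise KeyError(domain_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "domain_id": [r.domain_id for r in self.records],
                "sccs": [r.classification.sccs for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "description": [r.description for r in self.records],
                "span_count": [r.span_count for r in self.records],
            }
        )


@dataclass
class ReadReport:
    """Per-record problems encountered while reading a database file."""

    n_parsed: int = 0
    n_kept: int = 0
    errors: list[tuple[str, str]] = field(default_factory=list)

    def add_error(self, entry: str, message: str) -> None:
        self.errors.append((entry, message))
        logger.warning("skipping %s: %s", entry, message)


def read_astral_fasta(path) -> tuple[DomainDatabase, ReadReport]:
    """Read an Astral-dialect FASTA file into a :class:`DomainDatabase`.

    Header layout: ``<domain_id> <sccs> (<region>) <description>``.  The
    span count is the number of comma-separated pieces in the first
    parenthesised region field.  Entries whose header lacks a parseable
    depth-4 sccs token are skipped and reported, not fatal; duplicate domain
    ids and an empty file are fatal.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise SchemaError(f"{path}: empty FASTA file")
    report = ReadReport(n_parsed=len(entries))
    records: list[DomainRecord] = []
    for entry in entries:
        header = entry.description
        tokens = header.split()
        if len(tokens) < 2:
            report.add_error(tokens[0] if tokens else "<blank>", "header lacks an sccs token")
            continue
        domain_id, sccs_token = tokens[0], tokens[1]
        try:
            classification = parse_sccs(sccs_token)
        except SccsParseError as exc:
            report.add_error(domain_id, f"bad sccs token {sccs_token!r}: {exc}")
            continue
        region_match = _REGION_RE.search(header)
        span_count = region_match.group(1).count(",") + 1 if region_match else 1
        description = header[region_match.end():].strip() if region_match else " ".join(tokens[2:])
        try:
            records.append(
                DomainRecord(
                    domain_id=domain_id,
                    classification=classification,
                    sequence=str(entry.seq).upper(),
                    description=description,
                    span_count=span_count,
                )
            )
        except SchemaError as exc:
            report.add_error(domain_id, str(exc))
    db = DomainDatabase(tuple(records))
    report.n_kept = len(db)
    return db, report


REQUIRED_TABLE_COLUMNS = ("domain_id", "sccs", "sequence")


def read_annotation_table(path) -> tuple[DomainDatabase, ReadReport]:
    """Read a TSV annotation table (``domain_id``, ``sccs``, ``sequence``).

    Optional columns ``description`` and ``span_count`` are honoured so that
    :func:`write_annotation_table` round-trips.  Rows with malformed or
    shallow sccs are skipped and reported.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    report = ReadReport(n_parsed=len(frame))
    records: list[DomainRecord] = []
    for row in frame.itertuples(index=False):
        try:
            classification = parse_sccs(row.sccs)
            if classification.depth != 4:
                raise SchemaError(
                    f"sccs {row.sccs!r} has depth {classification.depth}; domains require depth 4"
                )
            records.append(
                DomainRecord(
                    domain_id=row.domain_id,
                    classification=classification,
                    sequence=str(row.sequence).upper(),
                    description=getattr(row, "description", ""),
                    span_count=int(getattr(row, "span_count", 1) or 1),
                )
            )
        except (SccsParseError, SchemaError, ValueError) as exc:
            report.add_error(str(row.domain_id), str(exc))
    if not records:
        warnings.warn(f"{path}: no valid domain records", stacklevel=2)
    db = DomainDatabase(tuple(records))
    report.n_kept = len(db)
    return db, report


def write_annotation_table(db: DomainDatabase, path) -> None:
    """Write a database as a TSV annotation table (round-trips with the reader)."""
    db.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    """Counts of records removed by each preprocessing rule."""

    n_input: int
    removed_by_rule: dict[str, int]
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "count": v} for k, v in self.removed_by_rule.items()]
        rows.append({"rule": "retained", "count": self.n_retained})
        return pd.DataFrame(rows)


def apply_preprocessing_filters(
    db: DomainDatabase,
    excluded_fold_ids: frozenset[str] | set[str] = frozenset(),
    require_single_span: bool = False,
) -> tuple[DomainDatabase, FilterReport]:
    """Drop domains in excluded folds and, optionally, multi-span domains.

    The excluded-fold list is configuration (e.g. Rossmann-like folds and
    four- to eight-bladed beta-propellers in curated benchmark setups); the
    single-span rule keeps only sequences representing one continuous
    structural span.  A record is attributed to the first rule it matches.
    """
    excluded_fold_ids = frozenset(excluded_fold_ids)
    removed = {"excluded_fold": 0, "multi_span": 0}
    kept: list[DomainRecord] = []
    for rec in db:
        if rec.classification.fold_id in excluded_fold_ids:
            removed["excluded_fold"] += 1
        elif require_single_span and rec.span_count > 1:
            removed["multi_span"] += 1
        else:
            kept.append(rec)
    if not kept:
        warnings.warn("preprocessing filters removed every record", stacklevel=2)
    filtered = DomainDatabase(tuple(kept), db.identity_threshold_label)
    return filtered, FilterReport(len(db), removed, len(filtered))


def _make_aligner() -> PairwiseAligner:
    # simple stated scheme: match 1, mismatch 0, linear gap -1, global ends
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global percent identity: identical positions / alignment length.

    The alignment maximises score under match 1 / mismatch 0 / linear gap -1;
    the alignment length counts gap columns.  Non-standard residue codes
    count as mismatches unless literally equal.
    """
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def greedy_identity_filter(
    db: DomainDatabase, th: float, max_length: int = 2000
) -> DomainDatabase:
    """Toy-scale identity filtering: greedily retain longest-first domains.

    Returns a subset in which no retained pair has global percent identity
    strictly greater than ``th``.  Ordering is deterministic: candidates are
    considered longest sequence first, ties broken by ascending domain id;
    retained records keep the original database order.  This is a desk-scale
    stand-in for dedicated clustering tools and guards against quadratic
    blow-up by rejecting sequences longer than ``max_length``.
    """
    if not 0.0 < th <= 1.0:
        raise ParameterError(f"identity threshold {th} outside (0, 1]")
    too_long = [r.domain_id for r in db if len(r.sequence) > max_length]
    if too_long:
        raise ParameterError(
            f"sequences longer than {max_length} residues unsuitable for the toy "
            f"identity filter: {too_long}"
        )
    aligner = _make_aligner()
    order = sorted(db, key=lambda r: (-len(r.sequence), r.domain_id))
    retained: list[DomainRecord] = []
    for rec in order:
        if all(
            pairwise_identity(rec.sequence, kept.sequence, aligner) <= th
            for kept in retained
        ):
            retained.append(rec)
    retained_ids = {r.domain_id for r in retained}
    kept_in_order = tuple(r for r in db if r.domain_id in retained_ids)
    return DomainDatabase(kept_in_order, identity_threshold_label=th)
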