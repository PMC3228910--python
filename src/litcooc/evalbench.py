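"""Instance-level evaluation against a gold-standard pair set, with the
pooled-truth protocol, recall stratification, and persistence of user
validation tables.

The evaluation unit is the (PMID, unordered pair) instance. Predicted
pairs match gold pairs on normalized term keys within the same abstract
— no fuzzy name matching; synonym mismatches remain visible as a
stratification category rather than being silently repaired.

The pooled-truth protocol: the curated gold set is first filtered to
interactions the method can detect by definition (no self-interactions,
no partners that are not gene/protein symbols), then unioned with
manually confirmed novel predictions. Recall and precision of any
prediction set are computed against this pooled set, cumulatively per
confidence type threshold (type 1; types 1-2; types 1-3).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

from .cooccur import CoOccurrence, Pair, make_pair
from .lexicon import normalize_term

PathLike = Union[str, Path]

Key = tuple[str, Pair]  # (pmid, pair)

STRATA = ("all", "both_in_dictionary", "both_detected", "not_complex")


class GoldFormatError(ValueError):
    pass


class ValidationConflictError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gold standard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldInteraction:
    """One curated (PMID, pair) interaction with three-state flags
    (True/False/None=unknown) describing detectability."""

    pmid: str
    pair: Pair
    is_self: Optional[bool] = None
    non_gene_symbol: Optional[bool] = None
    both_in_dictionary: Optional[bool] = None
    both_detected: Optional[bool] = None
    complex_sentence: Optional[bool] = None

    @property
    def key(self) -> Key:
        return (self.pmid, self.pair)


@dataclass
class GoldLoad:
    records: list[GoldInteraction]
    duplicates: int = 0

    def __iter__(self) -> Iterator[GoldInteraction]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_FLAG_COLUMNS = (
    "is_self", "non_gene_symbol", "both_in_dictionary",
    "both_detected", "complex_sentence",
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_flag(value: str | None, lineno: int, column: str) -> Optional[bool]:
    if value is None or value.strip() == "" or value.strip().lower() in {"na", "nan", "?"}:
        return None
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise GoldFormatError(f"line {lineno}: bad flag value {value!r} in column {column}")


def load_gold(path: PathLike) -> GoldLoad:
    """Load a gold-standard TSV with columns pmid, term1, term2 and
    optional flag columns. Terms are normalized exactly as the tagger
    normalizes surface keys. Duplicated (pmid, pair) rows collapse to
    the first occurrence and are counted."""
    records: dict[Key, GoldInteraction] = {}
    duplicates = 0
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"pmid", "term1", "term2"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise GoldFormatError(f"gold file missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            pmid = (row.get("pmid") or "").strip()
            t1 = normalize_term(row.get("term1") or "")
            t2 = normalize_term(row.get("term2") or "")
            if not pmid or not t1 or not t2:
                raise GoldFormatError(
                    f"line {lineno}: pmid, term1 and term2 are required"
                )
            flags = {
                col: _parse_flag(row.get(col), lineno, col) for col in _FLAG_COLUMNS
            }
            if t1 == t2:
                flags["is_self"] = True
            rec = GoldInteraction(pmid=pmid, pair=make_pair(t1, t2), **flags)
            if rec.key in records:
                duplicates += 1
                continue
            records[rec.key] = rec
    return GoldLoad(records=list(records.values()), duplicates=duplicates)


def filter_gold(
    gold: Iterable[GoldInteraction],
) -> tuple[list[GoldInteraction], dict[str, int]]:
    """Drop interactions the method cannot detect by definition:
    self-interactions (homo-dimers) and pairs where a partner is not a
    gene/protein symbol. Returns the retained records and a per-reason
    exclusion report."""
    retained: list[GoldInteraction] = []
    report = {"total": 0, "self": 0, "non_gene_symbol": 0, "retained": 0}
    for rec in gold:
        report["total"] += 1
        if rec.is_self:
            report["self"] += 1
            continue
        if rec.non_gene_symbol:
            report["non_gene_symbol"] += 1
            continue
        retained.append(rec)
    report["retained"] = len(retained)
    return retained, report


def pool_truth(
    filtered_gold: Iterable[GoldInteraction],
    confirmed_predictions: Iterable[Union[Key, GoldInteraction]] = (),
) -> list[GoldInteraction]:
    """Union the filtered gold set with manually confirmed novel
    predictions on (pmid, pair) keys. Confirmed instances already in
    gold count once; new ones enter with unknown flags. The curation
    itself is an input here — it is never automated."""
    pooled: dict[Key, GoldInteraction] = {g.key: g for g in filtered_gold}
    for item in confirmed_predictions:
        if isinstance(item, GoldInteraction):
            rec = item
        else:
            pmid, pair = item
            rec = GoldInteraction(pmid=pmid, pair=make_pair(*pair))
        pooled.setdefault(rec.key, rec)
    return list(pooled.values())


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalResult:
    """Precision/recall at one cumulative type threshold.

    ``recall``/``precision`` are unrounded percentages; ``recall_pct``/
    ``precision_pct`` are rounded to the nearest integer for report
    display. Precision is None (missing, not zero) when there are no
    predictions.
    """

    threshold: int
    tp: int
    fp: int
    truth_size: int
    n_predictions: int
    recall: float
    precision: Optional[float]

    @property
    def recall_pct(self) -> int:
        return round(self.recall)

    @property
    def precision_pct(self) -> Optional[int]:
        return None if self.precision is None else round(self.precision)


@dataclass(frozen=True)
class StratumRecall:
    """Recall with the truth denominator restricted to one stratum.
    Truth records whose stratum flag is unknown are excluded from
    restricted strata and counted in ``unknown_excluded``."""

    stratum: str
    threshold: int
    tp: int
    truth_size: int
    recall: float
    unknown_excluded: int = 0

    @property
    def recall_pct(self) -> int:
        return round(self.recall)


def predictions_from_cooccurrences(
    cooccurrences: Iterable[CoOccurrence],
) -> dict[Key, int]:
    """Collapse instances to the best (minimum) type per (pmid, pair)."""
    best: dict[Key, int] = {}
    for c in cooccurrences:
        key = (c.pmid, c.pair)
        if c.cooc_type < best.get(key, 5):
            best[key] = c.cooc_type
    return best


def _predicted_keys(predictions: Mapping[Key, int], threshold: int) -> set[Key]:
    return {k for k, t in predictions.items() if t <= threshold}


def score(
    pooled_truth: Iterable[GoldInteraction],
    predictions: Mapping[Key, int],
    threshold: int,
) -> EvalResult:
    """Score a prediction set at a cumulative type threshold.

    The prediction set is every (pmid, pair) whose best type is <=
    threshold, so counts nest across thresholds. tp is the intersection
    with the pooled truth on (pmid, pair) keys.
    """
    if threshold not in (1, 2, 3):
        raise ValueError(f"threshold must be 1, 2 or 3, got {threshold}")
    truth_keys = {g.key for g in pooled_truth}
    if not truth_keys:
        raise ValueError("pooled truth is empty: recall undefined")
    pred = _predicted_keys(predictions, threshold)
    tp = len(pred & truth_keys)
    fp = len(pred - truth_keys)
    return EvalResult(
        threshold=threshold,
        tp=tp,
        fp=fp,
        truth_size=len(truth_keys),
        n_predictions=len(pred),
        recall=100.0 * tp / len(truth_keys),
        precision=(100.0 * tp / (tp + fp)) if (tp + fp) else None,
    )


def _in_stratum(rec: GoldInteraction, stratum: str) -> Optional[bool]:
    if stratum == "all":
        return True
    if stratum == "both_in_dictionary":
        return rec.both_in_dictionary
    if stratum == "both_detected":
        return rec.both_detected
    if stratum == "not_complex":
        return None if rec.complex_sentence is None else not rec.complex_sentence
    raise ValueError(f"unknown stratum {stratum!r} (choose from {STRATA})")


def stratify_recall(
    pooled_truth: Iterable[GoldInteraction],
    predictions: Mapping[Key, int],
    threshold: int,
    stratum: str = "all",
) -> StratumRecall:
    """Recall with the denominator restricted to truths satisfying the
    stratum (strata nest: all ⊇ in-dictionary ⊇ detected ⊇ not-complex)."""
    if threshold not in (1, 2, 3):
        raise ValueError(f"threshold must be 1, 2 or 3, got {threshold}")
    in_keys: set[Key] = set()
    unknown = 0
    total = 0
    for rec in pooled_truth:
        total += 1
        member = _in_stratum(rec, stratum)
        if member is None:
            unknown += 1
        elif member:
            in_keys.add(rec.key)
    if not in_keys:
        raise ValueError(
            "pooled truth is empty: recall undefined" if total == 0
            else f"stratum {stratum!r} is empty: recall undefined"
        )
    pred = _predicted_keys(predictions, threshold)
    tp = len(pred & in_keys)
    return StratumRecall(
        stratum=stratum,
        threshold=threshold,
        tp=tp,
        truth_size=len(in_keys),
        recall=100.0 * tp / len(in_keys),
        unknown_excluded=unknown,
    )


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def format_score_report(results: Iterable[EvalResult], label: str = "predictions") -> str:
    """Human-readable recall/precision table, one row per threshold."""
    lines = [f"{'':24s}\tRecall\tPrecision"]
    for r in results:
        prec = (
            f"{r.tp}/{r.tp + r.fp} ({r.precision_pct}%)"
            if r.precision is not None
            else "missing (no predictions)"
        )
        lines.append(
            f"{label} (type {r.threshold})\t"
            f"{r.tp}/{r.truth_size} ({r.recall_pct}%)\t{prec}"
        )
    return "\n".join(lines) + "\n"


def format_strata_report(rows: Iterable[StratumRecall]) -> str:
    """Recall-by-stratum table, one row per threshold, one column per
    stratum."""
    by_threshold: dict[int, dict[str, StratumRecall]] = {}
    for row in rows:
        by_threshold.setdefault(row.threshold, {})[row.stratum] = row
    header = "\t".join(["", *STRATA])
    lines = [header]
    for t in sorted(by_threshold):
        cells = [f"Type {t}"]
        for stratum in STRATA:
            r = by_threshold[t].get(stratum)
            cells.append(
                f"{r.tp}/{r.truth_size} ({r.recall_pct}%)" if r is not None else ""
            )
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Validation tables
# ---------------------------------------------------------------------------

VALID_STATUSES = ("validated", "rejected")


@dataclass(frozen=True)
class ValidationRecord:
    """A user's confirm/reject annotation of one extracted pair in one
    abstract. Later timestamps supersede earlier ones."""

    pmid: str
    pair: Pair
    status: str
    timestamp: str  # ISO-8601; compared lexicographically

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"status must be one of {VALID_STATUSES}")

    @property
    def key(self) -> Key:
        return (self.pmid, self.pair)


def save_validations(records: Iterable[ValidationRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pmid", "term1", "term2", "status", "timestamp"])
        for r in sorted(records, key=lambda r: (r.pmid, r.pair, r.timestamp)):
            writer.writerow([r.pmid, r.pair[0], r.pair[1], r.status, r.timestamp])


def load_validations(path: PathLike) -> list[ValidationRecord]:
    """Load a validation table; for each (pmid, pair) the record with
    the latest timestamp wins. Two records for one key with the same
    timestamp but different statuses are a conflict and raise."""
    effective: dict[Key, ValidationRecord] = {}
    conflicts: list[Key] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            rec = ValidationRecord(
                pmid=row["pmid"].strip(),
                pair=make_pair(normalize_term(row["term1"]), normalize_term(row["term2"])),
                status=row["status"].strip(),
                timestamp=row["timestamp"].strip(),
            )
            cur = effective.get(rec.key)
            if cur is None or rec.timestamp > cur.timestamp:
                effective[rec.key] = rec
            elif rec.timestamp == cur.timestamp and rec.status != cur.status:
                conflicts.append(rec.key)
    if conflicts:
        raise ValidationConflictError(
            f"conflicting same-timestamp validations for: {sorted(set(conflicts))}"
        )
    return list(effective.values())


def confirmed_keys(records: Iterable[ValidationRecord]) -> set[Key]:
    """The (pmid, pair) keys the user marked as validated."""
    return {r.key for r in records if r.status == "validated"}
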