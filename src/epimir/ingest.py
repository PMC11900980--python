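"""Reading and validating the three tabular inputs.

The pipeline consumes exported tables, never live web services:

* a differential-expression (DE) miRNA table: miRNA id, fold change,
  direction (or a signed fold change) and p-value;
* two miRNA->gene prediction exports: source ``A`` carries an integer-like
  *target score* in [50, 100] (miRDB style), source ``B`` a *binding
  probability* in [0, 1] (miRWalk style).

Identifiers are normalized on ingest so that downstream joins are exact:
miRNA names are lowercased with any species prefix ("rno-", "hsa-", ...)
stripped, gene symbols are folded to the rodent Title-case convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ParameterError, TableError, ValidationError

log = logging.getLogger(__name__)

Source = Literal["A", "B"]

SCORE_RANGES: dict[str, tuple[float, float]] = {"A": (50.0, 100.0), "B": (0.0, 1.0)}

_SPECIES_PREFIX = re.compile(r"^[a-z]{2,4}-(?=(?:mir|let)-)")


def normalize_mirna_id(raw: str) -> str:
    """Canonical miRNA name: lowercase, species prefix stripped, no whitespace.

    ``"rno-miR-92b-3p" -> "mir-92b-3p"``; ``"let-7d-5p"`` is already
    canonical. Idempotent: the prefix is only stripped when it precedes a
    ``mir-``/``let-`` stem, so a second pass is a no-op.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("empty miRNA identifier")
    name = re.sub(r"\s+", "", str(raw)).lower()
    return _SPECIES_PREFIX.sub("", name)


def normalize_gene_symbol(raw: str) -> str:
    """Gene symbol in rodent convention: first letter upper, rest lower."""
    if raw is None or not str(raw).strip():
        raise ValidationError("empty gene symbol")
    sym = re.sub(r"\s+", "", str(raw))
    return sym[:1].upper() + sym[1:].lower()


@dataclass(frozen=True)
class DEMiRNA:
    """One differentially expressed miRNA.

    ``fold_change`` is the expression-ratio magnitude (>= 1 by convention);
    the sign of the change is carried separately in ``direction``
    (+1 up, -1 down), matching how the source dataset publishes it.
    """

    mirna_id: str
    fold_change: float
    direction: int
    p_value: float

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValidationError(f"{self.mirna_id}: fold_change must be > 0")
        if self.direction not in (1, -1):
            raise ValidationError(f"{self.mirna_id}: direction must be +1 or -1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"{self.mirna_id}: p_value outside [0, 1]")


@dataclass(frozen=True)
class PredictionRecord:
    """One predictor's miRNA -> gene call with its raw score."""

    mirna_id: str
    gene_symbol: str
    source: Source
    raw_score: float

    def __post_init__(self):
        if self.source not in SCORE_RANGES:
            raise ValidationError(f"unknown predictor source {self.source!r}")
        lo, hi = SCORE_RANGES[self.source]
        if not lo <= self.raw_score <= hi:
            raise ValidationError(
                f"source {self.source} score {self.raw_score} outside [{lo}, {hi}]"
                f" for ({self.mirna_id}, {self.gene_symbol})"
            )


_DE_COLUMNS = {
    "mirna_id": ("mirna_id", "mirna", "mir", "mirna name", "name", "id"),
    "fold_change": ("fold_change", "fc", "foldchange", "fold change", "ratio"),
    "direction": ("direction", "dir", "regulation", "updown"),
    "p_value": ("p_value", "pvalue", "p", "pval", "p.value", "p-value"),
}

_PRED_COLUMNS = {
    "mirna_id": _DE_COLUMNS["mirna_id"],
    "gene_symbol": ("gene_symbol", "gene", "symbol", "target", "target_symbol"),
    "raw_score": ("raw_score", "score", "target_score", "binding_probability", "probability"),
}


def _read_table(path, dialect):
    sep = {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    try:
        if sep is None:
            return pd.read_csv(path, sep=None, engine="python")
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise TableError("file has no header row", path=path)


def _map_columns(frame: pd.DataFrame, wanted: dict, path, required: Iterable[str]):
    lookup = {str(c).strip().lower(): c for c in frame.columns}
    mapping = {}
    for canonical, synonyms in wanted.items():
        for syn in synonyms:
            if syn in lookup:
                mapping[canonical] = lookup[syn]
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise TableError(f"missing column(s): {', '.join(missing)}", path=path)
    return mapping


def _parse_float(value, what: str, path, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise TableError(f"unparseable {what}: {value!r}", path=path, row=row)
    if pd.isna(out):
        raise TableError(f"unparseable {what}: {value!r}", path=path, row=row)
    return out


def _parse_direction(value, path, row: int) -> int:
    text = str(value).strip().lower()
    if text in {"1", "+1", "up", "upregulated", "increased"}:
        return 1
    if text in {"-1", "down", "downregulated", "decreased"}:
        return -1
    raise TableError(f"unparseable direction: {value!r}", path=path, row=row)


def read_de_table(path, dialect: str | None = None) -> list[DEMiRNA]:
    """Parse a DE-miRNA table into validated records.

    Accepts either an explicit ``direction`` column or a signed fold-change
    column (the sign then carries the direction and the magnitude is kept).
    Duplicate miRNA ids (after normalization) are an error.
    """
    frame = _read_table(path, dialect)
    cols = _map_columns(frame, _DE_COLUMNS, path, required=("mirna_id", "fold_change", "p_value"))
    records: list[DEMiRNA] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        try:
            mirna = normalize_mirna_id(row[cols["mirna_id"]])
        except ValidationError as exc:
            raise TableError(str(exc), path=path, row=i)
        fc = _parse_float(row[cols["fold_change"]], "fold change", path, i)
        if "direction" in cols:
            direction = _parse_direction(row[cols["direction"]], path, i)
            fc = abs(fc)
        else:
            direction = 1 if fc >= 0 else -1
            fc = abs(fc)
        p = _parse_float(row[cols["p_value"]], "p-value", path, i)
        if mirna in seen:
            raise TableError(f"duplicate miRNA id {mirna!r}", path=path, row=i)
        seen.add(mirna)
        try:
            records.append(DEMiRNA(mirna, fc, direction, p))
        except ValidationError as exc:
            raise TableError(str(exc), path=path, row=i)
    log.info("read %d DE records from %s", len(records), path)
    return records


def filter_de(
    records: Sequence[DEMiRNA], fc_min: float = 2.0, p_max: float = 0.05
) -> list[DEMiRNA]:
    """Keep records with fold_change >= ``fc_min`` and p < ``p_max``.

    The fold-change cut is inclusive ("2-fold or greater"); the p cut is
    strict. Order is preserved and the result is a subset of the input, so
    the operation is idempotent.
    """
    if fc_min <= 0:
        raise ParameterError("fc_min must be positive")
    if not 0 < p_max <= 1:
        raise ParameterError("p_max must be in (0, 1]")
    kept = [r for r in records if r.fold_change >= fc_min and r.p_value < p_max]
    log.info("DE filter (fc>=%g, p<%g): %d of %d kept", fc_min, p_max, len(kept), len(records))
    return kept


def read_prediction_table(
    path,
    source: Source,
    dedupe: Literal["max", "error"] = "max",
    dialect: str | None = None,
) -> list[PredictionRecord]:
    """Parse one predictor export into range-checked records.

    Predictor B reports one row per putative binding site, so the same
    (miRNA, gene) pair can recur; ``dedupe="max"`` (default) collapses such
    rows to the best-evidence score, ``dedupe="error"`` refuses them.
    """
    if source not in SCORE_RANGES:
        raise ValidationError(f"unknown predictor source {source!r}")
    if dedupe not in ("max", "error"):
        raise ParameterError(f"unknown dedupe policy {dedupe!r}")
    frame = _read_table(path, dialect)
    cols = _map_columns(frame, _PRED_COLUMNS, path, required=tuple(_PRED_COLUMNS))
    best: dict[tuple[str, str], PredictionRecord] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        try:
            mirna = normalize_mirna_id(row[cols["mirna_id"]])
            gene = normalize_gene_symbol(row[cols["gene_symbol"]])
            rec = PredictionRecord(
                mirna, gene, source, _parse_float(row[cols["raw_score"]], "score", path, i)
            )
        except ValidationError as exc:
            raise TableError(str(exc), path=path, row=i)
        key = (mirna, gene)
        if key in best:
            if dedupe == "error":
                raise TableError(f"duplicate pair {key}", path=path, row=i)
            if rec.raw_score > best[key].raw_score:
                best[key] = rec
        else:
            best[key] = rec
    records = list(best.values())
    log.info("read %d source-%s predictions from %s", len(records), source, path)
    return records


def write_de_table(records: Sequence[DEMiRNA], path) -> None:
    """Write DE records so that :func:`read_de_table` round-trips them."""
    pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "fold_change": [r.fold_change for r in records],
            "direction": [r.direction for r in records],
            "p_value": [r.p_value for r in records],
        }
    ).to_csv(path, index=False)


def write_prediction_table(records: Sequence[PredictionRecord], path) -> None:
    """Write predictions so that :func:`read_prediction_table` round-trips them."""
    pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "raw_score": [r.raw_score for r in records],
        }
    ).to_csv(path, index=False)
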