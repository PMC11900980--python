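"""Consensus identification of epi-miRNAs.

The core procedure: a miRNA–regulator interaction is accepted only when
*both* independent predictors call it — source A (target score) at >= 60
and source B (binding probability) at >= 0.8. Accepted interactions get a
cumulative prediction score

    cumulative = target_score / 100 + binding_probability        in [1.4, 2.0]

and a high-confidence flag when both predictors clear the stricter tier
(target score >= 80 and binding probability >= 0.92, hence cumulative
>= 1.72). A miRNA with at least one accepted interaction on an epigenetic
regulator is an epi-miRNA.

All threshold comparisons are inclusive. Gene symbols are resolved through
catalog aliases before the intersection, so predictor exports using a
synonym (Clock vs Kat13d) still match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .catalog import Catalog
from .errors import ParameterError, ValidationError
from .ingest import DEMiRNA, PredictionRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Predictor acceptance thresholds (all inclusive)."""

    min_target_score: float = 60.0
    min_binding_prob: float = 0.8
    high_target_score: float = 80.0
    high_binding_prob: float = 0.92

    def __post_init__(self):
        if not 50 <= self.min_target_score <= 100 or not 50 <= self.high_target_score <= 100:
            raise ParameterError("target-score thresholds must lie in [50, 100]")
        if not 0 <= self.min_binding_prob <= 1 or not 0 <= self.high_binding_prob <= 1:
            raise ParameterError("binding-probability thresholds must lie in [0, 1]")


DEFAULT_THRESHOLDS = Thresholds()


def cumulative_score(target_score: float, binding_prob: float) -> float:
    """Combined confidence: target_score/100 + binding probability.

    Exact formula, no internal rounding; reports round to two decimals
    (half-up) only at presentation time.
    """
    if not 50 <= target_score <= 100:
        raise ValidationError(f"target score {target_score} outside [50, 100]")
    if not 0 <= binding_prob <= 1:
        raise ValidationError(f"binding probability {binding_prob} outside [0, 1]")
    return target_score / 100.0 + binding_prob


@dataclass(frozen=True)
class ConsensusInteraction:
    """A miRNA–regulator pair accepted by both predictors."""

    mirna_id: str
    direction: int
    gene_symbol: str
    target_score: float
    binding_prob: float
    cumulative_score: float
    high_confidence: bool
    previously_reported: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_symbol)


@dataclass(frozen=True)
class EpiMiRNASummary:
    """Per-miRNA roll-up of its accepted regulator targets."""

    mirna_id: str
    direction: int
    targets: tuple[tuple[str, float], ...]
    has_high_confidence: bool
    previously_reported: bool = False

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def consensus_interactions(
    de: Sequence[DEMiRNA],
    preds_a: Iterable[PredictionRecord],
    preds_b: Iterable[PredictionRecord],
    catalog: Catalog,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    previously_reported: Mapping[tuple[str, str], bool] | None = None,
) -> list[ConsensusInteraction]:
    """Intersect the two predictors over the DE miRNAs and the catalog.

    A pair (m, g) is emitted iff m is in the DE list, g resolves (directly
    or via an alias) to a catalog regulator, and both predictors call it at
    or above their thresholds. Output order is deterministic: miRNA name,
    then cumulative score descending, then gene symbol.
    """
    previously_reported = previously_reported or {}
    directions = {r.mirna_id: r.direction for r in de}

    def resolved(records: Iterable[PredictionRecord], source: str):
        scores: dict[tuple[str, str], float] = {}
        for rec in records:
            if rec.source != source:
                raise ValidationError(f"expected source {source}, got {rec.source}")
            reg = catalog.resolve(rec.gene_symbol)
            if reg is None:
                continue
            key = (rec.mirna_id, reg.symbol)
            scores[key] = max(scores.get(key, float("-inf")), rec.raw_score)
        return scores

    a_scores = resolved(preds_a, "A")
    b_scores = resolved(preds_b, "B")

    out: list[ConsensusInteraction] = []
    for (mirna, gene), a in a_scores.items():
        if mirna not in directions or a < thresholds.min_target_score:
            continue
        b = b_scores.get((mirna, gene))
        if b is None or b < thresholds.min_binding_prob:
            continue
        out.append(
            ConsensusInteraction(
                mirna_id=mirna,
                direction=directions[mirna],
                gene_symbol=gene,
                target_score=a,
                binding_prob=b,
                cumulative_score=cumulative_score(a, b),
                high_confidence=(
                    a >= thresholds.high_target_score and b >= thresholds.high_binding_prob
                ),
                previously_reported=previously_reported.get((mirna, gene), False),
            )
        )
    out.sort(key=lambda i: (i.mirna_id, -i.cumulative_score, i.gene_symbol))
    log.info(
        "consensus: %d interactions, %d miRNAs, %d genes",
        len(out),
        len({i.mirna_id for i in out}),
        len({i.gene_symbol for i in out}),
    )
    return out


def identify_epi_mirnas(
    interactions: Sequence[ConsensusInteraction],
    previously_reported_mirnas: Iterable[str] = (),
) -> list[EpiMiRNASummary]:
    """One summary per distinct miRNA with >= 1 accepted interaction.

    Target lists are sorted by cumulative score descending, ties broken by
    gene symbol; ``has_high_confidence`` is the OR over the miRNA's
    interactions.
    """
    prev = set(previously_reported_mirnas)
    by_mirna: dict[str, list[ConsensusInteraction]] = {}
    for i in interactions:
        by_mirna.setdefault(i.mirna_id, []).append(i)
    summaries = []
    for mirna in sorted(by_mirna):
        group = sorted(by_mirna[mirna], key=lambda i: (-i.cumulative_score, i.gene_symbol))
        summaries.append(
            EpiMiRNASummary(
                mirna_id=mirna,
                direction=group[0].direction,
                targets=tuple((i.gene_symbol, i.cumulative_score) for i in group),
                has_high_confidence=any(i.high_confidence for i in group),
                previously_reported=mirna in prev or any(i.previously_reported for i in group),
            )
        )
    return summaries


def count_novel(
    interactions: Sequence[ConsensusInteraction],
    known_pairs: set[tuple[str, str]],
    previously_reported_mirnas: Iterable[str] = (),
) -> tuple[int, int]:
    """(novel interactions, novel epi-miRNAs) against prior literature.

    An interaction is novel when its (miRNA, gene) pair is not among the
    previously confirmed pairs; an epi-miRNA is novel when it has never
    been reported as an epi-miRNA (an input annotation — the literature
    search itself is not computation this package can redo).
    """
    novel_i = sum(1 for i in interactions if i.pair not in known_pairs)
    summaries = identify_epi_mirnas(interactions, previously_reported_mirnas)
    novel_m = sum(1 for s in summaries if not s.previously_reported)
    return novel_i, novel_m


def interactions_frame(interactions: Sequence[ConsensusInteraction]) -> pd.DataFrame:
    """Tidy report table; cumulative scores rounded to 2 decimals half-up."""
    return pd.DataFrame(
        {
            "mirna_id": [i.mirna_id for i in interactions],
            "direction": [i.direction for i in interactions],
            "gene_symbol": [i.gene_symbol for i in interactions],
            "target_score": [i.target_score for i in interactions],
            "binding_prob": [i.binding_prob for i in interactions],
            "cumulative_score": [round_half_up(i.cumulative_score, 2) for i in interactions],
            "high_confidence": [i.high_confidence for i in interactions],
            "previously_reported": [i.previously_reported for i in interactions],
        }
    )
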