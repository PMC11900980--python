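"""Net direction of an epigenetic mark from the epi-miRNA landscape.

The bookkeeping model: a miRNA going up is assumed to push its target
transcript down (and vice versa), a chromatin mark moves *with* its writer
enzymes and *against* its erasers. Each accepted interaction therefore
contributes one signed unit to the mark it touches:

    predicted target change  = -(miRNA direction)
    writer contribution      = predicted target change
    eraser contribution      = -(predicted target change)
    net score                = sum over contributing interactions

Equivalently, net = (down_writer - up_writer) + (up_eraser - down_eraser)
where the four terms are interaction counts split by miRNA direction. A
positive net score predicts the mark increases. The qualitative call gets
a "slightly" qualifier when |net| is at most a configurable fraction
(default 20%) of the contributing interactions — the figure convention
distinguishes slight from clear shifts without stating a rule, so the band
is an explicit, tunable choice here.

An optional refinement weighs each interaction by its cumulative
prediction score instead of 1; it is off by default because the published
procedure counts interactions.

The output is qualitative bookkeeping over *predicted* interactions — no
residue-level resolution, no enzyme kinetics, no claim of validated
biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .catalog import CATEGORY_GO, Catalog
from .consensus import ConsensusInteraction
from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkSpec:
    """Writer and eraser function categories for one epigenetic mark."""

    mark: str
    writer_categories: frozenset[str]
    eraser_categories: frozenset[str]

    def __post_init__(self):
        unknown = (self.writer_categories | self.eraser_categories) - set(CATEGORY_GO)
        if unknown:
            raise ValidationError(f"{self.mark}: unknown categories {sorted(unknown)}")
        if self.writer_categories & self.eraser_categories:
            raise ValidationError(f"{self.mark}: writer and eraser sets overlap")
        if not (self.writer_categories or self.eraser_categories):
            raise ValidationError(f"{self.mark}: needs at least one category")


DEFAULT_MARK_SPECS: tuple[MarkSpec, ...] = (
    MarkSpec(
        "DNA methylation",
        frozenset({"DNA methyltransferase"}),
        frozenset({"DNA demethylase"}),
    ),
    MarkSpec(
        "histone acetylation",
        frozenset({"histone acetyltransferase"}),
        frozenset({"histone deacetylase"}),
    ),
    MarkSpec(
        "histone methylation",
        frozenset({"histone methyltransferase"}),
        frozenset({"histone demethylase"}),
    ),
)


@dataclass(frozen=True)
class NetDirectionReport:
    """Inferred net change of one mark, with its up/down bookkeeping."""

    mark: str
    n_writer_up: int
    n_writer_down: int
    n_eraser_up: int
    n_eraser_down: int
    net_score: float
    direction: str
    contributing: tuple[tuple[str, str, str], ...] = field(default=())
    # (mirna, gene, role) listing for auditability

    @property
    def n_contributing(self) -> int:
        return self.n_writer_up + self.n_writer_down + self.n_eraser_up + self.n_eraser_down


def _call_direction(net: float, n_contributing: int, slight_fraction: float) -> str:
    if net == 0:
        return "no change"
    word = "increased" if net > 0 else "decreased"
    if abs(net) <= slight_fraction * n_contributing:
        return f"slightly {word}"
    return word


def infer_mark_direction(
    interactions: Sequence[ConsensusInteraction],
    catalog: Catalog,
    spec: MarkSpec,
    slight_fraction: float = 0.2,
    weight_by_score: bool = False,
) -> NetDirectionReport:
    """Aggregate up/down epi-miRNA pressure on one mark's writers and erasers.

    Interactions whose gene has neither a writer nor an eraser category for
    this mark are ignored (logged). A gene annotated as both writer and
    eraser cannot occur (:class:`MarkSpec` keeps the sets disjoint).
    """
    if not 0 <= slight_fraction < 1:
        raise ParameterError("slight_fraction must be in [0, 1)")
    counts = {("writer", 1): 0, ("writer", -1): 0, ("eraser", 1): 0, ("eraser", -1): 0}
    net = 0.0
    contributing: list[tuple[str, str, str]] = []
    skipped = 0
    for i in interactions:
        reg = catalog.resolve(i.gene_symbol)
        if reg is None:
            raise ValidationError(f"target {i.gene_symbol!r} missing from catalog")
        if reg.categories & spec.writer_categories:
            role = "writer"
        elif reg.categories & spec.eraser_categories:
            role = "eraser"
        else:
            skipped += 1
            continue
        counts[(role, i.direction)] += 1
        target_change = -i.direction  # miRNA up represses its target
        contribution = target_change if role == "writer" else -target_change
        net += contribution * (i.cumulative_score if weight_by_score else 1.0)
        contributing.append((i.mirna_id, i.gene_symbol, role))
    if skipped:
        log.info("%s: %d interactions outside writer/eraser categories ignored", spec.mark, skipped)
    n_contrib = len(contributing)
    report = NetDirectionReport(
        mark=spec.mark,
        n_writer_up=counts[("writer", 1)],
        n_writer_down=counts[("writer", -1)],
        n_eraser_up=counts[("eraser", 1)],
        n_eraser_down=counts[("eraser", -1)],
        net_score=net if weight_by_score else int(net),
        direction=_call_direction(net, n_contrib, slight_fraction),
        contributing=tuple(contributing),
    )
    log.info("%s: net %+g over %d interactions -> %s", spec.mark, net, n_contrib, report.direction)
    return report


def infer_all_marks(
    interactions: Sequence[ConsensusInteraction],
    catalog: Catalog,
    specs: Sequence[MarkSpec] = DEFAULT_MARK_SPECS,
    slight_fraction: float = 0.2,
    weight_by_score: bool = False,
) -> list[NetDirectionReport]:
    """Run :func:`infer_mark_direction` for every configured mark."""
    return [
        infer_mark_direction(interactions, catalog, spec, slight_fraction, weight_by_score)
        for spec in specs
    ]
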