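"""Summaries of the consensus interaction set.

Per-target regulation counts (how many up-/down-regulated miRNAs hit each
gene), the up-only / down-only / both Venn partition of targets, per-
function-category tallies and shares, disease-annotation fractions, and a
generic hypergeometric over-representation test with Benjamini–Hochberg
correction as plumbing for set-enrichment questions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._util import percent
from .catalog import CATEGORY_GO, Catalog
from .consensus import ConsensusInteraction
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSummary:
    """Up/down targeting counts for one regulator gene."""

    gene_symbol: str
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    @property
    def regulation_class(self) -> str:
        if self.n_up and self.n_down:
            return "both"
        return "up_only" if self.n_up else "down_only"


def target_summaries(interactions: Sequence[ConsensusInteraction]) -> list[TargetSummary]:
    """One row per distinct target gene, sorted by total count then symbol."""
    ups: dict[str, int] = {}
    downs: dict[str, int] = {}
    for i in interactions:
        if i.direction == 1:
            ups[i.gene_symbol] = ups.get(i.gene_symbol, 0) + 1
            downs.setdefault(i.gene_symbol, 0)
        else:
            downs[i.gene_symbol] = downs.get(i.gene_symbol, 0) + 1
            ups.setdefault(i.gene_symbol, 0)
    rows = [TargetSummary(g, ups[g], downs[g]) for g in ups]
    rows.sort(key=lambda s: (-s.n_total, s.gene_symbol))
    return rows


def venn_partition(summaries: Sequence[TargetSummary]) -> tuple[int, int, int]:
    """(up-only, down-only, both) target counts; they sum to the target count."""
    classes = [s.regulation_class for s in summaries]
    return (
        classes.count("up_only"),
        classes.count("down_only"),
        classes.count("both"),
    )


@dataclass(frozen=True)
class CategoryTally:
    """Targeting burden of one function category."""

    category: str
    targeted: int
    share_of_targets: float  # percent of distinct targets, 1 decimal
    catalog_total: Optional[int] = None
    fraction_of_catalog: Optional[float] = None  # percent, 1 decimal


def category_tallies(
    interactions: Sequence[ConsensusInteraction],
    catalog: Catalog,
    reference_catalog: Optional[Catalog] = None,
) -> list[CategoryTally]:
    """Distinct targeted regulators per function category.

    A target annotated to k categories contributes to all k tallies;
    ``share_of_targets`` always uses the distinct-target denominator.
    ``reference_catalog`` (the full expressed-regulator universe) enables
    the targeted/catalog fraction; without it the fraction is absent.
    """
    targets = sorted({i.gene_symbol for i in interactions})
    per_cat: dict[str, set[str]] = {}
    for gene in targets:
        reg = catalog.resolve(gene)
        if reg is None:
            raise ValidationError(f"target {gene!r} missing from catalog")
        for cat in reg.categories:
            per_cat.setdefault(cat, set()).add(reg.symbol)
    ref_counts: dict[str, int] = {}
    if reference_catalog is not None:
        for reg in reference_catalog:
            for cat in reg.categories:
                ref_counts[cat] = ref_counts.get(cat, 0) + 1
    out = []
    for cat in sorted(per_cat, key=list(CATEGORY_GO).index):
        targeted = len(per_cat[cat])
        total = ref_counts.get(cat) if reference_catalog is not None else None
        out.append(
            CategoryTally(
                category=cat,
                targeted=targeted,
                share_of_targets=percent(targeted, len(targets)),
                catalog_total=total,
                fraction_of_catalog=percent(targeted, total) if total else None,
            )
        )
    return out


def disease_tally(
    summaries: Sequence[TargetSummary],
    catalog: Catalog,
    disease_labels: Iterable[str],
) -> dict[str, tuple[int, float]]:
    """Distinct targets annotated per disease label, plus ``"any"``.

    Returns label -> (count, percent of distinct targets, half-up at one
    decimal). Unknown labels count zero (logged), they are not an error.
    """
    genes = [s.gene_symbol for s in summaries]
    total = len(genes)
    annotations = {}
    for gene in genes:
        reg = catalog.resolve(gene)
        annotations[gene] = reg.diseases if reg is not None else frozenset()
    known = set().union(*annotations.values()) if annotations else set()
    out: dict[str, tuple[int, float]] = {}
    for label in disease_labels:
        if label not in known:
            log.info("disease label %r not present in catalog annotations", label)
        count = sum(1 for g in genes if label in annotations[g])
        out[label] = (count, percent(count, total))
    n_any = sum(1 for g in genes if annotations[g])
    out["any"] = (n_any, percent(n_any, total))
    return out


def mirnas_with_min_targets(
    interactions: Sequence[ConsensusInteraction], min_targets: int
) -> tuple[int, float]:
    """(count, percent) of miRNAs targeting at least ``min_targets`` regulators."""
    per_mirna: dict[str, set[str]] = {}
    for i in interactions:
        per_mirna.setdefault(i.mirna_id, set()).add(i.gene_symbol)
    hit = sum(1 for genes in per_mirna.values() if len(genes) >= min_targets)
    return hit, percent(hit, len(per_mirna))


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    overlap: int
    set_size: int
    p_value: float
    adjusted_p: float


def overrepresentation(
    target_set: set[str],
    annotation_sets: Mapping[str, set[str]],
    universe: set[str],
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of each annotation set.

    For a universe of size N, a target list of size n and an annotation set
    of size K overlapping the targets in k genes, the p-value is
    P[X >= k] with X ~ Hypergeom(N, K, n). Adjustment across sets is
    Benjamini–Hochberg by default (any ``statsmodels`` method name works).
    """
    if not universe:
        raise ValidationError("empty universe")
    if not target_set <= universe:
        raise ValidationError("target set must be a subset of the universe")
    names, pvals, rows = [], [], []
    n_univ, n_targets = len(universe), len(target_set)
    for name in sorted(annotation_sets):
        ann = annotation_sets[name]
        if not ann <= universe:
            raise ValidationError(f"annotation set {name!r} not a subset of the universe")
        k = len(target_set & ann)
        p = float(hypergeom.sf(k - 1, n_univ, len(ann), n_targets))
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, k, len(ann)))
    adjusted = multipletests(pvals, method=correction)[1] if pvals else []
    return [
        EnrichmentResult(name, k, size, p, float(adj))
        for (name, k, size), p, adj in zip(rows, pvals, adjusted)
    ]
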