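"""The epigenetic-regulator universe.

A *regulator* is an enzyme (or enzyme-complex subunit) whose Gene Ontology
molecular function places it in the epigenetic machinery: writers and
erasers of DNA methylation and of histone acetylation, methylation,
ubiquitination and phosphorylation, plus a handful of rarer acyl marks and
two chromatin-programming process terms. The catalog is a flat, delimited
file — no GO graph traversal — carrying per gene: canonical symbol, alias
symbols (e.g. Kat13d for Clock), one or more function categories, a heart
expression level (TPM and/or a coarse bin) and free-text disease-ontology
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

import pandas as pd

from .errors import CatalogError, ParameterError, ValidationError
from .ingest import normalize_gene_symbol

log = logging.getLogger(__name__)

#: The configured GO molecular-function / process terms defining the
#: regulator universe (label -> GO accession).
CATEGORY_GO: dict[str, str] = {
    "DNA methyltransferase": "GO:0009008",
    "DNA demethylase": "GO:0035514",
    "histone acetyltransferase": "GO:0004402",
    "histone deacetylase": "GO:0004407",
    "histone methyltransferase": "GO:0042054",
    "histone demethylase": "GO:0032452",
    "histone ubiquitin ligase": "GO:0140852",
    "histone deubiquitinase": "GO:0140934",
    "histone kinase": "GO:0035173",
    "histone phosphatase": "GO:0140789",
    "histone succinyltransferase": "GO:0106078",
    "histone lactyltransferase": "GO:0120301",
    "histone glutaryltransferase": "GO:0106229",
    "histone butyryltransferase": "GO:0140069",
    "CpG island demethylation": "GO:0044029",
    "male pronucleus epigenetic programming": "GO:0044727",
}

#: Ordered coarse expression scale. Bin anchors follow the published
#: RNA-seq convention: low = 0.5-10 TPM, medium = 11-1000 TPM; the printed
#: bins leave (10, 11) unassigned, resolved here as gap-free intervals
#: low = [0.5, 10], medium = (10, 1000], high > 1000.
EXPRESSION_BINS: tuple[str, ...] = ("none", "low", "medium", "high")

_BIN_RANK = {b: i for i, b in enumerate(EXPRESSION_BINS)}


def bin_expression(tpm: float) -> str:
    """Coarse expression bin for a TPM value (monotone in ``tpm``)."""
    if tpm < 0:
        raise ValidationError(f"negative TPM: {tpm}")
    if tpm < 0.5:
        return "none"
    if tpm <= 10:
        return "low"
    if tpm <= 1000:
        return "medium"
    return "high"


@dataclass(frozen=True)
class Regulator:
    """One catalog entry."""

    symbol: str
    categories: frozenset[str]
    aliases: frozenset[str] = field(default_factory=frozenset)
    tpm: Optional[float] = None
    expression_bin: str = "none"
    diseases: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.categories:
            raise CatalogError(f"{self.symbol}: at least one category required")
        unknown = self.categories - set(CATEGORY_GO)
        if unknown:
            raise CatalogError(f"{self.symbol}: unknown categories {sorted(unknown)}")
        if self.expression_bin not in _BIN_RANK:
            raise CatalogError(f"{self.symbol}: unknown expression bin {self.expression_bin!r}")
        if self.symbol in self.aliases:
            raise CatalogError(f"{self.symbol}: symbol may not appear among its aliases")
        if self.tpm is not None and bin_expression(self.tpm) != self.expression_bin:
            raise CatalogError(
                f"{self.symbol}: bin {self.expression_bin!r} inconsistent with tpm={self.tpm}"
            )


class Catalog:
    """Symbol-indexed regulator collection with alias resolution.

    Lookup is case-insensitive on the normalized symbol; an alias resolves
    to its canonical :class:`Regulator`. Unknown names return ``None``
    (not-found is not an error); a duplicate canonical symbol or an alias
    colliding with another gene's symbol is.
    """

    def __init__(self, regulators):
        self._by_symbol: dict[str, Regulator] = {}
        self._index: dict[str, Regulator] = {}
        for reg in regulators:
            if reg.symbol in self._by_symbol:
                raise CatalogError(f"duplicate canonical symbol {reg.symbol!r}")
            self._by_symbol[reg.symbol] = reg
        for reg in self._by_symbol.values():
            for name in (reg.symbol, *reg.aliases):
                key = name.lower()
                clash = self._index.get(key)
                if clash is not None and clash.symbol != reg.symbol:
                    raise CatalogError(
                        f"name {name!r} maps to both {clash.symbol!r} and {reg.symbol!r}"
                    )
                self._index[key] = reg

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __iter__(self) -> Iterator[Regulator]:
        return iter(sorted(self._by_symbol.values(), key=lambda r: r.symbol))

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) is not None

    def resolve(self, name: str) -> Optional[Regulator]:
        """Canonical regulator for a symbol or alias, or ``None``."""
        if not name or not str(name).strip():
            return None
        return self._index.get(normalize_gene_symbol(name).lower())

    def symbols(self) -> list[str]:
        return sorted(self._by_symbol)

    def expressed_subset(self, min_bin: str = "low") -> "Catalog":
        """Regulators at or above ``min_bin`` on the none<low<medium<high scale."""
        if min_bin not in _BIN_RANK:
            raise ParameterError(f"unknown expression bin {min_bin!r}")
        floor = _BIN_RANK[min_bin]
        kept = [r for r in self if _BIN_RANK[r.expression_bin] >= floor]
        log.info("expression filter (>= %s): %d of %d kept", min_bin, len(kept), len(self))
        return Catalog(kept)


def expressed_subset(catalog: Catalog, min_bin: str = "low") -> Catalog:
    """Functional alias for :meth:`Catalog.expressed_subset`."""
    return catalog.expressed_subset(min_bin)


def _split_multi(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return frozenset()
    return frozenset(p.strip() for p in str(value).split("|") if p.strip())


def load_catalog(path) -> Catalog:
    """Load a catalog from delimited text.

    Expected columns: ``symbol``, ``aliases`` ("|"-separated, optional),
    ``categories`` ("|"-separated), ``tpm`` and/or ``expression_bin``,
    ``diseases`` ("|"-separated, optional). When only TPM is given the bin
    is derived; when both are given they must agree.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    if "symbol" not in frame.columns or "categories" not in frame.columns:
        raise CatalogError(f"catalog needs 'symbol' and 'categories' columns ({path})")
    regulators = []
    for row in frame.to_dict("records"):
        symbol = normalize_gene_symbol(row["symbol"])
        aliases = frozenset(normalize_gene_symbol(a) for a in _split_multi(row.get("aliases")))
        tpm = row.get("tpm")
        tpm = None if tpm is None or pd.isna(tpm) else float(tpm)
        bin_ = row.get("expression_bin")
        if bin_ is None or pd.isna(bin_) or str(bin_).strip() == "":
            bin_ = bin_expression(tpm) if tpm is not None else "none"
        regulators.append(
            Regulator(
                symbol=symbol,
                aliases=aliases - {symbol},
                categories=_split_multi(row["categories"]),
                tpm=tpm,
                expression_bin=str(bin_).strip().lower(),
                diseases=_split_multi(row.get("diseases")),
            )
        )
    catalog = Catalog(regulators)
    log.info("loaded catalog of %d regulators from %s", len(catalog), path)
    return catalog


def load_packaged_catalog() -> Catalog:
    """The packaged 81-regulator catalog (targets observed in the study)."""
    ref = resources.files("epimir.data") / "table2_regulators.csv"
    with resources.as_file(ref) as path:
        return load_catalog(path)
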