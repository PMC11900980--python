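"""Synthetic inputs with planted ground truth, and the packaged study fixture.

Two entry points:

* :func:`generate_dataset` builds a complete, fully reproducible input set
  (DE table, two predictor exports, regulator catalog) around a planted
  set of consensus interactions plus decoys that must fail the consensus,
  so every pipeline stage is testable with no download. It emulates the
  *structure* of the real inputs, not miRNA biology.
* :func:`load_paper_fixture` returns the packaged transcription of the
  study's two result tables: 202 miRNA–regulator interactions over 71
  miRNAs and an 81-regulator catalog, with per-pair cumulative scores,
  high-confidence and prior-literature flags, and the per-gene up/down
  counts used for cross-validation. Packaged files are checksummed.

Because the published interaction table prints only the *cumulative* score,
the fixture derives a synthetic per-predictor split of each score so the
pipeline can be run end to end: binding probability is taken as large as
the [60, 100] target-score range allows (b = min(1, c - 0.6), the
high-confidence tier using its own floors), and the target score is the
remainder times 100. The split is synthetic; only its sum and tier are
anchored in the published table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, Regulator, bin_expression, load_catalog
from .consensus import ConsensusInteraction
from .errors import ParameterError, ValidationError
from .inference import DEFAULT_MARK_SPECS, MarkSpec
from .ingest import DEMiRNA, PredictionRecord, normalize_mirna_id

_DATA = "epimir.data"


# ---------------------------------------------------------------------------
# generator


@dataclass(frozen=True)
class SyntheticTruth:
    """What was planted, for exact-recovery checks."""

    planted_interactions: frozenset[tuple[str, str]]
    planted_epi_mirnas: frozenset[str]
    decoys: tuple[tuple[str, str, str], ...]  # (mirna, gene, failure mode)
    seed: int


@dataclass(frozen=True)
class SyntheticDataset:
    de_records: tuple[DEMiRNA, ...]
    predictions_a: tuple[PredictionRecord, ...]
    predictions_b: tuple[PredictionRecord, ...]
    catalog: Catalog
    truth: SyntheticTruth


_DEF_SCORE_PARAMS = {
    "a_range": (60.0, 100.0),  # planted target scores, uniform
    "b_range": (0.8, 1.0),  # planted binding probabilities, uniform
    "a_fail_range": (50.0, 59.0),  # sub-threshold target scores for decoys
    "b_fail_range": (0.0, 0.79),  # sub-threshold binding probabilities
}

_DECOY_MODES = ("only_in_a", "only_in_b", "a_subthreshold", "b_subthreshold")


def generate_dataset(
    n_mirnas: int = 94,
    n_regulators: int = 81,
    n_planted: int = 202,
    n_decoys: int = 200,
    p_decoy_single_db: float = 0.5,
    score_params: Optional[dict] = None,
    categories: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate DE + predictor + catalog inputs with a planted consensus set.

    Defaults mirror the study's scale: 94 differentially expressed miRNAs
    (directions Bernoulli(0.5)), 81 expressed regulators, 202 planted
    consensus interactions. Planted pairs receive scores that clear both
    thresholds; each decoy either exists in a single predictor only (with
    probability ``p_decoy_single_db``) or appears in both with one score
    below threshold, so the exact planted set is the unique consensus.
    Identical arguments (including ``seed``) give identical output.
    """
    if n_planted + n_decoys > n_mirnas * n_regulators:
        raise ParameterError("more planted+decoy pairs than the miRNA x gene grid holds")
    if not 0 <= p_decoy_single_db <= 1:
        raise ParameterError("p_decoy_single_db must be in [0, 1]")
    params = {**_DEF_SCORE_PARAMS, **(score_params or {})}
    if categories is None:
        categories = [
            "DNA methyltransferase",
            "DNA demethylase",
            "histone acetyltransferase",
            "histone deacetylase",
            "histone methyltransferase",
            "histone demethylase",
            "histone ubiquitin ligase",
            "histone deubiquitinase",
            "histone kinase",
        ]
    rng = np.random.default_rng(seed)

    mirnas = [f"mir-s{i + 1:03d}" for i in range(n_mirnas)]
    genes = [f"Reg{i + 1:03d}" for i in range(n_regulators)]

    directions = rng.choice([1, -1], size=n_mirnas)
    de_records = tuple(
        DEMiRNA(
            mirna_id=m,
            fold_change=float(np.round(rng.uniform(2.0, 10.0), 3)),
            direction=int(d),
            p_value=float(np.round(rng.uniform(1e-5, 0.049), 5)),
        )
        for m, d in zip(mirnas, directions)
    )

    tpms = np.round(rng.uniform(0.5, 1000.0, size=n_regulators), 2)
    regulators = [
        Regulator(
            symbol=g,
            categories=frozenset({categories[int(rng.integers(len(categories)))]}),
            tpm=float(t),
            expression_bin=bin_expression(float(t)),
        )
        for g, t in zip(genes, tpms)
    ]
    catalog = Catalog(regulators)

    grid_size = n_mirnas * n_regulators
    chosen = rng.choice(grid_size, size=n_planted + n_decoys, replace=False)
    pairs = [(mirnas[k // n_regulators], genes[k % n_regulators]) for k in chosen]
    planted, decoy_pairs = pairs[:n_planted], pairs[n_planted:]

    preds_a: list[PredictionRecord] = []
    preds_b: list[PredictionRecord] = []
    a_lo, a_hi = params["a_range"]
    b_lo, b_hi = params["b_range"]
    for m, g in planted:
        preds_a.append(
            PredictionRecord(m, g, "A", float(np.round(rng.uniform(max(60.0, a_lo), a_hi), 1)))
        )
        preds_b.append(
            PredictionRecord(m, g, "B", float(np.round(rng.uniform(max(0.8, b_lo), b_hi), 3)))
        )

    decoys: list[tuple[str, str, str]] = []
    for m, g in decoy_pairs:
        if rng.random() < p_decoy_single_db:
            mode = _DECOY_MODES[int(rng.integers(2))]  # one predictor only
        else:
            mode = _DECOY_MODES[2 + int(rng.integers(2))]  # sub-threshold score
        if mode == "only_in_a":
            preds_a.append(PredictionRecord(m, g, "A", float(np.round(rng.uniform(60, 100), 1))))
        elif mode == "only_in_b":
            preds_b.append(PredictionRecord(m, g, "B", float(np.round(rng.uniform(0.8, 1.0), 3))))
        elif mode == "a_subthreshold":
            lo, hi = params["a_fail_range"]
            preds_a.append(PredictionRecord(m, g, "A", float(np.round(rng.uniform(lo, hi), 1))))
            preds_b.append(PredictionRecord(m, g, "B", float(np.round(rng.uniform(0.8, 1.0), 3))))
        else:
            lo, hi = params["b_fail_range"]
            preds_a.append(PredictionRecord(m, g, "A", float(np.round(rng.uniform(60, 100), 1))))
            preds_b.append(PredictionRecord(m, g, "B", float(np.round(rng.uniform(lo, hi), 3))))
        decoys.append((m, g, mode))

    return SyntheticDataset(
        de_records=de_records,
        predictions_a=tuple(preds_a),
        predictions_b=tuple(preds_b),
        catalog=catalog,
        truth=SyntheticTruth(
            planted_interactions=frozenset(planted),
            planted_epi_mirnas=frozenset(m for m, _ in planted),
            decoys=tuple(decoys),
            seed=seed,
        ),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a generated dataset as the four delimited input files."""
    from . import ingest  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "de": outdir / "de_mirnas.csv",
        "predictions_a": outdir / "predictions_a.csv",
        "predictions_b": outdir / "predictions_b.csv",
        "catalog": outdir / "catalog.csv",
        "truth": outdir / "truth.json",
    }
    ingest.write_de_table(dataset.de_records, paths["de"])
    ingest.write_prediction_table(dataset.predictions_a, paths["predictions_a"])
    ingest.write_prediction_table(dataset.predictions_b, paths["predictions_b"])
    pd.DataFrame(
        {
            "symbol": [r.symbol for r in dataset.catalog],
            "aliases": ["|".join(sorted(r.aliases)) for r in dataset.catalog],
            "categories": ["|".join(sorted(r.categories)) for r in dataset.catalog],
            "tpm": [r.tpm for r in dataset.catalog],
            "expression_bin": [r.expression_bin for r in dataset.catalog],
            "diseases": ["|".join(sorted(r.diseases)) for r in dataset.catalog],
        }
    ).to_csv(paths["catalog"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": dataset.truth.seed,
                "planted_interactions": sorted(map(list, dataset.truth.planted_interactions)),
                "planted_epi_mirnas": sorted(dataset.truth.planted_epi_mirnas),
                "decoys": [list(d) for d in dataset.truth.decoys],
            },
            fh,
            indent=1,
        )
    return paths


# ---------------------------------------------------------------------------
# packaged study fixture


def split_cumulative_score(cumulative: float, high_confidence: bool) -> tuple[float, float]:
    """Synthetic (target score, binding probability) pair summing to ``cumulative``.

    The binding probability is pushed as high as the admissible target-score
    range allows; high-confidence pairs use the stricter floors and a pair
    that must *not* be high-confidence but whose forced target score
    reaches 80 caps its binding probability at 0.91.
    """
    if high_confidence:
        b = min(1.0, round(cumulative - 0.80, 2))
        a = round(100.0 * cumulative - 100.0 * b, 1)
        if not (a >= 80.0 and b >= 0.92):
            raise ValidationError(f"cannot split {cumulative} as high-confidence")
    else:
        b = min(1.0, round(cumulative - 0.60, 2))
        a = round(100.0 * cumulative - 100.0 * b, 1)
        if a >= 80.0 and b >= 0.92:  # would spuriously reach the high tier
            b = 0.91
            a = round(100.0 * cumulative - 91.0, 1)
        if not (60.0 <= a <= 100.0 and 0.8 <= b <= 1.0):
            raise ValidationError(f"cannot split {cumulative} below the high tier")
    return a, b


def derive_predictor_tables(
    frame: pd.DataFrame,
) -> tuple[tuple[PredictionRecord, ...], tuple[PredictionRecord, ...]]:
    """Per-predictor export tables reproducing a cumulative-score table."""
    preds_a, preds_b = [], []
    for row in frame.itertuples(index=False):
        a, b = split_cumulative_score(float(row.cumulative_score), bool(row.high_confidence))
        mirna = normalize_mirna_id(row.mirna)
        preds_a.append(PredictionRecord(mirna, row.gene, "A", a))
        preds_b.append(PredictionRecord(mirna, row.gene, "B", b))
    return tuple(preds_a), tuple(preds_b)


@dataclass(frozen=True)
class PaperFixture:
    """The packaged transcription of the study's result tables."""

    de_records: tuple[DEMiRNA, ...]
    interactions: tuple[ConsensusInteraction, ...]
    predictions_a: tuple[PredictionRecord, ...]
    predictions_b: tuple[PredictionRecord, ...]
    catalog: Catalog
    known_pairs: frozenset[tuple[str, str]]
    previously_reported_mirnas: frozenset[str]
    mark_specs: tuple[MarkSpec, ...] = DEFAULT_MARK_SPECS
    table2_counts: pd.DataFrame = field(default=None, repr=False)


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files(_DATA) / name
    manifest = json.loads((resources.files(_DATA) / "manifest.json").read_text())
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if manifest[name] != digest:
        raise ValidationError(f"packaged file {name} checksum mismatch")
    return pd.read_csv(resources.files(_DATA) / name)


def load_paper_fixture() -> PaperFixture:
    """Load and checksum the packaged fixture.

    The interaction list carries each pair's published cumulative score (2
    decimals), high-confidence flag and the per-row prior-literature flag of
    its miRNA; the catalog carries category, expression bin, disease labels
    and the published per-gene up/down counts (``table2_counts``) for
    cross-validation. The DE table's fold changes and p-values are synthetic
    stand-ins (the real per-miRNA statistics live in the source dataset's
    supplement); names and directions are the published ones, padded with
    clearly synthetic filler miRNAs to the published 94 (50 up / 44 down).
    """
    t1 = _read_packaged("table1_interactions.csv")
    known = _read_packaged("known_pairs.csv")
    de_frame = _read_packaged("de_mirnas_synthetic.csv")

    ref = resources.files(_DATA) / "table2_regulators.csv"
    _read_packaged("table2_regulators.csv")  # checksum only
    with resources.as_file(ref) as path:
        catalog = load_catalog(path)
        table2 = pd.read_csv(path)[["symbol", "n_total", "n_up", "n_down"]]

    interactions = []
    prev_mirnas = set()
    for row in t1.itertuples(index=False):
        mirna = normalize_mirna_id(row.mirna)
        a, b = split_cumulative_score(float(row.cumulative_score), bool(row.high_confidence))
        interactions.append(
            ConsensusInteraction(
                mirna_id=mirna,
                direction=int(row.direction),
                gene_symbol=row.gene,
                target_score=a,
                binding_prob=b,
                cumulative_score=float(row.cumulative_score),
                high_confidence=bool(row.high_confidence),
                previously_reported=bool(row.mirna_previously_reported),
            )
        )
        if row.mirna_previously_reported:
            prev_mirnas.add(mirna)

    de_records = tuple(
        DEMiRNA(
            normalize_mirna_id(r.mirna_id),
            float(r.fold_change),
            1 if str(r.direction).lower() in {"1", "+1", "up"} else -1,
            float(r.p_value),
        )
        for r in de_frame.itertuples(index=False)
    )
    preds_a, preds_b = derive_predictor_tables(t1)
    return PaperFixture(
        de_records=de_records,
        interactions=tuple(interactions),
        predictions_a=preds_a,
        predictions_b=preds_b,
        catalog=catalog,
        known_pairs=frozenset(
            (normalize_mirna_id(r.mirna), r.gene) for r in known.itertuples(index=False)
        ),
        previously_reported_mirnas=frozenset(prev_mirnas),
        table2_counts=table2,
    )
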