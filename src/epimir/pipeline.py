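"""End-to-end orchestration with a reproducible report bundle.

Runs ingest -> consensus -> network -> tally -> inference on a set of
input files and writes tidy tables plus JSON summaries. Every number in
the human-readable summary is recomputable from the emitted tables, and
the run log records record counts after each filter so the attrition from
the DE table down to the epi-miRNA set is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import round_half_up
from .catalog import load_catalog
from .consensus import (
    Thresholds,
    consensus_interactions,
    count_novel,
    identify_epi_mirnas,
    interactions_frame,
)
from .errors import EpimirError, ParameterError
from .inference import DEFAULT_MARK_SPECS, MarkSpec, infer_all_marks
from .ingest import filter_de, read_de_table, read_prediction_table
from .network import build_network, export_graph, find_hubs, mcl_cluster
from .tally import category_tallies, disease_tally, target_summaries, venn_partition

log = logging.getLogger(__name__)

DEFAULT_DISEASE_LABELS = ("congestive heart failure", "cardiomyopathy")


@dataclass
class RunConfig:
    """All inputs and tunables of one pipeline run."""

    de_table: str
    predictions_a: str
    predictions_b: str
    catalog: str
    output_dir: str
    known_pairs: Optional[str] = None
    reference_catalog: Optional[str] = None
    fc_min: float = 2.0
    p_max: float = 0.05
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_bin: str = "low"
    inflation: float = 3.0
    min_degree: int = 5
    slight_fraction: float = 0.2
    disease_labels: Sequence[str] = DEFAULT_DISEASE_LABELS
    mark_specs: Sequence[MarkSpec] = DEFAULT_MARK_SPECS
    seed: int = 0

    def __post_init__(self):
        if self.inflation <= 1:
            raise ParameterError("inflation must be > 1")
        for name in ("de_table", "predictions_a", "predictions_b", "catalog"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ParameterError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "mark_specs" in raw:
            raw["mark_specs"] = tuple(
                MarkSpec(
                    m["mark"],
                    frozenset(m.get("writer_categories", ())),
                    frozenset(m.get("eraser_categories", ())),
                )
                for m in raw["mark_specs"]
            )
        return cls(**raw)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    Writes, under ``config.output_dir``: interactions.csv, epi_mirnas.csv,
    target_summaries.csv, category_tallies.csv, disease_tally.csv,
    venn.json, network.sif, network.graphml, clusters.json,
    mark_directions.json, summary.json and run_log.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        de = filter_de(read_de_table(config.de_table), config.fc_min, config.p_max)
        preds_a = read_prediction_table(config.predictions_a, "A")
        preds_b = read_prediction_table(config.predictions_b, "B")
        catalog = load_catalog(config.catalog).expressed_subset(config.min_bin)
        known_pairs: set[tuple[str, str]] = set()
        if config.known_pairs:
            kp = pd.read_csv(config.known_pairs)
            known_pairs = {(m, g) for m, g in zip(kp.iloc[:, 0], kp.iloc[:, 1])}
        reference = (
            load_catalog(config.reference_catalog) if config.reference_catalog else None
        )

        stage = "consensus"
        interactions = consensus_interactions(
            de, preds_a, preds_b, catalog, config.thresholds
        )
        summaries = identify_epi_mirnas(interactions)
        novel_interactions, novel_mirnas = count_novel(interactions, known_pairs)
        interactions_frame(interactions).to_csv(out / "interactions.csv", index=False)
        pd.DataFrame(
            {
                "mirna_id": [s.mirna_id for s in summaries],
                "direction": [s.direction for s in summaries],
                "n_targets": [s.n_targets for s in summaries],
                "has_high_confidence": [s.has_high_confidence for s in summaries],
                "previously_reported": [s.previously_reported for s in summaries],
                "targets": [
                    "|".join(f"{g}:{round_half_up(c, 2):.2f}" for g, c in s.targets)
                    for s in summaries
                ],
            }
        ).to_csv(out / "epi_mirnas.csv", index=False)

        stage = "network"
        graph = build_network(interactions)
        hubs = find_hubs(graph, config.min_degree)
        mcl = mcl_cluster(graph, inflation=config.inflation)
        export_graph(graph, "sif", out / "network.sif")
        export_graph(graph, "graphml", out / "network.graphml")
        with open(out / "clusters.json", "w") as fh:
            json.dump(
                {
                    "inflation": mcl.inflation,
                    "n_iterations": mcl.n_iterations,
                    "converged": mcl.converged,
                    "clusters": [sorted(c) for c in mcl.clusters],
                },
                fh,
                indent=1,
            )

        stage = "tally"
        targets = target_summaries(interactions)
        venn = venn_partition(targets)
        cats = category_tallies(interactions, catalog, reference)
        diseases = disease_tally(targets, catalog, config.disease_labels)
        pd.DataFrame(
            {
                "gene_symbol": [t.gene_symbol for t in targets],
                "n_total": [t.n_total for t in targets],
                "n_up": [t.n_up for t in targets],
                "n_down": [t.n_down for t in targets],
                "regulation_class": [t.regulation_class for t in targets],
            }
        ).to_csv(out / "target_summaries.csv", index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in cats]).to_csv(
            out / "category_tallies.csv", index=False
        )
        pd.DataFrame(
            [(label, n, pct) for label, (n, pct) in diseases.items()],
            columns=["disease", "n_targets", "percent_of_targets"],
        ).to_csv(out / "disease_tally.csv", index=False)
        with open(out / "venn.json", "w") as fh:
            json.dump(
                {"up_only": venn[0], "down_only": venn[1], "both": venn[2]}, fh, indent=1
            )

        stage = "inference"
        marks = infer_all_marks(
            interactions, catalog, config.mark_specs, config.slight_fraction
        )
        with open(out / "mark_directions.json", "w") as fh:
            json.dump(
                [
                    {k: v for k, v in dataclasses.asdict(m).items() if k != "contributing"}
                    for m in marks
                ],
                fh,
                indent=1,
            )
    except EpimirError as exc:
        raise EpimirError(f"[{stage}] {exc}") from exc

    summary = {
        "n_de_mirnas": len(de),
        "n_interactions": len(interactions),
        "n_epi_mirnas": len(summaries),
        "n_epi_mirnas_up": sum(1 for s in summaries if s.direction == 1),
        "n_epi_mirnas_down": sum(1 for s in summaries if s.direction == -1),
        "n_high_confidence_epi_mirnas": sum(1 for s in summaries if s.has_high_confidence),
        "n_targets": len(targets),
        "novel_interactions": novel_interactions,
        "novel_epi_mirnas": novel_mirnas,
        "venn": {"up_only": venn[0], "down_only": venn[1], "both": venn[2]},
        "hubs": sorted(hubs),
        "n_clusters": len(mcl.clusters),
        "mark_directions": {m.mark: {"net_score": m.net_score, "call": m.direction} for m in marks},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fc_min": config.fc_min,
            "p_max": config.p_max,
            "thresholds": dataclasses.asdict(config.thresholds),
            "min_bin": config.min_bin,
            "inflation": config.inflation,
            "min_degree": config.min_degree,
            "slight_fraction": config.slight_fraction,
        },
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("de_table", "predictions_a", "predictions_b", "catalog")
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)
    log.info("pipeline finished: %d interactions, %d epi-miRNAs", len(interactions), len(summaries))
    return summary
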