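import random

import pytest

from epimir.catalog import Catalog, Regulator
from epimir.consensus import (
    ConsensusInteraction,
    Thresholds,
    consensus_interactions,
    count_novel,
    cumulative_score,
    identify_epi_mirnas,
)
from epimir.errors import ValidationError
from epimir.ingest import DEMiRNA, PredictionRecord

from oracles import brute_force_consensus

HAT = frozenset({"histone acetyltransferase"})


def small_catalog(n=4):
    return Catalog([Regulator(f"Gene{i}", HAT, expression_bin="low") for i in range(n)])


def de(n=3):
    return [DEMiRNA(f"mir-{i}", 2.5, 1 if i % 2 == 0 else -1, 0.01) for i in range(n)]


class TestCumulativeScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (100, 0.94, 1.94),
            (60, 0.80, 1.40),  # minimum attainable under thresholds
            (80, 0.92, 1.72),  # minimum attainable for high confidence
        ],
    )
    def test_formula(self, a, b, expected):
        assert cumulative_score(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("a, b", [(49, 0.9), (101, 0.9), (80, -0.1), (80, 1.1)])
    def test_range_checks(self, a, b):
        with pytest.raises(ValidationError):
            cumulative_score(a, b)


class TestConsensus:
    def test_pair_in_one_predictor_only_not_emitted(self):
        catalog = small_catalog()
        out = consensus_interactions(
            de(1), [PredictionRecord("mir-0", "Gene0", "A", 85.0)], [], catalog
        )
        assert out == []

    def test_both_thresholds_needed_for_high_confidence(self):
        catalog = small_catalog()
        out = consensus_interactions(
            de(1),
            [PredictionRecord("mir-0", "Gene0", "A", 70.0)],
            [PredictionRecord("mir-0", "Gene0", "B", 0.95)],
            catalog,
        )
        assert len(out) == 1 and not out[0].high_confidence
        assert out[0].cumulative_score == pytest.approx(1.65)

    def test_gene_resolved_through_alias(self):
        catalog = Catalog(
            [Regulator("Clock", HAT, aliases=frozenset({"Kat13d"}), expression_bin="low")]
        )
        out = consensus_interactions(
            de(1),
            [PredictionRecord("mir-0", "Kat13d", "A", 85.0)],
            [PredictionRecord("mir-0", "Clock", "B", 0.95)],
            catalog,
        )
        assert [i.gene_symbol for i in out] == ["Clock"]
        assert out[0].high_confidence

    def test_non_de_mirna_and_non_catalog_gene_excluded(self):
        catalog = small_catalog(1)
        preds_a = [
            PredictionRecord("mir-99", "Gene0", "A", 90.0),
            PredictionRecord("mir-0", "Other1", "A", 90.0),
        ]
        preds_b = [
            PredictionRecord("mir-99", "Gene0", "B", 0.99),
            PredictionRecord("mir-0", "Other1", "B", 0.99),
        ]
        assert consensus_interactions(de(1), preds_a, preds_b, catalog) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_inputs(self, seed):
        rng = random.Random(seed)
        catalog = small_catalog(6)
        des = de(5)
        preds_a, preds_b = [], []
        for m in [f"mir-{i}" for i in range(6)]:
            for g in [f"Gene{i}" for i in range(6)]:
                if rng.random() < 0.6:
                    preds_a.append(PredictionRecord(m, g, "A", rng.uniform(50, 100)))
                if rng.random() < 0.6:
                    preds_b.append(PredictionRecord(m, g, "B", rng.uniform(0, 1)))
        ours = {i.pair for i in consensus_interactions(des, preds_a, preds_b, catalog)}
        assert ours == brute_force_consensus(des, preds_a, preds_b, catalog)

    @pytest.mark.parametrize("seed", range(3))
    def test_lowering_thresholds_never_removes_interactions(self, seed):
        rng = random.Random(100 + seed)
        catalog = small_catalog(5)
        des = de(5)
        preds_a = [
            PredictionRecord(f"mir-{i}", f"Gene{j}", "A", rng.uniform(50, 100))
            for i in range(5)
            for j in range(5)
        ]
        preds_b = [
            PredictionRecord(f"mir-{i}", f"Gene{j}", "B", rng.uniform(0, 1))
            for i in range(5)
            for j in range(5)
        ]
        strict = {
            i.pair
            for i in consensus_interactions(
                des, preds_a, preds_b, catalog, Thresholds(70, 0.9, 80, 0.92)
            )
        }
        loose = {
            i.pair
            for i in consensus_interactions(
                des, preds_a, preds_b, catalog, Thresholds(60, 0.8, 80, 0.92)
            )
        }
        assert strict <= loose

    def test_deterministic_order(self):
        catalog = small_catalog(3)
        preds_a = [PredictionRecord("mir-0", f"Gene{j}", "A", 60 + 10 * j) for j in range(3)]
        preds_b = [PredictionRecord("mir-0", f"Gene{j}", "B", 0.9) for j in range(3)]
        out = consensus_interactions(de(1), preds_a, preds_b, catalog)
        assert [i.gene_symbol for i in out] == ["Gene2", "Gene1", "Gene0"]  # score desc


def interaction(mirna, gene, direction=1, cum=1.5, hc=False, prev=False):
    a = 80.0 if hc else 60.0
    return ConsensusInteraction(mirna, direction, gene, a, cum - a / 100, cum, hc, prev)


class TestEpiMiRNASummaries:
    def test_summary_rollup(self):
        interactions = [
            interaction("mir-1", "Gene0", cum=1.5),
            interaction("mir-1", "Gene1", cum=1.9, hc=True),
            interaction("mir-2", "Gene0", direction=-1, cum=1.6),
        ]
        summaries = identify_epi_mirnas(interactions)
        assert [s.mirna_id for s in summaries] == ["mir-1", "mir-2"]
        first = summaries[0]
        assert first.targets == (("Gene1", 1.9), ("Gene0", 1.5))  # score descending
        assert first.has_high_confidence and first.n_targets == 2
        assert not summaries[1].has_high_confidence

    def test_tie_broken_by_gene_symbol(self):
        interactions = [
            interaction("mir-1", "Geneb", cum=1.5),
            interaction("mir-1", "Genea", cum=1.5),
        ]
        assert identify_epi_mirnas(interactions)[0].targets == (
            ("Genea", 1.5),
            ("Geneb", 1.5),
        )

    def test_empty(self):
        assert identify_epi_mirnas([]) == []


class TestCountNovel:
    def test_empty_known_pairs_means_all_novel(self):
        interactions = [interaction("mir-1", "Gene0"), interaction("mir-2", "Gene1")]
        assert count_novel(interactions, set()) == (2, 2)

    def test_all_known_means_zero_novel_interactions(self):
        interactions = [interaction("mir-1", "Gene0")]
        assert count_novel(interactions, {("mir-1", "Gene0")})[0] == 0

    def test_previously_reported_mirnas_not_novel(self):
        interactions = [interaction("mir-1", "Gene0"), interaction("mir-2", "Gene1")]
        _, novel_m = count_novel(interactions, set(), previously_reported_mirnas=["mir-1"])
        assert novel_m == 1
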