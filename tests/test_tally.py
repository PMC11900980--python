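import math

import pytest

from epimir.catalog import Catalog, Regulator
from epimir.consensus import ConsensusInteraction
from epimir.errors import ValidationError
from epimir.tally import (
    TargetSummary,
    category_tallies,
    disease_tally,
    mirnas_with_min_targets,
    overrepresentation,
    target_summaries,
    venn_partition,
)

from oracles import hypergeometric_tail_by_enumeration


def interaction(mirna, gene, direction=1):
    return ConsensusInteraction(mirna, direction, gene, 60.0, 0.9, 1.5, False)


class TestTargetSummaries:
    def test_counts_split_by_direction(self):
        interactions = [
            interaction("mir-1", "Gene0", 1),
            interaction("mir-2", "Gene0", -1),
            interaction("mir-3", "Gene0", -1),
            interaction("mir-1", "Gene1", 1),
        ]
        rows = target_summaries(interactions)
        assert rows[0] == TargetSummary("Gene0", 1, 2)
        assert rows[0].regulation_class == "both" and rows[0].n_total == 3
        assert rows[1] == TargetSummary("Gene1", 1, 0)
        assert rows[1].regulation_class == "up_only"

    def test_total_counts_sum_to_interactions(self, fixture_consensus):
        rows = target_summaries(fixture_consensus)
        assert sum(r.n_total for r in rows) == len(fixture_consensus)

    def test_venn_sums_to_distinct_targets(self, fixture_consensus):
        rows = target_summaries(fixture_consensus)
        assert sum(venn_partition(rows)) == len(rows)

    def test_venn_empty(self):
        assert venn_partition([]) == (0, 0, 0)


class TestCategoryTallies:
    def test_multi_category_gene_counts_in_each(self):
        catalog = Catalog(
            [
                Regulator(
                    "Gene0",
                    frozenset({"histone acetyltransferase", "histone kinase"}),
                    expression_bin="low",
                ),
                Regulator("Gene1", frozenset({"histone kinase"}), expression_bin="low"),
            ]
        )
        tallies = category_tallies(
            [interaction("mir-1", "Gene0"), interaction("mir-2", "Gene1")], catalog
        )
        by_cat = {t.category: t for t in tallies}
        assert by_cat["histone acetyltransferase"].targeted == 1
        assert by_cat["histone kinase"].targeted == 2
        assert by_cat["histone kinase"].share_of_targets == 100.0

    def test_fraction_against_reference_catalog(self):
        hat = frozenset({"histone acetyltransferase"})
        reference = Catalog(
            [Regulator(f"Gene{i}", hat, expression_bin="low") for i in range(4)]
        )
        catalog = Catalog([Regulator(f"Gene{i}", hat, expression_bin="low") for i in range(2)])
        tallies = category_tallies(
            [interaction("mir-1", "Gene0"), interaction("mir-1", "Gene1")],
            catalog,
            reference_catalog=reference,
        )
        assert tallies[0].catalog_total == 4
        assert tallies[0].fraction_of_catalog == 50.0

    def test_target_missing_from_catalog_is_an_error(self):
        catalog = Catalog(
            [Regulator("Gene0", frozenset({"histone kinase"}), expression_bin="low")]
        )
        with pytest.raises(ValidationError):
            category_tallies([interaction("mir-1", "Other9")], catalog)

    def test_single_category_tallies_sum_to_distinct_targets(self, paper, fixture_consensus):
        # packaged catalog assigns exactly one category per gene
        tallies = category_tallies(fixture_consensus, paper.catalog)
        assert sum(t.targeted for t in tallies) == len(
            {i.gene_symbol for i in fixture_consensus}
        )


class TestDiseaseTally:
    def test_unknown_label_counts_zero(self, paper, fixture_consensus):
        rows = target_summaries(fixture_consensus)
        out = disease_tally(rows, paper.catalog, ["gout"])
        assert out["gout"] == (0, 0.0)

    def test_no_annotations(self):
        catalog = Catalog(
            [Regulator("Gene0", frozenset({"histone kinase"}), expression_bin="low")]
        )
        out = disease_tally([TargetSummary("Gene0", 1, 0)], catalog, ["cardiomyopathy"])
        assert out == {"cardiomyopathy": (0, 0.0), "any": (0, 0.0)}


class TestMinTargets:
    def test_threshold_readings(self):
        interactions = [
            interaction("mir-1", "Gene0"),
            interaction("mir-1", "Gene1"),
            interaction("mir-2", "Gene0"),
        ]
        assert mirnas_with_min_targets(interactions, 2) == (1, 50.0)
        assert mirnas_with_min_targets(interactions, 1) == (2, 100.0)


class TestOverrepresentation:
    def test_matches_exhaustive_enumeration_on_tiny_universe(self):
        universe = {f"g{i}" for i in range(10)}
        targets = {f"g{i}" for i in range(4)}
        annotation = {f"g{i}" for i in range(3)}  # fully inside targets
        result = overrepresentation(targets, {"set": annotation}, universe)[0]
        expected = hypergeometric_tail_by_enumeration(10, 3, 4, result.overlap)
        assert result.overlap == 3
        assert result.p_value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k_min", [1, 2, 3])
    def test_partial_overlaps_match_enumeration(self, k_min):
        universe = {f"g{i}" for i in range(12)}
        annotation = {f"g{i}" for i in range(5)}
        targets = {f"g{i}" for i in range(k_min)} | {f"g{i}" for i in range(8, 12)}
        result = overrepresentation(targets, {"set": annotation}, universe)[0]
        expected = hypergeometric_tail_by_enumeration(12, 5, len(targets), result.overlap)
        assert result.p_value == pytest.approx(expected, abs=1e-12)

    def test_disjoint_annotation_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        result = overrepresentation(
            {"g0", "g1"}, {"set": {"g8", "g9"}}, universe
        )[0]
        assert math.isclose(result.p_value, 1.0, abs_tol=1e-12)

    def test_single_set_bh_identity(self):
        universe = {f"g{i}" for i in range(10)}
        result = overrepresentation({"g0", "g1"}, {"set": {"g0", "g5"}}, universe)[0]
        assert result.adjusted_p == pytest.approx(result.p_value)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation(set(), {}, set())
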