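"""Rearrangement detection, RF/RS statistics and arrangement typing."""

import random

import pytest

from mitocompare import (
    ArrangementType,
    CircularGeneOrder,
    OrderedGene,
    classify_arrangement,
    insect_typical,
    rearranged_genes,
    rearrangement_frequency,
    rearrangement_score,
    trnv_shifted,
)
from mitocompare.errors import IncomparableOrdersError, UnclassifiableOrderError
from mitocompare.gene_order import gryllidea_arrangement, transpose_gene
from mitocompare.vocab import GENES, PCGS


def oracle_statuses(order, ref):
    """Independent brute-force re-derivation of per-gene rearrangement:
    restrict by list filtering, find flanks by explicit modular scan."""
    shared = sorted(set(order.names) & set(ref.names))
    a = [g for g in order.genes if g.name in shared]
    b = [g for g in ref.genes if g.name in shared]

    def flanks(lst, gene):
        idx = [i for i, g in enumerate(lst) if g.name == gene][0]
        return lst[(idx - 1) % len(lst)], lst[(idx + 1) % len(lst)]

    out = {}
    for g in shared:
        (ua, da), (ub, db) = flanks(a, g), flanks(b, g)
        pos = {ua.name, da.name} != {ub.name, db.name}
        strand = [x for x in a if x.name == g][0].strand != [
            x for x in b if x.name == g
        ][0].strand
        out[g] = (pos, strand)
    return out


def random_order(rng, genes):
    perm = list(genes)
    rng.shuffle(perm)
    return CircularGeneOrder(
        tuple(OrderedGene(g, rng.choice("+-")) for g in perm)
    )


class TestRearrangedGenes:
    def test_reference_against_itself_is_all_false(self, ref_order):
        assert all(
            not s.rearranged for s in rearranged_genes(ref_order, ref_order)
        )

    def test_type_ii_inversion_detected_with_strand_changes(self, type_orders):
        by_gene = {s.gene: s for s in rearranged_genes(type_orders["II"], insect_typical)}
        for g in ("trnN", "trnS1", "trnE"):
            assert by_gene[g].rearranged
            assert by_gene[g].strand_changed
        # the middle gene keeps its unordered neighbor pair
        assert not by_gene["trnS1"].position_changed

    def test_type_ivg_moves_trnv_but_not_the_nse_block(self, type_orders):
        by_gene = {s.gene: s for s in rearranged_genes(type_orders["IVG"], insect_typical)}
        assert by_gene["trnV"].position_changed
        for g in ("trnN", "trnS1", "trnE"):
            assert not by_gene[g].rearranged

    def test_too_few_shared_genes_incomparable(self, ref_order):
        tiny = CircularGeneOrder.from_line("COI,CYTB")
        with pytest.raises(IncomparableOrdersError):
            rearranged_genes(tiny, ref_order)

    def test_matches_bruteforce_oracle_on_random_orders(self):
        rng = random.Random(20240915)
        pool = list(GENES)
        for _ in range(60):
            k = rng.randint(4, 15)
            genes = rng.sample(pool, k)
            a, b = random_order(rng, genes), random_order(rng, genes)
            expected = oracle_statuses(a, b)
            got = {s.gene: (s.position_changed, s.strand_changed)
                   for s in rearranged_genes(a, b)}
            assert got == expected


class TestRearrangementFrequency:
    def test_cohort_rf_for_inverted_trnas(self, analytic_cohort):
        report = rearrangement_frequency(analytic_cohort, insect_typical)
        # 30 of 38 genomes (Types II and III) carry the inversion
        for g in ("trnN", "trnS1", "trnE"):
            assert report.rf[g] == 78.94

    def test_cohort_rf_zero_for_all_pcgs(self, analytic_cohort):
        report = rearrangement_frequency(analytic_cohort, insect_typical)
        assert all(report.rf[g] == 0.0 for g in PCGS)

    def test_rf_truncates_rather_than_rounds(self):
        # 2/3 = 66.666... must print as 66.66, not 66.67
        ii = gryllidea_arrangement("II")
        cohort = [ii, ii, insect_typical]
        report = rearrangement_frequency(cohort, insect_typical)
        assert report.rf["trnS1"] == 66.66

    def test_identity_cohort_is_all_zero(self, ref_order):
        report = rearrangement_frequency([ref_order], ref_order)
        assert set(report.rf.values()) == {0.0}
        assert report.cohort_size == 1

    def test_rf_bounds_and_missing_gene_denominator(self, ref_order, type_orders):
        partial = type_orders["II"].restricted(set(GENES) - {"trnE"})
        report = rearrangement_frequency([partial, type_orders["II"]], ref_order)
        assert all(0.0 <= v <= 100.0 for v in report.rf.values())
        # trnE present in only one genome; rearranged there
        assert report.n_present["trnE"] == 1
        assert report.rf["trnE"] == 100.0

    def test_empty_cohort_rejected(self, ref_order):
        with pytest.raises(ValueError):
            rearrangement_frequency([], ref_order)


class TestRearrangementScore:
    def test_self_score_zero(self, ref_order):
        assert rearrangement_score(ref_order, ref_order) == 0.0

    def test_frozen_scores_against_typical_benchmark(self, type_orders):
        """Scores verified against the brute-force neighbor enumeration:
        the inversion costs 4 position + 3 strand changes, the trnV
        transposition 4 position changes."""
        scores = {
            t: rearrangement_score(o, insect_typical) for t, o in type_orders.items()
        }
        assert scores == {"I": 0.0, "II": 7.0, "III": 11.0, "IVG": 4.0}
        for t, o in type_orders.items():
            oracle = sum(
                pos + strand for pos, strand in oracle_statuses(o, insect_typical).values()
            )
            assert scores[t] == oracle

    def test_weights_split_position_and_strand(self, type_orders):
        only_pos = rearrangement_score(type_orders["II"], insect_typical, (1.0, 0.0))
        only_strand = rearrangement_score(type_orders["II"], insect_typical, (0.0, 1.0))
        assert (only_pos, only_strand) == (4.0, 3.0)

    def test_extra_transposition_strictly_increases_score(self, type_orders):
        base = rearrangement_score(type_orders["II"], insect_typical)
        more = transpose_gene(type_orders["II"], "trnD", "CYTB")
        assert rearrangement_score(more, insect_typical) > base

    def test_type_score_ordering_under_shipped_benchmark(self, type_orders):
        """Regression: the arrangement-type score ordering
        II > III > I > IVG under the shipped benchmark and default
        weights. This ordering breaks loudly if the benchmark or the
        scoring convention changes."""
        s = {t: rearrangement_score(o, trnv_shifted) for t, o in type_orders.items()}
        assert s["II"] > s["III"] > s["I"] > s["IVG"]


class TestClassification:
    @pytest.mark.parametrize("label", ["I", "II", "III", "IVG"])
    def test_types_classified_by_their_diagnostic_blocks(self, type_orders, label):
        result = classify_arrangement(type_orders[label])
        assert result.label == ArrangementType(label)

    def test_typical_order_is_type_i(self, ref_order):
        result = classify_arrangement(ref_order)
        assert result.label == ArrangementType.I
        assert not result.nsE_inverted
        assert result.rRNA_block == "16S-trnV-12S"

    def test_evidence_reported_alongside_label(self, type_orders):
        r3 = classify_arrangement(type_orders["III"])
        assert r3.nsE_inverted and r3.rRNA_block == "16S-12S-trnV"
        r4 = classify_arrangement(type_orders["IVG"])
        assert not r4.nsE_inverted and r4.rRNA_block == "16S-12S-trnV"

    def test_rotation_invariant(self, type_orders):
        for label, order in type_orders.items():
            for k in (1, 9, 23, 36):
                assert classify_arrangement(order.rotated(k)).label == ArrangementType(
                    label
                )

    def test_off_block_deviation_is_novel_with_evidence(self, ref_order):
        moved = transpose_gene(ref_order, "trnI", "COI")
        result = classify_arrangement(moved)
        assert result.label == ArrangementType.NOVEL
        assert not result.nsE_inverted
        assert result.rRNA_block == "16S-trnV-12S"

    def test_missing_diagnostic_gene_unclassifiable(self, ref_order):
        partial = ref_order.restricted(set(ref_order.names) - {"trnV"})
        with pytest.raises(UnclassifiableOrderError):
            classify_arrangement(partial)

    def test_cohort_has_exactly_four_equivalence_classes(self, analytic_cohort):
        from mitocompare import orders_equal

        classes = []
        for order in analytic_cohort:
            if not any(orders_equal(order, rep) for rep in classes):
                classes.append(order)
        assert len(classes) == 4
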