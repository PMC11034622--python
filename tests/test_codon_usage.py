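"""RSCU, amino-acid frequencies, numt screening, and NG86 dN/dS."""

import random
from itertools import permutations

import pytest

from mitocompare import (
    INVERTEBRATE_MITO,
    amino_acid_frequencies,
    nei_gojobori,
    numt_screen,
    rscu,
)
from mitocompare.codon_usage import pathway_differences, site_counts
from mitocompare.errors import NumtSuspectError

CODE = INVERTEBRATE_MITO
SENSE = sorted(CODE.family_of)


class TestGeneticCode:
    def test_family_partition_covers_62_sense_codons(self):
        codons = [c for fam in CODE.families.values() for c in fam]
        assert len(codons) == 62 and len(set(codons)) == 62
        assert set(CODE.stop_codons) == {"TAA", "TAG"}

    def test_families_translate_identically_and_split_leu_ser(self):
        for fam, codons in CODE.families.items():
            assert len({CODE.translate(c) for c in codons}) == 1
        assert set(CODE.families["Leu(UUR)"]) == {"TTA", "TTG"}
        assert set(CODE.families["Ser(AGN)"]) == {"AGA", "AGC", "AGG", "AGT"}
        # table 5: AGA/AGG are serine, ATA is methionine, TGA tryptophan
        assert CODE.translate("AGA") == "S"
        assert CODE.translate("ATA") == "M"
        assert CODE.translate("TGA") == "W"


class TestRSCU:
    def test_uniform_two_codon_family(self):
        # Asp family GAT/GAC used 10:10
        table = rscu(["GATGAC" * 10])
        assert table.rscu["GAT"] == pytest.approx(1.0)
        assert table.rscu["GAC"] == pytest.approx(1.0)

    def test_exclusive_two_codon_family(self):
        table = rscu(["GAT" * 20])
        assert table.rscu["GAT"] == pytest.approx(2.0)
        assert table.rscu["GAC"] == 0.0

    def test_stop_codons_and_ambiguous_codons_not_counted(self):
        table = rscu(["ATGTAA", "ATNGAT"])
        assert sum(table.counts.values()) == 2  # ATG and GAT only
        assert table.counts["ATG"] == 1

    def test_family_sums_conserved_on_random_input(self):
        rng = random.Random(4242)
        for _ in range(20):
            cds = "".join(rng.choices(SENSE, k=rng.randint(30, 120)))
            table = rscu([cds])
            for fam, codons in CODE.families.items():
                if table.family_totals[fam] > 0:
                    assert sum(table.rscu[c] for c in codons) == pytest.approx(
                        len(codons)
                    )
                else:
                    assert all(table.rscu[c] == 0.0 for c in codons)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rscu([])


class TestAminoAcidFrequencies:
    def test_single_cds_example(self):
        # ATG TTA TAA -> Met, Leu(UUR), stop dropped
        freqs = amino_acid_frequencies(["ATGTTATAA"])
        assert freqs["Met"] == pytest.approx(50.0)
        assert freqs["Leu(UUR)"] == pytest.approx(50.0)

    def test_frequencies_sum_to_100(self):
        rng = random.Random(7)
        cds = "".join(rng.choices(SENSE, k=300))
        assert sum(amino_acid_frequencies([cds]).values()) == pytest.approx(100.0)


class TestNumtScreen:
    def test_clean_cds_passes(self, sim_genome):
        from mitocompare import extract_gene_sequence
        from mitocompare.vocab import PCGS

        for gene in PCGS:
            cds = extract_gene_sequence(sim_genome, gene)
            assert numt_screen(cds) == []

    def test_internal_stop_position_reported(self):
        cds = "ATG" + "AAA" * 4 + "TAA" + "AAA" * 94 + "TAA"
        assert numt_screen(cds) == [5]

    def test_final_stop_not_reported(self):
        assert numt_screen("ATGAAATAA") == []

    def test_frameshift_detection_rate(self, sim_genome):
        """A +1 frameshift of a long clean CDS almost always creates an
        internal stop under the AT-rich composition."""
        from mitocompare import extract_gene_sequence
        from mitocompare.vocab import PCGS

        long_genes = [
            g for g in PCGS
            if sim_genome.feature(g).length >= 300
        ]
        hits = sum(
            bool(numt_screen(extract_gene_sequence(sim_genome, g)[1:]))
            for g in long_genes
        )
        assert hits / len(long_genes) >= 0.95


def mutated_pair(rng, n_codons, n_subs):
    """A random CDS and a copy with a few codons substituted (kept far
    from saturation so the distance correction stays defined)."""
    codons = rng.choices(SENSE, k=n_codons)
    other = list(codons)
    for i in rng.sample(range(n_codons), n_subs):
        other[i] = rng.choice(SENSE)
    return "".join(codons), "".join(other)


def oracle_site_counts(codon):
    """Definition-level recount: per position, the fraction of the three
    alternative bases giving a synonymous, non-stop codon."""
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut not in CODE.stop_codons and CODE.translate(mut) == CODE.translate(codon):
                syn += 1 / 3
    return syn, 3 - syn


def oracle_pathway_diffs(c1, c2):
    """Exhaustive pathway enumeration written independently: walk every
    ordering of the differing positions, skipping stop-crossing paths."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        cur, steps, ok = c1, [], True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in CODE.stop_codons and nxt != c2:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        results.append((ok, steps))
    usable = [s for ok, s in results if ok] or [s for _, s in results]
    syn = sum(
        sum(1 for a, b in steps
            if a not in CODE.stop_codons and b not in CODE.stop_codons
            and CODE.translate(a) == CODE.translate(b))
        for steps in usable
    )
    total = sum(len(steps) for steps in usable)
    return syn / len(usable), (total - syn) / len(usable)


class TestNeiGojobori:
    def test_identical_sequences(self):
        r = nei_gojobori("ATGAAACCC", "ATGAAACCC")
        assert r.dn == r.ds == 0.0
        assert r.z_statistic == 0.0
        assert r.n_sites + r.s_sites == pytest.approx(9.0)

    def test_synonymous_change_gives_ds_only(self):
        r = nei_gojobori("ATGGGATTTAAACCTGAT", "ATGGGATTTAAACCTGAC")
        assert r.dn == 0.0 and r.ds > 0.0

    def test_nonsynonymous_change_gives_dn_only(self):
        r = nei_gojobori("ATGGGATTTAAACCTGAT", "ATGGGATTTAAACCTAAT")
        assert r.ds == 0.0 and r.dn > 0.0

    def test_symmetry(self):
        rng = random.Random(3)
        for _ in range(5):
            a, b = mutated_pair(rng, 30, 4)
            ra = nei_gojobori(a, b, seed=1)
            rb = nei_gojobori(b, a, seed=1)
            assert ra.n_sites == pytest.approx(rb.n_sites)
            assert ra.pn == pytest.approx(rb.pn)
            assert ra.ps == pytest.approx(rb.ps)

    def test_sites_total_three_per_codon(self):
        rng = random.Random(13)
        a, b = mutated_pair(rng, 50, 6)
        r = nei_gojobori(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.n_codons)

    def test_internal_stop_is_numt_suspect_error(self):
        with pytest.raises(NumtSuspectError):
            nei_gojobori("ATGTAAAAAGAT", "ATGAAAAAAGAT")

    def test_gap_columns_complete_deleted(self):
        r = nei_gojobori("ATG---GGAGAT", "ATGAAAGGAGAC")
        assert r.n_codons == 3

    def test_site_counts_match_definition_for_all_codons(self):
        for codon in SENSE:
            s, n = site_counts(codon, CODE)
            es, en = oracle_site_counts(codon)
            assert s == pytest.approx(es, abs=1e-9)
            assert n == pytest.approx(en, abs=1e-9)

    def test_pathway_differences_match_oracle_for_all_pairs(self):
        for c1 in SENSE:
            for c2 in SENSE:
                sd, nd = pathway_differences(c1, c2, CODE)
                esd, end_ = oracle_pathway_diffs(c1, c2)
                assert sd == pytest.approx(esd, abs=1e-9), (c1, c2)
                assert nd == pytest.approx(end_, abs=1e-9), (c1, c2)

    def test_bootstrap_z_is_seed_deterministic(self):
        rng = random.Random(8)
        a, b = mutated_pair(rng, 60, 8)
        r1 = nei_gojobori(a, b, seed=5, n_bootstrap=300)
        r2 = nei_gojobori(a, b, seed=5, n_bootstrap=300)
        assert r1.z_statistic == r2.z_statistic
        assert 0.0 <= r1.p_value <= 1.0
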