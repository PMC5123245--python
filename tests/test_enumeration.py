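"""Coding-space classification against independent brute-force oracles."""

import pytest
from Bio.Seq import Seq

from mtanno import GeneLocus, classify_substitution, enumerate_coding_space
from mtanno.enumeration import (
    ReferenceIntegrityError,
    reverse_complement,
    translate_codon,
)
from mtanno.fixtures import generate_toy_genome


def brute_force_effect(coding: str, off0: int, alt: str) -> str:
    """Mutate the raw coding string and re-translate the whole protein."""
    ref_prot = str(Seq(coding).translate(table=2))
    mut_prot = str(Seq(coding[:off0] + alt + coding[off0 + 1:]).translate(table=2))
    i = off0 // 3
    ref_aa, alt_aa = ref_prot[i], mut_prot[i]
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_loss"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


class TestClassifySubstitution:
    @pytest.mark.parametrize("codon", ["TAT", "TTT", "TAA", "TGG", "ATA", "AGA"])
    def test_all_nine_substitutions_match_oracle(self, codon):
        genome = "ATG" + codon + "TAA"
        gene = GeneLocus("G", 1, 9, "H", "protein_coding")
        for cp in range(3):
            off0 = 3 + cp
            for alt in "ACGT":
                if alt == codon[cp]:
                    continue
                rec = classify_substitution(gene, off0 + 1, alt, genome)
                assert rec.effect == brute_force_effect(genome, off0, alt)
                assert rec.codon_index == 2 and rec.codon_pos == cp + 1

    def test_tat_third_position_stop_gain(self):
        genome = "TATTAA"
        gene = GeneLocus("G", 1, 6, "H", "protein_coding")
        rec = classify_substitution(gene, 3, "A", genome)
        assert rec.effect == "stop_gain" and rec.alt_codon == "TAA"

    def test_ttt_never_stop_gain(self):
        genome = "TTTTAA"
        gene = GeneLocus("G", 1, 6, "H", "protein_coding")
        effects = {classify_substitution(gene, p, a, genome).effect
                   for p in (1, 2, 3) for a in "ACGT" if a != "T"}
        assert "stop_gain" not in effects

    def test_stop_codon_first_position_stop_loss(self):
        genome = "ATGTAA"
        gene = GeneLocus("G", 1, 6, "H", "protein_coding")
        rec = classify_substitution(gene, 4, "C", genome)
        assert rec.effect == "stop_loss"
        assert translate_codon("CAA") == "Q"

    def test_mito_code_specifics(self):
        assert translate_codon("TGA") == "W"
        assert translate_codon("ATA") == "M"
        assert translate_codon("AGA") == "*" and translate_codon("AGG") == "*"

    def test_reference_mismatch_raises(self):
        gene = GeneLocus("G", 1, 6, "H", "protein_coding")
        with pytest.raises(ValueError):
            classify_substitution(gene, 2, "T", "ATGTAA")  # alt == ref

    def test_incomplete_terminal_codon_not_silently_classified(self):
        gene = GeneLocus("G", 1, 7, "H", "protein_coding")
        with pytest.raises(ValueError):
            classify_substitution(gene, 7, "C", "ATGTAAT")


class TestEnumerate:
    def test_synthetic_gene_counts_match_brute_force(self):
        genome = "ATGTATTAA" + "CCCCC"
        gene = GeneLocus("G1", 1, 9, "H", "protein_coding")
        bundle = _mini_bundle([gene], genome)
        result = enumerate_coding_space(bundle, genome)
        assert sum(result.counts.values()) == 27
        expected = {"synonymous": 0, "nonsynonymous": 0, "stop_gain": 0,
                    "stop_loss": 0}
        for off0 in range(9):
            for alt in "ACGT":
                if alt == genome[off0]:
                    continue
                expected[brute_force_effect(genome[:9], off0, alt)] += 1
        assert result.counts == expected

    def test_zero_gene_map_all_zero(self):
        bundle = _mini_bundle([], "ATGC" * 10)
        result = enumerate_coding_space(bundle, "ATGC" * 10)
        assert sum(result.counts.values()) == 0

    def test_missing_reference_rejected(self, toy_bundle):
        with pytest.raises(ValueError):
            enumerate_coding_space(toy_bundle, "")

    @pytest.mark.parametrize("seed", range(8))
    def test_toy_genomes_match_oracle(self, seed):
        truth = generate_toy_genome(seed, n_genes=3, codons_per_gene=5 + seed % 4)
        bundle = truth.bundle()
        result = enumerate_coding_space(bundle, truth.genome)
        got = {(r.gene, r.pos, r.alt): r.effect for r in result.records}
        want = {(g, pos, alt): eff
                for g, table in truth.effects.items()
                for (pos, alt), eff in table.items()}
        assert got == want

    def test_conservation_partition(self, toy, toy_bundle):
        result = enumerate_coding_space(toy_bundle, toy.genome)
        for gene in toy_bundle.loci_by_biotype("protein_coding"):
            in_frame = 3 * (gene.length(len(toy.genome)) // 3)
            assert sum(result.per_gene[gene.name].values()) == 3 * in_frame

    def test_strand_metamorphic(self):
        # classifying an L-strand gene equals re-annotating the
        # reverse-complemented genome with the mirrored H-strand locus
        truth = generate_toy_genome(11, n_genes=2, codons_per_gene=6)
        genome = truth.genome
        n = len(genome)
        l_genes = [g for g in truth.gene_map
                   if g.biotype == "protein_coding" and g.strand == "L"]
        assert l_genes
        for g in l_genes:
            rc = reverse_complement(genome)
            mirrored = GeneLocus(g.name, n - g.end + 1, n - g.start + 1, "H",
                                 "protein_coding")
            fwd = enumerate_coding_space(_mini_bundle([g], genome), genome)
            mir = enumerate_coding_space(_mini_bundle([mirrored], rc), rc)
            assert fwd.counts == mir.counts

    def test_overlapping_genes_classified_per_frame(self):
        truth = generate_toy_genome(3, n_genes=2, codons_per_gene=7,
                                    overlapping_pair=True)
        bundle = truth.bundle()
        result = enumerate_coding_space(bundle, truth.genome)
        per_site = {}
        for r in result.records:
            per_site.setdefault((r.pos, r.alt), set()).add(r.gene)
        multi = [k for k, genes in per_site.items() if len(genes) > 1]
        assert multi  # overlap positions appear once per gene context
        dedup_total = sum(result.counts_dedup.values())
        assert dedup_total == len(per_site)

    def test_incomplete_stop_convention(self):
        # 7-nt gene: two full codons plus a trailing T completed by polyA
        genome = "ATGTATT" + "CCC"
        gene = GeneLocus("G", 1, 7, "H", "protein_coding")
        bundle = _mini_bundle([gene], genome)
        base = enumerate_coding_space(bundle, genome)
        assert sum(base.counts.values()) == 18
        inc = enumerate_coding_space(bundle, genome, include_incomplete_stops=True)
        assert sum(inc.counts.values()) == 21


def _mini_bundle(genes, genome):
    from mtanno.reference import ReferenceBundle

    return ReferenceBundle(genes, {}, (), {}, {},
                           {"schema_version": 1, "genome_length": len(genome),
                            "passthrough_columns": []})
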