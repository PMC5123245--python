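"""Synthetic reference data with embedded ground truth.

Everything the annotation, enumeration and track modules consume can be
generated here deterministically from a single integer seed: tRNA structure
maps of any of the four structural classes, toy circular genomes carrying
coding genes on both strands, and variant lists with expected annotations.
Ground truth is computed by deliberately simple, independent code paths
(raw alignment lookup; string mutation plus whole-protein re-translation via
Bio.Seq), never by the modules under test, and fixtures serialize to the
production bundle format so tests exercise the real loaders.

The generators default to uniform base composition; ``at_rich=True``
re-weights the transcript alphabet toward A/U/C, mimicking the strong
light-strand nucleotide bias of real mt-tRNAs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq

from .reference import GeneLocus, ReferenceBundle, RnaPathoRecord, TrnaStructureMap
from .scoring import SCHEMES, normalize_score
from .trna import (
    D_STEM_SPRINZL,
    build_structure_map,
    canonical_domains,
    tertiary_groups_for_type,
)
from .variants import Variant


class GenerationError(ValueError):
    pass


# Sprinzl positions that may be dropped without touching the anticodon loop
# or any tertiary-interaction member
_DELETABLE = (16, 17, 20, 21, 47, 59, 60)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_trna_map(
    seed: int,
    trna_type: str = "0",
    gap_count: int = 0,
    gene: str = "SYN-T1",
    at_rich: bool = False,
):
    """A valid synthetic structure map plus its raw alignment oracle table.

    Returns ``(TrnaStructureMap, raw_table)`` where the raw table is a list
    of ``(offset, sprinzl, domain, mature_nt, folding)`` tuples computed
    directly from the alignment, independent of the production builder.
    """
    rng = random.Random(seed)
    removed: set[int] = set()
    if trna_type == "III":
        removed |= set(D_STEM_SPRINZL)
    pool = [n for n in _DELETABLE if n not in removed]
    if gap_count < 0 or gap_count > len(pool):
        raise GenerationError(
            f"gap_count {gap_count} infeasible (at most {len(pool)} deletable positions)")
    if 73 - len(removed) - gap_count < 60:
        raise GenerationError("gap_count leaves fewer than 60 mapped positions")
    removed |= set(rng.sample(pool, gap_count))

    sprinzl_seq = [n for n in range(1, 74) if n not in removed]
    alignment = [(i + 1, s) for i, s in enumerate(sprinzl_seq)]
    alphabet = "AAUUCCG" if at_rich else "ACGU"
    transcript = "".join(rng.choice(alphabet) for _ in alignment)
    groups = tertiary_groups_for_type(trna_type)
    struct = build_structure_map(gene, trna_type, alignment, transcript,
                                 tertiary=groups, species=gene)

    domains = canonical_domains()
    mapped = set(sprinzl_seq)
    folded = {n for g in groups if g <= mapped for n in g}
    raw_table = [(off, s, domains[s], transcript[off - 1], s in folded)
                 for off, s in alignment]
    return struct, raw_table


def _random_cds(rng: random.Random, n_codons: int) -> str:
    stops = set(("TAA", "TAG", "AGA", "AGG"))
    codons = [rng.choice(("ATG", "ATA"))]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(rng.choice("ACGT") for _ in range(3))
            if c not in stops:
                break
        codons.append(c)
    codons.append(rng.choice(sorted(stops)))
    return "".join(codons)


def _oracle_effects(gene: GeneLocus, genome: str) -> dict[tuple[int, str], str]:
    """(genomic pos, genomic alt) -> effect, by mutate-and-retranslate."""
    n = len(genome)
    if gene.strand == "H":
        coding = genome[gene.start - 1:gene.end]
    else:
        coding = str(Seq(genome[gene.start - 1:gene.end]).reverse_complement())
    prot_ref = str(Seq(coding).translate(table=2))
    out: dict[tuple[int, str], str] = {}
    n_codons = len(coding) // 3
    for off0 in range(3 * n_codons):
        for coding_alt in "ACGT":
            if coding_alt == coding[off0]:
                continue
            mutated = coding[:off0] + coding_alt + coding[off0 + 1:]
            prot_alt = str(Seq(mutated).translate(table=2))
            idx = off0 // 3
            ref_aa, alt_aa = prot_ref[idx], prot_alt[idx]
            if ref_aa != "*" and alt_aa == "*":
                effect = "stop_gain"
            elif ref_aa == "*" and alt_aa != "*":
                effect = "stop_loss"
            elif ref_aa == alt_aa:
                effect = "synonymous"
            else:
                effect = "nonsynonymous"
            if gene.strand == "H":
                pos = gene.start + off0
                alt = coding_alt
            else:
                pos = gene.end - off0
                alt = coding_alt.translate(_COMPLEMENT)
            out[(pos, alt)] = effect
    return out


@dataclass
class SyntheticTruth:
    """A toy circular genome with its complete ground truth."""

    seed: int
    genome: str
    gene_map: tuple[GeneLocus, ...]
    structure_maps: dict[str, TrnaStructureMap]
    raw_alignments: dict[str, list]
    effects: dict[str, dict[tuple[int, str], str]]  # gene -> (pos, alt) -> effect
    rna_patho: dict[tuple[int, str, str], RnaPathoRecord]

    def bundle(self) -> ReferenceBundle:
        manifest = {
            "schema_version": 1,
            "genome_length": len(self.genome),
            "seqid": "chrM",
            "passthrough_columns": [],
            "provenance": f"synthetic fixture, seed={self.seed}",
        }
        bundle = ReferenceBundle(self.gene_map, self.structure_maps, (),
                                 self.rna_patho, {}, manifest)
        bundle.validate()
        return bundle

    def save_bundle(self, dir_path) -> None:
        self.bundle().save(dir_path)

    def save_genome(self, path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(">chrM synthetic circular toy genome\n")
            for i in range(0, len(self.genome), 70):
                fh.write(self.genome[i:i + 70] + "\n")


def generate_toy_genome(
    seed: int,
    n_genes: int = 2,
    codons_per_gene: int = 8,
    n_trnas: int = 2,
    at_rich: bool = False,
    overlapping_pair: bool = False,
) -> SyntheticTruth:
    """A circular toy genome with coding genes on both strands plus tRNAs.

    Coding genes start ATG/ATA and end in a vertebrate-mitochondrial stop;
    per-substitution effect classes are pre-computed by the string-mutation
    oracle.  With ``overlapping_pair`` the first two genes overlap by four
    bases in different frames, exercising per-frame classification.
    """
    if n_genes < 1:
        raise GenerationError("n_genes must be >= 1")
    if codons_per_gene < 2:
        raise GenerationError("codons_per_gene must be >= 2")
    rng = random.Random(seed)

    pieces: list[str] = []
    loci: list[GeneLocus] = []
    structures: dict[str, TrnaStructureMap] = {}
    raw_alignments: dict[str, list] = {}
    cursor = 1

    def spacer():
        nonlocal cursor
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 15)))
        pieces.append(s)
        cursor += len(s)

    spacer()
    for i in range(n_genes):
        cds = _random_cds(rng, codons_per_gene)
        strand = "H" if i % 2 == 0 else "L"
        segment = cds if strand == "H" else str(Seq(cds).reverse_complement())
        start = cursor
        pieces.append(segment)
        loci.append(GeneLocus(f"GENE{i + 1}", start, start + len(cds) - 1,
                              strand, "protein_coding"))
        cursor += len(segment)
        spacer()

    if overlapping_pair:
        # an extra frame-shifted reading frame over the tail of gene 1:
        # positions inside the overlap are classified once per gene context
        g1 = loci[0]
        shift = 4
        ovl_len = 3 * ((g1.end - g1.start + 1 - shift) // 3)
        if ovl_len >= 3:
            loci.append(GeneLocus("GENE1OVL", g1.start + shift,
                                  g1.start + shift + ovl_len - 1, "H",
                                  "protein_coding"))

    for j in range(n_trnas):
        trna_type = ("0", "II", "I", "III")[j % 4]
        name = f"SYN-T{j + 1}"
        gaps = rng.randint(0, 3)
        struct, raw = generate_trna_map(rng.randrange(2 ** 31), trna_type, gaps,
                                        gene=name, at_rich=at_rich)
        transcript_dna = "".join(p.mature_nt for p in struct.positions)
        # synthetic maps carry no modifications, so mature bases are plain
        transcript_dna = transcript_dna.replace("U", "T")
        strand = "H" if j % 2 == 0 else "L"
        segment = (transcript_dna if strand == "H"
                   else str(Seq(transcript_dna).reverse_complement()))
        start = cursor
        pieces.append(segment)
        loci.append(GeneLocus(name, start, start + len(segment) - 1, strand, "tRNA"))
        structures[name] = struct
        raw_alignments[name] = raw
        cursor += len(segment)
        spacer()

    genome = "".join(pieces)
    if len(genome) < 20:
        raise GenerationError("genome too small for the requested gene content")

    effects = {g.name: _oracle_effects(g, genome)
               for g in loci if g.biotype == "protein_coding"}

    # a few scored RNA variants inside the synthetic tRNAs
    rna_patho: dict[tuple[int, str, str], RnaPathoRecord] = {}
    trna_loci = [g for g in loci if g.biotype == "tRNA"]
    for g in trna_loci[:2]:
        for _ in range(2):
            pos = rng.randint(g.start, g.end)
            ref = genome[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            raw_score = rng.randint(0, 20)
            rec = RnaPathoRecord(
                pos, ref, alt, "tRNA", raw_score,
                normalize_score(raw_score, SCHEMES["tRNA"]),
                SCHEMES["tRNA"].label_map[raw_score], "synthetic-fixture")
            rna_patho[(pos, ref, alt)] = rec

    return SyntheticTruth(seed, genome, tuple(loci), structures,
                          raw_alignments, effects, rna_patho)


@dataclass(frozen=True)
class VariantExpectation:
    """A generated variant with its independently derived expected row."""

    variant: Variant
    loci: tuple[str, ...]
    trna_annotation: str  # five-field string, or "" outside tRNA genes
    effects: dict  # gene -> expected coding effect (may be empty)


def _expected_for(pos: int, alt: str, truth: SyntheticTruth) -> VariantExpectation:
    # brute-force interval scan, independent of ReferenceBundle.loci_at
    hits = tuple(sorted((g for g in truth.gene_map if
                         (g.start <= pos <= g.end if not g.wraps
                          else pos >= g.start or pos <= g.end)),
                        key=lambda g: (g.start, g.end, g.name)))
    annotation = ""
    trna_hits = [g for g in hits if g.biotype == "tRNA"]
    if trna_hits:
        g = trna_hits[0]
        off = pos - g.start + 1 if g.strand == "H" else g.end - pos + 1
        struct = truth.structure_maps[g.name]
        for off2, sprinzl, domain, base, folding in truth.raw_alignments[g.name]:
            if off2 == off:
                annotation = ";".join([
                    "-" if sprinzl is None else str(sprinzl),
                    struct.trna_type, domain, base, "Y" if folding else "N"])
                break
    effects = {g.name: truth.effects[g.name][(pos, alt)]
               for g in hits
               if g.biotype == "protein_coding" and (pos, alt) in truth.effects[g.name]}
    ref = truth.genome[pos - 1]
    return VariantExpectation(Variant(pos, ref, alt), tuple(g.name for g in hits),
                              annotation, effects)


def generate_variants(seed: int, truth: SyntheticTruth, n: int,
                      region: str = "any") -> list[VariantExpectation]:
    """Sample ``n`` distinct-site substitutions with expected annotations.

    ``region`` restricts sampling: ``"tRNA"``, ``"coding"``, ``"intergenic"``
    or ``"any"``.
    """
    rng = random.Random(seed)
    in_gene: dict[int, set[str]] = {}
    for g in truth.gene_map:
        for pos in range(g.start, g.end + 1):
            in_gene.setdefault(pos, set()).add(g.biotype)
    candidates = []
    for pos in range(1, len(truth.genome) + 1):
        biotypes = in_gene.get(pos, set())
        if region == "tRNA" and "tRNA" not in biotypes:
            continue
        if region == "coding" and "protein_coding" not in biotypes:
            continue
        if region == "intergenic" and biotypes:
            continue
        candidates.append(pos)
    if n > len(candidates):
        raise GenerationError(
            f"requested {n} variants but only {len(candidates)} distinct sites available")
    sites = rng.sample(candidates, n)
    out = []
    for pos in sorted(sites):
        ref = truth.genome[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        out.append(_expected_for(pos, alt, truth))
    return out
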