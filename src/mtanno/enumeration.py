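"""Exhaustive enumeration of the mtDNA protein-coding mutational space.

Every in-frame coding position admits three single-nucleotide substitutions;
each is classified as synonymous, nonsynonymous, stop-gain or stop-loss
under the vertebrate mitochondrial genetic code (UGA=Trp, AUA=Met, AGA/AGG
stop — the only code table that reproduces mitochondrial stop-gain counts).
Genes transcribed from the complementary strand are handled through the
strand flag of their locus, never by name.  Positions shared by overlapping
genes are classified once per reading frame; de-duplication by
(position, ref, alt) is a reporting option.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .reference import GeneLocus, ReferenceBundle

#: NCBI translation table 2.
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

EFFECTS = ("synonymous", "nonsynonymous", "stop_gain", "stop_loss")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = ("A", "C", "G", "T")


class ReferenceIntegrityError(ValueError):
    """The supplied reference sequence contradicts a gene model or allele."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str, code: CodonTable.CodonTable = MITO_TABLE) -> str:
    """Amino acid for ``codon``, ``*`` for a stop."""
    codon = codon.upper()
    if codon in code.stop_codons:
        return "*"
    return code.forward_table[codon]


@dataclass(frozen=True)
class CodingSubstitution:
    """One classified single-nucleotide substitution in a coding gene.

    ``ref``/``alt`` are reference-strand (genomic) bases; ``ref_codon`` /
    ``alt_codon`` are in the gene's coding orientation.
    """

    gene: str
    pos: int
    ref: str
    alt: str
    codon_index: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    effect: str


def gene_sequence(gene: GeneLocus, ref_seq: str, genome_length: Optional[int] = None) -> str:
    """Coding-orientation sequence of ``gene`` from the circular genome."""
    n = genome_length or len(ref_seq)
    seq = "".join(ref_seq[(gene.position_at(off, n) - 1) % n]
                  for off in range(1, gene.length(n) + 1)
                  ) if gene.strand == "L" or gene.wraps else ref_seq[gene.start - 1:gene.end]
    if gene.strand == "L":
        # position_at already walks end->start; bases still need complementing
        seq = seq.translate(_COMPLEMENT)
    return seq.upper()


def classify_substitution(
    gene: GeneLocus,
    pos: int,
    alt: str,
    ref_seq: str,
    code: CodonTable.CodonTable = MITO_TABLE,
    genome_length: Optional[int] = None,
) -> CodingSubstitution:
    """Classify the substitution of ``alt`` at genomic position ``pos``.

    ``alt`` is a reference-strand base; for L-strand genes the coding codon
    is built from complemented bases.  Raises
    :class:`ReferenceIntegrityError` on a reference/model mismatch and
    ``ValueError`` when the position falls in an incomplete terminal codon
    (callers decide the convention; nothing is dropped silently here).
    """
    n = genome_length or len(ref_seq)
    if not gene.contains(pos):
        raise ValueError(f"position {pos} not inside {gene.name}")
    alt = alt.upper()
    if alt not in _BASES:
        raise ValueError(f"bad alternate base {alt!r}")
    ref = ref_seq[pos - 1].upper()
    if ref not in _BASES:
        raise ReferenceIntegrityError(f"reference base {ref!r} at {pos} is not ACGT")
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref} at {pos}")

    offset = gene.offset_of(pos, n)  # 1-based along coding direction
    codon_index = (offset - 1) // 3 + 1
    codon_pos = (offset - 1) % 3 + 1
    if codon_index > gene.length(n) // 3:
        raise ValueError(
            f"position {pos} lies in the incomplete terminal codon of {gene.name}")

    first = (codon_index - 1) * 3 + 1
    ref_codon = "".join(
        ref_seq[(gene.position_at(first + k, n) - 1) % n].upper() for k in range(3))
    coding_ref, coding_alt = ref, alt
    if gene.strand == "L":
        ref_codon = ref_codon.translate(_COMPLEMENT)
        coding_ref, coding_alt = complement(ref), complement(alt)
    if ref_codon[codon_pos - 1] != coding_ref:
        raise ReferenceIntegrityError(
            f"{gene.name} codon {codon_index} has {ref_codon[codon_pos - 1]} at "
            f"codon position {codon_pos}, expected {coding_ref}")
    alt_codon = (ref_codon[:codon_pos - 1] + coding_alt + ref_codon[codon_pos:])

    ref_aa = translate_codon(ref_codon, code)
    alt_aa = translate_codon(alt_codon, code)
    if ref_aa != "*" and alt_aa == "*":
        effect = "stop_gain"
    elif ref_aa == "*" and alt_aa != "*":
        effect = "stop_loss"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return CodingSubstitution(gene.name, pos, ref, alt, codon_index, codon_pos,
                              ref_codon, alt_codon, effect)


@dataclass
class EnumerationResult:
    """Effect-partitioned coding mutational space plus summary counts."""

    records: tuple[CodingSubstitution, ...]
    counts: dict[str, int]                  # per-gene-context records
    counts_dedup: dict[str, int]            # unique (pos, ref, alt)
    per_gene: dict[str, dict[str, int]]
    include_incomplete_stops: bool

    def summary(self) -> dict:
        return {
            "effects_per_gene_context": dict(self.counts),
            "effects_deduplicated_by_site": dict(self.counts_dedup),
            "per_gene": {g: dict(c) for g, c in self.per_gene.items()},
            "include_incomplete_stops": self.include_incomplete_stops,
            "n_records": len(self.records),
        }


def enumerate_coding_space(
    bundle: ReferenceBundle,
    ref_seq: str,
    include_incomplete_stops: bool = False,
    code: CodonTable.CodonTable = MITO_TABLE,
) -> EnumerationResult:
    """Classify all three alternates at every in-frame coding position.

    Incomplete terminal codons (stops completed by polyadenylation) are
    excluded by default; with ``include_incomplete_stops`` the trailing
    partial codon is A-padded to length three and enumerated over its
    gene-encoded positions.
    """
    if not ref_seq:
        raise ValueError("reference sequence is required for enumeration")
    n = len(ref_seq)
    records: list[CodingSubstitution] = []
    per_gene: dict[str, Counter] = {}
    for gene in bundle.loci_by_biotype("protein_coding"):
        length = gene.length(n)
        if length > n:
            raise ReferenceIntegrityError(
                f"gene model {gene.name} longer than reference ({length} > {n})")
        gene_counter = per_gene.setdefault(gene.name, Counter())
        full = 3 * (length // 3)
        for off in range(1, full + 1):
            pos = gene.position_at(off, n)
            ref = ref_seq[pos - 1].upper()
            for alt in _BASES:
                if alt == ref:
                    continue
                rec = classify_substitution(gene, pos, alt, ref_seq, code, n)
                records.append(rec)
                gene_counter[rec.effect] += 1
        if include_incomplete_stops and length % 3:
            tail = gene_sequence(gene, ref_seq, n)[full:]
            pad = tail + "A" * (3 - len(tail))
            for k, base in enumerate(tail):
                off = full + 1 + k
                pos = gene.position_at(off, n)
                ref = ref_seq[pos - 1].upper()
                for alt in _BASES:
                    if alt == ref:
                        continue
                    coding_alt = complement(alt) if gene.strand == "L" else alt
                    alt_codon = pad[:k] + coding_alt + pad[k + 1:]
                    ref_aa = translate_codon(pad, code)
                    alt_aa = translate_codon(alt_codon, code)
                    if ref_aa != "*" and alt_aa == "*":
                        effect = "stop_gain"
                    elif ref_aa == "*" and alt_aa != "*":
                        effect = "stop_loss"
                    elif ref_aa == alt_aa:
                        effect = "synonymous"
                    else:
                        effect = "nonsynonymous"
                    rec = CodingSubstitution(gene.name, pos, ref, alt,
                                             length // 3 + 1, k + 1, pad,
                                             alt_codon, effect)
                    records.append(rec)
                    gene_counter[rec.effect] += 1

    counts = Counter(r.effect for r in records)
    best: dict[tuple[int, str, str], str] = {}
    for r in records:  # first gene context wins for the de-duplicated view
        best.setdefault((r.pos, r.ref, r.alt), r.effect)
    counts_dedup = Counter(best.values())
    return EnumerationResult(
        records=tuple(records),
        counts={e: counts.get(e, 0) for e in EFFECTS},
        counts_dedup={e: counts_dedup.get(e, 0) for e in EFFECTS},
        per_gene={g: {e: c.get(e, 0) for e in EFFECTS} for g, c in per_gene.items()},
        include_incomplete_stops=include_incomplete_stops,
    )
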