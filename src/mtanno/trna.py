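"""Five-field structural annotation of tRNA gene positions.

Every position of a mitochondrial tRNA gene is annotated with
``sprinzl;type;domain;mature;folding`` — the Sprinzl structural number
(1-73, CCA end excluded, ``-`` if the position has no counterpart in the
standard numbering), the structural class of the tRNA (0/I/II/III), the
cloverleaf domain, the mature (post-transcriptionally modified) nucleotide
and a Y/N flag for participation in tertiary pair/triplet interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .reference import (
    ANTICODON_SPRINZL,
    GENE_TO_SPECIES,
    GeneLocus,
    ModificationRecord,
    ReferenceBundle,
    TRNA_DOMAINS,
    TRNA_TYPES,
    TrnaPositionRecord,
    TrnaStructureMap,
)


class StructureBuildError(ValueError):
    """Raised when a structure map cannot be built from its raw inputs."""


class DataIntegrityError(RuntimeError):
    """A bundled map fails to cover a position it must cover."""


class AnnotationFormatError(ValueError):
    """A five-field annotation string cannot be formatted or parsed."""


#: Canonical cloverleaf domain layout over Sprinzl numbers 1-73:
#: acceptor stem 1-7 / 66-72, junctions 8-9 and 26, D stem 10-13 / 22-25,
#: D loop 14-21, anticodon stem 27-31 / 39-43, anticodon loop 32-38
#: (anticodon triplet at 34-36), variable loop 44-48, T stem 49-53 / 61-65,
#: T loop 54-60, discriminator/3' end 73.
_CANONICAL_RANGES = (
    (1, 7, "AS"), (8, 9, "-"), (10, 13, "DS"), (14, 21, "DL"),
    (22, 25, "DS"), (26, 26, "-"), (27, 31, "CS"), (32, 38, "CL"),
    (39, 43, "CS"), (44, 48, "VL"), (49, 53, "TS"), (54, 60, "TL"),
    (61, 65, "TS"), (66, 72, "AS"), (73, 73, "E"),
)


def canonical_domains() -> dict[int, str]:
    """Sprinzl number -> cloverleaf domain for the canonical layout."""
    out = {}
    for lo, hi, dom in _CANONICAL_RANGES:
        for n in range(lo, hi + 1):
            out[n] = dom
    return out


#: Tertiary pair/triplet interactions stabilizing the L-shaped fold, in
#: Sprinzl numbering: the three triplets (10-25-45, 9-23-12, 13-22-46) and
#: the classic pairs 8-14, 15-48, 26-44 and 54-58.  The D-loop/T-loop
#: pairing 18-55 / 19-56 is present only in the quasi-canonical type-0
#: tRNAs; type II lost it, and the D-arm-less type III cannot form any
#: D-stem-anchored group.
BASE_TERTIARY_GROUPS = (
    frozenset({10, 25, 45}), frozenset({9, 23, 12}), frozenset({13, 22, 46}),
    frozenset({8, 14}), frozenset({15, 48}), frozenset({26, 44}),
    frozenset({54, 58}),
)
DT_LOOP_PAIRS = (frozenset({18, 55}), frozenset({19, 56}))
D_STEM_SPRINZL = frozenset({10, 11, 12, 13, 22, 23, 24, 25})


def tertiary_groups_for_type(trna_type: str) -> tuple[frozenset[int], ...]:
    """Tertiary interaction groups expected for a structural class."""
    groups = BASE_TERTIARY_GROUPS + (DT_LOOP_PAIRS if trna_type == "0" else ())
    if trna_type == "III":
        groups = tuple(g for g in groups if not (g & D_STEM_SPRINZL))
    return groups


#: Precedence used when one residue carries two alternative modifications:
#: the more-derived modification wins (taurinomethyl-2-thiouridine over
#: taurinomethyluridine, methylthio-isopentenyl over isopentenyl).
_MOD_PRECEDENCE = {"Ǝ": 2, "*": 2}


@dataclass(frozen=True)
class TrnaAnnotation:
    """The five-field structural annotation of one tRNA position."""

    sprinzl: Optional[int]
    trna_type: str
    domain: str
    mature_nt: str
    folding: bool

    def __str__(self) -> str:
        return format_trna_annotation(self)


def format_trna_annotation(a: TrnaAnnotation) -> str:
    """Render the five fields joined by ";" with no spaces.

    Unmapped Sprinzl positions render as ``-`` in the first field so the
    contract stays fixed at five fields.
    """
    if a.domain not in TRNA_DOMAINS:
        raise AnnotationFormatError(f"unknown domain code {a.domain!r}")
    if a.trna_type not in TRNA_TYPES:
        raise AnnotationFormatError(f"unknown tRNA type {a.trna_type!r}")
    if not a.mature_nt or len(a.mature_nt) != 1:
        raise AnnotationFormatError(f"mature nucleotide must be one character, got {a.mature_nt!r}")
    sprinzl = "-" if a.sprinzl is None else str(a.sprinzl)
    return ";".join([sprinzl, a.trna_type, a.domain, a.mature_nt,
                     "Y" if a.folding else "N"])


def parse_trna_annotation(s: str) -> TrnaAnnotation:
    """Inverse of :func:`format_trna_annotation`."""
    fields = s.split(";")
    if len(fields) != 5:
        raise AnnotationFormatError(f"expected five ';'-separated fields, got {s!r}")
    raw_sprinzl, trna_type, domain, mature, folding = fields
    if folding not in ("Y", "N"):
        raise AnnotationFormatError(f"bad folding flag {folding!r}")
    a = TrnaAnnotation(
        sprinzl=None if raw_sprinzl == "-" else int(raw_sprinzl),
        trna_type=trna_type, domain=domain, mature_nt=mature,
        folding=folding == "Y")
    # re-validate through the formatter so parse(format(a)) == a holds
    format_trna_annotation(a)
    return a


def annotate_trna_position(pos: int, bundle: ReferenceBundle) -> Optional[TrnaAnnotation]:
    """Structural annotation of a genomic position, or None outside tRNA genes.

    When a position lies in two overlapping tRNA genes the map of the gene
    with the smaller start coordinate is reported.
    """
    loci = [g for g in bundle.loci_at(pos) if g.biotype == "tRNA"]
    if not loci:
        return None
    gene = loci[0]
    struct = bundle.structures.get(gene.name)
    if struct is None:
        raise DataIntegrityError(f"no structure map for tRNA gene {gene.name}")
    rec = struct.record_at_offset(gene.offset_of(pos, bundle.genome_length))
    if rec is None:
        raise DataIntegrityError(
            f"structure map of {gene.name} does not cover position {pos}")
    return TrnaAnnotation(rec.sprinzl, struct.trna_type, rec.domain,
                          rec.mature_nt, rec.folding)


def build_structure_map(
    gene,
    trna_type: str,
    alignment: Sequence[tuple[int, Optional[int]]],
    transcript: str,
    domains: Optional[Mapping[int, str]] = None,
    mods: Iterable[ModificationRecord] = (),
    tertiary: Iterable[Iterable[int]] = (),
    species: Optional[str] = None,
) -> TrnaStructureMap:
    """Assemble a validated :class:`TrnaStructureMap` from raw curation inputs.

    Parameters
    ----------
    gene
        Gene symbol or :class:`GeneLocus`.
    alignment
        Ordered (offset, sprinzl-or-None) pairs covering every gene offset
        exactly once; Sprinzl numbers must be strictly increasing.
    transcript
        Mature-transcript plain bases (RNA alphabet) by offset; overridden
        by the matching modification records.
    domains
        Sprinzl number -> domain; defaults to the canonical cloverleaf
        layout.  Must assign CL to the anticodon triplet.
    tertiary
        Pair/triplet groups of Sprinzl numbers; groups with members missing
        from the alignment are dropped.  ``folding`` is Y exactly at the
        retained groups' members.
    species
        tRNA species name (modification-table convention) used to match
        modification records;
        inferred from the gene symbol for the 22 human genes.
    """
    name = gene.name if isinstance(gene, GeneLocus) else str(gene)
    if trna_type not in TRNA_TYPES:
        raise StructureBuildError(f"unknown tRNA type {trna_type!r}")
    offsets = [off for off, _ in alignment]
    if offsets != list(range(1, len(offsets) + 1)):
        raise StructureBuildError(
            f"{name}: alignment must cover offsets 1..n exactly once in order")
    if len(transcript) != len(offsets):
        raise StructureBuildError(
            f"{name}: transcript length {len(transcript)} != alignment length {len(offsets)}")
    sprinzls = [s for _, s in alignment if s is not None]
    if any(b >= a for a, b in zip(sprinzls[1:], sprinzls)):
        raise StructureBuildError(f"{name}: Sprinzl numbers not strictly increasing")
    if any(not 1 <= s <= 73 for s in sprinzls):
        raise StructureBuildError(f"{name}: Sprinzl numbers must lie in 1..73")

    domain_of = dict(canonical_domains() if domains is None else domains)
    seen_dom: dict[int, str] = {}
    for n, dom in domain_of.items():
        if dom not in TRNA_DOMAINS:
            raise StructureBuildError(f"{name}: unknown domain {dom!r} at Sprinzl {n}")
        if n in seen_dom:  # a dict cannot overlap; guard kept for range-style inputs
            raise StructureBuildError(f"{name}: domain ranges overlap at Sprinzl {n}")
        seen_dom[n] = dom
    for n in ANTICODON_SPRINZL:
        if domain_of.get(n) != "CL":
            raise StructureBuildError(
                f"{name}: the anticodon triplet (Sprinzl 34-36) must be domain CL, "
                f"got {domain_of.get(n)!r} at {n}")

    if species is None:
        species = GENE_TO_SPECIES.get(name, name)
    mature_override: dict[int, str] = {}
    for m in mods:
        if m.trna != species:
            continue
        prev = mature_override.get(m.position)
        if prev is None or (
            _MOD_PRECEDENCE.get(m.modomics_symbol, 1),
            m.modomics_symbol,
        ) > (_MOD_PRECEDENCE.get(prev, 1), prev):
            mature_override[m.position] = m.modomics_symbol

    mapped = set(sprinzls)
    groups = [frozenset(int(n) for n in g) for g in tertiary]
    kept = frozenset(g for g in groups if g <= mapped)
    folded = {n for g in kept for n in g}

    records = []
    for (off, sprinzl), base in zip(alignment, transcript.upper()):
        if sprinzl is None:
            records.append(TrnaPositionRecord(name, off, None, "-", base, False))
            continue
        records.append(TrnaPositionRecord(
            name, off, sprinzl, domain_of.get(sprinzl, "-"),
            mature_override.get(sprinzl, base), sprinzl in folded))
    struct = TrnaStructureMap(name, trna_type, tuple(records), kept)
    struct.validate()
    return struct
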