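"""GFF3 custom-track generation for genome-browser display.

Four tracks are produced, mirroring the browser tracks the annotation layer
feeds: ``MT-patho.CDS`` (every possible nonsynonymous coding substitution),
``MT-patho.STOP`` (every possible stop-gain and stop-loss), ``MT-patho.RNA``
(literature-scored tRNA/rRNA variants with normalized scores and
predictions) and ``MT-RNA`` (per-position structural annotations of all
tRNA and rRNA gene positions).  Records are sorted by start; variant
records carry an HGVS ``Name`` attribute and a ``kind`` attribute so tracks
can be filtered by transition/transversion/insertion/deletion and merged
back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional
from urllib.parse import quote, unquote

from .enumeration import EnumerationResult
from .reference import ReferenceBundle
from .scoring import SCHEMES, classify_rna_variant
from .trna import format_trna_annotation, annotate_trna_position, TrnaAnnotation
from .variants import Variant, hgvs_name

GFF_VERSION_LINE = "##gff-version 3"

#: seqid dialects accepted by the writer.
SEQID_DIALECTS = ("chrM", "MT", "NC_012920.1")

TRACK_NAMES = ("MT-patho.CDS", "MT-patho.STOP", "MT-patho.RNA", "MT-RNA")

_SOURCE = "mtanno"

# GFF3 column-9 reserved characters that must be percent-encoded.
_ATTR_SAFE = "".join(chr(c) for c in range(33, 127) if chr(c) not in ";=&,%")


def _encode(value: str) -> str:
    return quote(str(value), safe=_ATTR_SAFE + " ")


class Gff3ParseError(ValueError):
    pass


@dataclass(frozen=True)
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str  # "." or a formatted number
    strand: str
    phase: str
    attributes: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def attr(self, key: str) -> Optional[str]:
        for k, v in self.attributes:
            if k == key:
                return v
        return None

    def to_line(self) -> str:
        attrs = ";".join(f"{_encode(k)}={_encode(v)}" for k, v in self.attributes)
        return "\t".join([self.seqid, self.source, self.type, str(self.start),
                          str(self.end), self.score, self.strand, self.phase,
                          attrs or "."])

    @classmethod
    def from_line(cls, line: str) -> "Gff3Record":
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise Gff3ParseError(f"expected 9 columns, got {len(cols)}: {line!r}")
        attrs: list[tuple[str, str]] = []
        if cols[8] != ".":
            for pair in cols[8].split(";"):
                if not pair:
                    continue
                if "=" not in pair:
                    raise Gff3ParseError(f"malformed attribute {pair!r}")
                k, v = pair.split("=", 1)
                attrs.append((unquote(k), unquote(v)))
        return cls(cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]),
                   cols[5], cols[6], cols[7], tuple(attrs))


def write_gff3(records: Iterable[Gff3Record], path) -> None:
    records = list(records)
    starts = [r.start for r in records]
    if starts != sorted(starts):
        raise RuntimeError("track records must be sorted by start before writing")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(GFF_VERSION_LINE + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_gff3(path) -> list[Gff3Record]:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("##gff-version 3"):
            raise Gff3ParseError(f"{path}: missing '##gff-version 3' header")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            records.append(Gff3Record.from_line(line))
    return records


def _sort(records: list[Gff3Record]) -> list[Gff3Record]:
    return sorted(records, key=lambda r: (r.start, r.end, r.type,
                                          r.attr("ID") or ""))


def _strand_symbol(strand: str) -> str:
    return "+" if strand == "H" else "-"


# ---------------------------------------------------------------------------
# individual tracks
# ---------------------------------------------------------------------------


def build_cds_track(enumeration: EnumerationResult, seqid: str = "chrM") -> list[Gff3Record]:
    """All possible nonsynonymous substitutions, one record per gene context."""
    records = []
    for i, sub in enumerate(s for s in enumeration.records if s.effect == "nonsynonymous"):
        v = Variant(sub.pos, sub.ref, sub.alt)
        records.append(Gff3Record(
            seqid, _SOURCE, "sequence_variant", sub.pos, sub.pos, ".",
            "+", ".", (
                ("ID", f"cds.{i + 1}"),
                ("Name", hgvs_name(v)),
                ("gene", sub.gene),
                ("kind", v.kind),
                ("effect", sub.effect),
                ("codon_change", f"{sub.ref_codon}>{sub.alt_codon}"),
            )))
    return _sort(records)


def build_stop_track(enumeration: EnumerationResult, seqid: str = "chrM") -> list[Gff3Record]:
    """All possible stop-gain and stop-loss substitutions."""
    records = []
    wanted = [s for s in enumeration.records if s.effect in ("stop_gain", "stop_loss")]
    for i, sub in enumerate(wanted):
        v = Variant(sub.pos, sub.ref, sub.alt)
        records.append(Gff3Record(
            seqid, _SOURCE, "sequence_variant", sub.pos, sub.pos, ".",
            "+", ".", (
                ("ID", f"stop.{i + 1}"),
                ("Name", hgvs_name(v)),
                ("gene", sub.gene),
                ("kind", v.kind),
                ("effect", sub.effect),
                ("codon_change", f"{sub.ref_codon}>{sub.alt_codon}"),
            )))
    return _sort(records)


def build_rna_patho_track(bundle: ReferenceBundle, seqid: str = "chrM") -> list[Gff3Record]:
    """Literature-scored tRNA/rRNA variants with normalized scores."""
    records = []
    entries = sorted(bundle.rna_patho.values(),
                     key=lambda r: (r.position, r.ref, r.alt))
    for i, rec in enumerate(entries):
        v = Variant(rec.position, rec.ref, rec.alt)
        loci = bundle.loci_at(rec.position)
        records.append(Gff3Record(
            seqid, _SOURCE, "sequence_variant", rec.position,
            rec.position + len(rec.ref) - 1, f"{rec.normalized_score:.3f}",
            "+", ".", (
                ("ID", f"rna.{i + 1}"),
                ("Name", hgvs_name(v)),
                ("gene", "/".join(g.name for g in loci)),
                ("kind", v.kind),
                ("scheme", rec.scheme),
                ("raw_score", str(rec.raw_score)),
                ("prediction", rec.prediction),
                ("classification",
                 classify_rna_variant(rec.normalized_score, SCHEMES[rec.scheme])),
            )))
    return _sort(records)


def build_mt_rna_track(bundle: ReferenceBundle, seqid: str = "chrM") -> list[Gff3Record]:
    """Per-position annotations of every tRNA and rRNA gene position.

    One record per (gene, position); a position shared by two genes yields
    one record per gene, each with its own structural annotation.
    """
    records = []
    counter = 0
    for gene in bundle.genes:
        if gene.biotype not in ("tRNA", "rRNA"):
            continue
        struct = bundle.structures.get(gene.name)
        for off in range(1, gene.length(bundle.genome_length) + 1):
            pos = gene.position_at(off, bundle.genome_length)
            counter += 1
            attrs = [("ID", f"pos.{counter}"), ("gene", gene.name),
                     ("biotype", gene.biotype), ("offset", str(off))]
            if struct is not None:
                rec = struct.record_at_offset(off)
                ann = TrnaAnnotation(rec.sprinzl, struct.trna_type, rec.domain,
                                     rec.mature_nt, rec.folding)
                attrs.append(("trna_annotation", format_trna_annotation(ann)))
            records.append(Gff3Record(
                seqid, _SOURCE, "sequence_feature", pos, pos, ".",
                _strand_symbol(gene.strand), ".", tuple(attrs)))
    return _sort(records)


def build_tracks(
    bundle: ReferenceBundle,
    enumeration: Optional[EnumerationResult],
    seqid: str = "chrM",
) -> dict[str, list[Gff3Record]]:
    """Build all four named tracks; enumeration feeds the two coding tracks."""
    if seqid not in SEQID_DIALECTS:
        raise ValueError(f"seqid {seqid!r} not one of {SEQID_DIALECTS}")
    if enumeration is None:
        raise ValueError(
            "an enumeration result (reference FASTA) is required for the "
            "MT-patho.CDS and MT-patho.STOP tracks")
    return {
        "MT-patho.CDS": build_cds_track(enumeration, seqid),
        "MT-patho.STOP": build_stop_track(enumeration, seqid),
        "MT-patho.RNA": build_rna_patho_track(bundle, seqid),
        "MT-RNA": build_mt_rna_track(bundle, seqid),
    }


def partition_by_kind(records: Iterable[Gff3Record]) -> dict[str, list[Gff3Record]]:
    """Split a track by the variant-kind attribute (browser-style filtering)."""
    out: dict[str, list[Gff3Record]] = {}
    for rec in records:
        out.setdefault(rec.attr("kind") or "none", []).append(rec)
    return out


def merge_partitions(parts: dict[str, list[Gff3Record]]) -> list[Gff3Record]:
    merged = [rec for records in parts.values() for rec in records]
    return _sort(merged)
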