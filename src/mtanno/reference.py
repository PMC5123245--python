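"""Reference data model for mitochondrial variant annotation.

The annotation layer is table-driven: a *reference bundle* is a directory of
tab-delimited tables plus a JSON manifest, describing

* the mtDNA gene map on the rCRS coordinate system (1-based, inclusive,
  16,569 bp circular genome),
* one structural map per tRNA gene, assigning every gene position a Sprinzl
  number (1-73, CCA end excluded), a cloverleaf domain, the mature
  (post-transcriptionally modified) nucleotide and a tertiary-folding flag,
* the post-transcriptional modification table (Modomics one-character
  symbols),
* literature RNA pathogenicity scores for tRNA/rRNA variants, normalized to
  a 0-1 range on load,
* pass-through annotation columns (MITOMAP disease, ClinVar, dbSNP, OMIM,
  conservation, variability) keyed by variant.

All invariants are checked at load time; a violated rule raises
:class:`BundleValidationError` naming the table, row and rule.  A bundle can
be re-serialized with :meth:`ReferenceBundle.save` and reloaded losslessly,
which is what the synthetic-fixture generator relies on so tests exercise
the production loaders.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

#: Length of the rCRS human mitochondrial genome (GenBank J01415.2).
GENOME_LENGTH = 16569

#: Sequence names accepted as the mitochondrial contig in variant inputs.
MT_SEQIDS = {"chrM", "chrMT", "MT", "M", "NC_012920", "NC_012920.1", "J01415.2"}

#: Valid cloverleaf domain codes: stems (acceptor, dihydrouridine,
#: anticodon, T-psi-C), loops (D, anticodon, variable, T), 3' end and
#: junction/unmapped positions.
TRNA_DOMAINS = ("AS", "DS", "DL", "CS", "CL", "VL", "TS", "TL", "E", "-")

#: Structural classes of human mt-tRNAs.
TRNA_TYPES = ("0", "I", "II", "III")

#: Sentinel for gene positions with no Sprinzl counterpart
#: (structural-alignment gaps); rendered "-" in formatted annotations.
UNMAPPED = None

BIOTYPES = ("tRNA", "rRNA", "protein_coding", "control", "other")

#: Anticodon triplet positions in Sprinzl numbering.
ANTICODON_SPRINZL = (34, 35, 36)

MANIFEST_NAME = "manifest.json"
REQUIRED_TABLES = (
    "genes.tsv",
    "trna_structure.tsv",
    "tertiary.tsv",
    "modifications.tsv",
    "rna_patho.tsv",
    "passthrough.tsv",
)


class BundleError(Exception):
    """Base class for reference-bundle problems."""


class BundleLoadError(BundleError):
    """A bundle file is missing or structurally unreadable."""


class BundleValidationError(BundleError):
    """A loaded table violates a documented invariant."""

    def __init__(self, table: str, row, rule: str):
        self.table = table
        self.row = row
        self.rule = rule
        super().__init__(f"{table} (row {row}): {rule}")


class RangeError(BundleError, ValueError):
    """A genomic position lies outside the genome bounds."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    """One mtDNA gene or region on the rCRS.

    Coordinates are 1-based inclusive.  A locus spanning the replication
    origin (the control region) is represented with ``end < start`` and
    flagged by :attr:`wraps`.  ``strand`` is ``H`` for features read off the
    reference (heavy) strand and ``L`` for features transcribed from the
    complementary (light) strand.
    """

    name: str
    start: int
    end: int
    strand: str  # {"H", "L"}
    biotype: str

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"bad biotype {self.biotype!r} for {self.name}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int = GENOME_LENGTH) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def offset_of(self, pos: int, genome_length: int = GENOME_LENGTH) -> int:
        """1-based offset of ``pos`` along the feature's own 5'->3' reading.

        For L-strand features the transcript runs from ``end`` down to
        ``start``, so offset 1 corresponds to genomic position ``end``.
        """
        if not self.contains(pos):
            raise ValueError(f"position {pos} not inside {self.name}")
        if self.wraps:
            fwd = (pos - self.start if pos >= self.start
                   else genome_length - self.start + pos)
            if self.strand == "H":
                return fwd + 1
            return self.length(genome_length) - fwd
        if self.strand == "H":
            return pos - self.start + 1
        return self.end - pos + 1

    def position_at(self, offset: int, genome_length: int = GENOME_LENGTH) -> int:
        """Inverse of :meth:`offset_of`."""
        if not 1 <= offset <= self.length(genome_length):
            raise ValueError(f"offset {offset} outside {self.name}")
        if self.wraps:
            fwd = offset - 1 if self.strand == "H" else self.length(genome_length) - offset
            pos = self.start + fwd
            return pos if pos <= genome_length else pos - genome_length
        if self.strand == "H":
            return self.start + offset - 1
        return self.end - offset + 1


@dataclass(frozen=True)
class TrnaPositionRecord:
    """Structural annotation of a single tRNA gene position.

    ``offset`` counts 1-based along the tRNA's own 5'->3' direction;
    ``sprinzl`` is the standard 1-73 structural number or :data:`UNMAPPED`;
    ``mature_nt`` is the post-transcriptional nucleotide (RNA alphabet, or a
    one-character Modomics symbol); ``folding`` marks participation in
    tertiary pair/triplet interactions.
    """

    gene: str
    offset: int
    sprinzl: Optional[int]
    domain: str
    mature_nt: str
    folding: bool


@dataclass
class TrnaStructureMap:
    """Per-gene table mapping every gene offset to its structural annotation."""

    gene: str
    trna_type: str
    positions: tuple[TrnaPositionRecord, ...]
    tertiary: frozenset[frozenset[int]]

    def __post_init__(self):
        self._by_offset = {p.offset: p for p in self.positions}

    @property
    def tertiary_sprinzl(self) -> frozenset[int]:
        return frozenset(n for group in self.tertiary for n in group)

    def record_at_offset(self, offset: int) -> Optional[TrnaPositionRecord]:
        return self._by_offset.get(offset)

    def validate(self, table: str = "trna_structure.tsv") -> None:
        if self.trna_type not in TRNA_TYPES:
            raise BundleValidationError(table, self.gene, f"unknown tRNA type {self.trna_type!r}")
        offsets = [p.offset for p in self.positions]
        if offsets != list(range(1, len(offsets) + 1)):
            raise BundleValidationError(table, self.gene, "offsets must cover 1..length exactly once")
        last = 0
        for p in self.positions:
            if p.domain not in TRNA_DOMAINS:
                raise BundleValidationError(table, (self.gene, p.offset), f"unknown domain {p.domain!r}")
            if p.sprinzl is not None:
                if not 1 <= p.sprinzl <= 73:
                    raise BundleValidationError(
                        table, (self.gene, p.offset), "Sprinzl number outside 1..73")
                if p.sprinzl <= last:
                    raise BundleValidationError(
                        table, (self.gene, p.offset),
                        "Sprinzl numbers must be strictly increasing with offset")
                last = p.sprinzl
                if p.sprinzl in ANTICODON_SPRINZL and p.domain != "CL":
                    raise BundleValidationError(
                        table, (self.gene, p.offset),
                        "anticodon positions (Sprinzl 34-36) must lie in domain CL")
                if p.domain == "CL" and not 32 <= p.sprinzl <= 38:
                    raise BundleValidationError(
                        table, (self.gene, p.offset),
                        "domain CL (anticodon loop) is restricted to Sprinzl 32-38")
            elif p.domain != "-":
                raise BundleValidationError(
                    table, (self.gene, p.offset), "unmapped positions must carry domain '-'")
        folded = {p.sprinzl for p in self.positions if p.folding}
        tert = self.tertiary_sprinzl
        if folded != tert:
            raise BundleValidationError(
                table, self.gene,
                f"folding flags ({sorted(folded, key=lambda x: (x is None, x))}) must mark exactly "
                f"the tertiary-interaction Sprinzl set ({sorted(tert)})")
        mapped = {p.sprinzl for p in self.positions if p.sprinzl is not None}
        for group in self.tertiary:
            if not group <= mapped:
                raise BundleValidationError(
                    table, self.gene,
                    f"tertiary group {sorted(group)} references unmapped Sprinzl positions")


@dataclass(frozen=True)
class ModificationRecord:
    """One post-transcriptional modification entry.

    ``trna`` names the tRNA species by amino-acid code with codon-family
    suffix where duplicated (e.g. ``Leu(UUR)``); ``evidence`` records
    whether the residue is confirmed in human, predicted from the bovine
    model, or predicted from model organisms.
    """

    position: int
    mod_name: str
    modomics_symbol: str
    trna: str
    evidence: str  # {"human", "bovine", "model_organism"}


@dataclass(frozen=True)
class RnaPathoRecord:
    """A literature-scored RNA variant with its normalized score."""

    position: int
    ref: str
    alt: str
    scheme: str  # {"tRNA", "rRNA"}
    raw_score: int
    normalized_score: float
    prediction: str
    source: str = ""


# ---------------------------------------------------------------------------
# bundle container
# ---------------------------------------------------------------------------

#: Gene symbol -> tRNA species naming used by the modification table
#: (amino-acid code with codon-family suffix where duplicated).
GENE_TO_SPECIES = {
    "MT-TA": "Ala", "MT-TR": "Arg", "MT-TN": "Asn", "MT-TD": "Asp",
    "MT-TC": "Cys", "MT-TQ": "Gln", "MT-TE": "Glu", "MT-TG": "Gly",
    "MT-TH": "His", "MT-TI": "Ile", "MT-TL1": "Leu(UUR)", "MT-TL2": "Leu(CUN)",
    "MT-TK": "Lys", "MT-TM": "Met", "MT-TF": "Phe", "MT-TP": "Pro",
    "MT-TS1": "Ser(UCN)", "MT-TS2": "Ser(AGY)", "MT-TT": "Thr",
    "MT-TW": "Trp", "MT-TY": "Tyr", "MT-TV": "Val",
}


class ReferenceBundle:
    """A fully cross-validated set of annotation tables."""

    def __init__(self, genes, structures, modifications, rna_patho,
                 passthrough, manifest):
        self.genes: tuple[GeneLocus, ...] = tuple(sorted(genes, key=lambda g: (g.start, g.end, g.name)))
        self.structures: dict[str, TrnaStructureMap] = dict(structures)
        self.modifications: tuple[ModificationRecord, ...] = tuple(modifications)
        self.rna_patho: dict[tuple[int, str, str], RnaPathoRecord] = dict(rna_patho)
        self.passthrough: dict[tuple[int, str, str], dict] = dict(passthrough)
        self.manifest: dict = dict(manifest)
        self._by_name = {g.name: g for g in self.genes}

    @property
    def genome_length(self) -> int:
        return int(self.manifest.get("genome_length", GENOME_LENGTH))

    def gene(self, name: str) -> GeneLocus:
        return self._by_name[name]

    def loci_by_biotype(self, biotype: str) -> tuple[GeneLocus, ...]:
        return tuple(g for g in self.genes if g.biotype == biotype)

    def loci_at(self, pos: int) -> list[GeneLocus]:
        """All loci containing ``pos``, ordered by start coordinate."""
        if not 1 <= pos <= self.genome_length:
            raise RangeError(
                f"position {pos} outside genome bounds 1..{self.genome_length}")
        return [g for g in self.genes if g.contains(pos)]

    def structure_for(self, gene: str) -> TrnaStructureMap:
        return self.structures[gene]

    # -- counts used by the manifest and the MT-RNA track ------------------

    def position_count(self, biotype: str, distinct: bool = False) -> int:
        loci = self.loci_by_biotype(biotype)
        if not distinct:
            return sum(g.length(self.genome_length) for g in loci)
        seen: set[int] = set()
        for g in loci:
            for off in range(1, g.length(self.genome_length) + 1):
                seen.add(g.position_at(off, self.genome_length))
        return len(seen)

    def modified_residue_count(self) -> int:
        """Distinct (tRNA species, Sprinzl position) pairs in the mod table."""
        return len({(m.trna, m.position) for m in self.modifications})

    def modification_type_count(self) -> int:
        return len({m.mod_name for m in self.modifications})

    # -- serialization -----------------------------------------------------

    def save(self, dir_path) -> None:
        """Write the bundle back to ``dir_path`` in the loadable format."""
        out = Path(dir_path)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "genes.tsv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["name", "start", "end", "strand", "biotype"])
            for g in self.genes:
                w.writerow([g.name, g.start, g.end, g.strand, g.biotype])
        with (out / "trna_structure.tsv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene", "trna_type", "offset", "sprinzl", "domain",
                        "mature_nt", "folding"])
            for name in sorted(self.structures):
                m = self.structures[name]
                for p in m.positions:
                    w.writerow([m.gene, m.trna_type, p.offset,
                                "-" if p.sprinzl is None else p.sprinzl,
                                p.domain, p.mature_nt, "Y" if p.folding else "N"])
        with (out / "tertiary.tsv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene", "members"])
            for name in sorted(self.structures):
                for group in sorted(self.structures[name].tertiary, key=sorted):
                    w.writerow([name, "-".join(str(n) for n in sorted(group))])
        with (out / "modifications.tsv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["position", "mod_name", "modomics_symbol", "trna", "evidence"])
            for m in self.modifications:
                w.writerow([m.position, m.mod_name, m.modomics_symbol, m.trna, m.evidence])
        with (out / "rna_patho.tsv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["position", "ref", "alt", "scheme", "raw_score",
                        "prediction_label", "source_citation"])
            for rec in sorted(self.rna_patho.values(), key=lambda r: (r.position, r.ref, r.alt)):
                w.writerow([rec.position, rec.ref, rec.alt, rec.scheme,
                            rec.raw_score, rec.prediction, rec.source])
        pcols = self.manifest.get("passthrough_columns", [])
        with (out / "passthrough.tsv").open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["position", "ref", "alt"] + list(pcols))
            for (pos, ref, alt), row in sorted(self.passthrough.items()):
                w.writerow([pos, ref, alt] + [row.get(c, "") for c in pcols])
        manifest = dict(self.manifest)
        manifest["tables"] = {
            "genes.tsv": len(self.genes),
            "trna_structure.tsv": sum(len(m.positions) for m in self.structures.values()),
            "tertiary.tsv": sum(len(m.tertiary) for m in self.structures.values()),
            "modifications.tsv": len(self.modifications),
            "rna_patho.tsv": len(self.rna_patho),
            "passthrough.tsv": len(self.passthrough),
        }
        manifest.setdefault("genome_length", self.genome_length)
        manifest["counts"] = {
            "trna_genes": len(self.loci_by_biotype("tRNA")),
            "rrna_genes": len(self.loci_by_biotype("rRNA")),
            "protein_coding_genes": len(self.loci_by_biotype("protein_coding")),
            "trna_positions": self.position_count("tRNA"),
            "trna_distinct_positions": self.position_count("tRNA", distinct=True),
            "rrna_positions": self.position_count("rRNA"),
            "modified_residues": self.modified_residue_count(),
            "modification_types": self.modification_type_count(),
        }
        with (out / MANIFEST_NAME).open("w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, ensure_ascii=False, sort_keys=True)
            fh.write("\n")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        counts = self.manifest.get("counts", {})
        for key, actual in (
            ("trna_genes", len(self.loci_by_biotype("tRNA"))),
            ("rrna_genes", len(self.loci_by_biotype("rRNA"))),
            ("protein_coding_genes", len(self.loci_by_biotype("protein_coding"))),
            ("trna_positions", self.position_count("tRNA")),
            ("rrna_positions", self.position_count("rRNA")),
            ("modified_residues", self.modified_residue_count()),
            ("modification_types", self.modification_type_count()),
        ):
            if key in counts and counts[key] != actual:
                raise BundleValidationError(
                    MANIFEST_NAME, key,
                    f"manifest declares {counts[key]} but bundle has {actual}")
        wrapping = [g for g in self.genes if g.wraps]
        if len(wrapping) > 1:
            raise BundleValidationError(
                "genes.tsv", [g.name for g in wrapping],
                "at most one locus may wrap the origin")
        for g in self.genes:
            if g.wraps:
                continue
            if not (1 <= g.start <= g.end <= self.genome_length):
                raise BundleValidationError(
                    "genes.tsv", g.name,
                    f"coordinates {g.start}..{g.end} outside 1..{self.genome_length}")
        for g in self.loci_by_biotype("tRNA"):
            m = self.structures.get(g.name)
            if m is None:
                raise BundleValidationError(
                    "trna_structure.tsv", g.name, "tRNA locus has no structure map")
            if len(m.positions) != g.length(self.genome_length):
                raise BundleValidationError(
                    "trna_structure.tsv", g.name,
                    f"map covers {len(m.positions)} offsets but gene length is "
                    f"{g.length(self.genome_length)}")
            m.validate()
        for name in self.structures:
            if name not in self._by_name:
                raise BundleValidationError(
                    "trna_structure.tsv", name, "structure map for unknown gene")
        seen_mod = set()
        symbol_for: dict[str, str] = {}
        for i, m in enumerate(self.modifications):
            key = (m.position, m.mod_name, m.trna)
            if key in seen_mod:
                raise BundleValidationError(
                    "modifications.tsv", i, f"duplicate (position, mod, tRNA) triple {key}")
            seen_mod.add(key)
            prev = symbol_for.setdefault(m.mod_name, m.modomics_symbol)
            if prev != m.modomics_symbol:
                raise BundleValidationError(
                    "modifications.tsv", i,
                    f"{m.mod_name} maps to both symbols {prev!r} and {m.modomics_symbol!r}")
            if m.evidence not in ("human", "bovine", "model_organism"):
                raise BundleValidationError("modifications.tsv", i,
                                            f"bad evidence {m.evidence!r}")
        # late import: scoring depends on this module's types
        from .scoring import SCHEMES, normalize_score

        for key, rec in self.rna_patho.items():
            scheme = SCHEMES.get(rec.scheme)
            if scheme is None:
                raise BundleValidationError("rna_patho.tsv", key,
                                            f"unknown scheme {rec.scheme!r}")
            expect = normalize_score(rec.raw_score, scheme)
            if abs(rec.normalized_score - expect) > 1e-9:
                raise BundleValidationError(
                    "rna_patho.tsv", key,
                    f"normalized_score {rec.normalized_score} != raw/max = {expect}")
            if rec.prediction != scheme.label_map[rec.raw_score]:
                raise BundleValidationError(
                    "rna_patho.tsv", key,
                    f"label {rec.prediction!r} inconsistent with raw score {rec.raw_score}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_tsv(path: Path) -> list[dict]:
    try:
        with path.open("r", encoding="utf-8", newline="") as fh:
            return list(csv.DictReader(fh, delimiter="\t"))
    except OSError as exc:  # pragma: no cover - propagated as load error
        raise BundleLoadError(f"cannot read {path.name}: {exc}") from exc


def load_reference_bundle(dir_path) -> ReferenceBundle:
    """Load and cross-validate a reference bundle directory.

    Raises :class:`BundleLoadError` listing every missing required file, or
    :class:`BundleValidationError` naming table, row and rule on the first
    violated invariant.
    """
    root = Path(dir_path)
    missing = [n for n in REQUIRED_TABLES + (MANIFEST_NAME,) if not (root / n).is_file()]
    if missing:
        raise BundleLoadError(
            f"bundle at {root} is missing required files: {', '.join(sorted(missing))}")

    with (root / MANIFEST_NAME).open("r", encoding="utf-8") as fh:
        try:
            manifest = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleLoadError(f"unreadable manifest.json: {exc}") from exc

    genes = []
    for i, row in enumerate(_read_tsv(root / "genes.tsv")):
        try:
            genes.append(GeneLocus(row["name"], int(row["start"]), int(row["end"]),
                                   row["strand"], row["biotype"]))
        except (KeyError, ValueError) as exc:
            raise BundleValidationError("genes.tsv", i + 2, str(exc)) from exc

    tertiary: dict[str, set[frozenset[int]]] = {}
    for i, row in enumerate(_read_tsv(root / "tertiary.tsv")):
        try:
            members = frozenset(int(x) for x in row["members"].split("-"))
        except (KeyError, ValueError) as exc:
            raise BundleValidationError("tertiary.tsv", i + 2, str(exc)) from exc
        if len(members) not in (2, 3):
            raise BundleValidationError(
                "tertiary.tsv", i + 2, "tertiary groups are pairs or triplets")
        tertiary.setdefault(row["gene"], set()).add(members)

    rows_by_gene: dict[str, list] = {}
    type_by_gene: dict[str, str] = {}
    for i, row in enumerate(_read_tsv(root / "trna_structure.tsv")):
        try:
            gene = row["gene"]
            sprinzl = None if row["sprinzl"] == "-" else int(row["sprinzl"])
            rec = TrnaPositionRecord(gene, int(row["offset"]), sprinzl,
                                     row["domain"], row["mature_nt"],
                                     row["folding"] == "Y")
        except (KeyError, ValueError) as exc:
            raise BundleValidationError("trna_structure.tsv", i + 2, str(exc)) from exc
        rows_by_gene.setdefault(gene, []).append(rec)
        prev = type_by_gene.setdefault(gene, row["trna_type"])
        if prev != row["trna_type"]:
            raise BundleValidationError(
                "trna_structure.tsv", i + 2,
                f"{gene} declared with two tRNA types ({prev!r}, {row['trna_type']!r})")
    structures = {}
    for gene, recs in rows_by_gene.items():
        recs.sort(key=lambda r: r.offset)
        structures[gene] = TrnaStructureMap(
            gene, type_by_gene[gene], tuple(recs),
            frozenset(tertiary.get(gene, set())))

    modifications = []
    for i, row in enumerate(_read_tsv(root / "modifications.tsv")):
        try:
            modifications.append(ModificationRecord(
                int(row["position"]), row["mod_name"], row["modomics_symbol"],
                row["trna"], row["evidence"]))
        except (KeyError, ValueError) as exc:
            raise BundleValidationError("modifications.tsv", i + 2, str(exc)) from exc

    from .scoring import SCHEMES, normalize_score

    rna_patho = {}
    for i, row in enumerate(_read_tsv(root / "rna_patho.tsv")):
        try:
            raw = int(row["raw_score"])
            scheme_name = row["scheme"]
            scheme = SCHEMES.get(scheme_name)
            if scheme is None:
                raise ValueError(f"unknown scheme {scheme_name!r}")
            rec = RnaPathoRecord(
                int(row["position"]), row["ref"], row["alt"], scheme_name, raw,
                normalize_score(raw, scheme), row["prediction_label"],
                row.get("source_citation", ""))
        except (KeyError, ValueError) as exc:
            raise BundleValidationError("rna_patho.tsv", i + 2, str(exc)) from exc
        rna_patho[(rec.position, rec.ref, rec.alt)] = rec

    passthrough = {}
    pass_rows = _read_tsv(root / "passthrough.tsv")
    pcols = [c for c in (pass_rows[0].keys() if pass_rows else
                         manifest.get("passthrough_columns", []))
             if c not in ("position", "ref", "alt")]
    manifest.setdefault("passthrough_columns", list(pcols))
    for i, row in enumerate(pass_rows):
        try:
            key = (int(row["position"]), row["ref"], row["alt"])
        except (KeyError, ValueError) as exc:
            raise BundleValidationError("passthrough.tsv", i + 2, str(exc)) from exc
        passthrough[key] = {c: row.get(c, "") for c in pcols}

    bundle = ReferenceBundle(genes, structures, modifications, rna_patho,
                             passthrough, manifest)
    bundle.validate()
    return bundle


def locate_position(pos: int, bundle: ReferenceBundle) -> list[GeneLocus]:
    """All loci whose interval (with origin-wrap handling) contains ``pos``."""
    return bundle.loci_at(pos)


@lru_cache(maxsize=1)
def load_default_bundle() -> ReferenceBundle:
    """Load the bundle packaged with mtanno (human rCRS annotation tables)."""
    data_dir = resources.files("mtanno.data") / "bundle"
    with resources.as_file(data_dir) as path:
        return load_reference_bundle(path)
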