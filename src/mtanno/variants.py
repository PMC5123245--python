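"""Variant input parsing, HGVS naming and the annotated variant table.

Inputs are VCF 4.x (mitochondrial contig only; multi-allelic records are
split) or a tab-delimited list of ``position<TAB>ref<TAB>alt`` with an
optional fourth sample-id column.  Output is a pandas DataFrame with a
fixed, documented column set modelled on the MToolBox annotation table:
locus, the five-field tRNA structural annotation, the normalized RNA
pathogenicity score and classification, and pass-through columns filled
from the bundled tables when present and left empty otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reference import MT_SEQIDS, ReferenceBundle
from .scoring import SCHEMES, classify_rna_variant, lookup_rna_prediction
from .trna import annotate_trna_position, format_trna_annotation

log = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = {"A", "C", "G", "T"}

VARIANT_KINDS = ("transition", "transversion", "insertion", "deletion")


class VariantParseError(ValueError):
    """A malformed input row; carries the offending line number."""

    def __init__(self, path, line: int, message: str):
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def variant_kind(ref: str, alt: str) -> str:
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    pairs = [(r, a) for r, a in zip(ref, alt) if r != a]
    transitions = all(
        (r in _PURINES and a in _PURINES) or (r in _PYRIMIDINES and a in _PYRIMIDINES)
        for r, a in pairs)
    return "transition" if transitions else "transversion"


@dataclass(frozen=True)
class Variant:
    """A normalized mtDNA variant (rCRS position, DNA-alphabet alleles)."""

    pos: int
    ref: str
    alt: str
    sample: str = ""
    kind: str = field(init=False)

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("empty allele")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical ({self.ref}) at {self.pos}")
        bad = (set(self.ref) | set(self.alt)) - _BASES
        if bad:
            raise ValueError(f"non-ACGT characters {sorted(bad)} at {self.pos}")
        object.__setattr__(self, "kind", variant_kind(self.ref, self.alt))

    @property
    def hgvs(self) -> str:
        return hgvs_name(self)


def hgvs_name(v: Variant) -> str:
    """HGVS genomic name on the mitochondrial ``m.`` coordinate system.

    Substitutions render as ``m.<pos><ref>><alt>``; VCF-style anchored
    alleles are reduced for deletions (``m.<pos>del`` / ``m.<p1>_<p2>del``)
    and insertions (``m.<pos>_<pos+1>ins<seq>``).
    """
    if not v.ref or not v.alt:
        raise ValueError("cannot name a variant with an empty allele")
    if len(v.ref) == 1 and len(v.alt) == 1:
        return f"m.{v.pos}{v.ref}>{v.alt}"
    # strip the shared left anchor common to VCF indel encoding
    k = 0
    while k < min(len(v.ref), len(v.alt)) and v.ref[k] == v.alt[k]:
        k += 1
    if v.kind == "deletion" and k == len(v.alt):
        first = v.pos + k
        last = v.pos + len(v.ref) - 1
        return f"m.{first}del" if first == last else f"m.{first}_{last}del"
    if v.kind == "insertion" and k == len(v.ref):
        ins = v.alt[k:]
        left = v.pos + k - 1
        return f"m.{left}_{left + 1}ins{ins}"
    # delins fallback for non-anchored length changes and MNVs
    last = v.pos + len(v.ref) - 1
    span = f"m.{v.pos}" if v.pos == last else f"m.{v.pos}_{last}"
    return f"{span}delins{v.alt}"


def _read_tsv_variants(path: Path) -> list[Variant]:
    variants = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[0].strip().isdigit():
                continue  # tolerated header line
            if len(fields) < 3:
                raise VariantParseError(path, lineno, "expected at least 3 tab-separated fields")
            try:
                variants.append(Variant(int(fields[0]), fields[1].upper(),
                                        fields[2].upper(),
                                        fields[3] if len(fields) > 3 else ""))
            except ValueError as exc:
                raise VariantParseError(path, lineno, str(exc)) from exc
    return variants


def _read_vcf_variants(path: Path) -> list[Variant]:
    from cyvcf2 import VCF

    variants = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if rec.CHROM not in MT_SEQIDS:
                skipped += 1
                continue
            for alt in rec.ALT:
                try:
                    variants.append(Variant(rec.POS, rec.REF.upper(), alt.upper()))
                except ValueError as exc:
                    raise VariantParseError(path, rec.POS, str(exc)) from exc
    finally:
        vcf.close()
    if skipped:
        log.warning("skipped %d records on non-mitochondrial contigs in %s",
                    skipped, path)
    return variants


def read_variants(path, format: str = "tsv") -> list[Variant]:
    """Read and normalize a variant list from a VCF or TSV file."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf_variants(path)
    if format == "tsv":
        return _read_tsv_variants(path)
    raise ValueError(f"unknown variant format {format!r} (expected 'vcf' or 'tsv')")


#: Fixed output column order of the annotated table.
ANNOTATION_COLUMNS = (
    "HGVS", "Position", "Ref", "Alt", "Kind", "Locus",
    "tRNA_Annotation", "RNA_Prediction_Score", "RNA_Prediction",
    "RNA_Classification",
    "RSRS", "MHCS", "rCRS", "Nt_Variability",
    "MITOMAP_Associated_Diseases", "MITOMAP_Homoplasmy", "MITOMAP_Heteroplasmy",
    "ClinVar", "OMIM", "dbSNP", "Mamit_tRNA",
    "PhastCons20Way", "PhyloP20Way",
)

#: passthrough.tsv column -> output column
_PASSTHROUGH_MAP = {
    "rsrs": "RSRS", "mhcs": "MHCS", "rcrs": "rCRS",
    "nt_variability": "Nt_Variability",
    "mitomap_diseases": "MITOMAP_Associated_Diseases",
    "mitomap_homoplasmy": "MITOMAP_Homoplasmy",
    "mitomap_heteroplasmy": "MITOMAP_Heteroplasmy",
    "clinvar": "ClinVar", "omim": "OMIM", "dbsnp": "dbSNP",
    "mamit_trna": "Mamit_tRNA",
    "phastcons20way": "PhastCons20Way", "phylop20way": "PhyloP20Way",
}


def annotate_variants(variants, bundle: ReferenceBundle) -> pd.DataFrame:
    """One annotated row per input variant, order preserved.

    Empty annotation cells are rendered as empty strings (not "NA").
    Unknown positions annotate with an empty Locus; nothing is fatal.
    """
    rows = []
    for v in variants:
        row = {c: "" for c in ANNOTATION_COLUMNS}
        row.update(HGVS=v.hgvs, Position=v.pos, Ref=v.ref, Alt=v.alt, Kind=v.kind)
        try:
            loci = bundle.loci_at(v.pos)
        except Exception:
            loci = []
        row["Locus"] = "/".join(g.name for g in loci)
        ann = annotate_trna_position(v.pos, bundle)
        if ann is not None:
            row["tRNA_Annotation"] = format_trna_annotation(ann)
        patho = lookup_rna_prediction(v, bundle)
        if patho is not None:
            row["RNA_Prediction_Score"] = patho.normalized_score
            row["RNA_Prediction"] = patho.prediction
            row["RNA_Classification"] = classify_rna_variant(
                patho.normalized_score, SCHEMES[patho.scheme])
        passthrough = bundle.passthrough.get((v.pos, v.ref, v.alt), {})
        for src, dst in _PASSTHROUGH_MAP.items():
            if src in passthrough and passthrough[src] != "":
                row[dst] = passthrough[src]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def annotation_summary(table: pd.DataFrame, bundle: ReferenceBundle) -> dict:
    """Basic per-run statistics for the JSON run summary."""
    by_biotype: dict[str, int] = {}
    for _, row in table.iterrows():
        loci = row["Locus"].split("/") if row["Locus"] else []
        biotypes = {bundle.gene(name).biotype for name in loci if name} or {"intergenic"}
        for b in sorted(biotypes):
            by_biotype[b] = by_biotype.get(b, 0) + 1
    classifications = table["RNA_Classification"].value_counts().to_dict()
    return {
        "n_variants": int(len(table)),
        "variants_per_biotype": by_biotype,
        "variants_per_kind": table["Kind"].value_counts().to_dict() if len(table) else {},
        "rna_damaging": int(classifications.get("damaging", 0)),
        "rna_neutral": int(classifications.get("neutral", 0)),
        "rna_scored": int((table["RNA_Prediction_Score"] != "").sum()) if len(table) else 0,
    }
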