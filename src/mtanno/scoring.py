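"""Normalization and classification of literature RNA pathogenicity scores.

Two published scoring systems are consumed: a 0-20 integer scale for tRNA
gene variants and a 0-5 scale for (12S) rRNA gene variants.  Raw scores are
the citable source of truth; they are divided by the scale maximum and
rounded half-even to three decimals, giving exact 0.050 steps on the tRNA
scale and 0.200 steps on the rRNA scale.  A variant is called *damaging*
when its normalized score is greater than or equal to the scheme threshold
(0.350 for tRNA, 0.600 for rRNA; the comparison is inclusive), *neutral*
below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .reference import ReferenceBundle, RnaPathoRecord


@dataclass(frozen=True)
class ScoringScheme:
    name: str
    max_raw: int
    threshold: float
    label_map: dict[int, str]

    def __post_init__(self):
        # threshold must be attainable by normalization, i.e. a multiple of
        # 1/max_raw; label_map must cover the whole raw range.
        steps = self.threshold * self.max_raw
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"threshold {self.threshold} not a multiple of 1/{self.max_raw}")
        if set(self.label_map) != set(range(self.max_raw + 1)):
            raise ValueError(f"label_map must cover 0..{self.max_raw}")


def _trna_label(raw: int) -> str:
    if raw <= 6:
        return "Neutral"
    if raw <= 10:
        return "Possibly pathogenic"
    if raw <= 13:
        return "Possibly/definitely pathogenic"
    return "Definitely pathogenic"


TRNA_SCHEME = ScoringScheme(
    name="tRNA",
    max_raw=20,
    threshold=0.350,
    label_map={raw: _trna_label(raw) for raw in range(21)},
)

RRNA_SCHEME = ScoringScheme(
    name="rRNA",
    max_raw=5,
    threshold=0.600,
    label_map={
        0: "Unlikely pathogenic",
        1: "Undetermined",
        2: "Not enough evidence",
        3: "Likely pathogenic",
        4: "Expectedly pathogenic",
        5: "Proven pathogenic",
    },
)

SCHEMES = {"tRNA": TRNA_SCHEME, "rRNA": RRNA_SCHEME}


def normalize_score(raw: int, scheme: ScoringScheme) -> float:
    """``raw / max_raw`` rounded half-even to 3 decimals."""
    if not isinstance(raw, int) or isinstance(raw, bool):
        raise TypeError(f"raw score must be an integer, got {raw!r}")
    if not 0 <= raw <= scheme.max_raw:
        raise ValueError(
            f"raw score {raw} outside 0..{scheme.max_raw} for scheme {scheme.name}")
    return round(raw / scheme.max_raw, 3)


def classify_rna_variant(normalized: float, scheme: ScoringScheme) -> str:
    """``"damaging"`` iff ``normalized >= threshold`` (inclusive), else ``"neutral"``."""
    if not 0.0 <= normalized <= 1.0:
        raise ValueError(f"normalized score {normalized} outside [0, 1]")
    return "damaging" if normalized >= scheme.threshold else "neutral"


def lookup_rna_prediction(variant, bundle: ReferenceBundle) -> Optional[RnaPathoRecord]:
    """Exact (position, ref, alt) lookup in the bundled scored-variant table.

    Allele-aware by design: distinct substitutions at one site carry
    distinct published scores, so there is no fallback to position-only
    matching.  Accepts anything with ``pos``, ``ref`` and ``alt``
    attributes.
    """
    return bundle.rna_patho.get((variant.pos, variant.ref, variant.alt))
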