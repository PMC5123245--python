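# Methods

## The annotation model

`mtanno` is table-driven by design: mt-tRNA secondary and tertiary structure
cannot be predicted reliably from sequence alone (mitochondrial tRNAs are
strongly non-canonical), so every structural statement the package makes comes
from a curated *reference bundle* rather than from folding computation. The
bundle is a directory of tab-delimited UTF-8 tables plus a JSON manifest, and
all invariants — strictly increasing Sprinzl numbers along each gene, the
anticodon triplet confined to the anticodon loop, folding flags exactly
matching the tertiary interaction sets, normalized scores consistent with raw
scores — are re-checked every time a bundle is loaded. A bundle that
round-trips through `ReferenceBundle.save` reloads identically, and the
synthetic fixtures serialize through the same writer so tests always exercise
the production loaders.

Coordinates are 1-based inclusive on the rCRS throughout, matching the `m.`
HGVS convention; the genome is treated as circular and exactly one locus (the
control region, 16024..576) wraps the origin. Gene offsets count along each
feature's own 5′→3′ transcription direction, so for light-strand genes offset
1 sits at the genomic *end* coordinate and transcript bases are complements of
the reference. The strand flag is stored per gene from the standard rCRS
annotation (8 tRNAs and ND6 on the light strand) rather than inferred.

## The packaged bundle: curated versus synthetic

The full 22-gene Sprinzl alignment is not published in one place; the packaged
bundle is therefore an explicit mixture, regenerated deterministically by
`scripts/build_default_bundle.py`:

* **Real, curated:** gene coordinates and strands; the modification table (116
  entries across human-confirmed, bovine-predicted and model-organism-predicted
  evidence, covering 110 distinct modified residues with 16 modification
  types); Modomics symbols; anticodon identities at Sprinzl 34–36; the scoring
  schemes; the worked-example anchor for MT-TM (gene offset 49 = Sprinzl 53,
  TΨC stem, mature G, no tertiary involvement) and the two literature-anchored
  scored variants (m.4450G>A, m.1555A>G).
* **Approximate curation:** the structural-class assignment beyond the
  published anchors (MT-TM type II; the single D-arm-less type III is
  Ser(AGY); type I assigned to Ser(UCN); a six-gene type-0 set with type II
  remaining the most common class), and the placement of alignment gaps, which
  follows a fixed priority list over dispensable D-loop/variable-loop/T-loop
  positions (17, 47, 20, 16, 59, 21, 46, 60, …) consistent with the MT-TM
  anchor and with the variable D/T-loop sizes characteristic of mt-tRNAs.
* **Synthetic placeholders:** mature plain bases at unanchored, unmodified
  positions. The true per-position gene sequences are not bundled; these bases
  are generated deterministically per gene and declared as placeholders in the
  manifest (`provenance.mature_base_provenance`). Rows of the scored-variant
  and pass-through tables added purely for testing carry
  `synthetic-fixture` in their source column.

Consequences: annotations of the *anchored* fields (locus, Sprinzl number,
domain, type, folding, scores, modified residues) are faithful; the mature-base
field for unanchored positions is structurally valid but not the true human
base, and a production deployment would swap in sequences from the primary
resources using the same bundle format.

Two counting conventions in the bundle deserve note. First, "modified
residues" counts distinct (tRNA species, Sprinzl position) pairs — six residues
carry two alternative modifications (Glu/Gln at 34; Phe, Ser(UCN), Trp, Tyr at
37), so 116 table entries describe 110 residues. Where the two alternatives
would both claim the mature-base symbol, the more-derived modification wins
(5-taurinomethyl-2-thiouridine over 5-taurinomethyluridine,
2-methylthio-N6-isopentenyladenosine over N6-isopentenyladenosine). Second,
the `MT-RNA` track and the manifest count tRNA positions *per gene*: the 22
genes span 1508 gene-position records (1504 distinct genomic positions, since
MT-TI/MT-TQ overlap by three bases and MT-TC/MT-TY share one); rRNA genes span
2513. A position inside two tRNA genes genuinely has two structural
annotations, so per-gene records are kept; single-variant annotation reports
the earlier-starting gene's map.

## Scoring

Raw literature scores are the source of truth and are stored as integers;
normalization (`raw / max_raw`, half-even rounding to 3 decimals) happens on
load and on demand. The damaging/neutral decision is `normalized ≥ threshold`
with thresholds 0.350 (tRNA, i.e. raw 7 of 20) and 0.600 (rRNA, raw 3 of 5);
the boundary is deliberately inclusive. Score lookup never falls back to
position-only matching because different substitutions at one site have
different published scores.

## Enumeration

Effect classification uses NCBI translation table 2 (vertebrate mitochondrial)
via Biopython. A substitution is stop-gain iff the reference codon translates
to an amino acid and the alternate codon is a stop, stop-loss for the
converse; the four classes are mutually exclusive and exhaustive, so per gene
`synonymous + nonsynonymous + stop_gain + stop_loss = 3 × (in-frame coding
positions)`. Incomplete terminal codons (stops completed by polyadenylation,
e.g. trailing 1–2 bases of several mt genes) are excluded by default and
enumerable behind `include_incomplete_stops`, which A-pads the trailing codon
— the convention is explicit because published full-genome totals do not state
theirs. Overlapping genes are classified once per reading frame by default;
the summary always reports both the per-gene-context and the
de-duplicated-by-site counts so either convention can be read off. Full-genome
enumeration requires the user-supplied rCRS FASTA (never fetched at runtime
and not bundled, since the true sequence is not shipped); the CLI then prints
the comparison against the published totals of 24,202 nonsynonymous, 1,740
stop-gain and 77 stop-loss substitutions.

## Synthetic fixtures

The generators emulate exactly what the annotation layer consumes: valid
structure maps of all four structural classes (type III built without a
D-stem; type 0 with the D/T-loop pairs), toy circular genomes with coding
genes on both strands (start codons ATG/ATA, vertebrate-mitochondrial stops,
optional frame-shifted overlapping locus), and variant lists spanning tRNA,
coding and intergenic regions. Ground truth is computed by independent code
paths — raw alignment lookup for structure, whole-protein re-translation of
mutated sequence strings for effects — so agreement tests are genuine
dual-route checks. One `random.Random(seed)` stream drives each generator;
regeneration is bit-identical.

What the fixtures do *not* emulate: realistic mutation spectra, heteroplasmy,
sequencing error, genome-scale gene density, or the true rCRS sequence.
Passing fixture tests therefore demonstrates correctness of the annotation
*logic* under the documented conventions, not concordance with every curated
value a production bundle would carry.

Default fixture sizes (3 genes × ~9 codons, two tRNAs, ≤ 25 variants; oracle
sweeps over 20 seeds at ≤ 30 codons) were chosen as the smallest problems that
still exercise both strands, overlaps, all four structural classes and all
four effect classes.

## Numerical and formatting choices

* Half-even rounding to 3 decimals for scores (`round()` semantics), making
  the tRNA grid exact multiples of 0.050 and the rRNA grid of 0.200.
* Mature nucleotides are reported in the RNA alphabet (U not T) because they
  describe the transcript; variant alleles stay in the DNA alphabet.
* Unmapped Sprinzl positions render as `-` in field 1; the five-field contract
  never varies in field count.
* The folding flag encodes tertiary pair/triplet participation only — base
  stacking involves nearly every nucleotide and would make the flag
  uninformative.
* GFF3 output is 1-based like the rest of the package; seqid defaults to
  `chrM` with `MT` and `NC_012920.1` dialects available; the score column
  carries the normalized RNA score where applicable and `.` otherwise;
  attribute values percent-encode the reserved characters; records are sorted
  by start and the writer refuses unsorted input.
* Empty annotation cells are empty strings, not `NA`.
* Variant kind: transitions are single-base A↔G / C↔T exchanges; length
  changes are insertions/deletions by allele-length comparison; equal-length
  multi-base replacements are called transitions only if every mismatched
  column is a transition.
* Deterministic tie-breaks throughout: multi-locus annotation uses the
  earlier-starting gene; de-duplicated enumeration keeps the first gene
  context; track sorting is by (start, end, type, ID).

## Known limitations

* Mature bases at unanchored positions are synthetic placeholders (above).
* Structural-class membership and gap placement beyond the anchored genes are
  approximate curation; per-gene alignments can be replaced wholesale via the
  bundle format without code changes.
* Pass-through columns (MITOMAP, ClinVar, dbSNP, OMIM, conservation,
  variability) are static bundled snapshots, not live queries, and the
  packaged bundle carries them only for the anchored variants.
* No read mapping, heteroplasmy quantification, haplogroup assignment or
  missense pathogenicity prediction — upstream or out of scope by design.
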