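# mtanno

Structure-aware annotation of human mitochondrial DNA variants, with first-class
support for the 22 mt-tRNA genes.

Most variant annotation tools say little about mitochondrial tRNA variants beyond
"non-coding". Yet mt-tRNA genes are mutational hot spots, and whether a
substitution matters depends on *where it lands in the folded tRNA*: the acceptor
stem, the anticodon triplet, a post-transcriptionally modified residue, or a
position engaged in the tertiary interactions that hold the L-shaped fold
together. `mtanno` gives clinicians and mitochondrial researchers that context
for any variant on the rCRS (the 16,569-bp revised Cambridge Reference Sequence,
GenBank J01415.2), plus normalized literature pathogenicity scores, an exhaustive
map of the protein-coding mutational space, and GFF3 tracks for genome browsers.

## What it computes

**tRNA structural annotation.** Every position of every mt-tRNA gene is mapped to
a five-field annotation string

```
sprinzl;type;domain;mature;folding        e.g.  53;II;TS;G;N
```

* *sprinzl* — the standard structural numbering 1–73 (CCA end excluded;
  anticodon at 34–36); positions with no counterpart in the standard numbering
  render `-`.
* *type* — structural class 0/I/II/III of the tRNA (quasi-canonical with the
  D-loop/T-loop interaction; atypical anticodon stem; D/T interaction lost;
  D-stem absent).
* *domain* — cloverleaf region: stems `AS`, `DS`, `CS`, `TS`, loops `DL`, `CL`,
  `VL`, `TL`, 3′ end `E`, junctions `-`.
* *mature* — the nucleotide in the functional tRNA after post-transcriptional
  modification, as a one-character Modomics symbol (`P` pseudouridine, `Q`
  queuosine, `Ê` 5-taurinomethyluridine, …) or a plain RNA base.
* *folding* — `Y` if the position participates in the tertiary pairs/triplets
  (10-25-45, 9-23-12, 13-22-46, 8-14, 15-48, 26-44, 54-58, and 18-55/19-56 in
  type-0 tRNAs) that stabilise the three-dimensional fold.

**RNA pathogenicity scoring.** Literature scores for tRNA (integer 0–20) and
rRNA (0–5) variants are normalized as

&nbsp;&nbsp;&nbsp;&nbsp;*s* = raw / raw<sub>max</sub>, rounded half-even to 3 decimals,

and classified **damaging** when *s* ≥ threshold (0.350 for tRNA, 0.600 for
rRNA; the comparison is inclusive), **neutral** otherwise. Lookups are
allele-aware: `(position, ref, alt)` must match exactly.

**Coding-space enumeration.** All 3 possible substitutions at every in-frame
position of the 13 protein-coding genes, classified as synonymous /
nonsynonymous / stop-gain / stop-loss under the vertebrate mitochondrial
genetic code (UGA=Trp, AUA=Met, AGA/AGG=stop), with strand handled through each
gene's orientation flag and overlapping genes classified once per reading frame.

**Tracks.** Four browser-ready GFF3 tracks: `MT-patho.CDS` (all nonsynonymous
substitutions), `MT-patho.STOP` (stop-gain + stop-loss), `MT-patho.RNA` (scored
RNA variants) and `MT-RNA` (per-position tRNA/rRNA annotations).

## Worked example

Annotate the myopathy-associated MT-TM variant m.4450G>A:

```bash
printf '4450\tG\tA\n' > variant.tsv
mtanno annotate --input variant.tsv --format tsv --out out/
```

`out/annotated.tsv` contains (abridged):

| HGVS | Locus | tRNA_Annotation | RNA_Prediction_Score | RNA_Classification | MITOMAP_Associated_Diseases |
|---|---|---|---|---|---|
| m.4450G>A | MT-TM | 53;II;TS;G;N | 0.65 | damaging | Myopathy |

Read: the variant hits Sprinzl position 53 of tRNA-Met (a type-II mt-tRNA), in
the TΨC stem, an unmodified G, not engaged in tertiary folding; its literature
raw score 13/20 normalizes to 0.65, above the 0.350 tRNA threshold, hence
damaging. `out/summary.json` records the run parameters and tallies
(`"rna_damaging": 1`).

Other commands:

```bash
mtanno fixtures  --seed 11 --out fx/                 # synthetic genome + bundle + truth
mtanno enumerate --reference fx/genome.fasta --bundle fx/bundle --out enum/
mtanno tracks    --reference fx/genome.fasta --bundle fx/bundle --out tracks/
```

`enumerate` writes the full classified substitution table and a counts JSON
(both per-gene-context and de-duplicated by site); when run on the 16,569-bp
human reference it additionally reports the comparison against the published
full-genome totals. The variant TSV input format is 1-based
`position<TAB>ref<TAB>alt` with an optional sample-id column; VCF 4.x is
accepted with `--format vcf`.

The packaged reference bundle (`src/mtanno/data/bundle/`) carries the rCRS gene
map, per-tRNA structure maps, the 116-entry post-transcriptional modification
table (110 distinct modified residues, 16 modification types) and the scored
RNA variant tables. `scripts/build_default_bundle.py` is the curation record
that regenerates it; see `docs/methods.md` for what is curated versus
synthetic placeholder.

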