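{
 "counts": {
  "modification_types": 16,
  "modified_residues": 110,
  "protein_coding_genes": 13,
  "rrna_genes": 2,
  "rrna_positions": 2513,
  "trna_distinct_positions": 1504,
  "trna_genes": 22,
  "trna_positions": 1508
 },
 "genome_length": 16569,
 "passthrough_columns": [
  "rsrs",
  "mhcs",
  "rcrs",
  "nt_variability",
  "mitomap_diseases",
  "mitomap_homoplasmy",
  "mitomap_heteroplasmy",
  "clinvar",
  "omim",
  "dbsnp",
  "mamit_trna",
  "phastcons20way",
  "phylop20way"
 ],
 "provenance": {
  "coordinates": "standard rCRS annotation (GenBank J01415.2)",
  "mature_base_provenance": "Modomics symbols at modified residues and anticodons at Sprinzl 34-36 are curated; other plain bases are deterministic synthetic placeholders",
  "rna_patho": "see source_citation column; synthetic rows labelled"
 },
 "schema_version": 1,
 "seqid": "chrM",
 "tables": {
  "genes.tsv": 38,
  "modifications.tsv": 116,
  "passthrough.tsv": 2,
  "rna_patho.tsv": 6,
  "tertiary.tsv": 159,
  "trna_structure.tsv": 1508
 }
}
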