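# splicepep

Build exhaustive, MS-searchable peptide databases that represent protein
isoforms of a eukaryotic genome: in-frame exonic peptides, annotated and
hypothetical splice-junction peptides, and single-SNP variant peptides —
plus peptide→protein mapping, sequence queries, reversed-decoy databases,
and multi-level target-decoy FDR evaluation.

## What it generates

For every protein-coding gene, five kinds of *peptide regions* are
enumerated from a genome FASTA and a CDS annotation (GFF3):

| type      | source                                   | cDNA window | frames    | stop codons |
|-----------|------------------------------------------|-------------|-----------|-------------|
| `EXON_KB` | each coding exon                         | whole exon  | annotated | not tolerated |
| `E_E_KB`  | annotated exon–exon junctions            | ≤ 240 bp    | annotated | not tolerated |
| `E_I_TH`  | exon + adjacent downstream intron        | ≤ 240 bp    | all 3     | tolerated in the intron (truncating) |
| `I_E_TH`  | adjacent upstream intron + exon          | ≤ 240 bp    | all 3     | not tolerated |
| `E_E_TH`  | unannotated exon–exon combinations       | ≤ 240 bp    | all 3     | tolerated in the 3′ exon (truncating) |

Junction windows take up to 120 nt on each side of the splice site (240 nt
≈ an 80-residue peptide, the longest routinely observed in MS), so any
identifiable junction-crossing peptide is contained in some region. A stop
codon as the final codon of a region is stripped; elsewhere it invalidates
or truncates the candidate according to the table above. Exonic SNPs from a
VCF are then substituted one at a time into each region's cDNA, re-translated
under the same protocol, and kept when non-synonymous — yielding
`REGnnnnnnnnn` region records and `PEPnnnnnnnnn` peptide records with
peptide–SNP mappings.

## Command line

```sh
# make a synthetic genome + GFF3 + VCF fixture with known ground truth
splicepep simulate --seed 1 --n-genes 3 --cassette --out-dir sim/

# build the peptide database (presets: PEPPI_KB = exonic + annotated
# junctions; PEPPI_without_SNP = all five region types; PEPPI_with_SNP =
# all five types plus SNP variant peptides)
splicepep build --genome sim/genome.fasta --annotation sim/annotation.gff3 \
    --vcf sim/snps.vcf --preset PEPPI_with_SNP --out-dir db/

# map peptides onto a protein FASTA (Aho-Corasick, all occurrences)
splicepep map --peptides db/peptides.fasta --proteins sim/proteins.fasta \
    --out hits.tsv

# query a peptide sequence
splicepep search --peptides db/peptides.fasta MAGWK

# reversed-decoy database and target-decoy FDR
splicepep decoy proteins.fasta decoy.fasta
splicepep fdr --hits hits_table.tsv --level peptide --max-fdr 0.01
```

`build` writes `peptides.fasta` (one record per peptide, header
`>PEPnnnnnnnnn REG=… TYPE=… GENE=… ORF=… SNP=… LOC=chrom:a-b[|c-d](±)`),
four TSV tables (regions, peptides, peptide–SNP map, peptide–protein hits)
and a rejection log. All outputs are deterministic functions of the inputs.

FDR levels: `ms2`, `protein_gene` and `peppi` use the concatenated-search
estimator 2d/(t+d); `peptide` uses d/(t+d). Entities at the peptide and
higher levels must be observed in ≥ 2 distinct samples by default.

## Library layout

- `splicepep.genome_model` — domain types and FASTA/GFF3/VCF readers,
  oriented sequence extraction, translation.
- `splicepep.preprocess` — coding-gene filter, exon knowledgebase,
  exon-adjacency knowledgebase, exonic-SNP filter.
- `splicepep.region_gen` — the five region generators and the stop-codon
  protocols.
- `splicepep.snp_variants` — SNP placement, variant translation,
  peptide–SNP links.
- `splicepep.mapping_search` — peptide→protein mapping, sequence search,
  differential mapping with cassette-exon inference.
- `splicepep.decoy_fdr` — decoy FASTA, two-sample filtering, multi-level
  FDR estimators, E-value threshold sweep.
- `splicepep.fixtures` — seeded synthetic genome/annotation/VCF generator
  with ground truth, and an independent brute-force oracle used by the
  tests.
- `splicepep.export` / `splicepep.cli` — FASTA/TSV writers and the CLI.

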