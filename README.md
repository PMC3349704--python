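# snoverify

Tools for identifying C/D box snoRNA genes in vertebrate genomes, telling
genes apart from their pseudogenes, and checking claimed guide–target
assignments against the rules of 2'-O-methylation guidance.

## The problem

C/D box snoRNAs direct 2'-O-methylation of rRNA (and some snRNAs). A
functional gene copy has a recognizable anatomy: a terminal inverted
repeat (the stem), the C box (consensus `UGAUGA`) near the 5' end and the
D box (`CUGA`) near the 3' end, often-imperfect internal copies C' and D',
and — immediately upstream of the D and/or D' box — an antisense element of
9–20 nt complementary to the target RNA. In the guide:target duplex the
target nucleotide paired four nucleotides from the D/D' box is methylated
(the guide partner sits at box start − 5, so exactly four snoRNA
nucleotides lie strictly between it and the box). Nearly all vertebrate
snoRNA genes sit inside host-gene introns and are processed from the host
pre-mRNA; only a handful (SNORD3, SNORD13, SNORD118, SCARNA2, SCARNA17)
carry their own promoters.

Automated censuses routinely conflate genes with pseudogenes: intergenic
retro-copies, copies with substitutions in the conserved boxes, and
truncated copies are counted as genes; whole inter-box fragments are
annotated as "antisense elements"; methylation targets are claimed at
sites more than four nucleotides from the box, or in eukaryotic 5S rRNA,
which carries no 2'-O-methylated nucleotides at all. `snoverify`
implements the anatomy checks, the guide geometry, the genomic-context
logic and a relaxed homolog search so these calls can be made — and
audited — programmatically, and proposes uniform species-prefixed names
for homologs of human snoRNAs (`mmusSNORD87` for the mouse homolog of
SNORD87).

## What is in the package

| module | contents |
| --- | --- |
| `snoverify.motif` | degenerate-consensus box scanning (C, D, C', D', H, ACA), C/D layout assembly, terminal-stem finder |
| `snoverify.duplex` | antisense-element duplexes (Watson–Crick + G-U), the four-nucleotide site rule, claimed-target validation with machine-readable error classes |
| `snoverify.context` | intron enumeration, intronic / exon-overlap / intergenic calls, transcript-evidence containment |
| `snoverify.search` | seeded gapped local alignment (word size 3, first gap character cost 1) with an exhaustive-local-alignment limit, host-gene-guided search, end-gap-free global identity |
| `snoverify.classifier` | gene / pseudogene / uncertain verdicts with reason codes; per-family census |
| `snoverify.nomenclature` | four-letter species prefixes and homolog names |
| `snoverify.simulate` | seeded generator of snoRNA genes, pseudogene classes, host genes, toy genomes and truth tables |
| `snoverify.pipeline` | genome-wide discover → locate → classify runs |
| `snoverify.cli` | the `snoverify` command (scan, targets, validate-targets, search, classify, census, name, simulate) |

## Worked example

Generate a three-family toy genome with one intronic gene copy and five
pseudogene-class copies per family, classify every locus, and summarize:

```sh
snoverify simulate --seed 4 --out-dir fx
snoverify classify --genome fx/genome.fa --gff fx/genes.gff3 \
    --catalog fx/catalog.tsv --targets fx/targets.fa --out calls.tsv
snoverify census --calls calls.tsv --species toy --out census.tsv
```

The classify step prints `classified 18 candidate locus/loci -> calls.tsv`.
The first rows of `calls.tsv` (selected columns):

```
candidate_id                family    location    label       reasons
chr1_SNORD951:421-481(+)    SNORD951  intronic    gene
chr1_SNORD951:2181-2241(+)  SNORD951  intergenic  pseudogene  BOX_MUT_D;INTERGENIC
chr1_SNORD951:2477-2528(+)  SNORD951  intergenic  pseudogene  TRUNC_5;BOX_MUT_C;BOX_MUT_DPRIME;NO_STEM;INTERGENIC
```

The intact copy inside the host intron is a gene; the intergenic copy with
a D-box substitution and the 5'-truncated copy are pseudogenes, each with
the evidence spelled out. `census.tsv` separates what a raw homolog count
would have merged:

```
family    species  n_genes  n_pseudogenes  n_uncertain
SNORD951  toy      1        4              1
SNORD952  toy      1        4              1
SNORD953  toy      1        4              1
```

The `n_uncertain` column holds the intact-but-intergenic retro-copies:
nothing in their sequence rules function out, but without transcript
evidence their independent transcription is unsupported. Finally,

```sh
snoverify name --species "Mus musculus" --gene SNORD87
# mmusSNORD87
```

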