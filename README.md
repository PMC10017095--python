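# refsmith

Analyzing a functional-genomics experiment (ATAC-, ChIP-, RNA-seq, ...)
starts with reference data: a genome assembly FASTA and a gene
annotation, retrievable from several organizations in several versions
with divergent naming, formats and quality. Fetching and preparing
these by hand is tedious and poorly reproducible. **refsmith** is a
library and CLI that searches assembly metadata, installs (fetches and
preprocesses) genomes and annotations with controllable
masking/filtering, generates supporting files (byte-offset index,
contig sizes, assembly-gap intervals), interconverts annotation
formats, harmonizes contig naming between annotation and genome, and
logs provenance — designed so that every feature is testable entirely
offline against a filesystem-backed provider and synthetic fixtures
with known ground truth.

It is aimed at bioinformaticians who want one reproducible command (or
Python call) between "I need GRCz11 soft-masked without alt contigs"
and a ready-to-align reference directory.

## What it computes

* **Search** — cached per-provider metadata tables are queried by free
  text, taxonomy ID, or INSDC assembly accession
  (`GC[AF]_` + 9 digits + optional `.version`); the query type is
  recognized automatically, and a version-less accession matches every
  version.
* **Genome store** — a faidx-style index maps a 0-based base offset
  *b* of a contig with line geometry (offset *o*, bases/line *l*,
  bytes/line *w*) to the file byte `o + (b // l)·w + (b % l)`, giving
  O(1) extraction of any region, with IUPAC-aware reverse complement
  for the minus strand. Masking levels follow FASTA convention:
  *soft* keeps lowercase repeat masking, *hard* replaces every
  lowercase base with `N`, *none* uppercases. Assembly gaps are the
  maximal runs of `N`/`n`. Random regions are drawn uniformly from the
  pool of valid start positions, so a contig's sampling probability is
  proportional to its valid-start count.
* **Annotation** — GFF3, GTF and BED12 all parse into one transcript
  model (ordered disjoint exons + optional CDS span, the BED12 "thick"
  region), which converts losslessly among the three. Contig names
  are harmonized against the genome by deterministic ordered rules:
  exact match > alias-group lookup (assembly-report-style tables) >
  `chr`-prefix add/remove > case-insensitive match; ambiguities are
  errors, never guesses.
* **Install** — one pipeline: fetch, decompress, drop alternate-locus
  contigs (they cause multi-mapping during alignment), regex contig
  filter, masking transform, rewrap, index, sizes, gaps, annotation
  conversion + harmonization, plugins, and a provenance README listing
  time, source files, processing steps, and every filtered contig.

## Worked example

Build a synthetic provider and install from it (all offline):

```python
from refsmith import fixtures as fx
fx.build_provider(fx.FixtureSpec(seed=11), "provider", annotation_scheme="ensembl")
```

```console
$ refsmith search Synthetica --cache-root provider
name     provider     accession        taxonomy_id  annotations  species
synasm1  fixtureprov  GCA_128570202.7  424242       + - -        Synthetica exempli

$ refsmith install synasm1 --provider fixtureprov \
      --cache-root provider --provider-root provider --output genomes
genomes/synasm1
```

The one search hit shows the assembly, its accession and taxonomy ID,
and one availability mark per annotation source (`+ - -`: GFF3 yes,
GTF/BED12 no). The install directory contains the processed genome and
every supporting file:

```console
$ refsmith genome sizes genomes/synasm1/synasm1.fa
chr1	24014
chr2	31245
chr3	43521
chrUn_KN149601v1	28078

$ head -3 genomes/synasm1/synasm1.gaps.bed
chr1	3458	3500
chr1	12896	12917
chr2	14649	14669

$ refsmith genome extract genomes/synasm1/synasm1.fa chr1:1001-1032
AACAACCTTCTTGGTATACTTACTACGAGCGT

$ refsmith annotation genomes/synasm1/synasm1.annotation.gtf -n 2
# format: gtf
chr2	refsmith	transcript	53	437	.	-	.	gene_id "gene0011"; transcript_id "tx0011.2"; gene_name "GENE0011";
chr2	refsmith	exon	434	437	.	-	.	gene_id "gene0011"; transcript_id "tx0011.2"; gene_name "GENE0011"; exon_number "1";
```

Sizes are per-contig base counts; the gaps BED is 0-based half-open;
extraction addresses are 1-based fully-closed (samtools convention).
Note the annotation was shipped by the provider in GFF3 with
Ensembl-style contig names (`1`, `2`, ...) and has been converted to
GTF/BED12 and renamed to the genome's names (`chr2`), with
`exon_number 1` assigned to the rightmost exon on the minus strand.
The alternate-locus contig shipped with the genome was removed and is
listed under `## filtered contigs` in `genomes/synasm1/README.txt`,
alongside every source URI and processing step.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch: it builds a
seeded synthetic provider, searches the metadata cache, runs a full
install, and re-verifies the installed index, contig sizes, gap
intervals, 500 random sequence extractions, the converted annotation,
and the provenance README against independent brute-force oracles,
then writes the results JSON to `--out`. A non-zero exit means a
verification failed.
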