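# Methods

This note records the models, conventions and deliberate choices
behind refsmith, in the spirit of the methods documentation of mature
scientific packages: what each component assumes, which knobs matter,
and what a passing test does and does not establish.

## Coordinate conventions

Everything internal is 0-based half-open (BED-native). GTF and GFF3
are 1-based fully-closed on disk; conversion happens exactly once at
the parse/emit boundary, so (1-closed → 0-half-open → 1-closed) is the
identity by construction. User-facing region strings
(`contig:start-end`) are 1-based fully-closed, the samtools
convention, converted only in `parse_region`/`format_region`.

## Genome store

**Index.** The index is a per-contig table of (name, length, first
sequence byte, bases per line, bytes per line) over the uncompressed
byte stream — the faidx layout, computed in one streaming pass. It
requires the standard well-formedness property (all sequence lines of
a record except the last have equal length); ragged or blank interior
lines are hard errors naming the contig and line, because silent
tolerance would corrupt the seek arithmetic. Empty records index with
length 0. gzip input is handled by transparent decompression; gzip
output is written with a zeroed mtime so identical inputs give
byte-identical archives.

**Extraction.** A region's bytes are located by line-geometry
arithmetic and whitespace is stripped after the read, so extraction is
O(region length) after an O(1) seek. The minus strand applies the
full IUPAC complement table (A↔T, C↔G, R↔Y, S↔S, W↔W, K↔M, B↔V, D↔H,
N↔N), case-preserving, then reverses.

**Masking.** The only masking signal a FASTA carries is case, so
*hard* replaces exactly the lowercase alphabet with `N` and *none*
uppercases it; uppercase repeats are unknowable and untouched. Both
transforms are byte-local: headers, line wrapping and lengths are
preserved, which makes hard/none idempotent and *soft* the literal
byte identity. Genome normalization (rewrapping at 80 bases/line) is
a separate, explicit installer step rather than a side effect of
masking or filtering, so those operations keep byte-identical records
and diffs stay meaningful.

**Gaps.** A gap is a maximal run of `N`/`n`, minimum length 1. Other
IUPAC ambiguity codes are not gaps; they denote polymorphism, not
missing assembly sequence.

**Alt contigs.** Alternate-locus contigs are recognized purely by
header-token patterns (case-insensitive `_alt` substring, `alt`
suffix, or `hap` followed by a digit), the signal providers actually
put in names. No length- or similarity-based analysis is attempted;
the pattern list is an argument and can be overridden. This is a
documented stand-in: a provider could in principle name an alt locus
outside these conventions.

**Random regions.** Each contig contributes its count of valid start
positions (positions where a region of the requested length fits
entirely inside the contig and, when gap exclusion is on, overlaps no
gap — computed exactly by interval subtraction, not rejection
sampling). A start index is drawn uniformly from the concatenated
pool with a seeded NumPy generator, which makes the
length-proportional sampling property provable and the function a pure
function of (index, n, length, seed, exclude_gaps, gaps).

## Annotation model

The conversion pivot is the transcript — BED12 is transcript-level, so
genes are re-derivable metadata, not stored objects. A transcript is
(ids, contig, strand, ordered pairwise-disjoint exons, optional CDS
span contained in the exon envelope). Strand `.` is preserved on
input and treated as `+` only where an orientation is forced
(`exon_number` assignment).

Dialect scope is deliberately bounded: GTF attributes are
`key "value";` pairs with escaped quotes rejected; GFF3
percent-encoding is decoded for the reserved characters only; GFF3
assembly follows the ID/Parent graph with forward references allowed
(two passes) and cycles rejected. `thickStart == thickEnd` encodes
"no CDS" (UCSC convention). No stop-codon ±3 adjustment is applied
between dialects — the CDS span is taken verbatim from CDS features —
so converting between annotations that disagree on stop-codon
inclusion will preserve, not reconcile, that difference.

**Harmonization.** Annotation contigs map to genome contigs by the
first applicable rule: (1) exact name, (2) alias-group lookup from an
assembly-report-style table, (3) `chr`-prefix addition/removal,
(4) case-insensitive match. The resulting map must be injective onto
the genome's contigs; two annotation contigs claiming one genome
contig is an error listing both, never a guess. Because mapped names
are genome names, a second application hits rule 1 everywhere —
idempotence falls out of the design. Unmapped contigs are reported,
and their transcripts dropped only by the separate, explicit
`filter_by_contigs` step.

## Search

Query classification is total and deterministic: `GC[AF]_` + digit
prefix → accession; all digits → taxonomy ID; anything else → text.
An all-digit assembly name can only be found via the `--as-text`
escape hatch — determinism was preferred over cleverness. Accession
queries match by prefix on the version-less accession; an explicit
version restricts to that version; GCA/GCF are distinct. Search is a
linear predicate scan (the cache is small); output order is
(provider, assembly name) so CLI output is stable. Cached metadata
records `fetched_at` but never auto-expires — reproducibility over
freshness.

## Installer

The pipeline is a fixed sequence; every executed step appends one
provenance entry, and the README (deterministic layout, round-trips
through `parse_readme` byte-identically) lists sources, steps with
timestamps, and every filtered contig exhaustively. Installs are
atomic: work happens in a temp directory renamed into place, partial
failures leave a quarantined temp dir, and re-installing requires
`force`. With a fixed clock injected, two installs from the same
config are byte-identical — the only nondeterminism is the timestamp.

Annotation source preference is GFF3 > GTF > BED12 (richest hierarchy
and attribute model first); a provider exposing other labeled sources
(UCSC-style four-way flags) falls back to the first available label in
the provider's own order.

Plugins run after core processing in registration order; all ship
disabled, and states persist in a small JSON config
(`REFSMITH_CONFIG` or `~/.config/refsmith/config.json`). The
blacklist plugin harmonizes the blacklist's contig names with the same
rules as annotations. Aligner-index plugins (bwa, bowtie2, minimap2,
gmap, star, hisat2) are registered no-op hooks that record "external
tool not invoked": invoking external aligners is out of scope, and a
disabled plugin leaves no trace by construction.

Transport is a single `fetch_uri` seam: plain paths and `file://`
URIs (used by the offline provider and the whole test suite), with
`http(s)` available through urllib but exercised nowhere in tests.
Optional SHA-256 checksums are verified post-fetch.

## Synthetic data

The fixture generator states one world per spec, driven by a single
seeded generator (no hidden global randomness): a few primary
chromosomes (default 3, 20–50 kb — large enough for thousands of
distinct regions, small enough for sub-second tests), one unplaced
scaffold whose UCSC-style and Ensembl-style names differ beyond a
`chr` prefix (so alias-based harmonization is genuinely exercised, not
just the prefix rule), alt contigs named by the documented patterns,
~10% soft-masked bases in 50–500 b runs, two planted N-gap runs of
20–200 b per contig, and 20 genes × 2 transcripts of 1–6 exons placed
outside gaps, plus 2 orphan transcripts on contigs absent from the
genome. Alias tables always include an `identity` scheme equal to the
genome's names so exact-match harmonization is covered alongside the
other rules.

The generator emulates structure, not biology: uniform base
composition, no repeat families, no realistic gene density or provider
server behavior. A green test therefore establishes that parsing,
indexing, conversion and bookkeeping are exact on well-formed inputs
of realistic shape — not that the package has been validated against
any real provider's quirks.

## Numerical and tie-breaking choices

* Sampling proportionality is tested against an exact valid-start
  count with a 3σ binomial band at n = 10⁴ draws.
* Attribute-dictionary conflicts keep the first occurrence and count
  the rest; keys with missing values are omitted.
* Emitted BED12/GTF lines sort by (contig order, start, transcript
  id); search results by (provider, assembly name) — all ties broken
  lexicographically for deterministic output.
* Duplicate transcript ids across contigs, overlapping exons within a
  transcript, duplicate contig names, and ambiguous harmonization are
  loud integrity errors rather than silent repairs.

## Known limitations

* No live provider clients: the provider interface is filesystem/URL
  only by design; real NCBI/Ensembl/UCSC/GENCODE layouts are out of
  scope.
* Alt-contig recognition is name-based and can miss unconventional
  names.
* BED12 carries no gene metadata, so gene ids/names do not survive a
  trip through BED12 (transcript id doubles as gene id on re-read).
* GFF3 FASTA sections, UTR/codon feature emission, and annotation
  liftover are unsupported.
* Extraction from gzip input works but seeks by re-decompression;
  index uncompressed FASTA for random access at scale.
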