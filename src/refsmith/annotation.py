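"""Gene-annotation handling: GFF3/GTF/BED12 readers onto a common
transcript model, format conversion, contig-name harmonization against
a genome, attribute dictionaries, and cross-scheme contig maps.

The pivot for every conversion is the transcript: a contig, a strand,
ordered disjoint exon intervals, and an optional CDS span.  Gene
records are re-derivable from transcript attributes and are not stored.

Coordinate conventions: GTF and GFF3 are 1-based fully-closed on disk,
BED12 is 0-based half-open; everything internal is 0-based half-open,
converted exactly at the parse/emit boundary.

Dialect scope (bounded, deliberate):

* GTF attributes are ``key "value";`` pairs; escaped quotes inside a
  value are unsupported and raise a format error.
* GFF3 attributes are ``key=value;`` pairs; percent-encoding is decoded
  for the reserved characters only (``; = & , %`` tab CR LF).
* No stop-codon CDS adjustment is made between dialects: the CDS span
  is taken verbatim from the CDS features.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    BoundsError,
    FieldError,
    FormatError,
    IntegrityError,
    SchemeError,
)

logger = logging.getLogger("refsmith")

#: Fixed (non-attribute) transcript fields addressable by
#: :func:`attribute_dictionary`.
FIXED_FIELDS = ("transcript_id", "gene_id", "gene_name", "contig", "strand")

# GFF3 reserved characters and their percent encodings; only these are
# decoded/encoded, per the bounded dialect scope.
_GFF3_DECODE = {
    "%3B": ";",
    "%3D": "=",
    "%26": "&",
    "%2C": ",",
    "%09": "\t",
    "%0A": "\n",
    "%0D": "\r",
    "%25": "%",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ExonInterval:
    """One exon, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise IntegrityError(
                f"empty/inverted exon interval ({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript with ordered exons and an optional CDS span."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str  # + - .
    exons: list[ExonInterval]
    gene_name: str | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    attributes: dict[str, str] = field(default_factory=dict)
    source_line_numbers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise IntegrityError(
                f"transcript {self.transcript_id!r}: bad strand {self.strand!r}"
            )
        if not self.exons:
            raise IntegrityError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise IntegrityError(
                    f"transcript {self.transcript_id!r}: overlapping exons "
                    f"({a.start},{a.end}) and ({b.start},{b.end})"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise IntegrityError(
                f"transcript {self.transcript_id!r}: half-specified CDS"
            )
        if self.cds_start is not None:
            if not (
                self.exons[0].start <= self.cds_start
                < self.cds_end  # type: ignore[operator]
                <= self.exons[-1].end
            ):
                raise IntegrityError(
                    f"transcript {self.transcript_id!r}: CDS span "
                    f"({self.cds_start},{self.cds_end}) outside exon span"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def structure_key(self) -> tuple:
        """Format-independent identity: ids, placement, exons, CDS."""
        return (
            self.transcript_id,
            self.gene_id,
            self.gene_name,
            self.contig,
            self.strand,
            tuple((e.start, e.end) for e in self.exons),
            self.cds_start,
            self.cds_end,
        )


@dataclass
class AnnotationTable:
    """All transcripts of one annotation file plus contig order."""

    transcripts: list[TranscriptModel]
    source_format: str  # gff3 | gtf | bed12
    contig_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate transcript ids: {dupes}")
        known = set(self.contig_order)
        for t in self.transcripts:
            if t.contig not in known:
                self.contig_order.append(t.contig)
                known.add(t.contig)

    def __len__(self) -> int:
        return len(self.transcripts)

    def sorted_transcripts(self) -> list[TranscriptModel]:
        order = {c: i for i, c in enumerate(self.contig_order)}
        return sorted(
            self.transcripts,
            key=lambda t: (order[t.contig], t.start, t.transcript_id),
        )


@dataclass
class ContigAliasMap:
    """Groups of alias names for physical contigs, one canonical name
    per naming scheme (e.g. ucsc ``chr1`` vs ensembl ``1``)."""

    schemes: list[str]
    groups: list[dict[str, str]]  # scheme label -> name; missing = absent

    def __post_init__(self) -> None:
        self._by_name: dict[str, int] = {}
        for i, group in enumerate(self.groups):
            for scheme, name in group.items():
                if scheme not in self.schemes:
                    raise IntegrityError(f"alias group uses unknown scheme {scheme!r}")
                if name in self._by_name and self._by_name[name] != i:
                    raise IntegrityError(
                        f"alias name {name!r} appears in more than one group"
                    )
                self._by_name[name] = i

    def group_of(self, name: str) -> dict[str, str] | None:
        i = self._by_name.get(name)
        return self.groups[i] if i is not None else None

    def aliases_of(self, name: str) -> set[str]:
        group = self.group_of(name)
        return set(group.values()) if group else {name}


def read_alias_table(path: str | Path) -> ContigAliasMap:
    """TSV with a header row naming schemes, one column per scheme, one
    row per alias group; empty cells mean the scheme lacks a name."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"empty alias table {path}")
    schemes = lines[0].split("\t")
    groups = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        groups.append(
            {s: c for s, c in zip(schemes, cells) if c}
        )
    return ContigAliasMap(schemes=schemes, groups=groups)


def write_alias_table(aliases: ContigAliasMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(aliases.schemes) + "\n")
        for group in aliases.groups:
            fh.write("\t".join(group.get(s, "") for s in aliases.schemes) + "\n")


# ---------------------------------------------------------------------------
# Attribute dialects
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


def _parse_gtf_attributes(text: str, line_no: int) -> dict[str, str]:
    if '\\"' in text:
        raise FormatError(
            f"line {line_no}: escaped quotes in GTF attributes are unsupported"
        )
    attrs: dict[str, str] = {}
    for m in _GTF_ATTR_RE.finditer(text):
        attrs.setdefault(m.group(1), m.group(2))
    return attrs


def _format_gtf_attributes(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def _gff3_decode(value: str) -> str:
    return re.sub(r"%[0-9A-Fa-f]{2}", lambda m: _GFF3_DECODE.get(m.group(0).upper(), m.group(0)), value)


def _gff3_encode(value: str) -> str:
    value = value.replace("%", "%25")
    for enc, raw in _GFF3_DECODE.items():
        if raw != "%":
            value = value.replace(raw, enc)
    return value


def _parse_gff3_attributes(text: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"line {line_no}: bad GFF3 attribute {item!r}")
        key, _, value = item.partition("=")
        attrs.setdefault(key.strip(), _gff3_decode(value.strip()))
    return attrs


def _format_gff3_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={_gff3_encode(v)}" for k, v in attrs.items())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _split_columns(line: str, line_no: int) -> list[str]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise FormatError(f"line {line_no}: expected 9 tab-separated columns")
    return cols


@dataclass
class _TxAccumulator:
    contig: str
    strand: str
    exons: list[ExonInterval] = field(default_factory=list)
    cds_lo: int | None = None
    cds_hi: int | None = None
    attributes: dict[str, str] = field(default_factory=dict)
    lines: list[int] = field(default_factory=list)

    def add_feature(
        self, feature: str, start0: int, end0: int, contig: str, strand: str,
        attrs: dict[str, str], line_no: int, tid: str,
    ) -> None:
        if contig != self.contig:
            raise IntegrityError(
                f"transcript {tid!r} spans contigs {self.contig!r} and {contig!r}"
            )
        if strand != self.strand:
            raise IntegrityError(
                f"transcript {tid!r} has conflicting strands"
            )
        if feature == "exon":
            self.exons.append(ExonInterval(start0, end0))
        elif feature == "CDS":
            self.cds_lo = start0 if self.cds_lo is None else min(self.cds_lo, start0)
            self.cds_hi = end0 if self.cds_hi is None else max(self.cds_hi, end0)
        for k, v in attrs.items():
            self.attributes.setdefault(k, v)
        self.lines.append(line_no)


def _finish(tid: str, gid: str, gname: str | None, acc: _TxAccumulator) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        gene_name=gname,
        contig=acc.contig,
        strand=acc.strand,
        exons=acc.exons,
        cds_start=acc.cds_lo,
        cds_end=acc.cds_hi,
        attributes=acc.attributes,
        source_line_numbers=tuple(acc.lines),
    )


def read_gtf(path: str | Path) -> AnnotationTable:
    """Assemble transcripts by grouping exon/CDS features on their
    ``transcript_id`` attribute.  1-based closed coordinates are
    converted to 0-based half-open; ``#`` comment lines are skipped."""
    accs: dict[str, _TxAccumulator] = {}
    contig_order: list[str] = []
    n_data = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = _split_columns(line, line_no)
            contig, _, feature, start1, end1, _, strand, _, attr_text = cols
            n_data += 1
            if contig not in contig_order:
                contig_order.append(contig)
            if feature not in ("exon", "CDS", "transcript"):
                continue
            attrs = _parse_gtf_attributes(attr_text, line_no)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(
                    f"line {line_no}: {feature} feature lacks transcript_id"
                )
            start0, end0 = int(start1) - 1, int(end1)
            acc = accs.get(tid)
            if acc is None:
                acc = accs[tid] = _TxAccumulator(contig=contig, strand=strand)
            acc.add_feature(
                feature, start0, end0, contig, strand, attrs, line_no, tid
            )
    transcripts = []
    for tid, acc in accs.items():
        if not acc.exons:
            logger.warning("transcript %r has no exon features; skipped", tid)
            continue
        gid = acc.attributes.get("gene_id", tid)
        transcripts.append(
            _finish(tid, gid, acc.attributes.get("gene_name"), acc)
        )
    if n_data and not transcripts:
        logger.warning("%s: no transcripts assembled from %d lines", path, n_data)
    return AnnotationTable(
        transcripts=transcripts, source_format="gtf", contig_order=contig_order
    )


def read_gff3(path: str | Path) -> AnnotationTable:
    """Assemble transcripts via the ID/Parent graph (exon -> transcript
    -> gene).  Forward references are allowed: the file is scanned once
    to collect features, then links are resolved.  An exon whose Parent
    lists several transcripts is duplicated under each."""
    by_id: dict[str, dict] = {}
    children: list[dict] = []
    contig_order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = _split_columns(line, line_no)
            contig, _, feature, start1, end1, _, strand, _, attr_text = cols
            if contig not in contig_order:
                contig_order.append(contig)
            attrs = _parse_gff3_attributes(attr_text, line_no)
            rec = {
                "feature": feature,
                "contig": contig,
                "start0": int(start1) - 1,
                "end0": int(end1),
                "strand": strand,
                "attrs": attrs,
                "line_no": line_no,
            }
            fid = attrs.get("ID")
            if fid is not None:
                if fid in by_id and feature not in ("CDS", "exon"):
                    raise IntegrityError(f"line {line_no}: duplicate ID {fid!r}")
                by_id.setdefault(fid, rec)
            if "Parent" in attrs:
                children.append(rec)

    # cycle detection over the Parent graph
    for fid, rec in by_id.items():
        seen = {fid}
        cur = rec
        while True:
            parents = cur["attrs"].get("Parent")
            if not parents:
                break
            pid = parents.split(",")[0]
            if pid in seen:
                raise IntegrityError(f"cyclic Parent links involving {pid!r}")
            seen.add(pid)
            cur = by_id.get(pid)
            if cur is None:
                break

    accs: dict[str, _TxAccumulator] = {}
    tx_meta: dict[str, dict] = {}

    def transcript_meta(tid: str, child: dict) -> dict:
        meta = tx_meta.get(tid)
        if meta is not None:
            return meta
        tx = by_id.get(tid)
        if tx is None:
            raise FormatError(
                f"line {child['line_no']}: unresolvable Parent {tid!r}"
            )
        gid = tx["attrs"].get("Parent", "").split(",")[0] or tid
        gene = by_id.get(gid)
        gname = tx["attrs"].get("gene_name") or (
            gene["attrs"].get("Name") if gene else None
        )
        meta = {"gene_id": gid, "gene_name": gname, "attrs": tx["attrs"]}
        tx_meta[tid] = meta
        return meta

    for rec in children:
        if rec["feature"] not in ("exon", "CDS"):
            continue
        for tid in rec["attrs"]["Parent"].split(","):
            meta = transcript_meta(tid, rec)
            acc = accs.get(tid)
            if acc is None:
                acc = accs[tid] = _TxAccumulator(
                    contig=rec["contig"], strand=rec["strand"]
                )
                for k, v in meta["attrs"].items():
                    acc.attributes.setdefault(k, v)
            acc.add_feature(
                rec["feature"], rec["start0"], rec["end0"], rec["contig"],
                rec["strand"], rec["attrs"], rec["line_no"], tid,
            )

    transcripts = []
    for tid, acc in accs.items():
        if not acc.exons:
            logger.warning("transcript %r has no exon children; skipped", tid)
            continue
        meta = tx_meta[tid]
        transcripts.append(_finish(tid, meta["gene_id"], meta["gene_name"], acc))
    return AnnotationTable(
        transcripts=transcripts, source_format="gff3", contig_order=contig_order
    )


def read_bed12(path: str | Path) -> AnnotationTable:
    """Reconstruct exons from chromStart + blockStarts/blockSizes and
    the CDS from thickStart/thickEnd (absent when equal).  The name
    column is the transcript id, doubling as gene id."""
    transcripts = []
    contig_order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"line {line_no}: expected 12 columns, got {len(cols)}"
                )
            (chrom, chrom_start, chrom_end, name, _score, strand,
             thick_start, thick_end, _rgb, block_count,
             block_sizes, block_starts) = cols
            chrom_start, chrom_end = int(chrom_start), int(chrom_end)
            sizes = [int(x) for x in block_sizes.rstrip(",").split(",")]
            starts = [int(x) for x in block_starts.rstrip(",").split(",")]
            if len(sizes) != int(block_count) or len(starts) != int(block_count):
                raise FormatError(
                    f"line {line_no}: blockCount {block_count} inconsistent "
                    f"with blockSizes/blockStarts lengths"
                )
            exons = [
                ExonInterval(chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            if exons[-1].end > chrom_end:
                raise BoundsError(
                    f"line {line_no}: blocks extend past chromEnd {chrom_end}"
                )
            ts, te = int(thick_start), int(thick_end)
            cds = (ts, te) if te > ts else (None, None)
            if chrom not in contig_order:
                contig_order.append(chrom)
            transcripts.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    contig=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=cds[0],
                    cds_end=cds[1],
                    source_line_numbers=(line_no,),
                )
            )
    return AnnotationTable(
        transcripts=transcripts, source_format="bed12", contig_order=contig_order
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def table_to_bed12(table: AnnotationTable) -> list[str]:
    """One BED12 line per transcript: blocks are the exons in ascending
    order regardless of strand, the thick region is the CDS span (or
    chromStart twice when absent), score 0; lines sorted by
    (contig order, chromStart, transcript_id)."""
    lines = []
    for t in table.sorted_transcripts():
        if t.cds_start is not None:
            thick = (t.cds_start, t.cds_end)
        else:
            thick = (t.start, t.start)
        sizes = ",".join(str(len(e)) for e in t.exons)
        offsets = ",".join(str(e.start - t.start) for e in t.exons)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    t.contig, t.start, t.end, t.transcript_id, 0, t.strand,
                    thick[0], thick[1], 0, len(t.exons), sizes, offsets,
                )
            )
        )
    return lines


# kept for symmetry with the documented conversion names
gtf_to_bed12 = table_to_bed12


def table_to_gtf(table: AnnotationTable) -> list[str]:
    """Emit transcript, exon and (when present) CDS features with
    gene_id/transcript_id/gene_name attributes.  ``exon_number`` counts
    1..n in transcription order, so it runs right-to-left on the minus
    strand; coordinates go back to 1-based closed."""
    lines = []
    for t in table.sorted_transcripts():
        base = {"gene_id": t.gene_id, "transcript_id": t.transcript_id}
        if t.gene_name is not None:
            base["gene_name"] = t.gene_name

        def row(feature: str, start0: int, end0: int, attrs: dict[str, str]) -> str:
            return "\t".join(
                (
                    t.contig, "refsmith", feature, str(start0 + 1), str(end0),
                    ".", t.strand, ".", _format_gtf_attributes(attrs),
                )
            )

        lines.append(row("transcript", t.start, t.end, base))
        ordered = t.exons if t.strand != "-" else list(reversed(t.exons))
        for i, exon in enumerate(ordered, start=1):
            lines.append(
                row("exon", exon.start, exon.end, {**base, "exon_number": str(i)})
            )
        if t.cds_start is not None:
            lines.append(row("CDS", t.cds_start, t.cds_end, base))
    return lines


def table_to_gff3(table: AnnotationTable) -> list[str]:
    """Emit gene / mRNA / exon / CDS features linked through ID/Parent.
    Gene features are re-derived by grouping transcripts on gene_id."""
    lines = ["##gff-version 3"]
    order = {c: i for i, c in enumerate(table.contig_order)}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in table.sorted_transcripts():
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = sorted(
        by_gene.items(),
        key=lambda kv: (order[kv[1][0].contig], min(t.start for t in kv[1]), kv[0]),
    )

    def row(contig, feature, start0, end0, strand, attrs) -> str:
        return "\t".join(
            (
                contig, "refsmith", feature, str(start0 + 1), str(end0),
                ".", strand, ".", _format_gff3_attributes(attrs),
            )
        )

    for gid, txs in genes:
        g_start = min(t.start for t in txs)
        g_end = max(t.end for t in txs)
        g_attrs = {"ID": gid}
        if txs[0].gene_name is not None:
            g_attrs["Name"] = txs[0].gene_name
        lines.append(row(txs[0].contig, "gene", g_start, g_end, txs[0].strand, g_attrs))
        for t in txs:
            lines.append(
                row(t.contig, "mRNA", t.start, t.end, t.strand,
                    {"ID": t.transcript_id, "Parent": gid})
            )
            for i, exon in enumerate(t.exons, start=1):
                lines.append(
                    row(t.contig, "exon", exon.start, exon.end, t.strand,
                        {"ID": f"{t.transcript_id}.exon{i}",
                         "Parent": t.transcript_id})
                )
            if t.cds_start is not None:
                lines.append(
                    row(t.contig, "CDS", t.cds_start, t.cds_end, t.strand,
                        {"ID": f"{t.transcript_id}.cds",
                         "Parent": t.transcript_id})
                )
    return lines


# ---------------------------------------------------------------------------
# Harmonization and filtering
# ---------------------------------------------------------------------------


@dataclass
class HarmonizationReport:
    mapping: dict[str, str]      # annotation contig -> genome contig
    unmapped: list[str]          # annotation contigs with no rule hit
    unmatched_transcripts: list[str]  # ids left on unmapped contigs

    @property
    def changed(self) -> dict[str, str]:
        return {a: g for a, g in self.mapping.items() if a != g}


def _match_contig(
    name: str,
    genome_contigs: Sequence[str],
    genome_set: set[str],
    lower_map: dict[str, str],
    aliases: ContigAliasMap | None,
) -> str | None:
    # rule 1: exact
    if name in genome_set:
        return name
    # rule 2: alias-group lookup
    if aliases is not None:
        group = aliases.group_of(name)
        if group is not None:
            for candidate in genome_contigs:
                if candidate in group.values():
                    return candidate
    # rule 3: chr-prefix addition or removal
    if name.startswith("chr") and name[3:] in genome_set:
        return name[3:]
    if "chr" + name in genome_set:
        return "chr" + name
    # rule 4: case-insensitive exact
    return lower_map.get(name.lower())


def harmonize_contig_names(
    table: AnnotationTable,
    genome_contigs: Sequence[str],
    aliases: ContigAliasMap | None = None,
) -> tuple[AnnotationTable, HarmonizationReport]:
    """Rename annotation contigs to the genome's names by the first
    applicable rule: exact match > alias group > ``chr`` prefix
    add/remove > case-insensitive match.  The mapping must be injective
    onto genome contigs; an ambiguity is an error, never a guess.
    Idempotent: a second application is the identity."""
    if not genome_contigs:
        raise IntegrityError("genome contig list is empty")
    genome_set = set(genome_contigs)
    lower_map: dict[str, str] = {}
    for g in genome_contigs:
        lower_map.setdefault(g.lower(), g)

    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    target_of: dict[str, str] = {}
    for name in table.contig_order:
        target = _match_contig(name, genome_contigs, genome_set, lower_map, aliases)
        if target is None:
            unmapped.append(name)
            continue
        if target in target_of and target_of[target] != name:
            raise IntegrityError(
                f"annotation contigs {target_of[target]!r} and {name!r} "
                f"both map to genome contig {target!r}"
            )
        target_of[target] = name
        mapping[name] = target

    new_transcripts = []
    unmatched: list[str] = []
    for t in table.transcripts:
        if t.contig in mapping:
            new_contig = mapping[t.contig]
            new_transcripts.append(
                t if new_contig == t.contig else replace(t, contig=new_contig)
            )
        else:
            unmatched.append(t.transcript_id)
            new_transcripts.append(t)
    new_order = [mapping.get(c, c) for c in table.contig_order]
    out = AnnotationTable(
        transcripts=new_transcripts,
        source_format=table.source_format,
        contig_order=new_order,
    )
    return out, HarmonizationReport(
        mapping=mapping, unmapped=unmapped, unmatched_transcripts=sorted(unmatched)
    )


def filter_by_contigs(
    table: AnnotationTable, genome_contigs: Sequence[str]
) -> tuple[AnnotationTable, list[str]]:
    """Drop transcripts on contigs absent from the genome (run after
    harmonization).  Returns the filtered table and the removed ids."""
    genome_set = set(genome_contigs)
    kept = [t for t in table.transcripts if t.contig in genome_set]
    removed = sorted(
        t.transcript_id for t in table.transcripts if t.contig not in genome_set
    )
    out = AnnotationTable(
        transcripts=kept,
        source_format=table.source_format,
        contig_order=[c for c in table.contig_order if c in genome_set],
    )
    return out, removed


# ---------------------------------------------------------------------------
# Dictionaries and scheme maps
# ---------------------------------------------------------------------------


def _field_value(t: TranscriptModel, name: str) -> str | None:
    if name in FIXED_FIELDS:
        return getattr(t, name)
    return t.attributes.get(name)


def attribute_dictionary(
    table: AnnotationTable, key_field: str, value_field: str
) -> tuple[dict[str, str], int]:
    """Build a key→value map over all transcripts from two fixed
    columns or attribute keys (e.g. gene_id → gene_name).  On conflict
    the first occurrence wins; the conflict count is returned.  Keys
    with a missing value are omitted."""
    available = set(FIXED_FIELDS)
    for t in table.transcripts:
        available.update(t.attributes)
    for name in (key_field, value_field):
        if name not in available:
            raise FieldError(
                f"unknown field {name!r}; available: {', '.join(sorted(available))}"
            )
    mapping: dict[str, str] = {}
    conflicts = 0
    for t in table.transcripts:
        k = _field_value(t, key_field)
        v = _field_value(t, value_field)
        if k is None or v is None:
            continue
        if k in mapping:
            if mapping[k] != v:
                conflicts += 1
        else:
            mapping[k] = v
    return mapping, conflicts


def map_contig_scheme(
    names: Iterable[str], aliases: ContigAliasMap, target_scheme: str
) -> tuple[dict[str, str], list[str]]:
    """Resolve each name to its alias group's canonical name under
    ``target_scheme``.  Names in no group (or whose group lacks the
    scheme) are reported as missing rather than guessed."""
    if target_scheme not in aliases.schemes:
        raise SchemeError(
            f"unknown scheme {target_scheme!r}; known: {aliases.schemes}"
        )
    mapping: dict[str, str] = {}
    missing: list[str] = []
    for name in names:
        group = aliases.group_of(name)
        if group is None or target_scheme not in group:
            missing.append(name)
        else:
            mapping[name] = group[target_scheme]
    return mapping, missing


# ---------------------------------------------------------------------------
# Format detection and preview
# ---------------------------------------------------------------------------


def detect_format(path: str | Path) -> str:
    """Classify a file as gff3, gtf, or bed12 from its first data line
    (gff3 additionally from its ``##gff-version`` pragma)."""
    first_data = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return "gff3"
            if line.startswith("#") or not line.strip():
                continue
            first_data = line.rstrip("\n")
            break
    if first_data is None:
        raise FormatError(f"{path}: no data lines to detect a format from")
    cols = first_data.split("\t")
    if len(cols) == 12:
        try:
            int(cols[1]), int(cols[2]), int(cols[9])
            return "bed12"
        except ValueError:
            pass
    if len(cols) == 9:
        attr = cols[8]
        if _GTF_ATTR_RE.search(attr):
            return "gtf"
        if "=" in attr:
            return "gff3"
    raise FormatError(f"{path}: not recognizable as gff3, gtf, or bed12")


READERS = {"gff3": read_gff3, "gtf": read_gtf, "bed12": read_bed12}


def read_annotation(path: str | Path, fmt: str | None = None) -> AnnotationTable:
    """Read any of the three formats, auto-detecting when needed."""
    fmt = fmt or detect_format(path)
    try:
        reader = READERS[fmt]
    except KeyError:
        raise FormatError(f"unknown annotation format {fmt!r}") from None
    return reader(path)


def annotation_head(path: str | Path, n_lines: int) -> tuple[list[str], str]:
    """First ``n_lines`` non-comment lines plus the detected format."""
    fmt = detect_format(path)
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            out.append(line.rstrip("\n"))
            if len(out) >= n_lines:
                break
    return out, fmt
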