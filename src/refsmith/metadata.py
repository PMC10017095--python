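"""Assembly-metadata search over cached per-provider tables.

The cache is a directory with one UTF-8 tab-separated table per
provider, named ``<provider>.tsv``, with the fixed header::

    assembly_name  accession  taxonomy_id  species  description  annotations

``accession`` and ``taxonomy_id`` may be empty.  ``description`` holds
free-text fields joined by ``|``.  ``annotations`` is a comma-separated
``label:0/1`` list, ordered; a UCSC-style provider carries four labels.

Query-type recognition is fully deterministic: a token beginning with
``GCA_``/``GCF_`` plus at least one digit is an accession; an all-digit
token is a taxonomy ID (use the ``--as-text`` CLI flag to search for a
numeric assembly name); everything else is free text.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, ProviderUnavailableError, QueryError

CACHE_COLUMNS = [
    "assembly_name",
    "accession",
    "taxonomy_id",
    "species",
    "description",
    "annotations",
]

#: INSDC assembly-accession grammar: GCA_/GCF_ + 9 digits + optional .version
ACCESSION_RE = re.compile(r"GC[AF]_\d{9}(\.\d+)?$", re.IGNORECASE)
_ACCESSION_QUERY_RE = re.compile(r"GC[AF]_\d+(\.\d+)?$", re.IGNORECASE)


@dataclass(frozen=True)
class AssemblyRecord:
    """One provider assembly's metadata row."""

    provider_name: str
    assembly_name: str
    species: str
    accession: str | None = None
    taxonomy_id: int | None = None
    description_fields: tuple[str, ...] = ()
    annotation_flags: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.accession is not None and not ACCESSION_RE.fullmatch(self.accession):
            raise IntegrityError(
                f"accession {self.accession!r} violates GCA_/GCF_ grammar"
            )
        if self.taxonomy_id is not None and self.taxonomy_id <= 0:
            raise IntegrityError(f"taxonomy_id must be > 0, got {self.taxonomy_id}")
        if not self.annotation_flags:
            raise IntegrityError("annotation_flags must carry at least one label")

    @property
    def has_annotation(self) -> bool:
        return any(avail for _, avail in self.annotation_flags)


@dataclass(frozen=True)
class SearchQuery:
    raw: str
    query_type: str  # text | taxonomy | accession


@dataclass
class MetadataCache:
    records: list[AssemblyRecord]
    fetched_at: datetime.datetime
    source_descriptor: str = ""

    def __post_init__(self) -> None:
        keys = [(r.provider_name, r.assembly_name) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate assembly rows: {dupes}")


def classify_query(raw: str) -> SearchQuery:
    """Recognize the query type from the token alone.

    Total and deterministic; invariant under surrounding whitespace.
    """
    token = raw.strip()
    if not token:
        raise QueryError("empty query")
    if re.match(r"GC[AF]_\d", token, re.IGNORECASE):
        qtype = "accession"
    elif token.isdigit():
        qtype = "taxonomy"
    else:
        qtype = "text"
    return SearchQuery(raw=token, query_type=qtype)


def _split_version(accession: str) -> tuple[str, str | None]:
    if "." in accession:
        base, _, ver = accession.partition(".")
        return base, ver
    return accession, None


def _accession_matches(query: str, accession: str | None) -> bool:
    """Prefix match on the version-less accession.  GCA vs GCF
    distinguish records; a version-less query matches all versions; an
    explicit version matches only that version."""
    if accession is None:
        return False
    q_base, q_ver = _split_version(query.upper())
    r_base, r_ver = _split_version(accession.upper())
    if not r_base.startswith(q_base):
        return False
    return q_ver is None or q_ver == r_ver


def _record_matches(record: AssemblyRecord, query: SearchQuery) -> bool:
    if query.query_type == "accession":
        return _accession_matches(query.raw, record.accession)
    if query.query_type == "taxonomy":
        return record.taxonomy_id == int(query.raw)
    needle = query.raw.lower()
    haystacks = (record.assembly_name, record.species, *record.description_fields)
    return any(needle in h.lower() for h in haystacks)


def search_records(
    cache: MetadataCache, query: SearchQuery
) -> list[AssemblyRecord]:
    """Linear predicate scan; result order is (provider, assembly_name)
    lexicographic so CLI output is deterministic.  An empty result is a
    valid answer, not an error."""
    hits = [r for r in cache.records if _record_matches(r, query)]
    hits.sort(key=lambda r: (r.provider_name, r.assembly_name))
    return hits


def _parse_annotation_flags(text: str, ctx: str) -> tuple[tuple[str, bool], ...]:
    flags = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        label, _, bit = item.rpartition(":")
        if not label or bit not in ("0", "1"):
            raise IntegrityError(f"{ctx}: bad annotation flag {item!r}")
        flags.append((label, bit == "1"))
    return tuple(flags)


def load_metadata_cache(provider_root: str | Path) -> MetadataCache:
    """Load every ``<provider>.tsv`` under ``provider_root``.

    Malformed rows are reported with their table and line number; a
    duplicate (provider, assembly_name) pair is an integrity error.
    """
    provider_root = Path(provider_root)
    tables = sorted(provider_root.glob("*.tsv"))
    if not tables:
        raise ProviderUnavailableError(
            f"no provider metadata tables (*.tsv) under {provider_root}"
        )
    records: list[AssemblyRecord] = []
    for table in tables:
        provider = table.stem
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in CACHE_COLUMNS if c not in df.columns]
        if missing:
            raise IntegrityError(f"{table.name}: missing columns {missing}")
        for i, row in df.iterrows():
            line_no = i + 2  # header is line 1
            ctx = f"{table.name} line {line_no}"
            try:
                taxid = int(row.taxonomy_id) if row.taxonomy_id else None
            except ValueError:
                raise IntegrityError(f"{ctx}: non-integer taxonomy_id") from None
            records.append(
                AssemblyRecord(
                    provider_name=provider,
                    assembly_name=row.assembly_name,
                    species=row.species,
                    accession=row.accession or None,
                    taxonomy_id=taxid,
                    description_fields=tuple(
                        f for f in row.description.split("|") if f
                    ),
                    annotation_flags=_parse_annotation_flags(row.annotations, ctx),
                )
            )
    return MetadataCache(
        records=records,
        fetched_at=datetime.datetime.now(datetime.timezone.utc),
        source_descriptor=str(provider_root),
    )


def format_search_table(records: list[AssemblyRecord], tsv: bool = False) -> str:
    """Render records as a text table (or machine-readable TSV), one
    row per record, sorted by (provider, name).  Annotation availability
    renders one mark per annotation source."""
    header = ["name", "provider", "accession", "taxonomy_id", "annotations", "species"]
    rows = [header]
    for r in sorted(records, key=lambda r: (r.provider_name, r.assembly_name)):
        marks = " ".join("+" if avail else "-" for _, avail in r.annotation_flags)
        rows.append(
            [
                r.assembly_name,
                r.provider_name,
                r.accession or "na",
                str(r.taxonomy_id) if r.taxonomy_id is not None else "na",
                marks,
                r.species,
            ]
        )
    if tsv:
        return "\n".join("\t".join(row) for row in rows) + "\n"
    widths = [max(len(row[i]) for row in rows) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    ]
    return "\n".join(lines) + "\n"
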