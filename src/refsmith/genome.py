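"""Genome FASTA computation: byte-offset indexing, random access,
masking transforms, contig filtering, sizes, assembly-gap detection,
and exact/random sequence extraction.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere.  User-facing
  region strings (``contig:start-end``) are 1-based fully-closed, the
  samtools convention, and converted only at the boundary
  (:func:`parse_region` / :func:`format_region`).
* The index is a faidx-style text table: one line per contig with
  ``name  length  offset  bases_per_line  bytes_per_line``, offsets
  into the *uncompressed* byte stream, in genome file order.
* gzip-compressed FASTA (``.gz`` suffix) is read transparently; the
  index is built on the uncompressed stream.
* A gap is a maximal run of ``N``/``n`` of length >= 1.  Other IUPAC
  ambiguity codes are not gaps.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    BoundsError,
    FormatError,
    IntegrityError,
    LookupFailure,
    PatternError,
    SamplingError,
)

logger = logging.getLogger("refsmith")

# Header-token patterns identifying alternate-locus contigs.  Matched
# case-insensitively, unanchored except where anchored below.  These are
# name heuristics, not a provider contract; callers may override.
DEFAULT_ALT_PATTERNS: tuple[str, ...] = (r"_alt", r"alt$", r"hap\d")

#: Default line width when rewrapping FASTA output.
WRAP_WIDTH = 80

_IUPAC_FWD = "ACGTURYSWKMBDHVN"
_IUPAC_REV = "TGCAAYRSWMKVHDBN"
_COMPLEMENT = str.maketrans(
    _IUPAC_FWD + _IUPAC_FWD.lower(), _IUPAC_REV + _IUPAC_REV.lower()
)


def _open_bytes(path: str | Path) -> io.BufferedReader:
    """Open a FASTA for reading, decompressing ``.gz`` transparently.

    The returned handle is seekable in uncompressed-byte coordinates
    (gzip handles seek by re-decompression).
    """
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rb")  # type: ignore[return-value]
    return open(path, "rb")


def _open_write(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        # mtime=0 keeps gzip output byte-deterministic across runs
        return gzip.GzipFile(path, "wb", mtime=0)
    return open(path, "wb")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexEntry:
    """Line geometry of one contig: enough for O(1) seeks."""

    name: str
    length: int
    offset: int  # byte offset of first sequence byte
    bases_per_line: int
    bytes_per_line: int


@dataclass
class GenomeIndex:
    """Ordered per-contig byte-offset records for a FASTA file."""

    entries: list[IndexEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise IntegrityError("duplicate contig names in index")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> IndexEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise LookupFailure(f"unknown contig {name!r}") from None

    @property
    def contig_names(self) -> list[str]:
        return [e.name for e in self.entries]


@dataclass(frozen=True)
class Region:
    """Strand-aware genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise BoundsError(f"invalid region bounds {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise BoundsError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapRecord:
    """Maximal N/n run within a contig, 0-based half-open."""

    contig: str
    start: int
    end: int


class MaskingLevel:
    """Closed vocabulary for sequence masking: soft, hard, none."""

    SOFT = "soft"
    HARD = "hard"
    NONE = "none"
    ALL = (SOFT, HARD, NONE)

    @classmethod
    def validate(cls, value: str) -> str:
        if value not in cls.ALL:
            raise FormatError(
                f"unknown masking level {value!r}; expected one of {cls.ALL}"
            )
        return value


# ---------------------------------------------------------------------------
# Indexing
# ---------------------------------------------------------------------------


def build_index(fasta: str | Path) -> GenomeIndex:
    """Scan a FASTA once and record per-contig line geometry.

    Within a record every sequence line except the last must have the
    same length; a ragged interior line is a format error naming the
    contig and line number.
    """
    entries: list[IndexEntry] = []
    seen: set[str] = set()

    name: str | None = None
    length = 0
    offset = 0
    bases_per_line = 0
    bytes_per_line = 0
    prev_line_bases = -1  # bases on the previous sequence line
    prev_line_no = -1
    blank_seen = False  # blank line inside a record ends its sequence

    def flush() -> None:
        nonlocal name
        if name is None:
            return
        if name in seen:
            raise IntegrityError(f"duplicate contig name {name!r}")
        seen.add(name)
        entries.append(
            IndexEntry(name, length, offset, bases_per_line, bytes_per_line)
        )
        name = None

    pos = 0
    with _open_bytes(fasta) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip(b"\r\n")
            if raw.startswith(b">"):
                flush()
                token = line[1:].split()
                if not token:
                    raise FormatError(f"unnamed FASTA record at line {line_no}")
                name = token[0].decode()
                length = 0
                offset = pos + len(raw)
                bases_per_line = 0
                bytes_per_line = 0
                prev_line_bases = -1
                blank_seen = False
            elif line:
                if name is None:
                    raise FormatError(
                        f"sequence before first header at line {line_no}"
                    )
                if blank_seen:
                    raise FormatError(
                        f"blank line inside contig {name!r} before line {line_no}"
                    )
                if bases_per_line == 0:
                    bases_per_line = len(line)
                    bytes_per_line = len(raw)
                elif prev_line_bases != bases_per_line or len(line) > bases_per_line:
                    raise FormatError(
                        f"ragged line in contig {name!r} at line "
                        f"{prev_line_no if len(line) <= bases_per_line else line_no}"
                    )
                length += len(line)
                prev_line_bases = len(line)
                prev_line_no = line_no
            else:
                blank_seen = name is not None
            pos += len(raw)
        flush()
    return GenomeIndex(entries)


def write_index(index: GenomeIndex, path: str | Path) -> None:
    """Serialize to the 5-column faidx-compatible text layout."""
    with open(path, "w") as fh:
        for e in index.entries:
            fh.write(
                f"{e.name}\t{e.length}\t{e.offset}\t"
                f"{e.bases_per_line}\t{e.bytes_per_line}\n"
            )


def read_index(path: str | Path) -> GenomeIndex:
    entries = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(f"bad index line {line_no}: {line!r}")
            entries.append(
                IndexEntry(parts[0], *(int(p) for p in parts[1:]))
            )
    return GenomeIndex(entries)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    """IUPAC reverse complement, case preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


def _file_offset(entry: IndexEntry, base: int) -> int:
    if entry.bases_per_line == 0:
        return entry.offset
    lines, rem = divmod(base, entry.bases_per_line)
    return entry.offset + lines * entry.bytes_per_line + rem


def extract_sequence(
    index: GenomeIndex, fasta: str | Path, region: Region
) -> str:
    """Return bases ``[start, end)`` of the region's contig; strand
    ``-`` returns the reverse complement.  Out-of-bounds regions raise,
    never clamp.
    """
    entry = index[region.contig]
    if region.end > entry.length:
        raise BoundsError(
            f"region end {region.end} beyond contig "
            f"{entry.name!r} length {entry.length}"
        )
    if region.start == region.end:
        return ""
    lo = _file_offset(entry, region.start)
    hi = _file_offset(entry, region.end - 1) + 1
    with _open_bytes(fasta) as fh:
        fh.seek(lo)
        chunk = fh.read(hi - lo)
    seq = re.sub(rb"\s+", b"", chunk).decode()
    if region.strand == "-":
        seq = reverse_complement(seq)
    return seq


def parse_region(text: str, index: GenomeIndex | None = None) -> Region:
    """Parse ``contig:start-end`` (1-based, fully closed) into a Region."""
    m = re.fullmatch(r"(.+):(\d+)-(\d+)", text)
    if not m:
        raise FormatError(f"cannot parse region {text!r}; expected contig:start-end")
    contig, start1, end1 = m.group(1), int(m.group(2)), int(m.group(3))
    if start1 < 1 or end1 < start1:
        raise BoundsError(f"invalid 1-based region {text!r}")
    region = Region(contig, start1 - 1, end1)
    if index is not None:
        index[contig]  # raises on unknown contig
    return region


def format_region(region: Region) -> str:
    return f"{region.contig}:{region.start + 1}-{region.end}"


# ---------------------------------------------------------------------------
# Random region sampling
# ---------------------------------------------------------------------------


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _valid_start_intervals(
    entry: IndexEntry,
    length: int,
    gaps: Sequence[GapRecord],
) -> list[tuple[int, int]]:
    """Half-open intervals of start positions yielding a fully in-contig
    region that overlaps no gap."""
    hi = entry.length - length
    if hi < 0:
        return []
    blocked = []
    for g in gaps:
        if g.contig != entry.name:
            continue
        # start s overlaps [g.start,g.end) iff s < g.end and s+length > g.start
        b_lo = max(0, g.start - length + 1)
        b_hi = min(g.end, hi + 1)
        if b_lo < b_hi:
            blocked.append((b_lo, b_hi))
    blocked = _merge_intervals(blocked)
    allowed = []
    cursor = 0
    for s, e in blocked:
        if cursor < s:
            allowed.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi + 1:
        allowed.append((cursor, hi + 1))
    return allowed


def random_regions(
    index: GenomeIndex,
    n: int,
    length: int,
    seed: int,
    exclude_gaps: bool = False,
    gaps: Sequence[GapRecord] = (),
) -> list[Region]:
    """Sample ``n`` regions of fixed ``length`` uniformly from the pool
    of all valid start positions across contigs, so a contig's sampling
    probability is proportional to its number of valid starts.  Pure
    function of its arguments; the same seed yields identical output.
    """
    if n < 0:
        raise SamplingError("n must be >= 0")
    pools: list[tuple[str, list[tuple[int, int]], int]] = []
    total = 0
    for entry in index.entries:
        ivals = _valid_start_intervals(
            entry, length, gaps if exclude_gaps else ()
        )
        count = sum(e - s for s, e in ivals)
        if count:
            pools.append((entry.name, ivals, count))
            total += count
    if n == 0:
        return []
    if total == 0:
        raise SamplingError(
            f"no valid start position for length {length} anywhere in genome"
        )
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, total, size=n)
    cum = np.cumsum([c for _, _, c in pools])
    out = []
    for d in draws:
        ci = int(np.searchsorted(cum, d, side="right"))
        name, ivals, _ = pools[ci]
        rem = int(d) - (int(cum[ci - 1]) if ci else 0)
        for s, e in ivals:
            if rem < e - s:
                start = s + rem
                break
            rem -= e - s
        out.append(Region(name, start, start + length))
    return out


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

_LOWER = bytes(range(ord("a"), ord("z") + 1))
_HARD_TABLE = bytes.maketrans(_LOWER, b"N" * 26)


def apply_masking(
    fasta_in: str | Path, level: str, fasta_out: str | Path
) -> int:
    """Write ``fasta_in`` to ``fasta_out`` at the requested masking
    level and return the number of bases changed.

    soft: bytes copied unchanged.  hard: every lowercase base becomes
    uppercase ``N``.  none: every lowercase base is uppercased.
    Headers, line wrapping and sequence lengths are preserved.
    """
    MaskingLevel.validate(level)
    changed = 0
    with _open_bytes(fasta_in) as src, _open_write(fasta_out) as dst:
        for raw in src:
            if raw.startswith(b">") or level == MaskingLevel.SOFT:
                dst.write(raw)
                continue
            if level == MaskingLevel.HARD:
                new = raw.translate(_HARD_TABLE)
            else:
                new = raw.upper()
            changed += sum(a != b for a, b in zip(raw, new))
            dst.write(new)
    return changed


# ---------------------------------------------------------------------------
# Contig filtering
# ---------------------------------------------------------------------------


def _iter_raw_records(
    fasta: str | Path,
) -> Iterator[tuple[str, list[bytes]]]:
    """Yield (header token, raw record lines) preserving bytes."""
    token: str | None = None
    lines: list[bytes] = []
    with _open_bytes(fasta) as fh:
        for raw in fh:
            if raw.startswith(b">"):
                if token is not None:
                    yield token, lines
                parts = raw[1:].split()
                token = parts[0].decode() if parts else ""
                lines = [raw]
            else:
                if token is None:
                    raise FormatError("sequence before first FASTA header")
                lines.append(raw)
        if token is not None:
            yield token, lines


def filter_contigs(
    fasta_in: str | Path,
    pattern: str,
    keep_matches: bool,
    fasta_out: str | Path,
) -> tuple[list[str], list[str]]:
    """Keep or drop contigs whose header token matches ``pattern``
    (unanchored regex search).  Returns (kept, removed) name lists; the
    two always partition the original contig set.
    """
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise PatternError(f"invalid regex {pattern!r}: {exc}") from exc
    kept: list[str] = []
    removed: list[str] = []
    with _open_write(fasta_out) as dst:
        for token, lines in _iter_raw_records(fasta_in):
            if bool(rx.search(token)) == keep_matches:
                kept.append(token)
                for line in lines:
                    dst.write(line)
            else:
                removed.append(token)
    if not kept:
        logger.warning(
            "pattern %r with keep=%s removed every contig", pattern, keep_matches
        )
    return kept, removed


def is_alt_contig(
    token: str, patterns: Iterable[str] = DEFAULT_ALT_PATTERNS
) -> bool:
    return any(re.search(p, token, re.IGNORECASE) for p in patterns)


def exclude_alt_contigs(
    fasta_in: str | Path,
    fasta_out: str | Path,
    patterns: Iterable[str] = DEFAULT_ALT_PATTERNS,
) -> list[str]:
    """Drop alternate-locus contigs recognized by name pattern; all
    other records pass through byte-identically.  Returns removed names.
    """
    patterns = tuple(patterns)
    removed = []
    with _open_write(fasta_out) as dst:
        for token, lines in _iter_raw_records(fasta_in):
            if is_alt_contig(token, patterns):
                removed.append(token)
            else:
                for line in lines:
                    dst.write(line)
    return removed


def rewrap_fasta(
    fasta_in: str | Path, fasta_out: str | Path, width: int = WRAP_WIDTH
) -> None:
    """Rewrite with sequence lines wrapped at ``width`` bases.  Headers
    are preserved verbatim; sequence content is unchanged."""
    with _open_bytes(fasta_in) as src, _open_write(fasta_out) as dst:
        buf = b""

        def drain(final: bool) -> None:
            nonlocal buf
            while len(buf) >= width:
                dst.write(buf[:width] + b"\n")
                buf = buf[width:]
            if final and buf:
                dst.write(buf + b"\n")
                buf = b""

        for raw in src:
            if raw.startswith(b">"):
                drain(final=True)
                dst.write(raw if raw.endswith(b"\n") else raw + b"\n")
            else:
                buf += raw.rstrip(b"\r\n")
                drain(final=False)
        drain(final=True)


# ---------------------------------------------------------------------------
# Sizes and gaps
# ---------------------------------------------------------------------------


def compute_contig_sizes(index: GenomeIndex) -> list[tuple[str, int]]:
    """Per-contig lengths in index (= genome file) order."""
    return [(e.name, e.length) for e in index.entries]


def write_sizes(sizes: list[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes:
            fh.write(f"{name}\t{length}\n")


def iter_fasta(fasta: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (contig token, full sequence) per record."""
    for token, lines in _iter_raw_records(fasta):
        seq = b"".join(line.rstrip(b"\r\n") for line in lines[1:])
        yield token, seq.decode()


def read_fasta(fasta: str | Path) -> dict[str, str]:
    return dict(iter_fasta(fasta))


_GAP_RX = re.compile(r"[Nn]+")


def compute_gaps(fasta: str | Path) -> list[GapRecord]:
    """Maximal N/n runs per contig, in (contig order, start) order."""
    gaps = []
    for name, seq in iter_fasta(fasta):
        for m in _GAP_RX.finditer(seq):
            gaps.append(GapRecord(name, m.start(), m.end()))
    return gaps


def write_gaps_bed(gaps: Sequence[GapRecord], path: str | Path) -> None:
    """3-column BED, 0-based half-open."""
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\n")


def read_gaps_bed(path: str | Path) -> list[GapRecord]:
    gaps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e = line.rstrip("\n").split("\t")[:3]
            gaps.append(GapRecord(c, int(s), int(e)))
    return gaps
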