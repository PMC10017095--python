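"""Synthetic genomes, annotations, alias tables, metadata caches and
blacklists with known ground truth, so every other module is testable
entirely offline.

The generator states a small but structurally realistic world: a few
primary chromosomes plus an unplaced scaffold whose UCSC-style and
Ensembl-style names diverge beyond a ``chr`` prefix (exercising
alias-based harmonization), alternate-locus contigs named by the
documented alt patterns, soft-masked (lowercase) runs, planted N-gap
runs, and a transcript set with multi-exon structure and CDS spans.
It does not model realistic nucleotide composition, repeat content, or
provider server behavior; a green test against it establishes format
and bookkeeping correctness, not biological plausibility.

All randomness flows from one seeded generator per spec; the same seed
reproduces every artifact byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation as ann
from . import genome as gn
from .errors import SpecError

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FixtureSpec:
    """Knobs of the stated synthetic world (all counts >= 0,
    fractions in [0, 1])."""

    seed: int = 0
    n_contigs: int = 3
    contig_length_range: tuple[int, int] = (20_000, 50_000)
    softmask_fraction: float = 0.10
    gap_runs_per_contig: int = 2
    gap_length_range: tuple[int, int] = (20, 200)
    alt_contig_count: int = 1
    unplaced_contig_count: int = 1
    n_genes: int = 20
    transcripts_per_gene: int = 2
    exons_per_transcript_range: tuple[int, int] = (1, 6)
    n_orphan_transcripts: int = 2
    naming_schemes: tuple[str, ...] = ("ucsc", "ensembl")
    wrap_width: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.softmask_fraction <= 1:
            raise SpecError("softmask_fraction must be in [0, 1]")
        for name in (
            "n_contigs", "gap_runs_per_contig", "alt_contig_count",
            "unplaced_contig_count", "n_genes", "transcripts_per_gene",
            "n_orphan_transcripts",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.gap_runs_per_contig and (
            self.gap_length_range[1] * self.gap_runs_per_contig * 3
            > self.contig_length_range[0]
        ):
            raise SpecError("gap runs do not plausibly fit in the shortest contig")


@dataclass
class GroundTruth:
    """Everything the generated files encode, recorded independently so
    each module's output can be checked against it."""

    spec: FixtureSpec
    sequences: dict[str, str] = field(default_factory=dict)  # genome names
    mask_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    gap_intervals: list[gn.GapRecord] = field(default_factory=list)
    transcripts: list[ann.TranscriptModel] = field(default_factory=list)
    orphan_transcript_ids: list[str] = field(default_factory=list)
    aliases: ann.ContigAliasMap | None = None
    alt_contig_names: list[str] = field(default_factory=list)

    @property
    def primary_contigs(self) -> list[str]:
        alts = set(self.alt_contig_names)
        return [c for c in self.sequences if c not in alts]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)].copy()


def _plant_intervals(
    rng: np.random.Generator,
    length: int,
    count: int,
    span_range: tuple[int, int],
    occupied: list[tuple[int, int]],
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Sample non-overlapping, non-adjacent intervals avoiding
    ``occupied`` (adjacency would merge two planted gap runs)."""
    out: list[tuple[int, int]] = []
    for _ in range(count):
        for _ in range(max_tries):
            span = int(rng.integers(span_range[0], span_range[1] + 1))
            if span >= length:
                continue
            start = int(rng.integers(0, length - span + 1))
            end = start + span
            if all(end < s or start > e for s, e in occupied + out):
                out.append((start, end))
                break
        else:
            raise SpecError(
                f"could not place an interval of {span_range} in contig of {length}"
            )
    return sorted(out)


def _write_fasta(
    sequences: dict[str, str], path: str | Path, wrap_width: int
) -> None:
    with gn._open_write(path) as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n".encode())
            for i in range(0, len(seq), wrap_width):
                fh.write(seq[i : i + wrap_width].encode() + b"\n")


def _contig_names(spec: FixtureSpec) -> list[dict[str, str]]:
    """Per physical contig, its name under every scheme (genome uses
    the ucsc-style names)."""
    groups = []
    for i in range(1, spec.n_contigs + 1):
        groups.append({"identity": f"chr{i}", "ucsc": f"chr{i}", "ensembl": str(i)})
    for i in range(1, spec.unplaced_contig_count + 1):
        groups.append(
            {
                "identity": f"chrUn_KN1496{i:02d}v1",
                "ucsc": f"chrUn_KN1496{i:02d}v1",
                "ensembl": f"KN1496{i:02d}.1",
            }
        )
    return groups


def generate_genome(
    spec: FixtureSpec, fasta_path: str | Path
) -> GroundTruth:
    """Write a FASTA of primary + unplaced + alt contigs and return its
    full ground truth (sequences, masks, gaps, transcripts, aliases)."""
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(spec=spec)
    groups = _contig_names(spec)

    for group in groups:
        name = group["ucsc"]
        length = int(rng.integers(*spec.contig_length_range, endpoint=True))
        arr = _random_seq(rng, length)
        gaps = _plant_intervals(
            rng, length, spec.gap_runs_per_contig, spec.gap_length_range, []
        )
        for s, e in gaps:
            arr[s:e] = b"N"
            truth.gap_intervals.append(gn.GapRecord(name, s, e))
        masks = []
        if spec.softmask_fraction > 0:
            target = int(length * spec.softmask_fraction)
            covered = 0
            while covered < target:
                span = int(rng.integers(50, 500))
                try:
                    (iv,) = _plant_intervals(
                        rng, length, 1, (span, span), gaps + masks
                    )
                except SpecError:
                    break
                masks.append(iv)
                covered += iv[1] - iv[0]
                s, e = iv
                arr[s:e] = np.char.lower(arr[s:e].astype("U1")).astype("S1")
        truth.mask_intervals[name] = sorted(masks)
        truth.sequences[name] = arr.tobytes().decode()

    for i in range(1, spec.alt_contig_count + 1):
        name = f"chr1_KI27{i:03d}v1_alt"
        length = int(rng.integers(1_000, 3_000))
        truth.sequences[name] = _random_seq(rng, length).tobytes().decode()
        truth.alt_contig_names.append(name)
        truth.mask_intervals[name] = []

    schemes = ["identity", *spec.naming_schemes]
    # deduplicate while keeping order
    schemes = list(dict.fromkeys(schemes))
    truth.aliases = ann.ContigAliasMap(
        schemes=schemes,
        groups=[{s: g[s] for s in schemes if s in g} for g in groups],
    )

    _generate_transcripts(spec, rng, truth)
    _write_fasta(truth.sequences, fasta_path, spec.wrap_width)
    return truth


def _gap_free_window(
    rng: np.random.Generator,
    contig_len: int,
    gaps: list[tuple[int, int]],
    span: int,
    max_tries: int = 200,
) -> tuple[int, int] | None:
    for _ in range(max_tries):
        if contig_len <= span:
            return None
        start = int(rng.integers(0, contig_len - span))
        end = start + span
        if all(end <= s or start >= e for s, e in gaps):
            return (start, end)
    return None


def _generate_transcripts(
    spec: FixtureSpec, rng: np.random.Generator, truth: GroundTruth
) -> None:
    primaries = truth.primary_contigs
    gaps_by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in primaries}
    for g in truth.gap_intervals:
        gaps_by_contig[g.contig].append((g.start, g.end))

    def make_tx(tid: str, gid: str, gname: str | None, contig: str,
                contig_len: int, gaps: list[tuple[int, int]]) -> ann.TranscriptModel | None:
        n_exons = int(rng.integers(*spec.exons_per_transcript_range, endpoint=True))
        span = int(rng.integers(200 * n_exons, 400 * n_exons))
        window = _gap_free_window(rng, contig_len, gaps, span)
        if window is None:
            return None
        w_start, w_end = window
        # cut the window into n_exons exons separated by introns
        cuts = sorted(rng.choice(np.arange(1, span), size=2 * n_exons - 1, replace=False))
        bounds = [0, *map(int, cuts), span]
        exons = [
            ann.ExonInterval(w_start + bounds[2 * k], w_start + bounds[2 * k + 1])
            for k in range(n_exons)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        cds_start = cds_end = None
        if rng.random() < 0.8:
            lo, hi = exons[0].start, exons[-1].end
            cds_start = int(rng.integers(lo, hi - 1))
            cds_end = int(rng.integers(cds_start + 1, hi + 1))
        return ann.TranscriptModel(
            transcript_id=tid, gene_id=gid, gene_name=gname, contig=contig,
            strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end,
        )

    for g in range(1, spec.n_genes + 1):
        if not primaries:
            raise SpecError("cannot place genes: no primary contigs")
        contig = primaries[int(rng.integers(0, len(primaries)))]
        contig_len = len(truth.sequences[contig])
        gid, gname = f"gene{g:04d}", f"GENE{g:04d}"
        for t in range(1, spec.transcripts_per_gene + 1):
            tx = make_tx(
                f"tx{g:04d}.{t}", gid, gname, contig, contig_len,
                gaps_by_contig[contig],
            )
            if tx is None:
                raise SpecError(
                    f"requested transcripts do not fit on contig {contig!r}"
                )
            truth.transcripts.append(tx)

    for i in range(1, spec.n_orphan_transcripts + 1):
        tx = make_tx(
            f"orphan{i:04d}.1", f"orphan_gene{i:04d}", f"ORPHAN{i:04d}",
            f"scaffold_unplaced_{i}", 10_000, [],
        )
        assert tx is not None
        truth.transcripts.append(tx)
        truth.orphan_transcript_ids.append(tx.transcript_id)


# ---------------------------------------------------------------------------
# Annotation and supporting files
# ---------------------------------------------------------------------------


def _rename_for_scheme(truth: GroundTruth, scheme: str) -> ann.AnnotationTable:
    if scheme not in (truth.aliases.schemes if truth.aliases else []):
        raise SpecError(f"scheme {scheme!r} not in the fixture's naming schemes")
    from dataclasses import replace

    renamed = []
    for t in truth.transcripts:
        group = truth.aliases.group_of(t.contig)
        name = group.get(scheme, t.contig) if group else t.contig
        renamed.append(replace(t, contig=name) if name != t.contig else t)
    return ann.AnnotationTable(transcripts=renamed, source_format="gtf")


def generate_annotation(
    truth: GroundTruth, scheme: str, fmt: str, path: str | Path
) -> ann.AnnotationTable:
    """Render the truth's transcripts in one format using one naming
    scheme's contig names (orphan contigs keep their names — they have
    no alias group by construction)."""
    table = _rename_for_scheme(truth, scheme)
    if fmt == "gtf":
        lines = ann.table_to_gtf(table)
    elif fmt == "gff3":
        lines = ann.table_to_gff3(table)
    elif fmt == "bed12":
        lines = ann.table_to_bed12(table)
    else:
        raise SpecError(f"unknown annotation format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")
    return table


def generate_blacklist(
    truth: GroundTruth, path: str | Path, n_intervals: int = 7,
    scheme: str = "identity",
) -> list[tuple[str, int, int]]:
    """Random blacklist intervals on primary contigs, named under one
    scheme; returns the intervals written."""
    rng = np.random.default_rng(truth.spec.seed + 104729)
    out = []
    primaries = truth.primary_contigs
    for _ in range(n_intervals):
        contig = primaries[int(rng.integers(0, len(primaries)))]
        clen = len(truth.sequences[contig])
        span = int(rng.integers(100, 1000))
        start = int(rng.integers(0, max(1, clen - span)))
        group = truth.aliases.group_of(contig) if truth.aliases else None
        name = group.get(scheme, contig) if group else contig
        out.append((name, start, start + span))
    out.sort()
    with open(path, "w") as fh:
        for contig, s, e in out:
            fh.write(f"{contig}\t{s}\t{e}\n")
    return out


def generate_metadata_cache(
    assemblies: list[dict], provider_root: str | Path, seed: int = 0
) -> None:
    """Write one ``<provider>.tsv`` metadata table per provider.

    Each assembly dict needs ``provider`` and ``assembly_name``;
    ``species``, ``taxonomy_id``, ``accession``, ``description`` and
    ``annotations`` (list of (label, bool)) are filled with plausible
    values when absent.  Generated accessions obey the GCA_/GCF_
    grammar by construction.
    """
    rng = np.random.default_rng(seed)
    provider_root = Path(provider_root)
    provider_root.mkdir(parents=True, exist_ok=True)
    by_provider: dict[str, list[dict]] = {}
    for a in assemblies:
        by_provider.setdefault(a["provider"], []).append(a)
    for provider, items in by_provider.items():
        lines = ["\t".join(
            ["assembly_name", "accession", "taxonomy_id", "species",
             "description", "annotations"]
        )]
        for a in items:
            accession = a.get(
                "accession",
                f"GC{'AF'[int(rng.integers(0, 2))]}_"
                f"{int(rng.integers(0, 10**9)):09d}.{int(rng.integers(1, 9))}",
            )
            taxid = a.get("taxonomy_id", int(rng.integers(1, 10**6)))
            flags = a.get("annotations", [("gff3", True), ("gtf", True), ("bed12", False)])
            lines.append(
                "\t".join(
                    [
                        a["assembly_name"],
                        accession or "",
                        str(taxid) if taxid else "",
                        a.get("species", "Synthetica exempli"),
                        "|".join(a.get("description", ["synthetic fixture assembly"])),
                        ",".join(f"{label}:{int(avail)}" for label, avail in flags),
                    ]
                )
            )
        (provider_root / f"{provider}.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Whole-provider convenience
# ---------------------------------------------------------------------------


def build_provider(
    spec: FixtureSpec,
    root: str | Path,
    provider: str = "fixtureprov",
    assembly_name: str = "synasm1",
    species: str = "Synthetica exempli",
    taxonomy_id: int = 424242,
    annotation_format: str = "gff3",
    annotation_scheme: str = "ensembl",
    compress_genome: bool = False,
) -> GroundTruth:
    """Assemble a complete filesystem-backed provider directory: the
    metadata table plus genome, annotation (in a divergent naming
    scheme, so installs exercise harmonization), alias table and
    blacklist for one assembly."""
    root = Path(root)
    asm_dir = root / provider / assembly_name
    asm_dir.mkdir(parents=True, exist_ok=True)
    genome_name = "genome.fa.gz" if compress_genome else "genome.fa"
    truth = generate_genome(spec, asm_dir / genome_name)
    generate_annotation(
        truth, annotation_scheme, annotation_format,
        asm_dir / f"annotation.{annotation_format}",
    )
    ann.write_alias_table(truth.aliases, asm_dir / "aliases.tsv")
    generate_blacklist(truth, asm_dir / "blacklist.bed", scheme=annotation_scheme)
    flags = [(fmt, fmt == annotation_format) for fmt in ("gff3", "gtf", "bed12")]
    generate_metadata_cache(
        [
            {
                "provider": provider,
                "assembly_name": assembly_name,
                "species": species,
                "taxonomy_id": taxonomy_id,
                "annotations": flags,
            }
        ],
        root,
        seed=spec.seed,
    )
    return truth
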