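"""Install orchestration: resolve a source (provider entry or explicit
URL/path), fetch, process genome and annotation, run enabled plugins,
and write a provenance README.

Pipeline (one provenance entry per executed step): fetch -> decompress
-> alt-contig exclusion (unless keep_alts) -> regex filter (if any) ->
masking transform -> rewrap/write genome -> index -> sizes -> gaps ->
annotation fetch (most descriptive available) -> parse -> harmonize
contig names -> filter to genome contigs -> emit GTF + BED12 ->
plugins -> README.

A filesystem-backed provider keeps assemblies under
``<provider_root>/<provider>/<assembly>/`` with files ``genome.fa[.gz]``,
``annotation.{gff3,gtf,bed12}``, ``aliases.tsv`` and ``blacklist.bed``;
explicit ``source_uris`` (plain paths or ``file://`` URIs) override it,
which is also how non-provider assemblies are installed.

Installs are atomic: work happens in a temp directory next to the
target, renamed into place on success; a partial failure leaves the
quarantined temp directory and never a half-written install.
Re-installing requires ``force=True``.
"""

from __future__ import annotations

import datetime
import difflib
import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from . import __version__
from . import annotation as ann
from . import genome as gn
from .errors import IntegrityError, InstallExistsError, NotFoundError, RefsmithError
from .metadata import AssemblyRecord, MetadataCache

logger = logging.getLogger("refsmith")

#: Annotation formats from most to least descriptive.
FORMAT_PREFERENCE = ("gff3", "gtf", "bed12")

#: Registered plugin names in registration (execution) order.  The
#: aligner-index plugins are no-op hooks: invoking the external tools is
#: out of scope, so they only record that fact in provenance.
PLUGIN_NAMES = ("blacklist", "bwa", "bowtie2", "minimap2", "gmap", "star", "hisat2")

#: All plugins ship disabled; enabling is an explicit user choice.
DEFAULT_PLUGIN_STATES = {name: False for name in PLUGIN_NAMES}


# ---------------------------------------------------------------------------
# Config and provenance types
# ---------------------------------------------------------------------------


@dataclass
class InstallConfig:
    assembly_name: str
    output_root: Path
    provider_name: str = "path"  # a provider name, or "url"/"path"
    source_uris: dict[str, str] = field(default_factory=dict)  # role -> URI
    masking: str = gn.MaskingLevel.SOFT
    keep_alts: bool = False
    contig_regex: str | None = None
    regex_keep: bool = True
    want_annotation: bool = True
    compress_output: bool = False
    force: bool = False
    checksums: dict[str, str] = field(default_factory=dict)  # role -> sha256

    def __post_init__(self) -> None:
        self.output_root = Path(self.output_root)
        gn.MaskingLevel.validate(self.masking)


@dataclass
class ProvenanceRecord:
    assembly_name: str
    tool_version: str = __version__
    source_uris: dict[str, str] = field(default_factory=dict)
    entries: list[tuple[str, str, str]] = field(default_factory=list)
    filtered_contig_names: list[str] = field(default_factory=list)

    def log(self, step_label: str, detail: str, timestamp: str) -> None:
        self.entries.append((timestamp, step_label, detail))


def write_readme(record: ProvenanceRecord, path: str | Path) -> str:
    """Emit the provenance README in a deterministic, round-trippable
    layout: header, sources, steps in execution order, filtered contigs."""
    lines = [
        "# refsmith installation README",
        f"assembly: {record.assembly_name}",
        f"tool_version: {record.tool_version}",
        "",
        "## sources",
    ]
    for role in sorted(record.source_uris):
        lines.append(f"{role}: {record.source_uris[role]}")
    lines += ["", "## steps"]
    for ts, label, detail in record.entries:
        lines.append(f"{ts}\t{label}\t{detail}")
    lines += ["", "## filtered contigs"]
    for name in record.filtered_contig_names:
        lines.append(name)
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


def parse_readme(path: str | Path) -> ProvenanceRecord:
    """Inverse of :func:`write_readme`; write -> parse -> write is
    byte-identical."""
    record = ProvenanceRecord(assembly_name="", tool_version="")
    section = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("## "):
            section = line[3:]
            continue
        if not line or line.startswith("# "):
            continue
        if section is None:
            key, _, value = line.partition(": ")
            if key == "assembly":
                record.assembly_name = value
            elif key == "tool_version":
                record.tool_version = value
        elif section == "sources":
            role, _, uri = line.partition(": ")
            record.source_uris[role] = uri
        elif section == "steps":
            ts, label, detail = line.split("\t", 2)
            record.entries.append((ts, label, detail))
        elif section == "filtered contigs":
            record.filtered_contig_names.append(line)
    return record


# ---------------------------------------------------------------------------
# Transport
# ---------------------------------------------------------------------------


def fetch_uri(uri: str, dest: Path, sha256: str | None = None) -> None:
    """Copy a source into place.  Plain paths and ``file://`` URIs use
    the filesystem; ``http(s)://`` goes through urllib (unused in the
    offline test suite).  A checksum, when configured, is verified
    post-fetch."""
    if uri.startswith("file://"):
        src: str | Path = uri[len("file://"):]
    elif uri.startswith(("http://", "https://")):
        import urllib.request

        with urllib.request.urlopen(uri) as resp, open(dest, "wb") as out:
            shutil.copyfileobj(resp, out)
        src = None  # already written
    else:
        src = uri
    if src is not None:
        if not Path(src).exists():
            raise NotFoundError(f"source not found: {uri}")
        shutil.copyfile(src, dest)
    if sha256 is not None:
        digest = hashlib.sha256(dest.read_bytes()).hexdigest()
        if digest != sha256:
            raise IntegrityError(
                f"checksum mismatch for {uri}: expected {sha256}, got {digest}"
            )


# ---------------------------------------------------------------------------
# Source resolution
# ---------------------------------------------------------------------------

_ANNOTATION_FILES = {fmt: f"annotation.{fmt}" for fmt in FORMAT_PREFERENCE}


def resolve_annotation_source(record: AssemblyRecord) -> str | None:
    """Pick the most descriptive available annotation source label:
    gff3 > gtf > bed12, then any other available label in the
    provider's flag order (covers UCSC-style four-way flags)."""
    flags = dict(record.annotation_flags)
    for fmt in FORMAT_PREFERENCE:
        for label, avail in record.annotation_flags:
            if avail and label.lower() == fmt:
                return label
    for label, avail in record.annotation_flags:
        if avail:
            return label
    return None


def _resolve_sources(
    config: InstallConfig,
    cache: MetadataCache | None,
    provider_root: Path | None,
) -> tuple[dict[str, str], AssemblyRecord | None]:
    """Determine a URI per role, from explicit config first and the
    filesystem provider layout second."""
    uris = dict(config.source_uris)
    record = None
    if config.provider_name not in ("url", "path"):
        if cache is not None:
            matches = [
                r
                for r in cache.records
                if r.provider_name == config.provider_name
                and r.assembly_name == config.assembly_name
            ]
            if not matches:
                names = sorted(
                    r.assembly_name
                    for r in cache.records
                    if r.provider_name == config.provider_name
                )
                near = difflib.get_close_matches(config.assembly_name, names, n=3)
                raise NotFoundError(
                    f"assembly {config.assembly_name!r} not found at provider "
                    f"{config.provider_name!r}"
                    + (f"; did you mean: {', '.join(near)}?" if near else "")
                )
            record = matches[0]
        if provider_root is None:
            raise NotFoundError(
                f"no provider root given for provider {config.provider_name!r}"
            )
        asm_dir = Path(provider_root) / config.provider_name / config.assembly_name
        if "genome" not in uris:
            for cand in ("genome.fa", "genome.fa.gz"):
                if (asm_dir / cand).exists():
                    uris["genome"] = str(asm_dir / cand)
                    break
        if "annotation" not in uris and config.want_annotation:
            label = resolve_annotation_source(record) if record else None
            fmts = (
                [label] if label in _ANNOTATION_FILES else list(FORMAT_PREFERENCE)
            )
            for fmt in fmts:
                cand = asm_dir / _ANNOTATION_FILES[fmt]
                if cand.exists():
                    uris["annotation"] = str(cand)
                    break
        for role, fname in (("aliases", "aliases.tsv"), ("blacklist", "blacklist.bed")):
            if role not in uris and (asm_dir / fname).exists():
                uris[role] = str(asm_dir / fname)
    if "genome" not in uris:
        raise NotFoundError(
            f"no genome source resolvable for {config.assembly_name!r}"
        )
    return uris, record


# ---------------------------------------------------------------------------
# Plugin framework
# ---------------------------------------------------------------------------


@dataclass
class InstallContext:
    """What a plugin gets to see: the finished core install."""

    config: InstallConfig
    layout_dir: Path
    genome_fasta: Path
    index: gn.GenomeIndex
    source_uris: dict[str, str]
    aliases: ann.ContigAliasMap | None
    provenance: ProvenanceRecord
    timestamp: Callable[[], str]


def _config_path(config_path: str | Path | None) -> Path:
    if config_path is not None:
        return Path(config_path)
    env = os.environ.get("REFSMITH_CONFIG")
    if env:
        return Path(env)
    return Path.home() / ".config" / "refsmith" / "config.json"


def _load_states(config_path: str | Path | None) -> dict[str, bool]:
    path = _config_path(config_path)
    states = dict(DEFAULT_PLUGIN_STATES)
    if path.exists():
        stored = json.loads(path.read_text()).get("plugins", {})
        for name, enabled in stored.items():
            if name in states:
                states[name] = bool(enabled)
    return states


def plugin_list(config_path: str | Path | None = None) -> dict[str, bool]:
    """All registered plugins with their persisted enabled states."""
    return _load_states(config_path)


def plugin_toggle(
    name: str, enabled: bool, config_path: str | Path | None = None
) -> dict[str, bool]:
    """Persist one plugin's state in the user config; unknown names
    report the valid ones."""
    if name not in PLUGIN_NAMES:
        raise NotFoundError(
            f"unknown plugin {name!r}; valid plugins: {', '.join(PLUGIN_NAMES)}"
        )
    states = _load_states(config_path)
    states[name] = enabled
    path = _config_path(config_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"plugins": states}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return states


def blacklist_plugin(context: InstallContext) -> Path | None:
    """Copy the assembly's blacklist BED into the layout, harmonizing
    its contig names to the installed genome with the same rules used
    for annotations.  Without a configured blacklist: a warning entry,
    no file."""
    uri = context.source_uris.get("blacklist")
    if uri is None:
        context.provenance.log(
            "plugin:blacklist",
            "warning: no blacklist configured for this assembly",
            context.timestamp(),
        )
        return None
    raw = context.layout_dir / ".blacklist.src.bed"
    fetch_uri(uri, raw)
    genome_contigs = context.index.contig_names
    genome_set = set(genome_contigs)
    lower_map: dict[str, str] = {}
    for g in genome_contigs:
        lower_map.setdefault(g.lower(), g)
    out_path = context.layout_dir / f"{context.config.assembly_name}.blacklist.bed"
    n = 0
    with open(raw) as src, open(out_path, "w") as dst:
        for line in src:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            target = ann._match_contig(
                fields[0], genome_contigs, genome_set, lower_map, context.aliases
            )
            if target is None:
                continue
            fields[0] = target
            dst.write("\t".join(fields) + "\n")
            n += 1
    raw.unlink()
    context.provenance.log(
        "plugin:blacklist",
        f"wrote {out_path.name} with {n} intervals harmonized to genome names",
        context.timestamp(),
    )
    return out_path


def _aligner_hook(name: str):
    def run(context: InstallContext) -> None:
        context.provenance.log(
            f"plugin:{name}",
            "external tool not invoked (aligner indexing out of scope)",
            context.timestamp(),
        )

    return run


PLUGIN_RUNNERS: dict[str, Callable[[InstallContext], object]] = {
    "blacklist": blacklist_plugin,
    **{name: _aligner_hook(name) for name in PLUGIN_NAMES if name != "blacklist"},
}


# ---------------------------------------------------------------------------
# Install
# ---------------------------------------------------------------------------


def _default_clock() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def install(
    config: InstallConfig,
    cache: MetadataCache | None = None,
    provider_root: str | Path | None = None,
    plugin_config_path: str | Path | None = None,
    clock: Callable[[], str] = _default_clock,
) -> tuple[Path, ProvenanceRecord]:
    """Run the full install pipeline and return the layout directory
    and its provenance record.

    The layout is ``<output_root>/<assembly>/`` holding ``<name>.fa``
    (+ ``.gz`` when compressing), ``<name>.fa.fai``, ``<name>.fa.sizes``,
    ``<name>.gaps.bed``, ``<name>.annotation.gtf``,
    ``<name>.annotation.bed`` and ``README.txt``.
    """
    name = config.assembly_name
    target = config.output_root / name
    if target.exists():
        if not config.force:
            raise InstallExistsError(
                f"{target} already exists; pass force=True / --force to replace"
            )
        shutil.rmtree(target)

    uris, record = _resolve_sources(
        config, cache, Path(provider_root) if provider_root else None
    )
    prov = ProvenanceRecord(assembly_name=name, source_uris=dict(uris))

    tmp = config.output_root / f".{name}.tmp-install"
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        _run_pipeline(config, uris, prov, tmp, plugin_config_path, clock)
        tmp.rename(target)
    except Exception:
        logger.error("install failed; partial results quarantined in %s", tmp)
        raise
    return target, prov


def _run_pipeline(
    config: InstallConfig,
    uris: dict[str, str],
    prov: ProvenanceRecord,
    out: Path,
    plugin_config_path: str | Path | None,
    clock: Callable[[], str],
) -> None:
    name = config.assembly_name
    src_suffix = ".gz" if uris["genome"].endswith(".gz") else ""
    work = out / f".work.fa{src_suffix}"
    fetch_uri(uris["genome"], work, config.checksums.get("genome"))
    prov.log("fetch", f"genome from {uris['genome']}", clock())

    if src_suffix:
        plain = out / ".work.fa"
        with gn._open_bytes(work) as fin, open(plain, "wb") as fout:
            shutil.copyfileobj(fin, fout)
        work.unlink()
        work = plain
        prov.log("decompress", "gunzipped genome source", clock())

    filtered: list[str] = []
    if not config.keep_alts:
        nxt = out / ".work.noalt.fa"
        removed = gn.exclude_alt_contigs(work, nxt)
        filtered.extend(removed)
        work.unlink()
        work = nxt
        prov.log(
            "exclude_alts", f"removed {len(removed)} alternate-locus contigs", clock()
        )

    if config.contig_regex is not None:
        nxt = out / ".work.filtered.fa"
        _, removed = gn.filter_contigs(
            work, config.contig_regex, config.regex_keep, nxt
        )
        filtered.extend(removed)
        work.unlink()
        work = nxt
        prov.log(
            "filter_contigs",
            f"regex {config.contig_regex!r} keep={config.regex_keep} "
            f"removed {len(removed)} contigs",
            clock(),
        )
    prov.filtered_contig_names = filtered

    nxt = out / ".work.masked.fa"
    changed = gn.apply_masking(work, config.masking, nxt)
    work.unlink()
    work = nxt
    prov.log("masking", f"level={config.masking} bases_changed={changed}", clock())

    fa_name = f"{name}.fa" + (".gz" if config.compress_output else "")
    genome_fa = out / fa_name
    gn.rewrap_fasta(work, genome_fa, gn.WRAP_WIDTH)
    work.unlink()
    prov.log("write_genome", f"{fa_name} rewrapped at {gn.WRAP_WIDTH} bases/line", clock())

    index = gn.build_index(genome_fa)
    gn.write_index(index, out / f"{fa_name}.fai")
    prov.log("index", f"{fa_name}.fai with {len(index)} contigs", clock())

    sizes = gn.compute_contig_sizes(index)
    gn.write_sizes(sizes, out / f"{fa_name}.sizes")
    prov.log("sizes", f"{fa_name}.sizes ({sum(s for _, s in sizes)} bases)", clock())

    gaps = gn.compute_gaps(genome_fa)
    gn.write_gaps_bed(gaps, out / f"{name}.gaps.bed")
    prov.log("gaps", f"{name}.gaps.bed with {len(gaps)} gaps", clock())

    aliases = None
    if "aliases" in uris:
        alias_path = out / f"{name}.aliases.tsv"
        fetch_uri(uris["aliases"], alias_path)
        aliases = ann.read_alias_table(alias_path)

    if config.want_annotation:
        if "annotation" in uris:
            _process_annotation(config, uris, prov, out, index, aliases, clock)
        else:
            logger.warning("annotation requested but none available for %s", name)
            prov.log(
                "annotation",
                "warning: annotation requested but none available",
                clock(),
            )

    context = InstallContext(
        config=config,
        layout_dir=out,
        genome_fasta=genome_fa,
        index=index,
        source_uris=uris,
        aliases=aliases,
        provenance=prov,
        timestamp=clock,
    )
    for pname, enabled in _load_states(plugin_config_path).items():
        if enabled:
            PLUGIN_RUNNERS[pname](context)

    write_readme(prov, out / "README.txt")


def _process_annotation(
    config: InstallConfig,
    uris: dict[str, str],
    prov: ProvenanceRecord,
    out: Path,
    index: gn.GenomeIndex,
    aliases: ann.ContigAliasMap | None,
    clock: Callable[[], str],
) -> None:
    name = config.assembly_name
    uri = uris["annotation"]
    raw = out / (".work.annotation" + Path(uri).suffix)
    fetch_uri(uri, raw, config.checksums.get("annotation"))
    prov.log("annotation_fetch", f"annotation from {uri}", clock())

    table = ann.read_annotation(raw)
    prov.log(
        "annotation_parse",
        f"format={table.source_format} transcripts={len(table)}",
        clock(),
    )
    raw.unlink()

    table, report = ann.harmonize_contig_names(table, index.contig_names, aliases)
    prov.log(
        "harmonize_contigs",
        f"mapped={len(report.changed)} unmapped={len(report.unmapped)}",
        clock(),
    )
    table, removed = ann.filter_by_contigs(table, index.contig_names)
    prov.log(
        "annotation_filter",
        f"removed {len(removed)} transcripts on missing contigs",
        clock(),
    )

    gtf_path = out / f"{name}.annotation.gtf"
    gtf_path.write_text("\n".join(ann.table_to_gtf(table)) + "\n")
    prov.log("emit_gtf", f"{gtf_path.name} with {len(table)} transcripts", clock())

    bed_path = out / f"{name}.annotation.bed"
    bed_path.write_text("\n".join(ann.table_to_bed12(table)) + "\n")
    prov.log("emit_bed12", f"{bed_path.name} with {len(table)} transcripts", clock())
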