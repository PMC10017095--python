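import os
from pathlib import Path

import pytest

from refsmith import fixtures as fx
from refsmith import metadata as md


@pytest.fixture(scope="session")
def spec() -> fx.FixtureSpec:
    """One small but fully featured synthetic world shared by the suite."""
    return fx.FixtureSpec(
        seed=7,
        n_contigs=3,
        contig_length_range=(8_000, 15_000),
        softmask_fraction=0.10,
        gap_runs_per_contig=2,
        gap_length_range=(20, 120),
        alt_contig_count=1,
        unplaced_contig_count=1,
        n_genes=12,
        transcripts_per_gene=2,
        n_orphan_transcripts=2,
    )


@pytest.fixture(scope="session")
def genome_fixture(spec, tmp_path_factory):
    """(fasta path, ground truth) for the shared genome."""
    path = tmp_path_factory.mktemp("genome") / "genome.fa"
    truth = fx.generate_genome(spec, path)
    return path, truth


@pytest.fixture(scope="session")
def provider_fixture(spec, tmp_path_factory):
    """A complete filesystem-backed provider with one assembly whose
    annotation uses ensembl-style names (divergent from the genome)."""
    root = tmp_path_factory.mktemp("provider")
    truth = fx.build_provider(spec, root, annotation_scheme="ensembl")
    return root, truth


@pytest.fixture(scope="session")
def cache(provider_fixture) -> md.MetadataCache:
    root, _ = provider_fixture
    return md.load_metadata_cache(root)


@pytest.fixture()
def plugin_config(tmp_path, monkeypatch) -> Path:
    """Isolated plugin-state config so tests never touch ~/.config."""
    path = tmp_path / "refsmith-config.json"
    monkeypatch.setenv("REFSMITH_CONFIG", str(path))
    return path
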