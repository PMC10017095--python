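"""Annotation model: format readers, conversions/round trips,
contig-name harmonization, dictionaries and scheme maps."""

import pytest

from refsmith import annotation as ann, errors, fixtures as fx


def structures(table):
    return sorted(t.structure_key() for t in table.transcripts)


def exon_structures(table):
    """Identity without gene metadata (BED12 cannot carry it)."""
    return sorted(
        (t.transcript_id, t.contig, t.strand,
         tuple((e.start, e.end) for e in t.exons), t.cds_start, t.cds_end)
        for t in table.transcripts
    )


@pytest.fixture(scope="module")
def truth_table(genome_fixture):
    _, truth = genome_fixture
    return ann.AnnotationTable(transcripts=list(truth.transcripts), source_format="gtf")


class TestReadGtf:
    def test_two_exon_lines_one_model(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t11\t20\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\texon\t31\t40\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        table = ann.read_gtf(gtf)
        (t,) = table.transcripts
        assert [(e.start, e.end) for e in t.exons] == [(10, 20), (30, 40)]
        assert t.gene_id == "g1" and t.cds_start is None

    def test_cds_span_is_min_max_over_cds_features(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\texon\t1\t100\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\ts\tCDS\t11\t30\t.\t+\t0\ttranscript_id "t1";\n'
            'chr1\ts\tCDS\t51\t70\t.\t+\t0\ttranscript_id "t1";\n'
        )
        (t,) = ann.read_gtf(gtf).transcripts
        assert (t.cds_start, t.cds_end) == (10, 70)

    def test_gene_only_file_yields_zero_transcripts(self, tmp_path, caplog):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "g1";\n')
        with caplog.at_level("WARNING", logger="refsmith"):
            table = ann.read_gtf(gtf)
        assert len(table) == 0 and caplog.records

    def test_exon_without_transcript_id_reports_line(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\ts\texon\t1\t10\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(errors.FormatError, match="line 1"):
            ann.read_gtf(gtf)

    def test_overlapping_exons_rejected(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\texon\t1\t20\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\ts\texon\t10\t30\t.\t+\t.\ttranscript_id "t1";\n'
        )
        with pytest.raises(errors.IntegrityError, match="overlap"):
            ann.read_gtf(gtf)

    def test_transcript_spanning_contigs_rejected(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\texon\t1\t20\t.\t+\t.\ttranscript_id "t1";\n'
            'chr2\ts\texon\t1\t20\t.\t+\t.\ttranscript_id "t1";\n'
        )
        with pytest.raises(errors.IntegrityError):
            ann.read_gtf(gtf)

    def test_escaped_quote_unsupported(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\texon\t1\t20\t.\t+\t.\ttranscript_id "t\\"1";\n'
        )
        with pytest.raises(errors.FormatError):
            ann.read_gtf(gtf)

    def test_fixture_bookkeeping(self, genome_fixture, tmp_path):
        _, truth = genome_fixture
        path = tmp_path / "a.gtf"
        fx.generate_annotation(truth, "identity", "gtf", path)
        table = ann.read_gtf(path)
        assert len(table) == len(truth.transcripts)
        want = {t.transcript_id: len(t.exons) for t in truth.transcripts}
        got = {t.transcript_id: len(t.exons) for t in table.transcripts}
        assert got == want


class TestReadGff3:
    def test_mrna_with_two_exon_children(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t11\t40\t.\t+\t.\tID=g1;Name=GeneA\n"
            "chr1\ts\tmRNA\t11\t40\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\ts\texon\t11\t20\t.\t+\t.\tParent=t1\n"
            "chr1\ts\texon\t31\t40\t.\t+\t.\tParent=t1\n"
        )
        (t,) = ann.read_gff3(gff).transcripts
        assert [(e.start, e.end) for e in t.exons] == [(10, 20), (30, 40)]
        assert t.gene_id == "g1" and t.gene_name == "GeneA"

    def test_multi_parent_exon_duplicated(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "chr1\ts\tmRNA\t1\t40\t.\t+\t.\tID=t1\n"
            "chr1\ts\tmRNA\t1\t40\t.\t+\t.\tID=t2\n"
            "chr1\ts\texon\t1\t40\t.\t+\t.\tParent=t1,t2\n"
        )
        table = ann.read_gff3(gff)
        assert sorted(t.transcript_id for t in table.transcripts) == ["t1", "t2"]

    def test_forward_reference_allowed(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "chr1\ts\texon\t1\t40\t.\t+\t.\tParent=t1\n"
            "chr1\ts\tmRNA\t1\t40\t.\t+\t.\tID=t1\n"
        )
        assert len(ann.read_gff3(gff)) == 1

    def test_unresolvable_parent(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("chr1\ts\texon\t1\t40\t.\t+\t.\tParent=ghost\n")
        with pytest.raises(errors.FormatError, match="ghost"):
            ann.read_gff3(gff)

    def test_cyclic_parent_links(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "chr1\ts\tmRNA\t1\t40\t.\t+\t.\tID=a;Parent=b\n"
            "chr1\ts\tmRNA\t1\t40\t.\t+\t.\tID=b;Parent=a\n"
        )
        with pytest.raises(errors.IntegrityError, match="cyclic"):
            ann.read_gff3(gff)

    def test_percent_decoding_of_reserved_chars(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "chr1\ts\tmRNA\t1\t40\t.\t+\t.\tID=t1;note=a%3Bb%3Dc%25\n"
            "chr1\ts\texon\t1\t40\t.\t+\t.\tParent=t1\n"
        )
        (t,) = ann.read_gff3(gff).transcripts
        assert t.attributes["note"] == "a;b=c%"

    def test_gff3_and_gtf_from_same_truth_parse_identically(
        self, genome_fixture, tmp_path
    ):
        _, truth = genome_fixture
        fx.generate_annotation(truth, "identity", "gtf", tmp_path / "a.gtf")
        fx.generate_annotation(truth, "identity", "gff3", tmp_path / "a.gff3")
        assert structures(ann.read_gtf(tmp_path / "a.gtf")) == structures(
            ann.read_gff3(tmp_path / "a.gff3")
        )


class TestReadBed12:
    LINE = "chr1\t10\t40\tt1\t0\t+\t14\t35\t0\t2\t10,10\t0,20\n"

    def test_column_semantics(self, tmp_path):
        (tmp_path / "a.bed").write_text(self.LINE)
        (t,) = ann.read_bed12(tmp_path / "a.bed").transcripts
        assert [(e.start, e.end) for e in t.exons] == [(10, 20), (30, 40)]
        assert (t.cds_start, t.cds_end) == (14, 35)
        assert t.transcript_id == t.gene_id == "t1"

    def test_thick_equal_means_no_cds(self, tmp_path):
        line = "chr1\t10\t40\tt1\t0\t+\t10\t10\t0\t2\t10,10\t0,20\n"
        (tmp_path / "a.bed").write_text(line)
        (t,) = ann.read_bed12(tmp_path / "a.bed").transcripts
        assert t.cds_start is None and t.cds_end is None

    def test_block_count_mismatch(self, tmp_path):
        line = "chr1\t10\t40\tt1\t0\t+\t10\t10\t0\t3\t10,10\t0,20\n"
        (tmp_path / "a.bed").write_text(line)
        with pytest.raises(errors.FormatError, match="blockCount"):
            ann.read_bed12(tmp_path / "a.bed")

    def test_blocks_past_chrom_end(self, tmp_path):
        line = "chr1\t10\t35\tt1\t0\t+\t10\t10\t0\t2\t10,10\t0,20\n"
        (tmp_path / "a.bed").write_text(line)
        with pytest.raises(errors.BoundsError):
            ann.read_bed12(tmp_path / "a.bed")


class TestConversions:
    def test_bed12_line_matches_reader_example(self, tmp_path):
        table = ann.AnnotationTable(
            transcripts=[
                ann.TranscriptModel(
                    transcript_id="t1", gene_id="g1", contig="chr1", strand="+",
                    exons=[ann.ExonInterval(10, 20), ann.ExonInterval(30, 40)],
                    cds_start=14, cds_end=35,
                )
            ],
            source_format="gtf",
        )
        (line,) = ann.table_to_bed12(table)
        assert line == "chr1\t10\t40\tt1\t0\t+\t14\t35\t0\t2\t10,10\t0,20"

    def test_single_exon_no_cds(self):
        table = ann.AnnotationTable(
            transcripts=[
                ann.TranscriptModel(
                    transcript_id="t1", gene_id="g1", contig="c", strand="+",
                    exons=[ann.ExonInterval(0, 5)],
                )
            ],
            source_format="gtf",
        )
        (line,) = ann.table_to_bed12(table)
        cols = line.split("\t")
        assert cols[6] == cols[7] == "0" and cols[10] == "5" and cols[11] == "0"

    def test_exon_number_in_transcription_order(self):
        table = ann.AnnotationTable(
            transcripts=[
                ann.TranscriptModel(
                    transcript_id="t1", gene_id="g1", contig="c", strand="-",
                    exons=[ann.ExonInterval(10, 20), ann.ExonInterval(30, 40)],
                )
            ],
            source_format="gtf",
        )
        exon_lines = [l for l in ann.table_to_gtf(table) if "\texon\t" in l]
        first = exon_lines[0].split("\t")
        assert first[3] == "31" and 'exon_number "1"' in first[8]

    def test_plus_strand_exon_coordinates_one_based(self):
        table = ann.AnnotationTable(
            transcripts=[
                ann.TranscriptModel(
                    transcript_id="t1", gene_id="g1", contig="chr1", strand="+",
                    exons=[ann.ExonInterval(10, 20), ann.ExonInterval(30, 40)],
                    cds_start=14, cds_end=35,
                )
            ],
            source_format="gtf",
        )
        exon_lines = [l.split("\t") for l in ann.table_to_gtf(table) if "\texon\t" in l]
        assert [(l[3], l[4]) for l in exon_lines] == [("11", "20"), ("31", "40")]

    def test_gtf_round_trip_on_fixture(self, truth_table, tmp_path):
        path = tmp_path / "rt.gtf"
        path.write_text("\n".join(ann.table_to_gtf(truth_table)) + "\n")
        assert structures(ann.read_gtf(path)) == structures(truth_table)

    def test_bed12_round_trip_on_fixture(self, truth_table, tmp_path):
        path = tmp_path / "rt.bed"
        path.write_text("\n".join(ann.table_to_bed12(truth_table)) + "\n")
        assert exon_structures(ann.read_bed12(path)) == exon_structures(truth_table)

    def test_gff3_round_trip_on_fixture(self, truth_table, tmp_path):
        path = tmp_path / "rt.gff3"
        path.write_text("\n".join(ann.table_to_gff3(truth_table)) + "\n")
        assert structures(ann.read_gff3(path)) == structures(truth_table)

    def test_emitted_bed12_blocks_ascend_and_counts_agree(self, truth_table):
        for line in ann.table_to_bed12(truth_table):
            cols = line.split("\t")
            sizes = [int(x) for x in cols[10].split(",")]
            starts = [int(x) for x in cols[11].split(",")]
            assert len(sizes) == len(starts) == int(cols[9])
            assert starts == sorted(starts)

    def test_matches_gffutils_parse(self, truth_table, tmp_path):
        """Independent oracle: gffutils groups the same exons per
        transcript from our emitted GTF."""
        import gffutils

        path = tmp_path / "oracle.gtf"
        path.write_text("\n".join(ann.table_to_gtf(truth_table)) + "\n")
        db = gffutils.create_db(
            str(path), ":memory:", disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        want = {
            t.transcript_id: [(e.start, e.end) for e in t.exons]
            for t in truth_table.transcripts
        }
        got = {}
        for tx in db.features_of_type("transcript"):
            tid = tx.attributes["transcript_id"][0]
            got[tid] = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
            )
        assert got == want


class TestHarmonization:
    def test_chr_prefix_rule(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "chr1")], source_format="gtf"
        )
        out, report = ann.harmonize_contig_names(table, ["1", "2"])
        assert out.transcripts[0].contig == "1"
        assert report.mapping == {"chr1": "1"}

    def test_alias_group_rule(self):
        aliases = ann.ContigAliasMap(
            schemes=["ncbi", "ucsc"],
            groups=[{"ncbi": "KN149696.1", "ucsc": "chrUn_KN149696v1"}],
        )
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "KN149696.1")], source_format="gtf"
        )
        out, report = ann.harmonize_contig_names(
            table, ["chrUn_KN149696v1"], aliases
        )
        assert out.transcripts[0].contig == "chrUn_KN149696v1"

    def test_exact_match_is_identity(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "chr1")], source_format="gtf"
        )
        out, report = ann.harmonize_contig_names(table, ["chr1"])
        assert report.changed == {} and report.unmapped == []

    def test_case_insensitive_rule(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "CHRM")], source_format="gtf"
        )
        out, _ = ann.harmonize_contig_names(table, ["chrM"])
        assert out.transcripts[0].contig == "chrM"

    def test_unmapped_contigs_flagged_not_dropped(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "chr1"), _tx("t2", "weird")],
            source_format="gtf",
        )
        out, report = ann.harmonize_contig_names(table, ["chr1"])
        assert report.unmapped == ["weird"]
        assert report.unmatched_transcripts == ["t2"]
        assert len(out) == 2

    def test_ambiguous_mapping_is_error(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "1"), _tx("t2", "chr1")], source_format="gtf"
        )
        with pytest.raises(errors.IntegrityError, match="both map"):
            ann.harmonize_contig_names(table, ["chr1"])

    def test_idempotent(self, genome_fixture, tmp_path):
        _, truth = genome_fixture
        fx.generate_annotation(truth, "ensembl", "gtf", tmp_path / "a.gtf")
        table = ann.read_gtf(tmp_path / "a.gtf")
        genome_contigs = truth.primary_contigs
        once, r1 = ann.harmonize_contig_names(table, genome_contigs, truth.aliases)
        twice, r2 = ann.harmonize_contig_names(once, genome_contigs, truth.aliases)
        assert structures(once) == structures(twice)
        assert r2.changed == {}


class TestFilterByContigs:
    def test_counts(self):
        table = ann.AnnotationTable(
            transcripts=[_tx(f"t{i}", "chr1") for i in range(3)]
            + [_tx("o1", "scaf"), _tx("o2", "scaf")],
            source_format="gtf",
        )
        out, removed = ann.filter_by_contigs(table, ["chr1"])
        assert len(out) == 3 and removed == ["o1", "o2"]

    def test_no_mismatch_is_identity(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "chr1")], source_format="gtf"
        )
        out, removed = ann.filter_by_contigs(table, ["chr1"])
        assert removed == [] and structures(out) == structures(table)

    def test_planted_orphans_removed(self, genome_fixture, tmp_path):
        _, truth = genome_fixture
        fx.generate_annotation(truth, "identity", "gtf", tmp_path / "a.gtf")
        table = ann.read_gtf(tmp_path / "a.gtf")
        _, removed = ann.filter_by_contigs(table, list(truth.sequences))
        assert removed == sorted(truth.orphan_transcript_ids)


class TestAttributeDictionary:
    def test_gene_id_to_gene_name(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "c", gene_id="g1", gene_name="GeneA")],
            source_format="gtf",
        )
        mapping, conflicts = ann.attribute_dictionary(table, "gene_id", "gene_name")
        assert mapping == {"g1": "GeneA"} and conflicts == 0

    def test_identity_map(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "c", gene_id="g1"), _tx("t2", "c", gene_id="g2")],
            source_format="gtf",
        )
        mapping, _ = ann.attribute_dictionary(table, "gene_id", "gene_id")
        assert mapping == {"g1": "g1", "g2": "g2"}

    def test_first_occurrence_wins_and_conflicts_counted(self):
        table = ann.AnnotationTable(
            transcripts=[
                _tx("t1", "c", gene_id="g1", gene_name="A"),
                _tx("t2", "c", gene_id="g1", gene_name="B"),
            ],
            source_format="gtf",
        )
        mapping, conflicts = ann.attribute_dictionary(table, "gene_id", "gene_name")
        assert mapping == {"g1": "A"} and conflicts == 1

    def test_missing_value_omits_key(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "c", gene_id="g1", gene_name=None)],
            source_format="gtf",
        )
        mapping, _ = ann.attribute_dictionary(table, "gene_id", "gene_name")
        assert mapping == {}

    def test_unknown_field_lists_available(self):
        table = ann.AnnotationTable(
            transcripts=[_tx("t1", "c")], source_format="gtf"
        )
        with pytest.raises(errors.FieldError, match="gene_id"):
            ann.attribute_dictionary(table, "nope", "gene_id")


class TestSchemeMap:
    def test_basic(self):
        aliases = ann.ContigAliasMap(
            schemes=["ensembl", "ucsc"], groups=[{"ensembl": "1", "ucsc": "chr1"}]
        )
        mapping, missing = ann.map_contig_scheme(["1"], aliases, "ucsc")
        assert mapping == {"1": "chr1"} and missing == []

    def test_absent_name_reported(self):
        aliases = ann.ContigAliasMap(
            schemes=["ensembl", "ucsc"], groups=[{"ensembl": "1", "ucsc": "chr1"}]
        )
        mapping, missing = ann.map_contig_scheme(["weird"], aliases, "ucsc")
        assert mapping == {} and missing == ["weird"]

    def test_unknown_scheme(self):
        aliases = ann.ContigAliasMap(schemes=["ucsc"], groups=[{"ucsc": "chr1"}])
        with pytest.raises(errors.SchemeError):
            ann.map_contig_scheme(["chr1"], aliases, "refseq")

    def test_full_fixture_equals_group_inversion(self, genome_fixture):
        _, truth = genome_fixture
        names = [g["ensembl"] for g in truth.aliases.groups if "ensembl" in g]
        mapping, missing = ann.map_contig_scheme(names, truth.aliases, "ucsc")
        oracle = {
            g["ensembl"]: g["ucsc"]
            for g in truth.aliases.groups
            if "ensembl" in g and "ucsc" in g
        }
        assert mapping == oracle and missing == []

    def test_alias_table_round_trip(self, genome_fixture, tmp_path):
        _, truth = genome_fixture
        ann.write_alias_table(truth.aliases, tmp_path / "a.tsv")
        back = ann.read_alias_table(tmp_path / "a.tsv")
        assert back.schemes == truth.aliases.schemes
        assert back.groups == truth.aliases.groups


class TestDetectionAndHead:
    def test_head_gtf(self, genome_fixture, tmp_path):
        _, truth = genome_fixture
        fx.generate_annotation(truth, "identity", "gtf", tmp_path / "a.gtf")
        lines, fmt = ann.annotation_head(tmp_path / "a.gtf", 2)
        assert fmt == "gtf" and len(lines) == 2
        assert all("\t" in l for l in lines)

    def test_comment_only_gff3(self, tmp_path):
        (tmp_path / "a.gff3").write_text("##gff-version 3\n# nothing else\n")
        lines, fmt = ann.annotation_head(tmp_path / "a.gff3", 5)
        assert lines == [] and fmt == "gff3"

    def test_bed12_by_column_heuristic(self, genome_fixture, tmp_path):
        _, truth = genome_fixture
        fx.generate_annotation(truth, "identity", "bed12", tmp_path / "a.bed")
        _, fmt = ann.annotation_head(tmp_path / "a.bed", 1)
        assert fmt == "bed12"

    def test_unrecognized_format(self, tmp_path):
        (tmp_path / "a.txt").write_text("hello world\n")
        with pytest.raises(errors.FormatError):
            ann.annotation_head(tmp_path / "a.txt", 1)


def _tx(tid, contig, gene_id="g", gene_name=None, strand="+"):
    return ann.TranscriptModel(
        transcript_id=tid, gene_id=gene_id, gene_name=gene_name, contig=contig,
        strand=strand, exons=[ann.ExonInterval(0, 10)],
    )
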