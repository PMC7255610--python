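"""GTF parsing, gene reconstruction and derived-feature inference."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srannot import (
    build_feature_set,
    infer_introns,
    infer_utrs,
    make_vicinity,
    parse_config,
    read_gtf,
    reconstruct_genes,
)
from srannot.annotation import (
    AnnotationRecord,
    GeneModel,
    GenomicInterval,
    GeneModelError,
    GtfParseError,
    format_gtf_record,
    merge_intervals,
    parse_gtf_line,
    write_gtf,
)


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def exon_record(start, end, gene_id, strand="+", feature="exon", source="src"):
    return AnnotationRecord(
        interval=iv(start, end, strand),
        source=source,
        feature=feature,
        attributes=(("gene_id", gene_id),),
    )


class TestGtfParsing:
    def test_field_mapping(self):
        rec = parse_gtf_line('chr1\t.\tmiRNA\t100\t120\t.\t+\t.\tgene_id "mirA";', 1)
        assert rec.source == "."
        assert rec.feature == "miRNA"
        assert (rec.interval.start, rec.interval.end) == (100, 120)
        assert rec.interval.strand == "+"
        assert rec.attr == {"gene_id": "mirA"}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        assert read_gtf(path) == []

    def test_comments_skipped(self, tmp_path):
        path = tmp_path / "c.gtf"
        path.write_text('# header\nchr1\ts\texon\t1\t10\t.\t+\t.\tgene_id "g";\n')
        assert len(read_gtf(path)) == 1

    def test_round_trip(self, tmp_path):
        rows = [
            exon_record(100, 200, "g1"),
            exon_record(300, 400, "g1"),
            exon_record(150, 350, "g1", feature="CDS"),
            exon_record(100, 400, "g1", feature="gene"),
            exon_record(500, 520, "mirA", feature="miRNA"),
        ]
        path = tmp_path / "toy.gtf"
        write_gtf(rows, path)
        back = read_gtf(path)
        assert back == rows
        assert [format_gtf_record(r) for r in back] == [
            format_gtf_record(r) for r in rows
        ]

    @pytest.mark.parametrize(
        "line, fragment",
        [
            ("chr1\t.\tmiRNA\t100\t120\t.\t+\t.", "9 tab-separated"),
            ('chr1\t.\tmiRNA\tten\t120\t.\t+\t.\tgene_id "x";', "non-integer"),
            ('chr1\t.\tmiRNA\t200\t120\t.\t+\t.\tgene_id "x";', "invalid coordinates"),
        ],
    )
    def test_malformed_lines_name_the_line(self, line, fragment):
        with pytest.raises(GtfParseError, match=rf"line 7.*{fragment}"):
            parse_gtf_line(line, 7)


class TestGeneReconstruction:
    def test_grouping_by_id(self):
        genes = reconstruct_genes(
            [exon_record(100, 200, "g1"), exon_record(300, 400, "g1")]
        )
        assert len(genes) == 1
        assert [(e.start, e.end) for e in genes[0].exons] == [(100, 200), (300, 400)]

    def test_overlapping_exons_merged(self):
        genes = reconstruct_genes(
            [exon_record(100, 200, "g1"), exon_record(150, 250, "g1")]
        )
        assert [(e.start, e.end) for e in genes[0].exons] == [(100, 250)]

    def test_missing_id_attribute(self):
        rec = AnnotationRecord(iv(1, 10), "s", "exon", ())
        with pytest.raises(GeneModelError, match="lacks attribute 'gene_id'"):
            reconstruct_genes([rec])

    def test_mixed_strands_rejected(self):
        with pytest.raises(GeneModelError, match="mixed strands"):
            reconstruct_genes(
                [exon_record(1, 10, "g1", "+"), exon_record(20, 30, "g1", "-")]
            )

    def test_cds_attached(self):
        genes = reconstruct_genes(
            [exon_record(100, 400, "g1"), exon_record(150, 350, "g1", feature="CDS")]
        )
        assert [(c.start, c.end) for c in genes[0].cds] == [(150, 350)]

    @given(st.data())
    @settings(max_examples=25, derandomize=True)
    def test_random_exons_equal_bruteforce_union(self, data):
        """Exon unions per gene equal a per-base brute-force union."""
        n = data.draw(st.integers(10, 50))
        recs = []
        truth: dict[str, set[int]] = {}
        for i in range(n):
            gid = f"g{data.draw(st.integers(0, 4))}"
            start = data.draw(st.integers(1, 500))
            end = start + data.draw(st.integers(0, 80))
            recs.append(exon_record(start, end, gid))
            truth.setdefault(gid, set()).update(range(start, end + 1))
        for gene in reconstruct_genes(recs):
            bases = set()
            for e in gene.exons:
                assert not bases & set(range(e.start, e.end + 1))
                bases.update(range(e.start, e.end + 1))
            assert bases == truth[gene.gene_id]


class TestIntrons:
    def test_gap_between_exons(self):
        gene = GeneModel("g", "chr1", "+", [iv(100, 200), iv(301, 400)])
        assert [(i.start, i.end) for i in infer_introns(gene)] == [(201, 300)]

    def test_single_exon_no_intron(self):
        gene = GeneModel("g", "chr1", "+", [iv(100, 400)])
        assert infer_introns(gene) == []

    def test_random_genes_complement_oracle(self):
        """Introns are exactly the span bases not covered by exons."""
        rng = random.Random(42)
        for _ in range(100):
            n_ex = rng.randint(2, 6)
            starts = sorted(rng.sample(range(1, 2000), n_ex * 2))
            exons = [
                iv(starts[2 * i], starts[2 * i + 1]) for i in range(n_ex)
            ]
            gene = GeneModel("g", "chr1", "+", merge_intervals(exons))
            span = range(gene.span.start, gene.span.end + 1)
            exonic = {b for e in gene.exons for b in range(e.start, e.end + 1)}
            intronic = {
                b for i in infer_introns(gene) for b in range(i.start, i.end + 1)
            }
            assert exonic & intronic == set()
            assert exonic | intronic == set(span)


class TestUtrs:
    def test_plus_strand(self):
        gene = GeneModel("g", "chr1", "+", [iv(100, 400)], [iv(150, 350)])
        five, three = infer_utrs(gene)
        assert [(u.start, u.end) for u in five] == [(100, 149)]
        assert [(u.start, u.end) for u in three] == [(351, 400)]

    def test_minus_strand_mirrored(self):
        gene = GeneModel(
            "g", "chr1", "-", [iv(100, 400, "-")], [iv(150, 350, "-")]
        )
        five, three = infer_utrs(gene)
        assert [(u.start, u.end) for u in five] == [(351, 400)]
        assert [(u.start, u.end) for u in three] == [(100, 149)]

    def test_cds_outside_exons_rejected(self):
        gene = GeneModel("g", "chr1", "+", [iv(100, 400)], [iv(350, 450)])
        with pytest.raises(GeneModelError, match="not contained"):
            infer_utrs(gene)

    def test_random_spliced_genes_partition_oracle(self):
        """5'UTR + CDS + 3'UTR partition the exon union, base by base."""
        rng = random.Random(7)
        for _ in range(100):
            n_ex = rng.randint(1, 5)
            bounds = sorted(rng.sample(range(1, 3000), n_ex * 2))
            exons = merge_intervals(
                [iv(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex)]
            )
            exonic = sorted(
                b for e in exons for b in range(e.start, e.end + 1)
            )
            if len(exonic) < 3:
                continue
            lo = rng.randrange(1, len(exonic) - 1)
            hi = rng.randrange(lo, len(exonic) - 1)
            cds_bases = set(exonic[lo : hi + 1])
            cds = merge_intervals(
                [iv(b, b) for b in sorted(cds_bases)]
            )
            strand = rng.choice("+-")
            gene = GeneModel(
                "g",
                "chr1",
                strand,
                [iv(e.start, e.end, strand) for e in exons],
                [iv(c.start, c.end, strand) for c in cds],
            )
            five, three = infer_utrs(gene)
            five_b = {b for u in five for b in range(u.start, u.end + 1)}
            three_b = {b for u in three for b in range(u.start, u.end + 1)}
            # per-base oracle: classify each exonic base by CDS boundaries
            want_left = {b for b in exonic if b < exonic[lo]}
            want_right = {b for b in exonic if b > exonic[hi]}
            if strand == "-":
                want_left, want_right = want_right, want_left
            assert five_b == want_left
            assert three_b == want_right
            assert five_b | cds_bases | three_b == set(exonic)
            assert not (five_b | three_b) & cds_bases


class TestVicinity:
    def test_plus_strand(self):
        up, down = make_vicinity(iv(5000, 6000), 3000)
        assert (up.start, up.end) == (2000, 4999)
        assert (down.start, down.end) == (6001, 9000)

    def test_minus_strand_mirrored(self):
        up, down = make_vicinity(iv(5000, 6000, "-"), 3000)
        assert (up.start, up.end) == (6001, 9000)
        assert (down.start, down.end) == (2000, 4999)

    def test_clipped_at_position_one(self):
        up, _ = make_vicinity(iv(100, 200), 3000)
        assert (up.start, up.end) == (1, 99)

    def test_clipped_at_chromosome_end(self):
        _, down = make_vicinity(iv(100, 200), 3000, chrom_length=1000)
        assert (down.start, down.end) == (201, 1000)

    def test_feature_at_start_has_no_upstream(self):
        up, down = make_vicinity(iv(1, 50), 100)
        assert up is None
        assert down is not None


class TestBuildFeatureSet:
    def test_worked_example_feature_content(self, worked_example_result):
        by_class = {}
        for f in worked_example_result.features:
            by_class.setdefault(f.class_label, []).append(f)
        assert len(by_class["miRNA"]) == 5
        assert len(by_class["CDS (+)"]) == 2
        assert len(by_class["intron"]) == 1
        assert len(by_class["upstream"]) == 1
        assert len(by_class["downstream"]) == 1
        assert [(f.interval.start, f.interval.end) for f in by_class["5'UTR"]] == [
            (1001, 1500)
        ]
        assert [(f.interval.start, f.interval.end) for f in by_class["3'UTR (+)"]] == [
            (5501, 6000)
        ]

    def test_no_derivation_requested(self):
        records = [
            exon_record(100, 120, "mirA", feature="miRNA"),
            exon_record(1, 500, "g1", feature="gene"),
        ]
        cfg = parse_config("Order:\nmiRNA\n")
        feats = build_feature_set(records, cfg)
        assert [f.origin for f in feats] == ["primary"]
        assert feats[0].class_label == "miRNA"

    def test_unmatched_selector_warns(self):
        records = [exon_record(100, 120, "mirA", feature="miRNA")]
        cfg = parse_config("Order:\nmiRNA\ntRNA\n")
        with pytest.warns(UserWarning, match="'tRNA' matched no annotation"):
            build_feature_set(records, cfg)

    def test_order_independence(self, scenario, tmp_path):
        """The feature set does not depend on GTF record order."""
        gtf = tmp_path / "a.gtf"
        gtf.write_text(scenario.gtf_text)
        records = read_gtf(gtf)
        cfg = parse_config(scenario.config_text)
        reference = build_feature_set(records, cfg)
        rng = random.Random(3)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert build_feature_set(shuffled, cfg) == reference

    def test_derived_features_match_per_gene_oracles(self, tmp_path):
        """Randomised GTF: every derived feature equals the per-gene oracle."""
        rng = random.Random(11)
        records = []
        for g in range(8):
            gid = f"g{g}"
            base = 10_000 * (g + 1)
            strand = rng.choice("+-")
            exons = merge_intervals(
                [
                    iv(base + s, base + s + rng.randint(50, 300), strand)
                    for s in sorted(rng.sample(range(0, 5000, 100), rng.randint(1, 4)))
                ]
            )
            for e in exons:
                records.append(exon_record(e.start, e.end, gid, strand))
        cfg = parse_config(
            "Introns:\ngene\n\nVicinity:\ngene\n\nOrder:\nexon\nintron\nupstream\ndownstream\n"
        )
        feats = build_feature_set(records, cfg, vicinity_size=500)
        genes = {g.gene_id: g for g in reconstruct_genes(records)}
        derived = {}
        for f in feats:
            if f.origin != "primary":
                derived.setdefault((f.feature_id, f.origin), []).append(f.interval)
        for gid, gene in genes.items():
            assert derived.get((gid, "intron"), []) == infer_introns(gene)
            up, down = make_vicinity(gene.span, 500)
            assert derived.get((gid, "upstream"), []) == ([up] if up else [])
            assert derived.get((gid, "downstream"), []) == ([down] if down else [])
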