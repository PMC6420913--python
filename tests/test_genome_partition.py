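"""Gene models, region partitioning, offsets and length groups."""

import pandas as pd
import pytest

from irscape.genome_partition import (
    GeneModel,
    Region,
    build_gene_models,
    convergent_gene_ids,
    length_groups,
    partition,
    regions_to_frame,
    relative_offset,
)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "strand", "tss",
            "start_codon", "stop_codon", "polya_site",
        ],
    )


# A (+) gene followed by a (-) gene facing it: a convergent pair.
# 1-based anchors; the 0-based equivalents are one less.
TWO_GENE_TABLE = _table(
    [
        ("gA", "c", "+", 101, 121, 420, 490),
        ("gB", "c", "-", 969, 919, 620, 550),
    ]
)


class TestBuildGeneModels:
    def test_coordinates_become_zero_based(self):
        gA, gB = build_gene_models(TWO_GENE_TABLE)
        assert (gA.tss, gA.start_codon, gA.stop_codon, gA.polya) == (100, 120, 419, 489)
        assert gA.clear_ends
        assert (gB.polya, gB.stop_codon, gB.start_codon, gB.tss) == (549, 619, 918, 968)

    def test_missing_transcript_ends_allowed(self):
        table = _table([("g1", "c", "+", None, 121, 420, None)])
        (g,) = build_gene_models(table)
        assert not g.clear_ends
        with pytest.raises(ValueError, match="no tss"):
            g.anchor("tss")

    def test_rejects_anchor_order_violation(self):
        table = _table([("g1", "c", "+", 200, 121, 420, 490)])  # tss after start
        with pytest.raises(ValueError, match="anchor ordering"):
            build_gene_models(table)

    def test_rejects_duplicate_gene_id(self):
        table = _table(
            [("g1", "c", "+", 1, 21, 320, 390), ("g1", "c", "+", 501, 521, 820, 890)]
        )
        with pytest.raises(ValueError, match="duplicate gene id"):
            build_gene_models(table)

    def test_rejects_missing_columns(self):
        with pytest.raises(ValueError, match="lacks columns"):
            build_gene_models(pd.DataFrame({"gene_id": ["g1"]}))


class TestIntervals:
    def test_plus_strand_intervals(self):
        gA = build_gene_models(TWO_GENE_TABLE)[0]
        assert gA.utr5_interval() == (100, 120)   # 20 bp
        assert gA.orf_interval() == (120, 420)    # 300 bp, stop base included
        assert gA.utr3_interval() == (420, 490)   # 70 bp, polya base included

    def test_minus_strand_intervals(self):
        gB = build_gene_models(TWO_GENE_TABLE)[1]
        assert gB.utr3_interval() == (549, 619)
        assert gB.orf_interval() == (619, 919)
        assert gB.utr5_interval() == (919, 969)

    def test_transcript_interval_spans_both_ends(self):
        gA, gB = build_gene_models(TWO_GENE_TABLE)
        assert gA.transcript_interval() == (100, 490)
        assert gB.transcript_interval() == (549, 969)


class TestPartition:
    def test_region_kinds_and_bounds(self):
        genes = build_gene_models(TWO_GENE_TABLE)
        regions = partition(genes)
        got = {(r.kind, r.start, r.end) for r in regions}
        assert got == {
            ("UTR5", 100, 120),
            ("ORF", 120, 420),
            ("UTR3", 420, 490),
            ("CON", 490, 549),  # both facing polya bases excluded: 59 bp
            ("UTR3", 549, 619),
            ("ORF", 619, 919),
            ("UTR5", 919, 969),
        }
        con = next(r for r in regions if r.kind == "CON")
        assert con.left_anchor == ("polya", "gA")
        assert con.right_anchor == ("polya", "gB")
        assert convergent_gene_ids(regions) == {"gA", "gB"}

    @pytest.mark.parametrize(
        "strands, kind",
        [(("+", "+"), "TAN"), (("-", "-"), "TAN"), (("-", "+"), "DIV")],
    )
    def test_intergenic_orientation(self, strands, kind):
        rows = []
        for i, (strand, base) in enumerate(zip(strands, (0, 1000))):
            if strand == "+":
                rows.append((f"g{i}", "c", "+", base + 1, base + 21, base + 320, base + 390))
            else:
                rows.append((f"g{i}", "c", "-", base + 390, base + 370, base + 71, base + 1))
        regions = partition(build_gene_models(_table(rows)))
        inter = [r for r in regions if r.kind in ("TAN", "DIV", "CON")]
        assert [r.kind for r in inter] == [kind]

    def test_unclear_gene_keeps_orf_but_blocks_intergenic(self):
        table = _table(
            [
                ("gA", "c", "+", 101, 121, 420, 490),
                ("gMid", "c", "+", None, 621, 920, None),
                ("gC", "c", "+", 1201, 1221, 1520, 1590),
            ]
        )
        regions = partition(build_gene_models(table))
        kinds = [r.kind for r in regions]
        assert kinds.count("ORF") == 3
        assert kinds.count("UTR5") == 2 and kinds.count("UTR3") == 2
        # the single intergenic spans between the two clear-ended genes
        inter = [r for r in regions if r.kind == "TAN"]
        assert [(r.start, r.end) for r in inter] == [(490, 1200)]

    def test_excluded_feature_drops_intergenic(self):
        genes = build_gene_models(TWO_GENE_TABLE)
        regions = partition(genes, excluded_features=[("c", 500, 520)])
        assert not any(r.kind == "CON" for r in regions)
        # a non-overlapping excluded feature changes nothing
        regions = partition(genes, excluded_features=[("c", 10, 20)])
        assert any(r.kind == "CON" for r in regions)

    def test_utr3_utr3_overlap_becomes_our3(self):
        # convergent pair with overlapping 3'-UTRs (no intergenic gap)
        table = _table(
            [
                ("gA", "c", "+", 1, 21, 140, 201),
                ("gB", "c", "-", 401, 380, 261, 181),
            ]
        )
        regions = partition(build_gene_models(table))
        by_kind = {}
        for r in regions:
            by_kind.setdefault(r.kind, []).append((r.start, r.end))
        assert by_kind["OUR3"] == [(180, 201)]
        # plain UTR3s are trimmed to the non-overlapping remainder
        assert sorted(by_kind["UTR3"]) == [(140, 180), (201, 260)]
        assert "CON" not in by_kind  # overlap, not a gap

    def test_utr5_utr5_overlap_becomes_our1(self):
        # divergent pair with overlapping 5'-UTRs
        table = _table(
            [
                ("gA", "c", "-", 390, 370, 71, 1),
                ("gB", "c", "+", 381, 421, 720, 790),
            ]
        )
        regions = partition(build_gene_models(table))
        ours = [(r.kind, r.start, r.end) for r in regions if r.kind.startswith("OUR")]
        assert ours == [("OUR1", 380, 390)]


class TestRelativeOffset:
    def test_plus_strand_downstream_positive(self):
        gA = build_gene_models(TWO_GENE_TABLE)[0]
        assert relative_offset(499, "polya", gA) == 10
        assert relative_offset(489, "polya", gA) == 0
        assert relative_offset(479, "polya", gA) == -10

    def test_minus_strand_downstream_positive(self):
        gB = build_gene_models(TWO_GENE_TABLE)[1]
        assert relative_offset(539, "polya", gB) == 10
        assert relative_offset(559, "polya", gB) == -10
        assert relative_offset(968, "tss", gB) == 0


class TestLengthGroups:
    def _regions(self, lengths):
        return [Region("UTR3", "c", i * 100, i * 100 + L) for i, L in enumerate(lengths)]

    def test_even_split_drops_shortest_group(self):
        groups = length_groups(self._regions(range(1, 11)), k=5)
        assert [g.name for g in groups] == ["Q1", "Q2", "Q3", "Q4"]
        assert [(g.min_length, g.max_length) for g in groups] == [
            (3, 4), (5, 6), (7, 8), (9, 10)
        ]

    def test_remainder_goes_to_shortest_groups(self):
        # 12 regions, k=5 -> sizes 3,3,2,2,2; lengths 1..12
        groups = length_groups(self._regions(range(1, 13)), k=5)
        assert [len(g.regions) for g in groups] == [3, 2, 2, 2]
        assert groups[0].min_length == 4 and groups[0].max_length == 6

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            length_groups(self._regions([1, 2, 3]), k=5)


def test_regions_to_frame_round_trip_columns():
    regions = partition(build_gene_models(TWO_GENE_TABLE))
    frame = regions_to_frame(regions)
    assert list(frame.columns) == ["chrom", "start", "end", "kind", "genes"]
    assert len(frame) == len(regions)
    assert (frame["end"] > frame["start"]).all()
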