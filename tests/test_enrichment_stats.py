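"""Genome randomization, binned profiles and the Grubbs outlier calls."""

import numpy as np
import pytest

from irscape.alphabet import encode
from irscape.enrichment_stats import (
    EnrichmentAnalysis,
    bin_ir_centers,
    coding_noncoding_segments,
    grubbs_call,
    grubbs_critical,
    randomize_genome,
)
from irscape.genome_partition import (
    GeneModel,
    Region,
    partition,
)

from conftest import random_sequence


def _gene(gid="g1", chrom="c", strand="+", tss=100, start=120, stop=419, polya=489):
    return GeneModel(gid, chrom, strand, start, stop, tss, polya)


class TestRandomization:
    def _genome(self):
        rng = np.random.default_rng(5)
        return {"c": encode(random_sequence(rng, 1000, 0.62))}

    def test_segments_tile_chromosome(self):
        genome = self._genome()
        genes = [_gene()]
        segs = coding_noncoding_segments(genome, genes)["c"]
        assert segs[0] == (0, 120)
        assert (120, 420) in segs
        assert segs[-1][1] == 1000
        cursor = 0
        for s, e in segs:
            assert s == cursor
            cursor = e

    def test_shuffle_preserves_per_segment_composition(self):
        genome = self._genome()
        segs = coding_noncoding_segments(genome, [_gene()])
        shuffled = randomize_genome(genome, segs, seed=11)["c"]
        original = genome["c"]
        assert not np.array_equal(shuffled, original)
        for s, e in segs["c"]:
            assert np.array_equal(
                np.bincount(shuffled[s:e], minlength=4),
                np.bincount(original[s:e], minlength=4),
            )

    def test_seed_reproducibility(self):
        genome = self._genome()
        segs = coding_noncoding_segments(genome, [_gene()])
        a = randomize_genome(genome, segs, seed=7)["c"]
        b = randomize_genome(genome, segs, seed=7)["c"]
        c = randomize_genome(genome, segs, seed=8)["c"]
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rejects_non_tiling_segments(self):
        genome = self._genome()
        with pytest.raises(ValueError, match="tile"):
            randomize_genome(genome, {"c": [(0, 500), (600, 1000)]}, seed=1)
        with pytest.raises(ValueError, match="tile"):
            randomize_genome(genome, {"c": [(0, 500)]}, seed=1)


class TestGrubbs:
    def test_critical_value_formula(self):
        # published one-sided Grubbs critical value: N=100, alpha=0.01 -> 3.600
        assert grubbs_critical(100, 0.01) == pytest.approx(3.600, abs=5e-3)
        assert grubbs_critical(101, 0.001) > grubbs_critical(101, 0.01)
        with pytest.raises(ValueError):
            grubbs_critical(2, 0.01)

    def test_worked_example_count_ten_vs_zero_controls(self):
        call = grubbs_call(10, [0] * 100)
        assert call.g_statistic == pytest.approx(9.9504, abs=1e-4)
        assert call.direction == "enrichment"
        assert call.level == "0.001"

    def test_all_equal_is_not_significant(self):
        call = grubbs_call(5, [5] * 100)
        assert call.level == "ns" and call.direction == "none"

    def test_deficiency_direction(self):
        call = grubbs_call(0, [10] * 100)
        assert call.direction == "deficiency" and call.level == "0.001"

    def test_moderate_deviation_is_ns(self):
        rng = np.random.default_rng(3)
        controls = rng.normal(50, 5, size=100)
        call = grubbs_call(float(controls.mean() + controls.std()), controls)
        assert call.level == "ns"

    def test_requires_controls(self):
        with pytest.raises(ValueError):
            grubbs_call(1, [0, 0])


class TestBinning:
    def test_counts_land_in_offset_bins(self):
        gene = _gene()
        region = Region("UTR3", "c", 420, 490, ("stop_codon", "g1"), ("polya", "g1"), ("g1",))
        # centers at polya offsets -55, -35, -34, +5 (the last outside span)
        centers = {"c": np.array([434, 454, 455, 494])}
        prof = bin_ir_centers(
            centers, [region], {"g1": gene}, "polya", span=(-60, 0),
            bin_width=10, retain="all",
        )
        assert prof.counts.tolist() == [1, 0, 2, 0, 0, 0]
        assert prof.bin_edges.tolist() == [-60, -50, -40, -30, -20, -10, 0]
        assert prof.n_samples == 1

    def test_minus_strand_offsets_are_gene_oriented(self):
        gene = _gene(strand="-", polya=100, stop=170, start=469, tss=489)
        region = Region("UTR3", "c", 100, 170, ("polya", "g1"), ("stop_codon", "g1"), ("g1",))
        centers = {"c": np.array([135])}  # polya offset 100-135 = -35
        prof = bin_ir_centers(
            centers, [region], {"g1": gene}, "polya", span=(-60, 0),
            bin_width=10, retain="all",
        )
        assert prof.counts.tolist() == [0, 0, 1, 0, 0, 0]

    def test_above_mean_retention(self):
        gene = _gene()
        mk = lambda s, e: Region("UTR3", "c", s, e, None, None, ("g1",))
        regions = [mk(0, 10), mk(20, 40), mk(50, 100)]  # mean length 26.7
        prof = bin_ir_centers(
            {}, regions, {"g1": gene}, "polya", span=(-50, 0), retain="above_mean"
        )
        assert prof.n_samples == 1

    def test_span_widened_to_bin_multiple_with_warning(self):
        gene = _gene()
        region = Region("UTR3", "c", 420, 490, None, None, ("g1",))
        with pytest.warns(UserWarning, match="widened"):
            prof = bin_ir_centers(
                {}, [region], {"g1": gene}, "polya", span=(-55, 0), retain="all"
            )
        assert prof.span == (-55, 5)

    def test_mixed_kinds_rejected(self):
        regions = [
            Region("UTR3", "c", 0, 10, None, None, ("g1",)),
            Region("UTR5", "c", 20, 30, None, None, ("g1",)),
        ]
        with pytest.raises(ValueError, match="mixed kinds"):
            bin_ir_centers({}, regions, {"g1": _gene()}, "polya", span=(-10, 0))

    def test_intergenic_regions_need_side_anchor(self):
        region = Region("CON", "c", 490, 549, ("polya", "g1"), ("polya", "g2"), ("g1", "g2"))
        with pytest.raises(ValueError, match="left"):
            bin_ir_centers(
                {"c": np.array([495])}, [region], {"g1": _gene()}, "polya",
                span=(-10, 0), retain="all",
            )
        prof = bin_ir_centers(
            {"c": np.array([495])}, [region], {"g1": _gene()}, "left",
            span=(0, 10), retain="all",
        )
        assert prof.counts.tolist() == [1]  # offset +6 downstream of gA polya


@pytest.fixture(scope="module")
def analysis(small_synth):
    genes = small_synth.genes
    regions = partition(genes)
    return EnrichmentAnalysis(
        small_synth.genome, genes, regions, n_controls=20, seed=100
    )


class TestEnrichmentAnalysis:
    def test_control_seeds_follow_base_seed(self, analysis):
        assert analysis.control_seeds == tuple(range(101, 121))
        assert len(analysis.control_centers) == 20

    def test_planted_utr3_bins_called_enriched(self, small_synth, analysis):
        result = analysis.panel("UTR3", "polya")
        frame = result.to_frame()
        planted = frame[(frame["bin_start"] >= -60) & (frame["bin_end"] <= -30)]
        assert (planted["count"] > planted["control_mean"]).all()
        sig = planted[planted["level"] != "ns"]
        assert len(sig) >= 2
        assert (sig["direction"] == "enrichment").all()

    def test_default_spans(self, analysis):
        assert analysis.default_span("ORF", "start_codon") == ((0, 200), "all")
        assert analysis.default_span("ORF", "stop_codon") == ((-200, 0), "all")
        assert analysis.default_span("CON", "left") == ((0, 200), "all")
        assert analysis.default_span("CON", "right") == ((-200, 0), "all")
        (lo, hi), retain = analysis.default_span("UTR3", "polya")
        assert retain == "above_mean"
        assert hi == 10 and lo < -100  # window covers the mean UTR3 length

    def test_type_filter_reduces_counts(self, small_synth, analysis):
        from irscape.ir_classify import type_filter

        genes = small_synth.genes
        regions = partition(genes)
        filtered = EnrichmentAnalysis(
            small_synth.genome, genes, regions, n_controls=3, seed=100,
            ir_filter=type_filter("III"),
        )
        total_all = sum(v.size for v in analysis.real_centers.values())
        total_iii = sum(v.size for v in filtered.real_centers.values())
        assert 0 < total_iii < total_all
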