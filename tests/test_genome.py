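"""Composition statistics, circular interval arithmetic, region catalogue."""

import math

import pytest

from mitocistron.genome import (
    CircularGenome,
    GeneFeature,
    GenomeAnnotation,
    composition_stats,
    gap_between,
    intron_count_table,
    locate,
    region_catalogue,
    reverse_complement,
)
from mitocistron.fixtures import ANCHORS, TABLE1_INTRON_COUNTS
from mitocistron.simulate import SimConfig, intron_plan_for, make_genome


class TestCompositionStats:
    @pytest.mark.parametrize(
        "seq, at_skew, gc_skew, at_percent",
        [
            ("ATAT", 0.0, None, 100.0),
            ("GGGC", None, 0.5, 0.0),
            # hand count: A=2 T=1 G=1 C=0 -> (2-1)/3, (1-0)/1, 3/4
            ("AATG", 1 / 3, 1.0, 75.0),
        ],
    )
    def test_worked_examples(self, seq, at_skew, gc_skew, at_percent):
        st = composition_stats(seq)
        assert st.at_percent == pytest.approx(at_percent)
        if at_skew is None:
            assert st.at_skew is None
        else:
            assert st.at_skew == pytest.approx(at_skew)
        if gc_skew is None:
            assert st.gc_skew is None
        else:
            assert st.gc_skew == pytest.approx(gc_skew)

    def test_n_bases_excluded_from_denominators(self):
        with_n = composition_stats("AATGNNNN")
        without = composition_stats("AATG")
        assert with_n.at_skew == without.at_skew
        assert with_n.gc_skew == without.gc_skew
        assert with_n.at_percent == without.at_percent

    def test_all_n_sequence_has_undefined_skews(self):
        st = composition_stats("NNNN")
        assert st.at_skew is None and st.gc_skew is None
        assert math.isnan(st.at_percent)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_stats("")

    def test_skew_antisymmetric_under_reverse_complement(self):
        seq = "AATGGGCCTTAGCATTTACG"
        fwd = composition_stats(seq)
        rev = composition_stats(reverse_complement(seq))
        assert rev.at_skew == pytest.approx(-fwd.at_skew)
        assert rev.gc_skew == pytest.approx(-fwd.gc_skew)


class TestGapBetween:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((25000, 25172), (25199, 25300), 26),   # contig B12 end -> trnG start
            ((31000, 31900), (31954, 32191), 53),   # contig C8 -> C9
            ((100, 200), (201, 300), 0),            # abutting
            ((10540, 12490), (12470, 12830), -21),  # B3/B4 overlap, 21 bp
        ],
    )
    def test_printed_anchors(self, a, b, expected):
        assert gap_between(a, b, 40000) == expected

    def test_wrap_gap_through_origin(self, fixture_ann):
        trnP = fixture_ann.feature("trnP")
        rnl = fixture_ann.feature("rnl")
        assert gap_between(trnP, rnl, fixture_ann.genome) == ANCHORS["gap_trnP_rnl"]

    def test_identical_intervals_rejected(self):
        with pytest.raises(ValueError):
            gap_between((5, 10), (5, 10), 100)

    def test_gap_additivity_collinear(self):
        a, b, c = (10, 20), (30, 45), (60, 80)
        total = gap_between(a, b, 1000) + (45 - 30 + 1) + gap_between(b, c, 1000)
        assert total == c[0] - a[1] - 1


class TestRegionCatalogue:
    def test_fixture_overlaps_and_pair_partition(self, fixture_ann):
        cat = region_catalogue(fixture_ann)
        assert ("nad2", "nad3", 1) in cat.overlaps
        assert ("nad4L", "nad5", 1) in cat.overlaps
        n_pairs = len(cat.intergenic) + len(cat.overlaps) + len(cat.abutting)
        assert n_pairs == len(fixture_ann.top_level())
        assert cat.total_intergenic_bp == sum(g for _, _, g in cat.intergenic)

    def test_intron_fraction_worked_example(self, toy_factory):
        # 10,422 bp of introns on a 35,999 bp genome -> 28.95%
        L = 35999
        ann = toy_factory(
            [
                ("rnl", "rRNA", 1, 12000, [(1001, 6422), (7000, 12000 - 1)]),
                ("cox1", "PCG", 13000, 15999),
                ("control_region", "control", 20000, 20500),
            ],
            L,
        )
        intron_bp = (6422 - 1001 + 1) + (11999 - 7000 + 1)
        assert intron_bp == 10422
        cat = region_catalogue(ann)
        assert cat.intron_total_bp == 10422
        assert round(cat.intron_fraction, 2) == 28.95

    def test_zero_introns_zero_fraction(self, toy_factory):
        ann = toy_factory([("cox1", "PCG", 10, 100), ("nad1", "PCG", 200, 400)], 1000)
        assert region_catalogue(ann).intron_fraction == 0.0

    def test_nonadjacent_overlap_is_error(self, toy_factory):
        ann = toy_factory(
            [("a", "PCG", 10, 300), ("b", "PCG", 150, 200),
             ("c", "PCG", 250, 280), ("d", "PCG", 400, 500)],
            1000,
        )
        with pytest.raises(ValueError, match="non-adjacent"):
            region_catalogue(ann)

    def test_intron_fraction_matches_locate_bruteforce(self, fixture_ann):
        L = fixture_ann.length
        n_intron = sum(
            1 for p in range(1, L + 1, 7) if locate(p, fixture_ann).kind == "intron"
        )
        # strided brute force: fraction within sampling error of the catalogue
        cat = region_catalogue(fixture_ann)
        assert n_intron / (L // 7 + 1) * 100 == pytest.approx(cat.intron_fraction, abs=0.5)


class TestIntronCountTable:
    def test_panel_reproduces_published_totals(self):
        panel = {}
        for strain in TABLE1_INTRON_COUNTS.index:
            cfg = SimConfig(seed=11, strain=strain, intron_plan=intron_plan_for(strain))
            _, ann, _ = make_genome(cfg)
            panel[strain] = ann
        table = intron_count_table(panel)
        for strain in TABLE1_INTRON_COUNTS.index:
            expected = TABLE1_INTRON_COUNTS.loc[strain]
            assert table.loc[strain, "Total"] == expected.sum()
            for gene in TABLE1_INTRON_COUNTS.columns:
                assert table.loc[strain, gene] == expected[gene]

    def test_unexpected_host_gene_gets_new_column(self, toy_factory):
        a1 = toy_factory([("nad4", "PCG", 10, 400, [(100, 200)])], 1000, genome_id="s1")
        a2 = toy_factory([("nad4", "PCG", 10, 400)], 1000, genome_id="s2")
        table = intron_count_table([a1, a2])
        assert "nad4" in table.columns
        assert table.loc["s1", "Total"] == 1 and table.loc["s2", "Total"] == 0


class TestLocate:
    def test_fixture_labels(self, fixture_ann):
        assert str(locate(17400, fixture_ann)) == "exon of trnR_2"
        assert str(locate(5800, fixture_ann)) == "control"
        loc = locate(2000, fixture_ann)  # inside the rps3-bearing rnl intron
        assert loc.kind == "intron" and loc.gene == "rnl" and loc.nested_gene == "rps3"
        assert locate(1605, fixture_ann).nested_gene is None  # intron, outside rps3
        assert locate(5100, fixture_ann).kind == "intergenic"

    def test_out_of_range_rejected(self, fixture_ann):
        with pytest.raises(ValueError):
            locate(0, fixture_ann)
        with pytest.raises(ValueError):
            locate(fixture_ann.length + 1, fixture_ann)
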