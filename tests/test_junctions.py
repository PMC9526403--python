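"""Junction graph construction, merge rules, unit inference, TSS."""

import pytest

from mitocistron.evidence import ContentResolutionError, ContigAlignment
from mitocistron.fixtures import (
    ABSTRACT_UNIT_STRING,
    ANCHORS,
    CANONICAL_GENE_ORDER,
    VALIDATED_JUNCTIONS,
)
from mitocistron.junctions import (
    JunctionStatus,
    MergeParams,
    assess_all_junctions,
    build_junctions,
    infer_tss,
    infer_units,
    render_report,
    unit_gene_string,
)


def _status(evidence, up, down):
    for ev in evidence:
        if ev.junction.upstream == up and ev.junction.downstream == down:
            return ev
    raise KeyError((up, down))


class TestBuildJunctions:
    def test_one_junction_per_adjacent_gene_pair(self, fixture_ann):
        junctions = build_junctions(fixture_ann)
        assert len(junctions) == len(fixture_ann.genes()) == len(CANONICAL_GENE_ORDER)
        pairs = {(j.upstream, j.downstream) for j in junctions}
        assert ("trnM_3", "trnM_1") in pairs  # wrap pair through the control region

    @pytest.mark.parametrize(
        "up, down, gap",
        [
            ("trnM_1", "trnL_1", 2),
            ("trnY", "trnD", 3),
            ("trnV", "trnI", 2),
            ("trnG", "nad6", 53),
            ("cox3", "trnG", 26),
        ],
    )
    def test_published_gap_distances(self, fixture_ann, up, down, gap):
        j = next(x for x in build_junctions(fixture_ann) if x.upstream == up)
        assert j.downstream == down and j.gap_bp == gap

    def test_control_junction_flagged(self, fixture_ann):
        j = next(x for x in build_junctions(fixture_ann) if x.upstream == "trnM_3")
        assert j.crosses_control
        trna, other, unann = j.gap_composition
        assert other > 0.9  # the gap is mostly the control region itself


@pytest.fixture(scope="module")
def evidence(fixture_ann, table2_contigs):
    return assess_all_junctions(fixture_ann, table2_contigs, VALIDATED_JUNCTIONS)


class TestAssessJunction:
    def test_contig_spanning_pair_is_supported(self, evidence):
        ev = _status(evidence, "trnM_2", "nad2")
        assert ev.status is JunctionStatus.SUPPORTED
        assert "B2" in ev.supporting_contigs

    def test_validated_pairs_reported_distinctly(self, evidence):
        for up, down in VALIDATED_JUNCTIONS:
            assert _status(evidence, up, down).status is JunctionStatus.VALIDATED

    def test_trna_bridge_without_validation(self, fixture_ann, table2_contigs):
        # withholding the PCR list, the cleaved-tRNA rule still bridges
        evidence = assess_all_junctions(fixture_ann, table2_contigs, ())
        assert _status(evidence, "cox1", "trnR_2").status is JunctionStatus.TRNA_BRIDGE
        assert _status(evidence, "cox3", "trnG").status is JunctionStatus.TRNA_BRIDGE
        assert _status(evidence, "trnG", "nad6").status is JunctionStatus.TRNA_BRIDGE

    def test_small_gap_bridge_between_covered_genes(self, evidence):
        assert _status(evidence, "trnY", "trnD").status is JunctionStatus.SMALL_GAP_BRIDGE
        assert _status(evidence, "trnV", "trnI").status is JunctionStatus.SMALL_GAP_BRIDGE

    def test_control_junction_unsupported(self, evidence):
        assert _status(evidence, "trnM_3", "trnM_1").status is JunctionStatus.UNSUPPORTED

    def test_isolated_large_gap_unsupported(self, fixture_ann):
        lone = [ContigAlignment("x", "ATCC 90518", 14313, 17358, gene_content=("cox1",))]
        evidence = assess_all_junctions(fixture_ann, lone, ())
        assert _status(evidence, "atp6", "rns").status is JunctionStatus.UNSUPPORTED

    def test_unknown_content_gene_is_error(self, fixture_ann):
        bad = [ContigAlignment("x", "s", 10, 20, gene_content=("nadZ",))]
        with pytest.raises(ContentResolutionError, match="nadZ"):
            assess_all_junctions(fixture_ann, bad, ())


class TestInferUnits:
    def test_no_evidence_gives_singletons(self, fixture_ann):
        evidence = assess_all_junctions(fixture_ann, [], ())
        units = infer_units(evidence)
        assert len(units) == len(fixture_ann.genes())
        assert all(len(u.genes) == 1 for u in units)

    def test_full_coverage_gives_single_circular_unit(self, fixture_ann):
        whole = [ContigAlignment("all", "ATCC 90518", 1, fixture_ann.length,
                                 gene_content=tuple(CANONICAL_GENE_ORDER[37:] + CANONICAL_GENE_ORDER[:37]))]
        evidence = assess_all_junctions(fixture_ann, whole, ())
        units = infer_units(evidence)
        assert len(units) == 1 and units[0].circular

    def test_published_table_yields_single_unit_with_abstract_order(
        self, fixture_ann, table2_contigs
    ):
        evidence = assess_all_junctions(fixture_ann, table2_contigs, VALIDATED_JUNCTIONS)
        units = infer_units(evidence)
        assert len(units) == 1
        unit = units[0]
        assert not unit.circular
        assert unit_gene_string(unit, fixture_ann) == ABSTRACT_UNIT_STRING
        broken = [
            (ev.junction.upstream, ev.junction.downstream)
            for ev in evidence if ev.status is JunctionStatus.UNSUPPORTED
        ]
        assert broken == [("trnM_3", "trnM_1")]

    def test_units_partition_genes(self, fixture_ann, table2_contigs):
        evidence = assess_all_junctions(fixture_ann, table2_contigs[:8], ())
        units = infer_units(evidence)
        seen = [g for u in units for g in u.genes]
        assert sorted(seen) == sorted(fixture_ann.gene_names())

    def test_unit_genes_contiguous_in_annotation_order(self, fixture_ann, table2_contigs):
        order = fixture_ann.gene_names()
        doubled = order + order
        evidence = assess_all_junctions(fixture_ann, table2_contigs[:10], ())
        for u in infer_units(evidence):
            genes = list(u.genes)
            assert any(doubled[i : i + len(genes)] == genes for i in range(len(order)))

    def test_adding_evidence_never_increases_unit_count(self, fixture_ann, table2_contigs):
        counts = []
        for k in range(0, len(table2_contigs) + 1, 4):
            evidence = assess_all_junctions(fixture_ann, table2_contigs[:k], VALIDATED_JUNCTIONS)
            counts.append(len(infer_units(evidence)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestInferTss:
    def test_terminal_contig_extension_into_control(self, fixture_ann, table2_contigs):
        hits = infer_tss(table2_contigs, fixture_ann)
        (hit,) = [t for t in hits if t.contig_id == "A"]
        assert hit.extension_bp == ANCHORS["contig_A_end"] - ANCHORS["trnM_3_end"] == 121
        assert hit.candidate_region == (ANCHORS["trnM_3_end"] + 1, ANCHORS["contig_A_end"])

    def test_contig_ending_at_gene_end_has_zero_extension(self, fixture_ann):
        c = ContigAlignment("z", "ATCC 90518", 5000, ANCHORS["trnM_3_end"])
        (hit,) = infer_tss([c], fixture_ann)
        assert hit.extension_bp == 0 and hit.candidate_region is None

    def test_no_contigs_near_control_is_empty(self, fixture_ann):
        c = ContigAlignment("c", "ATCC 90518", 14313, 17358)
        assert infer_tss([c], fixture_ann) == []

    def test_missing_control_region_is_error(self, toy_factory):
        ann = toy_factory([("cox1", "PCG", 10, 100)], 1000)
        with pytest.raises(ValueError):
            infer_tss([], ann)


class TestRenderReport:
    def test_report_contents(self, fixture_ann, table2_contigs):
        evidence = assess_all_junctions(fixture_ann, table2_contigs, VALIDATED_JUNCTIONS)
        units = infer_units(evidence)
        tss = infer_tss(table2_contigs, fixture_ann)
        text, data = render_report(units, evidence, tss, fixture_ann)
        assert data["n_units"] == 1
        assert data["units"][0]["genes"].startswith("trnM_1-trnL_1-trnA-")
        assert data["units"][0]["genes"].endswith("-trnT-trnE-trnM_3")
        assert "rnl(rps3)" in data["units"][0]["genes"]
        assert "121 bp" in text
        assert len(data["junctions"]) == len(CANONICAL_GENE_ORDER)

    def test_empty_evidence_report(self, fixture_ann):
        evidence = assess_all_junctions(fixture_ann, [], ())
        units = infer_units(evidence)
        text, data = render_report(units, evidence, None, fixture_ann)
        assert data["n_units"] == len(CANONICAL_GENE_ORDER)
        assert all(j["status"] == "unsupported" for j in data["junctions"])
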