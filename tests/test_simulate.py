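"""Generator contracts: determinism, processing-stage order, evidence
soundness, end-to-end unit recovery."""

import pytest

from mitocistron.evidence import classify_contig, detect_polyA
from mitocistron.genome import composition_stats, region_catalogue
from mitocistron.introns import check_splice_boundaries, splice_gene
from mitocistron.junctions import MergeParams, assess_all_junctions, infer_units
from mitocistron.simulate import (
    SimConfig,
    fragment_to_evidence,
    intron_plan_for,
    make_genome,
    simulate,
    simulate_processing,
)

BREAKS = {
    1: (),
    2: (("cox1", "trnR_2"),),
    3: (("cox1", "trnR_2"), ("rns", "trnY")),
}


class TestMakeGenome:
    def test_canonical_complement(self):
        _, ann, _ = make_genome(SimConfig(seed=1))
        kinds = {}
        for f in ann.features:
            kinds[f.kind] = kinds.get(f.kind, 0) + 1
        assert kinds["tRNA"] == 25
        assert kinds["rRNA"] == 2
        assert kinds["PCG"] == 15  # incl. nested rps3
        assert kinds["control"] == 1
        assert ann.feature("rps3").nested_in == "rnl"

    def test_at_percent_near_target(self):
        genome, _, _ = make_genome(SimConfig(seed=2, at_percent=73.0))
        assert composition_stats(genome.sequence).at_percent == pytest.approx(73.0, abs=1.0)

    def test_zero_intron_plan_zero_fraction(self):
        _, ann, _ = make_genome(SimConfig(seed=3, intron_plan={}))
        assert region_catalogue(ann).intron_fraction == 0.0

    def test_table1_profile_total(self):
        plan = intron_plan_for("B. brongniartii GYU-BMZ03")
        _, ann, _ = make_genome(SimConfig(seed=3, intron_plan=plan))
        assert sum(len(f.introns) for f in ann.features) == 8

    def test_planted_boundaries_canonical(self):
        genome, ann, _ = make_genome(SimConfig(seed=5, intron_plan={"cox2": 1, "nad5": 1}))
        for gene in ("cox2", "nad5"):
            for chk in check_splice_boundaries(ann.feature(gene), genome):
                assert chk.group1_ok and chk.gtag_ok

    def test_determinism_byte_identical(self):
        a = simulate(SimConfig(seed=7))
        b = simulate(SimConfig(seed=7))
        assert a[0].genome.sequence == b[0].genome.sequence
        assert [(c.contig_id, c.start, c.end, c.gene_content) for c in a[2]] == [
            (c.contig_id, c.start, c.end, c.gene_content) for c in b[2]
        ]
        assert [(r.read_id, r.segments, r.softclip_tail) for r in a[3]] == [
            (r.read_id, r.segments, r.softclip_tail) for r in b[3]
        ]

    def test_splice_round_trip_reproduces_exon_sequence(self):
        genome, ann, truth = make_genome(SimConfig(seed=9))
        for gene in truth.intron_intervals:
            assert splice_gene(ann.feature(gene), genome) == truth.gene_exonic_seq[gene]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(trna_cleavage_dropout=1.5)
        with pytest.raises(ValueError):
            make_genome(SimConfig(intron_plan={"not_a_gene": 1}))
        with pytest.raises(ValueError):
            SimConfig(gene_order=("cox1", "cox1"))


class TestProcessing:
    def test_polya_before_splicing_leaves_intronful_polyadenylated_molecule(self):
        _, ann, truth = make_genome(SimConfig(seed=1, polyA_before_splicing=True))
        mols = simulate_processing(ann, truth)
        assert any(m.polyadenylated and m.contains_intron for m in mols)

    def test_splice_first_has_no_such_molecule(self):
        _, ann, truth = make_genome(SimConfig(seed=1, polyA_before_splicing=False))
        mols = simulate_processing(ann, truth)
        assert not any(m.polyadenylated and m.contains_intron for m in mols)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_forced_breaks_give_k_units(self, k):
        _, ann, truth = make_genome(SimConfig(seed=2, unit_breaks=BREAKS[k]))
        assert len(truth.units) == k
        assert sorted(g for u in truth.units for g in u) == sorted(truth.config.gene_order)

    def test_cleavage_releases_every_unit_trna(self):
        _, ann, truth = make_genome(SimConfig(seed=2))
        simulate_processing(ann, truth)
        trnas = {g for g in truth.config.gene_order if g.startswith("trn")}
        assert set(truth.cleaved_trnas) == trnas


class TestEvidence:
    def test_contig_intervals_within_some_molecule_footprint(self):
        ann, truth, contigs, _ = simulate(SimConfig(seed=6))
        mols = {m.molecule_id: m for m in truth.molecules}
        L = ann.length
        for c in contigs:
            mol = mols[truth.contig_provenance[c.contig_id]]
            fp = set()
            for s, e in mol.footprint:
                fp.update((p - 1) % L + 1 for p in range(s, e + 1))
            for s, e in c.intervals():
                span = range(s, e + 1) if s <= e else list(range(s, L + 1)) + list(range(1, e + 1))
                assert all(p in fp for p in span)

    def test_full_dropout_removes_all_punctuation_trna_evidence(self):
        ann, truth, contigs, _ = simulate(SimConfig(seed=6, trna_cleavage_dropout=1.0))
        trnas = [f for f in ann.genes() if f.kind == "tRNA"]
        for c in contigs:
            assert not any(t.name in c.gene_content for t in trnas)

    def test_zero_dropout_single_unit_contiguous_coverage(self):
        ann, truth, contigs, _ = simulate(
            SimConfig(seed=6, trna_cleavage_dropout=0.0, coverage_gap_rate=0.0)
        )
        units = infer_units(assess_all_junctions(ann, contigs))
        assert len(units) == 1

    def test_polya_discriminator(self):
        for flag, expected in [(True, True), (False, False)]:
            ann, truth, contigs, reads = simulate(SimConfig(seed=3, polyA_before_splicing=flag))
            polyA_mols = {
                m.molecule_id for m in truth.molecules if m.polyadenylated
            } & {
                r.read_id.removeprefix("polyA.")
                for r in reads
                if r.softclip_tail and detect_polyA(r, ann) is not None
            }
            n = sum(
                1 for c in contigs
                if classify_contig(c, ann) == "intron_containing"
                and c.source_molecule in polyA_mols
            )
            assert (n > 0) is expected


class TestRecovery:
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_unit_count_recovered(self, k):
        hits = 0
        for seed in range(5):
            ann, truth, contigs, _ = simulate(SimConfig(seed=seed, unit_breaks=BREAKS[k]))
            units = infer_units(assess_all_junctions(ann, contigs))
            hits += len(units) == k
        assert hits >= 4

    def test_disabling_bridges_fragments_units(self):
        ann, truth, contigs, _ = simulate(SimConfig(seed=0))
        params = MergeParams(enable_trna_bridge=False, enable_small_gap_bridge=False)
        units = infer_units(assess_all_junctions(ann, contigs, params=params))
        assert truth.dropped_trnas  # at default dropout some tRNA vanished
        assert len(units) > len(truth.units)
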