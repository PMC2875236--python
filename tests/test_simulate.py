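import pytest

from concerta import (
    Event,
    SimConfig,
    align_codons,
    recovery_report,
    scenario_conversion,
    scenario_pair,
    scenario_vtg,
    simulate_family,
)
from concerta.codons import translate
from concerta.geneconv import ConversionFragment
from concerta.seqs import span_length


class TestDeterminism:
    def test_fixed_seed_identical_output_bytes(self):
        a = simulate_family(scenario_vtg(3, n_codons=200))
        b = simulate_family(scenario_vtg(3, n_codons=200))
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
        assert a.tree_newick == b.tree_newick
        assert a.event_log == b.event_log

    def test_different_seeds_differ(self):
        a = simulate_family(scenario_vtg(3, n_codons=200))
        b = simulate_family(scenario_vtg(4, n_codons=200))
        assert [r.sequence for r in a.records] != [r.sequence for r in b.records]

    def test_config_json_roundtrip(self, tmp_path):
        cfg = scenario_vtg(5, n_codons=100)
        cfg.to_json(tmp_path / "c.json")
        back = SimConfig.from_json(tmp_path / "c.json")
        assert back == cfg


class TestSequenceValidity:
    def test_no_internal_stops_ever(self):
        for seed in range(3):
            truth = simulate_family(scenario_vtg(seed, n_codons=300))
            for rec in truth.records:
                _, internal = translate(rec.cds(), strip_terminal_stop=True)
                assert not internal

    def test_regions_annotated_and_cds_in_frame(self):
        truth = simulate_family(scenario_vtg(1, n_codons=120))
        for rec in truth.records:
            assert rec.start_coord == -truth.config.promoter_len
            assert len(rec.cds()) == 3 * truth.config.n_codons
            names = {r.name for r in rec.regions}
            assert {"promoter", "exon1", "intron1", "exon2",
                    "intron2", "exon3", "three_prime"} <= names

    def test_true_tree_structure(self):
        truth = simulate_family(scenario_vtg(1, n_codons=60))
        assert truth.tree_newick.count("sp1|Vg_a") == 1
        assert truth.tree_newick.endswith(";")


class TestEvents:
    def test_conversion_homogenises_only_the_tract(self):
        # convert at the very end: tract identical, flanks untouched
        n = 400
        end = 3 * n + 2 * 70 + 200
        cfg = SimConfig(n_codons=n, omega=0.5, t_end=0.1, seed=9, events=[
            Event(0.0, "duplicate", gene="Vg", new_gene="Vg2"),
            Event(0.1, "convert", species="anc", donor="Vg", recipient="Vg2",
                  begin=301, end=900),
        ])
        truth = simulate_family(cfg)
        a = truth.record("anc|Vg").sequence
        b = truth.record("anc|Vg2").sequence
        rec = truth.record("anc|Vg")
        lo, hi = rec.offset(301), rec.offset(900)
        assert a[lo : hi + 1] == b[lo : hi + 1]
        flank_mismatch = sum(x != y for x, y in zip(a[:lo], b[:lo]))
        assert flank_mismatch > 0

    def test_tract_outside_gene_rejected(self):
        cfg = SimConfig(n_codons=50, t_end=0.1, events=[
            Event(0.05, "convert", species="anc", donor="Vg", recipient="Vg",
                  begin=1, end=10**6)])
        with pytest.raises(ValueError, match="outside"):
            simulate_family(cfg)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            SimConfig(omega=-0.1)

    def test_decreasing_event_times_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            SimConfig(t_end=1.0, events=[
                Event(0.5, "duplicate", gene="Vg", new_gene="b"),
                Event(0.2, "duplicate", gene="Vg", new_gene="c")])


class TestModelCalibration:
    def test_neutral_omega_estimates_near_one(self):
        truth = simulate_family(scenario_pair(n_codons=1500, omega=1.0,
                                              target_ds=0.2, seed=2))
        from concerta.dnds import dnds

        aln = align_codons([r.cds() for r in truth.records],
                           [r.id for r in truth.records])
        res = dnds(aln, 0, 1, B=300, seed=2)
        assert res.omega == pytest.approx(1.0, abs=0.15)

    def test_realized_omega_converges_at_long_sequences(self):
        truth = simulate_family(scenario_pair(n_codons=5000, omega=0.4,
                                              target_ds=0.2, seed=5))
        assert abs(truth.counts.realized_omega - 0.4) < 0.03

    def test_scenario_vtg_diagnostic_pattern(self, vtg_truth, vtg_codon_aln):
        from concerta.dnds import count_pair

        ids = vtg_codon_aln.ids
        ps = {}
        for i in range(4):
            for j in range(i + 1, 4):
                ps[(ids[i], ids[j])] = count_pair(vtg_codon_aln, i, j, B=0).Ps
        par = [ps[("sp1|Vg_a", "sp1|Vg_b")], ps[("sp2|Vg_a", "sp2|Vg_b")]]
        orth = [ps[("sp1|Vg_a", "sp2|Vg_a")], ps[("sp1|Vg_b", "sp2|Vg_b")]]
        assert max(par) < min(orth)


class TestRecoveryReport:
    def _fragment(self, begin, end):
        return ConversionFragment(
            gene_i="sp1|Vg_a", gene_j="sp1|Vg_b", begin_i=begin, end_i=end,
            begin_j=begin, end_j=end, length_i=span_length(begin, end),
            length_j=span_length(begin, end), n_poly=5, n_mismatch=0,
            score=5.0, global_p=0.001, pair_p=0.001, aln_begin=0, aln_end=1)

    def test_perfect_detection_full_recall(self):
        truth = simulate_family(scenario_conversion(seed=1, n_codons=300,
                                                    tract_begin=301))
        tract = truth.tracts[0]
        rep = recovery_report(truth, [self._fragment(tract.begin, tract.end)])
        assert rep.recall == 1.0 and rep.precision == 1.0

    def test_no_detection_zero_recall(self):
        truth = simulate_family(scenario_conversion(seed=1, n_codons=300,
                                                    tract_begin=301))
        rep = recovery_report(truth, [])
        assert rep.recall == 0.0

    def test_unknown_gene_id_rejected(self):
        truth = simulate_family(scenario_conversion(seed=1, n_codons=300,
                                                    tract_begin=301))
        bad = self._fragment(1, 10)
        object.__setattr__(bad, "gene_i", "nope|x")
        with pytest.raises(ValueError, match="unknown gene"):
            recovery_report(truth, [bad])
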