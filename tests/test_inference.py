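import pytest
from hypothesis import given, strategies as st

from concerta import (
    GeneRecord,
    NucAlignment,
    assign_homology,
    classify_mode,
    mosaic_dnds,
    permutation_test,
)
from concerta.align import CodonAlignment
from concerta.dnds import dnds
from concerta.geneconv import ConversionFragment

from oracles import mutate_codons, random_sense_codons


class TestClassifyMode:
    def test_low_paralog_ps_means_concerted(self):
        # the diagnostic contrast observed in Culex Vg1: within-species
        # synonymous divergence an order below the between-species one
        v = classify_mode([0.0316, 0.0525], [0.1809, 0.1851])
        assert v.mode == "concerted"
        assert v.ratio == pytest.approx(0.0525 / 0.1809)

    def test_equal_ps_means_purifying_only(self):
        assert classify_mode([0.18], [0.18]).mode == "purifying_only"

    def test_saturated_ps_is_indeterminate(self):
        assert classify_mode([0.45], [0.5]).mode == "saturated_indeterminate"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_mode([], [0.2])

    def test_mechanism_note_follows_declared_organisation(self):
        v = classify_mode([0.03], [0.2], tandem_head_to_tail=True)
        assert any("unequal crossover" in n for n in v.notes)

    @given(shrink=st.floats(0.1, 1.0))
    def test_monotone_in_paralog_ps(self, shrink):
        base = [0.1, 0.15]
        verdict = classify_mode(base, [0.25])
        smaller = classify_mode([p * shrink for p in base], [0.25])
        if verdict.mode == "concerted":
            assert smaller.mode == "concerted"


class TestAssignHomology:
    def _rec(self, gid, species, promoter, cds):
        seq = promoter + cds
        return GeneRecord(gid, seq, species=species, start_coord=-len(promoter))

    def test_identical_promoters_reciprocal_pair(self, rng):
        prom = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        cds = "ATG" + "".join(random_sense_codons(rng, 30))
        recs = [self._rec("s1|g", "s1", prom, cds), self._rec("s2|g", "s2", prom, cds)]
        hm = assign_homology(recs, promoter_window_bp=400)
        assert hm.ortholog_pairs == [("s1|g", "s2|g")]
        assert hm.promoter_identity("s1|g", "s2|g") == 100.0

    def test_shuffled_promoter_below_floor(self, rng):
        prom = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        shuffled = "".join(rng.permutation(list(prom)))
        cds = "ATG" + "".join(random_sense_codons(rng, 30))
        recs = [self._rec("s1|g", "s1", prom, cds),
                self._rec("s2|g", "s2", shuffled, cds)]
        hm = assign_homology(recs, promoter_window_bp=400, identity_floor=75.0)
        assert hm.ortholog_pairs == []

    def test_one_species_only_rejected(self, rng):
        prom = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        recs = [self._rec("s1|a", "s1", prom, "ATGAAA"),
                self._rec("s1|b", "s1", prom, "ATGAAA")]
        with pytest.raises(ValueError, match="2 species"):
            assign_homology(recs)

    def test_vtg_scenario_orthologs_resolved(self, vtg_truth):
        hm = assign_homology(vtg_truth.records)
        assert sorted(hm.ortholog_pairs) == [("sp1|Vg_a", "sp2|Vg_a"),
                                             ("sp1|Vg_b", "sp2|Vg_b")]
        assert hm.paralog_sets == {"sp1": ["sp1|Vg_a", "sp1|Vg_b"],
                                   "sp2": ["sp2|Vg_a", "sp2|Vg_b"]}


def _pair_alignment(rng, n_codons=500, p=0.1):
    ca = random_sense_codons(rng, n_codons)
    cb = mutate_codons(rng, ca, p)
    return CodonAlignment(ids=["a", "b"], rows=["".join(ca), "".join(cb)])


def _fragment(begin, end, p=0.001):
    from concerta.seqs import span_length

    return ConversionFragment(gene_i="a", gene_j="b", begin_i=begin, end_i=end,
                              begin_j=begin, end_j=end,
                              length_i=span_length(begin, end),
                              length_j=span_length(begin, end),
                              n_poly=10, n_mismatch=0, score=10.0, global_p=p,
                              pair_p=p, aln_begin=begin - 1, aln_end=end - 1)


class TestMosaic:
    def test_no_fragments_equals_plain_dnds(self, rng):
        aln = _pair_alignment(rng)
        rep = mosaic_dnds(aln, 0, 1, [], B=100, seed=3)
        assert not rep.whole_gene_converted and len(rep.segments) == 1
        plain = dnds(aln, 0, 1, B=100, seed=3)
        seg = rep.segments[0]
        assert seg.counts.Ps == pytest.approx(plain.counts.Ps)
        assert seg.result.omega == pytest.approx(plain.omega)

    def test_engineered_tract_partitions_cds(self, rng):
        # masking codons 100-200 of a 500-codon pair leaves 297 bp + 900 bp
        aln = _pair_alignment(rng)
        frag = _fragment(begin=3 * 99 + 1, end=3 * 200)
        rep = mosaic_dnds(aln, 0, 1, [frag], B=100, seed=3)
        sizes = [(s.size_bp_i, s.size_bp_j) for s in rep.segments if not s.combined]
        assert sizes == [(297, 297), (900, 900)]
        assert rep.masked_codons + sum(len(range(s.codon_cols[0], s.codon_cols[1] + 1))
                                       for s in rep.segments if not s.combined) \
            == rep.total_codons

    def test_combined_row_pools_codons(self, rng):
        aln = _pair_alignment(rng)
        frag = _fragment(begin=3 * 99 + 1, end=3 * 200)
        rep = mosaic_dnds(aln, 0, 1, [frag], B=100, seed=3)
        combined = [s for s in rep.segments if s.combined]
        assert len(combined) == 1
        parts = [s for s in rep.segments if not s.combined]
        assert combined[0].counts.Sd == pytest.approx(sum(s.counts.Sd for s in parts))

    def test_insignificant_fragments_not_masked(self, rng):
        aln = _pair_alignment(rng)
        frag = _fragment(begin=3 * 99 + 1, end=3 * 200, p=0.5)
        rep = mosaic_dnds(aln, 0, 1, [frag], B=100, seed=3)
        assert len(rep.segments) == 1 and rep.masked_codons == 0

    def test_whole_gene_conversion_signal(self, rng):
        aln = _pair_alignment(rng)
        frag = _fragment(begin=1, end=1500)
        rep = mosaic_dnds(aln, 0, 1, [frag], B=100, seed=3)
        assert rep.whole_gene_converted and rep.segments == []

    def test_vtg_whole_gene_signal_end_to_end(self, vtg_truth, vtg_codon_aln):
        aln = NucAlignment.from_prealigned(vtg_truth.records)
        frags = permutation_test(aln, n_perm=300, seed=17, g=2.0)
        i = vtg_codon_aln.index("sp1|Vg_a")
        j = vtg_codon_aln.index("sp1|Vg_b")
        rep = mosaic_dnds(vtg_codon_aln, i, j, frags,
                          cds_coords_i=vtg_truth.record("sp1|Vg_a").cds_coords(),
                          cds_coords_j=vtg_truth.record("sp1|Vg_b").cds_coords(),
                          B=100, seed=3)
        assert rep.whole_gene_converted


class TestConcertedRecoveryOnSimulatedFamily:
    def test_converted_pair_classified_concerted_and_omega_recovered(self, vtg_truth,
                                                                     vtg_codon_aln):
        ids = vtg_codon_aln.ids
        hm = assign_homology(vtg_truth.records)
        from concerta.dnds import count_pair

        def ps(a, b):
            return count_pair(vtg_codon_aln, ids.index(a), ids.index(b), B=0).Ps

        ps_par = [ps(*p) for genes in hm.paralog_sets.values()
                  for p in [tuple(genes)]]
        ps_orth = [ps(a, b) for a, b in hm.ortholog_pairs]
        v = classify_mode(ps_par, ps_orth)
        assert v.mode == "concerted"
        # orthologue omega unaffected by within-species conversion
        res = dnds(vtg_codon_aln, ids.index("sp1|Vg_a"), ids.index("sp2|Vg_a"),
                   B=300, seed=2)
        se3 = 3 * (res.se_dN / res.dS + res.se_dS * res.dN / res.dS**2)
        assert abs(res.omega - vtg_truth.config.omega) < max(se3, 0.12)
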