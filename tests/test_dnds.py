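import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from concerta import align_codons, scenario_pair, simulate_family
from concerta.align import CodonAlignment
from concerta.codons import GENETIC_CODE, CodonError, codon_differences, codon_sites
from concerta.dnds import (
    SaturationError,
    count_pair,
    dnds,
    jukes_cantor,
    windowed_dnds,
)

from oracles import (
    SENSE,
    oracle_differences,
    oracle_pair_counts,
    oracle_sites,
    mutate_codons,
    random_sense_codons,
)


class TestCodonSites:
    def test_phe_third_position(self):
        s, n = codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_has_no_synonymous_sites(self):
        # TGG: the only stop-free changes at position 3 (TGC/TGT) change the aa
        assert codon_sites("TGG") == (0.0, 3.0)

    def test_leu_cta_fourfold_third_position(self):
        # all third-position changes of CTA stay Leu, so s includes a full site
        assert all(GENETIC_CODE["CT" + b] == "L" for b in "ACGT")
        s, _ = codon_sites("CTA")
        s12, _ = oracle_sites("CTA")
        assert s == pytest.approx(s12)
        assert s >= 1.0

    def test_stop_codon_rejected(self):
        with pytest.raises(CodonError):
            codon_sites("TGA")

    @pytest.mark.parametrize("codon", SENSE)
    def test_every_sense_codon_matches_enumeration(self, codon):
        assert codon_sites(codon) == pytest.approx(oracle_sites(codon))


class TestCodonDifferences:
    @pytest.mark.parametrize("a,b,expected", [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTA", (0.0, 1.0)),       # Phe -> Leu, one nonsynonymous step
        ("TTT", "GTA", (0.5, 1.5)),       # two pathways averaged
    ])
    def test_known_pairs(self, a, b, expected):
        assert codon_differences(a, b) == pytest.approx(expected)

    def test_sd_nd_sum_to_positions_changed(self, rng):
        for _ in range(50):
            a, b = random_sense_codons(rng, 2)
            sd, nd = codon_differences(a, b)
            ndiff = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(ndiff)

    def test_pathways_through_stops_excluded(self, rng):
        # TGT <-> TAC: path via TAT is fine, path via TGC is fine, but
        # random pairs adjacent to stops exercise the exclusion; compare
        # everything against the independent enumerator
        for _ in range(200):
            a, b = random_sense_codons(rng, 2)
            assert codon_differences(a, b) == pytest.approx(oracle_differences(a, b))

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b = random_sense_codons(rng, 2)
            assert codon_differences(a, b) == pytest.approx(codon_differences(b, a))


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.0525) == pytest.approx(0.05443, abs=1e-5)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    @given(st.floats(0.0, 0.74))
    def test_monotone_and_inflating(self, p):
        d = jukes_cantor(p)
        assert d >= p * (1 - 1e-12)
        if p > 0.01:
            assert jukes_cantor(p - 0.01) < d


def _aln(pairs):
    return CodonAlignment(ids=["a", "b"], rows=["".join(x) for x in zip(*pairs)])


class TestCountPair:
    def test_identical_rows_zero_proportions(self):
        aln = _aln([("TTT", "TTT"), ("GGG", "GGG")])
        cp = count_pair(aln, 0, 1, B=0)
        assert cp.Ps == 0.0 and cp.Pn == 0.0

    def test_hand_computed_two_codon_example(self):
        # TTT GGG vs TTC GGG: one synonymous difference at the Phe codon
        aln = _aln([("TTT", "TTC"), ("GGG", "GGG")])
        cp = count_pair(aln, 0, 1, B=0)
        s_ttt, _ = oracle_sites("TTT")
        s_ttc, _ = oracle_sites("TTC")
        s_ggg, _ = oracle_sites("GGG")
        S = (s_ttt + s_ttc) / 2 + s_ggg
        assert cp.Sd == 1.0 and cp.Nd == 0.0
        assert cp.Ps == pytest.approx(1.0 / S)

    def test_gap_and_n_codons_dropped_pairwise(self):
        aln = _aln([("TTT", "TTC"), ("---", "GGG"), ("AAN", "AAA"), ("TGA", "TGG")])
        cp = count_pair(aln, 0, 1, B=0)
        assert cp.n_codons_compared == 1

    def test_site_sum_invariant(self, vtg_codon_aln):
        cp = count_pair(vtg_codon_aln, 0, 1, B=0)
        assert cp.S + cp.N == pytest.approx(3 * cp.n_codons_compared, rel=1e-9)
        assert 0.0 <= cp.Ps <= 1.0 and 0.0 <= cp.Pn <= 1.0

    def test_swap_symmetry(self, vtg_codon_aln):
        a = count_pair(vtg_codon_aln, 0, 1, B=200, seed=9)
        b = count_pair(vtg_codon_aln, 1, 0, B=200, seed=9)
        assert (a.S, a.N, a.Sd, a.Nd) == (b.S, b.N, b.Sd, b.Nd)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            ca = random_sense_codons(rng, 50)
            cb = mutate_codons(rng, ca, 0.08)
            aln = _aln(list(zip(ca, cb)))
            cp = count_pair(aln, 0, 1, B=0)
            n, S, N, Sd, Nd = oracle_pair_counts(ca, cb)
            assert cp.n_codons_compared == n
            assert (cp.S, cp.N, cp.Sd, cp.Nd) == pytest.approx((S, N, Sd, Nd))


class TestDnds:
    def test_identical_sequences_no_test(self):
        aln = _aln([("TTT", "TTT"), ("GGG", "GGG"), ("AAA", "AAA")] * 10)
        res = dnds(aln, 0, 1, B=100, seed=1)
        assert res.omega_undefined and not res.testable

    def test_seeded_bootstrap_is_reproducible(self, vtg_codon_aln):
        r1 = dnds(vtg_codon_aln, 0, 1, B=300, seed=77)
        r2 = dnds(vtg_codon_aln, 0, 1, B=300, seed=77)
        assert (r1.se_diff, r1.Z, r1.p_value) == (r2.se_diff, r2.Z, r2.p_value)

    def test_jc_inflates_and_z_sign(self, vtg_codon_aln):
        res = dnds(vtg_codon_aln, 0, 1, B=300, seed=5)
        assert res.dS >= res.counts.Ps and res.dN >= res.counts.Pn
        assert math.copysign(1, res.Z) == math.copysign(1, res.dS - res.dN)
        assert 0 < res.p_value <= 1

    def test_recovers_simulated_omega_within_three_se(self):
        truth = simulate_family(scenario_pair(n_codons=1500, omega=0.3,
                                              target_ds=0.2, seed=1))
        aln = align_codons([r.cds() for r in truth.records],
                           [r.id for r in truth.records])
        res = dnds(aln, 0, 1, B=500, seed=1)
        se_omega = 3 * (res.se_dN / res.dS + res.se_dS * res.dN / res.dS**2)
        assert abs(res.omega - 0.3) < max(se_omega, 0.05)


class TestWindowedScan:
    def test_identical_sequences_all_untestable(self):
        aln = _aln([("TTT", "TTT")] * 40)
        wins = windowed_dnds(aln, 0, 1, window_codons=20, step_codons=10, B=50)
        assert wins and all(w.untestable for w in wins)

    def test_window_longer_than_alignment_degrades_to_one(self, vtg_codon_aln):
        wins = windowed_dnds(vtg_codon_aln, 0, 1, window_codons=10**6,
                             step_codons=10, B=50, seed=3)
        assert len(wins) == 1

    def test_engineered_nonsynonymous_segment_is_the_maximum(self, rng):
        # mostly synonymous divergence, with codons 40-59 made heavily
        # nonsynonymous: that window must carry the largest omega
        ca = random_sense_codons(rng, 120)
        cb = list(ca)
        syn_map = {"TTT": "TTC", "GGG": "GGA", "AAA": "AAG", "CCC": "CCT"}
        for k in range(0, 120, 4):
            cb[k] = syn_map.get(cb[k], cb[k])
        for k in range(40, 60):
            cb[k] = "TGG" if ca[k] != "TGG" else "CCC"
        aln = _aln(list(zip(ca, cb)))
        wins = windowed_dnds(aln, 0, 1, window_codons=20, step_codons=5, B=50, seed=2)
        testable = [w for w in wins if not w.untestable]
        best = max(testable, key=lambda w: w.omega)
        # the top window overlaps the engineered segment
        assert best.start_codon <= 59 and best.end_codon >= 40

    def test_uniform_low_omega_never_flags_positive_selection(self):
        truth = simulate_family(scenario_pair(n_codons=800, omega=0.2,
                                              target_ds=0.2, seed=11))
        aln = align_codons([r.cds() for r in truth.records],
                           [r.id for r in truth.records])
        wins = windowed_dnds(aln, 0, 1, window_codons=60, step_codons=30,
                             B=200, seed=4)
        for w in wins:
            if w.untestable:
                continue
            # no window significantly above 1 (one-sided check on omega > 1)
            assert not (w.result.omega > 1 and w.result.Z < -2.33)
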