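"""Unit tests for binding-configuration enumeration and occupancy."""

import math

import numpy as np
import pytest

from promotherm.model import (
    EnergyModel,
    InvalidAlphabetError,
    PlacementError,
    PromoterSequence,
    UndefinedOccupancyError,
    classify_configuration,
    configuration_energy,
    enumerate_configurations,
    find_rbs,
    pon_extended,
    pon_from_energies,
    pon_standard,
    reverse_complement,
)

from conftest import consensus_sequence
from oracles import naive_log10_pon_extended, naive_log10_pon_standard


class TestConfigurationEnergy:
    def test_consensus_at_optimal_spacer_scores_zero(self, default_model):
        seq = consensus_sequence(default_model)
        e = configuration_energy(seq, "forward", 0,
                                 default_model.optimal_spacer, default_model)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_single_substitution_adds_exactly_the_matrix_entry(
            self, default_model, rng):
        m = default_model
        seq = consensus_sequence(m)
        for _ in range(10):
            p = int(rng.integers(0, m.n_contacts))
            b = int(rng.integers(0, 4))
            # sequence coordinate of contact p at optimal spacer, offset 0
            coord = p if p < m.l35 else m.l35 + m.optimal_spacer + (p - m.l35)
            mutated = seq[:coord] + "ACGT"[b] + seq[coord + 1:]
            e = configuration_energy(mutated, "forward", 0, m.optimal_spacer,
                                     m, include_dinucleotides=False)
            expected = m.contact_matrix()[b, p]
            assert e == pytest.approx(expected, abs=1e-12)

    def test_non_optimal_spacer_matches_hand_summed_oracle(
            self, default_model, random_seq_factory):
        m = default_model
        spacer = m.optimal_spacer + 2
        seq = random_seq_factory(m.width(spacer))
        # hand-summed oracle: walk the sequence position by position
        expected = m.spacer_penalties[spacer]
        for k in range(m.l35):
            expected += m.upstream_block["ACGT".index(seq[k]), k]
        for k in range(m.l10):
            expected += m.downstream_block[
                "ACGT".index(seq[m.l35 + spacer + k]), k]
        for t in m.dinucleotide_terms:
            ci = t.pos_i if t.pos_i < m.l35 else m.l35 + spacer + t.pos_i - m.l35
            cj = t.pos_j if t.pos_j < m.l35 else m.l35 + spacer + t.pos_j - m.l35
            if seq[ci] == t.base_i and seq[cj] == t.base_j:
                expected += t.delta_e
        e = configuration_energy(seq, "forward", 0, spacer, m)
        assert e == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_placement_raises(self, default_model):
        seq = "A" * default_model.min_width
        with pytest.raises(PlacementError):
            configuration_energy(seq, "forward", 5,
                                 default_model.optimal_spacer, default_model)

    def test_ambiguous_base_is_a_hard_error(self, default_model):
        with pytest.raises(InvalidAlphabetError):
            configuration_energy("N" * 40, "forward", 0,
                                 default_model.optimal_spacer, default_model)


class TestEnumeration:
    def test_placement_count_both_strands(self, default_model):
        # L=36, 24 contacts, spacers 7..11: sum_s (36-24-s+1) = 6+5+4+3+2
        # = 20 per strand (verified by brute-force enumeration)
        seq = PromoterSequence("x", "ACGT" * 9)
        cfgs = enumerate_configurations(seq, default_model)
        brute = sum(36 - (24 + s) + 1 for s in default_model.spacer_lengths)
        assert brute == 20
        assert len(cfgs) == 2 * brute
        fwd = [c for c in cfgs if c.strand == "forward"]
        assert len(fwd) == brute
        # each (strand, offset, spacer) exactly once
        keys = {(c.strand, c.offset, c.spacer_length) for c in cfgs}
        assert len(keys) == len(cfgs)

    def test_minimal_width_single_placement_per_strand(self, default_model):
        seq = PromoterSequence("x", "A" * default_model.min_width)
        cfgs = enumerate_configurations(seq, default_model)
        assert len(cfgs) == 2
        assert all(c.spacer_length == min(default_model.spacer_lengths)
                   for c in cfgs)

    def test_below_minimal_width_returns_empty(self, default_model):
        seq = PromoterSequence("x", "A" * (default_model.min_width - 1))
        assert enumerate_configurations(seq, default_model) == []

    def test_energies_match_per_configuration_recomputation(
            self, compact_model, random_seq_factory):
        seq = PromoterSequence("x", random_seq_factory(40))
        for c in enumerate_configurations(seq, compact_model):
            offset = c.offset if c.strand == "forward" \
                else len(seq) - c.offset - compact_model.width(c.spacer_length)
            e = configuration_energy(seq, c.strand, offset, c.spacer_length,
                                     compact_model)
            assert e == pytest.approx(c.energy, abs=1e-12)


class TestClassification:
    def test_cutoff_boundary(self, default_model):
        # -10 end 11 bp upstream of the RBS: occlusive; 12 bp: productive
        ten_end = 50
        rbs_11 = ten_end + 1 + 11
        rbs_12 = ten_end + 1 + 12
        assert classify_configuration("forward", ten_end, rbs_11,
                                      default_model) == "occlusive_unproductive"
        assert classify_configuration("forward", ten_end, rbs_12,
                                      default_model) == "productive"

    def test_reverse_complement_always_unproductive(self, default_model):
        assert classify_configuration("reverse_complement", 10, 50,
                                      default_model) \
            == "reverse_complement_unproductive"

    def test_no_rbs_means_no_occlusion(self, default_model):
        assert classify_configuration("forward", 10, None,
                                      default_model) == "productive"

    def test_site_overlapping_rbs_is_occlusive(self, default_model):
        assert classify_configuration("forward", 30, 20,
                                      default_model) == "occlusive_unproductive"


class TestPonStandard:
    def test_logistic_midpoint_at_mu(self, compact_model):
        import dataclasses
        m = compact_model
        seq = PromoterSequence("x", "A" * m.min_width)
        cfgs = enumerate_configurations(seq, m, include_dinucleotides=False)
        e_fwd = min(c.energy - m.spacer_penalties[c.spacer_length]
                    for c in cfgs if c.strand == "forward")
        tuned = dataclasses.replace(m, mu=e_fwd)
        assert pon_standard(seq, tuned) == pytest.approx(0.5, abs=1e-12)

    def test_only_the_minimum_energy_site_matters(self, default_model,
                                                  random_seq_factory):
        # adding sequence (hence weaker sites) never changes the standard
        # value when the strongest site is preserved
        m = default_model
        seq = consensus_sequence(m)
        padded = seq + random_seq_factory(20)
        v1 = pon_standard(PromoterSequence("a", seq), m, log10=True)
        v2 = pon_standard(PromoterSequence("b", padded), m, log10=True)
        # consensus site has energy 0; padding can only add sites with E >= 0
        assert v2 <= v1 + 1e-12
        assert v2 == pytest.approx(v1, abs=1e-9)

    def test_matches_naive_sliding_oracle(self, default_model,
                                          random_seq_factory):
        for _ in range(25):
            s = random_seq_factory(40)
            got = pon_standard(PromoterSequence("x", s), default_model,
                               log10=True)
            want = naive_log10_pon_standard(s, default_model)
            assert abs(got - want) < 1e-12

    def test_too_short_sequence_raises(self, default_model):
        with pytest.raises(UndefinedOccupancyError):
            pon_standard(PromoterSequence("x", "ACGT"), default_model)


class TestPonExtended:
    def test_single_site_reduces_to_two_state_formula(self):
        # one productive site, nothing else, R = 0
        e, mu = 1.7, -0.4
        got = pon_from_energies(np.array([e]), np.array([]), mu)
        assert got == pytest.approx(1 / (1 + math.exp(e - mu)), rel=1e-12)

    def test_two_identical_sites_hand_formula(self):
        e, mu = 2.0, -1.0
        got = pon_from_energies(np.array([e, e]), np.array([]), mu)
        w = 2 * math.exp(-(e - mu))
        assert got == pytest.approx(w / (1 + w), rel=1e-12)

    def test_r_zero_limit_continuous(self, default_model, random_seq_factory):
        import dataclasses
        seq = PromoterSequence("x", random_seq_factory(50))
        m0 = dataclasses.replace(default_model, clearance_rate=0.0)
        m_eps = dataclasses.replace(default_model, clearance_rate=1e-12)
        a = pon_extended(seq, m0, log10=True)
        b = pon_extended(seq, m_eps, log10=True)
        assert abs(a - b) < 1e-9

    def test_mu_shift_degeneracy_of_clearance_for_single_site(self):
        # with one on-site, P_on(mu, R) = P_on(mu + log(1+R), 0) / (1+R):
        # a constant shift of log10 P_on that the logistic link absorbs,
        # making R a fully degenerate degree of freedom in fits
        R = 0.31
        for e in (-3.0, 1.2, 6.0):
            for mu in (-2.0, 0.5):
                with_r = pon_from_energies(np.array([e]), np.array([]),
                                           mu, R, log10=True)
                shifted = pon_from_energies(np.array([e]), np.array([]),
                                            mu + math.log1p(R), 0.0,
                                            log10=True)
                assert with_r == pytest.approx(
                    shifted - math.log10(1 + R), abs=1e-12)

    def test_empty_configuration_set_gives_zero(self, default_model):
        seq = PromoterSequence("x", "A" * (default_model.min_width - 1))
        assert pon_extended(seq, default_model) == 0.0

    def test_matches_naive_oracle(self, default_model, compact_model,
                                  random_seq_factory):
        for model in (default_model, compact_model):
            for _ in range(20):
                s = random_seq_factory(60)
                seq = PromoterSequence("x", s, rbs_start=55)
                got = pon_extended(seq, model, log10=True)
                want = naive_log10_pon_extended(s, model, rbs_start=55)
                assert abs(got - want) < 1e-9


class TestOccupancyProperties:
    def test_monotone_in_mu(self, default_model, random_seq_factory):
        import dataclasses
        s = PromoterSequence("x", random_seq_factory(60))
        vals = [pon_extended(s, dataclasses.replace(default_model, mu=mu))
                for mu in np.linspace(-10, 5, 12)]
        assert np.all(np.diff(vals) >= -1e-15)
        assert all(0 < v <= 1 for v in vals)

    def test_adding_productive_state_never_decreases(self, rng):
        for _ in range(50):
            on = rng.normal(2, 3, size=rng.integers(1, 6))
            off = rng.normal(2, 3, size=rng.integers(0, 6))
            extra = rng.normal(2, 3)
            base = pon_from_energies(on, off, mu=0.0)
            more = pon_from_energies(np.append(on, extra), off, mu=0.0)
            assert more >= base - 1e-15

    def test_adding_unproductive_state_never_increases(self, rng):
        for _ in range(50):
            on = rng.normal(2, 3, size=rng.integers(1, 6))
            off = rng.normal(2, 3, size=rng.integers(0, 6))
            extra = rng.normal(2, 3)
            base = pon_from_energies(on, off, mu=0.0)
            less = pon_from_energies(on, np.append(off, extra), mu=0.0)
            assert less <= base + 1e-15

    def test_strong_binding_saturates_at_clearance_limit(self):
        # single on-site energy -> -inf with R > 0: P_on -> (1/R)/(1 + 1/R)
        R = 0.31
        val = pon_from_energies(np.array([-200.0]), np.array([]), 0.0, R)
        assert val == pytest.approx((1 / R) / (1 + 1 / R), rel=1e-9)

    def test_reverse_complement_symmetry(self, default_model,
                                         random_seq_factory):
        # the RC of a sequence swaps the productive / RC energy partitions
        s = random_seq_factory(55)
        fwd = enumerate_configurations(PromoterSequence("a", s), default_model)
        rev = enumerate_configurations(
            PromoterSequence("b", reverse_complement(s)), default_model)
        e_fwd_on = sorted(c.energy for c in fwd if c.strand == "forward")
        e_rev_rc = sorted(c.energy for c in rev
                          if c.strand == "reverse_complement")
        assert np.allclose(e_fwd_on, e_rev_rc)


def test_find_rbs_locates_shine_dalgarno():
    assert find_rbs("TTTAGGAGCCC") == 3
    assert find_rbs("TTTTTT") is None
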