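"""Unit tests for genome scanning, region partition and depletion tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promotherm.genome import (
    cumulative_site_counts,
    depletion_test_gc_null,
    depletion_test_shuffled,
    energy_track,
    partition_regions,
    promoter_free_energy,
    random_genome,
    shuffle_matrix_columns,
)
from promotherm.model import PromoterSequence, configuration_energy

from conftest import consensus_sequence


class TestEnergyTrack:
    def test_homopolymer_track_is_constant_zero(self, compact_model):
        track = energy_track("A" * 200, compact_model)
        assert np.allclose(track.free_energy, 0.0)
        assert len(track) == 200 - compact_model.max_width + 1

    def test_minimum_at_planted_consensus_site(self, default_model, rng):
        site = consensus_sequence(default_model)
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        insert_at = 150
        genome = background[:insert_at] + site + background[insert_at:]
        track = energy_track(genome, default_model)
        ten_end = insert_at + len(site) - 1   # site ends with the -10 block
        best = track.positions[np.argmin(track.free_energy)]
        assert best == ten_end

    def test_matches_per_position_oracle(self, compact_model, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        track = energy_track(genome, compact_model)
        m = compact_model
        check = rng.choice(len(track), 40, replace=False)
        for k in check:
            p = track.positions[k]
            vals = []
            for s in m.spacer_lengths:
                o = p - (m.width(s) - 1)
                if o < 0:
                    continue
                vals.append(configuration_energy(genome, "forward", o, s, m))
            want = -np.log(np.sum(np.exp(-np.array(vals))))
            assert track.raw_free_energy[k] == pytest.approx(want, abs=1e-9)

    def test_minimum_is_offset_to_zero(self, compact_model, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        track = energy_track(genome, compact_model)
        assert track.free_energy.min() == pytest.approx(0.0, abs=1e-12)

    def test_too_short_genome_raises(self, compact_model):
        with pytest.raises(ValueError):
            energy_track("ACGT", compact_model)

    def test_circular_mode_covers_every_position(self, compact_model, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        track = energy_track(genome, compact_model, circular=True)
        assert len(track) == 300


class TestPartition:
    def test_half_genome_gene(self):
        feats = pd.DataFrame([{"type": "gene", "start": 0, "end": 500}])
        part = partition_regions(feats, "A" * 1000)
        assert part.within_fraction == pytest.approx(0.5)
        assert part.intergenic_fraction == pytest.approx(0.5)

    def test_trna_excluded_from_intergenic_but_not_genic(self):
        feats = pd.DataFrame([{"type": "tRNA", "start": 100, "end": 200}])
        part = partition_regions(feats, "A" * 1000)
        assert not part.within_genes[100:200].any()
        assert not part.intergenic[100:200].any()
        assert part.intergenic[:100].all()

    def test_empty_annotation_all_intergenic(self):
        part = partition_regions(pd.DataFrame(columns=["type", "start", "end"]),
                                 "ACGT" * 100)
        assert part.intergenic.all()
        assert part.within_fraction == 0.0

    def test_gc_summaries(self):
        feats = pd.DataFrame([{"type": "CDS", "start": 0, "end": 4}])
        part = partition_regions(feats, "GGCC" + "AATT")
        assert part.within_gc == pytest.approx(1.0)
        assert part.intergenic_gc == pytest.approx(0.0)


class TestDepletionGCNull:
    def test_zero_expected_zero_observed_gives_p_one(self):
        assert stats.poisson.cdf(0, 0) == 1.0

    def test_planted_depletion_detected(self, compact_model, rng):
        # a region scrubbed of strong sites must show tiny p-values in the
        # low-energy bins
        syn = random_genome(300_000, 0.5, rng)
        track = energy_track(syn, compact_model)
        cutoff = np.quantile(track.raw_free_energy, 0.02)
        keep = track.raw_free_energy >= cutoff
        depleted_vals = track.raw_free_energy[keep]
        edges = np.quantile(track.raw_free_energy, [0.005, 0.01, 0.5, 0.9])
        out = depletion_test_gc_null(depleted_vals, 0.5, compact_model,
                                     synthetic_length=300_000, edges=edges,
                                     seed=1)
        assert (out["p_value"].iloc[:2] < 1e-4).all()
        assert out["p_value"].iloc[3] > 0.01

    def test_empty_region_is_an_error(self, compact_model):
        with pytest.raises(ValueError):
            depletion_test_gc_null(np.array([]), 0.5, compact_model,
                                   1000, np.array([1.0]))


class TestDepletionShuffled:
    def test_identity_permutation_reproduces_real_histogram(
            self, compact_model, rng):
        genome = random_genome(20_000, 0.5, rng)
        real = energy_track(genome, compact_model,
                            include_dinucleotides=False)
        class _IdentityRng:
            def permutation(self, n):
                return np.arange(n)
        shuf = shuffle_matrix_columns(compact_model, _IdentityRng())
        t = energy_track(genome, shuf, include_dinucleotides=False)
        assert np.allclose(t.raw_free_energy, real.raw_free_energy)

    def test_column_constant_matrix_has_zero_shuffle_variance(self, rng):
        from promotherm.model import EnergyModel
        col = np.array([0.0, 1.0, 2.0, 3.0])
        m = EnergyModel(upstream_block=np.tile(col[:, None], (1, 4)),
                        downstream_block=np.tile(col[:, None], (1, 4)),
                        spacer_penalties={3: 0.0}, mu=0.0)
        genome = random_genome(5_000, 0.5, rng)
        edges = np.array([2.0, 5.0, 9.0])
        out = depletion_test_shuffled(genome, m, edges, n_shuffles=5, seed=0)
        assert (out["null_sd"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()

    def test_shuffle_preserves_column_multiset(self, compact_model, rng):
        shuf = shuffle_matrix_columns(compact_model, rng)
        a = sorted(map(tuple, compact_model.contact_matrix().T.tolist()))
        b = sorted(map(tuple, shuf.contact_matrix().T.tolist()))
        assert a == b


class TestPromoterFreeEnergy:
    def test_single_strong_site_dominates_window(self, default_model, rng):
        site = consensus_sequence(default_model)
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        genome = background[:150] + site + background[150:]
        track = energy_track(genome, default_model)
        anchor = 150 + len(site) - 1
        out = promoter_free_energy(track, np.array([anchor]), window=40)
        site_f = track.raw_free_energy[track.positions == anchor][0]
        assert out["free_energy"].iloc[0] <= site_f
        assert out["free_energy"].iloc[0] == pytest.approx(site_f, abs=0.5)

    def test_disjoint_windows_on_homopolymer_identical(self, compact_model):
        track = energy_track("A" * 400, compact_model)
        out = promoter_free_energy(track, np.array([100, 300]), window=40)
        assert out["free_energy"].iloc[0] == pytest.approx(
            out["free_energy"].iloc[1], abs=1e-9)

    def test_matches_direct_window_sum(self, compact_model, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        track = energy_track(genome, compact_model)
        anchor = 250
        out = promoter_free_energy(track, np.array([anchor]), window=40)
        sel = (track.positions >= anchor - 20) & (track.positions <= anchor + 20)
        want = -np.log(np.exp(-track.raw_free_energy[sel]).sum())
        assert out["free_energy"].iloc[0] == pytest.approx(want, abs=1e-9)

    def test_truncated_window_is_flagged(self, compact_model):
        track = energy_track("ACGT" * 50, compact_model)
        out = promoter_free_energy(track, np.array([5]), window=40)
        assert out["truncated"].iloc[0]


def test_cumulative_counts_monotone(rng):
    vals = rng.normal(size=1000)
    edges = np.array([-1.0, 0.0, 1.0])
    counts = cumulative_site_counts(vals, edges)
    assert (np.diff(counts) >= 0).all()
    assert counts[1] == (vals <= 0).sum()
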