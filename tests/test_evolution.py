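"""Unit tests for SSWM evolution and the Kimura fixation probability."""

import dataclasses
import math

import numpy as np
import pytest

from promotherm.batch import PhenotypeEvaluator
from promotherm.evolution import (
    EvolutionSpec,
    batch_evolve,
    compare_models,
    evolve,
    kimura_fixation,
    random_start_sequences,
)
from promotherm.model import EnergyModel, seq_to_indices
from promotherm.synthetic import make_truth_model


class TestKimura:
    def test_neutral_limit_is_inverse_2n(self):
        for n in (1, 10, 1000):
            assert kimura_fixation(0.0, 100.0, n) == pytest.approx(1 / (2 * n))
            assert kimura_fixation(1e-14, 100.0, n) == pytest.approx(
                1 / (2 * n), rel=1e-6)

    def test_population_of_one_reduces_to_logistic(self):
        # (1-e^{-2x})/(1-e^{-4x}) = 1/(1+e^{-2x})
        for sd in (-1.5, -0.1, 0.2, 2.0):
            got = kimura_fixation(sd, 1.0, 1)
            assert got == pytest.approx(1 / (1 + math.exp(-2 * sd)), rel=1e-9)

    def test_deleterious_fixes_less_often_than_neutral(self):
        assert kimura_fixation(-0.01, 100.0, 100) < 1 / 200

    def test_beneficial_fixes_more_often_than_neutral(self):
        assert kimura_fixation(0.01, 100.0, 100) > 1 / 200

    def test_extreme_effects_do_not_overflow(self):
        assert kimura_fixation(-50.0, 100.0, 1000) == 0.0
        assert kimura_fixation(50.0, 100.0, 1000) == pytest.approx(1.0)

    def test_vectorized_matches_scalar(self):
        d = np.array([-0.5, 0.0, 0.3])
        v = kimura_fixation(d, 10.0, 50)
        assert np.allclose(v, [kimura_fixation(x, 10.0, 50) for x in d])


def _toy_single_site_model():
    """One contact per block, one spacer: a 3-bp binding site."""
    up = np.array([[0.0], [2.0], [2.0], [2.0]])
    down = np.array([[0.0], [3.0], [3.0], [3.0]])
    return EnergyModel(upstream_block=up, downstream_block=down,
                       spacer_penalties={1: 0.0}, mu=0.0)


class TestEvolve:
    def test_threshold_below_start_exits_immediately(self):
        model = _toy_single_site_model()
        spec = EvolutionSpec(model, mode="standard", threshold=-10.0,
                             length=3, n_pop=10)
        run = evolve(spec, "AAA", seed=0)
        assert run.exit_time == 0 and not run.censored

    def test_empty_mutable_region_censors_at_cap(self):
        model = _toy_single_site_model()
        spec = EvolutionSpec(model, mode="standard", threshold=-0.01,
                             length=3, mutable_length=0, n_pop=5)
        run = evolve(spec, "CCC", seed=0)
        assert run.censored and run.exit_time == spec.max_steps

    def test_trajectory_is_consistent_with_mutation_list(self):
        model = make_truth_model(3, mu=-4.0)
        spec = EvolutionSpec(model, mode="extended", threshold=-3.0,
                             length=60, n_pop=50, s=100.0)
        start = "ACGT" * 15
        run = evolve(spec, start, seed=1)
        ev = PhenotypeEvaluator(model, 60, "extended")
        assert ev.phi(seq_to_indices(run.final_sequence)) == pytest.approx(
            run.final_phi, abs=1e-9)

    def test_neutral_landscape_fixation_rate(self):
        # on a flat landscape every proposal is neutral: the empirical
        # fixation fraction must match 1/(2N)
        up = np.zeros((4, 1))
        down = np.zeros((4, 1))
        model = EnergyModel(upstream_block=up, downstream_block=down,
                            spacer_penalties={1: 0.0}, mu=0.0)
        n_pop = 20
        spec = EvolutionSpec(model, mode="standard", threshold=1.0,
                             length=10, n_pop=n_pop, max_steps=4000)
        run = evolve(spec, "A" * 10, seed=3)
        n_fixed = len(run.mutations)
        p = 1 / (2 * n_pop)
        se = math.sqrt(spec.max_steps * p * (1 - p))
        assert abs(n_fixed - spec.max_steps * p) < 3 * se

    def test_exit_time_matches_absorbing_chain_oracle(self):
        # exact expected absorption time of the SSWM chain on the full
        # 4^3-state toy landscape vs the Monte-Carlo mean
        model = _toy_single_site_model()
        s, n_pop = 30.0, 40
        ev = PhenotypeEvaluator(model, 3, "standard")
        phi = {i: ev.phi(np.array(list(np.base_repr(i, 4).zfill(3)),
                                  dtype=np.int8)) for i in range(64)}
        thresh = -0.31   # only the consensus site (phi = log10 0.5) absorbs
        absorbing = {i for i in range(64) if phi[i] >= thresh}
        # transition matrix over transient states
        transient = [i for i in range(64) if i not in absorbing]
        t_index = {i: k for k, i in enumerate(transient)}
        Q = np.zeros((len(transient), len(transient)))
        r_self = np.zeros(len(transient))
        for i in transient:
            digits = [(i // 4 ** (2 - p)) % 4 for p in range(3)]
            stay = 1.0
            for pos in range(3):
                for shift in (1, 2, 3):
                    j_digits = digits.copy()
                    j_digits[pos] = (j_digits[pos] + shift) % 4
                    j = j_digits[0] * 16 + j_digits[1] * 4 + j_digits[2]
                    p_fix = kimura_fixation(phi[j] - phi[i], s, n_pop) / 9
                    stay -= p_fix
                    if j not in absorbing:
                        Q[t_index[i], t_index[j]] += p_fix
            Q[t_index[i], t_index[i]] += stay
        expected_steps = np.linalg.solve(np.eye(len(transient)) - Q,
                                         np.ones(len(transient)))
        start = "CCC"
        start_i = 1 * 16 + 1 * 4 + 1
        want = expected_steps[t_index[start_i]]
        spec = EvolutionSpec(model, mode="standard", threshold=thresh,
                             length=3, n_pop=n_pop, s=s,
                             max_steps=100_000)
        rng = np.random.default_rng(10)
        times = [evolve(spec, start, int(rng.integers(2**31)), evaluator=ev)
                 .exit_time for _ in range(300)]
        got = np.mean(times)
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(got - want) < 4 * se

    def test_stochastically_faster_with_stronger_selection(self):
        model = _toy_single_site_model()
        start = "CCC"
        times = {}
        # weak enough that beneficial fixation is well below certainty
        for s in (0.3, 5.0):
            spec = EvolutionSpec(model, mode="standard", threshold=-0.31,
                                 length=3, n_pop=50, s=s, max_steps=50_000)
            rng = np.random.default_rng(4)
            times[s] = np.mean([
                evolve(spec, start, int(rng.integers(2**31))).exit_time
                for _ in range(60)])
        assert times[5.0] < times[0.3]


@pytest.fixture(scope="module")
def batch_model():
    return make_truth_model(6, mu=-4.5)


class TestBatchEvolve:
    @pytest.fixture
    def model(self, batch_model):
        return batch_model

    def test_identical_seeds_identical_tables(self, model):
        spec = EvolutionSpec(model, mode="extended", threshold=-3.5,
                             length=50, n_pop=30, max_steps=200)
        starts = random_start_sequences(3, 50, seed=0, below=-3.5,
                                        models=[(model, "extended")])
        a = batch_evolve(spec, starts, runs_per_start=4, seed=5)
        b = batch_evolve(spec, starts, runs_per_start=4, seed=5)
        assert a.equals(b)

    def test_censoring_fraction_reported(self, model):
        spec = EvolutionSpec(model, mode="standard", threshold=-0.5,
                             length=50, n_pop=20, max_steps=50)
        starts = random_start_sequences(2, 50, seed=1, below=-4.0,
                                        models=[(model, "standard")])
        table = batch_evolve(spec, starts, runs_per_start=5, seed=6)
        assert (table["censored_fraction"] == 1.0).all()

    def test_compare_models_reports_speedup_columns(self, model):
        kw = dict(threshold=-4.0, length=50, n_pop=20, max_steps=150)
        spec_e = EvolutionSpec(model, mode="extended", **kw)
        spec_s = EvolutionSpec(model, mode="standard", **kw)
        starts = random_start_sequences(
            3, 50, seed=2, below=-4.0,
            models=[(model, "extended"), (model, "standard")])
        out = compare_models(spec_e, spec_s, starts, runs_per_start=3, seed=7)
        assert {"extended_mean", "standard_mean", "speedup"} <= set(out.columns)
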