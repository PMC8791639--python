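"""Surveys of the random-sequence genotype space.

Given a fitted model and a measurable-expression cutoff (in log10 P_on),
these routines estimate how much of sequence space expresses: the
fraction of random sequences above the cutoff, the fraction of
non-expressing sequences rescued by their best single point mutation, and
the fraction of all point mutations that rescue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batch import PhenotypeEvaluator
from .model import EnergyModel


@dataclass
class SurveyResult:
    expressing_fraction: float
    n_sequences: int
    rescued_fraction: float | None = None
    rescuing_mutation_fraction: float | None = None
    n_non_expressing: int | None = None


def expressing_fraction(model: EnergyModel, cutoff: float, n: int,
                        length: int = 115, mode: str = "extended",
                        seed: int = 0, batch: int = 20_000) -> SurveyResult:
    """Fraction of uniform random sequences with phi >= cutoff."""
    rng = np.random.default_rng(seed)
    ev = PhenotypeEvaluator(model, length, mode)
    hits = 0
    done = 0
    while done < n:
        m = min(batch, n - done)
        bases = rng.integers(0, 4, size=(m, length), dtype=np.int8)
        hits += int((ev.phi_batch(bases) >= cutoff).sum())
        done += m
    return SurveyResult(expressing_fraction=hits / n, n_sequences=n)


def rescue_statistics(model: EnergyModel, cutoff: float, n: int,
                      length: int = 115, mode: str = "extended",
                      seed: int = 0) -> SurveyResult:
    """Single-point-mutation rescue of non-expressing random sequences.

    For each random sequence below the cutoff, evaluates all 3*length
    point mutants; reports the fraction of such sequences with at least
    one rescuing mutation and the overall fraction of point mutations
    that rescue.
    """
    rng = np.random.default_rng(seed)
    ev = PhenotypeEvaluator(model, length, mode)
    n_non = 0
    n_rescued = 0
    n_mut_total = 0
    n_mut_rescue = 0
    n_seen = 0
    # all single mutants of one sequence evaluated as one batch
    while n_non < n:
        n_seen += 1
        base = rng.integers(0, 4, size=length, dtype=np.int8)
        if ev.phi(base) >= cutoff:
            continue
        n_non += 1
        mutants = np.tile(base, (3 * length, 1))
        k = 0
        for pos in range(length):
            for shift in (1, 2, 3):
                mutants[k, pos] = (base[pos] + shift) % 4
                k += 1
        phis = ev.phi_batch(mutants)
        rescues = int((phis >= cutoff).sum())
        n_mut_total += mutants.shape[0]
        n_mut_rescue += rescues
        n_rescued += rescues > 0
    return SurveyResult(
        expressing_fraction=1.0 - n_non / max(n_seen, 1),
        n_sequences=n_seen,
        rescued_fraction=n_rescued / n_non,
        rescuing_mutation_fraction=n_mut_rescue / n_mut_total,
        n_non_expressing=n_non)
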