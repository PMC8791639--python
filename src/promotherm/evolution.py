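"""Promoter evolution under strong-selection-weak-mutation (SSWM).

One mutation at a time appears at a uniformly random position of the
mutable region, changing the phenotype phi = log10 P_on by delta-phi, and
fixes in a population of size N with the Kimura probability

    P_fix = (1 - exp(-2 s dphi)) / (1 - exp(-4 N s dphi)),

where s is the selection strength on the phenotype (only the product
s * dphi -- the selection coefficient -- matters).  Time is counted in
units of inverse mutation rate: one proposed mutation per step.  A run
ends when phi reaches the target threshold or, censored, after a cap of
10 N steps.  Because truncation removes more of the slow runs, censored
comparisons between models are conservative: reported speed-ups of a
faster model are lower bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .batch import PhenotypeEvaluator
from .model import BASES, EnergyModel, seq_to_indices, indices_to_seq


def kimura_fixation(dphi, s: float, n_pop: int):
    """Kimura fixation probability for a phenotypic effect ``dphi``.

    Vectorized over ``dphi``.  The neutral limit (dphi -> 0) is 1/(2N);
    extreme selection coefficients are handled in log space so the result
    never overflows.
    """
    if n_pop < 1:
        raise ValueError("population size must be >= 1")
    d = np.asarray(dphi, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.empty_like(d)
    a = -2.0 * s * d          # numerator exponent
    b = -4.0 * n_pop * s * d  # denominator exponent
    near0 = np.abs(a) < 1e-9
    out[near0] = 1.0 / (2.0 * n_pop)
    rest = ~near0
    ar, br = a[rest], b[rest]
    with np.errstate(over="ignore"):
        num = -np.expm1(ar)
        den = -np.expm1(br)
    safe = np.isfinite(num) & np.isfinite(den) & (den != 0)
    r = np.empty_like(ar)
    r[safe] = num[safe] / den[safe]
    # strongly deleterious: both exponentials overflow; use the log ratio
    big = ~safe
    r[big] = np.exp(np.minimum(ar[big] - br[big], 0.0))
    out[rest] = np.clip(r, 0.0, 1.0)
    return float(out[0]) if scalar else out


@dataclass
class EvolutionSpec:
    """Configuration of one SSWM simulation.

    ``threshold`` is the target phenotype phi* in log10 P_on units (see
    :meth:`promotherm.fitting.LogisticLink.crossing_point` for deriving a
    measurable-expression cutoff from a fitted link).  The mutable region
    is the centered contiguous stretch of ``mutable_length`` bp inside the
    full ``length``-bp sequence; phenotypes always integrate over the full
    sequence.
    """

    model: EnergyModel
    mode: str = "extended"
    s: float = 100.0
    n_pop: int = 1000
    threshold: float = -4.0
    length: int = 115
    mutable_length: int | None = None
    max_steps: int | None = None       # default 10 * n_pop
    rbs_start: int | None = None

    def __post_init__(self) -> None:
        if self.n_pop < 1:
            raise ValueError("n_pop must be >= 1")
        if self.mutable_length is None:
            self.mutable_length = self.length
        if not 0 <= self.mutable_length <= self.length:
            raise ValueError("mutable region must fit inside the sequence")
        if self.max_steps is None:
            self.max_steps = 10 * self.n_pop

    @property
    def mutable_slice(self) -> slice:
        start = (self.length - self.mutable_length) // 2
        return slice(start, start + self.mutable_length)


@dataclass
class FixedMutation:
    position: int
    from_base: str
    to_base: str
    dphi: float
    step: int


@dataclass
class EvolutionRun:
    """Trajectory of one SSWM run: fixed mutations and the exit time."""

    start_sequence: str
    mutations: list[FixedMutation]
    exit_time: int
    censored: bool
    final_phi: float
    start_phi: float

    @property
    def final_sequence(self) -> str:
        idx = seq_to_indices(self.start_sequence)
        for m in self.mutations:
            idx[m.position] = BASES.index(m.to_base)
        return indices_to_seq(idx)


def evolve(spec: EvolutionSpec, start: str, seed: int,
           evaluator: PhenotypeEvaluator | None = None) -> EvolutionRun:
    """Run SSWM from one starting sequence until the threshold or the cap.

    Each step proposes a uniform random position in the mutable region and
    a uniform random alternative base (back-mutations allowed); the
    proposal fixes with the Kimura probability of its phenotypic effect.
    The step counter advances once per proposal, so exit times are in
    units of inverse mutation rate.
    """
    if len(start) != spec.length:
        raise ValueError(f"start sequence must have length {spec.length}")
    rng = np.random.default_rng(seed)
    if evaluator is None:
        evaluator = PhenotypeEvaluator(spec.model, spec.length, spec.mode,
                                       rbs_start=spec.rbs_start)
    idx = seq_to_indices(start).copy()
    phi = evaluator.phi(idx)
    start_phi = phi
    mutations: list[FixedMutation] = []
    if phi >= spec.threshold:
        return EvolutionRun(start, [], 0, False, phi, start_phi)
    sl = spec.mutable_slice
    if sl.stop - sl.start == 0:
        return EvolutionRun(start, [], spec.max_steps, True, phi, start_phi)
    positions = rng.integers(sl.start, sl.stop, size=spec.max_steps)
    base_shift = rng.integers(1, 4, size=spec.max_steps, dtype=np.int8)
    accept_u = rng.random(size=spec.max_steps)
    for step in range(spec.max_steps):
        pos = int(positions[step])
        old = idx[pos]
        new = (old + base_shift[step]) % 4
        idx[pos] = new
        phi_new = evaluator.phi(idx)
        p_fix = kimura_fixation(phi_new - phi, spec.s, spec.n_pop)
        if accept_u[step] < p_fix:
            mutations.append(FixedMutation(pos, BASES[old], BASES[new],
                                           phi_new - phi, step + 1))
            phi = phi_new
            if phi >= spec.threshold:
                return EvolutionRun(start, mutations, step + 1, False,
                                    phi, start_phi)
        else:
            idx[pos] = old
    return EvolutionRun(start, mutations, spec.max_steps, True, phi, start_phi)


def random_start_sequences(n: int, length: int, seed: int,
                           below: float | None = None,
                           models: list[tuple[EnergyModel, str]] | None = None,
                           max_tries: int = 10_000) -> list[str]:
    """Random sequences, optionally conditioned on low predicted expression.

    When ``below`` and ``models`` are given, only sequences whose phi is
    below the cutoff under *every* listed (model, mode) pair are returned
    -- the non-expressing starting pool for comparative evolution runs.
    """
    rng = np.random.default_rng(seed)
    evaluators = []
    if models is not None and below is not None:
        evaluators = [PhenotypeEvaluator(m, length, mode)
                      for m, mode in models]
    out: list[str] = []
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        idx = rng.integers(0, 4, size=length, dtype=np.int8)
        if all(ev.phi(idx) < below for ev in evaluators) if evaluators else True:
            out.append(indices_to_seq(idx))
    if len(out) < n:
        raise RuntimeError("could not find enough sub-threshold start sequences")
    return out


def batch_evolve(spec: EvolutionSpec, starts: list[str], runs_per_start: int,
                 seed: int) -> pd.DataFrame:
    """Replicated SSWM runs for each start; per-start exit-time summaries.

    Returns one row per start with the mean exit time, its standard error
    over replicates, and the censoring fraction.  Exit times of censored
    runs enter at the cap, so means are conservative (biased low) for slow
    landscapes.
    """
    rng = np.random.default_rng(seed)
    evaluator = PhenotypeEvaluator(spec.model, spec.length, spec.mode,
                                   rbs_start=spec.rbs_start)
    rows = []
    for i, start in enumerate(starts):
        times = np.empty(runs_per_start)
        censored = 0
        for r in range(runs_per_start):
            run = evolve(spec, start, int(rng.integers(2**31)),
                         evaluator=evaluator)
            times[r] = run.exit_time
            censored += run.censored
        rows.append({
            "start": i, "mean_exit_time": times.mean(),
            "sem_exit_time": times.std(ddof=1) / np.sqrt(runs_per_start)
            if runs_per_start > 1 else np.nan,
            "censored_fraction": censored / runs_per_start,
        })
    return pd.DataFrame(rows)


def compare_models(spec_ext: EvolutionSpec, spec_std: EvolutionSpec,
                   starts: list[str], runs_per_start: int, seed: int,
                   ) -> pd.DataFrame:
    """Extended-vs-Standard exit times on identical starts.

    Adds the per-start ratio of Standard to Extended mean exit time (> 1
    means the Extended model predicts faster adaptation).
    """
    ext = batch_evolve(spec_ext, starts, runs_per_start, seed)
    std = batch_evolve(spec_std, starts, runs_per_start, seed + 1)
    out = ext.rename(columns={
        "mean_exit_time": "extended_mean", "sem_exit_time": "extended_sem",
        "censored_fraction": "extended_censored"})
    out["standard_mean"] = std["mean_exit_time"]
    out["standard_sem"] = std["sem_exit_time"]
    out["standard_censored"] = std["censored_fraction"]
    out["speedup"] = out["standard_mean"] / out["extended_mean"]
    return out
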