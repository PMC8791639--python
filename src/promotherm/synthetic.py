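"""Synthetic mutant libraries and simulated sort-seq observations.

This module generates data with the statistical structure the fitting and
processing pipelines assume, so that the whole package is testable without
any experimental download:

* local-mutant libraries around a wildtype promoter (P_R-like: 12% total
  mutation rate per position, i.e. 4% per alternative base; P_L-like: 9%);
* fully-random core libraries (36N-like: 36 uniformly random positions
  between fixed flanks);
* sort-seq observations of such libraries under a ground-truth
  :class:`~promotherm.model.EnergyModel`: per-cell phenotypes
  ``log10 P_on`` plus Gaussian measurement noise are gated into 4 or 12
  fluorescence bins, read counts are multinomially downsampled to a target
  sequencing depth, and -- in 12-bin mode -- per-bin sequential-sorting
  bias factors are applied and a spike-in reference record is added, which
  is exactly what the 12-bin debiasing step is designed to undo.

The generator is also the ground-truth oracle for parameter-recovery
tests: libraries produced here, simulated and processed, must lead a fit
back to the model that generated them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batch import ConfigTable, FeatureFlags, encode_sequences
from .model import BASES, DinucleotideTerm, EnergyModel, PromoterSequence
from .sortseq import SortSeqLibrary


@dataclass
class LibrarySpec:
    """What kind of mutant library to draw.

    ``local`` mode mutates a wildtype: each position independently carries
    ``mutation_rate`` total probability of being non-wildtype, split
    equally over the three alternatives.  ``random`` mode draws a core of
    ``random_length`` uniform positions between fixed flanks.
    """

    mode: str = "local"
    wildtype: str | None = None
    mutation_rate: float = 0.12
    random_length: int = 36
    upstream_flank: str = ""
    downstream_flank: str = ""
    size: int = 10_000
    rbs_start: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("local", "random"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        if self.mode == "local" and not self.wildtype:
            raise ValueError("local mode requires a wildtype sequence")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


def generate_library(spec: LibrarySpec, seed: int,
                     ) -> tuple[list[PromoterSequence], np.ndarray]:
    """Draw i.i.d. sequences; duplicates collapsed with multiplicity.

    Returns (unique sequence records, multiplicities).  Records carry the
    spec's RBS annotation.
    """
    rng = np.random.default_rng(seed)
    if spec.mode == "local":
        wt = np.array([BASES.index(b) for b in spec.wildtype.upper()],
                      dtype=np.int8)
        L = wt.size
        draws = np.tile(wt, (spec.size, 1))
        mutate = rng.random((spec.size, L)) < spec.mutation_rate
        # equal chance for each of the three non-wildtype bases
        shift = rng.integers(1, 4, size=(spec.size, L), dtype=np.int8)
        draws[mutate] = (draws[mutate] + shift[mutate]) % 4
        cores = draws
    else:
        cores = rng.integers(0, 4, size=(spec.size, spec.random_length),
                             dtype=np.int8)
    strings = ["".join(BASES[i] for i in row) for row in cores]
    strings = [spec.upstream_flank + s + spec.downstream_flank for s in strings]
    uniq: dict[str, int] = {}
    for s in strings:
        uniq[s] = uniq.get(s, 0) + 1
    records = [PromoterSequence(identifier=f"syn{i:06d}", bases=s,
                                rbs_start=spec.rbs_start)
               for i, s in enumerate(uniq)]
    return records, np.array(list(uniq.values()))


@dataclass
class SortSimSpec:
    """Parameters of a simulated sort-seq experiment.

    ``gates`` are the B-1 interior gate boundaries in log10 P_on units
    (strictly increasing); a phenotype below the first boundary falls in
    bin 0.  ``bias_factors`` model the sequential-sorting read-rate bias
    of 12-bin experiments (ignored in 4-bin mode when left at None).
    ``noise_sd`` is the cell-to-cell measurement noise in log10 P_on.
    """

    model: EnergyModel
    gates: np.ndarray
    cells_per_sequence: int = 100
    noise_sd: float = 0.15
    depth: int = 100
    bias_factors: np.ndarray | None = None
    spike_in_cells: int = 1000
    mode: str = "extended"

    def __post_init__(self) -> None:
        self.gates = np.asarray(self.gates, dtype=float)
        if not np.all(np.diff(self.gates) > 0):
            raise ValueError("gates must be strictly increasing")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def n_bins(self) -> int:
        return self.gates.size + 1


def gates_from_phenotypes(phi: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-based gate boundaries covering a phenotype distribution."""
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    return np.quantile(np.asarray(phi, dtype=float), qs)


def true_phenotypes(seqs: list[PromoterSequence], model: EnergyModel,
                    mode: str = "extended") -> np.ndarray:
    """Ground-truth log10 P_on for an equal-length library."""
    bases = encode_sequences([s.bases for s in seqs])
    rbs = seqs[0].rbs_start
    if any(s.rbs_start != rbs for s in seqs):
        raise ValueError("library must share a single RBS annotation")
    table = ConfigTable(bases.shape[1], model, rbs_start=rbs)
    flags = (FeatureFlags.extended() if mode == "extended"
             else FeatureFlags.standard())
    return table.log10_pon_library(bases, model, flags)


def simulate_sortseq(seqs: list[PromoterSequence], sim: SortSimSpec,
                     seed: int, multiplicity: np.ndarray | None = None,
                     reference: PromoterSequence | None = None,
                     ) -> tuple[SortSeqLibrary, np.ndarray]:
    """Simulate sorting + sequencing of a library under a truth model.

    Each sequence contributes ``cells_per_sequence`` (scaled by its
    multiplicity) cells; each cell's noisy phenotype is gated into a bin.
    Reads are then multinomially sampled with expected per-sequence depth
    ``sim.depth``; in biased mode each bin's sampling rate is multiplied
    by its bias factor.  When a reference record is given (12-bin mode),
    ``spike_in_cells`` reference cells are added to *every* bin before
    sequencing, mimicking the spike-in used to undo the bias.

    Returns the raw count library and the vector of true phenotypes.
    """
    rng = np.random.default_rng(seed)
    phi = true_phenotypes(seqs, sim.model, sim.mode)
    n = len(seqs)
    B = sim.n_bins
    mult = np.ones(n) if multiplicity is None else np.asarray(multiplicity)

    # cell-level gating: cells ~ Multinomial(gate probabilities under noise)
    cells = np.zeros((n, B))
    for i in range(n):
        n_cells = int(round(sim.cells_per_sequence * mult[i]))
        if sim.noise_sd == 0:
            b = int(np.searchsorted(sim.gates, phi[i], side="right"))
            cells[i, b] = n_cells
        else:
            from scipy.stats import norm
            cdf = norm.cdf(sim.gates, loc=phi[i], scale=sim.noise_sd)
            p = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
            cells[i] = rng.multinomial(n_cells, p)

    bias = (np.ones(B) if sim.bias_factors is None
            else np.asarray(sim.bias_factors, dtype=float))
    ref_counts = None
    if reference is not None:
        ref_phi = true_phenotypes([reference], sim.model, sim.mode)[0]
        ref_cells = np.full(B, float(sim.spike_in_cells))
        lam_ref = ref_cells * bias * (sim.depth / sim.cells_per_sequence)
        ref_counts = rng.poisson(lam_ref)

    # sequencing: expected reads proportional to cells * per-bin bias
    lam = cells * bias[None, :] * (sim.depth / sim.cells_per_sequence)
    counts = rng.poisson(lam)

    lib = SortSeqLibrary(
        sequences=[s.bases for s in seqs],
        counts=counts,
        reference=(reference.bases, ref_counts) if reference is not None else None,
    )
    return lib, phi


# ---------------------------------------------------------------------------
# ground-truth model factories (fixture bundles for tests and experiments)


def consensus_matrix(rng: np.random.Generator, length: int,
                     consensus: str, core_scale: float = 2.5,
                     flank_scale: float = 0.8) -> np.ndarray:
    """A 4 x length penalty block with consensus structure.

    The consensus residue of each column costs 0; other residues cost a
    positive penalty drawn around ``core_scale`` at consensus (hexamer)
    positions and around ``flank_scale`` elsewhere.  Columns whose
    consensus character is '.' are flank positions.
    """
    mat = np.zeros((4, length))
    for j, c in enumerate(consensus):
        scale = flank_scale if c == "." else core_scale
        pen = np.abs(rng.normal(scale, scale / 3, size=4))
        if c == ".":
            best = rng.integers(0, 4)
        else:
            best = BASES.index(c)
        pen[best] = 0.0
        mat[:, j] = pen
    return mat


def make_truth_model(seed: int, l35: int = 12, l10: int = 12,
                     optimal_spacer: int = 9, spacer_flex: int = 2,
                     quadratic_pen: float = 0.9, mu: float = -5.0,
                     clearance_rate: float = 0.0,
                     n_dinucleotides: int = 0,
                     dinuc_magnitude: float = 0.3,
                     dinuc_positions: list[tuple[int, int]] | None = None,
                     wildtype_core: str | None = None,
                     rbs_occlusion_cutoff: int = 11) -> EnergyModel:
    """A random ground-truth model with sigma70-like structure.

    The upstream block centres the TTGACA consensus and the downstream
    block the TATAAT consensus, with random flank penalties; spacer
    penalties are quadratic around the optimum.  Optional planted
    dinucleotide interactions get random signs and magnitude
    ``dinuc_magnitude``; when ``wildtype_core`` is given, planted
    interaction residues are taken from it so that the interactions are
    observable in a local-mutant library.
    """
    rng = np.random.default_rng(seed)
    pad35 = (l35 - 6) // 2
    cons35 = "." * pad35 + "TTGACA" + "." * (l35 - 6 - pad35)
    pad10 = (l10 - 6) // 2
    cons10 = "." * pad10 + "TATAAT" + "." * (l10 - 6 - pad10)
    up = consensus_matrix(rng, l35, cons35)
    down = consensus_matrix(rng, l10, cons10)
    pens = {s: quadratic_pen * (s - optimal_spacer) ** 2
            for s in range(optimal_spacer - spacer_flex,
                           optimal_spacer + spacer_flex + 1)}
    terms: list[DinucleotideTerm] = []
    if n_dinucleotides:
        n_contacts = l35 + l10
        if dinuc_positions is None:
            # draw position-disjoint pairs: interactions sharing a contact
            # position are mutually confounded (the likelihood is nearly
            # invariant under redistributing their effects), so planted
            # sets are kept identifiable by construction
            all_pairs = [(i, j) for i in range(n_contacts)
                         for j in range(i + 1, n_contacts)]
            order = rng.permutation(len(all_pairs))
            dinuc_positions = []
            used: set[int] = set()
            for k in order:
                i, j = all_pairs[k]
                if i in used or j in used:
                    continue
                dinuc_positions.append((i, j))
                used.update((i, j))
                if len(dinuc_positions) == n_dinucleotides:
                    break
        if wildtype_core == "consensus":
            cons_idx = np.concatenate([up, down], axis=1).argmin(axis=0)
            wildtype_core = "".join(BASES[i] for i in cons_idx)
        for (pi, pj) in dinuc_positions[:n_dinucleotides]:
            if wildtype_core is not None:
                # anchor one residue on the wildtype and pair it with the
                # most tolerated (lowest-penalty) mutant residue: such
                # interactions touch a minority of a library yet still
                # occur in competitive configurations, which keeps them
                # identifiable (a pattern carried by nearly every sequence
                # is absorbed into the overall calibration, and one on a
                # heavily penalized residue almost never matters)
                mat = np.concatenate([up, down], axis=1)
                bi = wildtype_core[pi]
                alts = [b for b in BASES if b != wildtype_core[pj]]
                bj = min(alts, key=lambda b: mat[BASES.index(b), pj])
            else:
                bi = BASES[rng.integers(0, 4)]
                bj = BASES[rng.integers(0, 4)]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            terms.append(DinucleotideTerm(pi, bi, pj, bj,
                                          sign * dinuc_magnitude))
    return EnergyModel(upstream_block=up, downstream_block=down,
                       spacer_penalties=pens, dinucleotide_terms=terms,
                       mu=mu, clearance_rate=clearance_rate,
                       rbs_occlusion_cutoff=rbs_occlusion_cutoff)


def wildtype_for_model(model: EnergyModel, rng: np.random.Generator,
                       upstream_pad: int = 3, downstream_pad: int = 3,
                       spacer: int | None = None) -> str:
    """A strong-promoter wildtype: consensus footprint embedded in random
    flanks, at the optimal spacer unless another length is requested."""
    cons = model.contact_matrix().argmin(axis=0)
    s = model.optimal_spacer if spacer is None else spacer
    spacer_seq = rng.integers(0, 4, size=s)
    core = np.concatenate([cons[:model.l35], spacer_seq, cons[model.l35:]])
    up = rng.integers(0, 4, size=upstream_pad)
    down = rng.integers(0, 4, size=downstream_pad)
    return "".join(BASES[i] for i in np.concatenate([up, core, down]))
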