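"""Statistical-thermodynamic model of sigma70-RNAP binding to promoter DNA.

The central quantity is ``P_on``: the equilibrium probability that RNA
polymerase occupies a *productive* binding configuration on a sequence,
which serves as the proxy for constitutive expression level (expression is
proportional to ``log10 P_on``).

Two model variants are provided:

* **Standard** -- only the single strongest binding site on the forward
  strand matters, all spacer lengths are allowed at no energetic cost, and
  every bound state is productive::

      P_on = 1 / (1 + exp(min_i E_i - mu))

* **Extended** -- every placement of the polymerase on either strand, with
  every allowed spacer length, contributes.  Productive ("on")
  configurations add to expression cumulatively; occlusive configurations
  (those whose transcript would truncate the ribosome binding site) and all
  reverse-complement configurations are unproductive ("np") competitors.
  With a relative clearance rate ``R`` the statistical weight of a
  configuration with energy ``E`` is ``w = 1 / (R + exp(E - mu))`` and::

      P_on = sum_on w / (1 + sum_np w + sum_on w)

  At ``R = 0`` the weights reduce to Boltzmann factors ``exp(-(E - mu))``.

Energies are expressed in units of k_B*T (0.59 kcal/mol at room
temperature).  The energy matrix is normalized so that the strongest
(lowest-energy) residue in each column is zero, and the optimal spacer
length carries zero penalty; the chemical potential ``mu`` absorbs the
overall scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np

#: Thermal energy unit used throughout, in kcal/mol (room temperature).
KBT_KCAL_PER_MOL = 0.59

#: Fixed residue order for all energy-matrix rows.
BASES = "ACGT"

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

FORWARD = "forward"
REVERSE_COMPLEMENT = "reverse_complement"

PRODUCTIVE = "productive"
OCCLUSIVE_UNPRODUCTIVE = "occlusive_unproductive"
RC_UNPRODUCTIVE = "reverse_complement_unproductive"


class InvalidAlphabetError(ValueError):
    """A sequence contains a residue outside {A, C, G, T}."""


class PlacementError(IndexError):
    """A binding configuration does not fit inside the sequence."""


class UndefinedOccupancyError(ValueError):
    """No binding configuration exists, so the Standard P_on is undefined."""


def seq_to_indices(bases: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into :data:`BASES`.

    Raises :class:`InvalidAlphabetError` on any character outside ACGT
    (case-insensitive); ambiguity codes are never silently skipped.
    """
    arr = np.frombuffer(bases.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    if (out < 0).any():
        bad = sorted({chr(c) for c in arr[out < 0]})
        raise InvalidAlphabetError(f"non-ACGT residue(s) in sequence: {bad}")
    return out


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def reverse_complement_indices(idx: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[idx[::-1]]


def reverse_complement(bases: str) -> str:
    return indices_to_seq(reverse_complement_indices(seq_to_indices(bases)))


@dataclass(frozen=True)
class DinucleotideTerm:
    """Pairwise energy correction between two contact positions.

    Positions index the concatenated contact footprint (upstream block
    columns first, then downstream block columns); the correction ``delta_e``
    (k_B*T) applies whenever residue ``base_i`` sits at contact ``pos_i`` and
    ``base_j`` at ``pos_j`` within the same binding configuration.
    """

    pos_i: int
    base_i: str
    pos_j: int
    base_j: str
    delta_e: float


@dataclass
class EnergyModel:
    """Full parameter bundle of the sigma70-RNAP binding model.

    Parameters
    ----------
    upstream_block:
        4 x L35 matrix of per-position penalties (k_B*T), rows in ACGT
        order; covers the -35 element plus flanking contact positions.
    downstream_block:
        4 x L10 matrix covering the -10 element plus flanks.
    spacer_penalties:
        Mapping spacer length (bp) -> penalty (k_B*T).  The minimum value
        must be 0 (the optimal spacer).  Keys must form a contiguous range.
    dinucleotide_terms:
        Pairwise corrections over the L35 + L10 contact positions.
    mu:
        Chemical potential of free RNAP, in k_B*T units.
    clearance_rate:
        Relative clearance rate R >= 0.  R = 0 recovers the equilibrium
        (pure Boltzmann) model.
    rbs_occlusion_cutoff:
        Distance (bp) from the -10 end of a site to the RBS start at or
        below which a forward-strand configuration is unproductive.
    """

    upstream_block: np.ndarray
    downstream_block: np.ndarray
    spacer_penalties: dict[int, float]
    dinucleotide_terms: list[DinucleotideTerm] = field(default_factory=list)
    mu: float = 0.0
    clearance_rate: float = 0.0
    rbs_occlusion_cutoff: int = 11

    def __post_init__(self) -> None:
        self.upstream_block = np.asarray(self.upstream_block, dtype=float)
        self.downstream_block = np.asarray(self.downstream_block, dtype=float)
        self.validate()

    # -- geometry ---------------------------------------------------------
    @property
    def l35(self) -> int:
        return self.upstream_block.shape[1]

    @property
    def l10(self) -> int:
        return self.downstream_block.shape[1]

    @property
    def n_contacts(self) -> int:
        return self.l35 + self.l10

    @property
    def spacer_lengths(self) -> list[int]:
        return sorted(self.spacer_penalties)

    @property
    def optimal_spacer(self) -> int:
        return min(self.spacer_penalties, key=lambda s: (self.spacer_penalties[s], s))

    def width(self, spacer: int) -> int:
        """Total footprint width (bp) of a configuration with this spacer."""
        return self.l35 + spacer + self.l10

    @property
    def min_width(self) -> int:
        return self.width(min(self.spacer_lengths))

    @property
    def max_width(self) -> int:
        return self.width(max(self.spacer_lengths))

    def contact_matrix(self) -> np.ndarray:
        """Concatenated 4 x (L35 + L10) matrix over all contact positions."""
        return np.concatenate([self.upstream_block, self.downstream_block], axis=1)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name, block in (("upstream_block", self.upstream_block),
                            ("downstream_block", self.downstream_block)):
            if block.ndim != 2 or block.shape[0] != 4:
                raise ValueError(f"{name} must be 4 x L, got {block.shape}")
            if (block < 0).any():
                raise ValueError(f"{name} has negative entries; penalties are "
                                 "normalized to the strongest residue per column")
            if not np.allclose(block.min(axis=0), 0.0, atol=1e-9):
                raise ValueError(f"every column of {name} must contain a zero")
        if not self.spacer_penalties:
            raise ValueError("spacer_penalties must not be empty")
        spacers = self.spacer_lengths
        if spacers != list(range(spacers[0], spacers[-1] + 1)):
            raise ValueError("spacer lengths must form a contiguous range")
        pens = np.array([self.spacer_penalties[s] for s in spacers], dtype=float)
        if (pens < 0).any() or not np.isclose(pens.min(), 0.0, atol=1e-9):
            raise ValueError("spacer penalties must be >= 0 with minimum 0")
        if self.clearance_rate < 0:
            raise ValueError("clearance_rate must be >= 0")
        for t in self.dinucleotide_terms:
            for pos in (t.pos_i, t.pos_j):
                if not 0 <= pos < self.n_contacts:
                    raise ValueError(f"dinucleotide position {pos} outside the "
                                     f"{self.n_contacts} contact positions")
            for b in (t.base_i, t.base_j):
                if b not in _BASE_INDEX:
                    raise ValueError(f"invalid residue {b!r} in dinucleotide term")
            if t.pos_i == t.pos_j:
                raise ValueError("dinucleotide term must couple two distinct positions")

    def normalized(self) -> "EnergyModel":
        """Return an equivalent model in canonical gauge.

        Per-column offsets of the energy matrix and the overall spacer
        offset are degenerate with the chemical potential (every
        configuration touches every contact position exactly once); this
        subtracts each column's minimum and the spacer minimum and absorbs
        the total shift into ``mu``, leaving all P_on values unchanged.
        """
        up = self.upstream_block.copy()
        down = self.downstream_block.copy()
        shift = 0.0
        for block in (up, down):
            mins = block.min(axis=0)
            block -= mins
            shift += mins.sum()
        pen_min = min(self.spacer_penalties.values())
        pens = {s: p - pen_min for s, p in self.spacer_penalties.items()}
        shift += pen_min
        return dataclasses.replace(
            self, upstream_block=up, downstream_block=down,
            spacer_penalties=pens, mu=self.mu - shift)


@dataclass
class PromoterSequence:
    """A DNA sequence with an optional annotated ribosome binding site."""

    identifier: str
    bases: str
    rbs_start: int | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("sequence must be non-empty")
        if self.rbs_start is not None and not 0 <= self.rbs_start < len(self.bases):
            raise ValueError("rbs_start outside sequence bounds")

    def __len__(self) -> int:
        return len(self.bases)

    def indices(self) -> np.ndarray:
        return seq_to_indices(self.bases)


@dataclass(frozen=True)
class BindingConfiguration:
    """One placement of RNAP: strand, position, spacer, energy and class.

    ``offset`` is the 0-based forward-strand position of the most upstream
    contact residue of the footprint (for reverse-complement configurations
    this is still a forward-strand coordinate).  ``ten_end`` is the most
    downstream contact position of the downstream (-10) block on the strand
    the polymerase reads; distance to the RBS is measured from there.
    """

    strand: str
    offset: int
    spacer_length: int
    energy: float
    klass: str
    ten_end: int

    @property
    def is_productive(self) -> bool:
        return self.klass == PRODUCTIVE


def _contact_positions(model: EnergyModel, offset: int, spacer: int) -> np.ndarray:
    """Sequence coordinates of the contact residues for one placement."""
    up = offset + np.arange(model.l35)
    down = offset + model.l35 + spacer + np.arange(model.l10)
    return np.concatenate([up, down])


def configuration_energy(seq: PromoterSequence | str, strand: str, offset: int,
                         spacer: int, model: EnergyModel,
                         include_dinucleotides: bool = True) -> float:
    """Binding energy (k_B*T) of a single configuration.

    The energy is the sum of the upstream-block entries, the
    downstream-block entries, the spacer penalty and any matching
    dinucleotide corrections.  ``offset`` is a coordinate on the strand the
    polymerase reads (forward coordinates for the forward strand, reverse-
    complement coordinates for the RC strand).
    """
    bases = seq.bases if isinstance(seq, PromoterSequence) else seq
    idx = seq_to_indices(bases)
    if strand == REVERSE_COMPLEMENT:
        idx = reverse_complement_indices(idx)
    elif strand != FORWARD:
        raise ValueError(f"unknown strand {strand!r}")
    if spacer not in model.spacer_penalties:
        raise PlacementError(f"spacer {spacer} outside model range")
    if offset < 0 or offset + model.width(spacer) > len(idx):
        raise PlacementError(
            f"placement offset={offset} spacer={spacer} outside sequence of "
            f"length {len(idx)}")
    cols = _contact_positions(model, offset, spacer)
    residues = idx[cols]
    mat = model.contact_matrix()
    energy = float(mat[residues, np.arange(model.n_contacts)].sum())
    energy += model.spacer_penalties[spacer]
    if include_dinucleotides:
        for t in model.dinucleotide_terms:
            if (residues[t.pos_i] == _BASE_INDEX[t.base_i]
                    and residues[t.pos_j] == _BASE_INDEX[t.base_j]):
                energy += t.delta_e
    return energy


def classify_configuration(strand: str, ten_end: int, rbs_start: int | None,
                           model: EnergyModel) -> str:
    """Productive / unproductive class of a placement.

    Any reverse-complement configuration is unproductive.  A forward
    configuration is occlusive when its transcript would truncate the RBS,
    i.e. when the distance from the -10 end to the RBS start is at or below
    the cutoff (default 11 bp: sites 11 or fewer bp away are unproductive,
    12 or more contribute productively).  Sequences without an annotated
    RBS have no occlusive forward configurations -- occlusion is defined
    relative to a reporter RBS.
    """
    if strand == REVERSE_COMPLEMENT:
        return RC_UNPRODUCTIVE
    if rbs_start is None:
        return PRODUCTIVE
    distance = rbs_start - (ten_end + 1)
    if distance <= model.rbs_occlusion_cutoff:
        return OCCLUSIVE_UNPRODUCTIVE
    return PRODUCTIVE


def enumerate_configurations(seq: PromoterSequence,
                             model: EnergyModel,
                             include_dinucleotides: bool = True,
                             ) -> list[BindingConfiguration]:
    """Every placement of the polymerase on both strands, each exactly once.

    Returns an empty list when the sequence is shorter than the minimal
    footprint.  Forward-strand offsets and -10 ends are forward
    coordinates; reverse-complement energies are computed on the
    reverse-complement string and the reported ``offset`` is mapped back to
    the forward strand (leftmost footprint base), with ``ten_end`` kept in
    RC coordinates for classification symmetry.
    """
    L = len(seq)
    idx = seq.indices()
    rc_idx = reverse_complement_indices(idx)
    mat = model.contact_matrix()
    out: list[BindingConfiguration] = []
    for strand, strand_idx in ((FORWARD, idx), (REVERSE_COMPLEMENT, rc_idx)):
        for spacer in model.spacer_lengths:
            w = model.width(spacer)
            for o in range(L - w + 1):
                cols = _contact_positions(model, o, spacer)
                residues = strand_idx[cols]
                e = float(mat[residues, np.arange(model.n_contacts)].sum())
                e += model.spacer_penalties[spacer]
                if include_dinucleotides:
                    for t in model.dinucleotide_terms:
                        if (residues[t.pos_i] == _BASE_INDEX[t.base_i]
                                and residues[t.pos_j] == _BASE_INDEX[t.base_j]):
                            e += t.delta_e
                ten_end = o + w - 1
                klass = classify_configuration(strand, ten_end, seq.rbs_start, model)
                offset = o if strand == FORWARD else L - o - w
                out.append(BindingConfiguration(
                    strand=strand, offset=offset, spacer_length=spacer,
                    energy=e, klass=klass, ten_end=ten_end))
    return out


# ---------------------------------------------------------------------------
# occupancy


def _logsumexp(a: np.ndarray) -> float:
    if a.size == 0:
        return -np.inf
    m = a.max()
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.exp(a - m).sum()))


def log_weights(energies: np.ndarray, mu: float, clearance_rate: float) -> np.ndarray:
    """log of the per-configuration statistical weights.

    ``w = (R + exp(E - mu))**-1``; at R = 0 this is the Boltzmann factor
    ``exp(-(E - mu))``.  Computed in log space so that very strong or very
    weak sites never overflow.
    """
    e = np.asarray(energies, dtype=float)
    if clearance_rate == 0.0:
        return -(e - mu)
    return -np.logaddexp(np.log(clearance_rate), e - mu)


def pon_from_energies(on_energies: np.ndarray, np_energies: np.ndarray,
                      mu: float, clearance_rate: float = 0.0,
                      log10: bool = False) -> float:
    """Occupancy of the productive states given partitioned energy lists.

    ``P_on = S_on / (1 + S_np + S_on)`` with ``S_x`` the summed weights of
    class ``x``.  An empty productive set gives P_on = 0 by convention.
    """
    ls_on = _logsumexp(log_weights(on_energies, mu, clearance_rate))
    ls_np = _logsumexp(log_weights(np_energies, mu, clearance_rate))
    log_den = np.logaddexp(0.0, np.logaddexp(ls_on, ls_np))
    log_p = ls_on - log_den
    return log_p / np.log(10.0) if log10 else float(np.exp(log_p))


def pon_extended(seq: PromoterSequence, model: EnergyModel,
                 log10: bool = False) -> float:
    """Extended-model occupancy: cumulative, occlusive, RC and clearance.

    All configurations on both strands enter with weights
    ``(R + exp(E - mu))**-1``; productive ones in the numerator,
    unproductive ones only in the denominator.  Returns 0 (or -inf in
    log10 mode) when no productive configuration exists.
    """
    cfgs = enumerate_configurations(seq, model)
    on = np.array([c.energy for c in cfgs if c.is_productive])
    off = np.array([c.energy for c in cfgs if not c.is_productive])
    return pon_from_energies(on, off, model.mu, model.clearance_rate, log10=log10)


def pon_standard(seq: PromoterSequence, model: EnergyModel,
                 log10: bool = False) -> float:
    """Standard-model occupancy: single strongest forward site.

    Only forward-strand placements are considered; every spacer length is
    allowed but carries no penalty; dinucleotide terms, unproductive states
    and the clearance rate are all ignored.  Ties in the minimum are broken
    by smallest offset, then shortest spacer (the value is unaffected; the
    deterministic choice matters for reporting the winning site).
    """
    L = len(seq)
    idx = seq.indices()
    mat = model.contact_matrix()
    best: tuple[float, int, int] | None = None
    for spacer in model.spacer_lengths:
        w = model.width(spacer)
        for o in range(L - w + 1):
            cols = _contact_positions(model, o, spacer)
            e = float(mat[idx[cols], np.arange(model.n_contacts)].sum())
            if best is None or (e, o, spacer) < best:
                best = (e, o, spacer)
    if best is None:
        raise UndefinedOccupancyError(
            f"sequence of length {L} shorter than minimal footprint "
            f"{model.min_width}")
    e_min = best[0]
    # log-space logistic for numerical robustness
    log_p = -np.logaddexp(0.0, e_min - model.mu)
    return log_p / np.log(10.0) if log10 else float(np.exp(log_p))


def best_standard_site(seq: PromoterSequence, model: EnergyModel,
                       ) -> BindingConfiguration:
    """The winning configuration of the Standard model's argmin."""
    L = len(seq)
    idx = seq.indices()
    mat = model.contact_matrix()
    best: tuple[float, int, int] | None = None
    for spacer in model.spacer_lengths:
        w = model.width(spacer)
        for o in range(L - w + 1):
            cols = _contact_positions(model, o, spacer)
            e = float(mat[idx[cols], np.arange(model.n_contacts)].sum())
            if best is None or (e, o, spacer) < best:
                best = (e, o, spacer)
    if best is None:
        raise UndefinedOccupancyError("no configuration fits")
    e, o, spacer = best
    return BindingConfiguration(
        strand=FORWARD, offset=o, spacer_length=spacer, energy=e,
        klass=PRODUCTIVE, ten_end=o + model.width(spacer) - 1)


def find_rbs(bases: str, motif: str = "AGGAG") -> int | None:
    """0-based start of the first Shine-Dalgarno motif occurrence, if any."""
    pos = bases.upper().find(motif)
    return pos if pos >= 0 else None
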