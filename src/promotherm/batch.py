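"""Vectorized evaluation of P_on over many equal-length sequences.

The naive per-sequence enumeration in :mod:`promotherm.model` is the
reference implementation; this module is the fast path used by fitting,
evolution simulations and genome scans.  It exploits the fact that every
binding configuration's energy decomposes as

    E(strand, offset, spacer) = U(strand, offset)
                              + D(strand, offset + L35 + spacer)
                              + spacer_penalty + dinucleotide corrections

where ``U``/``D`` are sliding sums of the upstream/downstream block over
the sequence.  Gradients of the log-occupancy with respect to every model
parameter are computed analytically, which is what makes maximum-likelihood
fitting of the energy matrix tractable.

All arrays of sequences are int8 matrices of shape (n, L) with residues
encoded 0..3 in ACGT order (see :func:`promotherm.model.seq_to_indices`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .model import EnergyModel, _BASE_INDEX, seq_to_indices

LN10 = np.log(10.0)

# class codes
ON = 0
OCCLUSIVE = 1
RC = 2

_FEATURE_ORDER = ("spacer_penalty", "cumulative", "occlusive",
                  "reverse_complement", "dinucleotides", "clearance")


@dataclass(frozen=True)
class FeatureFlags:
    """Which structural features of the Extended model are active.

    With everything off the evaluation is the Standard model: the single
    strongest forward site, all spacers allowed at no cost.
    """

    spacer_penalty: bool = False
    cumulative: bool = False
    occlusive: bool = False
    reverse_complement: bool = False
    dinucleotides: bool = False
    clearance: bool = False

    @classmethod
    def standard(cls) -> "FeatureFlags":
        return cls()

    @classmethod
    def extended(cls) -> "FeatureFlags":
        return cls(True, True, True, True, True, True)

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "FeatureFlags":
        unknown = set(names) - set(_FEATURE_ORDER)
        if unknown:
            raise ValueError(f"unknown feature(s): {sorted(unknown)}")
        return cls(**{n: True for n in names})

    def names(self) -> list[str]:
        return [f.name for f in fields(self) if getattr(self, f.name)]


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-length DNA strings into an (n, L) int8 matrix."""
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have the same length")
    return np.stack([seq_to_indices(s) for s in seqs])


_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)


def reverse_complement_batch(bases: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of an (n, L) index matrix."""
    return _COMPLEMENT[bases[:, ::-1]]


def block_profile(bases: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Sliding sum of a 4 x l energy block along sequences.

    ``bases`` is (n, L) int8; returns (n, L - l + 1) where column ``o`` is
    the block energy for a block starting at sequence position ``o``.
    """
    n, L = bases.shape
    l = block.shape[1]
    n_off = L - l + 1
    if n_off <= 0:
        return np.zeros((n, 0))
    out = np.zeros((n, n_off))
    for k in range(l):
        out += block[:, k][bases[:, k:k + n_off]]
    return out


def _block_profile_grad(bases: np.ndarray, g_profile: np.ndarray,
                        l: int) -> np.ndarray:
    """Route a gradient on the sliding-sum profile back to block entries."""
    n_off = g_profile.shape[1]
    grad = np.zeros((4, l))
    gw = g_profile.ravel()
    for k in range(l):
        grad[:, k] = np.bincount(
            bases[:, k:k + n_off].ravel(), weights=gw, minlength=4)
    return grad


class ConfigTable:
    """Configuration bookkeeping for sequences of one fixed length.

    Enumerates every (strand, spacer, offset) placement that fits in a
    length-``L`` sequence, assigns each a productive/unproductive class
    given the RBS position, and evaluates energies, occupancies and
    parameter gradients for whole libraries at once.
    """

    def __init__(self, L: int, model: EnergyModel,
                 rbs_start: int | None = None) -> None:
        self.L = L
        self.l35 = model.l35
        self.l10 = model.l10
        self.spacers = model.spacer_lengths
        self.cutoff = model.rbs_occlusion_cutoff
        self.rbs_start = rbs_start

        # forward-strand configs first, then reverse-complement
        blocks = []          # (strand, spacer, c0, n_off)
        spacer_id: list[np.ndarray] = []
        klass: list[np.ndarray] = []
        c0 = 0
        for strand in (0, 1):
            for si, s in enumerate(self.spacers):
                w = self.l35 + s + self.l10
                n_off = L - w + 1
                if n_off <= 0:
                    continue
                blocks.append((strand, s, c0, n_off))
                spacer_id.append(np.full(n_off, si, dtype=np.int16))
                if strand == 1:
                    klass.append(np.full(n_off, RC, dtype=np.int8))
                elif rbs_start is None:
                    klass.append(np.full(n_off, ON, dtype=np.int8))
                else:
                    ten_end = np.arange(n_off) + w - 1
                    dist = rbs_start - (ten_end + 1)
                    klass.append(np.where(dist <= self.cutoff,
                                          OCCLUSIVE, ON).astype(np.int8))
                c0 += n_off
        self.blocks = blocks
        self.spacer_id = (np.concatenate(spacer_id) if spacer_id
                          else np.zeros(0, dtype=np.int16))
        self.klass = (np.concatenate(klass) if klass
                      else np.zeros(0, dtype=np.int8))
        self.n_configs = c0
        self.n_forward = int((np.concatenate(klass) != RC).sum()) if klass else 0

    # -- energies ---------------------------------------------------------

    def energies(self, bases: np.ndarray, mat_up: np.ndarray,
                 mat_down: np.ndarray, pens: np.ndarray,
                 dinuc: Sequence[tuple[int, int, int, int, float]] = (),
                 use_pens: bool = True, include_rc: bool = True,
                 bases_rc: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, dict]:
        """Per-configuration energies for a whole library.

        ``pens`` is aligned with the model's sorted spacer lengths; dinuc
        entries are (pos_i, base_i, pos_j, base_j, delta_e) with residues
        already encoded as 0..3.  Returns (E, cache) where E is
        (n, n_configs); reverse-complement columns are left at +inf when
        ``include_rc`` is false (they then never contribute).
        """
        n = bases.shape[0]
        if bases_rc is None and include_rc:
            bases_rc = reverse_complement_batch(bases)
        U = [block_profile(bases, mat_up), None]
        D = [block_profile(bases, mat_down), None]
        if include_rc:
            U[1] = block_profile(bases_rc, mat_up)
            D[1] = block_profile(bases_rc, mat_down)
        E = np.full((n, self.n_configs), np.inf)
        for strand, s, c0, n_off in self.blocks:
            if strand == 1 and not include_rc:
                continue
            d0 = self.l35 + s
            e = U[strand][:, :n_off] + D[strand][:, d0:d0 + n_off]
            if use_pens:
                e += pens[self.spacers.index(s)]
            E[:, c0:c0 + n_off] = e
        masks = {}
        if dinuc:
            strands = (bases, bases_rc)
            for j, (ki, bi, kj, bj, de) in enumerate(dinuc):
                m = np.zeros((n, self.n_configs), dtype=bool)
                for strand, s, c0, n_off in self.blocks:
                    if strand == 1 and not include_rc:
                        continue
                    sb = strands[strand]
                    di = ki if ki < self.l35 else self.l35 + s + (ki - self.l35)
                    dj = kj if kj < self.l35 else self.l35 + s + (kj - self.l35)
                    m[:, c0:c0 + n_off] = ((sb[:, di:di + n_off] == bi)
                                           & (sb[:, dj:dj + n_off] == bj))
                E += de * m
                masks[j] = m
        cache = {"bases": bases, "bases_rc": bases_rc, "include_rc": include_rc,
                 "dinuc_masks": masks}
        return E, cache

    def dinuc_mask(self, bases: np.ndarray, ki: int, bi: int, kj: int,
                   bj: int, include_rc: bool = True,
                   bases_rc: np.ndarray | None = None) -> np.ndarray:
        """Boolean (n, n_configs) indicator of one dinucleotide pattern.

        True where the configuration places residue ``bi`` at contact
        ``ki`` and ``bj`` at contact ``kj``.
        """
        n = bases.shape[0]
        if bases_rc is None and include_rc:
            bases_rc = reverse_complement_batch(bases)
        strands = (bases, bases_rc)
        m = np.zeros((n, self.n_configs), dtype=bool)
        for strand, s, c0, n_off in self.blocks:
            if strand == 1 and not include_rc:
                continue
            sb = strands[strand]
            di = ki if ki < self.l35 else self.l35 + s + (ki - self.l35)
            dj = kj if kj < self.l35 else self.l35 + s + (kj - self.l35)
            m[:, c0:c0 + n_off] = ((sb[:, di:di + n_off] == bi)
                                   & (sb[:, dj:dj + n_off] == bj))
        return m

    def energies_backward(self, gE: np.ndarray, cache: dict,
                          use_pens: bool = True) -> dict:
        """Gradients of sum(gE * E) with respect to matrix blocks and pens."""
        bases, bases_rc = cache["bases"], cache["bases_rc"]
        include_rc = cache["include_rc"]
        n = gE.shape[0]
        nU = self.L - self.l35 + 1
        nD = self.L - self.l10 + 1
        gU = [np.zeros((n, nU)), np.zeros((n, nU)) if include_rc else None]
        gD = [np.zeros((n, nD)), np.zeros((n, nD)) if include_rc else None]
        g_pens = np.zeros(len(self.spacers))
        for strand, s, c0, n_off in self.blocks:
            if strand == 1 and not include_rc:
                continue
            g = gE[:, c0:c0 + n_off]
            gU[strand][:, :n_off] += g
            d0 = self.l35 + s
            gD[strand][:, d0:d0 + n_off] += g
            if use_pens:
                g_pens[self.spacers.index(s)] += g.sum()
        g_up = _block_profile_grad(bases, gU[0], self.l35)
        g_down = _block_profile_grad(bases, gD[0], self.l10)
        if include_rc:
            g_up += _block_profile_grad(bases_rc, gU[1], self.l35)
            g_down += _block_profile_grad(bases_rc, gD[1], self.l10)
        g_dinuc = np.array([(gE * m).sum() for m in cache["dinuc_masks"].values()])
        return {"upstream": g_up, "downstream": g_down, "pens": g_pens,
                "dinuc": g_dinuc}

    # -- occupancy --------------------------------------------------------

    def class_vector(self, flags: FeatureFlags) -> np.ndarray:
        """Per-configuration class under the active feature set.

        Returns int8 codes: 0 productive, 1 unproductive, -1 excluded.
        With ``occlusive`` off, occlusive-class forward configurations are
        treated as productive; with ``reverse_complement`` off, RC
        configurations are excluded from the sum altogether.
        """
        out = np.zeros(self.n_configs, dtype=np.int8)
        out[self.klass == OCCLUSIVE] = 1 if flags.occlusive else 0
        out[self.klass == RC] = 1 if flags.reverse_complement else -1
        return out

    def log10_pon(self, E: np.ndarray, mu: float, R: float,
                  flags: FeatureFlags, want_grad: bool = False):
        """log10 P_on per sequence, optionally with a gradient closure.

        Extended form (``cumulative`` on): weights w = (R + e^(E-mu))^-1
        summed over productive and unproductive classes; Standard form:
        logistic of the minimum forward energy.  Everything is evaluated in
        log space.  When ``want_grad`` is true, also returns a function
        mapping an upstream gradient gx (n,) to (gE, g_mu, g_R).
        """
        if not flags.cumulative:
            return self._log10_pon_standard(E, mu, want_grad)
        cls = self.class_vector(flags)
        logw = np.where(np.isfinite(E), -(E - mu), -np.inf) if R == 0.0 else \
            -np.logaddexp(np.log(R), E - mu)
        logw[:, cls < 0] = -np.inf
        on = cls == 0
        # one exp pass with a per-row shift; all softmaxes reuse it
        m = logw.max(axis=1)
        m_safe = np.where(np.isfinite(m), m, 0.0)
        a = np.exp(logw - m_safe[:, None])
        S_on = a[:, on].sum(axis=1) if on.any() else np.zeros(E.shape[0])
        S_all = a.sum(axis=1)
        with np.errstate(divide="ignore"):
            ls_on = m_safe + np.log(S_on)
            ls_all = m_safe + np.log(S_all)
        ls_on[~np.isfinite(m)] = -np.inf
        ls_all[~np.isfinite(m)] = -np.inf
        log_den = np.logaddexp(0.0, ls_all)
        x = (ls_on - log_den) / LN10

        if not want_grad:
            return x

        def backward(gx: np.ndarray):
            # dx/dlogw_c = (p_c - q_c)/ln10 with p the on-softmax and q the
            # denominator softmax; dlogw/dE = -u, u = e^(E-mu+logw) <= 1.
            with np.errstate(invalid="ignore", divide="ignore"):
                inv_on = np.where(S_on > 0, 1.0 / S_on, 0.0)
            p = np.zeros_like(a)
            p[:, on] = a[:, on] * inv_on[:, None]
            q = a * np.exp(m_safe - log_den)[:, None]
            if R == 0.0:
                coef = (gx / LN10)[:, None] * (p - q)
                gE = -coef
                g_mu = float(coef.sum())
                g_R = 0.0
            else:
                with np.errstate(invalid="ignore"):
                    u = np.exp(np.minimum(E - mu + logw, 0.0))
                u[~np.isfinite(E) | (cls < 0)[None, :]] = 0.0
                coef = (gx / LN10)[:, None] * (p - q)
                gE = -coef * u
                g_mu = float((coef * u).sum())
                g_R = float(-(coef * np.exp(logw)).sum())
            return gE, g_mu, g_R

        return x, backward

    def _log10_pon_standard(self, E: np.ndarray, mu: float,
                            want_grad: bool = False):
        fwd = self.klass != RC
        Ef = E[:, fwd]
        c_star = np.argmin(Ef, axis=1)
        rows = np.arange(E.shape[0])
        e_min = Ef[rows, c_star]
        x = -np.logaddexp(0.0, e_min - mu) / LN10
        if not want_grad:
            return x

        fwd_cols = np.flatnonzero(fwd)

        def backward(gx: np.ndarray):
            sig = _sigmoid(e_min - mu)
            g_star = -(gx / LN10) * sig
            gE = np.zeros_like(E)
            gE[rows, fwd_cols[c_star]] = g_star
            return gE, float(-g_star.sum()), 0.0

        return x, backward

    # -- convenience ------------------------------------------------------

    def model_arrays(self, model: EnergyModel, flags: FeatureFlags):
        """Extract (mat_up, mat_down, pens, dinuc, mu, R) per active flags."""
        pens = np.array([model.spacer_penalties[s] for s in self.spacers])
        dinuc = []
        if flags.dinucleotides:
            dinuc = [(t.pos_i, _BASE_INDEX[t.base_i],
                      t.pos_j, _BASE_INDEX[t.base_j], t.delta_e)
                     for t in model.dinucleotide_terms]
        R = model.clearance_rate if flags.clearance else 0.0
        return (model.upstream_block, model.downstream_block, pens, dinuc,
                model.mu, R)

    def log10_pon_library(self, bases: np.ndarray, model: EnergyModel,
                          flags: FeatureFlags,
                          bases_rc: np.ndarray | None = None) -> np.ndarray:
        """One-call log10 P_on for an encoded library under a model."""
        up, down, pens, dinuc, mu, R = self.model_arrays(model, flags)
        E, _ = self.energies(
            bases, up, down, pens, dinuc,
            use_pens=flags.spacer_penalty,
            include_rc=flags.reverse_complement, bases_rc=bases_rc)
        return self.log10_pon(E, mu, R, flags)


def _lse_cols(a: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp tolerating all -inf rows."""
    m = a.max(axis=1)
    safe = np.isfinite(m)
    out = np.full(a.shape[0], -np.inf)
    if safe.any():
        am = a[safe] - m[safe, None]
        out[safe] = m[safe] + np.log(np.exp(am).sum(axis=1))
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PhenotypeEvaluator:
    """Fast ``phi = log10 P_on`` for single sequences of a fixed length.

    Caches the configuration table so that repeated evaluation inside
    evolution simulations costs only the sliding-sum assembly.
    """

    def __init__(self, model: EnergyModel, length: int,
                 mode: str = "extended", rbs_start: int | None = None):
        if mode not in ("standard", "extended"):
            raise ValueError("mode must be 'standard' or 'extended'")
        self.model = model
        self.flags = (FeatureFlags.extended() if mode == "extended"
                      else FeatureFlags.standard())
        self.table = ConfigTable(length, model, rbs_start=rbs_start)
        if self.table.n_configs == 0:
            raise ValueError(f"no configuration fits in length {length}")

    def phi(self, bases_row: np.ndarray) -> float:
        x = self.table.log10_pon_library(bases_row[None, :], self.model,
                                         self.flags)
        return float(x[0])

    def phi_batch(self, bases: np.ndarray) -> np.ndarray:
        return self.table.log10_pon_library(bases, self.model, self.flags)
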