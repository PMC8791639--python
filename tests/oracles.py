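"""Independent brute-force reference implementations used only by tests.

These deliberately share no energy/occupancy code with the package: plain
Python loops over explicit string slices, so that agreement with the
package is a genuine cross-check.
"""

from __future__ import annotations

import math

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_configurations(seq: str, model, rbs_start=None):
    """Enumerate (strand, offset, spacer, energy, productive) naively."""
    l35 = model.upstream_block.shape[1]
    l10 = model.downstream_block.shape[1]
    out = []
    for strand, s_seq in (("fwd", seq), ("rc", rc(seq))):
        for spacer, pen in sorted(model.spacer_penalties.items()):
            width = l35 + spacer + l10
            for o in range(len(s_seq) - width + 1):
                e = pen
                contacts = []
                for k in range(l35):
                    b = s_seq[o + k]
                    e += model.upstream_block[BASES.index(b), k]
                    contacts.append(b)
                for k in range(l10):
                    b = s_seq[o + l35 + spacer + k]
                    e += model.downstream_block[BASES.index(b), k]
                    contacts.append(b)
                for t in model.dinucleotide_terms:
                    if (contacts[t.pos_i] == t.base_i
                            and contacts[t.pos_j] == t.base_j):
                        e += t.delta_e
                ten_end = o + width - 1
                if strand == "rc":
                    productive = False
                elif rbs_start is None:
                    productive = True
                else:
                    productive = (rbs_start - (ten_end + 1)
                                  > model.rbs_occlusion_cutoff)
                out.append((strand, o, spacer, e, productive))
    return out


def naive_log10_pon_extended(seq: str, model, rbs_start=None) -> float:
    """Slow log-domain evaluation of the Extended occupancy."""
    cfgs = naive_configurations(seq, model, rbs_start)
    mu, R = model.mu, model.clearance_rate
    logws = []
    for strand, o, spacer, e, productive in cfgs:
        if R == 0.0:
            lw = -(e - mu)
        else:
            m = max(math.log(R), e - mu)
            lw = -(m + math.log(math.exp(math.log(R) - m)
                                + math.exp(e - mu - m)))
        logws.append((lw, productive))
    if not any(p for _, p in logws):
        return -math.inf
    lse_on = _lse([lw for lw, p in logws if p])
    lse_all = _lse([lw for lw, _ in logws])
    log_den = _lse([0.0, lse_all])
    return (lse_on - log_den) / math.log(10.0)


def naive_log10_pon_standard(seq: str, model) -> float:
    """Naive sliding-minimum Standard model (forward strand, no penalties)."""
    l35 = model.upstream_block.shape[1]
    l10 = model.downstream_block.shape[1]
    best = None
    for spacer in sorted(model.spacer_penalties):
        width = l35 + spacer + l10
        for o in range(len(seq) - width + 1):
            e = 0.0
            for k in range(l35):
                e += model.upstream_block[BASES.index(seq[o + k]), k]
            for k in range(l10):
                e += model.downstream_block[
                    BASES.index(seq[o + l35 + spacer + k]), k]
            if best is None or e < best:
                best = e
    if best is None:
        raise ValueError("no placement fits")
    z = best - model.mu
    # log10 of 1/(1+e^z)
    return -_lse([0.0, z]) / math.log(10.0)


def _lse(vals):
    m = max(vals)
    if m == -math.inf:
        return m
    return m + math.log(sum(math.exp(v - m) for v in vals))
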