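"""Processing of binned sort-seq count tables into expression estimates.

Input is a table of unique sequences with per-bin read counts (one column
per FACS gate).  The pipeline mirrors what is needed for two experimental
designs:

* **4-bin local-mutant libraries** (lambda P_R / P_L style): filtering on
  coverage, length, RBS position, distance to the ancestral sequence and
  bin-distribution ambiguity; the per-sequence expression statistic is the
  median bin.
* **12-bin fully-random libraries** (36N style): flank-mapping and
  core-length filters, debiasing of sequential-sorting bias through a
  spike-in reference, mode-template outlier cleaning, and two linear
  expression estimates -- eps_bin = sum_i a_i * i in bin units and
  eps_facs = sum_i a_i * log10(m_i) in fluorescence units (m_i the median
  fluorescence of gate i).

All filters are pure per-record predicates, so the retained set does not
depend on the order in which rules are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from Bio import Align

from .model import find_rbs


@dataclass
class SortSeqLibrary:
    """Unique sequences with per-bin read counts.

    ``counts`` is an (n, B) integer array aligned with ``sequences``.
    ``bin_medians`` are the per-gate median fluorescence values m_i (needed
    only for eps_facs).  ``reference`` optionally holds the spike-in
    record as (sequence, counts).  ``distributions`` holds normalized (and
    possibly debiased / template-filtered) bin distributions once computed.
    """

    sequences: list[str]
    counts: np.ndarray
    bin_medians: np.ndarray | None = None
    reference: tuple[str, np.ndarray] | None = None
    distributions: np.ndarray | None = None
    access_log: dict = field(default_factory=lambda: {"reads": 0})

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.sequences):
            raise ValueError("counts must be (n_sequences, n_bins)")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequences must be unique")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def counts_matrix(self) -> np.ndarray:
        """Counts accessor; increments the access log (split firewalling)."""
        self.access_log["reads"] += 1
        return self.counts

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def normalized(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov[:, None] > 0, self.counts / cov[:, None], 0.0)

    def subset(self, keep: np.ndarray) -> "SortSeqLibrary":
        keep = np.asarray(keep)
        return SortSeqLibrary(
            sequences=[s for s, k in zip(self.sequences, keep) if k],
            counts=self.counts[keep],
            bin_medians=self.bin_medians,
            reference=self.reference,
            distributions=(self.distributions[keep]
                           if self.distributions is not None else None),
        )

    def median_bin(self) -> np.ndarray:
        """Per-sequence median bin index (the conservative 4-bin statistic)."""
        out = np.empty(self.n, dtype=int)
        for i, row in enumerate(self.counts):
            out[i] = _weighted_median_bin(row)
        return out

    def mean_bin(self) -> np.ndarray:
        a = self.distributions if self.distributions is not None \
            else self.normalized()
        return a @ np.arange(self.n_bins)

    # -- IO ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sequence": self.sequences})
        for b in range(self.n_bins):
            df[f"count_bin_{b}"] = self.counts[:, b]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "SortSeqLibrary":
        bins = [c for c in df.columns if c.startswith("count_bin_")]
        bins.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
        return cls(sequences=df["sequence"].tolist(),
                   counts=df[bins].to_numpy(), **kw)


def _weighted_median_bin(row: np.ndarray) -> int:
    total = row.sum()
    if total == 0:
        return 0
    cum = np.cumsum(row)
    return int(np.searchsorted(cum, (total + 1) // 2))


# ---------------------------------------------------------------------------
# mapping score (36N flank matching)


def mapping_score(query: str, target: str) -> float:
    """Similarity in [0, 1] from local alignment.

    Match score 1/L and symmetric gap open/extend penalty -1/(2L), with L
    the length of the mapping region (the query); identical sequences
    score exactly 1.
    """
    L = len(query)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0 / L
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0 / (2 * L)
    aligner.extend_gap_score = -1.0 / (2 * L)
    if not query or not target:
        return 0.0
    return float(aligner.score(target, query))


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterRules:
    """Configuration of the per-record filters.

    Only the rules whose parameters are set are applied.  ``mode`` selects
    the library design: ``"local"`` (P_R / P_L style mutants of a known
    ancestor) or ``"random"`` (36N style with fixed flanks around a random
    core).
    """

    mode: str = "local"
    coverage_min: int = 30
    length_range: tuple[int, int] | None = None
    rbs_motif: str | None = None
    rbs_position: int | None = None
    ancestor: str | None = None
    max_ancestor_distance: float | None = 0.25   # fraction of length
    upstream_flank: str | None = None
    downstream_flank: str | None = None
    flank_similarity_min: float = 0.75
    core_length: int = 36
    core_length_tolerance: int = 2
    ambiguity_side_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("local", "random"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def bin_ambiguity_filter(a_raw: np.ndarray, side_fraction: float = 0.10) -> bool:
    """True to keep a record, False to drop it.

    Sort-seq passaging can over- or under-represent a mutant in one bin
    relative to its neighbours.  The (configurable) default drops records
    whose reads sit in two occupied bins separated by at least one empty
    bin with both sides holding more than ``side_fraction`` of the reads:
    such gapped distributions are ambiguous about the true bin.
    """
    a = np.asarray(a_raw, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need a 1-D distribution over >= 2 bins")
    total = a.sum()
    if total == 0:
        return True
    occupied = np.flatnonzero(a > 0)
    for i in range(len(occupied) - 1):
        lo, hi = occupied[i], occupied[i + 1]
        if hi - lo > 1:  # separated by at least one empty bin
            left = a[:lo + 1].sum()
            right = a[hi:].sum()
            if (left > side_fraction * total) and (right > side_fraction * total):
                return False
    return True


def filter_library(lib: SortSeqLibrary, rules: FilterRules,
                   ) -> tuple[SortSeqLibrary, pd.DataFrame]:
    """Apply the configured per-record filters.

    Returns the filtered library and an attrition table listing, for each
    rule, how many records it would remove on its own and how many remain
    after the full (order-insensitive) intersection.
    """
    n = lib.n
    keeps: dict[str, np.ndarray] = {}

    keeps["coverage"] = lib.coverage >= rules.coverage_min

    if rules.length_range is not None:
        lo, hi = rules.length_range
        lens = np.array([len(s) for s in lib.sequences])
        keeps["length"] = (lens >= lo) & (lens <= hi)

    if rules.mode == "local":
        if rules.rbs_motif is not None:
            pos = np.array([_find_or_minus1(s, rules.rbs_motif)
                            for s in lib.sequences])
            if rules.rbs_position is not None:
                keeps["rbs_position"] = pos == rules.rbs_position
            else:
                keeps["rbs_position"] = pos >= 0
        if rules.ancestor is not None and rules.max_ancestor_distance is not None:
            max_d = rules.max_ancestor_distance * len(rules.ancestor)
            dist = np.array([hamming(s, rules.ancestor) for s in lib.sequences])
            keeps["ancestor_distance"] = dist <= max_d
    else:  # random / 36N
        up, down = rules.upstream_flank, rules.downstream_flank
        if up is not None and down is not None:
            sim_ok = np.zeros(n, dtype=bool)
            core_ok = np.zeros(n, dtype=bool)
            for i, s in enumerate(lib.sequences):
                su = mapping_score(up, s)
                sd = mapping_score(down, s)
                sim_ok[i] = (su >= rules.flank_similarity_min
                             and sd >= rules.flank_similarity_min)
                core_len = len(s) - len(up) - len(down)
                core_ok[i] = (abs(core_len - rules.core_length)
                              <= rules.core_length_tolerance)
            keeps["flank_similarity"] = sim_ok
            keeps["core_length"] = core_ok

    keeps["bin_ambiguity"] = np.array(
        [bin_ambiguity_filter(row, rules.ambiguity_side_fraction)
         for row in lib.counts])

    keep_all = np.ones(n, dtype=bool)
    rows = []
    for rule, keep in keeps.items():
        rows.append({"rule": rule, "removed_alone": int((~keep).sum())})
        keep_all &= keep
    attrition = pd.DataFrame(rows)
    attrition["input_records"] = n
    attrition["remaining_after_all"] = int(keep_all.sum())
    return lib.subset(keep_all), attrition


def _find_or_minus1(s: str, motif: str) -> int:
    pos = find_rbs(s, motif)
    return -1 if pos is None else pos


# ---------------------------------------------------------------------------
# 12-bin debiasing and template filtering


def debias_12bin(lib: SortSeqLibrary) -> SortSeqLibrary:
    """Remove sequential-sorting bias using the spike-in reference.

    Each bin of the 12-gate experiment was sorted for a different time, so
    read counts are scaled by an unknown per-bin factor.  A known number
    of reference cells was added to every bin; dividing every record's
    distribution by the reference distribution cancels the factor:

        a_i <- (alpha_i / ref_i) / sum_j (alpha_j / ref_j)

    Bins where the reference has zero counts are unobservable and are
    excluded from both the ratio and the renormalization.
    """
    if lib.reference is None:
        raise ValueError("12-bin debiasing requires a spike-in reference record")
    _, ref = lib.reference
    ref = np.asarray(ref, dtype=float)
    observable = ref > 0
    ratio = np.zeros((lib.n, lib.n_bins))
    ratio[:, observable] = lib.counts[:, observable] / ref[observable]
    norm = ratio.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(norm > 0, ratio / norm, 0.0)
    out = replace_distributions(lib, a)
    return out


def replace_distributions(lib: SortSeqLibrary, a: np.ndarray) -> SortSeqLibrary:
    return SortSeqLibrary(sequences=list(lib.sequences), counts=lib.counts,
                          bin_medians=lib.bin_medians, reference=lib.reference,
                          distributions=a)


def template_filter(lib: SortSeqLibrary, background_ratio: float = 1 / 3,
                    min_members: int = 10,
                    ) -> tuple[SortSeqLibrary, pd.DataFrame]:
    """Mode-template outlier cleaning of debiased distributions.

    Sequences are grouped by the mode (argmax) of their debiased
    distribution; each group's average distribution is its template.  The
    per-template background level is estimated from the template mass far
    from the mode, and only bins where the background is at most
    ``background_ratio`` of the template value are retained; counts in all
    other bins are nullified and the distribution renormalized.  A single
    stray read in a low bin of a high-expressing sequence would otherwise
    be blown up by debiasing and wreck the mean-bin estimate.

    Groups smaller than ``min_members`` keep their distributions unmasked
    (flagged in the report).  Records whose whole mass is masked away are
    dropped.
    """
    if lib.distributions is None:
        raise ValueError("template_filter needs debiased distributions")
    a = lib.distributions.copy()
    modes = a.argmax(axis=1)
    B = lib.n_bins
    report_rows = []
    keep = np.ones(lib.n, dtype=bool)
    for mode in range(B):
        members = np.flatnonzero(modes == mode)
        if members.size == 0:
            continue
        if members.size < min_members:
            report_rows.append({"mode": mode, "members": int(members.size),
                                "masked": False, "kept_bins": B})
            continue
        template = a[members].mean(axis=0)
        # background: mean template mass outside the mode neighbourhood
        # (the FACS noise floor shared by all distributions of this mode)
        far = np.abs(np.arange(B) - mode) > 2
        background = float(template[far].mean()) if far.any() else 0.0
        mask = background <= background_ratio * template
        mask[mode] = True
        a[np.ix_(members, np.flatnonzero(~mask))] = 0.0
        norm = a[members].sum(axis=1)
        dead = members[norm == 0]
        keep[dead] = False
        alive = members[norm > 0]
        a[alive] /= a[alive].sum(axis=1, keepdims=True)
        report_rows.append({"mode": mode, "members": int(members.size),
                            "masked": True, "kept_bins": int(mask.sum())})
    out = replace_distributions(lib, a).subset(keep)
    return out, pd.DataFrame(report_rows)


def estimate_expression(a: np.ndarray, bin_medians: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, np.ndarray | None]:
    """Expression estimates from normalized bin distributions.

    eps_bin is the mean bin index; eps_facs the mean log10 median
    fluorescence (absent when no gate medians are supplied).  For gate
    medians forming a geometric series the two are affinely related.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    B = a.shape[1]
    eps_bin = a @ np.arange(B)
    eps_facs = None
    if bin_medians is not None:
        m = np.asarray(bin_medians, dtype=float)
        if (m <= 0).any():
            raise ValueError("bin medians must be positive for eps_facs")
        eps_facs = a @ np.log10(m)
    return eps_bin, eps_facs


def cross_mapping_prefilter(lib: SortSeqLibrary, top_k: int = 1000,
                            score_threshold: float = 0.7) -> SortSeqLibrary:
    """Optional removal of sequencing-error clouds around abundant sequences.

    Maps every sequence against the ``top_k`` most covered ones; a record
    that is not itself highly covered but maps above ``score_threshold`` to
    a more abundant sequence is treated as an error of that sequence and
    dropped.  Quadratic in the worst case -- intended for the
    moderate library sizes of unique-sequence tables.
    """
    order = np.argsort(lib.coverage)[::-1]
    top = order[:top_k]
    top_set = set(top.tolist())
    top_seqs = [(lib.sequences[i], lib.coverage[i]) for i in top]
    keep = np.ones(lib.n, dtype=bool)
    for i in range(lib.n):
        if i in top_set:
            continue
        cov_i = lib.coverage[i]
        for seq_t, cov_t in top_seqs:
            if cov_t <= cov_i:
                break
            if mapping_score(lib.sequences[i], seq_t) > score_threshold:
                keep[i] = False
                break
    return lib.subset(keep)
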