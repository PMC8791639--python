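"""Maximum-likelihood fitting of the energy model from sort-seq libraries.

The observation model is a weighted multinomial logistic regression of
``x = log10 P_on`` against the observed expression bin of each sequence:
each bin ``i`` gets a slope/intercept pair so that the log-odds of the bin
is linear in ``x``,

    log(pi_i / (1 - pi_i)) = a_i * x + b_i,    pi_i = sigmoid(a_i x + b_i),

and the probability of observing bin ``i`` is ``P_i = pi_i / sum_j pi_j``.
Fits are balanced: every observation is weighted inversely to the number
of observations in its bin.  The weighted log-likelihood of this link is
the objective for everything in this module, with analytic gradients with
respect to every energy-model parameter (matrix entries, spacer penalties,
dinucleotide terms, chemical potential, clearance rate) supplied by
:mod:`promotherm.batch`.

Model features are added sequentially (Standard model first), each stage
warm-started from the previous best fit; dinucleotide interactions are
selected through a multi-stage funnel before their values enter the model;
the clearance rate is profiled on a grid with the chemical potential
refit at each value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .batch import LN10, ConfigTable, FeatureFlags, encode_sequences, \
    reverse_complement_batch, _sigmoid
from .model import BASES, DinucleotideTerm, EnergyModel
from .sortseq import SortSeqLibrary

__all__ = [
    "LogisticLink", "FitReport", "split_library", "fit_logistic",
    "balanced_weights", "expression_labels", "weighted_r2",
    "optimize_model", "select_dinucleotides", "scan_clearance_rate",
]


# ---------------------------------------------------------------------------
# logistic link


@dataclass
class LogisticLink:
    """Per-bin slopes and intercepts of the normalized-sigmoid link."""

    a: np.ndarray
    b: np.ndarray
    intercept_only: bool = False

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1 or self.a.size < 2:
            raise ValueError("need matching a/b vectors over >= 2 bins")

    @property
    def n_bins(self) -> int:
        return self.a.size

    def log_probabilities(self, x: np.ndarray) -> np.ndarray:
        """(n, B) log P_i; rows normalize to 1 in probability space."""
        z = np.outer(np.asarray(x, dtype=float), self.a) + self.b
        log_pi = -np.logaddexp(0.0, -z)          # log sigmoid(z)
        lse = _row_lse(log_pi)
        return log_pi - lse[:, None]

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_probabilities(x))

    def loglik(self, x: np.ndarray, bins: np.ndarray,
               weights: np.ndarray | None = None) -> float:
        lp = self.log_probabilities(x)
        ll = lp[np.arange(len(bins)), bins]
        return float(ll.sum() if weights is None else (weights * ll).sum())

    def loglik_grad_x(self, x: np.ndarray, bins: np.ndarray,
                      weights: np.ndarray) -> tuple[float, np.ndarray]:
        """(weighted loglik, d loglik / d x_n)."""
        x = np.asarray(x, dtype=float)
        z = np.outer(x, self.a) + self.b
        log_pi = -np.logaddexp(0.0, -z)
        lse = _row_lse(log_pi)
        rows = np.arange(len(bins))
        ll = float((weights * (log_pi[rows, bins] - lse)).sum())
        P = np.exp(log_pi - lse[:, None])
        sig_neg = _sigmoid(-z)
        g = self.a[bins] * sig_neg[rows, bins] - (P * sig_neg) @ self.a
        return ll, weights * g

    def crossing_point(self, i: int = 0, j: int = 1) -> float:
        """x where bins i and j are equiprobable (e.g. the measurable-
        expression cutoff from the no/low bin pair)."""
        if np.isclose(self.a[i], self.a[j]):
            raise ValueError("bins have equal slopes; no crossing")
        return (self.b[j] - self.b[i]) / (self.a[i] - self.a[j])


def _row_lse(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def balanced_weights(bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Weights inversely proportional to per-bin observation counts,
    normalized to mean 1."""
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    w = 1.0 / counts[bins]
    return w * len(bins) / w.sum()


def fit_logistic(x: np.ndarray, bins: np.ndarray,
                 weights: np.ndarray | None = None,
                 n_bins: int | None = None,
                 ) -> tuple[LogisticLink, float]:
    """Maximum-likelihood link for fixed phenotypes ``x``.

    Raises on single-bin input.  Degenerate x (all equal) yields a flagged
    intercept-only link matching the empirical bin frequencies.
    """
    x = np.asarray(x, dtype=float)
    bins = np.asarray(bins)
    B = int(n_bins if n_bins is not None else bins.max() + 1)
    present = np.unique(bins)
    if present.size < 2:
        raise ValueError("need at least 2 distinct bins to fit the link")
    if weights is None:
        weights = balanced_weights(bins, B)

    if np.ptp(x) < 1e-12:
        freq = np.bincount(bins, minlength=B) / len(bins)
        freq = np.clip(freq, 1e-9, 1 - 1e-9)
        link = LogisticLink(a=np.zeros(B), b=np.log(freq / (1 - freq)),
                            intercept_only=True)
        return link, link.loglik(x, bins, weights)

    scale = 2.0 / max(np.std(x), 1e-9)
    a0 = (np.arange(B) - (B - 1) / 2) * scale
    b0 = -a0 * np.median(x)
    theta0 = np.concatenate([a0, b0])
    rows = np.arange(len(bins))

    def negll(theta):
        a, b = theta[:B], theta[B:]
        z = np.outer(x, a) + b
        log_pi = -np.logaddexp(0.0, -z)
        lse = _row_lse(log_pi)
        ll = (weights * (log_pi[rows, bins] - lse)).sum()
        P = np.exp(log_pi - lse[:, None])
        sig_neg = _sigmoid(-z)
        gz = -weights[:, None] * (P * sig_neg)
        gz[rows, bins] += weights * sig_neg[rows, bins]
        ga = gz.T @ x
        gb = gz.sum(axis=0)
        return -ll, -np.concatenate([ga, gb])

    res = optimize.minimize(negll, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 250, "gtol": 1e-5})
    link = LogisticLink(a=res.x[:B], b=res.x[B:])
    return link, -float(res.fun)


def expression_labels(lib: SortSeqLibrary, statistic: str | None = None,
                      ) -> np.ndarray:
    """Per-sequence observed expression bin for the regression.

    Median bin for few-bin (<= 4) libraries; for 12-bin libraries the mean
    expression in bin units, rounded to the nearest integer.
    """
    if statistic is None:
        statistic = "median" if lib.n_bins <= 4 else "mean"
    if statistic == "median":
        return lib.median_bin()
    if statistic == "mean":
        mean = lib.mean_bin()
        return np.clip(np.rint(mean).astype(int), 0, lib.n_bins - 1)
    raise ValueError(f"unknown statistic {statistic!r}")


def weighted_r2(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """r^2 of a weighted least-squares line of y on x (same weights as the
    logistic regression)."""
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    xm, ym = (w * x).sum() / W, (w * y).sum() / W
    cov = (w * (x - xm) * (y - ym)).sum()
    vx = (w * (x - xm) ** 2).sum()
    vy = (w * (y - ym) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov * cov / (vx * vy))


# ---------------------------------------------------------------------------
# data splits


def split_library(lib: SortSeqLibrary, fractions: Sequence[float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> tuple[SortSeqLibrary, ...]:
    """Random disjoint partition of a library by unique sequence."""
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    if lib.n < lib.n_bins:
        raise ValueError("fewer sequences than bins; cannot split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(lib.n)
    sizes = np.rint(fractions * lib.n).astype(int)
    sizes[-1] = lib.n - sizes[:-1].sum()
    out = []
    start = 0
    for sz in sizes:
        keep = np.zeros(lib.n, dtype=bool)
        keep[order[start:start + sz]] = True
        out.append(lib.subset(keep))
        start += sz
    return tuple(out)


# ---------------------------------------------------------------------------
# parameter packing


@dataclass
class _ThetaSpec:
    """Layout of the continuous parameter vector for one fitting stage."""

    l35: int
    l10: int
    n_spacers: int
    n_dinuc: int
    fit_matrix: bool = True
    fit_pens: bool = True
    fit_mu: bool = True
    fit_R: bool = False
    matrix_bound: float = 15.0
    pen_bound: float = 30.0
    dinuc_bound: float = 2.0
    r_bounds: tuple[float, float] = (1e-4, 10.0)

    def pack(self, model: EnergyModel) -> np.ndarray:
        parts = []
        if self.fit_matrix:
            parts.append(model.upstream_block.ravel())
            parts.append(model.downstream_block.ravel())
        if self.fit_pens:
            parts.append(np.array([model.spacer_penalties[s]
                                   for s in model.spacer_lengths]))
        if self.n_dinuc:
            parts.append(np.array([t.delta_e for t in model.dinucleotide_terms]))
        if self.fit_mu:
            parts.append([model.mu])
        if self.fit_R:
            parts.append([max(model.clearance_rate, self.r_bounds[0])])
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def unpack(self, theta: np.ndarray, template: EnergyModel) -> dict:
        i = 0
        out = {"up": template.upstream_block, "down": template.downstream_block,
               "pens": np.array([template.spacer_penalties[s]
                                 for s in template.spacer_lengths]),
               "dinuc_vals": np.array([t.delta_e
                                       for t in template.dinucleotide_terms]),
               "mu": template.mu, "R": template.clearance_rate}
        if self.fit_matrix:
            n_up = 4 * self.l35
            out["up"] = theta[i:i + n_up].reshape(4, self.l35)
            i += n_up
            n_down = 4 * self.l10
            out["down"] = theta[i:i + n_down].reshape(4, self.l10)
            i += n_down
        if self.fit_pens:
            out["pens"] = theta[i:i + self.n_spacers]
            i += self.n_spacers
        if self.n_dinuc:
            out["dinuc_vals"] = theta[i:i + self.n_dinuc]
            i += self.n_dinuc
        if self.fit_mu:
            out["mu"] = float(theta[i]); i += 1
        if self.fit_R:
            out["R"] = float(theta[i]); i += 1
        return out

    def bounds(self) -> list[tuple[float | None, float | None]]:
        bounds: list[tuple[float | None, float | None]] = []
        if self.fit_matrix:
            bounds += [(0.0, self.matrix_bound)] * (4 * (self.l35 + self.l10))
        if self.fit_pens:
            bounds += [(0.0, self.pen_bound)] * self.n_spacers
        if self.n_dinuc:
            bounds += [(-self.dinuc_bound, self.dinuc_bound)] * self.n_dinuc
        if self.fit_mu:
            bounds += [(None, None)]
        if self.fit_R:
            bounds += [self.r_bounds]
        return bounds


def _model_with(template: EnergyModel, parts: dict) -> EnergyModel:
    """Build a canonical-gauge model from raw fitted parameter arrays.

    Per-column matrix offsets and the overall spacer offset are absorbed
    into the chemical potential before construction, so the strict
    invariants (column minima of zero, spacer minimum of zero) hold.
    """
    up = np.maximum(parts["up"], 0.0).copy()
    down = np.maximum(parts["down"], 0.0).copy()
    shift = 0.0
    for block in (up, down):
        mins = block.min(axis=0)
        block -= mins
        shift += mins.sum()
    pens = np.maximum(np.asarray(parts["pens"], dtype=float), 0.0)
    pmin = pens.min()
    pens = pens - pmin
    shift += pmin
    terms = [dataclasses.replace(t, delta_e=float(v))
             for t, v in zip(template.dinucleotide_terms, parts["dinuc_vals"])]
    spacers = template.spacer_lengths
    return dataclasses.replace(
        template, upstream_block=up, downstream_block=down,
        spacer_penalties={s: float(p) for s, p in zip(spacers, pens)},
        dinucleotide_terms=terms, mu=parts["mu"] - shift,
        clearance_rate=parts["R"])


# ---------------------------------------------------------------------------
# the fitting engine


class _LibraryObjective:
    """Weighted negative log-likelihood and gradient for one library."""

    def __init__(self, lib: SortSeqLibrary, model: EnergyModel,
                 rbs_start: int | None, statistic: str | None = None):
        self.sequences = lib.sequences
        self.bases = encode_sequences(lib.sequences)
        self.bases_rc = reverse_complement_batch(self.bases)
        self.y = expression_labels(lib, statistic)
        self.n_bins = lib.n_bins
        self.weights = balanced_weights(self.y, lib.n_bins)
        self.table = ConfigTable(self.bases.shape[1], model, rbs_start=rbs_start)
        if self.table.n_configs == 0:
            raise ValueError("sequences shorter than the minimal footprint")

    def phenotypes(self, parts: dict, flags: FeatureFlags,
                   dinuc_terms: Sequence[DinucleotideTerm] = ()) -> np.ndarray:
        E, _ = self._energies(parts, flags, dinuc_terms)
        return self.table.log10_pon(
            E, parts["mu"], parts["R"] if flags.clearance else 0.0, flags)

    def _energies(self, parts, flags, dinuc_terms):
        dinuc = []
        if flags.dinucleotides and len(dinuc_terms):
            from .model import _BASE_INDEX
            dinuc = [(t.pos_i, _BASE_INDEX[t.base_i], t.pos_j,
                      _BASE_INDEX[t.base_j], float(v))
                     for t, v in zip(dinuc_terms, parts["dinuc_vals"])]
        return self.table.energies(
            self.bases, parts["up"], parts["down"], parts["pens"], dinuc,
            use_pens=flags.spacer_penalty,
            include_rc=flags.reverse_complement, bases_rc=self.bases_rc)

    def negll_and_grad(self, theta: np.ndarray, spec: _ThetaSpec,
                       template: EnergyModel, flags: FeatureFlags,
                       link: LogisticLink) -> tuple[float, np.ndarray]:
        parts = spec.unpack(theta, template)
        E, cache = self._energies(parts, flags, template.dinucleotide_terms)
        R = parts["R"] if flags.clearance else 0.0
        x, backward = self.table.log10_pon(E, parts["mu"], R, flags,
                                           want_grad=True)
        ll, gx = link.loglik_grad_x(x, self.y, self.weights)
        gE, g_mu, g_R = backward(gx)
        grads = self.table.energies_backward(gE, cache,
                                             use_pens=flags.spacer_penalty)
        parts_g = []
        if spec.fit_matrix:
            parts_g += [grads["upstream"].ravel(), grads["downstream"].ravel()]
        if spec.fit_pens:
            parts_g.append(grads["pens"])
        if spec.n_dinuc:
            g_d = grads["dinuc"]
            if g_d.size != spec.n_dinuc:   # dinucleotides disabled this stage
                g_d = np.zeros(spec.n_dinuc)
            parts_g.append(g_d)
        if spec.fit_mu:
            parts_g.append([g_mu])
        if spec.fit_R:
            parts_g.append([g_R])
        grad = np.concatenate([np.atleast_1d(g) for g in parts_g])
        return -ll, -grad


def _fit_stage(obj: _LibraryObjective, model: EnergyModel, flags: FeatureFlags,
               spec: _ThetaSpec, max_outer: int = 200, inner_maxiter: int = 40,
               tol: float = 1e-6) -> tuple[EnergyModel, LogisticLink, float, bool]:
    """Alternate link refits with bounded L-BFGS over the energy parameters."""
    template = model
    theta = spec.pack(template)
    parts = spec.unpack(theta, template)
    x = obj.phenotypes(parts, flags, template.dinucleotide_terms)
    link, ll = fit_logistic(x, obj.y, obj.weights, n_bins=obj.n_bins)
    converged = False
    for _ in range(max_outer):
        res = optimize.minimize(
            obj.negll_and_grad, theta, args=(spec, template, flags, link),
            jac=True, method="L-BFGS-B", bounds=spec.bounds(),
            options={"maxiter": inner_maxiter})
        theta = res.x
        parts = spec.unpack(theta, template)
        x = obj.phenotypes(parts, flags, template.dinucleotide_terms)
        link, ll_new = fit_logistic(x, obj.y, obj.weights, n_bins=obj.n_bins)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    fitted = _model_with(model, parts)
    return fitted, link, ll, converged


FEATURE_SEQUENCE = ("spacer_penalty", "cumulative", "occlusive",
                    "reverse_complement", "dinucleotides", "clearance")


@dataclass
class FitReport:
    """Outcome of a staged model fit.

    ``feature_ledger`` records, per stage, the feature added and the gain
    in validation variance explained; the evaluation split is only ever
    touched by :func:`evaluate_split` after fitting.
    """

    model: EnergyModel
    link: LogisticLink
    flags: FeatureFlags
    loglik: dict[str, float]
    r2: dict[str, float]
    feature_ledger: pd.DataFrame
    converged: bool


def optimize_model(training: SortSeqLibrary, start: EnergyModel,
                   feature_set: Sequence[str] = FEATURE_SEQUENCE[:4],
                   validation: SortSeqLibrary | None = None,
                   rbs_start: int | None = None,
                   statistic: str | None = None,
                   max_outer: int = 6, inner_maxiter: int = 40,
                   tol: float = 1e-6) -> FitReport:
    """Staged maximum-likelihood fit starting from the Standard model.

    Features are activated one at a time in the order given, each stage
    warm-starting from the previous optimum (searching only in its
    vicinity); the validation split enters only through the reported
    ledger (model selection), never the objective.  Dinucleotide *terms*
    must already be present on ``start`` (use
    :func:`select_dinucleotides`); the ``dinucleotides`` stage fits their
    magnitudes.
    """
    bad = [f for f in feature_set if f not in FEATURE_SEQUENCE]
    if bad:
        raise ValueError(f"unknown features: {bad}")
    obj = _LibraryObjective(training, start, rbs_start, statistic)
    val_obj = (_LibraryObjective(validation, start, rbs_start, statistic)
               if validation is not None and validation.n else None)

    model = start
    active: list[str] = []
    rows = []
    prev_val_r2 = None
    link = None
    converged = True
    ll = np.nan
    for stage_name in ["standard"] + list(feature_set):
        if stage_name != "standard":
            active.append(stage_name)
        flags = FeatureFlags.from_names(active)
        spec = _ThetaSpec(
            l35=model.l35, l10=model.l10,
            n_spacers=len(model.spacer_lengths),
            n_dinuc=(len(model.dinucleotide_terms)
                     if flags.dinucleotides else 0),
            fit_pens=flags.spacer_penalty, fit_R=flags.clearance)
        model, link, ll, conv = _fit_stage(
            obj, model, flags, spec, max_outer=max_outer,
            inner_maxiter=inner_maxiter, tol=tol)
        converged = converged and conv
        row = {"stage": stage_name, "training_loglik": ll}
        if val_obj is not None:
            vx = _phenotypes_for(val_obj, model, flags)
            row["validation_loglik"] = link.loglik(vx, val_obj.y,
                                                   val_obj.weights)
            vr2 = weighted_r2(vx, val_obj.y, val_obj.weights)
            row["validation_r2"] = vr2
            row["delta_var_explained"] = (vr2 - prev_val_r2
                                          if prev_val_r2 is not None else np.nan)
            prev_val_r2 = vr2
        rows.append(row)

    flags = FeatureFlags.from_names(active)
    tx = _phenotypes_for(obj, model, flags)
    report = FitReport(
        model=model, link=link, flags=flags,
        loglik={"training": ll},
        r2={"training": weighted_r2(tx, obj.y, obj.weights)},
        feature_ledger=pd.DataFrame(rows), converged=converged)
    if val_obj is not None:
        report.loglik["validation"] = rows[-1]["validation_loglik"]
        report.r2["validation"] = rows[-1]["validation_r2"]
    return report


def _phenotypes_for(obj: _LibraryObjective, model: EnergyModel,
                    flags: FeatureFlags) -> np.ndarray:
    spec = _ThetaSpec(l35=model.l35, l10=model.l10,
                      n_spacers=len(model.spacer_lengths),
                      n_dinuc=len(model.dinucleotide_terms),
                      fit_R=flags.clearance)
    parts = spec.unpack(spec.pack(model), model)
    return obj.phenotypes(parts, flags, model.dinucleotide_terms)


def evaluate_split(lib: SortSeqLibrary, report: FitReport,
                   rbs_start: int | None = None,
                   statistic: str | None = None) -> dict[str, float]:
    """Final, read-only evaluation of a fitted model on a held-out split."""
    obj = _LibraryObjective(lib, report.model, rbs_start, statistic)
    x = _phenotypes_for(obj, report.model, report.flags)
    return {"loglik": report.link.loglik(x, obj.y, obj.weights),
            "r2": weighted_r2(x, obj.y, obj.weights)}


# ---------------------------------------------------------------------------
# dinucleotide-interaction selection funnel


def all_dinucleotide_candidates(n_contacts: int,
                                ) -> list[tuple[int, str, int, str]]:
    """Every (pos_i, base_i, pos_j, base_j) over the contact footprint
    (4416 candidates for 24 contact positions)."""
    out = []
    for i in range(n_contacts):
        for j in range(i + 1, n_contacts):
            for bi in BASES:
                for bj in BASES:
                    out.append((i, bi, j, bj))
    return out


@dataclass
class DinucleotideSelection:
    accepted: list[DinucleotideTerm]
    table: pd.DataFrame
    stage_sizes: dict[str, int]


def select_dinucleotides(training: SortSeqLibrary,
                         validation: SortSeqLibrary,
                         base_model: EnergyModel,
                         candidates: Sequence[tuple[int, str, int, str]] | None = None,
                         rbs_start: int | None = None,
                         flags: FeatureFlags | None = None,
                         stage1_delta_ll: float = 2.0,
                         acceptance_threshold: float = 0.002,
                         group_size_2: int = 20, n_backgrounds_2: int = 10,
                         group_size_3: int = 50, n_backgrounds_3: int = 12,
                         l1_grid: Sequence[float] = (0.5, 2.0, 8.0),
                         seed: int = 0,
                         statistic: str | None = None,
                         ) -> DinucleotideSelection:
    """Multi-stage funnel selecting pairwise interaction terms.

    1.  Every candidate is fit independently (single free delta-E, link and
        chemical potential fixed at the base fit); survivors must improve
        the weighted log-likelihood by at least ``stage1_delta_ll`` nats.
    2.  Survivors are jointly refit in random groups of ``group_size_2``
        with L1 regularization over 50:50 splits of the pooled
        training+validation data, once per background; estimates below
        ``acceptance_threshold`` (k_B T) are discarded and the remaining
        per-candidate estimates are combined into mean +/- sd; candidates
        compatible with zero at 2 sigma are dropped.
    3.  Same with groups of ``group_size_3`` and a 3-sigma requirement.
    4.  Greedy sequential inclusion from most to least significant,
        requiring each term to stay 3-sigma significant in the background
        of everything accepted before it.

    Stages whose data demands exceed the library are skipped with a
    warning entry in the stage-size dictionary.
    """
    from .model import _BASE_INDEX
    rng = np.random.default_rng(seed)
    if flags is None:
        flags = FeatureFlags.from_names(
            ["spacer_penalty", "cumulative", "occlusive",
             "reverse_complement", "dinucleotides"])
    if candidates is None:
        candidates = all_dinucleotide_candidates(base_model.n_contacts)

    pooled = _concat_libraries(training, validation)
    obj = _LibraryObjective(pooled, base_model, rbs_start, statistic)
    spec0 = _ThetaSpec(l35=base_model.l35, l10=base_model.l10,
                       n_spacers=len(base_model.spacer_lengths), n_dinuc=0)
    parts0 = spec0.unpack(spec0.pack(base_model), base_model)
    E0, _ = obj._energies(parts0, dataclasses.replace(flags, dinucleotides=False), ())
    mu, R = base_model.mu, (base_model.clearance_rate if flags.clearance else 0.0)

    n_train = training.n
    train_rows = np.arange(n_train)   # pooled = training rows then validation
    x0 = obj.table.log10_pon(E0, mu, R, flags)
    link0, ll0_all = fit_logistic(x0[train_rows], obj.y[train_rows],
                                  obj.weights[train_rows], n_bins=obj.n_bins)

    def mask_for(cand):
        ki, bi, kj, bj = cand
        return obj.table.dinuc_mask(obj.bases, ki, _BASE_INDEX[bi],
                                    kj, _BASE_INDEX[bj],
                                    include_rc=flags.reverse_complement,
                                    bases_rc=obj.bases_rc)

    # ---- stage 1: independent single-interaction fits
    # scored on pre-sliced training arrays with sparse energy updates
    bases_tr = obj.bases[train_rows]
    rc_tr = obj.bases_rc[train_rows]
    E0_tr = np.ascontiguousarray(E0[train_rows])
    w_tr, y_tr = obj.weights[train_rows], obj.y[train_rows]
    idx_tr = np.arange(len(train_rows))

    def negll_tr(E):
        x = obj.table.log10_pon(E, mu, R, flags)
        lp = link0.log_probabilities(x)
        return -float((w_tr * lp[idx_tr, y_tr]).sum())

    ll0 = -negll_tr(E0_tr)

    # incremental evaluation: a single interaction rescales the Boltzmann
    # weight of its matching entries by exp(-d), so the on/total sums can
    # be updated from the baseline instead of recomputed densely.  Only
    # valid at R = 0 (the funnel's default regime); otherwise fall back.
    cls = obj.table.class_vector(flags)
    incremental = R == 0.0
    if incremental:
        logw0 = -(E0_tr - mu)
        logw0[:, cls < 0] = -np.inf
        m_row = logw0.max(axis=1, keepdims=True)
        a0 = np.exp(logw0 - m_row)
        on_cols = cls == 0
        S_on0 = (a0 * on_cols).sum(axis=1)
        S_all0 = a0.sum(axis=1)
        m_flat = m_row.ravel()
        n_cfg = obj.table.n_configs
        w_obs = w_tr

        def negll_inc(flat, rows_aff, on_aff, d):
            da = a0.ravel()[flat] * np.expm1(-d)
            dS_all = np.bincount(rows_aff, weights=da, minlength=len(idx_tr))
            dS_on = np.bincount(rows_aff[on_aff], weights=da[on_aff],
                                minlength=len(idx_tr))
            S_on = np.maximum(S_on0 + dS_on, 0.0)
            S_all = np.maximum(S_all0 + dS_all, 0.0)
            with np.errstate(divide="ignore"):
                x = (m_flat + np.log(S_on)
                     - np.logaddexp(0.0, m_flat + np.log(S_all))) / LN10
            lp = link0.log_probabilities(x)
            return -float((w_obs * lp[idx_tr, y_tr]).sum())

    stage1 = []
    for cand in candidates:
        ki, bi, kj, bj = cand
        m = obj.table.dinuc_mask(bases_tr, ki, _BASE_INDEX[bi],
                                 kj, _BASE_INDEX[bj],
                                 include_rc=flags.reverse_complement,
                                 bases_rc=rc_tr)
        flat = np.flatnonzero(m.ravel())
        if flat.size == 0:
            continue
        if incremental:
            rows_aff = flat // n_cfg
            on_aff = on_cols[flat % n_cfg]
            f1 = lambda d: negll_inc(flat, rows_aff, on_aff, d)
        else:
            def f1(d, flat=flat):
                E = E0_tr.copy()
                E.ravel()[flat] += d
                return negll_tr(E)

        res = optimize.minimize_scalar(
            f1, bounds=(-2.0, 2.0), method="bounded",
            options={"xatol": 5e-3, "maxiter": 20})
        gain = -res.fun - ll0
        if gain >= stage1_delta_ll:
            stage1.append((cand, float(res.x), float(gain)))
    stage_sizes = {"candidates": len(candidates), "stage1": len(stage1)}
    if not stage1:
        return DinucleotideSelection([], pd.DataFrame(), stage_sizes)

    survivors = [c for c, _, _ in stage1]
    warm = {c: d for c, d, _ in stage1}

    lam = _choose_l1(obj, E0, mu, R, flags, link0, survivors, warm,
                     mask_for, group_size_2, l1_grid, rng)

    def joint_stage(survivors, group_size, n_backgrounds, n_sigma):
        ests: dict = {c: [] for c in survivors}
        for _ in range(n_backgrounds):
            order = rng.permutation(len(survivors))
            half = rng.permutation(obj.bases.shape[0])
            half_rows = half[:obj.bases.shape[0] // 2]
            for g0 in range(0, len(survivors), group_size):
                group = [survivors[k] for k in order[g0:g0 + group_size]]
                vals = _joint_l1_fit(obj, E0, mu, R, flags, link0, group,
                                     warm, mask_for, half_rows, lam)
                for c, v in zip(group, vals):
                    if abs(v) > acceptance_threshold:
                        ests[c].append(v)
        out = []
        for c in survivors:
            vals = ests[c]
            if len(vals) < 2:
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1))
            if sd == 0 or abs(mean) > n_sigma * sd:
                out.append((c, mean, sd))
        return out

    stage2 = joint_stage(survivors, group_size_2, n_backgrounds_2, n_sigma=2)
    stage_sizes["stage2"] = len(stage2)
    survivors = [c for c, _, _ in stage2]
    warm.update({c: m for c, m, _ in stage2})
    if not survivors:
        return DinucleotideSelection([], pd.DataFrame(), stage_sizes)

    stage3 = joint_stage(survivors, group_size_3, n_backgrounds_3, n_sigma=3)
    stage_sizes["stage3"] = len(stage3)
    if not stage3:
        return DinucleotideSelection([], pd.DataFrame(), stage_sizes)

    # ---- stage 4: greedy sequential inclusion at 3 sigma
    stage3.sort(key=lambda t: -abs(t[1]) / max(t[2], 1e-12))
    accepted: list[tuple[tuple, float, float]] = []
    for cand, mean, sd in stage3:
        group = [c for c, _, _ in accepted] + [cand]
        vals = []
        for _ in range(6):
            half = rng.permutation(obj.bases.shape[0])
            rows = half[:obj.bases.shape[0] // 2]
            fit = _joint_l1_fit(obj, E0, mu, R, flags, link0, group, warm,
                                mask_for, rows, lam=lam)
            vals.append(fit[-1])
        m_hat = float(np.mean(vals))
        s_hat = float(np.std(vals, ddof=1))
        if s_hat == 0 or abs(m_hat) > 3 * s_hat:
            accepted.append((cand, m_hat, s_hat))
    stage_sizes["accepted"] = len(accepted)

    terms = [DinucleotideTerm(c[0], c[1], c[2], c[3], m)
             for c, m, _ in accepted]
    table = pd.DataFrame(
        [{"pos_i": c[0], "base_i": c[1], "pos_j": c[2], "base_j": c[3],
          "delta_e": m, "sd": s} for c, m, s in accepted])
    return DinucleotideSelection(terms, table, stage_sizes)


def _choose_l1(obj, E0, mu, R, flags, link, survivors, warm, mask_for,
               group_size, l1_grid, rng, tolerance: float = 1.0) -> float:
    """Pick the L1 strength by held-out likelihood on one 50:50 split.

    Among grid values whose held-out likelihood is within ``tolerance``
    nats of the best, the strictest (largest) penalty wins -- the usual
    one-standard-error style rule, matching the deliberately strict
    regularization of the selection funnel.
    """
    if len(l1_grid) == 1:
        return float(l1_grid[0])
    group = survivors[:group_size]
    n = obj.bases.shape[0]
    perm = rng.permutation(n)
    fit_rows, hold_rows = perm[:n // 2], perm[n // 2:]
    lls = {}
    for lam in l1_grid:
        vals = _joint_l1_fit(obj, E0, mu, R, flags, link, group, warm,
                             mask_for, fit_rows, lam)
        E = E0.copy()
        for c, v in zip(group, vals):
            E += v * mask_for(c)
        x = obj.table.log10_pon(E[hold_rows], mu, R, flags)
        lp = link.log_probabilities(x)
        lls[lam] = float((obj.weights[hold_rows]
                          * lp[np.arange(len(hold_rows)), obj.y[hold_rows]]).sum())
    best = max(lls.values())
    return float(max(lam for lam, ll in lls.items() if ll >= best - tolerance))


def _joint_l1_fit(obj, E0, mu, R, flags, link, group, warm, mask_for,
                  rows, lam) -> np.ndarray:
    """Jointly fit the delta-E values of one candidate group with an L1
    penalty, on a row subset; returns the fitted values in group order.

    L1 is handled by splitting each value into positive and negative
    parts, keeping the objective smooth for L-BFGS-B; energy updates and
    their gradients use sparse mask indices.
    """
    flat = [np.flatnonzero(mask_for(c)[rows].ravel()) for c in group]
    k = len(group)
    w = obj.weights[rows]
    y = obj.y[rows]
    idx = np.arange(len(rows))
    E_base = np.ascontiguousarray(E0[rows])

    def negll_grad(theta):
        d = theta[:k] - theta[k:]
        E = E_base.copy()
        Ef = E.ravel()
        for fj, dj in zip(flat, d):
            if dj != 0.0:
                Ef[fj] += dj
        x, backward = obj.table.log10_pon(E, mu, R, flags, want_grad=True)
        lp = link.log_probabilities(x)
        ll = float((w * lp[idx, y]).sum())
        _, gx = link.loglik_grad_x(x, y, w)
        gE, _, _ = backward(gx)
        gEf = gE.ravel()
        g_d = np.array([gEf[fj].sum() for fj in flat])
        grad = np.concatenate([-g_d + lam, g_d + lam])
        return -ll + lam * theta.sum(), grad

    theta0 = np.zeros(2 * k)
    for j, c in enumerate(group):
        v = warm.get(c, 0.0)
        if v >= 0:
            theta0[j] = v
        else:
            theta0[k + j] = -v
    res = optimize.minimize(negll_grad, theta0, jac=True, method="L-BFGS-B",
                            bounds=[(0.0, 4.0)] * (2 * k),
                            options={"maxiter": 40})
    return res.x[:k] - res.x[k:]


def _concat_libraries(a: SortSeqLibrary, b: SortSeqLibrary) -> SortSeqLibrary:
    return SortSeqLibrary(sequences=list(a.sequences) + list(b.sequences),
                          counts=np.concatenate([a.counts, b.counts]),
                          bin_medians=a.bin_medians,
                          reference=a.reference)


# ---------------------------------------------------------------------------
# clearance-rate scan


def scan_clearance_rate(training: SortSeqLibrary, model: EnergyModel,
                        grid: Sequence[float] = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0),
                        rbs_start: int | None = None,
                        statistic: str | None = None,
                        ) -> tuple[pd.DataFrame, float]:
    """Profile the training likelihood over clearance-rate values.

    For each R on the grid the chemical potential (and the link) is refit
    with all other parameters frozen; returns the per-R profile and the
    argmax.  The grid must include 0 so the equilibrium model is always a
    candidate.
    """
    grid = list(grid)
    if 0.0 not in grid:
        raise ValueError("the R grid must include 0")
    flags = FeatureFlags.extended()
    obj = _LibraryObjective(training, model, rbs_start, statistic)
    rows = []
    for R in grid:
        m = dataclasses.replace(model, clearance_rate=float(R))
        spec = _ThetaSpec(l35=m.l35, l10=m.l10,
                          n_spacers=len(m.spacer_lengths),
                          n_dinuc=len(m.dinucleotide_terms),
                          fit_matrix=False, fit_pens=False, fit_R=False)
        # mu-only refit (dinuc values frozen at the model's)
        spec.n_dinuc = 0
        _, _, ll, _ = _fit_stage(obj, m, flags, spec, max_outer=4,
                                 inner_maxiter=30)
        rows.append({"R": float(R), "training_loglik": ll})
    profile = pd.DataFrame(rows)
    best = float(profile.loc[profile["training_loglik"].idxmax(), "R"])
    return profile, best
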