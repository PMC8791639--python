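# Methods

## The occupancy model

The package predicts constitutive expression from promoter sequence
through the equilibrium occupancy of σ70-RNA polymerase.  A *binding
configuration* is one placement of the polymerase on one strand: an
upstream contact block (the −35 element plus flanking contacts, default
12 positions), a spacer of 7–11 bp, and a downstream contact block (the
−10 element plus flanks, default 12 positions).  Its energy, in units of
k_B·T (0.59 kcal/mol at room temperature), is the sum of per-position,
per-base penalties from the energy matrix, a spacer-length penalty, and
any matching pairwise (dinucleotide) corrections.  Matrix columns are
normalized so the strongest residue in each column costs zero; because
every configuration touches every contact position exactly once,
per-column offsets (and the overall spacer offset) are exactly degenerate
with the chemical potential μ, and fitted models are reported in this
canonical gauge.

Two occupancy summaries are provided:

* **Standard**: `P_on = 1 / (1 + exp(min_i E_i − μ))` over forward-strand
  placements, all spacer lengths allowed at no cost.  This is the
  single-strongest-site view of a promoter.
* **Extended**: every placement on both strands enters with statistical
  weight `w = 1 / (R + exp(E − μ))` and
  `P_on = Σ_on w / (1 + Σ_np w + Σ_on w)`.
  Productive ("on") configurations contribute cumulatively; unproductive
  ("np") configurations — placements whose −10 end lies within 11 bp of
  the ribosome binding site (occlusion: the transcript would truncate the
  RBS) and every reverse-complement placement — compete in the
  denominator only.  The clearance rate R caps the benefit of very strong
  binding (the polymerase must leave the site to transcribe); R = 0
  recovers pure equilibrium weights.  With a single productive site,
  `P_on(μ, R) = P_on(μ + log(1+R), 0) / (1+R)`: a constant shift of
  log10 P_on, absorbed by the regression link, which is why R is
  unidentifiable from single-site data.

All sums are evaluated in log space (log-sum-exp), so arbitrarily strong
or weak sites never overflow.  At R = 0 the occupancy is monotone
non-decreasing in μ; with clearance this can fail — a strong productive
site saturates at weight 1/R while unproductive competitors keep filling,
so raising polymerase availability can lower P_on.  Sequences without an annotated RBS (genome
scans, raw random sequences) have no occluded forward configurations —
occlusion is defined relative to a reporter RBS — while reverse-complement
placements remain unproductive.  Ambiguous bases are a hard error.
Expression is taken proportional to `log10 P_on` throughout.

The exact matrix footprint is not uniquely determined by the biology; the
default of 12+12 contacts with optimal internal spacer 9 bp (17 bp
between the canonical hexamers) is configurable in the parameter bundle,
and the pairwise-candidate count C(24,2)×16 = 4416 is consistent with
that choice.

## Fitting from binned sort-seq data

The observation model is a weighted multinomial logistic regression of
`x = log10 P_on` on the observed expression bin: each bin has a
slope/intercept pair, `π_i = σ(a_i x + b_i)`, and `P_i = π_i / Σ_j π_j`.
Observations are weighted inversely to their bin's count (balanced fit);
the weighted log-likelihood is the single objective used everywhere, and
the same weights are reused for the reported r² of the linear
x-versus-expression fit.  The expression statistic per sequence is the
median bin for 4-bin libraries and the rounded mean bin for 12-bin
libraries.

Libraries are split 60:20:20 into training / validation / evaluation by
unique sequence.  Model features are added one at a time (spacer penalty,
cumulative binding, occlusion, reverse complement, dinucleotides,
clearance), each stage warm-started from the previous optimum.  Within a
stage the fit alternates a link refit with bounded L-BFGS over the energy
parameters using fully analytic gradients (the gradient of the weighted
log-likelihood with respect to every matrix entry, spacer penalty,
pairwise term, μ and R is propagated through the log-space occupancy);
alternation stops when the likelihood improves by less than 1e−6 or after
a configurable number of outer rounds.  Matrix entries are bounded to
[0, 15] k_B·T and spacer penalties to [0, 30] k_B·T during optimization,
and the result is re-normalized to canonical gauge.  Warm starts come
from a consensus seed (TTGACA/TATAAT penalized at 2 k_B·T, flat flanks)
unless the caller provides a bundle.

### Dinucleotide selection

Pairwise terms are chosen by a multi-stage funnel before their values
enter the model: (1) each candidate is fit alone (link and μ frozen at
the base fit) and kept if it gains ≥ 2 nats of weighted log-likelihood —
the "2-fold improvement" rule is ambiguous in prose and is implemented as
a configurable nat threshold; (2) survivors are refit jointly in random
groups of 20 with L1 regularization on 50:50 splits of the pooled
training+validation data across 10 backgrounds, estimates below 0.002
k_B·T are discarded, and candidates compatible with zero at 2σ across
backgrounds are dropped; (3) the same with groups of 50, 12 backgrounds
and 3σ; (4) greedy inclusion from most to least significant, requiring
3σ in the background of everything already accepted.  The L1 strength is
chosen from {0.5, 2, 8} (per summed weighted log-likelihood) by held-out
likelihood on a 50:50 split, taking the strictest value within 1 nat of
the best: without a deliberately strict penalty, spurious "mirror"
patterns that proxy a real interaction saturate the fit bounds with
artificially zero variance and defeat the σ filters.  Stage-1 scoring
uses an incremental sum-space update (a single interaction rescales the
Boltzmann weights of its matching configurations by exp(−ΔE)), which is
what makes scanning all 4416-candidate geometries practical.

The clearance rate is profiled on a grid that must include 0, refitting μ
(and the link) at each value; with only weak binders or single-site
sequences the profile is flat, as expected from the degeneracy above.

## Sort-seq processing

Input is a unique-sequence count table.  All filters are pure per-record
predicates (coverage ≥ 30 by default; length window; RBS motif position;
Hamming distance to the ancestor ≤ 25% of its length for local-mutant
libraries; flank mapping similarity ≥ 0.75 and core length within ±2 bp
of 36 for fully-random libraries; a bin-gap ambiguity rule), so the
retained set does not depend on filter order.  The mapping score is a
local alignment with match score 1/L and symmetric gap penalty −1/(2L)
(L the mapping-region length), so identical sequences score exactly 1.
The ambiguity rule — drop records whose reads fall in two occupied bins
separated by an empty bin with both sides holding > 10% of reads — is our
quantification of an "unambiguous distribution" requirement that is not
numerically specified anywhere; both the rule and its threshold are
configurable.

Twelve-bin experiments are debiased by the spike-in reference: each
record's distribution is divided bin-wise by the reference distribution
and renormalized; reference-empty bins are treated as unobservable and
excluded.  Records are then grouped by mode, each group's mean
distribution is its template, the FACS noise floor is estimated as the
mean template mass far (> 2 bins) from the mode, and bins whose template
value is below 3× that floor are nullified before renormalization —
without this, a single stray read in a low bin of a high-expressing
sequence is amplified enormously by debiasing.  Expression estimates are
`ε_bin = Σ a_i·i` and `ε_facs = Σ a_i·log10 m_i` (gate medians m_i);
for geometric gate spacing the two are affine.

## Synthetic data

The generator emulates the three library designs: local mutants at 12%
(P_R-like) or 9% (P_L-like) per-position total mutation rate with equal
probability for each alternative base, and fully-random cores (36 bp by
default) between fixed flanks.  Sort-seq simulation draws per-cell
phenotypes `log10 P_on + N(0, sd)` (sd 0.15 by default — FACS gating
makes log-fluorescence noise the natural cell-level model), gates them
into 4 or 12 bins, and Poisson-samples reads at a target per-sequence
depth; 12-bin mode multiplies each bin's sampling rate by a
sequential-sorting bias factor and adds a spike-in reference present at
1000 cells in every bin.  Ground-truth models have consensus-structured
random matrices, quadratic spacer penalties, optional planted pairwise
terms and R ∈ {0, 0.3}.

What the generator does *not* emulate: PCR chimeras, index hopping,
sequencing-error clouds (beyond what the cross-mapping prefilter is
tested on), mRNA-stability effects, and any sequence dependence of the
clearance rate.  Passing recovery tests therefore demonstrates the
estimators' correctness under the stated statistical model, not
robustness to every artifact of a real experiment.

Planted pairwise interactions anchor one residue on the consensus and one
off it, and recovery experiments use a fully-random library: in a
local-mutant library a pattern carried by ~88% of sequences is absorbed
into the link calibration and every consensus position provides a nearly
identical anchor, so consensus–consensus pairs are structurally
unidentifiable there — mirroring the original finding that pairwise terms
became estimable only when the random library was pooled in.

## Evolution simulations

Strong-selection-weak-mutation: one proposed mutation per step (time unit
1/μ_mutation), uniform over the centered mutable region and the three
alternative bases (back-mutations allowed), fixed with the Kimura
probability `(1 − e^(−2sδφ)) / (1 − e^(−4Nsδφ))` with φ = log10 P_on;
the neutral limit 1/(2N) and extreme selection are handled analytically.
Default selection strength s = 100 puts typical mutational effects
(δφ ~ 10⁻³–10⁻²) at selection coefficients of 0.1–1.  δφ is always
computed by full re-evaluation of P_on (no incremental caching).  Runs
stop at the threshold φ* or are censored at 10N steps; censored runs
enter means at the cap, which biases the slower (Standard) model's times
downward, so reported Extended-over-Standard speed-ups are lower bounds.
Thresholds can be given explicitly or derived from a fitted logistic link
as the bin-0/bin-1 equiprobability point ("measurable expression"); in
comparative runs each model gets its own threshold from the same
calibration experiment, mirroring a single instrument cutoff mapped
through each model's link.

## Genome scanning

The free-energy track is `F(p) = −log Σ_s exp(−E(p, s))` over spacer
lengths, with each configuration aligned at the last base of its −10
element, computed by sliding block sums in O(G·contacts) time; the track
is offset so its minimum is zero, edges where no full configuration fits
are trimmed, and a circular mode wraps bacterial chromosomes (linear
scanning is the default).  Positions are *within genes* if covered by a
CDS/gene feature and *inter-genic* if covered by none of the excluded
annotation types (the exclusion list wins).

Depletion of strong sites is tested against (i) an i.i.d. GC-matched
synthetic genome — cumulative counts below each energy bin edge are
rescaled to the region size and used as Poisson means, the lower-tail CDF
being the one-tailed p-value — and (ii) 100 column-shuffled energy
matrices evaluated on the real genome, with Gaussian per-bin p-values and
an empirical 3rd–97th percentile band.  Bin edges are fixed-width in
k_B·T over a configurable range and recorded in the output.  Promoter
free energies integrate `−log Σ exp(−F_raw)` over a symmetric 40-bp
window around each transcript start.

## Problem sizes used in validation

The validation experiments regenerate everything from scratch: occupancy
oracle equivalence on 1000 random sequences (lengths 31–60); matrix and
spacer recovery from a 10,000-mutant P_R-like 4-bin library at depth 100
(the library mixes spacer-length-variant wildtypes at 70/10/10/5/5%,
emulating oligo-synthesis length variation — without any spacer variation
the non-optimal penalties are unidentifiable — and its no-expression gate
sits at an instrument-style floor under which ~85% of random constructs
fall); pairwise-interaction recovery from a 12,000-sequence fully-random
library under the compact 12-contact geometry (a scaled-down analog of
the pooled >30,000-mutant setting; smaller libraries leave the weakest
planted terms below the 3σ detection limit); the 12-bin debias round trip
at n = 2000, depth 150, bias factor 1.6 per bin; evolution on 20 random
115-bp starts × 20 replicates at N = 100; and null calibration on
independent 300-kb i.i.d. regions against a 6-Mb synthetic null (20× the
region, so its estimation noise is negligible) with 100 shuffled
matrices.  Because cumulative energy bins are nested, one unlucky region
draw flags many bins together; calibration is therefore summarized as the
median over region replicates of the per-region flagged-bin fraction,
with bin edges confined to the strong-site tail that the depletion
analysis targets.

The evolution and genotype-space-survey experiments mirror the original
two-model comparison: the Extended and the Standard model are *separately
fitted* to the same synthetic library, and each evolves toward (or is
surveyed against) its own measurable-expression cutoff, obtained by
translating the sorter floor into that model's log10 P_on units through
prevalence matching on the training library.  With a single shared
parameter set the two phenotype maps are nearly equally hard to climb and
the exit-time ratio hovers at 1; the asymmetry between the models — like
the original result — arises from what each fitted model learns.

## Known limitations

* The UP element, −10/−35 avidity, and sequence-dependent clearance are
  deliberately out of scope.
* The Standard-model objective is piecewise-smooth (the argmin switches
  sites), so its optimizer guarantees are weaker than the Extended
  model's; warm starts from the consensus seed behave well in practice.
* The dinucleotide funnel controls false positives through its σ filters
  but does not guarantee their absence; accepted sets typically include a
  few small-magnitude extras alongside the true interactions, as in the
  original procedure.
* Filters treat records independently; systematic artifacts correlated
  across sequences (e.g. shared PCR jackpots) are not modeled.
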