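# Methods

This note records the models, conventions, and design choices behind
`topohrv`, at the level of detail a maintainer or reviewer needs to
reproduce or audit results.

## 1. From R peaks to analysis windows

Input is a strictly increasing sequence of R-peak times (seconds) plus one
sleep-stage label (W/R/N) per 30-s epoch.

**Artifact correction.** Each RR interval is compared with the median of the
five intervals centered on it (window clipped at the borders).  An interval
below `low_ratio` × median marks a spurious detection: the later beat of the
pair is removed.  An interval above `high_ratio` × median marks missed
beats: the gap is split into round(gap/median) equal parts.  The rule is
re-applied until stable and is idempotent on its own output.  Defaults
`low_ratio = 0.7`, `high_ratio = 1.4` are conventional HRV artifact bounds;
the source protocol fixes only the 5-beat median structure, so both ratios
are exposed in `PipelineConfig`.

**IHR.** The instantaneous heart rate is 60/(r_i − r_{i−1}) bpm at knot r_i
(i ≥ 2), interpolated onto the absolute 0.25-s grid with scipy's PCHIP
(shape-preserving piecewise cubic).  PCHIP preserves local monotonicity, so
interpolated values never overshoot the surrounding knot range; a uniform
train at RR = 1 s yields exactly 60 bpm everywhere.

**Windows.** For epoch j (1-based; epoch j covers ((j−1)·30, j·30] s) the
window is the 360 samples t_j − 359/4 … t_j at 4 Hz, minus their median
(median-centering absorbs inter-individual heart-rate level).  Discarded
are: epochs 1–2 (no 90-s history), epochs whose own 30-s span holds fewer
than 5 corrected beats, and epochs whose 90-s span is not fully covered by
the IHR grid (the grid starts at the second beat and ends at the last, so
the first and final epochs of a recording typically drop out).  The
"< 5 beats" rule is evaluated on the 30-s epoch, not the 90-s window.

## 2. Persistence engines

**Simplexwise order.** Everywhere, simplexes entering at the same value are
ordered by (dimension, lexicographic vertex tuple); edges by (length, i, j),
triangles by (diameter, i, j, k).  This fixes the pairing for ties and makes
every diagram deterministic, including for degenerate inputs (duplicate
points, constant windows).

**Generic engine** (`compute_persistence`): classic Z2 column reduction of
the filtration-ordered boundary matrix; dim-0 merges follow the elder rule
(the component whose minimum entered later dies).  Zero-persistence pairs
are legal output of this core.  It is written for explicit desk-scale
filtrations and serves as the oracle for the optimized paths.

**Sub-level engine** (`sublevel_diagram`): union-find over samples in
ascending (value, index) order; a merge at value h emits (birth of the
younger component, h).  Exact value ties (plateaus) merge with zero
persistence and are not reported; the output is the min–max pairs plus the
single essential class (global minimum, ∞).  Whether the discrete series is
read as piecewise-linear or as a step function does not change these dim-0
pairs.

**Rips engine** (`vr_diagrams`): scale convention ε = diam(σ)/2 throughout.
Dim 0 is Kruskal-style union-find (finite deaths are half the Euclidean
minimum-spanning-tree edge weights; the essential (0, ∞) class is kept in
the diagram and only dropped by the featurizer).  Dim 1 uses the standard
machinery of modern flag-complex codes:

* simplexes with diameter above the *enclosing radius* (min over points of
  the max distance to the rest) are pruned — beyond it the flag complex is a
  cone, hence contractible, so diagrams in dim ≥ 1 are unchanged;
* spanning edges are *cleared* (their coboundary columns are skipped);
* *apparent pairs* — edge e whose minimal cofacet t has e as its maximal
  facet — are persistence pairs of the simplexwise filtration and are taken
  without reduction; on these filtrations they cover almost all pairs;
* the few remaining edge columns are reduced in the anti-transposed
  (coboundary) matrix with a lazy-cancellation max-heap for the working
  column and reduced columns stored as edge lists, regenerating coboundaries
  on demand.

Dim ≥ 1 output keeps only positive-persistence points (a pair with
diam(t) = diam(e) carries no class; e.g. an equilateral triangle has an
empty dim-1 diagram); dim 0 keeps death-0 pairs so duplicate points remain
visible.  With a finite `max_scale` below a death, that class is reported
with death = ∞ (truncated-filtration semantics).  `max_dim ≥ 2` falls back
to explicit enumeration through the generic engine and is meant for small
clouds only.

**Bottleneck distance**: exact, via binary search over the finite candidate
set (all pairwise ∞-norm costs and all diagonal costs) with a bipartite
perfect-matching feasibility test; diagrams with unequal essential counts in
the queried dimension are at distance ∞.  Intended for stability testing at
diagram sizes up to ~50 points, not production scale.

## 3. Persistence statistics

From a diagram's finite points, M = {(b+d)/2} and L = {d−b}.  The 16-vector
is [8 statistics of M, 8 of L] in the order mean, sd, skewness, kurtosis,
p25, p50, p75, entropy.  Conventions:

* population (biased) sd and skewness; non-excess kurtosis (normal → 3);
* percentiles with linear interpolation between order statistics;
* degenerate fallbacks: every statistic of an empty multiset is 0;
  sd/skewness/kurtosis of a zero-variance multiset are 0;
* no persistence cutoff: short- and zero-lifespan points present in the
  diagram contribute like any other.

**Entropy of signed midpoints.** The persistent-entropy formula
Σ −(v/S) log(v/S) requires non-negative masses, but the midpoints of a
sub-level diagram of a *median-centered* window can be negative, leaving
the formula ill-defined there.  The statistic therefore uses |v| as masses,
which coincides exactly with the plain definition on any non-negative
multiset (always for L, and for M from the Rips filtration).  The public
`persistent_entropy` function keeps the strict contract and rejects
negative input.

A window shifted by a constant changes only the location statistics (mean,
percentiles) of the sub-level M block — and its entropy, which is not
shift-invariant by construction — while both Rips blocks and all L
statistics are unchanged.

Feature layout (48 = 3 × 16): sub-level P₀, Rips P₀, Rips P₁, with
`FEATURE_NAMES` like `sub0_M_mean` … `vr1_L_entropy`.  The essential class
of each diagram is discarded by the M/L construction.

## 4. Classifier and evaluation

Tasks: wake/sleep (`ws`, R and N merged into S), REM/NREM (`rn`, wake
epochs excluded from both pools — the protocol leaves this open and
excluding wake is the natural reading), and 3-class (`wrn`).  Class display
order is wake, REM, NREM.

Training pools are balanced by down-sampling every majority class to the
minority size, uniformly without replacement under a fixed seed (default 1);
test sets are never balanced.  The model is libsvm's linear-kernel SVC at
C = 1 with no internal feature scaling (an optional `standardize` switch
z-scores on the balanced pool; off by default — the features enter raw).
For three classes libsvm's native one-vs-one scheme combines the three
pairwise machines.  Given data and seed, the balanced subset, model, and
predictions are fully deterministic.

Metrics from the m×m confusion matrix (rows = truth): SE_k = M_kk/row_k,
+P_k = M_kk/col_k, F1 their harmonic mean, Acc = trace/total,
EA = Σ row_p·col_p / total², kappa = (Acc−EA)/(1−EA).  Ratios with an empty
denominator are reported as 0 and flagged, so the degenerate all-majority
classifier shows sensitivity 0 for the missed class rather than NaN.
Per-subject reports give mean ± across-subject sample sd of each measure
next to the pooled values (the two differ when epoch counts differ); a
subject with no epochs of some class simply contributes nothing to that
class's averages.  AUC is the rank-based ROC area of the SVM decision
scores, emitted pooled and per subject.  Feature screening z-scores each
feature within subject, runs a two-sided Wilcoxon rank-sum test per feature,
and controls the family-wise level 0.05 by Bonferroni over the number of
features actually tested (16 or 48; recorded in the output).

## 5. Synthetic recordings

The generator is an integrate-and-fire beat model:
RR(t) = mean_rr(stage) + resp_amp·sin(2π·resp_freq·t + φ) + N(0, sd_rr),
floored at 0.3 s, with a Poisson number (default rate 2/epoch) of ~3-s
transient accelerations (RR × 0.8) during wake epochs.  Stage defaults —
wake (0.8 s, sd 0.06, weak 0.30-Hz modulation), REM (0.85 s, sd 0.045,
intermediate), NREM (1.0 s, sd 0.02, strong 0.25-Hz respiratory sinus
arrhythmia) — encode the physiology that motivates HRV sleep staging: wake
faster and more erratic, NREM slow and respiration-locked.  Everything is
driven by one seed.

What it does and does not emulate: it reproduces the data *contract*
(R-peak trains with stage-dependent rate, variability, and periodicity) and
plants a genuine class signal, so end-to-end tests demonstrate that the
pipeline extracts and classifies such structure deterministically.  It does
not model ectopy, apnea, stage-transition dynamics, circadian drift, or
recording noise, so classification scores on synthetic data say nothing
quantitative about performance on clinical recordings.

## 6. Problem sizes and numerical notes

The shipped study conditions run five synthetic subjects of 16 epochs
(three for training, two held out), i.e. ~70 Rips computations on 241-point
clouds in ℝ¹²⁰ — the package's desk-scale reference experiment; each such
diagram takes well under a second after JIT warm-up.  Oracle campaigns use
100 random filtrations (≤ 6 vertices) against brute-force Z2 ranks, 100
random series against a threshold-sweep component count, 50 random clouds
against scipy's MST, and 100 perturbation pairs for the stability bound
d_B ≤ ‖f−g‖_∞.

Floating-point notes: statistics are permutation-invariant only up to
summation order (tested at 1e−12); diagram values are exact copies of input
distances/sample values, so zero-persistence detection uses exact equality;
CSV artifacts round-trip bit-exactly (repr-faithful writing, round-trip
float parsing).

## 7. Known limitations

* Rips homology above dim 1 is supported only through the explicit
  desk-scale fallback.
* The bottleneck distance is exponential-free but still O(candidates ×
  matching) — fine for test diagrams, not for bulk distance computations.
* The 5-beat median correction is a single documented convention; real
  artifact correction may need detector-specific rules.
* REM is distinguishable from NREM in the generator mainly through
  variability and modulation amplitude; the synthetic REM/NREM contrast is
  weaker than wake/sleep, as in real HRV.
* No probability calibration on the SVM scores; AUC uses raw decision
  values.
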