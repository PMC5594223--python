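# Methods

This note documents the models, numerical choices and design decisions
behind `eegspect`, in the spirit of the methods documentation that
accompanies packages such as statsmodels or scanpy.  It describes what
the code computes and why; all empirical figures it mentions are the
quantities the test suite and `scripts/acceptance.py` themselves compute.

## The problem

The package implements a differential-diagnosis pipeline for four
clinically overlapping amnestic conditions — amnestic subjective
cognitive complaints (aSCC), amnestic mild cognitive impairment (aMCI),
Alzheimer's dementia (AD) and depressive cognitive impairment (DCI) —
from two modalities: resting-state EEG (17 channels of the 10–20
montage, 200 Hz, 3 minutes of artifact-free wakefulness) and HMPAO-SPECT
regional perfusion (46 region-to-cerebellum count ratios).  All six
pairwise group contrasts are classified with a linear SVM after an
aggressive, leakage-guarded feature-subset selection.

Because no patient data are deposited anywhere, the package ships a
synthetic cohort generator that reproduces the *structure* of such a
dataset (group sizes 41/71/39/69, channel count, sampling rate, segment
length, group-dependent directed coupling and regional perfusion means),
so every stage of the pipeline is testable end to end.

## MVAR model and estimator

EEG interactions are modelled with a multivariate autoregressive (MVAR)
process

    X(t) = Σ_{k=1..p} A_k X(t−k) + E(t),   E ~ (0, Σ).

The estimator is the Vieira–Morf variant of the multichannel Levinson
recursion: forward and backward prediction errors are updated through
reflection matrices built from the Cholesky-normalized partial
correlation of the two error sequences.  Covariances at lag stage k use
the unbiased divisor n−k.  The per-channel mean is removed before
fitting; no detrending, filtering or variance normalization is applied.
On 20 000-sample simulations the estimator recovers generating
coefficients to within a few times 1e−2 and agrees with an ordinary
least-squares lagged regression to ~1e−4 (both checked in the suite).

The production model order is p = 100 at 200 Hz (half the sampling
rate, so that one full cycle of a 2 Hz oscillation fits in the lag
window).  Correctness is order-independent, so the tests mostly use
p ≤ 5, which keeps the suite fast; the production profile (17 channels,
order 100) is exercised once on a shorter segment.

Frequency-domain transforms on the 1-Hz grid 2..80 Hz:

    Ā(f) = I − Σ_k A_k e^{−i2πfk/fs},  H(f) = Ā(f)^{−1},  S(f) = H Σ H*.

`S` is not scaled by 1/fs: only relative spectral values reach the
classifier, so the absolute power normalization is immaterial and left
out.

## Connectivity measures

Fourteen channel×channel measures are derived per frequency and then
averaged within delta (2–4), theta (5–7), alpha (8–13), beta (14–30) and
gamma (31–80 Hz).  Orientation is fixed repo-wide: entry (i, j) is the
influence of source j on sink i.  Complex quantities are reduced to real
values before band averaging — modulus everywhere, except the imaginary
part for iCOH and nothing for GGC (already real) — because the t-tests
and the SVM need real features.

* Coherency C = S_ij/√(S_ii S_jj); COH = |C| (magnitude, not
  magnitude-squared — a documented choice), iCOH = Im C, and partial
  coherence from P = S^{−1} as |P_ij|/√(P_ii P_jj).
* PDC family (column-normalized Ā): PDC, PDCF (inverse-noise-covariance
  weighting), GPDC (noise-variance weighting).
* DTF family (row-normalized H): DTF, ffDTF (normalized over the whole
  grid), dDTF = ffDTF·pCOH.
* GGC: Geweke's spectral Granger causality
  ln(S_ii/(S_ii − (Σ_jj − Σ_ij²/Σ_ii)|H_ij|²)) with the conditional
  innovation variance correcting for correlated residuals; non-positive
  log arguments (a finite-precision artifact) are clipped to 0 and
  logged.  The formula is a package choice: the measure's label admits
  several published variants.
* DC: |Ā_ij(f)| off the diagonal, 0 on it — the direct causal gain of
  the AR polynomial, used as a documented stand-in where the literature
  offers no single canonical definition.
* Raw reductions |S|, |H|, |Ā| are kept as features too; diagonals are
  retained everywhere (autospectra are informative; selection decides
  relevance).

The PDC column and DTF row normalization identities hold to machine
precision on every fitted model, structural zeros of PDC/DC are exact
under absent direct coupling, and the bounded measures stay in [0, 1];
all of this is asserted in the suite.

## Graph metrics

Each band-averaged matrix is reduced to five global summaries after
normalization (absolute values, zeroed diagonal, division by the matrix
maximum).  No thresholding or binarization is applied — the study's
choices there are unknown, and fully weighted graphs avoid an arbitrary
cut.  Metrics: out–in degree-correlation assortativity (directed);
global efficiency with edge length 1/weight (disconnected pairs
contribute 0); Fagiolo's directed weighted clustering coefficient;
modularity of the deterministic Clauset–Newman–Moore greedy partition on
the symmetrized matrix (no random restarts, so runs are reproducible);
and a weighted directed transitivity (total geometric-mean triangle
weight over total weighted triple count).  Degenerate graphs yield
flagged-missing (NaN) values that are imputed to 0, with a log entry,
when features are assembled.

## Feature scenarios

Seven scenarios assemble the per-subject features, each value carrying a
descriptor (modality, measure, band, source/sink electrode, metric or
region) so selections stay interpretable: per-measure EEG vectors
(17×17×5 = 1445 values), the 46-region SPECT vector, their
concatenation (1491), graph features (14×5×5 = 350) with and without
SPECT, and the two merged scenarios.  The merged vectors concatenate the
*optimized* (post-selection) per-measure vectors — and, for the +SPECT
variant, the optimized SPECT vector — deduplicated by descriptor; the
pipeline executes the per-measure runs first to honor this dependency.
Whether duplicates should be kept is unknowable from the study;
deduplication was chosen and is asserted in tests.

## Nested classification

The classifier is a linear 2-norm soft-margin SVM (squared-hinge slack
penalty, scikit-learn's LinearSVC, solver tolerance 1e-4).  Features are
standardized with training-set means/variances before every fit — the
original study is silent on scaling; the choice is applied identically
across all scenarios.

The three layers: a single stratified 90/10 outer split (the design
describes one division, not an outer k-fold; a repeated-outer variant is
available but off by default); a stratified 10-fold middle layer over
the outer training set, each fold running its own pooled-variance
two-sample t-test ranking (ascending p, ties by original index) and
greedy forward selection; and an inner stratified 10-fold CV scoring
each candidate vector.  Inner folds are drawn once per middle fold and
reused for all candidates, so accuracy comparisons are exact — they are
carried out on rational fold counts (`fractions.Fraction`), avoiding
floating-point tie artifacts.

Greedy inclusion criteria for a candidate (the running maxima are over
all previously *evaluated* candidates, which is what makes criterion (i)
"at least as high as the maximum of the previously obtained accuracies"
meaningful): (i) overall inner-CV accuracy ≥ running maximum; (ii) if
the best sensitivity (first-group accuracy) so far is < 0.75, the
candidate's sensitivity must be ≥ that best; (iii) if the best
specificity so far is < 0.5, the candidate's specificity must be > that
best.  Search stops on feature exhaustion, at 40 selected entries
(growth cap), or after consecutive rejections exceeding 10% of the
available features.  Votes across the 10 folds are consolidated at
thresholds 3, then 2, then 1 of 10; at most 41 features survive (90% of
the 46 SPECT regions — the design's cap), most-voted first, ties broken
by better mean position in the fold selections and then by index.  The
growth cap (40, during search) and the final cap (41, after voting) are
different stages, not a contradiction.

Reported metrics: overall accuracy, per-group accuracies (the
sensitivity/specificity analogue for pairwise contrasts), and the
maximum-chance criterion max(n1, n2)/(n1+n2) — for the published group
sizes this gives 0.63, 0.63, 0.65, 0.51 and 0.64 for the five
arithmetically consistent pairs (chance levels are reported rounded to
2 decimals, half away from zero).

Leakage guarantees: the outer test subjects never enter the t-test
ranking or the inner CV.  This holds by construction and is asserted by
an instrumentation test on the logged fold compositions.

## Synthetic cohort

The EEG generator *is* an MVAR process — deliberately the same family
the analysis fits, so that parameter recovery is an exact oracle rather
than an approximation.  Defaults: order-5 templates built from a damped
10 Hz resonance per channel (pole radius 0.92) plus group-specific
directed couplings at lag 1; innovations are unit-variance Gaussian.
Per-subject variability is multiplicative Gaussian jitter on the
coefficients (sd = 5% of each entry's magnitude), which preserves
structural zeros and hence the directed coupling structure; jittered
models are rejection-sampled for stability (≤ 100 retries).  Burn-in is
max(1000, 10·order) samples.

SPECT profiles are independent Gaussian draws per region around
group-specific means (baseline ratio 1.0, sd 0.05), truncated at zero by
redraw — not clipping — so small-sd means stay unbiased.  The group
patterns emulate textbook regional hypoperfusion: temporo-parietal and
posterior cingulate deficits of −0.06..−0.15 for the AD spectrum, a mild
frontal reduction for DCI.  No quantitative effect sizes for the group
differences exist in print; these are one-time package choices at a
magnitude a nuclear-medicine reader would call plausible, and they are
not tuned.

What the generator does *not* emulate: volume conduction and reference
effects, EEG artifacts, nonstationarity, 1/f broadband structure,
inter-subject electrode geometry, or correlated SPECT noise.  Passing
tests therefore demonstrate that the pipeline's machinery is correct and
calibrated (null cohorts classify at chance; injected effects are
recovered), not that the published patient-data accuracies are
reproducible — they cannot be, without the data.

## Problem sizes in the tests and acceptance script

The suite runs the reduced profile: 4-channel order-5 cohorts of 24
subjects per group with 10–15 s segments for end-to-end runs, 20 000
samples for estimator oracles, 20 null cohorts for calibration, and a
single order-100/17-channel fit as the production-profile check.  These
sizes are the package's own verification choices; the library itself has
no such limits.

## Known limitations

* The exact formal definitions of DC (and the precise COH/GGC variants)
  used in the original toolbox chain are not published in the main text;
  the implemented formulas are stated above and tested against analytic
  oracles, but equivalence with any specific toolbox is not claimed.
* PDC and DTF are invariant under *uniform* signal rescaling (asserted);
  they are not invariant under per-channel rescaling — that is precisely
  the motivation for GPDC — so no such claim is tested.
* Modularity uses a deterministic greedy agglomeration; it can return a
  sub-optimal Q on graphs where better partitions exist (the exhaustive
  oracle test covers a case where it is exact).
* The outer layer is a single 90/10 split; held-out accuracies on small
  test sets are coarse (multiples of 1/n_test), which is faithful to the
  design but makes single-run accuracies noisy.
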