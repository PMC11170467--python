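# Methods

## Overview

`eegconn` implements a multi-metric description of whole-brain functional
connectivity from region-level (source-space) EEG time series, together
with the statistical machinery needed to turn that description into group
contrasts and a classifier.  The registry of measures contains 101
configurations: four frequency-domain families — linear connectivity (LC),
coherence (Coh), nonlinear connectivity (nLC) and phase synchronization
(PS) — each decomposed into an instantaneous, a lagged and a total part and
evaluated in eight bands (δ 1.5–4, θ 4–8, α1 8–10, α2 10–13, β1 13–18,
β2 18–21, β3 21–30, γ 30–40 Hz), plus five broadband time-domain measures
(Pearson ρ, Gaussian-copula MI, conditional MI, symbol-weighted MI and
O-information).  4 × 3 × 8 + 5 = 101.

## Spectral decomposition

For a region pair with band cross-spectral matrix
S = [[Sxx, Sxy], [Syx, Syy]], the total linear dependence is the
log-determinant ratio

    F_total = ln(|Sxx| |Syy| / |S|),

the instantaneous (zero-lag) part replaces every block by its real part,

    F_inst = ln(|Re Sxx| |Re Syy| / |Re S|),

and F_lagged = F_total − F_inst.  All three are non-negative; LC reports
them directly (nats) and Coh maps each through ρ² = 1 − exp(−F), which
bounds it in [0, 1] and replaces additivity by the multiplicative identity
(1 − ρ²_tot) = (1 − ρ²_inst)(1 − ρ²_lag).  nLC and PS apply the same two
forms to the cross-spectrum of amplitude-normalized Fourier coefficients,
making them phase-only.  On univariate blocks (one mean series per region)
the forms reduce to scalar expressions of the complex coherency
c = Sxy/√(Sxx·Syy): total |c|², instantaneous Re(c)², lagged
Im(c)²/(1 − Re(c)²).  Both the general determinant forms and the vectorized
scalar path are implemented; tests pin them against each other at 1e-10.

The imaginary part of a cross-spectrum is untouched by any real
instantaneous mixing of sources, which is why the lagged parts are blind to
volume conduction; the instantaneous parts absorb it.  This is the reason
for carrying the decomposition rather than a single coherence number.

### Estimation choices

The cross-spectrum is estimated from non-overlapping 2 s epochs with a Hann
taper (0.5 Hz resolution, hence ≥ 3 usable bins in the narrowest band, α1);
Fourier-coefficient outer products are averaged over epochs and over the
bins whose center lies in the half-open band interval [f_lo, f_hi), so
adjacent bands never share a bin.  The Hann taper correlates neighbouring
bins, which reduces the effective number of averaged products by roughly
the main-lobe width — the sampling-noise floor of the estimates is
correspondingly higher than an independent-bin count would suggest, and
tests account for that.  Tiny negative lagged components from float
cancellation are clamped to zero; anything below −1e-8 is treated as an
invalid input.  Results of this estimator are property-reproducible rather
than bit-comparable with other software, since epoch length, taper and bin
weighting are estimator choices.

## Time-domain measures

All information measures use the Gaussian-copula estimator: marginals are
rank-transformed (average ranks on ties, scaled by 1/(n+1)) and pushed
through the inverse normal CDF; entropies are then closed-form Gaussian
entropies of the transformed covariance, in nats.  The estimator is exactly
invariant to strictly monotone marginal transforms.  MI(X;Y) =
H(X) + H(Y) − H(X,Y); CMI conditions a pair on the multivariate block of
every other region, which requires roughly ten samples per conditioning
dimension (enforced; an ill-conditioned joint covariance, condition number
above 1e10, is an error advising shrinkage or a smaller parcellation).

The symbol-weighted MI multiplies MI by the similarity
s_w = 1 − Hamming/length between the pair's local-trend symbol streams
('a' for a strictly increasing triple, 'b' for strictly decreasing, '0'
otherwise — exact ties fall into '0'), so 0 ≤ WMI ≤ MI.

O-information is evaluated pair-vs-rest over three blocks {x, y, Z}:
Ω = (n−2)H(all) + Σ_j [H(block_j) − H(all minus block_j)] with n = 3.
Positive values mark redundancy-dominated structure, negative synergy; with
fewer than three blocks it is identically zero.  The pairwise (3-block)
reading is a design choice: the statistic is defined for n scalar
variables, and treating the rest of the brain as one block matches the
pair-against-rest question the pipeline asks.  Whole-matrix evaluation
computes the copula transform and covariance once per subject and reads
every pair value off sub-determinants; tests pin it to the per-pair
operations.

## Synthetic cohorts

The generator emulates a two-group resting-state study at configurable
scale.  Desk-scale defaults: 16 regions, 10 subjects per group, 256 Hz,
60 s; the full-scale condition (82 regions, 512 Hz, 300 s = 153 600
samples) is reached by overriding fields.  Each region's signal sums
eight noise-driven AR(2) band oscillators (poles at the band centers,
amplitudes falling as 1/√f to mimic the 1/f resting spectrum) and a
broadband noise floor.

A planted coupling adds a lagged copy of the driver's band oscillation to
the receiver with coefficient s, giving band coherence ≈ s²/(1+s²) —
analytic and strictly monotone in s.  (A VAR cross-term formulation was
tried first and rejected: the coupled signal then passes through the
receiver's resonator, and near the pole the coherence saturates at ~1
regardless of the coefficient, so coupling strength had no usable effect on
band-averaged coherence.)  Coupling graphs must be acyclic per band and
group; cycles are rejected as unstable.  Default planted lags sit near a
quarter period of the band center so the dependence loads on the lagged
part.  Broadband ("time-domain") effects are planted as shared innovations
between the noise components of a pair.  Volume conduction is emulated by
post-hoc instantaneous mixing x ← (1−m)x + m·(ring-neighbour average) —
zero-lag by construction.  Default coupling strength is 0.9 (band) and 0.8
(broadband), present in one group only; these are deliberately large,
chosen so that recovery tests pass with margin at 10 subjects per group,
and make no claim to patient physiology.

What the generator does not emulate: realistic lead fields or voxel grids,
artifacts, non-stationarity, 1/f slope variation across subjects, and
spatially graded (distance-dependent) mixing.  Passing tests therefore
demonstrate the machinery's correctness and calibration, not expected
effect sizes or classification scores on real cohorts.

## Edge selection and consistency

Each (configuration, pair) cell is tested patient-vs-control with a
two-tailed permutation test: statistic |mean(A) − mean(B)|, p =
(b+1)/(n_perm+1) with 5000 label permutations by default (the +1 convention
avoids zero p; the minimum attainable p is therefore 1/5001 ≈ 2e-4, which
matters because the BH step-up threshold for a single survivor among 120
edges at α = 0.05 is ~4e-4 — fewer permutations can make survival
impossible).  BH-FDR is applied per configuration across its edges; the
correction family is a design choice matching per-metric reporting.
Direction (hypo = patients below controls, hyper = above) is assigned from
the observed means; only FDR survivors enter the consistency table, which
counts flagging configurations per pair and direction (maximum = registry
size, 101) and sums incident pair counts into region scores.  Lobe-level
contrasts compare region scores between lobes (pairwise two-sided t-tests,
Bonferroni over lobe pairs at the 0.005 family level; lobes with fewer than
two regions are excluded with a warning).

For recovery evaluation against planted truth, a pair counts as flagged
when at least five configurations agree.  A genuine band-limited effect is
visible to the lagged and total variants of all four spectral families
(≥ 8 configurations) and a broadband effect to the five time-domain
measures plus instantaneous spectral variants, whereas false flags come
from the correlated variants of a single family on one noisy edge and
empirically stay at ≤ 4 agreeing configurations; the five-way consensus
separates the two regimes with margin.

## Classification

Features are the FDR-surviving cells for one of three integration schemes:
one family+variant across all bands (`single_metric`), one family's three
variants across all bands (`complementary_frequency`), or the five
time-domain metrics (`time_domain`).  Training uses a stratified 80/20
train/test split; hyper-parameters (learning rate, tree depth, tree count,
row and column subsampling) are chosen by a seeded random search with a
25-iteration budget inside stratified k-fold CV on the training split only
(k = 10, dropping to 5 with fewer than 30 subjects).  Column subsampling is
part of the search space deliberately: with small cohorts many columns
separate the training sample perfectly, a single greedy split then
generalizes poorly, and decorrelated trees average over the separating
columns instead.

Reported scores (F1, accuracy, sensitivity, specificity, precision,
recall) are means with 95% CIs across held-out folds of a scoring CV whose
fold split differs from the tuning folds — reporting the winning
candidate's own CV score would carry the optimism of a max over 25
candidates (measured: shuffled-label F1 ≈ 0.60 when reporting the winner's
score, ≈ 0.49 with the separate split).  The test set is scored once.
The ROC band is a 5000-resample bootstrap of out-of-fold probabilities.
Attributions are TreeSHAP values computed by the boosted-tree library
itself; per-sample contributions sum to the margin output, and the global
ranking is mean |attribution|.

A caveat on chance-level F1: stratified CV on label-shuffled data with
3–4-subject folds is pessimistically biased (training and validation class
proportions anti-correlate), so the shuffled-label mean F1 fluctuates
around and somewhat below 0.5 depending on the shuffle seed (observed range
roughly 0.38–0.50 across seeds at 20 subjects).  This is a property of
fold-wise F1 at small n, not of the feature pipeline.

The progressive feature curve adds features in attribution-rank order
(forward inclusion; the rank comes from an all-feature fit on the training
split), records mean validation F1 at each step, and picks the smallest
feature count attaining the maximal validation F1 — ties resolve toward
fewer features, and the test set is touched once, for the optimum set only.
Forward inclusion over an importance ranking is the documented reading of
"progressive" selection; a backward-elimination variant would visit the
same curve in reverse at higher cost.

## Problem sizes used by tests and the acceptance script

Simulation-heavy checks run at desk scale as the package's own choice of
study condition: 16 regions / 10+10 subjects / 256 Hz / 60 s cohorts;
50 replicates with 1000 permutations for null FDR calibration; 5000
permutations for planted-effect selection; 20 shuffle seeds for the
chance-level control; 1000 random PSD draws for the oracle identities;
n = 20000 samples for MI recovery (absolute error ≤ 0.03 nats over
ρ ∈ {0.2…0.9}).  The progressive-curve bench uses 40+40 subjects with five
tapering-effect features and 25 noise features.

## Known limitations

- Connectivity is undirected; directed measures (Granger-type, transfer
  entropy) and cross-frequency or time-resolved coupling are out of scope.
- The copula estimator captures monotone-transformable dependence only;
  dependencies invisible to a Gaussian copula (e.g. variance coupling with
  zero rank correlation) are underestimated.
- CMI and O-information with the full rest-of-brain conditioning block
  need n ≫ n_regions samples; the guard refuses rather than shrinks by
  default.
- Consistency counts treat the 101 configurations as exchangeable votes,
  but configurations within a family are strongly correlated; counts are
  therefore not comparable across different registry compositions.
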