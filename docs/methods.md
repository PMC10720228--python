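# Methods

## Scope and data model

`connhc` operates entirely at the parcel level: its inputs are per-subject
T × P tables of regional time series, per-subject confound tables (six
rigid-body motion parameters, white-matter and CSF mean signals), a
subject manifest (id, group, sex, age, mean framewise displacement), and
an atlas lookup mapping each parcel to a network label. Image-space
operations (registration, smoothing, voxelwise extraction) are out of
scope; the package emulates a 400-parcel cortical parcellation restricted
to ten cognition-related sub-networks through its lookup table.

## Denoising

The confound model is the standard 24 + 8 expansion: the six motion
parameters, their backward-difference derivatives, and the squares of all
twelve, plus the two tissue signals with derivatives and squares.
Framewise displacement follows the Power convention,
FD(t) = Σ|Δtrans| + r·Σ|Δrot| with an assumed head radius r = 50 mm,
rotations in radians and FD(0) = 0. DVARS is the parcel-wise RMS of the
backward temporal difference; by default it is divided by its own median
so the conventional spike threshold of 3 applies to a unitless series (a
raw-RMS option exists, since published pipelines differ on this point).
Frames with FD > 0.5 mm or DVARS > 3 each contribute a one-hot spike
regressor (union semantics). Confound plus spike regression is ordinary
least squares per parcel, with rank-deficient confound sets repaired by
dropping collinear columns (pivoted QR, warning emitted). Band-pass
filtering (0.008–0.08 Hz) is a zero-phase order-2 Butterworth applied
forward-backward *after* nuisance regression, matching the listed order of
the emulated pipeline. Subject-level exclusion uses mean FD > 0.3 mm,
maximum FD > 5 mm, or more than 20% of frames above the spike threshold.

## Static connectivity and edge models

FC is the Fisher z-transform (atanh) of the Pearson correlation, with r
clipped to ±(1 − 1e−7) so degenerate, perfectly correlated parcels stay
finite without materially changing any estimate. Edges are vectorized in
row-major upper-triangle order of the atlas; that order is recorded and
every matrix round-trips losslessly.

Each connection gets one OLS model
`z ~ intercept + group + sex + age_std + mean_fd` with dummy-coded factors
(reference = the control-like label; p-values are invariant to the
coding), age standardized to mean 0 and sample (n−1) s.d. 1 over the
pooled analyzed sample, and the two-sided t-test on the group coefficient
(df = n − 5). Partial η² is computed as t²/(t² + df). Removing the
covariate columns reduces the model exactly to a two-sample t-test, which
the tests verify. Edges with zero residual variance are flagged rather
than aborting a cohort run; a flagged edge with a zero group coefficient
reports p = 1, one with a nonzero (perfect-fit) coefficient reports p = 0.
Global signal regression is deliberately not offered.

## Higher Criticism

With p(1) ≤ … ≤ p(N) sorted ascending,

HC = max over i ≤ floor(alpha0·N) of √N (i/N − p(i)) / √(p(i)(1 − p(i))).

`hc2004` maximizes over all such i; `hc_plus` (default) restricts to
order statistics with p(i) > 1/N. The default alpha0 = 0.5 is the
conventional choice. The statistic can be negative. Numerical safety:
p-values are clipped to [b, 1 − b] with b = min(1/(10N), 1e−8); the bound
is small enough never to move a p-value an edge-wise test can actually
produce, so the statistic agrees with a direct evaluation to 1e−10 while
still preventing division by zero at p ∈ {0, 1}. In the degenerate case
where *every* order statistic is ≤ 1/N (an overwhelming signal), `hc_plus`
falls back to the unrestricted maximum rather than returning an undefined
value; the `hc_plus ≤ hc2004` ordering is preserved.

Significance uses a Monte-Carlo empirical null: HC computed on M
independent uniform(0,1) samples of size N (default M = 10,000, fixed
seed), with the add-one empirical p-value (1 + #{null ≥ obs})/(M + 1).
Asymptotic HC thresholds are unreliable at these N, and published analyses
rarely state the threshold they used; calibration against the exact finite-N
null is the principled alternative. Null samples depend only on
(N, variant, alpha0) and are cached and shared across scopes and replicate
runs.

## The three-level hierarchy

Level 1 tests the global edge set (all parcel-pair p-values). Level 2 runs
one HC per network over its within-network edges, plus one HC over the 45
between-network connections; between-network p-values come from models on
network-mean ("concatenated") time series and are never pooled into the
global parcel-level set. Parcel edges crossing network boundaries appear
at levels 1 and 3 only. Level 3 applies Benjamini-Hochberg FDR (q = 0.05,
via `statsmodels.multipletests`) unconditionally — no sequential
alpha-spending is imposed, so level-3 results are reported whatever
levels 1–2 decide. Within-network FDR corrects over fewer tests than
global FDR and can therefore flag edges the global correction does not;
this asymmetry is intentional and tested. P-value histograms (20 equal
bins, first-bin excess ratio) accompany every HC result as the
plausibility diagnostic for an enrichment of low p-values.

Network-mean series are unweighted means of parcel series by default; a
size-weighted mean is available when parcel sizes are supplied, since
voxel-level masks do not exist at parcel level.

## Dynamic FC states

Windowed FC uses rectangular 18-volume windows (45 s at TR 2.5 s) with
60% overlap; the step is round(18 × 0.4) = 7 volumes and is configurable
because toolboxes round this differently. Window FC is raw r by default
(a Fisher-z option exists). Windows are pooled across the whole sample
and clustered jointly with k-means (20 restarts, 300 iterations max,
fixed seed). Correlation distance is realized by standardizing each
window's edge vector to mean 0 and unit variance, after which Euclidean
k-means is equivalent to clustering on 1 − r. The cluster count is
searched over k = 2..10; the Calinski-Harabasz maximizer is selected and
the Davies-Bouldin minimizer is computed as a cross-check. On
window-noise-dominated data DB decreases monotonically with k and the two
indices disagree; the conflict is logged and CH wins. Silhouette of the
selected solution quantifies separability — values near zero are expected
even for genuine planted states, because the within-state window noise
(correlation estimates from 18 samples) dwarfs the between-state contrast.

Per-subject dynamics: NT = number of consecutive-window state changes;
MDT per state = mean length of that state's maximal runs, in (partially
overlapping) windows, undefined and flagged for unvisited states;
FRC = fraction of windows per state (sums to 1). Group comparisons follow
the conventional layout: two-sided t-test for NT (mean ± sd summaries),
Mann-Whitney U for each state's MDT and FRC (median (range) summaries).

## Synthetic cohorts

The generator draws zero-mean Gaussian series whose population correlation
matrix has block structure: 1 on the diagonal, `within_network_corr`
(default 0.5) inside networks, `between_network_corr` (default 0.1)
elsewhere. The case group's matrix additionally has round(ε·E) randomly
chosen edges shifted by ±δ (sign per edge) and is then repaired to the
nearest positive-definite correlation matrix by Higham alternating
projection (tolerance 1e−8). Effects are planted on the correlation scale
because group differences are reported as z-transformed correlation
differences, and δ of this size maps almost linearly through atanh.

Covariates: age ~ uniform(18, 32) years, sex balanced Bernoulli(0.5),
target mean FD ~ normal(0.15, 0.06) truncated at 0.01 mm and realized
through synthetic random-walk motion traces whose increments are scaled so
the expected Power FD matches the target; the realized mean FD (computed
from the written motion trace) enters both the manifest and any configured
covariate effect. Configured covariate effects act additively on the
Fisher-z edge scale, matching the linearity the analysis stage assumes.

Between-subject heterogeneity: each subject's edge set receives an
independent Gaussian perturbation on the z scale (`subject_sigma`, default
0.12) before series are drawn, with an eigenvalue-clipping repair to keep
the matrix positive definite. Without this term the only between-subject
edge variance is Fisher-z sampling noise (≈ 1/√(T−3) ≈ 0.066 at T = 234),
which would make every planted effect individually detectable and destroy
the rare-weak regime the generator exists to create; 0.12 is at the low
end of inter-subject FC variability reported for resting-state cohorts.

The switching process for dynamic analyses is a first-order Markov chain
(uniform initial state; leave probability `state_transition_prob`, default
0.05 per volume). State 1 is the subject's block-structured matrix; the
second state is a compound-symmetry "integration" matrix at the midpoint
of the within/between correlations, dissolving the network dichotomy —
the qualitative contrast repeatedly described for empirical FC states.

Default cohort: 39 cases + 44 controls, 234 volumes at TR 2.5 s. The
default parcel count is 60 (10 networks × 6 parcels) rather than the
emulated 243, keeping replicate simulation studies tractable on one CPU;
every combinatorial contract (edge counts, 45 between-network pairs) is
exercised at full scale in the tests. The rare-weak defaults ε = 0.10,
δ = 0.05 were fixed by a pilot run as the regime in which the global HC
test rejects in essentially all replicates while global FDR returns zero
discoveries in the majority — the dissociation that motivates the
hierarchy — and are frozen; they are design choices for a validation
regime, not estimates of any empirical effect size.

All randomness flows from a single integer seed through named
`numpy.random.Generator` substreams (structure, subjects, null
calibration, k-means restarts); identical seeds give bit-identical
cohorts and outputs.

## What the simulations do and do not show

The generator reproduces the statistical skeleton the analysis assumes:
block covariance, sparse-weak group shifts, additive covariate effects,
Markov state switching, motion-consistent confounds. It omits hemodynamic
autocorrelation, physiological noise spectra, spatial dependence of
parcels beyond the block structure, non-Gaussian tails, and site/scanner
effects. Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions, not robustness of the
pipeline to real fMRI artifacts. Because windowed FC of temporally white
series is slightly less autocorrelated than real BOLD windows, dynamic-FC
separability here is, if anything, conservative.

## Numerical choices and degenerate inputs

- r clipped at ±(1 − 1e−7) before atanh; HC p-values clipped at
  min(1/(10N), 1e−8).
- HC ties are harmless: the statistic depends only on order statistics and
  a stable sort is used.
- Zero-variance parcels abort static FC with the parcel named;
  zero-variance windows are flagged (NaN row) and excluded from pooling.
- DVARS standardization errors out on constant series (zero median).
- k-means is deterministic given the seed and restart count; CH/DB/
  silhouette are computed on the standardized window matrix.
- Monte-Carlo nulls require ≥ 1,000 replicates; empirical p-values use
  add-one continuity so they are never exactly 0.

## Known limitations

- The Monte-Carlo HC null assumes independent p-values. Edge-wise
  p-values are positively dependent (edges share parcels and subjects), so
  global type-I error is approximate; the p-value histogram diagnostic is
  the guard the accompanying analyses rely on, and the synthetic null
  cohort test keeps the realized rate near nominal under the generator's
  dependence structure.
- Between-network inference uses network-mean series, which favors
  broadly distributed within-pair effects over focal ones.
- No mixed-effects, robust, or Bayesian edge models; no innovated HC or
  signal-proportion estimation; no hidden-Markov or co-activation-pattern
  alternatives for the dynamic stage; states are estimated jointly across
  groups.
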