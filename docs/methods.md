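# Methods

This note documents the models, numerical choices and limitations behind
`leidakit`, in the spirit of the methods documentation of simulation and
statistics packages.

## The synthetic cohort model

The generator emulates a test-retest study: `n_subjects` (default 24) are
scanned in `n_sessions` (default 3) with several acquisition modalities, each
an 8-minute run whose TR and volume count follow typical single-band and
multiband protocols: SB-ASSET2 (TR 2.0 s, 240 volumes), MB4-ARC1 (0.75 s,
644), MB4-ARC2 (0.75 s, 645), MB6-ARC1 (0.55 s, 873). Modalities differ
*only* in (TR, T); no modality-specific noise floor is modelled because no
quantitative model of it is available — this is a deliberate limitation, so
cross-modality reliability orderings produced by the generator are not
predictions about real sequences.

### Planted states

`n_roi` regions (default 105) are partitioned into `n_networks` (default 7)
near-equal disjoint blocks with positive within-block weights — a stand-in
for reference functional-network vectors. State *j* (of `k_true`, default 5)
assigns phase offset 0 to the regions of network *j* and offset π to all
others, so the ideal phase-locking matrix of a state is +1 within its
network community and −1 across, and its ideal leading eigenvector is the
±1/√N sign vector of the community. Balanced blocks keep all planted states
equally separated in eigenvector space, which makes cluster-number selection
well-posed.

### Dynamics and the target ICC

A hidden Markov chain over the `k_true` states drives each run, with a
population per-volume self-transition probability of 0.95 (mean dwell 20
volumes) and uniform off-diagonal mass. Subject-level heterogeneity adds
N(0, σ²_between) noise to the row logits of the population matrix, and each
session adds N(0, σ²_within) on top; a softmax keeps rows stochastic. Under
a first-order (delta-method) approximation, any smooth per-session statistic
of the dynamics — in particular the stationary occurrence probability of a
state — then has intraclass correlation

    target ICC = σ²_between / (σ²_between + σ²_within),

which the generator records (defaults 0.5/0.5 → 0.5). The map from logits to
occupancy is nonlinear, so the realized ICC deviates from the target by a
few points at the default perturbation scales; recovery tests therefore use
a ±10-point band.

### Signal model

Region *i* emits

    x_i(t) = A_i(t) · cos(2π f t·TR + θ_i(t) + jitter) + ε,

where the complex baseband A·e^{iθ} follows the current state's phase offset
and *f* is a common carrier (default 0.04 Hz, inside the 0.008–0.09 Hz
resting-state band). Phase jitter is white with SD 0.2 rad; observation
noise is white with SD 0.2 (carrier amplitude 1).

At a state switch the baseband is crossfaded through a short moving-average
envelope (default 6 s) rather than switching the cosine argument abruptly.
This choice matters: an abrupt offset switch forces the estimated
instantaneous phase to sweep between patterns over roughly one carrier
period (~25 s at 0.04 Hz), filling eigenvector space with transition blends
that corrupt single-linkage cluster-validity indices. With the crossfade,
the envelope dips toward zero exactly where the phase is undefined and the
phase steps sharply at the crossover — the behaviour of any band-limited
signal at an envelope zero (compare the phase flip at the node of a beat).
Within a state the envelope is 1 and the signal is a pure cosine, so
closed-form phase-locking values hold exactly in the noise-free case.

With these defaults the generator satisfies its design contract: clean
signals keep >90% of their variance inside the pass-band, and LEiDA on a
default-size single-modality cohort selects k = `k_true` by the Dunn index
with centroid-to-planted correlations ≈ 1. The defaults were chosen while
designing the generator against that contract and then frozen.

### Motion and artifacts

Motion traces are smooth low-amplitude drifts (≈0.05 mm / 0.0005 rad sums of
slow sinusoids) plus Bernoulli spikes (default rate 0.01/volume) of 1–3 mm
on one translation axis, sized to trip the 0.9 mm framewise-displacement
flag. Noise-compartment signals (default 30, emulating white-matter/CSF
signals) mix a motion-coupled artifact time course, a slow drift and white
noise. With `artifact_gain > 0` the same artifact is added to every region's
BOLD signal with random positive loadings, creating the FD–DVARS coupling
that denoising is expected to remove; the default cohort is artifact-free so
state-detection behaviour can be studied unconfounded.

## Quality control

* **Framewise displacement**: six control points at the face centers of a
  140 × 180 × 115 mm box centered at the origin; FD(t) is the maximum
  point displacement between the rigid transforms of volumes t−1 and t.
  Rotations are applied about the box center in order x→y→z; parameters are
  small-angle in practice. FD[0] = 0 so series align with volumes. FD is
  computed between consecutive volumes (not against a fixed reference).
* **DVARS**: RMS over regions of the volume-to-volume difference, after
  scaling each region to percent of its temporal mean (per-region scaling
  chosen for scale invariance; computed over ROI signals, not voxels, since
  the pipeline operates at ROI scale). DVARS[0] = 0.
* **Component-based denoising**: confounds are the mean compartment signal
  plus the first four principal-component time courses of the compartment
  signals within the subspace orthogonal to that mean; regression designs add
  an intercept and one unit-impulse regressor per flagged volume, so flagged
  volumes are absorbed exactly. Confound regression runs before band-pass
  filtering (`apply_bandpass` can be disabled to reorder externally).
* **Band-pass**: zero-phase (forward–backward) 2nd-order Butterworth over
  0.008–0.09 Hz; the high cutoff is validated against Nyquist (relevant at
  TR 2.0 s).
* **Group QC statistics**: per-run Pearson r between FD and DVARS (volumes
  t ≥ 1), Wilcoxon signed-rank tests of before-vs-after denoising values
  (Pratt handling of zero differences; exact null when feasible, normal
  approximation otherwise), Benjamini–Hochberg FDR across modalities.

## LEiDA numerical choices

* The first and last volume of each run are discarded after phase estimation
  (analytic-signal boundary distortion); configurable.
* "Largest magnitude eigenvalue" is taken literally (max |λ|, not max λ).
* Sign convention: a vector with more than N/2 strictly positive entries is
  negated; an exact N/2 split is resolved by making the first nonzero entry
  negative (determinism).
* k-means uses Euclidean distance on the unit eigenvectors (consistent with
  the Euclidean Dunn formula), k-means++ initialization, and the best of
  `replicates` seeded restarts by within-cluster sum of squares; replicate
  seeds derive from a master seed, so runs are reproducible. Empty clusters
  are handled by the underlying solver's relocation strategy.
* The Dunn index is the single-linkage / complete-diameter form: minimum
  over cluster pairs of the minimum cross-pair distance, divided by the
  maximum cluster diameter. Distances are computed blockwise (Gram-matrix
  chunks) so pooled sets of ~20k eigenvectors fit in memory. A clustering of
  singletons (all diameters 0) returns +inf. Ties in k-selection go to the
  smaller k (parsimony).
* Lifetimes of unvisited states are missing (NaN), not 0; downstream
  reliability tables drop affected subjects pairwise and count them.
  Lifetimes are reported both in volumes and seconds; with different TRs the
  two orderings can differ and neither is asserted as canonical. The
  switching-matrix diagonal is retained in the data structure; reliability
  consumes off-diagonal cells.

## State matching

Centroids are compared by Pearson correlation of the full signed vectors
(not a binarized community), with p from the t-transform on N−2 df.
Significance uses p < α/k with α = 0.01 and k the number of states of the
solution being tested. Assignment is greedy one-to-one by descending r among
significant pairs (ties to the lower state index); greedy matching mirrors
reporting a single best network label per state. Only networks significantly
matched in every modality are carried into the reliability layer; an empty
intersection produces a warning and a graceful halt of that stage.

## Reliability layer

The ICC uses the two-way ANOVA decomposition with *sample* variances
(n−1 denominators), which makes the decomposition identity
SS_total = MSR(n−1) + MSC(s−1) + MSE(n−1)(s−1) exact. The reported score is
(MSR − MSE)/(MSR + MSE) on a ±100 scale. Here the between-subject mean
square MSR plays the role of the "between-subject mean squared error" and
the residual MSE the "within-subject" one. Note this reported form differs
from the classical consistency ICC(C,1) = (MSR − MSE)/(MSR + (s−1)·MSE);
the classical variant is available via `variant="consistency"` and is the
estimator whose population value equals the variance ratio targeted by the
synthetic generator.

Confidence intervals transform the exact F(n−1, (n−1)(s−1)) interval for
MSR/MSE through the (monotone) ICC map of the chosen variant; with MSE = 0
both bounds collapse at 100. Category bands are resolved at integer
boundaries: poor ≤ 20 < fair ≤ 40 < moderate ≤ 60 < substantial ≤ 80 <
almost perfect.

Two modalities are compared by referring

    F = (MSR_A / MSE_A) · (1 − ρ̂_B) / (1 + (s−1)·ρ̂_B)

— with ρ̂_B the consistency ICC estimated from table B — to
F(n−1, (n−1)(s−1)); the two-sided p doubles the smaller tail. For identical
tables the statistic is exactly 1 and p ≈ 0.97 (not 1: the null F is not
centred at 1). Because ρ̂_B is estimated, the test's type-I error is
slightly above nominal; simulations keep it within a 2–9% band at α = 0.05.
FDR adjustment (Benjamini–Hochberg, via statsmodels) is applied within each
metric's family of states × modality-contrasts.

## Problem sizes in tests

Unit and property tests run on small fixtures (tens of ROIs, hundreds of
volumes). The end-to-end recovery checks use a 24-subject × 3-session
single-modality cohort (≈17k pooled eigenvectors) with 20 k-means restarts,
100 generator replicates for ICC recovery, and 1000 simulated tables for CI
coverage — sizes chosen to make the stochastic assertions stable while
keeping the default suite fast.

## Known limitations

* The generator's states are geometrically idealized (balanced ±1
  communities); real phase-locking states overlap and drift, so passing
  recovery tests demonstrates correctness of the machinery, not expected
  performance on real data.
* Per-volume (not per-second) transition dynamics mean faster-TR modalities
  switch states more often in real time; modality comparisons on synthetic
  data are therefore qualitative only.
* DVARS and denoising operate on ROI signals; voxel-level mask construction
  and atlas extraction are out of scope (region tables are user-supplied).
* The exact form of the ICC-equality F-test is reconstructed from its
  degrees-of-freedom structure; alternative published variants exist.
* No hemodynamic-response convolution or scanner-physics modelling.
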