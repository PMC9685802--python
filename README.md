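# leidakit

Phase-locking brain-state detection (LEiDA — Leading Eigenvector Dynamics
Analysis) with a full test-retest reliability layer, exercised end-to-end on
synthetic multi-subject, multi-session, multi-modality BOLD cohorts with
known ground truth.

## Who this is for

Researchers studying dynamic functional connectivity in resting-state fMRI
who want to (a) detect recurrent phase-locking states from ROI timeseries,
(b) quantify how reliably the state metrics reproduce across scanning
sessions and acquisition modalities (e.g. single-band vs multiband
sequences), and (c) validate the whole analysis chain against a generative
model in which the correct answer is known.

## The method

For each region *n* of an ROI-by-time matrix, the demeaned signal is written
through its analytic (Hilbert) representation as *x(t) = A(t) cos θ(t)*,
giving an instantaneous phase per region and volume. The pairwise
phase-locking matrix at volume *t* is

    dPL(b, a, t) = cos(θ(b, t) − θ(a, t))

(+1 full synchrony, −1 anti-phase). Its leading eigenvector **V**₁(t) — the
unit eigenvector of the largest-magnitude eigenvalue, sign-normalized so most
entries are non-positive — compresses the N(N−1)/2 couplings into N numbers.
Eigenvectors pooled over all subjects and sessions of one modality are
clustered with k-means (Euclidean distance, many seeded restarts) for
k = 5…10, and the Dunn index

    Dunn_K = min inter-cluster distance / max intra-cluster diameter

selects the number of recurrent states. Per run and state, three metrics are
extracted: occurrence probability, mean lifetime, and the switching
probability matrix.

Reliability of each metric across sessions is quantified with the intraclass
correlation computed from the two-way ANOVA decomposition of the
subjects-by-sessions table,

    ICC = (MSR − MSE) / (MSR + MSE),   scaled to −100…100,

with F-based 95% confidence intervals, five descriptive bands (poor / fair /
moderate / substantial / almost perfect), F-tests of ICC equality between
modalities with df (n−1, (n−1)(s−1)), and Benjamini–Hochberg FDR over the
family of states × contrasts. States detected independently per modality are
aligned by Pearson correlation of their centroids with reference
functional-network vectors at the Bonferroni-style threshold p < 0.01/k; only
networks matched in every modality enter the reliability analysis.

Quality control follows standard fMRI practice at the ROI level: framewise
displacement from a 140 × 180 × 115 mm bounding box (six face-center control
points), DVARS in percent signal change, outlier flags (FD > 0.9 mm or
global-signal |z| > 5), component-based nuisance regression (mean compartment
signal + top-4 PCs orthogonal to it + one spike regressor per flagged
volume), and zero-phase Butterworth band-pass over 0.008–0.09 Hz.

Because real multi-session fMRI cohorts cannot ship with a package, a
first-class synthetic cohort generator plants recurrent phase-locking states
(a hidden Markov chain over phase-offset patterns tied to reference
networks), injects subject- and session-level variance on the
transition-matrix logits so the target ICC is known analytically, and
optionally couples motion spikes into the signal so denoising has something
real to remove. See `docs/methods.md` for the model and its limitations.

## Worked example

`examples/02_detect_states.py` simulates 6 subjects × 3 sessions with four
planted states and recovers them:

```
pooled eigenvectors: 4284 volumes x 60 ROIs
  k=3: Dunn index 0.209
  k=4: Dunn index 0.247
  k=5: Dunn index 0.197
  k=6: Dunn index 0.234
  k=7: Dunn index 0.246
chosen k = 4 (planted 4)
best |r| of each centroid with a planted ideal eigenvector: [1. 1. 1. 1.]
```

The Dunn index peaks at the planted number of states, and every detected
centroid correlates perfectly with the ideal eigenvector of one planted
pattern. `examples/04_reliability.py` shows the reliability layer on tables
with known variance structure:

```
stable: ICC =  83.8 (95% CI 70 to 92) -> almost perfect
 noisy: ICC =  24.9 (95% CI -9 to 56) -> fair
equality F(23, 46) = 6.83, p = 3.7e-08
```

The other examples cover cohort simulation and on-disk round-tripping (01),
quality control on a motion-contaminated run (03), and the one-shot
pipeline with its text report (05).

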