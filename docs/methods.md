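# Methods

`tebench` quantifies how routine electrophysiological preprocessing —
IIR filtering and decimation — corrupts directed-network inference with
nearest-neighbor transfer entropy (TE).  Everything is simulated: three
generative networks with known coupling graphs produce trial-based
ensembles, a preprocessing layer applies the filter/decimation
conditions, a KSG-type estimator with optimized delay embeddings scans
candidate interaction delays, a trial-shuffle permutation test decides
significance, and detections are scored against the ground truth.

## Generative models

All models are driven-noise difference equations sampled at
fs = 1250 Hz, with coupling factor γ = 0.4 and interaction delays of
2–8 samples.  Defaults are the full study conditions: 100 datasets x 20
trials x 3000 samples.

* **Linear cascade (`kus`)** — five channels: a structured input
  channel drives X2 at lag 4, which drives X3 (lag 4) and X4 (lag 8);
  X5 is pure noise.  The input is a surrogate EEG-like signal: spectral
  synthesis of a 1/f-type background (amplitude ∝ 1/f above a 3 Hz
  knee) plus a narrowband 10 Hz rhythm at a 3:1 background:peak power
  ratio, normalized to zero mean and unit variance.  One realization is
  shared by all trials of a dataset (so trial-shuffle surrogates only
  destroy trial-specific transfer, as with a fixed recorded input);
  each dataset draws a fresh realization so datasets are genuine
  independent replicates.
* **Coupled logistic maps (`clmm`)** — three branches of four channels
  plus a common sink (13 channels).  Branch m couples through the
  logistic map f(x) = αx(1−x), α = 3.576 (weakly chaotic), iterated m
  times — progressively stronger nonlinearity.  Because the map lives
  on [0, 1], inputs and noise are min–max normalized per trial and
  every driven channel is rescaled by (ςγ + V), ς = number of inputs,
  which confines it to [0, 1]; a final clip guards against float
  round-off after external noise.
* **Coupled sigmoid equations (`csem`)** — a white-noise input drives a
  four-channel cascade through f(x) = 2/(1+e^(−ax)) − 1 with a = 6, a
  crude firing-threshold nonlinearity.  A fifth, uncoupled pure-noise
  channel (a synthetic addition — the four coupled equations leave no
  null channel) completes the network for false-positive scoring.

**Noise scaling.**  Internal (dynamic) noise enters each driven
channel's recursion; external (measurement) noise is added to every
channel after the dynamics.  Both are Gaussian and scaled so their
*variance* is `noise_fraction` (default 0.25) of the variance of the
noise-free input channel.  A literal-amplitude mode
(`strict_literal_noise`, multiplier 0.25σ² instead of 0.5σ) is exposed
for sensitivity checks; with it, injected noise variance falls to
(0.25σ²)², which we consider an unintended reading.  Each trial is
simulated with 32 extra burn-in samples (beyond the longest delay
chain, 18 samples) that are discarded.

## Preprocessing

Butterworth high-pass (1, 2 Hz) and low-pass (320, 160, 80 Hz) filters
of order 4, applied causally (forward recursion, MATLAB-`filter`-like)
or zero-phase (forward–backward; designed at order 2 so the effective
order matches the causal order-4 comparison).  Decimation by r ∈
{2, 6, 10} applies a zero-phase Chebyshev-I low-pass of order 8 at
0.8·f_ny/r (passband ripple 0.05 dB — the conventional decimation
default; the upstream description is silent) and keeps every r-th
sample; simulations for decimated conditions run r× longer so trials
keep 3000 (or the configured) samples.  Zero-phase runs use odd
reflection padding (scipy defaults).  Filters are designed as
second-order sections per (fs, spec) pair and cached.

## State-space reconstruction

Each channel is delay-embedded with dimension d and delay τ chosen by
the Ragwitz criterion: minimize the one-step root-mean-squared
prediction error of a local constant predictor (mean of the k = 4
nearest states' successors, max-norm) over d = 1..9 and
τ = {0.1, …, 1.0} × ACT (rounded to ≥ 1 sample, deduplicated), where
the ACT is the smallest lag at which the autocorrelation falls to 1/e,
aggregated over trials by maximum.  Two numerical choices:

* The selection error is computed on the *newly predicted sample* only
  (the state's most recent component).  Scoring whole successor states
  would trivially reward large d — d−1 of d components are pinned
  within the neighborhood radius — and would contradict the expected
  flat error landscape on white noise.
* Temporal neighbors within one ACT (the Theiler window) are excluded
  from every neighbor search; otherwise serial correlation biases both
  the predictor and the later TE counts.  The window is capped at 100
  samples in pipeline runs.

RMSPE is pooled across trials (summed squared errors) rather than
optimized per trial; ties break toward smaller d, then smaller τ.  For
large grids the predictor may be evaluated on an evenly spaced subset
of states (`max_points`, desk-scale default 600 in pipeline runs;
neighbors are always drawn from all states).

## Transfer entropy

TE(X→Y) is estimated in its self-prediction-optimal form: the
conditional mutual information between the source state ending at
t − u and y_t, given the target state ending at t − 1.  The estimator
is the digamma/neighbor-count form: the k = 4th-nearest-neighbor
distance of each (y_t, y-state, x-state) triple under the max-norm,
with strict (<) neighbor counts within that distance in the three
marginal subspaces; units are nats (estimates may be slightly negative
under the null — an estimator-bias property, not an error).  Seeded
uniform jitter of amplitude 1e−8·σ breaks distance ties on discretized
or heavily filtered data.  The interaction delay is reconstructed as
the argmax over the scanned u range (1–10 by default, 1–100 wherever
the sigmoid model's wider scan is wanted) of the trial-mean TE, ties
toward smaller u.

Two interchangeable backends compute the neighbor statistics: a fused
all-pairs pass (numba, exact, dimension-insensitive — the default) and
a cKDTree spatial-index path.  They agree bit-exactly and both are
checked against a plain-numpy brute-force oracle in the tests.

## Inference

Per channel pair: TE per trial on the original pairing; a surrogate
pairing built by a derangement of target trials (no trial keeps its
partner — guaranteeing coupling destruction, which an arbitrary
permutation would not); the *same* delay scan run on the surrogate
pairing.  The observed statistic is the original's max-over-u
trial-mean TE minus the surrogate's max-over-u trial-mean TE, and the
permutation null swaps each trial's *whole u-curve* between the two
groups, recomputing both maxima inside every permutation (a
max-statistic permutation test).  Two cheaper constructions were
measured and rejected: testing at the original's selected u only is
anti-conservative (the max over 10 scanned delays inflates the
original mean; ~20% false positives at α = 0.05), while comparing the
two groups' fixed selected-u values with per-trial sign flips is
far too conservative (0/200 null rejections), because original and
surrogate share trials and their maxima are strongly correlated.  The
max-statistic construction restores nominal calibration (~2–5%
measured).  p = (1 + #{null ≥ observed})/(1 + n_perm), one-sided, so
the smallest attainable p is 1/(1 + n_perm).  Full fidelity uses
190 100 permutations; desk-scale runs use 10 000.  Note the floor
implies at least 6 trials are needed for significance at α = 0.05.

## Scoring

Against the ground-truth graph, per condition: FNDC (% of direct edges
not significant), FNIC = 100·(1 − p_est/p_exp) over indirect pairs
(clamped to [0, 100]; excess detections tracked separately), FP (% of
unconnected ordered pairs significant — including reversals of true
edges; indirect pairs are scored by FNIC, not FP, with a
`fp_includes_indirect` mode reproducing the older convention that
counts them as FP), and the mean absolute deviation of the estimated
from the modeled delay over *detected* direct connections.  For
decimated data the modeled delay is re-expressed at the reduced rate;
delays rounding below one sample are undetectable by design and are
excluded from delay scoring (their detections still count for FNDC).
Condition comparisons: two-sided Fisher's exact test on detection
counts and Wilcoxon rank-sum on per-dataset delay deviations, both
Bonferroni-corrected.

## Scale

Full fidelity (100 datasets × 20 trials × 3000 samples ×
190 100 permutations × d 1–9) is hours-to-days on one CPU;
`full_fidelity()` restores it.  The packaged analyses, tests and the
acceptance script run a desk-scale rendition — 2 datasets × 7 trials ×
1500 samples (3000 for the logistic-map network, whose weakest edge,
the three-input common sink, is unreliable on shorter trials), d 1–4,
10 000 permutations, and pair subsets (one logistic-map branch instead
of all 156 ordered pairs) — chosen as the smallest conditions at which
control detection is reliable and the directional filter effects are
resolvable.  Note the permutation-p floor means at least 6 trials are
required for any detection at α = 0.05.  Count criteria at this scale
are judged against binomial Monte-Carlo envelopes rather than the
asymptotic percentages.

## What the synthetic data does and does not show

The generators emulate trial-based ensembles, internal vs external
noise, known delays and graded nonlinearity — the features the
benchmark manipulates.  They do not emulate nonstationarity, volume
conduction/field spread, 1/f measurement noise, line noise, or
multivariate common drive beyond the modeled graphs, so passing tests
demonstrate estimator/pipeline behavior under the modeled conditions,
not performance on real recordings.

## Known limitations and divergences

* **Decimation stress case.**  With zero-phase anti-aliased decimation
  by 10, this pipeline *still detects* the direct couplings (at u* = 1):
  the anti-alias filter smears the now sub-sample interaction delay
  into a strong, effectively instantaneous dependence, and since signal
  and noise are attenuated equally, the estimator resolves it against
  trial surrogates.  Reference results for this setting report the
  opposite (essentially no direct detections, while indirect pairs
  whose accumulated delays exceed one decimated sample remain
  detectable) — a pattern consistent with an estimator that is
  insensitive to sub-sample-lag dependence.  The corresponding
  acceptance check is kept faithful to the claim and fails against this
  implementation; the disagreement is confined to conditions where the
  decimation factor exceeds the interaction delay.
* Indirect-pair detection (FNIC) is power-limited at desk scale; the
  packaged runs typically miss most indirect pairs even unfiltered, so
  FNIC comparisons are only meaningful directionally.
* The bivariate estimator cannot flag common-drive or cascade effects;
  multivariate/conditional TE is out of scope.
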