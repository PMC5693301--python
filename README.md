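# tebench

How does routine electrophysiological preprocessing — IIR filtering and
decimation — corrupt the inference of directed interactions with
**transfer entropy (TE)**?  `tebench` answers this with a fully
simulated benchmark: three small coupled networks with known directed
edges and interaction delays generate trial-based ensembles; a
preprocessing layer applies filter/decimation conditions; a
nearest-neighbor TE estimator with optimized delay embeddings scans
candidate interaction delays; a trial-shuffle permutation test decides
significance; and detections are scored against the ground-truth graph
as false-negative direct (FNDC), false-negative indirect (FNIC) and
false-positive (FP) rates plus delay deviations.

It is written for methods researchers and electrophysiologists who want
to quantify, on networks where the truth is known, what a given filter
or downsampling choice does to TE-based connectivity results.

## The statistic

Transfer entropy from a source process X to a target Y is the
conditional mutual information

    TE(X -> Y) = I( x⁻_{t-u} ; y_t | y⁻_{t-1} )

where x⁻ and y⁻ are delay-embedded past states (Takens reconstruction,
dimension d and delay τ chosen by the Ragwitz criterion — minimal
one-step error of a local constant predictor) and u is the candidate
interaction delay.  TE is estimated with the
Kraskov–Stögbauer–Grassberger nearest-neighbor construction,

    TE = ψ(k) + ⟨ ψ(n_{y⁻}+1) − ψ(n_{y y⁻}+1) − ψ(n_{y⁻ x⁻}+1) ⟩ ,

with k = 4 neighbors under the max-norm, Theiler exclusion of serially
correlated points, and strict neighbor counts within the k-th joint
neighbor distance (units: nats).  TE(u) is maximal at the true coupling
delay, so the argmax over a scanned u range reconstructs the delay.
Significance per channel pair comes from trial-shuffled surrogates and
a max-statistic permutation test that repeats the delay-scan selection
inside every permutation.

## Worked example

Reconstruct the interaction delay of the coupled-sigmoid network's
first edge (modeled delay: 6 samples), before and after an 80 Hz
low-pass:

```
$ python analysis/03_delay_scan.py --seed 1
control: u* = 6, peak TE = 0.2183 nats
lp80: u* = 5, peak TE = 0.0064 nats
```

(The script also writes the full curves to `results/te_vs_u.csv`.)

Unpreprocessed, the TE-vs-u curve peaks exactly at the modeled delay
(u\* = 6) with a clear peak (0.22 nats).  After a causal 80 Hz
Butterworth low-pass the curve collapses (peak TE drops ~30×) and the
reconstructed delay shifts to u\* = 5 — filtering both weakens the
detectable transfer and biases the delay estimate downward, the
benchmark's central effect.

The other drivers follow the same pattern (each writes CSVs under
`results/` and prints what it found):

```
python analysis/01_simulate_models.py    # models + ground-truth graphs
python analysis/02_filter_responses.py   # the preprocessing grid
python analysis/04_benchmark_conditions.py   # detection scoring + stats
```

## Layout

```
src/tebench/        models, preprocessing, state_space, te, inference,
                    evaluation, experiment, io
analysis/           numbered narrative drivers (simulate, filters,
                    delay scan, condition benchmark)
tests/              pytest suite incl. brute-force estimator oracles
scripts/acceptance.py   full from-scratch recomputation
docs/methods.md     models, estimator, inference protocol, scale,
                    known limitations
```
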