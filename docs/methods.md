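# Methods

## The problem

A recurring question in (bio)signal analysis — photoplethysmograms, gait,
EEG, eye movements — is whether an observed signal comes from a chaotic or a
non-chaotic dynamical system. Classifiers trained on generic windows of
simulated signals learn *something*, but nothing in such windows forces them
to attend to the one property that defines chaos: **sensitive dependence on
initial conditions**. `chaosrefine` implements a data-refinement method that
manufactures exactly that evidence from a single observed signal: groups of
subsequences that start from nearly identical reconstructed states but at
widely separated times, so that within a group the subsequent courses diverge
for a chaotic source and stay parallel for a non-chaotic one.

## The refinement procedure

Given a scalar signal `s_0 … s_{N-1}` sampled at step `dt`:

1. **Phase-portrait reconstruction.** The M-dimensional state at index `i`
   is `(s_i, s'_i, …, s^{(M-1)}_i)`, built by repeated first-order forward
   differences (each divided by `dt`), truncated to the common length
   `N − M + 1`. Repeated one-sided differences are used — rather than, say,
   central differences — because successive truncation reproduces the
   `N − M + 1` window exactly and keeps every state vector aligned with a
   concrete start index in the source. Takens delay embedding
   (`delay_embed`) is provided for signals whose dynamical order is unknown;
   choosing its delay and dimension is left to the user.
2. **Fuzzy c-means clustering** of the state vectors into `C` clusters
   (`C = min(20, ⌊√K⌋)` by default). FCM rather than a crisp clusterer so
   that cluster centers are smooth functionals of the data; crisp labels for
   the later steps come from the membership argmax (ties to the lowest
   cluster index).
3. **Subclusters.** Per cluster, the `P = 5` members nearest the center
   (Euclidean distance; ties broken by earlier time index) — the candidate
   "near-identical initial conditions".
4. **Time separation.** Each subcluster is thinned greedily in
   nearest-to-center order: a member is kept iff its start index differs by
   at least `T = 100` samples from every already-kept member. Greedy in
   distance order keeps the most representative states; a max-cardinality
   search would rarely differ and is not attempted.
5. **Random subcluster selection.** Members whose subsequence would overrun
   the source (`t > N − T`) are pruned; subclusters retaining at least
   `Rw ≥ 2` members are *eligible*. Eligible subclusters are uniformly
   shuffled (seeded) and the shortest prefix whose total refined material
   `Σ Rw·T` reaches `N` is selected, so the refined dataset is at least as
   long as — and comparable in size to — the source. If even all eligible
   subclusters fall short, everything is returned with a
   `coverage_met=False` flag rather than an error; a pool with *no*
   eligible subcluster raises `RefinementError` naming the constraint.
6. **Extraction.** One length-`T` contiguous slice of the raw source per
   retained member. Every output sample is an exact copy of a source
   sample; the manifest records subcluster centers and time shifts.

With the defaults (`M=3, C=20, P=5, T=100, Rw≥2`) a 1000-sample chaotic
signal typically yields 10–12 subsequences totalling ≥ 1000 samples across
4–6 subclusters.

### Divergence diagnostic

`divergence_ratio` quantifies sensitivity: per subcluster, for every pair of
subsequences, the maximum absolute gap over the final 10% of `T` divided by
the maximum over the initial 10% (denominator floored at `ε = 1e−12`; two
identical subsequences score 1 by convention), averaged over pairs; the
overall statistic is the median across subclusters. The 10% windows make the
measure insensitive to the phase at which an oscillatory gap is sampled;
the ratio sits near 1 for a linear oscillator and well above 1 for Lorenz.

## Simulators

Source signals come from classical fixed-step RK4 integration, observing the
first state coordinate:

| system | order | parameters | dt | chaotic |
|---|---|---|---|---|
| Lorenz | 3 | σ=10, ρ=28, β=8/3 | 0.01 | yes |
| Rössler | 3 | a=b=0.2, c=5.7 | 0.05 | yes |
| linear oscillator | 2 | ω=2π, ζ=0 | 0.01 | no |

1000 warm-up samples are discarded so the retained window sits on the
attractor. Corpus generation jitters the reference initial state (Lorenz
(1,1,1); Rössler (1,1,0); oscillator (1,0)) uniformly by ±0.5 per
coordinate, so series of a system differ only in their initial condition.
The sampling steps are chosen so a 1000-sample window spans several
characteristic oscillations: Lorenz oscillates every ~0.7 time units; the
oscillator's period is exactly 1 time unit (100 samples, conveniently equal
to `T`); Rössler's orbit takes ~5.9 time units, which is why it is sampled
at 0.05 — at 0.01 a 1000-sample window covers less than two orbits, the
reconstructed state never revisits itself ≥ `T` apart, and step 4 leaves no
subcluster with two members.

What the simulators do *not* emulate: measurement noise, drift,
non-stationarity, or the breadth of a many-system benchmark corpus. Passing
tests therefore demonstrate the pipeline's behaviour on clean,
well-sampled signals, not robustness on real sensor data (the refinement
itself applies unchanged to any single-column signal file).

## Numerical choices

* FCM: fuzzifier `m = 2` (the universal default), convergence when the
  maximum center displacement < `1e−5` or 300 iterations, seeded random
  row-stochastic membership initialization. Coincident point/center
  distances assign full membership to the first coincident center instead
  of dividing by zero. Clustering operates on the raw reconstructed
  coordinates by default (an optional per-column standardization flag
  exists for signals whose derivative magnitudes dominate the distance).
* One integer seed per refinement run; FCM initialization and subcluster
  shuffling draw from independent child streams of that seed, so a
  `RefinedSet` is bitwise reproducible from `(signal, config, seed)`.
* Degenerate inputs: a constant signal collapses every state vector onto
  one point; after time-thinning no subcluster keeps two members and the
  run fails with an explicit `RefinementError` rather than a crash.

## Classifier validation harness

The harness rebuilds, at desk scale, the comparison that motivates
refinement: train a small recurrent classifier on (a) *refined*
subsequences, (b) *original* consecutive non-overlapping length-100 windows
of the same source signals, (c) their union (*augmented*), and evaluate all
on windows chopped from held-out source signals never used for training.

The classifier is a from-scratch numpy LSTM — input layer, one hidden layer
of `U` units, dense softmax — trained with categorical cross-entropy and
Adam (lr 0.001, β₁=0.9, β₂=0.999) at batch size 64, gradients clipped at
global norm 5 for stability on raw-amplitude signals. Training series are
fed raw (no per-series normalization) by default, matching how the refined
and source datasets are deposited; `HarnessConfig(standardize=True)` enables
per-series z-scoring. The default profile is 200 epochs — enough for the
desk-scale corpora here to converge — with the full 1000-epoch setting
available through `HarnessConfig(epochs=1000)`.

The desk-scale corpus uses four system variants (Lorenz and Rössler as the
chaotic class; two oscillator frequencies, ω=2π and ω=π, as the non-chaotic
class), ~50 source signals per system. A signal whose refinement fails is
skipped and counted. **Limitation:** at this scale the classification task
is far easier than on a many-system benchmark — both refined- and
original-trained models reach high-90s accuracy, so the comparison
typically shows the refined model matching rather than decisively beating
the original one; the refined model does so from ~1/10 the training
material per source signal. The harness asserts the ordering
(refined ≥ original) and the ≥95% floor, not the full gap reported on
large external corpora.

## Known limitations

* Derivative reconstruction amplifies high-frequency noise; for real sensor
  data a noise-robust derivative or delay embedding is advisable.
* Automated selection of the embedding dimension and delay is out of scope.
* Subcluster selection is uniformly random; selecting mutually distant
  subclusters to cover the phase space evenly is a known refinement not
  implemented here.
* The time-separation filter is greedy, not optimal in subcluster size.
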