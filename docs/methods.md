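# Methods

## Model overview

The network is a two-layer spiking architecture over latency-coded
spectro-temporal input, trained without labels.

**Front end.** Waveforms are framed with a per-clip window so that every
utterance produces exactly `M = 41` analysis frames: with clip length
`L` samples, the hop is `L / (M + 1)` and the window twice that (50%
overlap). Each frame goes through a Hann window, power spectrum, a
40-band triangular mel filterbank on the HTK scale spanning 0–Nyquist,
and a natural log with an energy floor of 1e−10. No DCT is applied: the
convolutional layer relies on spectral locality, which the DCT would
destroy. Each map is then min–max normalized per sample to [0, 1], and
entries at or below the 0.1 quantile are floored to 0 (treated as silent
by the encoder). Per-sample normalization is used because the latency
code needs a bounded intensity scale and each utterance supplies its own
dynamic range.

**Latency code.** Intensity `x ∈ (0, 1]` maps to a single spike at
integer step `round((1 − x)(T − 1))` in a window of `T = 30` steps;
`x = 0` is silent. Only spike *order* matters to the learning rule, so
`T` trades temporal resolution against simulation cost; 30 steps leave
the order of distinct intensities essentially intact after rounding.
Ties are quantized to the same step rather than broken sub-step.

**Convolutional layer.** Integrate-and-fire neurons,
`V(t) = V(t−1) + Wᵀ·S(t−1)`, with `V_rest = 0` and firing when
`V ≥ V_thresh` (the ≥ convention avoids never-firing edge cases at exact
integer threshold equality). A neuron at (map `m`, position `p`) covers
frames `[p, p+6)` across all 40 bands; stride 1 gives 36 positions. The
36 positions are divided into 9 sections of 4; each (map, section) pair
has one shared 6 × 40 weight matrix. With one section the layer reduces
exactly to global weight sharing (verified by test). Conv neurons fire
at most once per sample, and lateral inhibition freezes an entire
position (all maps: no further integration or firing) as soon as any map
fires there, so per sample at most 36 conv spikes exist network-wide.
When several maps cross threshold at a position in the same step the
highest potential wins, ties to the lowest map index — a deterministic
stand-in for the instantaneous inhibition the model assumes. Freezing
(rather than cancelling accumulated potential) is our reading of
"inhibited until the next sample"; since a frozen neuron can never fire
again within the sample, the two readings differ only in unobservable
state. All membrane state resets between samples.

**STDP.** Weights start from N(0.8, 0.05²) clipped to [0, 1]. For each
winner of the STDP competition, every synapse of its shared matrix is
updated: `Δw = a⁺·w(1−w)` if the input neuron spiked strictly before the
winner's fire step, else `Δw = −a⁻·w(1−w)` — late *and absent* input
spikes both depress, so silence carries evidence of feature absence. The
`w(1−w)` soft bound confines weights to [0, 1] (property-tested under
10⁴ aggressive updates). Rates are `a⁺ = 0.004`, `a⁻ = 0.003`. Input
spikes at step `t` are integrated at update step `t+1`, so the winner's
fire step lives on the update clock and "before" means delivered at or
prior to the crossing.

**STDP competition.** Spiking neurons are visited earliest-first (under
latency coding the earliest spikes belong to the best-matching receptive
fields); ties break by crossing potential, then map, then position. An
accepted winner blocks STDP within ±4 positions in its own map and at
its exact position in all maps, until the next sample. The ±4 radius
equals the section length, so one section's shared matrix receives at
most one (coherent) update per sample; the competition makes maps
specialize on distinct features.

**Stopping rule.** With soft-bounded rates of a few 1e−3, a single
update can never exceed `a⁺/4`, so convergence must be judged on
accumulated change. Training stops when a full epoch moves no weight by
more than 0.01, or at a 20-epoch cap. At desk scale the weight drift per
epoch typically plateaus around 0.04 — a small population of mid-value
synapses keeps oscillating under competing potentiation/depression — so
the epoch cap is the effective stop; the drift history is recorded in
every report so this behavior is visible.

**Pooling and readouts.** Pooling neurons are non-firing accumulators
with unit weights, one per (map, section); their final potentials equal
the section's spike count. Evaluation is three-staged: (1) unsupervised
STDP on the training set; (2) plasticity off, pool the training set, fit
the readout on counts + labels; (3) pool the test set and score. The
split is stratified by class at 7:3 (stratification stabilizes small
synthetic runs; the protocol itself only requires a random split).

The SVM readout is a linear SVM with default regularization (any linear
decision function satisfies the contract). The tempotron readout first
re-encodes each count vector with the same first-spike rule (largest
count fires at step 0; zero counts silent; a uniform nonzero vector is
treated as all-maximal). Each class neuron sums PSP kernels
`K(Δt) = v0·(e^{−Δt/τ_m} − e^{−Δt/τ_s})`, normalized to peak at 1, with
`τ_m = 15`, `τ_s = τ_m/4` steps — the conventional kernel-shape ratio;
the decision window extends 45 steps past the encoding window so late
spikes can still drive a peak. Training is one-vs-all: only the two
error cases (missed target fire, spurious non-target fire) move weights,
each afferent by `±lr·K(t* − t_i)` at the potential peak `t*`; silent
afferents are never touched. Decoding is argmax of peak potential (ties
to the lowest class index), which is threshold-independent; learning
rate 0.05, 100 epochs with early stop on an error-free epoch.

## Synthetic data

The generator emulates the one statistical property the architecture is
designed to exploit: speech features are *local in time* — position-
locked, class-specific spectro-temporal patterns. Each class template is
a 41 × 40 map whose 4 temporal segments each contain one smooth spectral
ridge (Gaussian in frequency, width 5 bands; Hann envelope in time) at
one of 4 evenly spaced center bands. The default assignment is cyclic —
class `c` places ridge `(c+g) mod 4` in segment `g` — so all classes
share the same ridge inventory and differ only in temporal arrangement.
Summing over time therefore erases class identity exactly (tested),
which is what makes global weight sharing demonstrably weaker on this
task while local sharing separates the classes. Samples add i.i.d.
Gaussian amplitude noise (σ = 0.1) and an integer per-segment time
jitter in {−1, 0, +1}, then clip at 0. The default size is 60 maps per
class (240 total; 168 train / 72 test at 7:3) — enough for stable STDP
statistics at interactive runtimes. A calibration check keeps the task
honest: nearest-template classification of the *raw* maps must succeed
(it does, at ~100%), i.e. the pipeline's job is representation, not
miracle separation.

What the generator does **not** emulate: formant trajectories and
coarticulation, speaker variability, channel/additive acoustic noise,
global time warps spanning segment boundaries, and correlated (non-white)
spectral noise. Passing tests therefore show that the mechanisms work as
specified on data with the assumed locality structure — not that the
trained network reaches any particular accuracy on real speech corpora.

## Numerical choices and degenerate inputs

- Forward simulation is exact integer-step accounting (no time
  discretization error); the per-sample drive is computed as a batched
  one-hot × shared-weight matmul, and agreement with a per-neuron,
  per-step, per-synapse brute-force simulation is asserted elementwise to
  1e−12 on random small instances.
- A constant (zero-contrast) map normalizes to all zeros with a warning
  and encodes as all-silent; an all-silent raster produces zero spikes,
  zero pooling, and no STDP updates.
- Zero-energy audio is representable thanks to the energy floor; with
  the floor disabled it raises.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; reports embed config plus content hashes, and identical
  config + seed reproduces reports byte-for-byte.

## Known limitations

- The stopping criterion usually terminates at the epoch cap rather than
  the drift threshold (see above); accuracy is insensitive to the extra
  epochs because pooled counts stabilize much earlier.
- The tempotron hyperparameters (τ_m, τ_s ratio, learning rate, window)
  are conventional defaults, not tuned; on the synthetic task both
  readouts saturate, so the comparison between them is only meaningful
  on harder data.
- Single conv + pooling layer only; no leaky membranes, no multi-spike
  codes, no recurrent or feedback connections.
- With very small `n_steps` the latency quantization can merge distinct
  intensities; rank order is preserved but resolution is lost.
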