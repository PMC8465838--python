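# Methods

`localte` benchmarks the inference of *signed* (excitatory vs inhibitory)
structural connectivity from calcium-imaging-like recordings. Everything is
generated in silico: a ground-truth network, its spiking dynamics, a
fluorescence forward model, and the inference stage — a transfer-entropy
estimator split into local excitatory and inhibitory components — scored
against the ground truth with ROC analysis. This note documents the model,
the estimator, every calibrated quantity, and what the benchmark does and
does not show.

## Network model

**Topology.** `n = 100` point cells placed i.i.d. uniformly on the unit
square, mimicking a dissociated culture on a plate. Each ordered pair
(i ≠ j) receives a directed link with probability
`exp(-d_ij² / σ_r²)` (independent Bernoulli draws; reciprocal links are
independent; no autapses). With `σ_r = 0.3` the mean in-degree is ≈ 20
(connection probability ≈ 0.2). 80% of cells are excitatory, 20%
inhibitory, the inhibitory subset drawn uniformly. Distances are plain
Euclidean (no wrap-around): the geometry is a plated culture, not a torus.

A "realization" of the benchmark keeps the positions *and* the adjacency
fixed and redraws only the E/I label sorting; `resample_adjacency=True`
redraws everything. Redrawing labels only is the stricter test of the
estimator — the same structural graph must be re-classified under a new
sign assignment.

**Single-cell dynamics.** Quadratic integrate-and-fire with adaptation:

    τ_v dv/dt = K_v (v − v_r)(v − v_t) − w + I_S + I_ext + ξ
    τ_w dw/dt = K_w (v − v_r) − w

with a spike recorded when `v ≥ v_p`, then `v ← v_c`, `w ← w + Δw`.
Defaults: `v_r = −60`, `v_t = −45`, `v_p = 35`, `v_c = −50` mV,
`τ_v = τ_w = 50` ms, `K_v = 0.5 /mV`, `K_w = 0.5`, `Δw = 50` mV.

**Synapses.** Each presynaptic spike at `t_s` delivers, after a 1 ms
synaptic delay, an alpha-function input `g_S D(t_s) (t/τ_S) e^(1−t/τ_S)`
signed by the source class: AMPA-like excitation (`g_E = 200` mV,
`τ_E = 1` ms) and fast GABA_A-like inhibition (`g_I = 400` mV, `τ_I = 5`
ms; the 1:2 ratio is the control condition). `D` is a short-term
depression resource: `D ← α D` (α = 0.8) at each presynaptic spike,
recovering as `dD/dt = (1 − D)/τ_D` with `τ_D = 1` s, read *before*
depletion when a spike's amplitude is set. Each cell additionally receives
independent Poisson events at λ = 0.5 Hz, injected as excitatory
alpha-inputs with amplitude `g_E`, no delay and no depression — extrinsic
drive plus synaptic shot noise, the seed of spontaneous activity.

**Membrane noise — a calibrated quantity.** The model's white-noise term
is specified here by the diffusion amplitude of the membrane potential,
`g_xi`, in mV·ms^-1/2: each step adds `g_xi √Δt N(0,1)` to `v`. The
literature this model family comes from prints noise amplitudes in units
that are not dimensionally consistent for a white-noise current, so the
constant is fixed operationally: `g_xi` was calibrated once against the
*emergent regime* the model is meant to produce — population
spiking/bursting oscillations at ~0.5–1 Hz with a mix of synchronous and
asynchronous epochs, as seen in cultured networks. A scan gave 0.39, 0.68,
0.90 and 1.16 population bursts/s at `g_xi` = 1.0, 1.1, 1.2, 1.3; the
default `g_xi = 1.1` centers the band (≈ 0.7 bursts/s, ≈ 0.9 Hz mean
firing). It was not adjusted afterwards.

**Integration.** All cells advance simultaneously with classical RK4 at a
fixed `Δt = 0.1` ms; the synaptic drive is held constant within a step,
while the alpha-synapse states themselves advance with their exact
linear-ODE update (the canonical second-order realization of the alpha
function; equivalence with explicit event summation is asserted in tests).
Noise is added once per step (Euler–Maruyama splitting). Spikes are
recorded at the step where `v ≥ v_p` with no sub-step interpolation —
`Δt` is 50–200× below every analysis bin size, but the per-spike reset
truncation does accumulate over long spike trains, which is why the
step-halving convergence test checks early spikes, not a whole train.
Initial conditions: `v(0) = v_r + U(−5, 5)` mV (jitter avoids artificial
initial synchrony), `w(0) = 0`, `D(0) = 1`.

## Calcium forward model

Spike trains are convolved with the causal kernel
`A e^(−t/τ_decay) (1 − e^(−t/τ_rise))`, `A = 1`, `τ_rise = 10` ms,
`τ_decay = 700` ms (peak 0.927·A at `τ_rise ln((τ_rise+τ_decay)/τ_rise)`
≈ 42.6 ms). The kernel is a difference of two exponentials, so the
convolution is computed with two recursive exponential filters — exact on
the spike grid and O(samples). Acquisition noise is i.i.d. Gaussian with
sd = 10% of A per sample. Traces are down-sampled to 5, 10 or 20 ms frames
by decimation, keeping the **last** sample of each half-open bin
[k·b, (k+1)·b) — the frame captured at the end of the exposure — so a
spike anywhere in bin k is visible in frame k. Because decimation keeps a
subset of samples and the noise is white, adding noise to the retained
samples is distributionally identical to adding it at full resolution
first; the implementation does the former and never materializes the
full-resolution noisy array.

**Spike re-extraction (calibrated).** Binary activity is recovered from
the coarse trace by thresholding its first difference. An onset opens a
segment when the derivative exceeds `onset_threshold` (and stays positive
for `confirm_bins` further bins, discarding isolated noise fluctuations);
the segment stays open while the derivative remains above
`sustain_threshold` and every bin in between is labelled active. A
positive sustain threshold means a segment survives only while the trace
still *rises fast*, i.e. while the cell keeps spiking — without it the
segment covers the whole ~40 ms rising phase of the last transient and
each activation is smeared over ~4 extra frames. `backfill` marks the bin
preceding a confirmed onset when the trace was already rising there, which
recovers spikes landing late in a frame (most of their rise appears in the
next frame). That smearing matters: with whole-rising-phase segments the
delayed suppression produced by inhibitory synapses aliases into the
zero-delay inhibitory TE component and corrupts the delay profile of the
estimator.

Thresholds are calibrated on the control simulation against
*reconstruction* targets only (spike-recovery fraction and segment
extension vs the true binned train): deterministic traces use
onset = sustain = 0.10 (99% recovery, ≈ 2.3× extension), noisy traces use
onset = 0.30, sustain = 0.15, confirm = 1 bin (≈ 92% recovery) — i.e.
near-perfect reconstruction without noise and ~90% with 10% noise. The
recovery metric is sensitivity-style: the fraction of true spike bins
overlapped by detected-active bins, since the detector intentionally marks
whole activation segments.

## Transfer entropy and its local E/I split

For binary target X and source Y, the plug-in estimate of

    TE_{Y→X} = Σ P(x_n, x⁻, y⁻) log₂ [ P(x_n | x⁻, y⁻) / P(x_n | x⁻) ]

with target embedding `x⁻ = [x_{n−1}, …, x_{n−k_x}]` and source embedding
`y⁻ = [y_{n−d}, …, y_{n−d−k_y+1}]`. Defaults `k_x = 1`, `k_y = 2`; the bin
delay d offsets the source window, and d = 0 includes the same-bin value —
essential when the frame interval exceeds the excitatory synaptic time
constant. Base-2 logarithms (bits); any base rescales all entries
uniformly and leaves ROC analysis unchanged. Zero-count states contribute
0 (the `0·log` convention); conditionals are only formed where the
conditioning count is positive.

Each summand is routed by comparing the target's current state with the
source embedding's *activity* (active iff any entry is 1): matching states
(both active or both silent) accumulate into TE_E, opposing states into
TE_I. Silent-source states follow the same rule — {source silent, target
silent} is a hidden excitatory signature, {source silent, target active} a
hidden inhibitory one. The full embedding vector still indexes all
probability tables; only the routing uses the any-entry activity. The two
subsets partition the summands, so TE_E + TE_I = TE exactly (asserted to
1e−12), and a lagged copier/inverter has TE_I = 0 / TE_E = 0 exactly.

**Dynamical-state (ROI) conditioning.** Counts can be restricted to time
bins whose network-average fluorescence lies below a threshold, excluding
globally synchronous bursts in which pairwise statistics are dominated by
the population event. Only the current index n must be selected; embedding
vectors may reach outside the mask. The benchmark sweeps 20 evenly spaced
levels between the min and max of the average trace (the average matching
the raster's provenance, deterministic or noisy) and the evaluation stage
reports the level with the best AUC. This best-ROI selection uses the
ground truth and is therefore **not blind** — it mirrors how such
benchmarks report their accuracy ceiling; for blind use, fix
`roi_threshold` a priori.

Implementation: per-neuron embeddings are integer-coded once per
configuration; each ordered pair's joint state histogram is a single
`bincount`, and the nested ROI masks are handled by bucketing time bins by
threshold level and cumulating histograms — one pass over the data for the
whole sweep.

## Evaluation

The E (I) component matrix is scored against the boolean excitatory
(inhibitory) adjacency: entry (i, j) positive iff j→i exists *with that
sign*; absent and opposite-sign links are negatives, and all n(n−1)
ordered off-diagonal pairs enter the ROC. Curves sweep all distinct TE
values (scikit-learn, no intermediate dropping), AUC by trapezoid; NaN
scores rank below every finite value. Youden's J = max(TPR − FPR), ties
broken toward higher specificity; sensitivity/specificity are read at the
J-optimal threshold. Mean ± sd aggregate the per-realization scalars, not
pooled curves. The AUC implementation is cross-checked in tests against an
independent Mann–Whitney concordance count (ties = ½).

## Benchmark scale and reproducibility

The reference conditions are 10 realizations of 5-minute simulations. The
shipped acceptance run and test suite use **3 realizations × 5 minutes** —
enough to estimate condition means to roughly ±0.03 AUC while keeping a
full grid (two strength ratios, three bin sizes, noisy + deterministic,
three delays) in the tens of minutes on one core. Four named seed streams
(topology, labels, dynamics, acquisition noise) derive from one base seed,
so the noisy-calcium analysis reuses identical spike trains and the whole
pipeline is bit-reproducible given the seed.

## What the synthetic benchmark does not show

- The forward model superposes a fixed kernel per spike: no indicator
  binding kinetics, saturation, photobleaching, ΔF/F normalization or
  segmentation errors. Real recordings degrade detection beyond the 10%
  white-noise model.
- Best-ROI reporting is an accuracy ceiling (see above).
- Only AMPA-like and fast GABA_A-like currents are modelled; slower NMDA /
  GABA_B synapses would shift the informative delays.
- No surrogate-based significance testing: TE matrices are ranked, not
  thresholded for significance, which suffices for ROC evaluation but not
  for claiming individual links on real data.
- Passing accuracy targets here means the estimator separates signed
  couplings *under this network model's dynamics*; transfer to other
  dynamical regimes must be established separately.
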