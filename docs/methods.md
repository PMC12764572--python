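# Methods

`burstnet` simulates a burst-coding spiking vision network and the
fixed-point digital datapath it compiles to. This note records the models,
the parameter choices that matter, and the places where the design was
genuinely open.

## Neuron model

The Hindmarsh–Rose (HR) neuron is the three-variable system

    dx/dt = y − a·x³ + b·x² − z + I
    dy/dt = c − d·x² − y
    dz/dt = r·(s·(x − q) − z)

with constants a=1, b=3, c=1, d=5, r=0.001, s=4, q=−1.618, chosen so the
cell fires in bursts. `x` is the membrane potential, `y` the fast Na/K
current, `z` the slow Ca current, `I` the input current. Integration is
forward Euler at Δt = 1/256; one dimensionless time unit is treated as
1 ms so neuron and synapse time constants share a clock.

The linear HR (LHR) variant replaces x³ and x² with fixed ten- and
eight-segment piecewise-linear tables (chords with breakpoints near
±0.47 … ±1.3), which is what a multiplier-less digital implementation
evaluates. Two transcription details: the quadratic table's final
condition is corrected to x > 1.21 (the printed bound is inconsistent
with the even symmetry of the other seven segments), and a breakpoint
value belongs to the segment on its right (half-open [lo, hi) intervals).

### A structural caveat about the LHR at I = 1.5

The substitution is *not* dynamically faithful at every operating point.
Near the I = 1.5 equilibrium (x* ≈ −1.303) the stability of the rest
state is governed by the sign of C′(x) + 2·S′(x), where C′ and S′ are the
local slopes of the cubic and quadratic terms. For the true HR this is
3x² + 4x ≈ −0.13 (unstable rest → recurrent bursting). The table chords
give ≈ +0.61, and because the true value is smaller in magnitude than the
slope error of any chord at this granularity, *every* coarse
piecewise-linear substitution stabilizes the rest state: the LHR fires a
long initial spike train (~400 ms) and then settles to rest, while the HR
keeps bursting. At I = 2 both models burst recurrently and their spike
and burst rates agree to within a few percent. The trace-comparison
metrics (`compare_traces`) therefore show good HR/LHR agreement at I = 2
and a large waveform divergence at I = 1.5; the comparison window, the
initial condition (−1, 0, 0) and the 50 ms transient discard are exposed
in configuration so the comparison conditions can be swept.

## Trace metrics

`compare_traces` reports NMAE, Pearson correlation and NRMSE of the
membrane-potential series (normalized by the maximum of the reference
trace) plus a normalized frequency difference (NFD) for spike and burst
event trains: the absolute difference of mean event rates over the
window, normalized by the reference train's peak instantaneous rate
(reciprocal of its shortest interval). Spikes are upward crossings of
x = 0.8; spikes closer than 50 ms belong to one burst. Both thresholds
are configuration, chosen from the scale of the HR waveform (x spans
roughly −1.6 to 2.2; intra-burst intervals are 8–30 ms, inter-burst
gaps several hundred ms).

## Error metrics for the tables

NMAE = Σ|ref−approx| / (n·max(ref)) and NRMSE = rms(ref−approx)/max(ref)
on a uniform 10 001-point grid: [−2, 2] for x² and x³ (spanning all
breakpoints with margin), [0, 50] ms for the plasticity exponential.
On these grids the printed tables achieve NMAE/NRMSE ≈ 0.011/0.017 (x²),
0.017/0.038 (x³) and 0.0024/0.0029 (exponential).

The best-approximation search (`PiecewiseFit`) draws candidate curve
points uniformly (balanced across half-domains), connects consecutive
points with chords, extends the outer chords, scores by NMAE on a dense
grid, and grows the point budget from 2 to at most 11 until the tolerance
is met. The sampling distribution and the point-adjustment strategy are
not fully specified by the original description; pure resampling with
many restarts (default 200 per point count) is used.

## Synapses

AMPA and GABA currents are rise/decay filter pairs
(τ_dA=2 ms, τ_rA=0.4 ms; τ_dG=5 ms, τ_rG=1 ms). A presynaptic spike
arriving after the τ_L=1 ms latency makes the auxiliary variable jump by
τ_m·exp(−r/D)·J — the discrete unit-pulse reading of the spike train, as
a digital pipeline delivers it (the alternative Dirac-integral reading
scales impulses by 1/τ_r and overdrives the LHR into its linearly
extended — and there unstable — outer region). τ_m is 20 ms for pyramidal
targets and 10 ms for interneurons; r is the Euclidean grid distance
between the neurons and D the distance scale. Refractoriness is enforced
at the source: spikes within τ_rp (2 ms pyramidal / 1 ms interneuron) of
the previous one are not transmitted. Net drive is I_A − I_G, clamped at
|I| ≤ 8 (receptor saturation; the fixed-point registers saturate anyway).

## Plasticity

BTDP changes a weight from every pairing of pre- and postsynaptic burst
onsets within a trial:

    W(IBI) = (A₊ + σ/γ₊)·exp(−IBI/τ)    IBI ≥ 0
    W(IBI) = (A₋ − σ/γ₋)·exp(+IBI/τ)    IBI < 0

with IBI = t_burst,post − t_burst,pre, A₊=0.07, A₋=−0.05, γ₊=20, γ₋=25,
τ=10 ms, and σ the difference of mean intra-burst inter-spike intervals
(post − pre). Restricting σ to intra-burst intervals keeps the adaptive
rate bounded; including inter-burst gaps lets σ reach tens of
milliseconds and destabilizes the weights. The per-synapse network forms
print the depression rate as A₋ + σ/γ₋ (sign inconsistent with the bare
window); the per-synapse forms are used for network learning and the bare
window kept verbatim in `btdp_window`. The branch order is swapped for
GABA synapses (inhibitory source), and updates onto interneuron targets
are scaled by 0.4. RBTDP multiplies the pairing sum by the dopamine
deviation (D − b_D). Weights are transmitter magnitudes clipped to
[0, w_max=5]; pairings are all-to-all within the trial (the exponential
decay of |IBI| localizes them in practice).

## Actor–critic and dopamine

The critic is a 20-neuron population whose mean burst rate is the value
v(t). The dopamine variable is D(t) = v̇ + r(t) − v/τ_r with τ_r = 200 ms
(unstated in the source; exposed in config), v̇ emulated by the two
delayed critic→RPE pathways as (v(t−1.5 ms) − v(t−25 ms))/23.5, and b_D
the 10 ms trailing mean of D. Reward is emulated through the
dopamine-source drive: doubled rate for the feedback window after a
correct classification, silence for 100 ms after an error.

The plasticity gate for a trial is the mean of (D − b_D) over the
feedback window, *minus a running (exponential, α=0.1) average of that
gate over recent trials*. The running average is the critic's reward
prediction at the trial timescale: without it the gate's mean is negative
whenever accuracy is below ⅔ and reinforcement uniformly erodes all
readout weights; with it, correct trials potentiate and errors depress at
every accuracy level. 

## Network

Layer 2 holds n₂ LHR neurons (80% pyramidal, 20% interneurons) on a
rectangular grid, recurrently wired with independent probability 0.2 and
distance-attenuated coupling exp(−r/D). The pseudo-retina (2×2/stride-2
average pooling, two stages; Poisson rate coding at rate_max=60 Hz per
unit intensity) feeds fixed-weight projections into layer 2; the output
and critic layers read layer 2 out; classification is the output neuron
with the most bursts in the 500 ms evaluation window after a 50 ms
transient discard (ties resolve to the lowest index and are logged).

Desk-scale operating point (publication scale is n₂ = 5000–10000 with a
2000 ms window and tens of thousands of trials; defaults here are n₂=200,
500 ms, and a few hundred trials):

- distance scale D = 2 grid spacings. At D ≈ grid side the attenuation is
  ineffective (exp(−r/D) ≈ 0.9 for neighbours) and synchronized recurrent
  excitation runs away; local coupling produces the sparse activity the
  architecture is designed around.
- input fan-out 4% (each ganglion cell reaches a random 4% of layer 2),
  giving each layer-2 neuron ~2 ganglion inputs and sharp class tuning.
- readout sparsity 5% with delivery gain √(5000/(sparsity·n₂)) onto the
  output/critic layers — variance compensation for summing over ~10
  rather than 5000 presynaptic partners, and initial tuning diversity for
  the reward loop to align.
- learning-rate scales: recurrent BTDP × 0.02 per trial, RBTDP × 0.01
  with per-output synaptic scaling (each readout neuron's total input
  weight is held at its initial budget after every update). Synaptic
  scaling removes the common-mode component of the reinforcement
  update — at this scale all outputs participate in the same global burst
  events, so without homeostasis the output-uniform part of the update
  overwhelms the winner-specific differential part and erases tuning.
  The RBTDP scale keeps the per-trial weight reallocation at a few
  percent of each output's budget, letting the reward-correlated
  component accumulate over trials instead of random-walking the tuning.
  An optional pre-training response calibration
  (``Network.calibrate_readout``) equalizes baseline output burst counts;
  it is off by default — in testing it removed useful tuning along with
  the baseline imbalance.
- weights are |N(0, 0.2)| magnitudes: the sign of a connection is carried
  by its transmitter, and the folded magnitude keeps the 4:1
  excitation/inhibition balance physical. The readout weight masks make
  each output sample a distinct random subset of layer 2, giving the
  reward loop initial tuning diversity to align.

## Fixed-point datapath

Registers are signed Q8.20 fixed point (8 integer, 20 fractional bits;
29-bit registers). Constant multiplications are signed power-of-two
shift-add programs, decomposed greedily until the residual is below one
unit in the last place (≤12 terms; per-constant residuals are reported by
the audit). Right shifts round half-up (add 2^(k−1) before shifting):
plain truncation leaves a floor bias that accumulates into spike-phase
drift (NRMSE 0.26 vs 0.01 against the float model over a 2000 ms run).
The Euler Δt = 1/256 is a right shift by 8. The format default came from
a divergence study: Q8.16 leaves NRMSE ≈ 0.26 against the float LHR over
2000 ms; Q8.20 gives ≈ 0.011.

The learning block evaluates the BTDP window with the piecewise-linear
exponential table in the same arithmetic; its unsupervised path uses no
multiplier (audited operator counts: shifts/adds/subs/compares only) and
the dopamine-gated path uses exactly one true multiply, for the (D − b_D)
gate. In network runs the fixed datapath replaces the neuron core while
synaptic filtering stays in float (the drive is quantized at the neuron
boundary each step); the fixed-vs-float task-accuracy comparison trains
once in float and evaluates under both datapaths — weights are frozen
during testing, so the comparison isolates the arithmetic.

## Synthetic data

`make_patterns` generates 28×28 grayscale prototypes (horizontal bar,
vertical bar, diagonal, centered blob, cycling with class index) plus
additive Gaussian pixel noise (σ = 0.05), clipped to [0, 1]; default 12
images per class, split 8 train / 4 test. It emulates the *interface* of
a digit/natural-image task — distinct spatial classes under pixel
noise — not its difficulty: classes are linearly separable at the
ganglion level, images have no translation, scale or style variation,
and the class count is small. Passing the learning tests shows the
burst-coding pipeline and the reinforcement loop work end to end at desk
scale; it does not certify accuracy on real image benchmarks.

## Known limitations

- The bipolar/ganglion cell dynamics of the biological retina are not
  modeled; the encoder is a pooled rate-to-Poisson surrogate with the
  same input/output shapes (28×28 → 7×7, 32×32 → 8×8).
- The LHR tables change the bifurcation structure at I = 1.5 (above);
  waveform-level HR/LHR agreement holds at I = 2, not at I = 1.5.
- Publication-scale accuracy figures require the full image datasets and
  orders of magnitude more training trials than the desk-scale protocol
  runs; the package's learning results are statements about the
  mechanism, not about benchmark performance.  Concretely, the
  desk-scale experiment (200-neuron layer 2, 144 training trials over 6
  epochs) yields held-out accuracies above chance but far below ceiling
  and with large seed-to-seed spread: the reinforcement signal per trial
  is the covariance between the reward gate and the per-output burst
  counts, and with all outputs participating in the same global burst
  events that covariance is weak relative to the trial-to-trial noise at
  a few hundred trials.  The acceptance suite measures and reports this
  honestly rather than presenting a tuned best case.
- The actor does not implement a full policy-gradient scheme; dopamine
  gating of the readout weights is the only reinforcement pathway, as in
  the modeled architecture.
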