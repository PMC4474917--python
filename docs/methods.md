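# Methods

`balnet` simulates the development of feature-specific recurrent
connectivity in a balanced random network of spiking neurons driven by
orientation-tuned input, under a voltage-based Hebbian plasticity rule.
This note documents the model, the numerical choices, and the scope of
what the test suite can and cannot establish.

## Network model

The network holds N = 500 leaky integrate-and-fire neurons, f = 80%
excitatory (E) and 20% inhibitory (I).  Subthreshold dynamics follow

    tau_m du/dt = -u + R I(t),    tau_m = 20 ms,

with threshold u_th = 20 mV, reset/rest at 0 mV and no refractory period
(t_ref is configurable but defaults to 0).  Synapses are delta-current
("jump") synapses: a presynaptic spike deflects the postsynaptic
potential instantaneously by the PSP amplitude J (mV).  We parameterize
couplings directly by J and never materialize R or the charge Q
(J = QR/tau_m); this is exactly equivalent for delta synapses and keeps
every coupling in millivolts.

Wiring is random: each E neuron contacts each possible target
independently with probability 30% (both E->E and E->I); I neurons
contact every permitted target (100%), with no autapses.  Excitatory
synapses start at J_exc = 0.5 mV (optionally drawn from N(J_exc, J_exc)
with negative draws clipped to zero); inhibitory synapses are
J_inh = -g * J_exc with inhibition dominance g = 8 by default, i.e.
-4 mV.  The network is inhibition-dominated and operates in the balanced
regime: the mean membrane potential stays below threshold and spikes are
fluctuation-driven (asserted by a test).

Feedforward drive lumps all afferents to a neuron into one Poisson
channel of amplitude J_ffw = 1 mV whose rate follows the cosine tuning

    s(theta, theta*) = s_b [1 + mu cos 2(theta - theta*)],

with baseline s_b = 2 kHz and relative modulation mu_exc = 20% for E and
mu_inh = 2% for I targets (inhibitory tuning is deliberately weak).
Each neuron's preferred orientation theta* is a property of its input.
The model is a rate abstraction: there are no images, receptive-field
filters or LGN stages.

**PO assignment.**  The distribution of preferred orientations across
neurons is not constrained by anything upstream; we space them uniformly
on [0, 180) within each population and index neurons in ascending PO
order, so weight matrices read directly as orientation-sorted maps.

## Integration scheme

Exact integration at fixed dt = 1 ms: the leak is applied with its exact
propagator exp(-dt/tau_m) and spikes are added as jumps, so the
free dynamics carries no discretization error (a test requires the
no-input decay to match the closed form to 1e-12 relative per step).
Spikes emitted at step t are delivered at step t+1 — a one-step
effective delay that removes within-step event-ordering ambiguity; the
underlying model has no synaptic delay in continuous time.  Feedforward
Poisson counts drawn for a step (counts, not 0/1 — at 2.4 kHz and
dt = 1 ms multi-spike bins are common) are delivered within that step.
Synaptic input accumulates in ascending presynaptic-index order, fixing
the floating-point summation order; a run is bit-reproducible given
(wiring seed, protocol seed, input seed).  Simulations repeated at
dt = 0.1 ms change evoked population rates by less than 10% (tested).

## Plasticity

E->E, E->I and I->E synapses evolve under the same voltage-based rule
(I->I stays frozen; feedforward weights are never plastic; no synapse is
created or deleted — structural zeros are invariant):

    dw/dt = -A_LTD(uu) X(t) [u- - theta-]+
            + A_LTP x(t) [u - theta+]+ [u+ - theta-]+

where u-, u+ are exponential low-pass filters of the postsynaptic
voltage (tau- = 10 ms, tau+ = 7 ms), x is the presynaptic spike trace
(tau_x = 15 ms), X the presynaptic spike train, and [.]+ half-wave
rectification.  Parameters: A_LTD = 14e-5, A_LTP = 8e-5,
theta- = -20 mV, theta+ = 7.5 mV.  The depression amplitude is
homeostatic, A_LTD(uu) = A_LTD uu^2 / u_ref^2 with u_ref^2 = 70 mV^2,
where uu is the mean depolarization over a trailing 100-ms boxcar window
(an exponential window of the same time constant is available via
`homeo_exponential` for sensitivity checks).  Hard bounds: [0, 2] mV for
excitatory weights, [0, 5] mV for inhibitory magnitudes.

Numerical choices, in the order they are applied each step:

- **Threshold clamping.**  The LIF has no spike waveform, so at a spike
  step the voltage entering the filters and the [u - theta+]+ factor is
  u_th (not the overshoot, not the reset value); the reset follows the
  weight update.  This preserves the rule's spike-coincidence
  sensitivity.
- **LTD discretization.**  The delta-train in the LTD term integrates to
  one discrete jump -A_LTD(uu) [u-(t) - theta-]+ per delivered
  presynaptic spike, avoiding dt-dependent double counting.
- **Trace normalization.**  A presynaptic spike increments x by
  1/tau_x — the impulse response of tau_x dx/dt = -x + X — so x has
  units of rate.  This convention is corroborated independently by the
  inhibitory rate rule below, whose fixed point then lands exactly on
  the 5 Hz target the rule is meant to enforce.
- **LTP discretization.**  Forward Euler at dt, using the trace after
  this step's increments (a delivered spike coinciding with
  depolarization potentiates immediately).
- **Sign convention for inhibition.**  The rule evolves the magnitude
  |w| of I->E weights (stored weight -|w|): "potentiation" of inhibition
  means a larger IPSP amplitude.  E->I and I->E use the voltage of their
  actual postsynaptic target; the rule is otherwise identical across
  classes.

The alternative I->E rule (rate-homeostatic, pre/post trace rule with
learning rate eta = 0.1 and depression factor alpha = 0.01) changes the
magnitude by eta (x_post - alpha) on presynaptic and eta x_pre on
postsynaptic spikes, sharing tau_x = 15 ms traces.  With the 1/tau_x
increment its fixed point is r = alpha / (2 k tau_x) = 5 Hz for the
excitatory population.  Both its event terms are evaluated at delivery
time (one step after emission), sharing the single delivered-spike trace
array; this shifts both terms by the same step and leaves the fixed
point unchanged.

The compiled engine (a single numba kernel) is validated against a
transparent pure-Python transcription of the same step order: spike
trains must match exactly and final weights to 1e-10 mV on small
networks, for all three I->E rule settings.

## Stimulation protocols

- **Learning**: batches of 20 stimuli, 100 ms each, orientations equally
  spaced at 9 deg (the count is fixed; the spacing is our choice).
  Under uniform statistics each batch is a random permutation of the 20
  orientations; under the cardinal-biased variant stimuli are i.i.d.
  with P(0 deg) = P(90 deg) = 0.25 and the remaining mass uniform over
  the other 18 orientations.  The default learning phase is 40 batches
  (80 s of simulated experience); the g-variant presets use 20 batches.
  (The source protocol descriptions are internally inconsistent about
  40 batches vs "20 x 20 x 0.1 s = 40 s"; we standardize on 40 batches
  = 80 s for the default and keep every count configurable.)
- **Tuning probe**: 8 orientations (0, 22.5, ..., 157.5 deg), 10 trials
  of 2 s each, orientation-major order, weights frozen.
- **Spontaneous**: untuned background at s_b/2 with mu = 0 (the
  denser-connectivity variant uses the full s_b), batched in 2-s blocks
  for weight snapshots.
- **Connectivity-factor rescaling**: C in {1, 2, 4} maps
  (s_b, mu_exc, J_ffw) -> (C s_b, mu_exc/C, J_ffw/C), preserving the
  absolute rate modulation s_b mu_exc and the mean drive s_b J_ffw while
  weakening the relative input tuning.

Filters, traces and the homeostatic window are never reset between
segments; stimulation is continuous.  Phases are chained by passing the
simulator state onward (learning -> spontaneous), while probes run on a
frozen copy.  One master seed fans out through `SeedSequence` into
independent sub-seeds for wiring, stimulus order, input spikes and
shuffle surrogates, so sweeps can hold stimulus randomness fixed.

## Analysis

- **OSI** = 1 - circular variance = |sum_k r_k e^{2i theta_k}| /
  sum_k r_k; NaN for all-zero curves, which are excluded from (and
  counted alongside) population distributions.
- **Population-average tuning**: each neuron's curve is aligned so its
  input PO sits at the center of a 180-bin axis, then bin-averaged; the
  OSI of the mean curve summarizes population selectivity.
- **Membrane-potential tuning**: per orientation, the time-averaged
  potential <u> and its free-potential correction
  u_free = <u> + tau_m u_th r (tau_m in s, r in Hz), which restores the
  voltage removed by resets.  The E/I decomposition disables the
  threshold for the probed neurons only (the rest of the network spikes
  normally) and integrates excitatory- and inhibitory-source input
  separately; their sum equals the free potential by linearity (tested).
- **Weight-vs-dPO**: dPO = circular PO difference in [0, 90] deg; group
  means over similar (< 30), indifferent (30-60) and dissimilar
  (> 60 deg) pairs.  The weight-tuning OSI maps the binned
  mean-magnitude profile onto a full orientation period via
  theta = 2 dPO (mirror construction) and applies the circular-variance
  formula; this is one consistent reading of an underspecified quantity,
  and only comparisons of this index across conditions are meaningful.
- **WBI** = mean over unordered E-E pairs of |w_ij| |w_ji| (scope
  configurable); WBI_norm divides by the mean WBI of 100 surrogates in
  which the non-zero weights of the scoped block are placed uniformly
  among its off-diagonal positions (weight multiset preserved).
  WBI_norm = 1 at chance; the shuffle's self-consistency
  (WBI_norm of a random matrix in [0.95, 1.05]) is tested.  All
  unordered in-scope pairs enter the average, connected or not.

## Problem sizes and runtime

All headline simulations run at full scale: N = 500, 40 learning
batches, three independent seeds, dt = 1 ms.  A full learning run
simulates 80 s of activity in roughly 10 s of wall time; the complete
default experiment (probes + learning + spontaneous) takes about half a
minute per seed.  Probes used inside cross-condition comparisons
(connectivity-factor invariance) use 3 trials per orientation instead of
10, which leaves the population-level OSI essentially unchanged.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions exactly: lumped Poisson
drive with cosine tuning, batched random orientation sequences, biased
statistics, untuned background.  It does not emulate natural-image
statistics, temporal stimulus structure within a segment, conduction
delays, conductance-based synapses, or orientation maps; passing tests
therefore establish properties of the model class (balanced random
networks with the stated rules), not of cortical data.  Comparisons to
experimental datasets are out of scope.

## Known limitations

- Desk-scale networks only; the connectivity scaling to larger N is not
  addressed (the connectivity-factor rescaling emulates it at the input
  level only).
- The absolute scale pairing of the trace increment with A_LTP is a
  convention (see above); connectivity-specificity indices are robust to
  it, but absolute weight-change rates are convention-dependent.
- The bimodal E->E weight distribution that develops under learning is
  bounded by the hard limits, not by a fixed point; longer learning
  drives weights toward the bounds.
- Only the probed neurons are made non-spiking in the free-potential
  decomposition; suppressing the whole network would change the
  recurrent input statistics.
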