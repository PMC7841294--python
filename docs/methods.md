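# Methods

`astrosnn` couples two models: a biophysical simulator of astrocyte-mediated
synaptic self-repair at a tripartite synapse, and a single-layer unsupervised
spiking classifier whose re-training rule (A-STDP) abstracts that repair
mechanism into a form usable at network scale. This note records the models,
their assumptions, the parameters that matter, and the design choices made
where more than one reasonable option existed.

## 1. Tripartite-synapse self-repair model

### Dynamics

A small network of leaky integrate-and-fire (LIF) post-neurons, each driven
by its own pool of Poisson pre-neurons through stochastic synapses, shares a
single astrocyte. Each synapse transmits a pre-synaptic spike with its
release probability PR; a transmitted spike adds a fixed depolarization
(`kick_mv`) to the post-neuron.

Every post-synaptic spike releases the endocannabinoid 2-AG:

    d(AG)/dt = -AG/tau_AG + r_AG * delta(t - t_spike)

2-AG acts along two pathways:

* **Direct (local)**: depression of the neuron's own synapses,
  `DSE = -K_AG * AG` (DSE <= 0).
* **Indirect (global)**: 2-AG drives astrocytic IP3 production
  (`d(IP3)/dt = (IP3* - IP3)/tau_IP3 + r_IP3 * sum(AG)`); IP3 gates calcium
  release from the endoplasmic reticulum following the standard Li-Rinzel
  reduction (channel, leak and SERCA-pump fluxes with the usual gating
  variable h); each *upward* crossing of the Ca2+ threshold releases one
  glutamate bolus (`r_Glu`, decay `tau_Glu`); and the potentiating signal
  relaxes toward the glutamate level, `tau_eSP d(eSP)/dt = -eSP + m_eSP Glu`.
  e-SP is astrocyte-global: every synapse under the astrocyte receives the
  identical value.

Release probabilities follow

    PR(t) = PR0 + PR0 * (DSE(t) + eSP(t)) / 100,  clipped to [0, 1],

with faulty synapses pinned to PR = 0. DSE and eSP are on a percent scale;
the division by 100 applies to their sum (the depression gain `K_AG` absorbs
any residual scale freedom).

In the fault-free network DSE and e-SP settle into a dynamic equilibrium
that pins PR at PR0, so firing rates are stationary. When a fraction of one
neuron's synapses die, that neuron's firing — hence its 2-AG and |DSE| —
collapses while the global e-SP persists; the sum DSE+eSP turns positive for
that neuron only, its surviving synapses' PR climbs, and its firing rate
recovers toward (but, with heavy faults, not fully to) the pre-fault value.

### Parameter choices

The Li-Rinzel constants are the standard published set (v1=6/s, v2=0.11/s,
v3=0.9 uM/s, k3=0.1 uM, d1=0.13, d2=1.049, d3=0.9434, d5=0.08234,
a2=0.2 /(uM s), c0=2 uM, c1=0.185). The coupling and gain constants have no
canonical values; the packaged defaults were fixed once by the following
design reasoning and are all user-overridable through `AstroParams`:

* **Baseline IP3 = 0.45 uM** places the astrocyte in the *spontaneously
  oscillatory* regime (the oscillation window for these constants is roughly
  IP3 in [0.42, 0.7] uM, period ~11 s, weakly IP3-dependent). This makes
  e-SP a slowly varying, nearly rate-independent background signal, so the
  potentiation pathway never collapses when neuronal firing is suppressed —
  without it, the depression loop alone traps the network in a low-rate
  state from which no repair is possible. The 2-AG->IP3 gain
  (`r_ip3 = 0.0035 uM/s` per AG unit) modulates the oscillation within the
  window over the operating range of network activity.
* **Gain balance**: at the fault-free operating point (~14 Hz per neuron,
  2-AG ~ 1.4) the gains `K_AG = 245` and `m_eSP = 200` make
  DSE ~ -350 and eSP ~ +350, cancelling so PR holds at PR0 = 0.5. The
  large magnitude of the (cancelling) signals sets the loop gain: after a
  70% fault the equilibrium shifts to PR ~ 0.85 for the surviving synapses,
  which recovers ~80% of the pre-fault firing rate.
* **Toy post-neuron** (`tau_mem = 15 ms`, `delta_ref = 50 ms`,
  `kick_mv = 14 mV`): the kick is suprathreshold, so the neuron acts as a
  dead-time counter of transmitted spikes, rate = R/(1 + R*t_ref). This
  compressive f-I curve is what lets a partial PR recovery translate into a
  nearly complete rate recovery, and it keeps the fault-free rate in the
  tens-of-Hz band. Homeostatic threshold adaptation is disabled in the toy
  (`theta_plus = 0`): the point of the scenario is that the *astrocyte*
  restores the rate.
* **Slow/fast separation**: `tau_AG = 10 s` smooths Poisson rate
  fluctuations before they reach DSE; `tau_Glu = 20 s` and `tau_eSP = 40 s`
  filter the discrete glutamate boluses into a smooth e-SP. Ripple on PR at
  equilibrium is a few percent.

### Numerics

Forward Euler at dt = 1 ms for all ODEs (spike events and threshold
crossings are step-aligned; adaptive steppers interact poorly with the
event-driven inputs). Convergence is verified by a dt-halving test on the
deterministic core (< 1% change in every state variable). A negative Ca2+
excursion — possible only with a pathologically coarse step or non-physical
parameters — is clamped to zero with a warning. Upward threshold crossings
only trigger glutamate release (one bolus per oscillation peak).

Each post-neuron owns private RNG streams with fixed per-step consumption,
so a fault experiment replays the unaffected neurons' input and transmission
draws exactly. Because e-SP is global, a fault on one neuron does perturb
its neighbours weakly through the shared astrocyte; the locality test bounds
this residual at < 20% of the direct effect.

The inner loop has two interchangeable backends: a numba-jitted kernel
(default when numba is importable) and a pure-numpy composition of the
public step operations; both consume identical RNG streams and are pinned
against each other in the test suite.

## 2. Unsupervised spiking classifier

The classifier is the classic cortical-microcircuit layout: one Poisson
input neuron per pixel (rate proportional to intensity, 63.75 Hz at
intensity 255), all-to-all plastic excitatory synapses to `n_neurons` LIF
neurons with adaptive thresholds (homeostasis), and static recurrent
inhibition (`w_recurrent`, soft winner-take-all). Parameters follow the
published convention: tau_mem = 100 ms, v_rest = -65 mV, v_reset = -60 mV,
theta0 = -52 mV, theta_plus = 0.05 mV, tau_theta = 1e7 ms,
delta_ref = 5 ms, tau_trace = 20 ms, eta_post = 1e-2, eta_pre = 1e-4,
w_recurrent = -120, 350 ms exposure per image, mini-batches of 16.

Update ordering within a 1 ms step is fixed and oracle-tested: integrate
membranes -> detect spikes -> queue lateral inhibition for the next step ->
advance traces (a spike sets the owner's trace to exactly 1 after decay) ->
apply plasticity with the current-step traces. Batch replicas share the
weights and theta (per-step weight deltas and theta increments are summed
across replicas) but keep private membrane/trace state, reset between
images; theta persists across images as the homeostasis memory. Evaluation
freezes theta and disables plasticity.

Weights live in [0, w_max] with w_max = 1. Per-neuron normalization rescales
each neuron's live incoming weights to the target w_norm after every
training batch. Two constraints collide when few synapses survive: the
exact column-sum target and the per-weight bound. The bound wins —
normalization clips at w_max, and the sum target is met exactly whenever no
weight would exceed the bound. This clipping loss after heavy fault
injection is deliberate and central: it is the damage that re-training
subsequently repairs. w_norm scales with input dimensionality (78.4 for
784-pixel images, 25.6 for the 256-pixel desk task) so the mean per-synapse
weight is scale-invariant.

## 3. Fault injection and A-STDP repair

Faults delete each input->output synapse independently with probability
`p_del`; dead synapses carry weight zero, are permanently masked, and never
update. Recurrent inhibition is untouched.

Repair re-trains the faulty network on the training stream, after one
explicit weight normalization (and with the per-batch normalization of the
training loop still running — the re-training procedure is the training
procedure). The A-STDP rule scales the potentiation branch per synapse:

    dw = eta_post * x_pre * (w / w_alpha)^sigma   on post-synaptic spike
    dw = -eta_pre * x_post                        on pre-synaptic spike

with `w_alpha` the alpha-th percentile (linear interpolation between order
statistics) of the pooled weight distribution of the whole input->output
matrix, dead synapses included as zeros, refreshed every batch and floored
at 1e-3 * w_max. Defaults alpha = 98, sigma = 2. The multiplier uses the
current weight at every step. sigma = 0 reduces the rule to plain STDP
bit-for-bit (the multiplier is identically 1), which the suite checks as a
full-run equality.

w_alpha is the repair progress signal: it drops when faults (and the
subsequent clipped normalization) flatten the top of the weight
distribution, rises as strong synapses relearn toward w_max, and saturates
there, switching the enhancement off. Pooling over the whole matrix
including zeros matches this trajectory; an `include_dead=False` variant is
exposed for comparison.

Reporting conventions: sole-STDP repair is reported as the state after one
re-learning epoch; A-STDP as the maximum-validation-accuracy checkpoint over
its epoch budget (default 2), evaluated every 20 batches. Checkpoint
selection never touches the test set: each run holds out a validation slice
(1/6) of the training set, and class labels for prediction are assigned from
a fixed 500-image training subset at every evaluation phase.

## 4. Synthetic task

The generator emulates the statistical structure the classifier assumes:
each of 10 classes is a fixed 16x16 template (four oriented bars, four
corner blobs, a cross, a ring) plus i.i.d. Gaussian pixel noise
(sd 20, clamped to [0, 255]); 2,000 training and 500 test images, balanced
to +-1, train/test from disjoint RNG streams. Templates carry
Gaussian-profiled strokes (peak intensity 102) rather than binary masks, for
two reasons: graded pixel intensities produce the graded learned-weight
distribution on which the w_alpha percentile is meaningful (binary templates
collapse the weight distribution to two points and pin w_alpha at w_max),
and the reduced contrast places the trained network below ceiling (~97%
test accuracy with 50 neurons), giving the fault/degradation/repair
phenomenology its dynamic range, in the spirit of the grayscale benchmarks.

What the generator does *not* emulate: within-class shape variability
(every example of a class is the same template under noise), correlated
noise, and class imbalance. Consequently the desk task cannot show one
mechanism present at benchmark scale — re-tuning of neurons to within-class
statistics during re-training — and passing the desk-scale tests
demonstrates the fault/repair *orderings*, not benchmark accuracy values.

Problem sizes for the packaged experiment (5 independent runs, 2 training
epochs, fault levels 0.5/0.8 repaired and 0.9 fault-only) were chosen so the
full protocol completes in minutes on a single CPU; the 28x28/225-neuron
configuration used for full-scale runs is exercised end-to-end on a reduced
image count in the test suite.

## 5. Known limitations

* The astrocyte gain constants are calibrated for the packaged two-neuron
  scenario; strongly different network sizes or input rates require
  re-balancing `K_AG`/`m_eSP` (both exposed).
* Prediction abstains (counted as an error) when no labeled neuron spikes,
  so accuracy under extreme faults can fall below the nominal 10% chance
  level of a 10-class task.
* Homeostatic thresholds only grow on the experiment's timescale
  (tau_theta = 1e7 ms), so very long re-training slowly sparsifies
  responses; the best-checkpoint convention reports the peak.
* The IDX loader/writer handles the standard single-file image and label
  containers, not compressed archives.
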