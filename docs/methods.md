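# Methods

`tdcsim` simulates how transcranial direct current stimulation (tDCS)
montages interact with Alzheimer-type degeneration of a brain network
model, and scores candidate electrode placements by whether they push
spectral and functional-connectivity markers back toward healthy values.
This note documents the model, the parameter choices, the numerical
scheme, and what the synthetic study can and cannot show.

## The neural mass

Each cortical region is a lumped two-population model: an excitatory
(pyramidal) and an inhibitory population, each described by an average
membrane potential (`Ve`, `Vi`, model units comparable to mV) and a pulse
density (`E`, `I`, pulses/s).  Potentials map to pulse densities through
sigmoid threshold functions

```
S[V] = Dmax / (1 + exp(-r (V - Vd)))
```

with saturation density `Dmax = 5`, threshold `Vd1 = 7` (excitatory) and
`Vd2 = 7` (inhibitory), and slopes `r1 = 0.56`, `r2 = 2.24`.  Pulse
densities map back to potentials through second-order synaptic impulse
responses `h(t) = A a t exp(-a t)`: excitatory `A = 3.25`, `a = 100 /s`
and inhibitory `B = 22`, `b = 45 /s`.  The excitatory population receives
stochastic thalamic input `P(t)` (Gaussian per step, clipped at zero) and
the pulse densities of connected regions; the inhibitory population is
driven by the local excitatory output (gain `C1 = 86.15`) and feeds back
negatively (gain `C2 = 1.655`).

The closed excitatory-inhibitory loop is a damped resonator.  Around the
operating point its open-loop gain is

```
L(jw) = g_e g_i C1 C2 |He(jw)| |Hi(jw)|,
```

with `g_e`, `g_i` the sigmoid slopes at the fixed point.  The phase
condition puts the resonance at `sqrt(a b) / 2pi ≈ 10.7 Hz`; the defaults
place `|L|` at about 0.95 with both populations at their sigmoid
midpoints, giving a noise-driven rhythm with a spectral peak near 9.5 Hz
and realistic run-to-run variability.  The model is deliberately tuned to
the alpha band; it does not attempt a 1/f background, delta/gamma
content, or conduction delays.

**Steeper inhibitory sigmoid.** `r2 > r1` makes the inhibitory population
act as a governor: it responds sharply when excitation rises, which
stabilizes the loop near criticality without flattening the excitatory
response to threshold changes - the handle the stimulation model uses.

**Thalamic calibration.** The mean thalamic pulse density is not a free
constant: it is computed (`resolve_thalamic_input`) so that, given the
average inter-mass drive of the intact network, the excitatory potential
settles exactly at its threshold, i.e. at the sigmoid midpoint where the
rhythm is strongest.  Two consequences: the healthy network starts from
its spectral optimum, and any loss of drive moves the spectrum
monotonically downhill - there is no artifactual early alpha boost from
an off-center healthy state.  The noise standard deviation defaults to a
tenth of the calibrated mean.

## Network embedding

The standard study couples 78 masses, one per cortical AAL region, by a
symmetric binary matrix scaled by a global coupling strength `S = 1` and
a synaptic `coupling_gain = 2` (synapse-count factor per unit weight).
Coupling is excitatory and reciprocal; the excitatory output `E_j(t)` of
each neighbor feeds the excitatory synaptic filter of mass `i` as
`S * sum_j w_ij E_j(t)`.  There are no conduction delays.  The reference
diffusion-imaging connectome is not redistributable, so the package ships
a seeded generator (`generate_synthetic_connectome`) producing connected
binary graphs with a heavy-tailed degree distribution: a configurable
minority of nodes carries a boosted edge propensity (Chung-Lu style),
standing in for the hub structure of the cortical connectome.  Hub nodes
occupy the lowest indices so spatial layouts can co-locate them.

## Activity-dependent degeneration (ADD)

After every epoch (one unit of virtual time) each mass's mean excitatory
pulse density `d_i` is divided by the saturation density and clipped to
[0, 1]; every synaptic pathway touching the mass then loses a proportional
fraction of its strength:

- inter-mass edge `w_ij` is multiplied by `1 - rate * (d_i + d_j) / 2`
  (endpoint mean; symmetry preserved),
- the mass's afferent input gain - thalamic drive and inter-mass coupling
  alike - is multiplied by `1 - rate * d_i`,
- the intra-mass gains `C1`, `C2` are multiplied by
  `1 - intra_rate_scale * rate * d_i`.

Damage is permanent and floors at zero.  Because damage is proportional
to activity, the most active regions - the hubs, which receive the most
network drive - degrade first, reproducing hub vulnerability.

Design choices worth flagging:

- **Fixed-reference normalization.** Densities are normalized by the
  saturation density rather than by the momentary network maximum.  A
  max-normalized rule couples every region's damage to the single most
  active region, so a strongly stimulated region would shield the whole
  network from damage - an interaction that reverses the polarity
  ranking of montages.  With a fixed reference, damage depends on each
  region's own activity only.
- **Afferent gain in scope.** Restricting damage to the inter-mass
  weights and `C1`/`C2` can only disinhibit a two-population mass (any
  intra-mass loss weakens the inhibitory loop), so the degenerate network
  would end hyperactive and a cathodal threshold shift would *help* - the
  opposite of the reference behavior.  Degrading the afferent synapses as
  well gives the characteristic biphasic course: mild disinhibition
  early, then progressive loss of drive, ending hypoactive with a
  collapsed, slowed spectrum.
- **Persistent background noise.** Synaptic loss attenuates the mean
  afferent drive and the coupling, while the stochastic background
  fluctuation persists (a deafferented region is quiet, not silent).
  Attenuating the noise along with the mean makes the degenerate network
  spuriously coherent.
- **Slower intra-mass damage** (`intra_rate_scale = 0.25`) keeps the
  local resonator intact while its drive fades, which is what lets an
  excitability intervention still act on the damaged network.

The default `rate = 0.03` per virtual time unit is set so that, on the
reference synthetic connectome, total spectral power falls by well over
half across the 40-timepoint protocol (the observed drop is ~85%) while
the decline is still in progress when stimulation starts at `t = 10`.

## Virtual tDCS

Current-flow modeling is consumed, not computed: a montage is defined by
its anode/cathode 10-20 positions plus the sets of regions whose area is
covered at least 50% by a sufficiently strong field, each region assigned
to its nearest electrode.  Targeting is binary by design.  Anodal regions
have `Vd1` lowered from 7 to 5 (easier excitation), cathodal regions
raised to 9; the change starts at the onset timepoint and is sustained to
the end of the run.

For self-contained studies, `synthetic_coverage` emulates coverage tables
over a schematic 2-D scalp: each electrode projects a field patch whose
covered-area fraction decays with distance, posterior electrodes
spreading wider than anterior ones (mirroring the diffuse
parieto-occipital versus focal frontal patterns of finite-element maps).
The geometry is polarity-independent, so a montage and its reversal
target exactly swapped region sets.  These synthetic tables are fixture
plumbing: region sets for real electrodes should come from current-flow
software.

Mechanism of the polarity effect in this model: once degeneration has
pulled `Ve` below threshold, lowering `Vd1` re-centers the excitatory
population on its sigmoid midpoint, restoring both local loop gain (more
alpha, higher peak frequency) and output to neighbors; raising `Vd1`
pushes the population further off-center and suppresses what rhythm
remains.  Because damage is activity-dependent, stimulation also feeds
back on the damage process itself (anodal regions degrade faster), which
is why intervention benefits fade toward the end of the protocol.

## Protocol and seeding

A condition is simulated as 100 independent runs (10 in the miniature
study) of 40 virtual timepoints (20 in the miniature study).  One virtual
timepoint = one epoch of 4096 samples at 1 kHz (dt = 1 ms) followed by
one ADD update; a 1000-sample warmup epoch precedes recording.  Virtual
time is abstract and not mapped to disease duration.  Stimulation starts
at `t = 10`.  Each run degenerates independently.

Every (run, mass) pair owns a noise stream spawned from the master seed,
so all conditions under one seed share thalamic noise (paired design,
lower contrast variance; switchable via `share_noise`).  Runs are
independent and order-invariant; a config hash accompanies every result
table and mismatched tables refuse to merge.

## Outcome measures and scoring

Per epoch and region the excitatory potential is analyzed with a Welch
periodogram (2048-sample segments, 0.49 Hz resolution): relative power in
theta 4-8, lower alpha 8-10, upper alpha 10-13 and beta 13-30 Hz against
the 4-30 Hz reference range; total power as mean signal variance;
posterior peak frequency as the argmax (ties to the lower bin) of the
posterior-averaged spectrum in 4-13 Hz.  Functional connectivity is
computed in the lower alpha band after zero-phase FIR band-pass and
Hilbert transform: PLI = |mean sign of the wrapped phase difference|,
AEC = Pearson correlation of amplitude envelopes (uncorrected - the model
has no volume conduction).  Pairwise values are averaged over the strict
upper triangle.  Theta and beta relative power are recorded for context
but not scored.

Scoring compares each intervention to the untreated ADD condition over
the window `t = 10..20` (run-wise window means, two-sided Welch t-test at
alpha = 0.05, no multiplicity correction): significantly closer to the
healthy mean scores +1, significantly farther -1, otherwise 0; the six
scored measures sum to a composite in [-6, 6].  Per-timepoint t-tests at
`t = 10, 15, 20` (and a head-to-head variant on differences from ADD) are
available for finer comparisons, as is the correlation of a region's
average anodal composite score with its AEC and degree profile.

## What the miniature study shows

The shipped fixture study (20 regions, 10 runs, 20 timepoints, seeded) is
sized to run in minutes.  On it the package reproduces directions, not
magnitudes: the healthy network holds a stable alpha peak; degeneration
monotonically reduces total power, alpha share, peak frequency, PLI and
AEC; an anodal-posterior montage (hub-rich coverage) shifts lower-alpha
power and peak frequency back toward healthy while its polarity reversal
does not.  Quantities tied to the 78-region diffusion connectome and to
real current-flow maps - exact trajectories, per-montage composite values,
the reported profile correlations - are not reproducible from a synthetic
stand-in and are out of scope for the tests.

## Numerical notes

- The synaptic filters are advanced by exact zero-order-hold
  discretization of `H(s) = A a / (s + a)^2` (closed-form transition
  matrix for the critically damped double pole); the sigmoid
  nonlinearity is evaluated once per step.  The scheme is fixed-step and
  explicit, unconditionally stable in the linear part, and matches the
  continuous impulse response to well under 1% at the default
  dt = 1 ms.
- The vectorized network integrator is held to exact (1e-12) agreement
  with the readable per-mass reference path by the test suite.
- Degenerate cases: flat spectra return the search-interval midpoint
  with a flag; constant envelopes make AEC NaN with a warning; zero
  run-variance scores 0 with a warning; empty frequency bands, negative
  densities, asymmetric matrices and mismatched sizes raise errors.

## Known limitations

- Two populations per mass; no multi-compartment or conductance-based
  detail, no plasticity, no subcortex, no conduction delays.
- The synthetic connectome and synthetic coverage tables are structural
  stand-ins; conclusions transfer to real anatomy only by direction.
- The damage rule's functional form (multiplicative, activity-
  proportional, fixed reference) is one defensible choice among several;
  rate constants are expressed per virtual time unit and have no
  physical timescale.
- Stimulation onset is fixed at `t = 10` per protocol; varying onset
  schedules are untested territory.
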