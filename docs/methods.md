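# Methods

## The model

Two identical populations of N single-compartment conductance-based neurons
(default N = 2000; the test fixture uses 400) are coupled bidirectionally by
sparse long-range excitatory projections.  Each neuron follows
Hodgkin–Huxley dynamics with Wang–Buzsáki-type Na/K kinetics (Traub–Miles
lineage, temperature factor folded into the rates):

    C_m dV/dt = -g_Na m_inf(V)^3 h (V - E_Na) - g_K n^4 (V - E_K)
                - g_L (V - E_L) + I_syn + I_ext

with the fast sodium activation gate replaced by its voltage-dependent
steady state `m_inf(V)`, so the neuron state is (V, n, h).  Parameters
(mS/cm², mV): g_Na = 35, g_K = 9, g_L = 0.1, E_Na = 55, E_K = -90,
E_L = -65.  Excitatory cells have C_m = 1 µF/cm²; inhibitory cells are fast
spiking, implemented as C_m = 0.5 µF/cm².  These conductance densities were
chosen over the stiffer classic Traub–Miles set (g_Na = 100, g_K = 80)
because the explicit Heun scheme at the default step of 0.05 ms is unstable
for the latter during spike repolarization.

Synapses are dual-exponential conductances
`g(t) = g_max c (exp(-t/tau_d) - exp(-t/tau_r))` with the normalization `c`
fixing the kernel peak at `g_max`; AMPA: tau_r = 0.5 ms, tau_d = 2 ms,
E = 0 mV; GABA_A: tau_r = 0.5 ms, tau_d = 4 ms, E = -80 mV.  The GABA_A
decay constant paces the collective rhythm: shortening it speeds the gamma
peak (measured by the decay-rank experiment).  A helper calibrates `g_max`
to a target unitary PSP amplitude at rest when physiological scaling is
wanted.

### Connectivity

Within a population, an undirected Watts–Strogatz ring (mean degree 100 at
N = 2000, rewiring probability 0.3) is duplicated into reciprocal directed
chemical synapses; a directed edge is AMPA or GABA_A according to its
presynaptic cell (80% excitatory).  Intra-population conduction delays are
gamma(shape 1, scale 1) ms, i.e. Exponential(1).  Across populations, 90%
of the excitatory cells project onto a random quarter of the other
population, with the total inter-edge count one tenth of the internal edge
count; inter-areal delays are gamma(shape tau, scale 1) ms, so the mean is
tau and the CV falls as 1/sqrt(tau).  A constant-delay mode (all delays
exactly tau) isolates the effect of delay variability; a unidirectional
mode keeps only the A-to-B projections.  Delays are rounded to integration
steps (half up, minimum one step) and served through per-step ring buffers,
so every synaptic effect follows its spike strictly causally.

### Drive and stimuli

Every neuron receives an excitatory Poisson train whose rate follows an
Ornstein–Uhlenbeck process (mean 1500 spikes/s, SD 100 spikes/s,
correlation time 16 ms, clipped at zero); by default one OU trace is shared
per population (a common rate fluctuation) with independent per-neuron
thinning, and an independent-per-neuron switch exists.  A larger rate SD
(~400 spikes/s) also produces the gamma regime but its common slow
fluctuations dominate LFP–MUA co-variation below 20 Hz, which is why the
default is modest.  Stimuli are step increments of the mean rate (seven
values, 0 to 3000 spikes/s) applied for 1 s to 120 long-range-projecting
excitatory neurons of the emitter population.

### Integration and recording

Everything is advanced by the Heun predictor–corrector scheme at
dt = 0.05 ms (order-2 convergence is asserted in the tests); inside the
numba kernel the gating rates come from dense lookup tables (0.02 mV grid,
linear interpolation) built from the exact closed forms.  Spikes are upward
crossings of 0 mV under a 2 ms lockout.  Trials discard a 200 ms warm-up;
currents are averaged within 1 ms windows to give 1 kHz traces.

## Observables

LFP(t) = R_e < |I_AMPA| + |I_GABA| > averaged over excitatory cells, with
the AMPA term including the external drive; R_e = 1 MOhm (it cancels in
coherence and MI).  MUA is the population spike count per 1 ms bin.  With
this amplitude-based LFP the spike volley sits on the rising
trough-to-peak phase of the band-passed LFP (~1/3 cycle after the trough,
just before the synaptic surge it causes); the locking test therefore
asserts a shuffle-corrected modulation depth (z > 3) plus a preferred
phase in the trough-to-peak half-cycle.

## Spectral analysis

Welch PSDs use Hamming windows with 50% overlap; at fixture scale segments
are 0.5 s (2 Hz resolution) so that ten trials give K = 60 segments.  Phase
coherence is the resultant length of unit-normalized per-segment
cross-spectrum phasors pooled over the trials of a condition; its chance
level is sqrt(pi)/(2 sqrt(K)), and significance uses four times the
band-averaged coherence of an uncoupled baseline computed at matched K.
The mean phase divides by 2 pi f to give the time shift (positive = first
population leads); an in-phase (anti-phase) label requires the shift within
T/8 of zero (of half a period).  Peak tracking takes the most prominent
in-band local maximum of the PSD (the gamma peak rides a 1/f background,
so a raw argmax can sit on the band edge) and all significant local
coherence maxima, which supports coexisting in-phase and anti-phase
branches.

## Mutual information

The response is single-trial LFP or MUA power at each frequency (one
Hamming periodogram over the 1 s stimulus window per trial).  Responses
pooled across stimuli are discretized into six equipopulated bins; the
plugin MI with uniform stimulus priors is corrected by the first-order
analytic bias term [sum_s (B_s - 1) - (B - 1)] / (2 N ln 2) and by
subtracting the mean of a stimulus-shuffle bootstrap (200 shuffles in the
library default, 100 in the batteries); a frequency is significant when
the analytically corrected value exceeds the null's 95th percentile.
Corrected values are floored at zero for reporting; the signed value is
retained.  The estimator stack is validated against a direct-summation
oracle on small joint tables and a numerical-integration oracle on
log-normal channels with known binned MI.

## Surrogate generators

Coherent pairs mix a shared and an independent narrowband Gaussian process
(complex-OU envelope, 200 ms correlation time, times a carrier at f0) with
weights sqrt(g) and sqrt(1-g), plus a small white-noise floor.  Joint
Gaussianity at each frequency bin gives the closed-form expected
resultant length R(g) = (pi/4) g 2F1(1/2, 1/2; 2; g^2), which the generator
inverts so the requested coherence level is the expectation of the
estimator; the phase lag enters exactly by rotating the analytic envelope.
The envelope diffusion (rather than pure phase diffusion) is what makes
this closed form available; it mimics the finite self-coherence of network
gamma.  Power-channel surrogates draw log-normal power with per-stimulus
median shifts; their exact binned MI is computed from the known normal
CDFs for any bin edges.

The surrogates emulate signal-level statistics only — no spike-level
structure, no 1/f background, no cross-frequency coupling — so tests
passing on them validate the estimators, not the realism of the network
model.

## Desk-scale study conditions

The experiment battery (`ctcsim.experiments`) runs on a 2 x 400-neuron
fixture, mean degree 80 (reduced less than proportionally from the
full-scale 100/2000 because collective gamma needs synaptic convergence;
per-edge conductances are rescaled by reference_degree/mean_degree to keep
the summed drive per neuron fixed), 2 s per trial: 8 trials per GABA-decay
value for the mechanism experiment, 10 trials per delay for coherence
(with a 10-trial uncoupled baseline for the threshold), 10 independent
10-trial repetitions for the branch-coexistence rate at tau = 4.5 ms, and
7 stimuli x 10 trials per delay for the information experiment at
tau = {0, T/2, T} with T the baseline gamma period.  Publication-scale
would use the full 2000-neuron populations and 50–200 trials; the fixture
sizes keep the battery within minutes on one CPU while the qualitative
outcomes (peak positions, phase classes, MI ordering) are stable under the
seed.

## Numerical choices and edge cases

- Delay rounding: half up with a one-step minimum; tau = 0 inter-areal
  delays deliver on the next step (0.05 ms), the closest causal analogue of
  instantaneous coupling.
- Zero cross-spectrum phasors (exactly zero power in a segment-bin) are
  excluded from the coherence average and counted.
- Equipopulated binning degrades (with a warning) when ties prevent the
  requested number of distinct edges; one effective bin yields zero MI
  downstream.  A value equal to an interior edge belongs to the bin above,
  so quantile edges that coincide with class boundaries keep classes
  separated.
- The x4 significance rule needs the baseline chance level well below real
  coherence values; at fixture scale this fixes the 0.5 s segment length.
- Voltages outside (-130, 80) mV abort the trial with the neuron index and
  time; gating variables are clamped to [0, 1] after each corrector step
  (excursions are O(dt^3)).

## Known limitations

- Absolute frequencies (the exact gamma-peak position) depend on parameter
  choices the source text delegates to its references; they are treated as
  configuration, and the package's claims are about structure (peak
  existence, decay pacing, phase classes, MI ordering), not about exact
  frequencies.
- The LFP proxy ignores electrode geometry and volume conduction.
- No NMDA, gap junctions, plasticity, or multi-compartment morphology.
- Process-level parallelism only; a trial is single-threaded.
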