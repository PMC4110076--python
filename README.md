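# ctcsim

Simulation and analysis of **communication through coherence** between two
delay-coupled spiking neuronal populations.

Cortical areas exchange spikes through long-range axons whose conduction
delays reach tens of milliseconds.  If each area sustains a gamma-band
rhythm (30–80 Hz) born from its excitatory/inhibitory recurrence, the delay
decides the phase relation at which the two rhythms can lock — and that
phase relation decides whether spikes from one area arrive during the
other's excitability windows, i.e. whether the areas *communicate*.  This
package is for computational neuroscientists who want to study that
interplay quantitatively: it simulates the coupled networks, extracts
LFP/MUA population signals, measures frequency-resolved phase coherence and
time shifts, and quantifies stimulus information transmission with
bias-corrected mutual information.

## The model and the measures

Each population is a Watts–Strogatz network of Hodgkin–Huxley neurons
(80% excitatory, 20% fast-spiking inhibitory) with dual-exponential AMPA
and GABA_A synapses, driven by Poisson spike trains whose rate follows an
Ornstein–Uhlenbeck process.  Inter-areal projections are excitatory, sparse,
and delayed by gamma-distributed conduction times with mean τ (scale 1,
shape τ, so CV = 1/√τ).  The observables are

* **LFP** `= R_e ⟨|I_AMPA| + |I_GABA|⟩` over excitatory cells,
* **MUA** — population spike count per unit time,
* **phase coherence** `C(f) = |K⁻¹ Σ_k S_xy,k(f)/|S_xy,k(f)||` — the
  resultant length of unit-normalized per-segment cross-spectrum phasors,
  with the mean phase Δφ(f) converted to a time shift Δτ = Δφ/(2πf),
* **mutual information** `I(S;R) = Σ_s P(s) Σ_r P(r|s) log₂ P(r|s)/P(r)`
  between a set of stimuli (external-rate increments to the emitter) and
  the receiver's single-trial spectral power, discretized into
  equipopulated bins and corrected for limited-sampling bias
  (Panzeri–Treves first-order term plus a stimulus-shuffle bootstrap).

The headline phenomenology: at zero delay the populations lock **in
phase**; near half the gamma period they lock in **anti-phase**; in between
both branches coexist at neighbouring frequencies; and stimulus information
in the receiver decreases as the delay grows.

## Worked example

```python
from ctcsim.experiments import coupled_delay_experiment, small_fixture, NPERSEG
from ctcsim.pipeline import GAMMA_BAND, uncoupled_baseline

cfg = small_fixture(seed=0)
threshold, _, _ = uncoupled_baseline(cfg, n_trials=6, nperseg=NPERSEG, band=GAMMA_BAND)
for tau in (0.0, 12.0):
    res = coupled_delay_experiment(tau, seed=0, n_trials=6, threshold=threshold)
    f, d = res["f_near"], res["dtau_near"]
    print(tau, res["f_lfp"], f, round(res["c_near"], 2), round(d, 1), res["classes"][f])
```

which is what `python examples/02_delay_coupled_coherence.py` narrates:

```
significance threshold (4 x uncoupled baseline): 0.57

tau =  0.0 ms: gamma peak 40 Hz
  coherence peak at 34 Hz: C = 0.85, time shift = -2.8 ms -> in-phase

tau = 12.0 ms: gamma peak 42 Hz
  coherence peak at 38 Hz: C = 0.73, time shift = +11.6 ms -> anti-phase
```

Read: both populations keep a ~40 Hz gamma peak regardless of the delay.
With instantaneous coupling the significant coherence peak sits near the
gamma peak with a time shift well inside an eighth of a cycle — zero-lag
synchronization.  With a 12 ms mean delay (about half the gamma period) the
locked time shift is half a period at the locking frequency (11.6 ms at
38 Hz, whose period is 26 ms): the rhythms alternate in anti-phase.
Coherence values are judged against four times the uncoupled baseline.

The other scripts in `examples/` demonstrate the single-population gamma
mechanism, the stimulus-information experiment, and the surrogate
generators with analytically known coherence and MI used to validate the
estimators.

A thin CLI mirrors the pipeline for shell use:
`ctcsim simulate|sweep-tau|sweep-stimulus|coherence|mi|synth|report`.

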