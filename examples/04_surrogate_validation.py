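"""Validating the analysis stack on surrogates with known ground truth.

Builds (i) pairs of narrowband signals with a controlled coherence level and
phase lag, and (ii) per-stimulus log-normal power samples with analytically
known mutual information, then checks that the estimators recover the
constructed values.
"""

import numpy as np

from ctcsim import SurrogateSpec, phase_coherence, surrogate_coherent_pair
from ctcsim.infotheory import equipopulated_bins, mi_spectrum
from ctcsim.synthetic import surrogate_power_channel

# --- coherent pair: target coherence 0.6, phase lag 0.8 rad at 50 Hz ------
spec = SurrogateSpec(f0=50.0, phase_lag=0.8, coherence_level=0.6, n_trials=8,
                     duration=2.0)
xs, ys = surrogate_coherent_pair(spec, seed=0)
res = phase_coherence(xs, ys, nperseg=500)
c, phi, dtau = res.at(spec.f0)
print(f"constructed coherence 0.60 -> estimated {c:.2f}")
print(f"constructed phase lag 0.80 rad -> estimated {phi:.2f} rad "
      f"(time shift {dtau:+.1f} ms, first signal leads)")

# --- power channel: informative only at one frequency ---------------------
effect = np.zeros(5)
effect[2] = 0.8
samples, channel = surrogate_power_channel(
    n_stimuli=5, effect_profile=effect, noise=0.5, n_trials=40, seed=1
)
mi = mi_spectrum(samples, n_bins=6, n_bootstrap=100, seed=2)
pooled = np.log10(np.concatenate([s[:, 2] for s in samples.samples]))
exact = channel.exact_mi(2, equipopulated_bins(pooled, 6))
print()
print(f"exact binned MI at the informative frequency: {exact:.2f} bits")
print(f"bias-corrected estimate                      : {mi.i_corrected[2]:.2f} bits")
print(f"corrected MI at an uninformative frequency   : {mi.i_corrected[0]:.2f} bits")
print()
print("The estimators recover the constructed coherence, lag and MI; the")
print("uninformative frequency corrects to about zero, showing the")
print("limited-sampling bias removal at work.")
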