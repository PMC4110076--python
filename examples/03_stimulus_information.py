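"""Stimulus information carried by the receiver's power spectrum.

Applies seven external-rate increments to the projecting excitatory neurons
of the emitter population and measures how much information about the
stimulus identity the *receiver* population's LFP power carries at each
frequency, for two inter-areal delays.  Uses fewer trials than the full
experiment so it runs in about two minutes.
"""

import numpy as np

from ctcsim.experiments import mi_experiment

res = mi_experiment(taus=(0.0, 12.0), seed=0, n_trials=6)

for tau, d in res["by_tau"].items():
    mi = d["mi_lfp"]
    print(f"tau = {tau} ms:")
    print(f"  receiver gamma peak      : {d['receiver_gamma_hz']:.0f} Hz")
    print(f"  max corrected LFP MI     : {d['mi_lfp_peak']:.2f} bits "
          f"at {d['mi_peak_hz']:.0f} Hz")
    print(f"  max corrected MUA MI     : {d['mi_mua_peak']:.2f} bits")
    n_sig = int(mi.significant.sum())
    print(f"  significant frequencies  : {n_sig} of {len(mi.freqs)}")
    print()

print("Information about the stimulus concentrates around the receiver's")
print("gamma rhythm (the peak and its harmonic, since the stimulus scales")
print("the rhythm's amplitude) and shrinks as the axonal delay grows; with")
print("an upper bound of log2(7) = 2.81 bits, even the zero-delay channel")
print("is lossy.")
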