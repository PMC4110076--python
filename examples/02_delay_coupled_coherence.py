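"""Phase coherence between two delay-coupled populations.

Couples the two fixture populations bidirectionally, once with
instantaneous coupling (tau = 0) and once with a mean axonal delay near
half the gamma period, and prints the time shift at the dominant coherence
peak.  Zero delay locks the pair in phase; a half-period delay locks it in
anti-phase.
"""

from ctcsim.experiments import NPERSEG, coupled_delay_experiment, small_fixture
from ctcsim.pipeline import GAMMA_BAND, uncoupled_baseline

cfg = small_fixture(seed=0)
threshold, _, _ = uncoupled_baseline(cfg, n_trials=6, nperseg=NPERSEG, band=GAMMA_BAND)
print(f"significance threshold (4 x uncoupled baseline): {threshold:.2f}\n")

for tau in (0.0, 12.0):
    res = coupled_delay_experiment(tau, seed=0, n_trials=6, threshold=threshold)
    print(f"tau = {tau:>4} ms: gamma peak {res['f_lfp']:.0f} Hz")
    if "f_near" in res:
        f, d = res["f_near"], res["dtau_near"]
        label = res["classes"][f]
        print(f"  coherence peak at {f:.0f} Hz: C = {res['c_near']:.2f}, "
              f"time shift = {d:+.1f} ms -> {label}")
    else:
        print("  no significant coherence peak")
    print()

print("At tau=0 the shift is within an eighth of a gamma cycle of zero")
print("(zero-lag locking); near half the gamma period the shift equals half")
print("the period at the locked frequency: the rhythms alternate in anti-phase.")
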