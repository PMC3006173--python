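"""Decode direction from cosine-tuned spiking, two ways.

Spike times are binned at 2 ms into 500 Hz count series and decoded by
the same CSP+ECOC pipeline used for LFP; a regularized-LDA baseline on
200 ms spike counts is reported alongside.
"""

import lfpdecode as ld

cfg = ld.SimConfig(seed=4, n_trials_per_class=20)
S = ld.simulate_spikes(cfg, n_units=24, base_rate=25.0, mod_depth=0.8)

B = ld.bin_spikes(S, bin_ms=2.0, epoch=(-2300.0, 1700.0))
print(f"binned: {B.counts.shape[0]} trials x {B.counts.shape[1]} units, "
      f"{B.fs_equiv:.0f} Hz equivalent rate")

res = ld.sua_csp_decode(B, ld.informative_bands(), (0.0, 1000.0),
                        folds=10, reps=3, seed=4)
print(f"CSP+ECOC on counts: DP = {res.dp:.3f}, rhoT = {res.rho_t:.3f}")

times, rlda = ld.rlda_decode(S, start_ms=-200.0, end_ms=1000.0,
                             folds=10, reps=3, seed=4)
best = max(range(len(rlda)), key=lambda i: rlda[i].dp)
print(f"rLDA best window ends {times[best]:+.0f} ms: "
      f"DP = {rlda[best].dp:.3f}, rhoT = {rlda[best].rho_t:.3f}")
print("Both routes decode the planted cosine tuning well above the 0.125 "
      "chance level; their ordering depends on unit count and trials.")
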