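"""Generate a direction-tuned synthetic session and decode it.

Builds a standard strong-effect session (32 channels, 40 trials per
direction), extracts delta-amplitude and gamma-envelope band tensors,
and runs the CSP+ECOC decoder under 10x10-fold cross-validation on the
peri-movement second.
"""

import numpy as np

import lfpdecode as ld

cfg = ld.SimConfig(seed=1)
T, truth = ld.simulate_session(cfg)
print(f"session: {T.n_trials} trials x {T.n_channels} channels "
      f"x {T.n_samples} samples at {T.fs:.0f} Hz")

banded = ld.preprocess_bands(T, ld.informative_bands())
res = ld.cross_validate(banded, T.labels, window_ms=(0.0, 1000.0),
                        folds=10, reps=10, seed=1)

print(f"decoding power  DP   = {res.dp:.3f}   (chance = 1/8 = 0.125)")
print(f"circular corr   rhoT = {res.rho_t:.3f}  (1 = perfect, 0 = none)")
print("confusion matrix (rows = actual direction, cols = predicted):")
print(res.confusion)

K = 8
errors = res.confusion.sum() - np.trace(res.confusion)
adjacent = sum(res.confusion[k, (k + 1) % K] + res.confusion[k, (k - 1) % K]
               for k in range(K))
print(f"{errors} errors, {100 * adjacent / max(errors, 1):.0f}% of them on "
      "adjacent (45 deg) directions — misreads stay close on the circle.")
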