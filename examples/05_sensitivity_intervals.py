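"""Resampling-based sensitivity intervals for a target concentration.

Trains the scaled profile briefly, predicts one synthetic sample, then
rescales all *other* predicted components (and the background) by factors
drawn from normal priors of increasing width, resynthesizes the inputs and
re-predicts.  The spread of the target's re-predictions is its sensitivity
interval; it grows with the prior width but stays much narrower than the
prior itself when the model is confident.
"""

import numpy as np

from jpresskit import PriorSpec, sensitivity_interval
from jpresskit.profiles import train_smoke
from jpresskit.training import VALIDATION_OFFSET

model, prof, _ = train_smoke(seed=0)
gen = prof.generator
sample = gen.generate_sample(gen.rng_for(VALIDATION_OFFSET + 42, 0))

target = "tNAA"
print(f"true {target} concentration: "
      f"{sample.concentrations[sample.component_names.index(target)]:.2f} mM")
print("prior sd | point est (mM) | 95% interval (mM)   | output rel. sd")
rng = np.random.default_rng(0)
for sd in [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]:
    res = sensitivity_interval(
        model, sample.input,
        PriorSpec(target_component=target, relative_sd=sd, n_resamples=30),
        rng)
    lo, hi = res.interval
    print(f"   {sd:4.2f}  | {res.point_estimate:13.2f} | "
          f"[{lo:6.2f}, {hi:6.2f}]   | {res.relative_sd_out:8.3f}")

print("\nThe target's factor is pinned at 1 in every resample; the output"
      " relative sd being below the prior sd means the prediction is"
      " driven by the target's own signal, not by the other components.")
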