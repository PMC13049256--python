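"""Phase/frequency/lineshape (PFL) robustness of the trained quantifier.

Applies random per-echo phase shifts (+-180 deg) and frequency offsets
(+-5 Hz), plus shared Voigt broadening, to one held-out synthetic sample
and compares re-predicted concentrations against the unperturbed
prediction.  The model is trained on PFL-augmented data, so its
concentration estimates should move only slightly.
"""

import numpy as np

from jpresskit import PerturbationSpec, perturb_dataset
from jpresskit.profiles import train_smoke
from jpresskit.training import VALIDATION_OFFSET

model, prof, _ = train_smoke(seed=0)
gen = prof.generator
sample = gen.generate_sample(gen.rng_for(VALIDATION_OFFSET + 43, 0))

base = model.predict(np.stack([sample.input.real, sample.input.imag], -1)[None])
spec = PerturbationSpec(mode="all", n_variants=30)
variants = perturb_dataset(sample.input, spec, gen.grid,
                           np.random.default_rng(1))
pred = model.predict(np.stack([variants.real, variants.imag], axis=-1))

names = gen.component_names
print("component | baseline (mM) | perturbed median (mM) | median |rel dev|")
rels = []
for i, name in enumerate(names):
    ref = base.concentrations[0, i]
    med = np.median(pred.concentrations[:, i])
    rel = np.median(np.abs(pred.concentrations[:, i] - ref)) / max(ref, 1e-6)
    if ref > 1.0:
        rels.append(rel)
    print(f"{name:9s} | {ref:13.2f} | {med:21.2f} | {rel:16.3f}")
print(f"\nmedian relative deviation over well-detected components: "
      f"{np.median(rels):.3f}")
print("Values well below 1 mean the learned representation is largely"
      " invariant to phase, frequency-offset and lineshape changes.")
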