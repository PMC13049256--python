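"""Canonical experiment profiles.

``full_profile`` mirrors the full-size acquisition and network (32 echoes
x 2048 points, 14 metabolites + water, 128-dim representation, 18 epochs);
training it is accelerator-scale and is provided for completeness.

``smoke_profile`` is the scaled-down CPU profile used throughout the test
suite and examples: 8 echoes x 512 points, three metabolites with distinct
spectral character (NAA: dominant singlet; Cr: two singlets; GABA: weakly
coupled multiplets) plus residual water, a 12-dimensional representation
with two encoder blocks, dilations 2-32 and PAB over the first 32 points.
The generative model (priors, T2 ranges, PFL ranges, noise) is identical in
both profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spins import builtin_systems
from .simulator import AcquisitionGrid, BasisSet, simulate_basis
from .datagen import GenConfig, SampleGenerator
from .model import JpressNet, ModelConfig
from .training import TrainConfig

__all__ = ["Profile", "smoke_profile", "full_profile", "train_smoke",
           "WATER_TARGET_SCALE"]

# Residual water amplitude sits roughly 30x above metabolite labels on the
# simulator scale; its targets are normalized by this factor for training.
WATER_TARGET_SCALE = 30.0

SMOKE_METABOLITES = ["NAA", "Cr", "GABA"]


@dataclass
class Profile:
    grid: AcquisitionGrid
    generator: SampleGenerator
    model_config: ModelConfig
    train_config: TrainConfig

    def new_model(self, seed: int = 0) -> JpressNet:
        return JpressNet(self.model_config, seed=seed)


def _target_scales(component_names: list[str]) -> list[float]:
    return [WATER_TARGET_SCALE if c == "water" else 1.0 for c in component_names]


def smoke_profile(basis: BasisSet | None = None, seed: int = 0,
                  gen_config: GenConfig | None = None) -> Profile:
    """The scaled-down single-CPU profile (8 TEs x 512 points)."""
    if basis is None:
        # 8 echoes spanning the full 35-315 ms TE range: fewer echoes, same
        # span, so the T2/J-evolution information along TE is preserved
        grid = AcquisitionGrid(n_te=8, te_values=0.035 + 0.040 * np.arange(8),
                               n_points=512)
        systems = builtin_systems()
        basis = simulate_basis(
            [systems[m] for m in SMOKE_METABOLITES + ["water"]], grid)
    gen = SampleGenerator(basis, gen_config)
    mcfg = ModelConfig(
        n_te=basis.grid.n_te, n_points=basis.grid.n_points,
        feature_dim=14, dilation_depth=5, pab_window=32, n_blocks=2,
        n_components=gen.n_components,
        target_scales=_target_scales(gen.component_names),
        component_names=gen.component_names)
    # small batches maximize optimizer steps on one CPU; the raised max_lr
    # compensates for the scaled run taking far fewer steps than the
    # accelerator-scale schedule.  Two cosine cycles (warm restarts): the
    # second high-lr phase reliably un-sticks weak components (GABA, tCr)
    # that can collapse to constant predictions in a single short cycle.
    tcfg = TrainConfig(epochs=20, n_samples=900, batch_size=8, max_lr=1e-2,
                       n_cycles=2, seed=seed)
    return Profile(basis.grid, gen, mcfg, tcfg)


def train_smoke(seed: int = 0, basis: BasisSet | None = None,
                callback=None):
    """Train the scaled-down profile end to end.

    Returns ``(model, profile, history)``; the single entry point used by
    the test suite, the acceptance script and the examples.
    """
    from .training import train
    prof = smoke_profile(basis=basis, seed=seed)
    model = prof.new_model(seed=seed)
    history = train(model, prof.generator, prof.train_config,
                    callback=callback)
    return model, prof, history


def full_profile(basis: BasisSet | None = None, seed: int = 0,
                  gen_config: GenConfig | None = None) -> Profile:
    """The full-size profile; training it needs accelerator-scale compute."""
    if basis is None:
        grid = AcquisitionGrid()
        basis = simulate_basis(list(builtin_systems().values()), grid)
    gen = SampleGenerator(basis, gen_config)
    mcfg = ModelConfig(
        n_components=gen.n_components,
        target_scales=_target_scales(gen.component_names),
        component_names=gen.component_names)
    tcfg = TrainConfig(epochs=18, n_samples=100_000, batch_size=32, seed=seed)
    return Profile(basis.grid, gen, mcfg, tcfg)
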