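"""Resampling-based sensitivity intervals and component-ablation tests.

The uncertainty of a predicted target concentration is probed by rescaling
every *other* predicted component FID (and the residual background) with
factors drawn from a normal prior centered at 1, resynthesizing the input
as the sum of scaled components, and re-predicting.  The target component's
factor is always exactly 1.  Phase, frequency-offset and lineshape
variations are not re-perturbed: the model is trained to be invariant to
them.  The ablation test instead removes one component entirely and checks
that its re-predicted concentration collapses toward zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import JpressNet

__all__ = ["PriorSpec", "SensitivityResult", "extract_background",
           "resample_datasets", "sensitivity_interval", "ablation_test"]

logger = logging.getLogger(__name__)


def _to_channels(fids: np.ndarray) -> np.ndarray:
    """Complex (..., n_te, n_points) -> real (..., n_te, n_points, 2)."""
    return np.stack([fids.real, fids.imag], axis=-1)


@dataclass
class PriorSpec:
    """Normal scaling prior: factors ~ N(1, relative_sd), target fixed at 1."""

    target_component: str
    relative_sd: float = 0.25
    n_resamples: int = 30

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class SensitivityResult:
    """Summary of the resampled target-concentration distribution."""

    target: str
    point_estimate: float            # mM, prediction on the original input
    resampled: np.ndarray            # (n_resamples,) mM
    interval: tuple                  # central 95% percentile interval
    relative_sd_out: float           # sd(resampled) / mean(resampled)
    prior: PriorSpec = field(repr=False, default=None)  # type: ignore


def extract_background(input_fids: np.ndarray,
                       reconstructed_fids: np.ndarray) -> np.ndarray:
    """Background = input minus the sum of all predicted components.

    ``input_fids``: (n_te, n_points) complex; ``reconstructed_fids``:
    (n_comp, n_te, n_points) complex.
    """
    input_fids = np.asarray(input_fids)
    recon = np.asarray(reconstructed_fids)
    if recon.shape[1:] != input_fids.shape:
        raise ValueError("shape mismatch between input and reconstructions")
    return input_fids - recon.sum(axis=0)


def _draw_factors(n_comp: int, target_idx: int, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Component + background scale factors; target pinned at 1; negative
    draws truncated at 0 (negative component scaling is unphysical)."""
    factors = rng.normal(1.0, sd, size=n_comp + 1)
    neg = factors < 0
    if np.any(neg):
        logger.info("truncating %d negative scale factors at 0", int(neg.sum()))
        factors[neg] = 0.0
    factors[target_idx] = 1.0
    return factors


def resample_datasets(components: np.ndarray, background: np.ndarray,
                      component_names: list, prior: PriorSpec,
                      rng: np.random.Generator):
    """Synthesize ``n_resamples`` inputs from a predicted decomposition.

    Each input is sum_c factor_c * component_c + factor_bg * background with
    the target component's factor identically 1.  Returns (inputs, factors)
    where factors has shape (n_resamples, n_comp + 1), background last.
    """
    if prior.target_component not in component_names:
        raise ValueError(f"unknown target component {prior.target_component!r}")
    idx = component_names.index(prior.target_component)
    n_comp = len(component_names)
    inputs, factors = [], []
    for _ in range(prior.n_resamples):
        fac = _draw_factors(n_comp, idx, prior.relative_sd, rng)
        inputs.append(np.tensordot(fac[:-1], components, axes=1)
                      + fac[-1] * background)
        factors.append(fac)
    return np.array(inputs), np.array(factors)


def sensitivity_interval(model: JpressNet, sample_input: np.ndarray,
                         prior: PriorSpec,
                         rng: np.random.Generator) -> SensitivityResult:
    """Predict, resample the decomposition, re-predict, summarize the target."""
    if model.cfg.component_names is None or not model.cfg.component_names:
        raise ValueError("model carries no component names; was it trained?")
    names = list(model.cfg.component_names)
    pred = model.predict(_to_channels(sample_input)[None])
    idx = names.index(prior.target_component)
    point = float(pred.concentrations[0, idx])
    background = extract_background(sample_input, pred.reconstructed_fids[0])
    inputs, _ = resample_datasets(pred.reconstructed_fids[0], background,
                                  names, prior, rng)
    re_pred = model.predict(_to_channels(inputs))
    vals = re_pred.concentrations[:, idx]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    mean = float(vals.mean())
    rel_sd = float(vals.std() / mean) if mean != 0 else float("inf")
    return SensitivityResult(
        target=prior.target_component, point_estimate=point,
        resampled=np.asarray(vals), interval=(float(lo), float(hi)),
        relative_sd_out=rel_sd, prior=prior)


def ablation_test(model: JpressNet, sample_input: np.ndarray, component: str,
                  n: int = 100, relative_sd: float = 0.25,
                  rng: np.random.Generator | None = None):
    """Re-predict a component from regenerated data with and without it.

    Builds ``n`` resampled datasets in which the named component's predicted
    FIDs are removed (its factor forced to 0) and ``n`` with them intact,
    all other components randomly rescaled; returns the two arrays of
    re-predicted concentrations for that component (without, with).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    names = list(model.cfg.component_names)
    if component not in names:
        raise ValueError(f"unknown component {component!r}")
    idx = names.index(component)
    pred = model.predict(_to_channels(sample_input)[None])
    comps = pred.reconstructed_fids[0]
    background = extract_background(sample_input, comps)
    out = {}
    batch = 25
    for label, keep in (("without", 0.0), ("with", 1.0)):
        xs = []
        for _ in range(n):
            fac = _draw_factors(len(names), idx, relative_sd, rng)
            fac[idx] = keep
            x = np.tensordot(fac[:-1], comps, axes=1) + fac[-1] * background
            xs.append(_to_channels(x))
        vals = np.concatenate([
            model.predict(np.stack(xs[k:k + batch])).concentrations[:, idx]
            for k in range(0, n, batch)])
        out[label] = vals
    return out["without"], out["with"]
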