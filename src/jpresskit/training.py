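"""Loss construction and the optimization loop.

All loss terms are mean absolute errors; negative predicted concentrations
and first-point amplitudes are clipped to zero inside the loss (equivalent
to a ReLU folded into the objective, leaving clipping optional at test
time).  Optimization uses Adam under cosine annealing of the learning rate.
Training data are generated on the fly from a :class:`SampleGenerator`:
every epoch consumes fresh counter-derived samples (never stored, never
revisited), and validation draws from a disjoint counter range, so the
whole run is reproducible from one seed.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, DTYPE, cosine_lr
from .model import JpressNet, ModelConfig
from .datagen import SampleGenerator

__all__ = ["TrainConfig", "composite_loss", "train", "batch_from_generator"]

logger = logging.getLogger(__name__)

# counter offset of the held-out validation stream (disjoint from training)
VALIDATION_OFFSET = 2 ** 30


@dataclass
class TrainConfig:
    """Optimization schedule and loss weighting.

    The full-scale schedule is 18 epochs at accelerator scale; the default
    here is the scaled-down CPU profile.
    """

    epochs: int = 5
    max_lr: float = 5e-4
    batch_size: int = 16
    n_samples: int = 1000          # logical training-set size
    val_fraction: float = 0.05
    loss_weights: tuple = (1.0, 1.0, 1.0, 1.0)  # conc, t2, amplitude, recon
    adam_beta2: float = 0.999
    min_lr: float = 0.0            # cosine-annealing floor (eta_min)
    n_cycles: int = 1              # cosine cycles (warm restarts if > 1)
    seed: int = 0
    divergence_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.max_lr <= 0:
            raise ValueError("max_lr must be positive")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")


def _mae(pred: np.ndarray, truth: np.ndarray, clip: bool):
    """(value, d value / d pred); clip folds max(pred, 0) into the loss."""
    p = np.maximum(pred, 0.0) if clip else pred
    diff = p - truth
    n = diff.size
    val = float(np.abs(diff).mean())
    grad = np.sign(diff).astype(DTYPE) / n
    if clip:
        grad = grad * (pred >= 0)
    return val, grad


def composite_loss(pred: dict, labels: dict, weights=(1.0, 1.0, 1.0, 1.0)):
    """Weighted sum of MAE terms on the network's scaled outputs.

    ``pred`` and ``labels`` hold ``conc``, ``t2``, ``amp``, ``recon`` on the
    network scale.  Returns (total, per-term dict, gradient dict).
    """
    terms, grads = {}, {}
    for key, w, clip in (("conc", weights[0], True), ("t2", weights[1], False),
                         ("amp", weights[2], True), ("recon", weights[3], False)):
        val, grad = _mae(pred[key], labels[key], clip)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite {key} loss")
        terms[key] = val
        grads[key] = (w * grad).astype(DTYPE)
    total = float(sum(weights[i] * terms[k]
                      for i, k in enumerate(("conc", "t2", "amp", "recon"))))
    return total, terms, grads


def batch_from_generator(gen: SampleGenerator, indices, seed: int,
                         cfg: ModelConfig, with_recon: bool = True) -> dict:
    """Materialize logical samples ``indices`` as scaled network tensors.

    ``with_recon=False`` skips the component-FID targets (the bulk of the
    memory) for evaluation-only batches.
    """
    xs, conc, t2, amp, recon = [], [], [], [], []
    for i in indices:
        s = gen.generate_sample(gen.rng_for(seed, int(i)))
        xs.append(s.as_channels())
        conc.append(s.concentrations)
        t2.append(s.avg_t2)
        amp.append(s.amplitudes)
        if with_recon:
            recon.append(np.stack([s.component_fids.real,
                                   s.component_fids.imag], -1))
    ts = np.asarray(cfg.target_scales, dtype=np.float64)
    out = {
        "x": (np.stack(xs) / cfg.input_scale).astype(DTYPE),
        "conc": (np.stack(conc) / (cfg.conc_scale * ts)).astype(DTYPE),
        "t2": (np.stack(t2) / cfg.t2_scale).astype(DTYPE),
        "amp": (np.stack(amp) / (cfg.amp_scale * ts)).astype(DTYPE),
    }
    if with_recon:
        out["recon"] = (np.stack(recon)
                        / (cfg.input_scale * ts[:, None, None, None])).astype(DTYPE)
    return out


def train(model: JpressNet, gen: SampleGenerator, cfg: TrainConfig,
          out_dir=None, callback=None) -> dict:
    """Train with on-the-fly data generation; returns the loss history.

    Validation uses a held-out slice of the logical sample stream
    (indices past the training range).  Aborts early if a full epoch's loss
    exceeds ``divergence_factor`` times the first epoch's.
    """
    mcfg = model.cfg
    opt = Adam(model.params(), beta2=cfg.adam_beta2)
    n_train = cfg.n_samples
    n_val = max(int(round(cfg.val_fraction * n_train)), 1)
    steps_per_epoch = int(np.ceil(n_train / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    # validation stream is disjoint from every training epoch's counter range
    val_idx = VALIDATION_OFFSET + np.arange(n_val)
    history = {"epochs": [], "config": asdict(cfg)}
    first_epoch_loss = None
    step = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        epoch_terms = {"conc": 0.0, "t2": 0.0, "amp": 0.0, "recon": 0.0}
        epoch_loss = 0.0
        for k in range(steps_per_epoch):
            lo = k * cfg.batch_size
            idx = epoch * n_train + np.arange(lo, min(lo + cfg.batch_size,
                                                      n_train))
            if len(idx) == 0:
                continue
            batch = batch_from_generator(gen, idx, cfg.seed, mcfg)
            out = model._forward(batch["x"])
            total, terms, grads = composite_loss(
                out, batch, weights=cfg.loss_weights)
            opt.zero_grad()
            model._backward(grads)
            cycle_len = max(total_steps // max(cfg.n_cycles, 1), 1)
            opt.step(cosine_lr(step % cycle_len, cycle_len,
                               cfg.max_lr, cfg.min_lr))
            step += 1
            epoch_loss += total
            for key in epoch_terms:
                epoch_terms[key] += terms[key]
        epoch_loss /= steps_per_epoch
        for key in epoch_terms:
            epoch_terms[key] /= steps_per_epoch
        val_batch = batch_from_generator(gen, val_idx, cfg.seed, mcfg)
        val_out = model._forward(val_batch["x"])
        val_total, val_terms, _ = composite_loss(val_out, val_batch,
                                                 weights=cfg.loss_weights)
        model.free_caches()  # validation activations are large and stale
        rec = {"epoch": epoch, "loss": epoch_loss, **{f"loss_{k}": v for k, v in epoch_terms.items()},
               "val_loss": val_total,
               **{f"val_loss_{k}": v for k, v in val_terms.items()},
               "seconds": time.time() - t0}
        history["epochs"].append(rec)
        logger.info("epoch %d loss %.4f val %.4f (%.1fs)",
                    epoch, epoch_loss, val_total, rec["seconds"])
        if callback is not None:
            callback(rec)
        if first_epoch_loss is None:
            first_epoch_loss = epoch_loss
        elif epoch_loss > cfg.divergence_factor * first_epoch_loss:
            rec["diverged"] = True
            logger.error("training diverged at epoch %d (loss %.3g vs initial %.3g)",
                         epoch, epoch_loss, first_epoch_loss)
            break
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "model.h5")
        with open(out / "history.json", "w") as fh:
            json.dump(history, fh, indent=1)
    return history
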