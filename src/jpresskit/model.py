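"""The JPRESS encoder-decoder network.

Per-echo gated dilated-convolution feature extraction (sequence length
preserved), GRU fusion across the ascending-TE axis at every time position,
repeated ``n_blocks`` times; pooling-at-the-beginning (PAB) over the first
``pab_window`` FID points yields TE-specific representations whose mean over
echoes is the unified JPRESS representation.  Dense heads map the JPRESS
representation to concentrations and metabolite-average T2s, a per-echo head
predicts first-point amplitudes, and a decoder conditioned on the raw input
plus every block's output reconstructs the individual component FIDs.

Setting ``pab_window = n_points`` reproduces the global-average-pooling
ablation.  Complex FIDs travel as two real channels throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import h5py

from .nn import DTYPE, Dense, GRU, GatedDilatedConv

__all__ = ["ModelConfig", "Predictions", "JpressNet", "receptive_field_extent"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters and label scalings.

    Defaults match the full-size acquisition (32 echoes x 2048 points,
    128-dimensional representation, dilations 2..256, PAB over 64 points,
    4 encoder blocks, 12 output components).  The scaled-down training
    profile overrides sizes, never wiring.
    """

    n_te: int = 32
    n_points: int = 2048
    feature_dim: int = 128
    dilation_depth: int = 8       # dilations 2^1 .. 2^dilation_depth
    kernel_size: int = 2
    pab_window: int = 64
    n_blocks: int = 4
    n_components: int = 12
    decoder_dim: int | None = None
    # fixed label/input scalings (simulator units -> network units)
    input_scale: float = 30.0
    conc_scale: float = 10.0      # mM
    t2_scale: float = 0.25        # s
    amp_scale: float = 30.0
    # per-component relative scale (residual water labels sit far above the
    # metabolites; training normalizes each target to order 1)
    target_scales: list = None  # type: ignore[assignment]
    component_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pab_window <= 0:
            raise ValueError("pab_window must be positive")
        if self.pab_window > self.n_points:
            raise ValueError("pab_window must not exceed n_points")
        if self.kernel_size != 2:
            raise ValueError("only kernel size 2 is implemented")
        if self.decoder_dim is None:
            self.decoder_dim = self.feature_dim
        if self.target_scales is None:
            self.target_scales = [1.0] * self.n_components
        if len(self.target_scales) != self.n_components:
            raise ValueError("target_scales must have one entry per component")

    @property
    def dilations(self) -> list[int]:
        return [2 ** k for k in range(1, self.dilation_depth + 1)]

    @property
    def max_dilation(self) -> int:
        return 2 ** self.dilation_depth


def receptive_field_extent(cfg: ModelConfig) -> int:
    """Forward reach (in samples) of a PAB output past the pooling window.

    Kernel-2 convolutions tap positions ``p`` and ``p + d``; the GRU mixes
    echoes, not positions, so the reach is the summed dilation of all conv
    layers across all blocks.
    """
    return cfg.n_blocks * sum(cfg.dilations)


@dataclass
class Predictions:
    """Network outputs on physical scales."""

    concentrations: np.ndarray          # (b, n_components) mM
    avg_t2: np.ndarray                  # (b, n_components) s
    first_point_amplitudes: np.ndarray  # (b, n_te, n_components)
    reconstructed_fids: np.ndarray      # (b, n_components, n_te, n_points) complex
    te_representations: np.ndarray      # (b, n_te, feature_dim)
    jpress_representation: np.ndarray   # (b, feature_dim)
    component_names: list = field(default_factory=list)


class JpressNet:
    """The encoder-decoder with manual forward/backward passes."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.feature_dim
        # conv stack sees an amplitude-compressed featurization (arcsinh of
        # both channels plus the phase-invariant magnitude); residual water
        # can sit orders of magnitude above the metabolites and would
        # otherwise saturate the gated units.  The decoder keeps raw skips.
        self.input_proj = Dense("input_proj", 3, f, rng)
        self.blocks = []
        for b in range(cfg.n_blocks):
            convs = [GatedDilatedConv(f"block{b}/conv{i}", f, d, rng)
                     for i, d in enumerate(cfg.dilations)]
            gru = GRU(f"block{b}/gru", f, rng)
            self.blocks.append((convs, gru))
        c = cfg.n_components
        self.conc_hidden = Dense("conc/hidden", f, f, rng, activation="tanh")
        self.conc_out = Dense("conc/out", f, c, rng, bias_init=0.5)
        self.t2_hidden = Dense("t2/hidden", f, f, rng, activation="tanh")
        self.t2_out = Dense("t2/out", f, c, rng, bias_init=0.8)
        self.amp_hidden = Dense("amp/hidden", f, f, rng, activation="tanh")
        self.amp_out = Dense("amp/out", f, c, rng, bias_init=0.3)
        # decoder skips: raw input + every block's sequence + the TE-specific
        # representation broadcast along the position axis (global component
        # content conditioning the pointwise reconstruction)
        dec_in = 2 + cfg.n_blocks * f + f
        self.dec_hidden = Dense("dec/hidden", dec_in, cfg.decoder_dim, rng,
                                activation="tanh")
        self.dec_out = Dense("dec/out", cfg.decoder_dim, 2 * c, rng)
        self._cache = None

    # ---- parameters ----
    def params(self):
        out = self.input_proj.params()
        for convs, gru in self.blocks:
            for cv in convs:
                out += cv.params()
            out += gru.params()
        for layer in (self.conc_hidden, self.conc_out, self.t2_hidden,
                      self.t2_out, self.amp_hidden, self.amp_out,
                      self.dec_hidden, self.dec_out):
            out += layer.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.v.size for p in self.params())

    # ---- spec-level operations (forward only) ----
    @staticmethod
    def _featurize(x: np.ndarray) -> np.ndarray:
        """(..., 2) channels -> (..., 3) compressed features."""
        mag = np.sqrt(x[..., :1] ** 2 + x[..., 1:] ** 2)
        return np.arcsinh(np.concatenate([x, mag], axis=-1)).astype(DTYPE)

    def wavenet_features(self, fid_channels: np.ndarray,
                         block: int = 0) -> np.ndarray:
        """(n_points, 2) or (n, n_points, 2) -> per-position features.

        Runs the input featurization/projection plus one block's conv
        stack; sequence length is preserved.
        """
        x = np.asarray(fid_channels, dtype=DTYPE)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.shape[1] != self.cfg.n_points:
            raise ValueError(
                f"expected sequence length {self.cfg.n_points}, got {x.shape[1]}")
        y = self.input_proj.forward(self._featurize(x))
        for cv in self.blocks[block][0]:
            y, _ = cv.forward(y)
        return y[0] if squeeze else y

    def gru_fuse(self, te_features: np.ndarray, block: int = 0,
                 te_values: np.ndarray | None = None) -> np.ndarray:
        """(n_te, n_points, f) or (b, n_te, ...) -> same shape, fused over TE."""
        if te_values is not None and np.any(np.diff(np.asarray(te_values)) <= 0):
            raise ValueError("TE axis must be strictly ascending")
        x = np.asarray(te_features, dtype=DTYPE)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        b, t, p, f = x.shape
        seq = x.transpose(1, 0, 2, 3).reshape(t, b * p, f)
        out = self.blocks[block][1].forward(seq)
        out = out.reshape(t, b, p, f).transpose(1, 0, 2, 3)
        return out[0] if squeeze else out

    def pab(self, features: np.ndarray, window: int | None = None) -> np.ndarray:
        """Mean over the first ``window`` positions of the position axis."""
        w = self.cfg.pab_window if window is None else window
        if w <= 0:
            raise ValueError("pooling window must be positive")
        if w > features.shape[-2]:
            raise ValueError("pooling window exceeds sequence length")
        return np.asarray(features, dtype=DTYPE)[..., :w, :].mean(axis=-2)

    def encode(self, x: np.ndarray):
        """(b, n_te, n_points, 2) -> (te_reps (b, n_te, f), jpress (b, f))."""
        out = self._forward(np.asarray(x, dtype=DTYPE))
        return out["te_reps"], out["jpress"]

    def heads(self, te_reps: np.ndarray, jpress: np.ndarray):
        """Representations -> (concentrations, avg T2s, amplitudes), scaled."""
        conc = self.conc_out.forward(self.conc_hidden.forward(jpress))
        t2 = self.t2_out.forward(self.t2_hidden.forward(jpress))
        amp = self.amp_out.forward(self.amp_hidden.forward(te_reps))
        return conc, t2, amp

    def decode(self, x: np.ndarray, block_outputs: list[np.ndarray],
               te_reps: np.ndarray) -> np.ndarray:
        """Skip tensors -> component FIDs (b, c, n_te, n_points, 2)."""
        if len(block_outputs) != self.cfg.n_blocks:
            raise ValueError("decoder needs the output of every encoder block")
        if te_reps is None:
            raise ValueError("decoder needs the TE-specific representations")
        b, t, p, _ = x.shape
        reps = np.broadcast_to(te_reps[:, :, None, :],
                               (b, t, p, self.cfg.feature_dim))
        dec_in = np.concatenate([x] + list(block_outputs) + [reps], axis=-1)
        y = self.dec_out.forward(self.dec_hidden.forward(dec_in))
        c = self.cfg.n_components
        return y.reshape(b, t, p, c, 2).transpose(0, 3, 1, 2, 4)

    # ---- fused forward/backward used for training ----
    def _forward(self, x: np.ndarray) -> dict:
        cfg = self.cfg
        if x.shape[1:] != (cfg.n_te, cfg.n_points, 2):
            raise ValueError(
                f"expected input (b, {cfg.n_te}, {cfg.n_points}, 2), got {x.shape}")
        x = np.asarray(x, dtype=DTYPE)
        b, t, p, _ = x.shape
        f = cfg.feature_dim
        cur = self.input_proj.forward(self._featurize(x))
        block_outs = []
        for convs, gru in self.blocks:
            y = cur.reshape(b * t, p, f)
            for cv in convs:
                y, _ = cv.forward(y)
            seq = y.reshape(b, t, p, f).transpose(1, 0, 2, 3).reshape(t, b * p, f)
            g = gru.forward(seq)
            cur = g.reshape(t, b, p, f).transpose(1, 0, 2, 3)
            block_outs.append(cur)
        te_reps = cur[:, :, :cfg.pab_window, :].mean(axis=2)
        jpress = te_reps.mean(axis=1)
        conc, t2, amp = self.heads(te_reps, jpress)
        reps_b = np.broadcast_to(te_reps[:, :, None, :], (b, t, p, f))
        dec_in = np.concatenate([x] + block_outs + [reps_b], axis=-1)
        dec_h = self.dec_hidden.forward(dec_in)
        recon = self.dec_out.forward(dec_h)
        recon = recon.reshape(b, t, p, cfg.n_components, 2).transpose(0, 3, 1, 2, 4)
        self._cache = {"x": x, "shape": (b, t, p, f)}
        return {"te_reps": te_reps, "jpress": jpress, "conc": conc, "t2": t2,
                "amp": amp, "recon": recon}

    def _backward(self, grads: dict) -> None:
        """Backpropagate gradients of the scaled outputs."""
        cfg = self.cfg
        b, t, p, f = self._cache["shape"]
        w = cfg.pab_window
        # decoder
        d_recon = grads["recon"].transpose(0, 2, 3, 1, 4).reshape(b, t, p, -1)
        d_dec_in = self.dec_hidden.backward(self.dec_out.backward(d_recon))
        d_blocks_dec = [d_dec_in[..., 2 + i * f: 2 + (i + 1) * f]
                        for i in range(cfg.n_blocks)]
        d_te_dec = d_dec_in[..., 2 + cfg.n_blocks * f:].sum(axis=2)
        # heads
        d_jpress = self.conc_hidden.backward(self.conc_out.backward(grads["conc"]))
        d_jpress = d_jpress + self.t2_hidden.backward(self.t2_out.backward(grads["t2"]))
        d_te = self.amp_hidden.backward(self.amp_out.backward(grads["amp"]))
        d_te = d_te + d_jpress[:, None, :] / t + d_te_dec
        # PAB
        d_cur = np.zeros((b, t, p, f), dtype=DTYPE)
        d_cur[:, :, :w, :] = d_te[:, :, None, :] / w
        for i in range(cfg.n_blocks - 1, -1, -1):
            convs, gru = self.blocks[i]
            d_cur = d_cur + d_blocks_dec[i]
            d_seq = d_cur.transpose(1, 0, 2, 3).reshape(t, b * p, f)
            d_g = gru.backward(d_seq)
            d_y = d_g.reshape(t, b, p, f).transpose(1, 0, 2, 3).reshape(b * t, p, f)
            for cv in reversed(convs):
                d_y = cv.backward(d_y)
            d_cur = d_y.reshape(b, t, p, f)
        self.input_proj.backward(d_cur)

    def free_caches(self) -> None:
        """Drop stored forward activations (inference memory hygiene)."""
        self.input_proj._cache = None
        for convs, gru in self.blocks:
            for cv in convs:
                cv._cache = None
            gru._cache = None
        for layer in (self.conc_hidden, self.conc_out, self.t2_hidden,
                      self.t2_out, self.amp_hidden, self.amp_out,
                      self.dec_hidden, self.dec_out):
            layer._cache = None
        self._cache = None

    # ---- inference ----
    def predict(self, x: np.ndarray, clip_negative: bool = True,
                batch_size: int = 16) -> Predictions:
        """Run the network on raw simulator-unit input (b, n_te, n_points, 2).

        Inference is chunked (``batch_size``) and forward caches are freed
        afterwards: layer activations for large batches would otherwise
        dominate memory.
        """
        cfg = self.cfg
        if x.ndim == 3:
            x = x[None]
        x = np.asarray(x, dtype=DTYPE)
        chunks = []
        for k in range(0, len(x), batch_size):
            out = self._forward(x[k:k + batch_size] / cfg.input_scale)
            chunks.append({key: out[key] for key in
                           ("conc", "t2", "amp", "recon", "te_reps", "jpress")})
        self.free_caches()
        out = {key: np.concatenate([c[key] for c in chunks])
               for key in chunks[0]}
        ts = np.asarray(cfg.target_scales, dtype=float)
        conc = out["conc"] * cfg.conc_scale * ts
        t2 = out["t2"] * cfg.t2_scale
        amp = out["amp"] * cfg.amp_scale * ts
        if clip_negative:
            conc = np.maximum(conc, 0.0)
            amp = np.maximum(amp, 0.0)
        rec = out["recon"] * (cfg.input_scale * ts[:, None, None, None])
        recon = (rec[..., 0] + 1j * rec[..., 1]).astype(complex)
        return Predictions(
            concentrations=conc, avg_t2=t2, first_point_amplitudes=amp,
            reconstructed_fids=recon, te_representations=out["te_reps"],
            jpress_representation=out["jpress"],
            component_names=list(cfg.component_names))

    # ---- persistence ----
    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["config"] = json.dumps(asdict(self.cfg))
            for prm in self.params():
                fh.create_dataset(prm.name, data=prm.v)

    @classmethod
    def load(cls, path) -> "JpressNet":
        with h5py.File(path, "r") as fh:
            cfg_d = json.loads(fh.attrs["config"])
            cfg = ModelConfig(**cfg_d)
            model = cls(cfg)
            for prm in model.params():
                prm.v[...] = fh[prm.name][...]
        return model
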