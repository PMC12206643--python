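"""Dual-stream fusion network: CNN-BiLSTM + DC-IGN (convolutional VAE).

Stream 1 (temporal): a small CNN — conv/ReLU/max-pool blocks with SAME
padding — encodes each of the T time-step maps with *shared* weights; a
bidirectional LSTM consumes the T step features and the final forward and
backward hidden states are merged by concatenation, summation, or averaging.

Stream 2 (probabilistic): the T×(8,9,B) sample is stacked into an
(8, 9, T·B) volume and passed through a DC-IGN-family convolutional VAE —
strided convolutional encoder to a diagonal Gaussian posterior
q(z|x) = N(μ, diag σ²), reparameterized sampling, and a mirror decoder
(dense → nearest-neighbour upsampling → convolutions) reconstructing the
volume.  The original DC-IGN ladder (5×5 kernels, stride 2, channels
64–1024, 256-d latent) targets image-sized inputs and remains expressible
through :class:`ModelConfig`; the default ladder is scaled to the EEG grid.

Fusion: the merged temporal feature is concatenated with the latent mean μ
(so evaluation is deterministic), passed through dense layers and a softmax
head.

Everything — forward passes, analytic gradients, Adam — is implemented on
NumPy; the analytic gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError, ShapeError

MERGE_MODES = ("concat", "sum", "average")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; all shapes derive from these."""

    n_classes: int = 3
    input_shape: tuple[int, int, int, int] = (6, 8, 9, 4)  # (T, rows, cols, bands)
    cnn_channels: tuple[int, ...] = (32, 64)
    cnn_kernel: int = 3
    bilstm_hidden: int = 64
    merge_mode: str = "concat"
    dcign_channels: tuple[int, ...] = (32, 64, 128)
    dcign_kernel: int = 3
    latent_dim: int = 64
    fusion_hidden: tuple[int, ...] = (128,)

    def __post_init__(self) -> None:
        if self.merge_mode not in MERGE_MODES:
            raise InvalidArgumentError(
                f"merge_mode must be one of {MERGE_MODES}, got {self.merge_mode!r}")
        if self.latent_dim < 1:
            raise InvalidArgumentError("latent_dim must be >= 1")
        if self.n_classes < 2:
            raise InvalidArgumentError("n_classes must be >= 2")
        if len(self.input_shape) != 4:
            raise InvalidArgumentError("input_shape must be (T, rows, cols, bands)")

    # -- derived shapes ----------------------------------------------------

    @property
    def step_shape(self) -> tuple[int, int, int]:
        return self.input_shape[1:]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        """DC-IGN input: time steps folded into channels."""
        T, r, c, b = self.input_shape
        return (r, c, T * b)

    @property
    def cnn_feature_dim(self) -> int:
        h, w, _ = self.step_shape
        for _ in self.cnn_channels:
            h, w = -(-h // 2), -(-w // 2)          # ceil-mode 2×2 pooling
        return h * w * self.cnn_channels[-1]

    @property
    def temporal_dim(self) -> int:
        return (2 if self.merge_mode == "concat" else 1) * self.bilstm_hidden

    @property
    def encoder_shapes(self) -> list[tuple[int, int]]:
        """Spatial dims entering each encoder conv, plus the final map."""
        h, w, _ = self.volume_shape
        shapes = [(h, w)]
        for _ in self.dcign_channels:
            h, w = -(-h // 2), -(-w // 2)          # stride-2 SAME convs
            shapes.append((h, w))
        return shapes

    @property
    def encoder_flat_dim(self) -> int:
        h, w = self.encoder_shapes[-1]
        return h * w * self.dcign_channels[-1]


def original_dcign_config(**overrides) -> ModelConfig:
    """The image-scale DC-IGN ladder (5×5, stride 2, 64→1024, 256-d latent);
    only usable with image-sized ``input_shape``."""
    kw = dict(dcign_channels=(64, 128, 256, 512, 1024), dcign_kernel=5,
              latent_dim=256)
    kw.update(overrides)
    return ModelConfig(**kw)


@dataclass(frozen=True)
class ModelOutput:
    """Forward-pass result for one sample."""

    probs: np.ndarray       # (n_classes,), simplex
    mu: np.ndarray          # (latent_dim,)
    logvar: np.ndarray      # (latent_dim,)
    recon: np.ndarray       # same shape as the input sample tensor


# --------------------------------------------------------------------------
# Layer primitives (forward + backward)
# --------------------------------------------------------------------------

def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _same_pad(size: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return out, total // 2, total - total // 2


def conv2d(x, W, b, stride=1):
    """SAME-padded 2-D convolution. x: (B,H,W,Cin), W: (kh,kw,Cin,Cout)."""
    B, H, Wd, Cin = x.shape
    kh, kw, Cin2, Cout = W.shape
    if Cin != Cin2:
        raise ShapeError(f"input has {Cin} channels, kernel expects {Cin2}")
    Ho, ph0, ph1 = _same_pad(H, kh, stride)
    Wo, pw0, pw1 = _same_pad(Wd, kw, stride)
    xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    out = np.broadcast_to(b, (B, Ho, Wo, Cout)).copy()
    for m in range(kh):
        for n in range(kw):
            patch = xp[:, m:m + (Ho - 1) * stride + 1:stride,
                       n:n + (Wo - 1) * stride + 1:stride, :]
            out += patch @ W[m, n]
    cache = (xp, x.shape, (ph0, pw0), stride, (Ho, Wo))
    return out, cache


def conv2d_backward(dout, W, cache):
    xp, xshape, (ph0, pw0), stride, (Ho, Wo) = cache
    kh, kw = W.shape[:2]
    dW = np.zeros_like(W)
    db = dout.sum(axis=(0, 1, 2))
    dxp = np.zeros_like(xp)
    for m in range(kh):
        for n in range(kw):
            hs = slice(m, m + (Ho - 1) * stride + 1, stride)
            ws = slice(n, n + (Wo - 1) * stride + 1, stride)
            patch = xp[:, hs, ws, :]
            dW[m, n] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, hs, ws, :] += dout @ W[m, n].T
    _, H, Wd, _ = xshape
    dx = dxp[:, ph0:ph0 + H, pw0:pw0 + Wd, :]
    return dx, dW, db


def maxpool2(x):
    """2×2 max pooling, stride 2, ceil mode (odd edges padded with −inf)."""
    B, H, W, C = x.shape
    Ho, Wo = -(-H // 2), -(-W // 2)
    xp = np.pad(x, ((0, 0), (0, 2 * Ho - H), (0, 2 * Wo - W), (0, 0)),
                constant_values=-np.inf)
    win = (xp.reshape(B, Ho, 2, Wo, 2, C)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(B, Ho, Wo, 4, C))
    idx = win.argmax(axis=3)
    out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (idx, x.shape)


def maxpool2_backward(dout, cache):
    idx, xshape = cache
    B, H, W, C = xshape
    Ho, Wo = -(-H // 2), -(-W // 2)
    dwin = np.zeros((B, Ho, Wo, 4, C), dtype=dout.dtype)
    np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dxp = (dwin.reshape(B, Ho, Wo, 2, 2, C)
               .transpose(0, 1, 3, 2, 4, 5)
               .reshape(B, 2 * Ho, 2 * Wo, C))
    return dxp[:, :H, :W, :]


def resize_nearest(x, out_h, out_w):
    """Nearest-neighbour spatial resize to (out_h, out_w)."""
    B, H, W, C = x.shape
    ri = np.floor((np.arange(out_h) + 0.5) * H / out_h).astype(int)
    ci = np.floor((np.arange(out_w) + 0.5) * W / out_w).astype(int)
    out = x[:, ri][:, :, ci]
    return out, (ri, ci, x.shape)


def resize_nearest_backward(dout, cache):
    ri, ci, xshape = cache
    B = xshape[0]
    dx = np.zeros(xshape, dtype=dout.dtype)
    bi = np.arange(B)[:, None, None]
    np.add.at(dx, (bi, ri[None, :, None], ci[None, None, :]), dout)
    return dx


def lstm_forward(seq, Wx, Wh, b):
    """Unidirectional LSTM over (B, T, F); returns all hidden states.

    Gate pre-activations are ordered [input, forget, cell, output]; the
    recursion is the standard
    f_t = σ(·), i_t = σ(·), c̃_t = tanh(·), c_t = f_t·c_{t−1} + i_t·c̃_t,
    o_t = σ(·), h_t = o_t·tanh(c_t).
    """
    B, T, F = seq.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=seq.dtype)
    c = np.zeros((B, H), dtype=seq.dtype)
    hs = np.zeros((B, T, H), dtype=seq.dtype)
    caches = []
    for t in range(T):
        x = seq[:, t]
        a = x @ Wx + h @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        caches.append((x, h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        hs[:, t] = h
    return hs, caches


def lstm_backward(dhs, seq, Wx, Wh, caches):
    """BPTT given per-step gradients dhs (B, T, H) on the hidden states."""
    B, T, F = seq.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=seq.dtype)
    dseq = np.zeros_like(seq)
    dh_next = np.zeros((B, H), dtype=seq.dtype)
    dc_next = np.zeros((B, H), dtype=seq.dtype)
    for t in reversed(range(T)):
        x, h_prev, c_prev, i, f, g, o, tc = caches[t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc ** 2)
        di, dg, df = dc * g, dc * i, dc * c_prev
        dc_next = dc * f
        da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
        dWx += x.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dseq[:, t] += da @ Wx.T
        dh_next = da @ Wh.T
    return dseq, dWx, dWh, db


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

def init_params(config: ModelConfig, seed: int = 0,
                dtype=np.float64) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, reproducible under seed."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}

    def glorot(*shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(dtype)

    def conv_w(name, k, cin, cout):
        params[f"{name}_W"] = glorot(k, k, cin, cout,
                                     fan_in=k * k * cin, fan_out=k * k * cout)
        params[f"{name}_b"] = np.zeros(cout, dtype=dtype)

    def dense_w(name, din, dout):
        params[f"{name}_W"] = glorot(din, dout, fan_in=din, fan_out=dout)
        params[f"{name}_b"] = np.zeros(dout, dtype=dtype)

    # CNN stream (weights shared over the T steps)
    cin = config.step_shape[-1]
    for i, cout in enumerate(config.cnn_channels):
        conv_w(f"cnn{i}", config.cnn_kernel, cin, cout)
        cin = cout

    # BiLSTM
    F, H = config.cnn_feature_dim, config.bilstm_hidden
    for d in ("f", "b"):
        params[f"lstm_{d}_Wx"] = glorot(F, 4 * H, fan_in=F, fan_out=4 * H)
        params[f"lstm_{d}_Wh"] = glorot(H, 4 * H, fan_in=H, fan_out=4 * H)
        params[f"lstm_{d}_b"] = np.zeros(4 * H, dtype=dtype)

    # DC-IGN encoder
    cin = config.volume_shape[-1]
    for i, cout in enumerate(config.dcign_channels):
        conv_w(f"enc{i}", config.dcign_kernel, cin, cout)
        cin = cout
    dense_w("enc_mu", config.encoder_flat_dim, config.latent_dim)
    dense_w("enc_lv", config.encoder_flat_dim, config.latent_dim)

    # DC-IGN decoder (mirror)
    dense_w("dec_fc", config.latent_dim, config.encoder_flat_dim)
    ch = list(config.dcign_channels)
    for i in range(len(ch) - 1, 0, -1):
        conv_w(f"dec{i}", config.dcign_kernel, ch[i], ch[i - 1])
    conv_w("dec_out", config.dcign_kernel, ch[0], config.volume_shape[-1])

    # Fusion head
    din = config.temporal_dim + config.latent_dim
    for i, width in enumerate(config.fusion_hidden):
        dense_w(f"fus{i}", din, width)
        din = width
    dense_w("out", din, config.n_classes)
    return params


# --------------------------------------------------------------------------
# The model
# --------------------------------------------------------------------------

class FusionModel:
    """CNN-BiLSTM + DC-IGN fusion classifier over (T, 8, 9, B) samples."""

    def __init__(self, config: ModelConfig,
                 params: dict[str, np.ndarray] | None = None,
                 seed: int = 0, dtype=np.float64):
        self.config = config
        self.dtype = dtype
        self.params = params if params is not None else init_params(
            config, seed=seed, dtype=dtype)

    # -- stream pieces (public op surface; batch-first) ---------------------

    def cnn_encode(self, step_tensor: np.ndarray) -> np.ndarray:
        """Encode one (8,9,B) map — or a batch of them — to a feature vector."""
        single = step_tensor.ndim == 3
        x = step_tensor[None] if single else step_tensor
        if x.shape[1:] != self.config.step_shape:
            raise ShapeError(f"expected step shape {self.config.step_shape}, "
                             f"got {x.shape[1:]}")
        out, _ = self._cnn_forward(x.astype(self.dtype))
        return out[0] if single else out

    def bilstm_encode(self, sequence: np.ndarray,
                      merge_mode: str | None = None) -> np.ndarray:
        """Merge final forward/backward hidden states over a (T, F) sequence
        (or a (B, T, F) batch)."""
        merge = merge_mode or self.config.merge_mode
        if merge not in MERGE_MODES:
            raise InvalidArgumentError(f"unknown merge mode {merge!r}")
        single = sequence.ndim == 2
        seq = sequence[None] if single else sequence
        if seq.shape[1] < 1:
            raise InvalidArgumentError("sequence must have at least one step")
        out, _ = self._bilstm_forward(seq.astype(self.dtype), merge)
        return out[0] if single else out

    def dcign_encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (μ, log σ²) for an (8,9,T·B) volume or batch."""
        single = x.ndim == 3
        v = x[None] if single else x
        if v.shape[1:] != self.config.volume_shape:
            raise ShapeError(f"expected volume shape {self.config.volume_shape}, "
                             f"got {v.shape[1:]}")
        (mu, logvar), _ = self._encoder_forward(v.astype(self.dtype))
        return (mu[0], logvar[0]) if single else (mu, logvar)

    @staticmethod
    def reparameterize(mu: np.ndarray, logvar: np.ndarray,
                       noise_seed=None) -> np.ndarray:
        """z = μ + exp(logvar/2)·ε, ε ~ N(0, I) from a seeded generator."""
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
            raise InvalidArgumentError("mu/logvar must be finite")
        rng = (noise_seed if isinstance(noise_seed, np.random.Generator)
               else np.random.default_rng(noise_seed))
        eps = rng.standard_normal(mu.shape).astype(mu.dtype)
        return mu + np.exp(0.5 * logvar) * eps

    def dcign_decode(self, z: np.ndarray) -> np.ndarray:
        """Reconstruct the encoder's input volume from latent z (or batch)."""
        single = z.ndim == 1
        zz = z[None] if single else z
        if zz.shape[-1] != self.config.latent_dim:
            raise ShapeError(f"latent dim {zz.shape[-1]} != "
                             f"{self.config.latent_dim}")
        recon, _ = self._decoder_forward(zz.astype(self.dtype))
        return recon[0] if single else recon

    def fuse_and_classify(self, temporal_feature: np.ndarray,
                          latent_mu: np.ndarray) -> np.ndarray:
        """Concatenate both streams, dense layers, softmax."""
        single = temporal_feature.ndim == 1
        t = temporal_feature[None] if single else temporal_feature
        m = latent_mu[None] if single else latent_mu
        if t.shape[-1] != self.config.temporal_dim or \
                m.shape[-1] != self.config.latent_dim:
            raise ShapeError("fusion input dims do not match the config")
        fused = np.concatenate([t, m], axis=-1).astype(self.dtype)
        probs, _ = self._head_forward(fused)
        return probs[0] if single else probs

    # -- full forward --------------------------------------------------------

    def forward(self, sample: np.ndarray, mode: str = "eval",
                noise_seed=None) -> ModelOutput:
        """Run one (T,8,9,B) sample through both streams.

        ``mode='eval'`` decodes from z = μ (deterministic); ``mode='train'``
        samples z by reparameterization with the seeded generator.
        """
        if sample.shape != self.config.input_shape:
            raise ShapeError(f"expected sample shape {self.config.input_shape}, "
                             f"got {sample.shape}")
        if mode not in ("eval", "train"):
            raise InvalidArgumentError("mode must be 'eval' or 'train'")
        x = sample[None].astype(self.dtype)
        eps = None
        if mode == "train":
            rng = (noise_seed if isinstance(noise_seed, np.random.Generator)
                   else np.random.default_rng(noise_seed))
            eps = rng.standard_normal((1, self.config.latent_dim)).astype(self.dtype)
        res, _ = self._forward_batch(x, eps)
        T, r, c, b = self.config.input_shape
        recon = res["recon"][0].reshape(r, c, T, b).transpose(2, 0, 1, 3)
        return ModelOutput(probs=res["probs"][0], mu=res["mu"][0],
                           logvar=res["logvar"][0], recon=recon)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax class predictions for a (N,T,8,9,B) array, eval mode."""
        preds = []
        for i in range(0, len(x), batch_size):
            res, _ = self._forward_batch(
                x[i:i + batch_size].astype(self.dtype), None)
            preds.append(res["probs"].argmax(axis=1))
        return np.concatenate(preds) if preds else np.zeros(0, dtype=int)

    def penultimate_features(self, x: np.ndarray,
                             batch_size: int = 256) -> np.ndarray:
        """Fused-layer activations (input to the class logits), eval mode."""
        feats = []
        for i in range(0, len(x), batch_size):
            res, cache = self._forward_batch(
                x[i:i + batch_size].astype(self.dtype), None)
            feats.append(cache["head_hidden"][-1])
        return np.concatenate(feats) if feats else np.zeros((0, 0))

    # -- internal forward pieces (return caches for backprop) ---------------

    def _volume(self, x: np.ndarray) -> np.ndarray:
        B, T, r, c, b = x.shape
        return x.transpose(0, 2, 3, 1, 4).reshape(B, r, c, T * b)

    def _cnn_forward(self, x):
        caches = []
        h = x
        for i in range(len(self.config.cnn_channels)):
            conv, ccache = conv2d(h, self.params[f"cnn{i}_W"],
                                  self.params[f"cnn{i}_b"])
            mask = conv > 0
            act = conv * mask
            pooled, pcache = maxpool2(act)
            caches.append((ccache, mask, pcache))
            h = pooled
        shape = h.shape
        return h.reshape(h.shape[0], -1), (caches, shape)

    def _cnn_backward(self, dflat, cache):
        caches, shape = cache
        dh = dflat.reshape(shape)
        for i in reversed(range(len(self.config.cnn_channels))):
            ccache, mask, pcache = caches[i]
            dact = maxpool2_backward(dh, pcache)
            dconv = dact * mask
            dh, dW, db = conv2d_backward(dconv, self.params[f"cnn{i}_W"], ccache)
            self._grads[f"cnn{i}_W"] += dW
            self._grads[f"cnn{i}_b"] += db
        return dh

    def _bilstm_forward(self, seq, merge):
        hs_f, cache_f = lstm_forward(seq, self.params["lstm_f_Wx"],
                                     self.params["lstm_f_Wh"],
                                     self.params["lstm_f_b"])
        seq_r = seq[:, ::-1]
        hs_b, cache_b = lstm_forward(seq_r, self.params["lstm_b_Wx"],
                                     self.params["lstm_b_Wh"],
                                     self.params["lstm_b_b"])
        hf, hb = hs_f[:, -1], hs_b[:, -1]
        if merge == "concat":
            out = np.concatenate([hf, hb], axis=1)
        elif merge == "sum":
            out = hf + hb
        else:
            out = 0.5 * (hf + hb)
        return out, (seq, seq_r, cache_f, cache_b, merge)

    def _bilstm_backward(self, dout, cache):
        seq, seq_r, cache_f, cache_b, merge = cache
        H = self.config.bilstm_hidden
        if merge == "concat":
            dhf, dhb = dout[:, :H], dout[:, H:]
        elif merge == "sum":
            dhf = dhb = dout
        else:
            dhf = dhb = 0.5 * dout
        B, T, _ = seq.shape
        dhs_f = np.zeros((B, T, H), dtype=seq.dtype)
        dhs_f[:, -1] = dhf
        dhs_b = np.zeros((B, T, H), dtype=seq.dtype)
        dhs_b[:, -1] = dhb
        dseq_f, dWx, dWh, db = lstm_backward(
            dhs_f, seq, self.params["lstm_f_Wx"], self.params["lstm_f_Wh"],
            cache_f)
        self._grads["lstm_f_Wx"] += dWx
        self._grads["lstm_f_Wh"] += dWh
        self._grads["lstm_f_b"] += db
        dseq_r, dWx, dWh, db = lstm_backward(
            dhs_b, seq_r, self.params["lstm_b_Wx"], self.params["lstm_b_Wh"],
            cache_b)
        self._grads["lstm_b_Wx"] += dWx
        self._grads["lstm_b_Wh"] += dWh
        self._grads["lstm_b_b"] += db
        return dseq_f + dseq_r[:, ::-1]

    def _encoder_forward(self, v):
        caches = []
        h = v
        for i in range(len(self.config.dcign_channels)):
            conv, ccache = conv2d(h, self.params[f"enc{i}_W"],
                                  self.params[f"enc{i}_b"], stride=2)
            mask = conv > 0
            h = conv * mask
            caches.append((ccache, mask))
        flat = h.reshape(h.shape[0], -1)
        mu = flat @ self.params["enc_mu_W"] + self.params["enc_mu_b"]
        logvar = flat @ self.params["enc_lv_W"] + self.params["enc_lv_b"]
        return (mu, logvar), (caches, flat, h.shape)

    def _encoder_backward(self, dmu, dlogvar, cache):
        caches, flat, hshape = cache
        self._grads["enc_mu_W"] += flat.T @ dmu
        self._grads["enc_mu_b"] += dmu.sum(axis=0)
        self._grads["enc_lv_W"] += flat.T @ dlogvar
        self._grads["enc_lv_b"] += dlogvar.sum(axis=0)
        dflat = dmu @ self.params["enc_mu_W"].T + \
            dlogvar @ self.params["enc_lv_W"].T
        dh = dflat.reshape(hshape)
        for i in reversed(range(len(self.config.dcign_channels))):
            ccache, mask = caches[i]
            dconv = dh * mask
            dh, dW, db = conv2d_backward(dconv, self.params[f"enc{i}_W"], ccache)
            self._grads[f"enc{i}_W"] += dW
            self._grads[f"enc{i}_b"] += db
        return dh

    def _decoder_forward(self, z):
        cfg = self.config
        shapes = cfg.encoder_shapes           # [(8,9),(4,5),(2,3),(1,2)] e.g.
        hk, wk = shapes[-1]
        fc = z @ self.params["dec_fc_W"] + self.params["dec_fc_b"]
        mask0 = fc > 0
        h = (fc * mask0).reshape(len(z), hk, wk, cfg.dcign_channels[-1])
        caches = [("fc", mask0, h.shape)]
        n = len(cfg.dcign_channels)
        for i in range(n - 1, 0, -1):
            target = shapes[i]
            up, rcache = resize_nearest(h, *target)
            conv, ccache = conv2d(up, self.params[f"dec{i}_W"],
                                  self.params[f"dec{i}_b"])
            mask = conv > 0
            h = conv * mask
            caches.append((f"dec{i}", rcache, ccache, mask))
        up, rcache = resize_nearest(h, *shapes[0])
        recon, ccache = conv2d(up, self.params["dec_out_W"],
                               self.params["dec_out_b"])
        caches.append(("dec_out", rcache, ccache))
        return recon, caches

    def _decoder_backward(self, drecon, caches):
        tag, rcache, ccache = caches[-1]
        dh, dW, db = conv2d_backward(drecon, self.params["dec_out_W"], ccache)
        self._grads["dec_out_W"] += dW
        self._grads["dec_out_b"] += db
        dh = resize_nearest_backward(dh, rcache)
        for entry in reversed(caches[1:-1]):
            name, rcache, ccache, mask = entry
            dconv = dh * mask
            dh, dW, db = conv2d_backward(dconv, self.params[f"{name}_W"], ccache)
            self._grads[f"{name}_W"] += dW
            self._grads[f"{name}_b"] += db
            dh = resize_nearest_backward(dh, rcache)
        _, mask0, hshape = caches[0]
        dfc = dh.reshape(hshape[0], -1) * mask0
        self._grads["dec_fc_W"] += self._dec_z.T @ dfc
        self._grads["dec_fc_b"] += dfc.sum(axis=0)
        return dfc @ self.params["dec_fc_W"].T

    def _head_forward(self, fused):
        hidden = [fused]
        masks = []
        h = fused
        for i in range(len(self.config.fusion_hidden)):
            pre = h @ self.params[f"fus{i}_W"] + self.params[f"fus{i}_b"]
            mask = pre > 0
            h = pre * mask
            masks.append(mask)
            hidden.append(h)
        logits = h @ self.params["out_W"] + self.params["out_b"]
        probs = softmax(logits)
        return probs, (hidden, masks)

    def _head_backward(self, dlogits, cache):
        hidden, masks = cache
        self._grads["out_W"] += hidden[-1].T @ dlogits
        self._grads["out_b"] += dlogits.sum(axis=0)
        dh = dlogits @ self.params["out_W"].T
        for i in reversed(range(len(self.config.fusion_hidden))):
            dpre = dh * masks[i]
            self._grads[f"fus{i}_W"] += hidden[i].T @ dpre
            self._grads[f"fus{i}_b"] += dpre.sum(axis=0)
            dh = dpre @ self.params[f"fus{i}_W"].T
        return dh

    def _forward_batch(self, x, eps):
        """Forward both streams for a (B,T,r,c,b) batch.

        ``eps`` is the reparameterization noise (B, latent) or None for
        z = μ (eval mode).
        """
        cfg = self.config
        if x.shape[1:] != cfg.input_shape:
            raise ShapeError(f"expected {cfg.input_shape}, got {x.shape[1:]}")
        B, T = x.shape[0], cfg.input_shape[0]
        steps = x.reshape((B * T,) + cfg.step_shape)
        feats, cnn_cache = self._cnn_forward(steps)
        seq = feats.reshape(B, T, -1)
        temporal, lstm_cache = self._bilstm_forward(seq, cfg.merge_mode)

        v = self._volume(x)
        (mu, logvar), enc_cache = self._encoder_forward(v)
        z = mu if eps is None else mu + np.exp(0.5 * logvar) * eps
        self._dec_z = z
        recon, dec_caches = self._decoder_forward(z)

        fused = np.concatenate([temporal, mu], axis=1)
        probs, head_cache = self._head_forward(fused)
        res = {"probs": probs, "mu": mu, "logvar": logvar, "recon": recon,
               "v": v, "z": z}
        cache = {"cnn": cnn_cache, "lstm": lstm_cache, "enc": enc_cache,
                 "dec": dec_caches, "head": head_cache,
                 "head_hidden": head_cache[0], "eps": eps, "B": B, "T": T}
        return res, cache

    # -- loss and gradients --------------------------------------------------

    def loss_and_grads(self, x, y, lambda_vae: float = 1.0, beta: float = 1.0,
                       eps=None):
        """Total loss CE + λ·MSE(recon, x) + β·KL and analytic gradients.

        ``eps``: reparameterization noise (B, latent_dim); None → z = μ.
        Returns (loss, grads dict, metrics dict).
        """
        x = np.ascontiguousarray(x, dtype=self.dtype)
        y = np.asarray(y)
        B = len(x)
        res, cache = self._forward_batch(x, eps)
        probs, mu, logvar, recon, v = (res["probs"], res["mu"], res["logvar"],
                                       res["recon"], res["v"])
        eps_used = cache["eps"]

        logp = np.log(np.clip(probs[np.arange(B), y], 1e-300, None))
        ce = -logp.mean()
        mse = float(((recon - v) ** 2).mean())
        kl = float(0.5 * (mu ** 2 + np.exp(logvar) - 1.0 - logvar).sum() / B)
        loss = ce + lambda_vae * mse + beta * kl
        metrics = {"ce": float(ce), "mse": mse, "kl": kl, "loss": float(loss),
                   "hits": int((probs.argmax(axis=1) == y).sum())}

        self._grads = {k: np.zeros_like(p) for k, p in self.params.items()}

        # classifier head
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dfused = self._head_backward(dlogits, cache["head"])
        dtemporal = dfused[:, :self.config.temporal_dim]
        dmu = dfused[:, self.config.temporal_dim:].copy()

        # reconstruction
        drecon = lambda_vae * 2.0 * (recon - v) / recon.size
        dz = self._decoder_backward(drecon, cache["dec"])
        dlogvar = np.zeros_like(logvar)
        dmu += dz
        if eps_used is not None:
            dlogvar += dz * eps_used * 0.5 * np.exp(0.5 * logvar)

        # KL
        dmu += beta * mu / B
        dlogvar += beta * 0.5 * (np.exp(logvar) - 1.0) / B

        self._encoder_backward(dmu, dlogvar, cache["enc"])

        # temporal stream
        dseq = self._bilstm_backward(dtemporal, cache["lstm"])
        dsteps = dseq.reshape(B * cache["T"], -1)
        self._cnn_backward(dsteps, cache["cnn"])

        grads = self._grads
        del self._grads, self._dec_z
        return loss, grads, metrics


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

def _normalize_ckpt_path(path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    return path


def save_checkpoint(model: FusionModel, path) -> None:
    """Write named parameter arrays (.npz) plus a JSON config sidecar."""
    path = _normalize_ckpt_path(path)
    np.savez(path, **model.params)
    sidecar = path.with_name(path.name + ".json")
    cfg = asdict(model.config)
    sidecar.write_text(json.dumps(cfg, sort_keys=True, indent=1))


def load_checkpoint(path) -> FusionModel:
    path = _normalize_ckpt_path(path)
    sidecar = path.with_name(path.name + ".json")
    cfg = json.loads(sidecar.read_text())
    for key in ("input_shape", "cnn_channels", "dcign_channels", "fusion_hidden"):
        cfg[key] = tuple(cfg[key])
    config = ModelConfig(**cfg)
    with np.load(path) as data:
        params = {k: data[k] for k in data.files}
    return FusionModel(config, params=params,
                       dtype=next(iter(params.values())).dtype)
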