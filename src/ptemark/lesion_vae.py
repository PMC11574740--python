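"""Unsupervised lesion scoring with a slice-wise variational autoencoder.

A VAE trained on (mostly) lesion-free 2-D brain slices learns to encode
normal anatomy; decoding an image that contains a lesion yields a
reconstruction without the anomaly, so the per-pixel difference between the
original and decoded image serves as a lesion score.  The pipeline is:
histogram matching to a reference subject, slice-wise VAE training,
reconstruction-error maps (median-filtered 7x7 to remove isolated pixels),
across-subject one-class outlier binarization per voxel, and per-ROI lesion
volumes by voxel counting.

The network (three stride-2 conv blocks with batch-norm/ReLU, a two-headed
fully connected bottleneck, and a mirrored deconvolutional decoder) is
implemented directly in NumPy: convolution via im2col, transposed convolution
as zero-stuffing followed by convolution, explicit backward passes, and an
Adam optimizer.  Inference decodes from the latent mean, so score maps are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats
from skimage.transform import resize
from sklearn.svm import OneClassSVM

from .synthetic_cohort import Parcellation

__all__ = [
    "VAEArchitecture",
    "TrainConfig",
    "VAEModel",
    "build_vae",
    "train_vae",
    "reconstruct",
    "histogram_match",
    "median_filter",
    "lesion_score_map",
    "score_from_difference",
    "extract_brain_slices",
    "binarize_lesions",
    "roi_lesion_volumes",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VAEArchitecture:
    """Slice VAE: 3 conv blocks down, FC bottleneck (mu, log-variance),
    FC + 3 deconv blocks up, final stride-1 deconv to the input size."""

    input_size: int = 128
    channels: tuple[int, int, int] = (32, 64, 128)
    latent_dim: int = 32
    kernel: int = 4
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three stride-2 stages)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 2e-3
    kl_weight: float = 1.0
    grad_clip: float = 1e4  # global-norm clip; tames early optimization spikes
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _im2col(x, k, s, p):
    """(N, C, H, W) -> flattened patches (N*L, C*k*k) with L = ho*wo."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, ho, wo


def _col2im(cols, n, c, ho, wo, out_hw, k, s, p, dtype):
    """Adjoint of _im2col: scatter-add patches back onto the (H, W) grid."""
    h, w = out_hw
    patches = np.ascontiguousarray(
        cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    )  # (n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * ho : s, j : j + s * wo : s] += patches[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w] if p else xp


class _Conv2d:
    """Plain convolution, NCHW, arbitrary stride, symmetric zero padding."""

    def __init__(self, cin, cout, k, stride, pad, rng, dtype):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.s, self.p = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        n = x.shape[0]
        cols, ho, wo = _im2col(x, self.k, self.s, self.p)
        y = cols @ self.W.T + self.b
        self._cache = (cols, x.shape, ho, wo)
        return (
            y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2).copy()
        )

    def backward(self, dy):
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            n * ho * wo, self.cout
        )
        self.dW = dyf.T @ cols
        self.db = dyf.sum(axis=0)
        dcols = dyf @ self.W
        return _col2im(dcols, n, c, ho, wo, (h, w), self.k, self.s, self.p, dy.dtype)


class _ConvTranspose2d:
    """Transposed convolution: the adjoint of a stride-s convolution.

    With kernel k, stride s and padding p, output size is (H-1)*s - 2p + k;
    the forward pass is a GEMM followed by a patch scatter-add (col2im), the
    backward pass an im2col followed by GEMMs — the exact mirror of _Conv2d.
    """

    def __init__(self, cin, cout, k, stride, pad, rng, dtype):
        fan_in = cin  # each output pixel receives k*k/s^2 taps per in-channel
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / (fan_in * k * k / stride**2)), (cin, cout * k * k)
        ).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.s, self.p = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        n, c, h, w = x.shape
        hout = (h - 1) * self.s - 2 * self.p + self.k
        wout = (w - 1) * self.s - 2 * self.p + self.k
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        dcols = xf @ self.W
        y = _col2im(
            dcols, n, self.cout, h, w, (hout, wout), self.k, self.s, self.p, x.dtype
        )
        self._cache = (xf, x.shape)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        xf, xshape = self._cache
        n, c, h, w = xshape
        cols, ho, wo = _im2col(dy, self.k, self.s, self.p)  # ho=h, wo=w
        self.dW = xf.T @ cols
        self.db = dy.sum(axis=(0, 2, 3))
        dxf = cols @ self.W.T
        return dxf.reshape(n, h, w, c).transpose(0, 3, 1, 2).copy()


class _BatchNorm2d:
    def __init__(self, c, dtype, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            inv[None, :, None, None]
            / m
            * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        )


class _ReLU:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Dense:
    def __init__(self, nin, nout, rng, dtype):
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nout, nin)).astype(dtype)
        self.b = np.zeros(nout, dtype=dtype)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W


class _Sigmoid:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class VAEModel:
    architecture: VAEArchitecture
    encoder: list
    fc_mu: _Dense
    fc_logvar: _Dense
    fc_dec: _Dense
    decoder: list
    seed: int
    dtype: type = np.float32
    epoch_losses: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.epoch_losses[-1] if self.epoch_losses else float("nan")

    def _layers(self):
        return [*self.encoder, self.fc_mu, self.fc_logvar, self.fc_dec, *self.decoder]

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def gradients(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads())
        return out

    def encode(self, x, train):
        h = x
        for layer in self.encoder:
            h = layer.forward(h, train)
        self._enc_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        return self.fc_mu.forward(flat, train), self.fc_logvar.forward(flat, train)

    def decode(self, z, train):
        a = self.architecture
        s = a.input_size // 8
        h = self.fc_dec.forward(z, train)
        h = h.reshape(z.shape[0], a.channels[2], s, s)
        for layer in self.decoder:
            h = layer.forward(h, train)
        return h

    def forward(self, x, eps=None, train=True):
        mu, logvar = self.encode(x, train)
        if eps is None:
            z = mu
        else:
            z = mu + np.exp(0.5 * logvar) * eps
        return self.decode(z, train), mu, logvar, z

    def loss_and_grads(self, x, eps, kl_weight, train=True):
        """Full forward/backward; returns (total, recon, kl) per-batch means.

        The evidence-bound loss is 0.5*||x - xhat||^2 (Gaussian reconstruction)
        plus kl_weight times the analytic Gaussian KL term.
        """
        n = x.shape[0]
        xhat, mu, logvar, z = self.forward(x, eps=eps, train=train)
        recon = 0.5 * float(((xhat - x) ** 2).sum()) / n
        kl = -0.5 * float((1.0 + logvar - mu**2 - np.exp(logvar)).sum()) / n
        loss = recon + kl_weight * kl

        dxhat = (xhat - x) / n
        dh = dxhat
        for layer in reversed(self.decoder):
            dh = layer.backward(dh)
        dz = self.fc_dec.backward(dh.reshape(n, -1))
        if eps is None:
            dmu = dz.copy()
            dlogvar = np.zeros_like(dz)
        else:
            dmu = dz.copy()
            dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar)
        dmu += kl_weight * mu / n
        dlogvar += kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n
        dflat = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlogvar)
        dh = dflat.reshape(self._enc_shape)
        for layer in reversed(self.encoder):
            dh = layer.backward(dh)
        return loss, recon, kl


def build_vae(
    architecture: VAEArchitecture, seed: int = 0, dtype=np.float32
) -> VAEModel:
    rng = np.random.default_rng(seed)
    a = architecture
    k = a.kernel
    c1, c2, c3 = a.channels
    enc = []
    cin = a.in_channels
    for cout in (c1, c2, c3):
        enc += [
            _Conv2d(cin, cout, k, 2, 1, rng, dtype),
            _BatchNorm2d(cout, dtype),
            _ReLU(),
        ]
        cin = cout
    s = a.input_size // 8
    flat = c3 * s * s
    fc_mu = _Dense(flat, a.latent_dim, rng, dtype)
    fc_logvar = _Dense(flat, a.latent_dim, rng, dtype)
    fc_dec = _Dense(a.latent_dim, flat, rng, dtype)
    dec = []
    cin = c3
    for cout in (c2, c1, c1):
        dec += [
            _ConvTranspose2d(cin, cout, k, 2, 1, rng, dtype),
            _BatchNorm2d(cout, dtype),
            _ReLU(),
        ]
        cin = cout
    dec += [_ConvTranspose2d(cin, a.in_channels, 3, 1, 1, rng, dtype), _Sigmoid()]
    return VAEModel(
        architecture=a,
        encoder=enc,
        fc_mu=fc_mu,
        fc_logvar=fc_logvar,
        fc_dec=fc_dec,
        decoder=dec,
        seed=seed,
        dtype=dtype,
    )


def save_model(model: VAEModel, path) -> None:
    """Single-file checkpoint: architecture, weights, running stats, seed."""
    a = model.architecture
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    bn_states = [
        layer
        for layer in model._layers()
        if isinstance(layer, _BatchNorm2d)
    ]
    for i, bn in enumerate(bn_states):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(
        path,
        input_size=a.input_size,
        channels=np.array(a.channels),
        latent_dim=a.latent_dim,
        kernel=a.kernel,
        in_channels=a.in_channels,
        seed=model.seed,
        epoch_losses=np.array(model.epoch_losses),
        **arrays,
    )


def load_model(path) -> VAEModel:
    with np.load(path) as data:
        arch = VAEArchitecture(
            input_size=int(data["input_size"]),
            channels=tuple(int(c) for c in data["channels"]),
            latent_dim=int(data["latent_dim"]),
            kernel=int(data["kernel"]),
            in_channels=int(data["in_channels"]),
        )
        model = build_vae(arch, seed=int(data["seed"]))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"param_{i}"].astype(p.dtype)
        bn_states = [l for l in model._layers() if isinstance(l, _BatchNorm2d)]
        for i, bn in enumerate(bn_states):
            bn.running_mean = data[f"bn_mean_{i}"].astype(bn.running_mean.dtype)
            bn.running_var = data[f"bn_var_{i}"].astype(bn.running_var.dtype)
        model.epoch_losses = [float(x) for x in data["epoch_losses"]]
    return model


__all__ += ["save_model", "load_model"]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def train_vae(
    slices: np.ndarray,
    architecture: VAEArchitecture,
    train_config: TrainConfig,
    dtype=np.float32,
) -> VAEModel:
    """Train the slice VAE; returns the model with per-epoch mean losses.

    ``slices`` is (n, input_size, input_size) in [0, 1].  Training is fully
    seeded (initialization, shuffling and the reparameterization noise), so
    the same seed reproduces the same final loss bit for bit.
    """
    slices = np.asarray(slices, dtype=dtype)
    if slices.ndim != 3 or slices.shape[1:] != (architecture.input_size,) * 2:
        raise ValueError(
            f"slices must be (n, {architecture.input_size}, {architecture.input_size})"
        )
    if slices.shape[0] < train_config.batch_size:
        raise ValueError("need at least one full batch of slices")
    model = build_vae(architecture, seed=train_config.seed, dtype=dtype)
    opt = _Adam(model.parameters(), train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed + 1)
    x_all = slices[:, None, :, :]
    n = x_all.shape[0]
    bs = train_config.batch_size
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            xb = x_all[order[start : start + bs]]
            eps = rng.standard_normal(
                (xb.shape[0], architecture.latent_dim)
            ).astype(dtype)
            loss, recon, kl = model.loss_and_grads(
                xb, eps, train_config.kl_weight, train=True
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // bs}"
                )
            grads = model.gradients()
            if train_config.grad_clip:
                gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads))
                if gnorm > train_config.grad_clip:
                    scale = train_config.grad_clip / gnorm
                    grads = [g * scale for g in grads]
            opt.step(model.parameters(), grads)
            losses.append(loss)
        model.epoch_losses.append(float(np.mean(losses)))
        logger.info("epoch %d: loss %.4f", epoch, model.epoch_losses[-1])
    return model


def reconstruct(model: VAEModel, slice_2d: np.ndarray) -> np.ndarray:
    """Deterministic decode from the latent mean (no sampling at inference)."""
    size = model.architecture.input_size
    slice_2d = np.asarray(slice_2d)
    if slice_2d.shape != (size, size):
        raise ValueError(f"slice shape {slice_2d.shape} != ({size}, {size})")
    x = slice_2d.astype(model.dtype)[None, None, :, :]
    xhat, _, _, _ = model.forward(x, eps=None, train=False)
    return xhat[0, 0].astype(np.float64)


# ---------------------------------------------------------------------------
# Score maps
# ---------------------------------------------------------------------------

def histogram_match(
    volume: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
    reference_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Monotone quantile mapping of in-mask intensities onto the reference's.

    The output's empirical in-mask CDF matches the reference's; background
    (out-of-mask) voxels are untouched.  A constant input volume carries no
    rank information and is mapped to the reference median (logged).
    """
    volume = np.asarray(volume, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mask is None:
        mask = volume != 0
    if reference_mask is None:
        reference_mask = reference != 0
    v = volume[mask]
    r = np.sort(reference[reference_mask])
    if v.size == 0 or r.size == 0:
        raise ValueError("empty mask: nothing to match")
    out = volume.copy()
    if np.ptp(v) == 0:
        logger.warning("constant input volume; filled with reference median")
        out[mask] = np.median(r)
        return out
    q = (stats.rankdata(v, method="average") - 0.5) / v.size
    out[mask] = np.interp(q, (np.arange(r.size) + 0.5) / r.size, r)
    return out


def median_filter(map_2d: np.ndarray, size: int = 7) -> np.ndarray:
    """size x size median filter with reflect padding (removes isolated pixels)."""
    if size % 2 == 0:
        raise ValueError("median filter size must be odd")
    map_2d = np.asarray(map_2d)
    if map_2d.ndim != 2:
        raise ValueError("median_filter expects a 2-D map")
    return ndimage.median_filter(map_2d, size=size, mode="reflect")


def score_from_difference(original: np.ndarray, decoded: np.ndarray, mode: str = "abs") -> np.ndarray:
    """Per-pixel lesion score from an original/decoded pair.

    ``abs`` takes |original - decoded| (captures decoder overshoot as well);
    ``positive`` keeps only original > decoded, matching hyperintense lesions.
    """
    diff = np.asarray(original, dtype=np.float64) - np.asarray(decoded, dtype=np.float64)
    if mode == "abs":
        return np.abs(diff)
    if mode == "positive":
        return np.clip(diff, 0.0, None)
    raise ValueError(f"unknown score mode {mode!r}")


def lesion_score_map(
    model: VAEModel,
    volume: np.ndarray,
    mode: str = "abs",
    filter_size: int = 7,
) -> np.ndarray:
    """Slice-wise VAE reconstruction-error score mapped back to the volume grid.

    Each brain-containing slice (third grid axis) is linearly resampled to the
    model's input size, decoded from the latent mean, scored as the
    original-minus-decoded difference, median-filtered (``filter_size`` x
    ``filter_size``) at the model resolution where the error was computed,
    and resampled back to the native slice grid.  Scores are nonnegative
    everywhere; slices without brain voxels score 0.
    """
    volume = np.asarray(volume, dtype=np.float64)
    size = model.architecture.input_size
    out = np.zeros_like(volume)
    for z in range(volume.shape[2]):
        sl = volume[:, :, z]
        if not np.any(sl != 0):
            continue
        native_shape = sl.shape
        if native_shape != (size, size):
            sl_in = resize(sl, (size, size), order=1, preserve_range=True,
                           anti_aliasing=False)
        else:
            sl_in = sl
        dec = reconstruct(model, sl_in)
        err = score_from_difference(sl_in, dec, mode=mode)
        err = median_filter(err, size=filter_size)
        if native_shape != (size, size):
            err = resize(err, native_shape, order=1, preserve_range=True,
                         anti_aliasing=False)
        out[:, :, z] = err
    return np.clip(out, 0.0, None)


def extract_brain_slices(volumes, input_size: int) -> np.ndarray:
    """All brain-containing 2-D slices of all volumes, resampled to the
    model input size.  The slice axis is the third grid axis."""
    out = []
    for vol in volumes:
        vol = np.asarray(vol, dtype=np.float64)
        for z in range(vol.shape[2]):
            sl = vol[:, :, z]
            if not np.any(sl != 0):
                continue
            if sl.shape != (input_size, input_size):
                sl = resize(sl, (input_size, input_size), order=1,
                            preserve_range=True, anti_aliasing=False)
            out.append(sl)
    if not out:
        raise ValueError("no brain-containing slices found")
    return np.stack(out)


# ---------------------------------------------------------------------------
# Binarization and ROI volumes
# ---------------------------------------------------------------------------

def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise squared distance.

    The kernel width is set to several times the robust scale implied by the
    median.  A wide kernel makes the one-class decision approximate a kernel
    density ranking of the scalar sample: an isolated extreme subject cannot
    be enclosed in its own kernel bump and is reliably flagged, while for a
    well-behaved sample the flagged fraction stays close to nu.
    """
    d2 = (x[:, None] - x[None, :]) ** 2
    med = np.median(d2[np.triu_indices(x.size, k=1)])
    if med <= 0:
        pos = d2[d2 > 0]
        if pos.size == 0:
            return 1.0
        med = float(np.median(pos))
    return 1.0 / (100.0 * med)


def binarize_lesions(
    score_maps: np.ndarray,
    nu: float = 0.1,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Across-subject one-class outlier detection at every in-mask voxel.

    At each voxel the across-subject score sample is fed to a one-class SVM
    (RBF kernel, bandwidth from the median heuristic, contamination ``nu``);
    subjects flagged as outliers there get that voxel set in their binary
    lesion mask.  Voxels where all subjects score identically flag no one.
    Equivariant under subject permutation.
    """
    score_maps = np.asarray(score_maps, dtype=np.float64)
    if score_maps.ndim < 2 or score_maps.shape[0] < 8:
        raise ValueError("need score maps from at least 8 subjects")
    if not (0.0 < nu < 1.0):
        raise ValueError("nu must be in (0, 1)")
    n = score_maps.shape[0]
    flat = score_maps.reshape(n, -1)
    if brain_mask is None:
        vox = np.arange(flat.shape[1])
    else:
        vox = np.flatnonzero(np.asarray(brain_mask).ravel())
    masks = np.zeros_like(flat, dtype=bool)
    n_degenerate = 0
    for v in vox:
        x = flat[:, v]
        if np.ptp(x) == 0:
            n_degenerate += 1
            continue
        gamma = _median_heuristic_gamma(x)
        det = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
        # fit on the sorted sample, then predict by value: the flag is a pure
        # function of a subject's score, so the result is exactly equivariant
        # under subject permutation (and tie-consistent)
        det.fit(np.sort(x)[:, None])
        masks[:, v] = det.predict(x[:, None]) == -1
    if n_degenerate:
        logger.info("%d voxels with identical scores across subjects: none flagged",
                    n_degenerate)
    return masks.reshape(score_maps.shape)


def roi_lesion_volumes(mask: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Voxel counts of the binary mask per ROI, in ROI-table order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != parcellation.label_volume.shape:
        raise ValueError("mask and parcellation are on different grids")
    n_roi = len(parcellation.roi_table)
    counts = np.bincount(parcellation.label_volume[mask], minlength=n_roi + 1)
    return counts[1 : n_roi + 1].astype(np.int64)
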