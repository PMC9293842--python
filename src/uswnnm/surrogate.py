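"""Learned surrogate of the iterative denoiser.

The slow patch-based denoiser is replicated by an image-to-image regressor:
an encoder--decoder convolutional network with skip connections (a U-Net
style generator) trained on (noisy, denoised) pairs, so that at deployment a
single forward pass reproduces the denoiser's output in real time.  Training
uses a masked mean-absolute-error loss — the mask marks the original image
region inside the zero-padded square canvas, so padded pixels never
contribute — and early stopping on a held-out validation split.

The network, its forward pass and its gradients are implemented directly on
NumPy arrays (strided 4x4 convolutions and transposed convolutions, Adam),
which keeps single-image prediction fully deterministic and the package free
of heavyweight runtime dependencies.  The "tiny" profile used for
desk-scale experiments trains in seconds; the "full" profile (10 stride-2
stages, 32..512 filters) is constructible but meant for offline training
on real hardware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from uswnnm.imaging_io import PhantomSpec, as_image, make_phantom, pad_to_square
from uswnnm.noise_sim import NoiseSpec, corrupt, speckle_equivalent_sigma
from uswnnm.wnnm import WNNMConfig, denoise, with_sigma

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SurrogateArch:
    """Encoder--decoder architecture contract.

    ``depth`` paired downsampling/upsampling stages, each a ``kernel``-sized
    convolution with the given ``stride``; stage ``i`` has
    ``min(base_filters * 2**i, max_filters)`` filters.  ``input_side`` is the
    square canvas every image is zero-padded to; it must be divisible by
    ``stride**depth`` so the spatial sizes halve and double exactly.
    """

    depth: int = 2
    kernel: tuple[int, int] = (4, 4)
    stride: tuple[int, int] = (2, 2)
    base_filters: int = 8
    max_filters: int = 32
    input_side: int = 64

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kernel != (4, 4) or self.stride != (2, 2):
            raise ValueError("this implementation supports kernel (4,4), stride (2,2)")
        if self.input_side % (self.stride[0] ** self.depth) != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by "
                f"stride^depth = {self.stride[0] ** self.depth}"
            )

    def stage_filters(self) -> list[int]:
        return [min(self.base_filters * 2**i, self.max_filters) for i in range(self.depth)]


def profile(name: str) -> SurrogateArch:
    """Named architecture profiles.

    ``tiny`` (depth 2, 8..32 filters, 64 px canvas) trains on a desktop CPU
    in seconds and is used throughout the test experiments.  ``full`` is
    the full-scale configuration (10 stride-2 stages, 32..512 filters); ten
    halvings force a 1024 px canvas, since a 600 px input is not divisible
    by 2^10.
    """
    if name == "tiny":
        return SurrogateArch(depth=2, base_filters=8, max_filters=32, input_side=64)
    if name == "small":
        return SurrogateArch(depth=3, base_filters=16, max_filters=64, input_side=128)
    if name == "full":
        return SurrogateArch(depth=10, base_filters=32, max_filters=512, input_side=1024)
    raise ValueError(f"unknown profile {name!r}")


@dataclass
class TrainingSet:
    """Paired (raw, target) images for supervised regression.

    ``split`` is the held-out validation fraction; ``district_tag`` labels
    the phantom family (anatomical district analogue) the set was built from.
    """

    pairs: list[tuple[np.ndarray, np.ndarray]]
    split: float = 0.1
    district_tag: str = ""

    def __post_init__(self) -> None:
        for raw, target in self.pairs:
            if raw.shape != target.shape:
                raise ValueError("raw and target shapes differ within a pair")
        if not (0.0 < self.split < 1.0):
            raise ValueError("validation split must be in (0, 1)")


def build_pairs(
    clean_specs: list[PhantomSpec],
    noise: NoiseSpec,
    cfg: WNNMConfig,
    split: float = 0.1,
    district_tag: str = "",
    calibrate: bool = True,
) -> TrainingSet:
    """Generate (noisy, denoised) training pairs from phantom specs.

    Each spec's phantom is corrupted with the noise family/intensity of
    ``noise`` under a seed derived deterministically from the spec seed, then
    denoised with ``cfg``; the noisy image is the network input, the denoised
    image the regression target.  Bit-reproducible end to end.

    With ``calibrate`` (default) the denoiser's assumed noise level is set
    per pair to match the generated noise: the variance-matched equivalent
    for speckle, or the Gaussian standard deviation directly.
    """
    if not clean_specs:
        raise ValueError("clean_specs must be non-empty")
    pairs = []
    for spec in clean_specs:
        clean = make_phantom(spec)
        pair_seed = (noise.seed * 1_000_003 + spec.seed) % (2**31)
        noisy = corrupt(clean, NoiseSpec(noise.family, noise.sigma, pair_seed))
        pair_cfg = cfg
        if calibrate:
            level = (
                speckle_equivalent_sigma(noisy, noise.sigma)
                if noise.family == "speckle"
                else noise.sigma
            )
            pair_cfg = with_sigma(cfg, level)
        try:
            target = denoise(noisy, pair_cfg)
        except Exception as exc:
            raise RuntimeError(f"denoiser failed on phantom spec {spec}") from exc
        pairs.append((noisy, target))
    return TrainingSet(pairs=pairs, split=split, district_tag=district_tag)


# ---------------------------------------------------------------------------
# conv / transposed-conv primitives (4x4 kernel, stride 2, pad 1)


def _conv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (B,C,H,W), w (F,C,4,4) -> (B,F,H/2,W/2)."""
    bsz, c, h, wd = x.shape
    ho, wo = h // 2, wd // 2
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((bsz, ho, wo, w.shape[0]))
    for u in range(4):
        for v in range(4):
            sl = xp[:, :, u : u + 2 * ho - 1 : 2, v : v + 2 * wo - 1 : 2]
            out += np.tensordot(sl, w[:, :, u, v], axes=([1], [1]))
    return out.transpose(0, 3, 1, 2) + b[None, :, None, None]


def _conv_bwd(
    x: np.ndarray, w: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of _conv_fwd w.r.t. input, weight and bias."""
    bsz, c, h, wd = x.shape
    ho, wo = h // 2, wd // 2
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for u in range(4):
        for v in range(4):
            sl = xp[:, :, u : u + 2 * ho - 1 : 2, v : v + 2 * wo - 1 : 2]
            gw[:, :, u, v] = np.tensordot(gy, sl, axes=([0, 2, 3], [0, 2, 3]))
            gsl = np.tensordot(gy, w[:, :, u, v], axes=([1], [0]))  # B,Ho,Wo,C
            gxp[:, :, u : u + 2 * ho - 1 : 2, v : v + 2 * wo - 1 : 2] += gsl.transpose(
                0, 3, 1, 2
            )
    gb = gy.sum(axis=(0, 2, 3))
    return gxp[:, :, 1:-1, 1:-1], gw, gb


def _deconv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Transposed conv: x (B,C,H,W), w (C,O,4,4) -> (B,O,2H,2W)."""
    bsz, c, h, wd = x.shape
    yp = np.zeros((bsz, w.shape[1], 2 * h + 2, 2 * wd + 2))
    for u in range(4):
        for v in range(4):
            contrib = np.tensordot(x, w[:, :, u, v], axes=([1], [0]))  # B,H,W,O
            yp[:, :, u : u + 2 * h - 1 : 2, v : v + 2 * wd - 1 : 2] += contrib.transpose(
                0, 3, 1, 2
            )
    return yp[:, :, 1 : 1 + 2 * h, 1 : 1 + 2 * wd] + b[None, :, None, None]


def _deconv_bwd(
    x: np.ndarray, w: np.ndarray, gy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of _deconv_fwd w.r.t. input, weight and bias."""
    bsz, c, h, wd = x.shape
    gyp = np.pad(gy, ((0, 0), (0, 0), (1, 1), (1, 1)))
    gx = np.zeros_like(x)
    gw = np.zeros_like(w)
    for u in range(4):
        for v in range(4):
            sl = gyp[:, :, u : u + 2 * h - 1 : 2, v : v + 2 * wd - 1 : 2]  # B,O,H,W
            gx += np.tensordot(sl, w[:, :, u, v], axes=([1], [1])).transpose(0, 3, 1, 2)
            gw[:, :, u, v] = np.tensordot(x, sl, axes=([0, 2, 3], [0, 2, 3]))
    gb = gy.sum(axis=(0, 2, 3))
    return gx, gw, gb


def _lrelu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _lrelu_grad(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


class SurrogateModel:
    """A trained (or freshly initialised) encoder--decoder regressor."""

    def __init__(self, arch: SurrogateArch, params: dict[str, np.ndarray]):
        self.arch = arch
        self.params = params

    # -- construction -------------------------------------------------------

    @classmethod
    def initialise(cls, arch: SurrogateArch, seed: int = 0) -> "SurrogateModel":
        rng = np.random.default_rng(seed)
        filt = arch.stage_filters()
        params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, f in enumerate(filt):
            params[f"enc{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / (c_in * 16)), (f, c_in, 4, 4)
            )
            params[f"enc{i}_b"] = np.zeros(f)
            c_in = f
        for i in range(arch.depth - 1, 0, -1):
            dec_in = filt[i] if i == arch.depth - 1 else 2 * filt[i]
            params[f"dec{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / (dec_in * 16)), (dec_in, filt[i - 1], 4, 4)
            )
            params[f"dec{i}_b"] = np.zeros(filt[i - 1])
        dec0_in = 2 * filt[0] if arch.depth > 1 else filt[0]
        params["dec0_W"] = rng.normal(0.0, np.sqrt(2.0 / (dec0_in * 16)), (dec0_in, 1, 4, 4))
        params["dec0_b"] = np.zeros(1)
        return cls(arch, params)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x (B,1,S,S) -> prediction (B,1,S,S); optionally return the
        intermediate activations needed for backprop."""
        p, d = self.params, self.arch.depth
        cache: dict[str, np.ndarray] = {"x0": x}
        h = x
        for i in range(d):
            z = _conv_fwd(h, p[f"enc{i}_W"], p[f"enc{i}_b"])
            cache[f"z{i}"] = z
            h = _lrelu(z)
            cache[f"e{i}"] = h
        for i in range(d - 1, 0, -1):
            z = _deconv_fwd(h, p[f"dec{i}_W"], p[f"dec{i}_b"])
            cache[f"dz{i}"] = z
            a = np.maximum(z, 0.0)
            h = np.concatenate([a, cache[f"e{i-1}"]], axis=1)
            cache[f"d{i}"] = h
        out = _deconv_fwd(h, p["dec0_W"], p["dec0_b"])
        if keep_cache:
            return out, cache
        return out

    def backward(self, cache: dict, gout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. every parameter, given d(loss)/d(out)."""
        p, d = self.params, self.arch.depth
        grads: dict[str, np.ndarray] = {}
        h_in = cache[f"d{1}"] if d > 1 else cache[f"e{d-1}"]
        gh, grads["dec0_W"], grads["dec0_b"] = _deconv_bwd(h_in, p["dec0_W"], gout)
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(1, d):
            f_up = p[f"dec{i}_W"].shape[1]
            ga = gh[:, :f_up]
            skip_grads[i - 1] = gh[:, f_up:]
            gz = ga * (cache[f"dz{i}"] > 0)
            h_in = cache[f"d{i+1}"] if i < d - 1 else cache[f"e{d-1}"]
            gh, grads[f"dec{i}_W"], grads[f"dec{i}_b"] = _deconv_bwd(
                h_in, p[f"dec{i}_W"], gz
            )
        ge = gh
        for i in range(d - 1, -1, -1):
            if i in skip_grads:
                ge = ge + skip_grads[i]
            gz = ge * _lrelu_grad(cache[f"z{i}"])
            h_in = cache[f"e{i-1}"] if i > 0 else cache["x0"]
            ge, grads[f"enc{i}_W"], grads[f"enc{i}_b"] = _conv_bwd(
                h_in, p[f"enc{i}_W"], gz
            )
        return grads

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single self-describing file: arch config, format version, weights."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "depth": self.arch.depth,
            "kernel": list(self.arch.kernel),
            "stride": list(self.arch.stride),
            "base_filters": self.arch.base_filters,
            "max_filters": self.arch.max_filters,
            "input_side": self.arch.input_side,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta['format_version']}")
        arch = SurrogateArch(
            depth=meta["depth"],
            kernel=tuple(meta["kernel"]),
            stride=tuple(meta["stride"]),
            base_filters=meta["base_filters"],
            max_filters=meta["max_filters"],
            input_side=meta["input_side"],
        )
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(arch, params)


def _masked_mae(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    return float(np.sum(np.abs(pred - target) * mask) / np.sum(mask))


def _pad_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]], side: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs, ts, ms = [], [], []
    for raw, target in pairs:
        pr = pad_to_square(np.clip(as_image(raw), 0.0, 1.0), side)
        pt = pad_to_square(np.clip(as_image(target), 0.0, 1.0), side)
        xs.append(pr.pixels)
        ts.append(pt.pixels)
        ms.append(pr.mask.astype(np.float64))
    return (
        np.stack(xs)[:, None],
        np.stack(ts)[:, None],
        np.stack(ms)[:, None],
    )


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train(
    ts: TrainingSet,
    arch: SurrogateArch,
    epochs_max: int = 200,
    patience: int = 5,
    seed: int = 0,
    lr: float = 2e-3,
    batch_size: int = 4,
    val_eval=None,
) -> tuple[SurrogateModel, TrainingLog]:
    """Train the surrogate with Adam on the masked MAE and early stopping.

    The pairs are zero-padded to ``arch.input_side``; the loss is computed
    only inside the masks.  A validation split (``ts.split`` of the pairs,
    at least one) is scored after every epoch; when it has not improved for
    ``patience`` consecutive epochs training stops and the parameters of the
    best-validation epoch are returned.  Fully deterministic under ``seed``.

    ``val_eval``, if given, replaces the built-in validation scorer; it is
    called as ``val_eval(model, epoch)`` and must return a loss value (used
    by the early-stopping unit tests and for custom validation sets).
    """
    for raw, _ in ts.pairs:
        if max(raw.shape) > arch.input_side:
            raise ValueError(
                f"pair of shape {raw.shape} exceeds the network canvas "
                f"{arch.input_side}"
            )
    rng = np.random.default_rng(seed)
    n = len(ts.pairs)
    n_val = max(1, int(round(ts.split * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ValueError("training set too small for the requested validation split")
    x_all, t_all, m_all = _pad_batch(ts.pairs, arch.input_side)
    xtr, ttr, mtr = x_all[train_idx], t_all[train_idx], m_all[train_idx]
    xva, tva, mva = x_all[val_idx], t_all[val_idx], m_all[val_idx]

    model = SurrogateModel.initialise(arch, seed=seed)
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def default_val(mdl: SurrogateModel, epoch: int) -> float:
        return _masked_mae(mdl.forward(xva), tva, mva)

    score = val_eval if val_eval is not None else default_val
    log = TrainingLog()
    best_val = np.inf
    best_params = model.copy_params()
    bad_epochs = 0
    n_tr = train_idx.size
    for epoch in range(epochs_max):
        order = rng.permutation(n_tr)
        epoch_losses = []
        for start in range(0, n_tr, batch_size):
            idx = order[start : start + batch_size]
            xb, tb, mb = xtr[idx], ttr[idx], mtr[idx]
            pred, cache = model.forward(xb, keep_cache=True)
            mask_sum = np.sum(mb)
            epoch_losses.append(float(np.sum(np.abs(pred - tb) * mb) / mask_sum))
            gout = np.sign(pred - tb) * mb / mask_sum
            grads = model.backward(cache, gout)
            step += 1
            corr = np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, g in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                model.params[k] -= lr * corr * adam_m[k] / (np.sqrt(adam_v[k]) + eps)
        log.train_loss.append(float(np.mean(epoch_losses)))
        vloss = float(score(model, epoch))
        log.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_params = model.copy_params()
            log.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                log.stopped_epoch = epoch
                break
    else:
        log.stopped_epoch = epochs_max - 1
    model.params = best_params
    return model, log


def predict(model: SurrogateModel, raw: np.ndarray) -> np.ndarray:
    """Denoise ``raw`` with one forward pass: pad, predict, unpad, clamp."""
    raw = as_image(raw)
    side = model.arch.input_side
    if max(raw.shape) > side:
        raise ValueError(f"image {raw.shape} larger than the network canvas {side}")
    padded = pad_to_square(np.clip(raw, 0.0, 1.0), side)
    out = model.forward(padded.pixels[None, None])[0, 0]
    h, w = raw.shape
    return np.clip(out[:h, :w], 0.0, 1.0)
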