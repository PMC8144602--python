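"""The spatial-spectral residual denoiser (SS-ResNet).

A U-net-style encoder-decoder operating on hyperspectral patches ordered
(lambda, y, x).  Each encoder level expands feature channels with a 1x1x1
convolution and runs a stack of SS-Conv blocks (parallel 1x3x3 spatial and
3x1x1 spectral convolutions, summed, ReLU); spatial-only (1,2,2) max pooling
links the levels, so the spectral sampling required by downstream unmixing
is never decimated.  The decoder mirrors the encoder with nearest-neighbour
upsampling and skip concatenation.  A final linear 1x1x1 head predicts the
*residual*, which is added to the network input: with a zeroed head the
model is exactly the identity.

Training minimizes the mean squared error between the prediction and the
frame-averaged ground truth on randomly sampled 3-D patches.  Raw and
ground-truth stacks are first mapped onto a common scale by percentile
normalization (0.3 / 99.7 by default); the parameters are stored with the
model and round-tripped at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..simulate import HyperspectralStack, TrainingPair
from ._layers import (
    Adam,
    Conv1x1,
    MaxPoolYX,
    SSConvBlock,
    UpsampleYX,
)

__all__ = [
    "DenoiserConfig",
    "NormalizationParams",
    "DenoiserModel",
    "percentile_normalize",
    "ss_conv_block",
    "build_denoiser",
    "train_denoiser",
    "fine_tune",
    "denoise",
    "save_model",
    "load_model",
]

_DT = np.float32


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the full-size network: 3 resolution levels, six SS-Conv
    blocks per level, base width 16 doubling per level, Adam at 1e-4.  Patch
    spatial dims must be divisible by 2**(n_levels - 1).
    """

    n_levels: int = 3
    blocks_per_level: int = 6
    base_channels: int = 16
    learning_rate: float = 1e-4
    batch_size: int = 4
    n_epochs: int = 50
    steps_per_epoch: int = 16
    patch_shape: tuple[int, int, int] = (32, 64, 64)  # (lambda, y, x)
    lo_percentile: float = 0.3
    hi_percentile: float = 99.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.blocks_per_level < 1 or self.base_channels < 1:
            raise ValueError("levels, blocks, and channels must be positive")
        factor = 2 ** (self.n_levels - 1)
        _, py, px = self.patch_shape
        if py % factor or px % factor:
            raise ValueError(
                f"patch spatial dims {self.patch_shape[1:]} must be divisible "
                f"by the total pooling factor {factor}"
            )

    def level_channels(self, level: int) -> int:
        return self.base_channels * 2**level


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile anchors of the affine intensity normalization."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("hi percentile value must exceed lo")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.lo) / (self.hi - self.lo)).astype(_DT)

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x.astype(np.float64) * (self.hi - self.lo) + self.lo


def percentile_normalize(
    stack: np.ndarray, lo_pct: float = 0.3, hi_pct: float = 99.7
) -> tuple[np.ndarray, NormalizationParams]:
    """Map intensities to (x - lo) / (hi - lo) using percentile anchors.

    Values are *not* clipped: outliers above the high percentile simply land
    above 1, keeping them out of the scale without destroying them.
    """
    data = stack.data if isinstance(stack, HyperspectralStack) else np.asarray(stack)
    lo = float(np.percentile(data, lo_pct))
    hi = float(np.percentile(data, hi_pct))
    if not hi > lo:
        raise ValueError("degenerate stack: percentile range is empty")
    params = NormalizationParams(lo=lo, hi=hi)
    return params.apply(data), params


def ss_conv_block(
    features: np.ndarray,
    spatial_weights: np.ndarray,
    spectral_weights: np.ndarray,
    bias: np.ndarray | None = None,
    relu: bool = True,
) -> np.ndarray:
    """Functional SS-Conv: parallel spatial/spectral convolutions, sum, ReLU.

    ``features`` is rank-4 (channels, lambda, y, x); weights are
    (c_out, c_in, 3, 3) and (c_out, c_in, 3).  Exposed for direct use and as
    the reference entry point for kernel-level verification.
    """
    if features.ndim != 4:
        raise ValueError("features must be rank-4 (channels, lambda, y, x)")
    c = spatial_weights.shape[0]
    rng = np.random.default_rng(0)
    block = SSConvBlock(c, rng, relu=relu)
    if spatial_weights.shape != block.spatial.W.shape:
        raise ValueError("spatial weights must be (c_out, c_in, 3, 3)")
    if spectral_weights.shape != block.spectral.W.shape:
        raise ValueError("spectral weights must be (c_out, c_in, 3)")
    block.spatial.W[...] = spatial_weights
    block.spectral.W[...] = spectral_weights
    if bias is not None:
        block.b[...] = bias
    return block.forward(features[None].astype(_DT))[0]


class _SSResNet:
    """The computational graph: explicit forward and reverse passes."""

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator) -> None:
        self.config = config
        L = config.n_levels
        self.enc_expand: list[Conv1x1] = []
        self.enc_blocks: list[list[SSConvBlock]] = []
        self.pools: list[MaxPoolYX] = []
        self.ups: list[UpsampleYX] = []
        self.dec_reduce: list[Conv1x1] = []
        self.dec_blocks: list[list[SSConvBlock]] = []

        prev = 1
        for i in range(L):
            ch = config.level_channels(i)
            self.enc_expand.append(Conv1x1(prev, ch, rng))
            self.enc_blocks.append(
                [SSConvBlock(ch, rng) for _ in range(config.blocks_per_level)]
            )
            if i < L - 1:
                self.pools.append(MaxPoolYX())
            prev = ch
        for i in range(L - 2, -1, -1):
            ch = config.level_channels(i)
            ch_below = config.level_channels(i + 1)
            self.ups.append(UpsampleYX())
            self.dec_reduce.append(Conv1x1(ch_below + ch, ch, rng))
            self.dec_blocks.append(
                [SSConvBlock(ch, rng) for _ in range(config.blocks_per_level)]
            )
        # Linear residual head, initialized at zero: the untrained network is
        # exactly the identity, so optimization starts from "no correction"
        # instead of from a random residual that must first be unlearned.
        self.head = Conv1x1(config.level_channels(0), 1, rng)
        self.head.W[...] = 0.0
        self.head.b[...] = 0.0

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list:
        out: list = []
        for i in range(self.config.n_levels):
            out.append(self.enc_expand[i])
            out.extend(self.enc_blocks[i])
        for j in range(self.config.n_levels - 1):
            out.append(self.dec_reduce[j])
            out.extend(self.dec_blocks[j])
        out.append(self.head)
        return out

    def parameters(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        params: list[np.ndarray] = []
        grads: list[np.ndarray] = []
        for layer in self.layers():
            params.extend(layer.params)
            grads.extend(layer.grads)
        return params, grads

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()[0]))

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (batch, 1, lambda, y, x) -> same shape, x + residual."""
        L = self.config.n_levels
        skips: list[np.ndarray] = []
        h = x
        for i in range(L):
            h = self.enc_expand[i].forward(h)
            for blk in self.enc_blocks[i]:
                h = blk.forward(h)
            if i < L - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        for j, i in enumerate(range(L - 2, -1, -1)):
            h = self.ups[j].forward(h)
            h = np.concatenate([h, skips[i]], axis=1)
            h = self.dec_reduce[j].forward(h)
            for blk in self.dec_blocks[j]:
                h = blk.forward(h)
        return x + self.head.forward(h)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        L = self.config.n_levels
        g = self.head.backward(grad_out)
        skip_grads: dict[int, np.ndarray] = {}
        # decoder stages were run for i = L-2 .. 0; reverse them
        for j in range(L - 2, -1, -1):
            i = (L - 2) - j  # encoder level this decoder stage targets
            for blk in reversed(self.dec_blocks[j]):
                g = blk.backward(g)
            g = self.dec_reduce[j].backward(g)
            ch_below = self.config.level_channels(i + 1)
            g_up, g_skip = g[:, :ch_below], g[:, ch_below:]
            skip_grads[i] = g_skip
            g = self.ups[j].backward(g_up)
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            for blk in reversed(self.enc_blocks[i]):
                g = blk.backward(g)
            g = self.enc_expand[i].backward(g)
        return g + grad_out  # identity path of the residual connection


@dataclass
class DenoiserModel:
    """Architecture + learned weights + normalization + training history."""

    config: DenoiserConfig
    net: _SSResNet = field(repr=False)
    normalization: NormalizationParams | None = None
    training_history: list[float] = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return self.normalization is not None and len(self.training_history) > 0

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def zero_residual_head(self) -> None:
        """Force the residual head to zero: the network becomes the identity."""
        self.net.head.W[...] = 0.0
        self.net.head.b[...] = 0.0


def build_denoiser(config: DenoiserConfig) -> DenoiserModel:
    """Construct an untrained SS-ResNet with seed-deterministic init."""
    rng = np.random.default_rng(config.seed)
    return DenoiserModel(config=config, net=_SSResNet(config, rng))


def _sample_patch(
    raw: np.ndarray, gt: np.ndarray, patch: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    nl, ny, nx = raw.shape
    pl, py, px = patch
    if pl > nl or py > ny or px > nx:
        raise ValueError("patch larger than the training stacks")
    l0 = rng.integers(nl - pl + 1)
    y0 = rng.integers(ny - py + 1)
    x0 = rng.integers(nx - px + 1)
    sl = (slice(l0, l0 + pl), slice(y0, y0 + py), slice(x0, x0 + px))
    return raw[sl], gt[sl]


def _fit(
    model: DenoiserModel,
    pairs: list[TrainingPair],
    n_epochs: int,
    rng: np.random.Generator,
) -> None:
    cfg = model.config
    if model.normalization is None:
        raise RuntimeError("normalization must be set before fitting")
    norm = model.normalization
    raws = [norm.apply(p.raw.data) for p in pairs]
    gts = [norm.apply(p.ground_truth.data) for p in pairs]

    params, grads = model.net.parameters()
    if not hasattr(model, "_opt") or model._opt is None:
        model._opt = Adam(params, grads, lr=cfg.learning_rate)
    opt: Adam = model._opt

    for _ in range(n_epochs):
        epoch_loss = 0.0
        for _ in range(cfg.steps_per_epoch):
            xb, yb = [], []
            for _ in range(cfg.batch_size):
                idx = int(rng.integers(len(pairs)))
                xr, yg = _sample_patch(raws[idx], gts[idx], cfg.patch_shape, rng)
                xb.append(xr)
                yb.append(yg)
            x = np.stack(xb)[:, None]  # (N,1,L,Y,X)
            y = np.stack(yb)[:, None]
            model.net.zero_grad()
            pred = model.net.forward(x)
            err = pred - y
            loss = float(np.mean(err.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at step {opt.t}; "
                    "lower the learning rate or check the input scaling"
                )
            model.net.backward((2.0 / err.size * err).astype(_DT))
            opt.step()
            epoch_loss += loss
        model.training_history.append(epoch_loss / cfg.steps_per_epoch)


def train_denoiser(pairs: list[TrainingPair], config: DenoiserConfig) -> DenoiserModel:
    """Train a fresh SS-ResNet on raw/ground-truth pairs.

    Normalization percentiles are computed over the pooled training raws and
    stored with the model.  Fully deterministic for a fixed config seed.
    """
    if len(pairs) == 0:
        raise ValueError("at least one training pair is required")
    shape = pairs[0].raw.shape
    if any(p.raw.shape != shape for p in pairs):
        raise ValueError("all training pairs must share dimensions")
    model = build_denoiser(config)
    pooled = np.concatenate([p.raw.data.ravel() for p in pairs])
    _, model.normalization = percentile_normalize(
        pooled, config.lo_percentile, config.hi_percentile
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    _fit(model, pairs, config.n_epochs, rng)
    return model


def fine_tune(
    model: DenoiserModel,
    new_pairs: list[TrainingPair],
    n_epochs: int | None = None,
) -> DenoiserModel:
    """Continue optimizing an already-trained model on new pairs (in place).

    Keeps the stored normalization (transfer between datasets acquired under
    the same imaging and digitizing conditions); appends to the history.
    ``n_epochs=0`` leaves the model untouched.
    """
    if not model.is_trained:
        raise RuntimeError("fine_tune requires a trained model")
    if len(new_pairs) == 0:
        raise ValueError("at least one pair is required")
    if new_pairs[0].raw.n_channels != model.config.patch_shape[0] and (
        new_pairs[0].raw.n_channels < model.config.patch_shape[0]
    ):
        raise ValueError("new pairs have fewer spectral channels than the patch")
    epochs = model.config.n_epochs if n_epochs is None else n_epochs
    rng = np.random.default_rng(
        np.random.SeedSequence([model.config.seed, 2, len(model.training_history)])
    )
    _fit(model, new_pairs, epochs, rng)
    return model


# ---------------------------------------------------------------------------
# inference


def receptive_margin(config: DenoiserConfig) -> tuple[int, int]:
    """Formal receptive-field radius (spectral, spatial) of the network.

    Each SS-Conv block contributes radius 1 at its resolution scale; pooling
    and upsampling add alignment slack at each level change.  The spectral
    axis is never pooled, so its radius is simply two passes (encoder and
    decoder) of the per-level blocks.
    """
    L, B = config.n_levels, config.blocks_per_level
    r_spatial = 2 * sum(B * 2**i for i in range(L)) + 2 * sum(2**i for i in range(L - 1))
    r_spectral = 2 * B * L
    return r_spectral, r_spatial


def _tile_starts(total: int, tile: int, margin: int, align: int) -> list[int]:
    """Aligned tile origins so that cropped centres cover [0, total)."""
    if total <= tile:
        return [0]
    step = tile - 2 * margin
    if step < 1:
        raise ValueError("tile too small for the requested margin")
    step -= step % align or 0
    step = max(step, align)
    starts = list(range(0, total - tile, step))
    if starts[-1] != total - tile:
        starts.append(total - tile)
    return starts


def denoise(
    stack: HyperspectralStack,
    model: DenoiserModel,
    tile_shape: tuple[int, int, int] | None = None,
    margin: tuple[int, int, int] | None = None,
) -> HyperspectralStack:
    """Apply a trained denoiser to a full stack.

    The stack is normalized with the model's stored parameters, evaluated
    tile by tile, and mapped back to the original intensity scale; output
    dimensions equal input dimensions.  Tiles (default: twice the training
    patch per axis) overlap by a margin (default: the network's formal
    receptive-field radius, clipped to keep tiling feasible) and only each
    tile's centre crop is kept, so tiled and whole-stack inference agree
    exactly wherever the margin covers the receptive field.  Stacks no
    larger than one tile run in a single pass.
    """
    if not model.is_trained:
        raise RuntimeError("denoise requires a trained model")
    norm = model.normalization
    data = norm.apply(stack.data)
    nl, ny, nx = data.shape
    factor = 2 ** (model.config.n_levels - 1)

    if tile_shape is None:
        pl, py, px = model.config.patch_shape
        tile_shape = (2 * pl, 2 * py, 2 * px)
    tl, ty, tx = (min(t, s) for t, s in zip(tile_shape, (nl, ny, nx)))
    ty += (-ty) % factor
    tx += (-tx) % factor
    pad = (max(0, tl - nl), max(0, ty - ny), max(0, tx - nx))
    if any(pad):
        data = np.pad(data, [(0, p) for p in pad], mode="reflect")

    if margin is None:
        r_spec, r_spat = receptive_margin(model.config)
        margin = (
            min(r_spec, max(0, (tl - 1) // 2)),
            min(r_spat, max(0, (ty - factor) // 2)),
            min(r_spat, max(0, (tx - factor) // 2)),
        )
    ml, my, mx = margin

    out = np.empty(data.shape, dtype=np.float64)
    tiled_axes = [data.shape[0] > tl, data.shape[1] > ty, data.shape[2] > tx]
    for l0 in _tile_starts(data.shape[0], tl, ml if tiled_axes[0] else 0, 1):
        for y0 in _tile_starts(data.shape[1], ty, my if tiled_axes[1] else 0, factor):
            for x0 in _tile_starts(data.shape[2], tx, mx if tiled_axes[2] else 0, factor):
                pred = model.net.forward(
                    data[l0:l0 + tl, y0:y0 + ty, x0:x0 + tx][None, None]
                )[0, 0]
                # keep the centre crop; tiles at the stack border keep their
                # outer margin too (there is no neighbour to supply it)
                keep = []
                for start, tile, m, total in (
                    (l0, tl, ml, data.shape[0]),
                    (y0, ty, my, data.shape[1]),
                    (x0, tx, mx, data.shape[2]),
                ):
                    lo = 0 if start == 0 else m
                    hi = tile if start + tile == total else tile - m
                    keep.append((lo, hi))
                (kl, kh), (yl, yh), (xl, xh) = keep
                out[l0 + kl:l0 + kh, y0 + yl:y0 + yh, x0 + xl:x0 + xh] = (
                    pred[kl:kh, yl:yh, xl:xh]
                )
    out = out[:nl, :ny, :nx]
    return HyperspectralStack(
        data=norm.invert(out).astype(np.float32), axis=stack.axis
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: DenoiserModel, path) -> None:
    """Write a single-file checkpoint (config, weights, normalization, history)."""
    params, _ = model.net.parameters()
    meta = {
        "config": asdict(model.config),
        "normalization": (
            None if model.normalization is None
            else {"lo": model.normalization.lo, "hi": model.normalization.hi}
        ),
        "history": model.training_history,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> DenoiserModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        cfg_dict = meta["config"]
        cfg_dict["patch_shape"] = tuple(cfg_dict["patch_shape"])
        config = DenoiserConfig(**cfg_dict)
        model = build_denoiser(config)
        params, _ = model.net.parameters()
        for i, p in enumerate(params):
            p[...] = archive[f"param_{i}"]
    if meta["normalization"] is not None:
        model.normalization = NormalizationParams(**meta["normalization"])
    model.training_history = list(meta["history"])
    return model
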