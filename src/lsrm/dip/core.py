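"""Unsupervised single-image denoising with an untrained encoder-decoder.

A randomly initialized CNN maps a fixed random input field to the image
domain and is optimized to reproduce one noisy target under a mean-squared
objective.  Because the network's inductive bias fits coherent structure
before pixel noise, stopping the optimization early returns a denoised
image; no external training data is involved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ..image_io import ImageSlice, ImageStack
from ._nn import Adam, Conv2d, InstanceNorm, LeakyReLU, Sigmoid, Upsample2

__all__ = [
    "EarlyStopRule",
    "DIPConfig",
    "DIPResult",
    "DeepPriorNet",
    "build_network",
    "fit_dip",
    "early_stop_check",
    "denoise_stack",
]


@dataclass(frozen=True)
class EarlyStopRule:
    """Stop when the block-averaged loss improvement over ``window``
    iterations stays below ``min_delta`` for ``patience`` consecutive
    checks; the kept iteration is the argmin of the smoothed loss."""

    window: int = 50
    min_delta: float = 1e-5
    patience: int = 3

    def __post_init__(self) -> None:
        if self.window < 1 or self.patience < 1 or self.min_delta < 0:
            raise ValueError("invalid early-stop rule")


@dataclass(frozen=True)
class DIPConfig:
    """Network and optimization hyperparameters.

    Defaults are sized for single-threaded CPU fitting (pure NumPy); all of
    them are configurable.  ``input_channels`` and ``input_noise_std``
    control the fixed random input field, which is drawn once per fit from
    ``seed`` and never updated.
    """

    depth: int = 3
    base_channels: int = 24
    skip_channels: int = 4
    input_channels: int = 16
    input_noise_std: float = 0.1
    iterations_max: int = 600
    learning_rate: float = 0.01
    early_stop: EarlyStopRule = field(default_factory=EarlyStopRule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.iterations_max < 1:
            raise ValueError("iterations_max must be >= 1")
        if self.learning_rate <= 0 or self.input_noise_std <= 0:
            raise ValueError("rates must be positive")
        if min(self.base_channels, self.skip_channels, self.input_channels) < 1:
            raise ValueError("channel counts must be >= 1")

    def replace(self, **changes) -> "DIPConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class DIPResult:
    denoised: ImageSlice
    loss_trace: np.ndarray
    stop_iteration: int
    config: DIPConfig

    def __post_init__(self) -> None:
        if len(self.loss_trace) == 0:
            raise ValueError("loss trace must be non-empty")
        if self.stop_iteration >= self.config.iterations_max + 1:
            raise ValueError("stop_iteration exceeds iterations_max")


class DeepPriorNet:
    """Encoder-decoder with per-level skip connections and sigmoid output.

    The encoder halves resolution per level (strided conv); the decoder
    mirrors it with nearest-neighbour upsampling, concatenating a 1x1-conv
    skip from the matching-resolution encoder feature (the fixed input field
    itself at full resolution).  Spatial dimensions are reflect-padded to a
    multiple of ``2**depth`` and the output is cropped back.
    """

    def __init__(self, config: DIPConfig, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        if h < 2**config.depth or w < 2**config.depth:
            raise ValueError(
                f"image {image_shape} too small for depth {config.depth}"
            )
        self.config = config
        self.image_shape = (h, w)
        mult = 2**config.depth
        self.padded_shape = (-(-h // mult) * mult, -(-w // mult) * mult)

        rng = np.random.default_rng(config.seed)
        d, base, skip, c_in = (
            config.depth,
            config.base_channels,
            config.skip_channels,
            config.input_channels,
        )
        self.enc_down = []
        self.enc_conv = []
        prev = c_in
        for _ in range(d):
            self.enc_down.append(Conv2d(rng, prev, base, 3, stride=2))
            self.enc_conv.append(Conv2d(rng, base, base, 3, 1))
            prev = base
        # skip m: full-resolution input field for m=0, encoder output m-1 otherwise
        self.skip_conv = [Conv2d(rng, c_in if m == 0 else base, skip, 1, 1) for m in range(d)]
        self.dec_conv = [Conv2d(rng, base + skip, base, 3, 1) for _ in range(d)]
        self.out_conv = Conv2d(rng, base, 1, 1, 1)

        self.enc_norm1 = [InstanceNorm(base) for _ in range(d)]
        self.enc_norm2 = [InstanceNorm(base) for _ in range(d)]
        self.skip_norm = [InstanceNorm(skip) for _ in range(d)]
        self.dec_norm = [InstanceNorm(base) for _ in range(d)]
        self.enc_act1 = [LeakyReLU() for _ in range(d)]
        self.enc_act2 = [LeakyReLU() for _ in range(d)]
        self.dec_act = [LeakyReLU() for _ in range(d)]
        self.up = [Upsample2() for _ in range(d)]
        self.sigmoid = Sigmoid()

        # fixed random input field, drawn once and never updated
        z_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        self.z = z_rng.normal(0.0, config.input_noise_std, (c_in, *self.padded_shape))

    # -- plumbing -----------------------------------------------------------

    @property
    def _layers(self) -> list:
        return (
            self.enc_down + self.enc_conv + self.skip_conv + self.dec_conv
            + [self.out_conv]
            + self.enc_norm1 + self.enc_norm2 + self.skip_norm + self.dec_norm
        )

    def parameters(self) -> list[np.ndarray]:
        return [p for c in self._layers for p in c.parameters]

    def gradients(self) -> list[np.ndarray]:
        return [g for c in self._layers for g in c.gradients]

    def count_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward/backward ---------------------------------------------------

    def forward(self) -> np.ndarray:
        """Network output on the fixed input field, padded shape ``(1, H', W')``."""
        d = self.config.depth
        x = self.z
        self._enc_out = []
        for i in range(d):
            x = self.enc_act1[i].forward(self.enc_norm1[i].forward(self.enc_down[i].forward(x)))
            x = self.enc_act2[i].forward(self.enc_norm2[i].forward(self.enc_conv[i].forward(x)))
            self._enc_out.append(x)
        sources = [self.z] + self._enc_out[: d - 1]
        skips = [
            self.skip_norm[m].forward(self.skip_conv[m].forward(sources[m]))
            for m in range(d)
        ]
        for m in range(d - 1, -1, -1):
            x = self.up[m].forward(x)
            x = np.concatenate([x, skips[m]], axis=0)
            x = self.dec_act[m].forward(self.dec_norm[m].forward(self.dec_conv[m].forward(x)))
        return self.sigmoid.forward(self.out_conv.forward(x))

    def backward(self, dout: np.ndarray) -> None:
        d = self.config.depth
        base = self.config.base_channels
        g = self.out_conv.backward(self.sigmoid.backward(dout))
        dskip: list[np.ndarray | None] = [None] * d
        for m in range(d):  # reverse of the decoder loop
            g = self.dec_conv[m].backward(
                self.dec_norm[m].backward(self.dec_act[m].backward(g))
            )
            dskip[m] = g[base:]
            g = self.up[m].backward(g[:base])
        for i in range(d - 1, -1, -1):
            if i <= d - 2:
                g = g + self.skip_conv[i + 1].backward(
                    self.skip_norm[i + 1].backward(dskip[i + 1])
                )
            g = self.enc_conv[i].backward(
                self.enc_norm2[i].backward(self.enc_act2[i].backward(g))
            )
            g = self.enc_down[i].backward(
                self.enc_norm1[i].backward(self.enc_act1[i].backward(g))
            )
        # weight grads only; the fixed input field receives no update
        self.skip_conv[0].backward(self.skip_norm[0].backward(dskip[0]))

    def predict(self) -> np.ndarray:
        """Cropped 2D output in (0, 1)."""
        h, w = self.image_shape
        return self.forward()[0, :h, :w]


def build_network(config: DIPConfig, image_shape: tuple[int, int]) -> DeepPriorNet:
    """Untrained network for the given image shape, seeded from the config."""
    return DeepPriorNet(config, image_shape)


def early_stop_check(
    loss_trace, rule: EarlyStopRule
) -> tuple[bool, int]:
    """Evaluate the plateau rule on a loss trace.

    Returns ``(stop, keep_iteration)`` where ``keep_iteration`` is the
    argmin of the trailing-moving-average smoothed loss (0-based) and
    ``stop`` is True once the mean loss of ``patience`` consecutive
    ``window``-blocks failed to improve by at least ``min_delta``.
    """
    t = np.asarray(loss_trace, dtype=np.float64)
    if t.size == 0:
        raise ValueError("loss trace is empty")
    w = rule.window
    cs = np.concatenate([[0.0], np.cumsum(t)])
    idx = np.arange(t.size)
    start = np.maximum(0, idx - w + 1)
    smoothed = (cs[idx + 1] - cs[start]) / (idx + 1 - start)
    keep = int(np.argmin(smoothed))

    nblocks = t.size // w
    if nblocks < 2:
        return False, keep
    block_means = t[: nblocks * w].reshape(nblocks, w).mean(axis=1)
    improvements = block_means[:-1] - block_means[1:]
    strikes = 0
    for imp in improvements[::-1]:
        if imp < rule.min_delta:
            strikes += 1
        else:
            break
    return strikes >= rule.patience, keep


def fit_dip(target: ImageSlice, config: DIPConfig | None = None) -> DIPResult:
    """Fit the prior network to one noisy slice and return the early-stopped
    output.

    The objective is the mean squared error between the network output and
    the target; the loss is recorded every iteration and the returned image
    is the output at the iteration selected by :func:`early_stop_check`
    (not necessarily the final one).
    """
    if config is None:
        config = DIPConfig()
    pixels = np.asarray(target.pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("target contains non-finite pixels")
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("target must be normalized to [0, 1]")

    net = build_network(config, pixels.shape)
    ph, pw = net.padded_shape
    h, w = pixels.shape
    y = np.pad(pixels, ((0, ph - h), (0, pw - w)), mode="reflect")[None]

    optimizer = Adam(net.parameters(), lr=config.learning_rate)
    trace: list[float] = []
    n = y.size
    best_smoothed = np.inf
    best_out: np.ndarray | None = None
    best_it = 0
    run_sum = 0.0
    wlen = config.early_stop.window

    for it in range(config.iterations_max):
        out = net.forward()
        diff = out - y
        loss = float(np.mean(diff**2))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {it}; try a lower learning rate"
            )
        trace.append(loss)
        run_sum += loss
        if len(trace) > wlen:
            run_sum -= trace[-wlen - 1]
        smoothed = run_sum / min(len(trace), wlen)
        if smoothed < best_smoothed:
            best_smoothed = smoothed
            best_out = out[0, :h, :w].copy()
            best_it = it
        if len(trace) % wlen == 0:
            stop, _ = early_stop_check(trace, config.early_stop)
            if stop:
                break
        net.backward(2.0 * diff / n)
        optimizer.step(net.gradients())

    assert best_out is not None
    denoised = ImageSlice(
        np.clip(best_out, 0.0, 1.0), target.pixel_pitch_um, "float", True
    )
    return DIPResult(denoised, np.asarray(trace), best_it, config)


def denoise_stack(
    stack: ImageStack, config: DIPConfig | None = None, progress: bool = False
) -> tuple[ImageStack, list[DIPResult]]:
    """Denoise every slice independently with per-slice seeds
    ``config.seed + slice_index`` so stack runs are reproducible."""
    if config is None:
        config = DIPConfig()
    results: list[DIPResult] = []
    out_slices: list[ImageSlice] = []
    for i, s in enumerate(stack):
        try:
            res = fit_dip(s, config.replace(seed=config.seed + i))
        except Exception as exc:  # annotate with the slice index
            raise RuntimeError(f"denoising failed at slice {i}: {exc}") from exc
        results.append(res)
        out_slices.append(res.denoised)
        if progress:
            print(f"slice {i + 1}/{stack.n_slices}: stop={res.stop_iteration}")
    return ImageStack(out_slices, stack.z_step_um), results
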