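"""The anti-aliased residual 1-D convolutional detector.

Reference architecture (input ``(2000, 10)``, base width ``D = 32``):

* stem: width-``D`` convolution (17 taps, bias);
* six pre-activation residual blocks — BN, ReLU, conv, BN, ReLU, conv —
  totaling 12 convolutional layers across three width stages
  (``D, D, D, 2D, 2D, 4D``; kernel sizes 5 in the first stage, 3 after);
* anti-aliased stride-2 temporal downsampling in blocks 2, 4 and 6
  (temporal length 2000 -> 1000 -> 500 -> 250), with the same fixed 3-tap
  Gaussian low-pass on the shortcut;
* 1x1 projection shortcuts at the two width changes;
* final BN + ReLU, global max pooling over time, and a bias-free dense unit
  with sigmoid output.

Convolutions (including projections) carry biases; the output unit does not.
With these choices the reference configuration has 165,664 trainable
parameters.  The ``no_antialias`` ablation replaces the blur-then-subsample
with a plain stride-2 convolution and max-pools the shortcut instead, leaving
the parameter count unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .augment import MiniBatch
from .nn import (BatchNorm, BlurPool, Conv1D, Dense, GlobalMaxPool, Layer,
                 MaxPool2, Param, ReLU, sigmoid)

#: width of the fixed Gaussian low-pass used before each subsampling
AA_SIGMA = 0.79577

VARIANTS = ("full", "no_zscore", "no_l2", "no_antialias",
            "bs32", "bs64", "no_discount", "baseline")


def gaussian_kernel3(sigma: float) -> np.ndarray:
    """Three-point Gaussian low-pass taps at offsets {-1, 0, +1}, sum 1."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.array([-1.0, 0.0, 1.0])
    w = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    return w / w.sum()


def antialiased_downsample(seq: np.ndarray,
                           sigma: float = AA_SIGMA) -> np.ndarray:
    """Blur with the 3-tap Gaussian (reflect padding) and halve the
    temporal axis, keeping every second sample starting at index 0.

    Accepts ``(L, C)`` or ``(B, L, C)``; ``L`` must be even.
    """
    seq = np.asarray(seq, dtype=np.float64)
    squeeze = seq.ndim == 2
    if squeeze:
        seq = seq[None]
    out = BlurPool(gaussian_kernel3(sigma)).forward(seq, training=False)
    return out[0] if squeeze else out


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the detector."""

    base_width: int = 32
    n_conv_layers: int = 12
    stage_widths: tuple[int, int, int] = (32, 64, 128)
    blocks_per_stage: tuple[int, int, int] = (3, 2, 1)
    stage_kernels: tuple[int, int, int] = (5, 3, 3)
    stem_kernel: int = 17
    n_downsamples: int = 3
    aa_sigma: float = AA_SIGMA
    aa_taps: int = 3
    l2_lambda: float = 0.01
    antialiased: bool = True
    input_shape: tuple[int, int] = (2000, 10)

    def __post_init__(self) -> None:
        if self.aa_taps % 2 == 0:
            raise ValueError("aa_taps must be odd")
        if self.n_downsamples != 3:
            raise ValueError("the detector uses exactly 3 downsamplings")
        if self.input_shape[0] % 2 ** self.n_downsamples:
            raise ValueError(
                f"input length {self.input_shape[0]} must be divisible by "
                f"{2 ** self.n_downsamples}"
            )
        if 2 * sum(self.blocks_per_stage) != self.n_conv_layers:
            raise ValueError(
                f"{sum(self.blocks_per_stage)} two-convolution blocks cannot "
                f"place {self.n_conv_layers} convolutional layers"
            )

    def scaled(self, base_width: int) -> "NetworkConfig":
        """The same layout at a different base width (stage widths scale)."""
        f = base_width / self.base_width
        return replace(
            self, base_width=base_width,
            stage_widths=tuple(int(round(w * f)) for w in self.stage_widths),
        )


@dataclass
class TrainingFlags:
    """Technique switches attached to a model by :func:`build_variant`."""

    zscore: str = "batch"          # "batch" | "per_sequence"
    l2_lambda: float = 0.01
    antialiased: bool = True
    discount: bool = True
    batch_size: int = 16


class PreActBlock(Layer):
    """Pre-activation residual block: BN-ReLU-conv-BN-ReLU-conv + shortcut.

    A downsampling block halves the temporal axis: anti-aliased (blur then
    subsample) on both paths, or — in the aliased ablation — a stride-2
    first convolution with a max-pooled shortcut.  Width-changing blocks
    project the (pre-activated) shortcut with a 1x1 convolution.
    """

    def __init__(self, cin: int, cout: int, k: int, *, downsample: bool,
                 antialiased: bool, blur_taps: np.ndarray, name: str,
                 rng: np.random.Generator):
        self.downsample = downsample
        self.antialiased = antialiased
        self.has_proj = cin != cout
        self.bn1 = BatchNorm(cin, name=f"{name}.bn1")
        self.relu1 = ReLU()
        stride = 2 if (downsample and not antialiased) else 1
        self.conv1 = Conv1D(cin, cout, k, stride=stride,
                            name=f"{name}.conv1", rng=rng)
        self.bn2 = BatchNorm(cout, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv1D(cout, cout, k, name=f"{name}.conv2", rng=rng)
        self.blur_main = BlurPool(blur_taps) if (downsample and antialiased) \
            else None
        if downsample:
            self.short_pool: Optional[Layer] = (
                BlurPool(blur_taps) if antialiased else MaxPool2())
        else:
            self.short_pool = None
        self.proj = Conv1D(cin, cout, 1, name=f"{name}.proj", rng=rng) \
            if self.has_proj else None

    def params(self) -> list[Param]:
        ps = (self.bn1.params() + self.conv1.params() + self.bn2.params()
              + self.conv2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(x, training), training)
        h = self.blur_main.forward(a, training) if self.blur_main else a
        h = self.conv1.forward(h, training)
        h = self.relu2.forward(self.bn2.forward(h, training), training)
        h = self.conv2.forward(h, training)
        if self.has_proj:
            sc = self.short_pool.forward(a, training) if self.short_pool \
                else a
            sc = self.proj.forward(sc, training)
        else:
            sc = self.short_pool.forward(x, training) if self.short_pool \
                else x
        return h + sc

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.conv2.backward(dy)
        d = self.bn2.backward(self.relu2.backward(d))
        d = self.conv1.backward(d)
        d_a = self.blur_main.backward(d) if self.blur_main else d
        dx_short = None
        if self.has_proj:
            ds = self.proj.backward(dy)
            d_a = d_a + (self.short_pool.backward(ds) if self.short_pool
                         else ds)
        else:
            dx_short = self.short_pool.backward(dy) if self.short_pool \
                else dy
        dx = self.bn1.backward(self.relu1.backward(d_a))
        if dx_short is not None:
            dx = dx + dx_short
        return dx


class ResNet1D:
    """The detector network; also serves as the ModelHandle."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.config = cfg
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0DE)))
        taps = gaussian_kernel3(cfg.aa_sigma)
        _, c_in = cfg.input_shape
        w1, w2, w3 = cfg.stage_widths
        self.stem = Conv1D(c_in, w1, cfg.stem_kernel, name="stem", rng=rng)
        widths, kernels = [], []
        for w, n, k in zip(cfg.stage_widths, cfg.blocks_per_stage,
                           cfg.stage_kernels):
            widths += [w] * n
            kernels += [k] * n
        n_blocks = len(widths)
        # downsample in every second block (2, 4, 6): 2000->1000->500->250
        ds_at = {1, 3, 5}
        self.blocks: list[PreActBlock] = []
        cin = w1
        for i, (w, k) in enumerate(zip(widths, kernels)):
            self.blocks.append(PreActBlock(
                cin, w, k, downsample=i in ds_at,
                antialiased=cfg.antialiased, blur_taps=taps,
                name=f"block{i + 1}", rng=rng))
            cin = w
        self.final_bn = BatchNorm(cin, name="final_bn")
        self.final_relu = ReLU()
        self.gmp = GlobalMaxPool()
        self.dense = Dense(cin, 1, bias=False, name="head", rng=rng)
        self.dtype = np.dtype(np.float64)
        assert n_blocks * 2 == cfg.n_conv_layers

    def astype(self, dtype) -> "ResNet1D":
        """Cast all parameters and fixed taps to *dtype* (in place).

        float32 roughly halves training time; gradient-accuracy-sensitive
        work (finite-difference checks, salience) should stay in the
        default float64.
        """
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = np.zeros_like(p.value)
        for bn in self._batchnorms():
            bn.running_mean = bn.running_mean.astype(dtype)
            bn.running_var = bn.running_var.astype(dtype)
        for b in self.blocks:
            if b.blur_main is not None:
                b.blur_main.taps = b.blur_main.taps.astype(dtype)
            if isinstance(b.short_pool, BlurPool):
                b.short_pool.taps = b.short_pool.taps.astype(dtype)
        self.dtype = np.dtype(dtype)
        return self

    # -- parameters --------------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params()
        for b in self.blocks:
            ps += b.params()
        ps += self.final_bn.params() + self.dense.params()
        return ps

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0.0

    def l2_penalty(self, lam: float) -> float:
        return lam * sum(float((p.value ** 2).sum())
                         for p in self.params() if p.l2)

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        L, C = self.config.input_shape
        if x.ndim != 3 or x.shape[1] != L or x.shape[2] != C:
            raise ValueError(
                f"expected input (B, {L}, {C}), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=self.dtype)
        h = self.stem.forward(x, training)
        for b in self.blocks:
            h = b.forward(h, training)
        h = self.final_relu.forward(self.final_bn.forward(h, training),
                                    training)
        h = self.gmp.forward(h, training)
        return self.dense.forward(h, training)[:, 0]

    def backward_logits(self, dlogit: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(input)."""
        d = self.dense.backward(dlogit[:, None])
        d = self.gmp.backward(d)
        d = self.final_bn.backward(self.final_relu.backward(d))
        for b in reversed(self.blocks):
            d = b.backward(d)
        return self.stem.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, training=False))

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._batchnorms()):
            state[f"_running/{i}/mean"] = bn.running_mean.copy()
            state[f"_running/{i}/var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"_running/{i}/mean"]
            bn.running_var[...] = state[f"_running/{i}/var"]

    def _batchnorms(self) -> list[BatchNorm]:
        bns = []
        for b in self.blocks:
            bns += [b.bn1, b.bn2]
        bns.append(self.final_bn)
        return bns

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, cfg: Optional[NetworkConfig] = None) -> "ResNet1D":
        model = cls(cfg or NetworkConfig())
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(cfg: Optional[NetworkConfig] = None,
                seed: int = 0) -> ResNet1D:
    """Instantiate the detector for *cfg* (reference config by default)."""
    return ResNet1D(cfg or NetworkConfig(), seed=seed)


def build_variant(cfg: Optional[NetworkConfig] = None,
                  variant: str = "full",
                  seed: int = 0) -> tuple[ResNet1D, TrainingFlags]:
    """A model plus training flags for one of the ablation variants."""
    cfg = cfg or NetworkConfig()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"expected one of {VARIANTS}")
    flags = TrainingFlags(l2_lambda=cfg.l2_lambda)
    if variant == "no_zscore":
        flags.zscore = "per_sequence"
    elif variant == "no_l2":
        flags.l2_lambda = 0.0
    elif variant == "no_antialias":
        cfg = replace(cfg, antialiased=False)
    elif variant == "bs32":
        flags.batch_size = 32
    elif variant == "bs64":
        flags.batch_size = 64
    elif variant == "no_discount":
        flags.discount = False
    elif variant == "baseline":
        cfg = replace(cfg, antialiased=False)
        flags = TrainingFlags(zscore="per_sequence", l2_lambda=0.0,
                              antialiased=False, discount=False,
                              batch_size=64)
    flags.antialiased = cfg.antialiased
    return ResNet1D(cfg, seed=seed), flags


def forward(model: ResNet1D, batch: MiniBatch | np.ndarray) -> np.ndarray:
    """Inference-mode probabilities for a batch, shape (B,), in (0, 1)."""
    x = batch.values if isinstance(batch, MiniBatch) else np.asarray(batch)
    return model.predict_proba(x)


def parameter_tally(model: ResNet1D) -> list[tuple[str, int]]:
    """Per-parameter sizes, for the layer-by-layer audit."""
    return [(p.name, p.value.size) for p in model.params()]
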