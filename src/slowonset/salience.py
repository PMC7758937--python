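"""Gradient salience: which timesteps drove the prediction.

For a window ``x`` (normalized exactly as the model sees it at inference)
and predicted probability ``y``, the salience of timestep ``t`` is the sum
over the ten channels of the absolute gradient

    salience(t) = sum_f | dy / dx[t, f] |,

normalized for visualization by its maximum so the strongest timestep is 1.
Because the network ends in global max pooling, gradients concentrate on the
few timesteps that produced the pooled maxima, so traces are typically
sparse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .data_model import Window
from .network import ResNet1D
from .nn import sigmoid


@dataclass
class SalienceTrace:
    values: np.ndarray          # (L,), non-negative
    normalized: bool
    prediction: float
    degenerate: bool = False
    window_ref: Optional[Window] = None


def input_gradient(model: ResNet1D, x: np.ndarray) -> tuple[np.ndarray, float]:
    """``dy/dx`` of the predicted probability for one window ``x (L, C)``."""
    model.zero_grad()
    logit = model.forward_logits(x[None], training=False)
    y = float(sigmoid(logit)[0])
    # d(prob)/d(logit) = y (1 - y); backward propagates to the input
    grad = model.backward_logits(np.array([y * (1.0 - y)]))
    return grad[0], y


def compute_salience(model: ResNet1D, win: Window) -> SalienceTrace:
    """Per-timestep channel-summed absolute input gradient.

    ``win`` must already be normalized the way it would be for inference
    (population z-scoring for the full method); the gradient is taken at
    the model's actual input.
    """
    grad, y = input_gradient(model, win.values)
    values = np.abs(grad).sum(axis=1)
    return SalienceTrace(values=values, normalized=False, prediction=y,
                         degenerate=bool(np.all(values == 0.0)),
                         window_ref=win)


def normalize_salience(trace: SalienceTrace) -> SalienceTrace:
    """Divide by the maximum; degenerate all-zero traces pass through."""
    if trace.degenerate or trace.values.max() == 0.0:
        return SalienceTrace(values=trace.values.copy(), normalized=True,
                             prediction=trace.prediction, degenerate=True,
                             window_ref=trace.window_ref)
    return SalienceTrace(values=trace.values / trace.values.max(),
                         normalized=True, prediction=trace.prediction,
                         degenerate=False, window_ref=trace.window_ref)


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def render_salience(win: Window, trace: SalienceTrace, out,
                    frames_dir=None, fps: int = 25,
                    fs: float = 200.0) -> None:
    """Stacked channel traces over a salience heat strip.

    The title reports the true label and the (half-to-even) rounded
    prediction, classifying the window as a true/false positive/negative.
    With ``frames_dir``, one frame per 1/``fps`` seconds is exported with a
    moving time cursor for video assembly.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not trace.normalized:
        trace = normalize_salience(trace)
    L, C = win.values.shape
    t = np.arange(L) / fs

    def draw(cursor: Optional[float] = None):
        fig, ax = plt.subplots(figsize=(10, 6))
        ax.imshow(trace.values[None, :], aspect="auto", cmap="inferno",
                  extent=(0, t[-1], -0.5, C - 0.5), alpha=0.5,
                  vmin=0.0, vmax=1.0)
        for c in range(C):
            ch = win.values[:, c]
            rng = np.ptp(ch) or 1.0
            ax.plot(t, (ch - ch.mean()) / rng * 0.8 + (C - 1 - c),
                    lw=0.5, color="w")
        if cursor is not None:
            ax.axvline(cursor, color="cyan", lw=1.0)
        yp = _round_half_even(trace.prediction)
        kind = {(1, 1): "true positive", (1, 0): "false negative",
                (0, 1): "false positive", (0, 0): "true negative"}[
                    (win.label, yp)]
        ax.set_title(f"y_true={win.label}, round(y_pred)={yp} ({kind})")
        ax.set_xlabel("time (s)")
        ax.set_yticks([])
        fig.tight_layout()
        return fig

    fig = draw()
    fig.savefig(out, dpi=100)
    plt.close(fig)
    if frames_dir is not None:
        frames_dir = Path(frames_dir)
        frames_dir.mkdir(parents=True, exist_ok=True)
        n_frames = int(round(L / fs * fps))
        for i in range(n_frames):
            f = draw(cursor=i / fps)
            f.savefig(frames_dir / f"frame_{i:05d}.png", dpi=60)
            plt.close(f)
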