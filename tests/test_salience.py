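import numpy as np
import pytest

from slowonset.data_model import N_CHANNELS, Window
from slowonset.network import ResNet1D
from slowonset.nn import sigmoid
from slowonset.salience import (SalienceTrace, compute_salience,
                                normalize_salience, render_salience)


def make_window(L=64, seed=0, p=1.0):
    rng = np.random.default_rng(seed)
    return Window(values=rng.normal(size=(L, N_CHANNELS)),
                  label=int(p > 0), p=p, t_i=0, t_f=L - 1)


def activation_pattern(model):
    """Snapshot of every ReLU mask and pooling argmax after a forward pass.

    A central difference is a valid derivative estimate only on an interval
    where the network stays in one affine region; comparing patterns at the
    two probe points detects kink crossings exactly.
    """
    parts = []
    for b in model.blocks:
        parts += [b.relu1._mask.copy(), b.relu2._mask.copy()]
    parts.append(model.final_relu._mask.copy())
    parts.append(model.gmp._arg.copy())
    return parts


def fd_check_trace(model, win, trace, n_coords=20, h=1e-3, rel=1e-2,
                   seed=8):
    """Assert channel-summed central differences match the salience trace
    at ``n_coords`` timesteps whose probe intervals are kink-free.
    Returns the number of coordinates actually checked."""
    rng = np.random.default_rng(seed)
    checked = 0
    candidates = rng.permutation(win.length)
    for t in candidates:
        if checked == n_coords:
            break
        s_fd = 0.0
        smooth = True
        for c in range(N_CHANNELS):
            xp, xm = win.values.copy(), win.values.copy()
            xp[t, c] += h
            xm[t, c] -= h
            yp = float(sigmoid(model.forward_logits(xp[None], False))[0])
            pat_p = activation_pattern(model)
            ym = float(sigmoid(model.forward_logits(xm[None], False))[0])
            pat_m = activation_pattern(model)
            if not all(np.array_equal(a, b)
                       for a, b in zip(pat_p, pat_m)):
                smooth = False
                break
            s_fd += abs((yp - ym) / (2 * h))
        if not smooth:
            continue
        assert s_fd == pytest.approx(trace.values[t], rel=rel, abs=1e-10)
        checked += 1
    return checked


class LinearSigmoidSurrogate:
    """y = sigmoid(sum_f w_f * mean_t x[t, f]) with known weights, so the
    salience has the closed form |sigma'| * sum_f |w_f| / L at every t."""

    def __init__(self, weights):
        self.w = np.asarray(weights, dtype=np.float64)

    def zero_grad(self):
        pass

    def forward_logits(self, x, training=False):
        self._L = x.shape[1]
        return x.mean(axis=1) @ self.w

    def backward_logits(self, dlogit):
        B = dlogit.shape[0]
        return (dlogit[:, None, None]
                * np.tile(self.w, (B, self._L, 1)) / self._L)


class TestComputeSalience:
    def test_surrogate_model_closed_form(self):
        w = np.array([0.5, -1.0, 2.0, 0.0, 1.5, -0.3, 0.7, 0.1, -2.0, 0.9])
        model = LinearSigmoidSurrogate(w)
        win = make_window(L=40, seed=1)
        trace = compute_salience(model, win)
        y = trace.prediction
        expected = y * (1 - y) * np.abs(w).sum() / 40
        assert np.allclose(trace.values, expected, rtol=1e-10)

    def test_finite_difference_agreement(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=2)
        # shrink the head so the prediction sits away from the sigmoid's
        # saturated tails, where central differences are well-conditioned
        model.dense.w.value *= 0.05
        win = make_window(L=64, seed=3)
        trace = compute_salience(model, win)
        assert 0.05 < trace.prediction < 0.95
        n_checked = fd_check_trace(model, win, trace, n_coords=20,
                                   h=1e-3, rel=1e-2)
        assert n_checked == 20

    def test_channel_sum_consistency(self, tiny_net_cfg):
        from slowonset.salience import input_gradient
        model = ResNet1D(tiny_net_cfg, seed=2)
        win = make_window(L=64, seed=4)
        trace = compute_salience(model, win)
        grad, _ = input_gradient(model, win.values)
        assert np.abs(np.abs(grad).sum(axis=1) - trace.values).max() < 1e-10

    def test_nonnegative_everywhere(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=2)
        trace = compute_salience(model, make_window(seed=5))
        assert np.all(trace.values >= 0)

    def test_zero_head_gives_degenerate_trace(self, tiny_net_cfg):
        model = ResNet1D(tiny_net_cfg, seed=2)
        model.dense.w.value[:] = 0.0
        trace = compute_salience(model, make_window(seed=6))
        assert trace.degenerate
        assert np.all(trace.values == 0.0)

    def test_gmp_trace_is_sparse_on_trained_model(self):
        # sparsity is a property of full-length windows through the pooled
        # head of a trained detector: only the timesteps feeding the pooled
        # maxima carry gradient
        from slowonset.augment import (compute_population_stats,
                                       population_zscore)
        from slowonset.network import NetworkConfig, build_variant
        from slowonset.synth import (GeneratorConfig, make_cohort,
                                     make_validation_windows)
        from slowonset.training import TrainConfig, train
        from slowonset.windows import WindowSetSpec, build_training_set

        gcfg = GeneratorConfig(n_train_patients=2, n_val_patients=1,
                               duration_range=(25.0, 30.0),
                               onset_fraction_range=(0.45, 0.55), seed=21)
        cohort = make_cohort(gcfg)
        tw = build_training_set(cohort, WindowSetSpec(
            rng_seed=0, max_pos_per_patient=8))
        vw = make_validation_windows(cohort, 4, 0.5)
        model, flags = build_variant(NetworkConfig().scaled(4), "full",
                                     seed=0)
        train(model, tw, vw, TrainConfig.from_flags(flags, epochs=2,
                                                    seed=0))
        stats = compute_population_stats(tw)
        fracs = []
        for win in population_zscore(vw, stats):
            trace = normalize_salience(compute_salience(model, win))
            if not trace.degenerate:
                fracs.append(float((trace.values > 0.1).mean()))
        assert fracs and max(fracs) < 0.5


class TestNormalize:
    def test_divides_by_max(self):
        t = SalienceTrace(values=np.array([2.0, 4.0, 1.0]),
                          normalized=False, prediction=0.7)
        out = normalize_salience(t)
        assert np.allclose(out.values, [0.5, 1.0, 0.25])
        assert out.values.max() == 1.0

    def test_idempotent(self):
        t = SalienceTrace(values=np.array([0.5, 1.0, 0.25]),
                          normalized=True, prediction=0.7)
        out = normalize_salience(normalize_salience(t))
        assert np.allclose(out.values, t.values)

    def test_all_zero_flagged_not_rescaled(self):
        t = SalienceTrace(values=np.zeros(5), normalized=False,
                          prediction=0.5)
        out = normalize_salience(t)
        assert out.degenerate
        assert np.all(out.values == 0.0)


class TestRender:
    def test_figure_written(self, tmp_path):
        win = make_window(L=2000, seed=9)
        t = SalienceTrace(values=np.abs(np.random.default_rng(0)
                                        .normal(size=2000)),
                          normalized=False, prediction=0.8)
        out = tmp_path / "fig.png"
        render_salience(win, t, out)
        assert out.exists() and out.stat().st_size > 0

    def test_frame_count_matches_duration_times_fps(self, tmp_path):
        win = make_window(L=2000, seed=9)  # 10 s at 200 Hz
        t = SalienceTrace(values=np.ones(2000), normalized=True,
                          prediction=0.2)
        frames = tmp_path / "frames"
        render_salience(win, t, tmp_path / "f.png", frames_dir=frames,
                        fps=2)
        assert len(list(frames.glob("frame_*.png"))) == 20  # 10 s * 2 fps
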