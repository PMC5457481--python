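"""Binocular neural network: structure, gradients, training, probes."""

import numpy as np
import pytest

from binodepth.bnn import (
    TrainConfig,
    depth_sign_map,
    drive_decomposition,
    evaluate,
    forward,
    init_bnn,
    lesion,
    load_model,
    loss_and_grads,
    optimal_stimulus,
    save_model,
    train,
)
from binodepth.stimgen import StepEdgeConfig, StereoPair, make_step_edge


@pytest.fixture(scope="module")
def model2():
    return init_bnn(n_outputs=2)


class TestStructure:
    def test_two_way_parameter_counts(self, model2):
        assert model2.conv_parameter_count() == 20_244
        assert model2.readout_parameter_count() == 1_010
        assert model2.parameter_count() == 21_254

    def test_conv_units_and_connections(self, model2):
        # 28 maps of 12x12 units, each wired to a 19x19x2 input window
        n_units = model2.n_kernels * 12 * 12
        assert n_units == 4_032
        assert n_units * 19 * 19 * 2 == 2_911_104
        # 36 pooled positions per map feed the readout
        assert model2.n_kernels * 36 == 1_008

    @pytest.mark.parametrize("n_out", [7, 11])
    def test_nway_parameter_counts(self, n_out):
        m = init_bnn(n_outputs=n_out)
        assert m.conv_parameter_count() == 28 * (19 * 19 * 2) + 28
        assert m.readout_parameter_count() == 28 * 36 * n_out + n_out

    def test_initial_kernels_have_no_disparity_selectivity(self, model2):
        assert np.array_equal(model2.kernels[..., 0], model2.kernels[..., 1])
        assert np.all(model2.b_out == 0) and np.all(model2.w_out == 0)

    def test_init_noise_breaks_eye_symmetry_reproducibly(self):
        a = init_bnn(init_noise=0.1, seed=3)
        b = init_bnn(init_noise=0.1, seed=3)
        assert not np.array_equal(a.kernels[..., 0], a.kernels[..., 1])
        assert np.array_equal(a.kernels, b.kernels)


class TestForward:
    def test_shape_chain_and_probabilities(self, model2):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, (5, 30, 30, 2))
        acts, probs, preds = forward(model2, x)
        assert acts["conv"].shape == (5, 12, 12, 28)
        assert acts["pooled"].shape == (5, 28 * 36)
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_readout_gives_uniform_probabilities(self, model2):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, (3, 30, 30, 2))
        _, probs, _ = forward(model2, x)
        assert np.allclose(probs, 0.5)

    def test_wrong_patch_shape_rejected(self, model2):
        with pytest.raises(ValueError):
            forward(model2, np.zeros((2, 20, 20, 2)))


class TestGradients:
    def test_analytic_matches_central_differences(self):
        # relative error < 1e-5 on a miniature float64 network
        rng = np.random.default_rng(0)
        model = init_bnn(n_kernels=3, kernel_size=5, input_size=8, dtype=np.float64)
        model.kernels += rng.normal(0, 0.1, model.kernels.shape)
        model.w_out = rng.normal(0, 0.1, model.w_out.shape)
        model.conv_bias = rng.normal(0, 0.1, model.conv_bias.shape)
        model.b_out = rng.normal(0, 0.1, model.b_out.shape)
        x = rng.uniform(-1, 1, (4, 8, 8, 2))
        y = rng.integers(0, 2, 4)
        _, grads = loss_and_grads(model, x, y)
        eps = 1e-6
        for name in ("kernels", "conv_bias", "w_out", "b_out"):
            arr = getattr(model, name)
            flat_idx = rng.choice(arr.size, min(15, arr.size), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp, _ = loss_and_grads(model, x, y)
                arr[ix] = orig - eps
                lm, _ = loss_and_grads(model, x, y)
                arr[ix] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name][ix]
                rel = abs(num - ana) / max(abs(num), abs(ana), 1e-8)
                assert rel < 1e-5, f"{name}{ix}: {rel}"


class TestTraining:
    def test_learns_separable_rds_task(self):
        from binodepth.analysis import make_rds_test_set

        tr = make_rds_test_set(n=800, disparities=(4,), seed=0)
        va = make_rds_test_set(n=200, disparities=(4,), seed=1)
        model = init_bnn(init_noise=0.1, seed=5)
        model, history = train(
            model, tr, va, TrainConfig(learning_rate=0.004, max_epochs=35, seed=0)
        )
        # training accuracy reaches the ceiling on this clean toy task
        acc, _ = evaluate(model, tr, tr.labels, n_boot=10, seed=0)
        assert acc > 97.0
        assert {"epoch", "iteration", "train_loss", "val_accuracy"} <= set(
            history.columns
        )

    def test_training_reproducible_under_seed(self):
        from binodepth.analysis import make_rds_test_set

        tr = make_rds_test_set(n=300, disparities=(4,), seed=2)
        va = make_rds_test_set(n=100, disparities=(4,), seed=3)
        runs = []
        for _ in range(2):
            m = init_bnn(init_noise=0.1, seed=9)
            m, _ = train(m, tr, va, TrainConfig(max_epochs=3, seed=1))
            runs.append(m)
        assert np.array_equal(runs[0].kernels, runs[1].kernels)
        assert np.array_equal(runs[0].w_out, runs[1].w_out)

    def test_unbalanceable_batch_rejected(self):
        from binodepth.stimgen import PatchSet

        bad = PatchSet(np.zeros((10, 30, 30)), np.zeros((10, 30, 30)), np.zeros(10, int))
        with pytest.raises(ValueError):
            train(init_bnn(), bad, bad, TrainConfig(max_epochs=1))


class TestEvaluate:
    def test_perfect_predictions_give_degenerate_ci(self, model2):
        # a model with uniform outputs predicts class 0 everywhere
        x = np.zeros((50, 30, 30, 2))
        acc, ci = evaluate(model2, x, np.zeros(50, int), n_boot=200, seed=0)
        assert acc == 100.0 and ci == (100.0, 100.0)

    def test_chance_level_for_random_labels(self, model2):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (600, 30, 30, 2))
        labels = rng.integers(0, 2, 600)
        acc, ci = evaluate(model2, x, labels, n_boot=300, seed=0)
        assert ci[0] < 50.0 < ci[1] or abs(acc - 50) < 5


class TestLesion:
    def test_empty_lesion_is_identity(self, model2):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, (3, 30, 30, 2))
        same = lesion(model2, [])
        _, p0, _ = forward(model2, x)
        _, p1, _ = forward(same, x)
        assert np.array_equal(p0, p1)

    def test_parameter_bookkeeping(self, model2):
        les = lesion(model2, [0, 3, 5, 7, 11, 13, 17])
        drop = model2.parameter_count() - les.parameter_count()
        assert drop == 7 * (19 * 19 * 2 + 1) + 7 * 36  # tied 2-way readout

    def test_cannot_remove_all_units(self, model2):
        with pytest.raises(ValueError):
            lesion(model2, list(range(28)))


class TestProbes:
    def test_optimal_stimulus_ascends_and_stabilizes(self, trained_bnn):
        snapshots, objective, corr = optimal_stimulus(
            trained_bnn, output_unit=1, iters=100, step=1.0, seed=0
        )
        assert objective[-1] > objective[0]
        assert corr[-1] > 0.99  # consecutive iterates saturate
        assert len(snapshots) == 3

    def test_optimal_stimulus_shift_matches_preferred_sign(self, trained_bnn):
        # the far unit's preferred image is translated toward positive lag
        for unit, sign in ((1, 1), (0, -1)):
            snaps, _, _ = optimal_stimulus(trained_bnn, unit, iters=100, seed=1)
            final = snaps[-1]
            lags = np.arange(-4, 5)
            left = final.left - final.left.mean()
            right = final.right - final.right.mean()
            vals = [
                np.sum(left[:, max(0, -d) : 30 - max(0, d)] *
                       right[:, max(0, d) : 30 + min(0, d)])
                for d in lags
            ]
            best = lags[int(np.argmax(vals))]
            assert np.sign(best) == sign

    def test_depth_sign_map_separates_step_halves(self, trained_bnn):
        cfg = StepEdgeConfig(noise_sd=0.0, seed=0)
        pair = make_step_edge(cfg)
        m = depth_sign_map(trained_bnn, pair).values
        w = m.shape[1]
        # near (left) half lower than far (right) half in most pixels
        left_half, right_half = m[:, : w // 2], m[:, w // 2 :]
        assert (left_half < np.median(m)).mean() > 0.5
        assert (right_half > np.median(m)).mean() > 0.5

    def test_depth_sign_map_rejects_small_inputs(self, trained_bnn):
        tiny = StereoPair(np.zeros((10, 10)), np.zeros((10, 10)))
        with pytest.raises(ValueError):
            depth_sign_map(trained_bnn, tiny)

    def test_drive_decomposition_reconstructs_logits(self, trained_bnn):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, (20, 30, 30, 2)).astype(np.float32)
        dec = drive_decomposition(trained_bnn, x)
        pre_bias = dec.logits - trained_bnn.b_out
        assert np.allclose(dec.excitatory + dec.suppressive, pre_bias, atol=1e-4)

    def test_ards_increases_suppression_at_preferred_disparity(self, trained_bnn):
        from binodepth.analysis import make_rds_test_set

        crds = make_rds_test_set(n=400, seed=31)
        ards = make_rds_test_set(n=400, correlated=False, seed=31)
        far = crds.labels == 1
        dec_c = drive_decomposition(trained_bnn, crds)
        dec_a = drive_decomposition(trained_bnn, ards)
        # suppressive drive to the preferred (far) output grows under
        # anticorrelation for far-disparity stimuli
        sup_c = dec_c.suppressive[far, 1].mean()
        sup_a = dec_a.suppressive[far, 1].mean()
        assert sup_a < sup_c  # more negative = stronger suppression


def test_model_serialization_round_trip(tmp_path, model2):
    path = str(tmp_path / "model.npz")
    save_model(path, model2)
    loaded = load_model(path)
    assert np.array_equal(loaded.kernels, model2.kernels)
    assert loaded.n_out == model2.n_out
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, (2, 30, 30, 2))
    _, p0, _ = forward(model2, x)
    _, p1, _ = forward(loaded, x)
    assert np.allclose(p0, p1)
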