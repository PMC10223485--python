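"""Head/ensemble construction contracts: shapes, parameter counts against
closed-form oracles, sub-model independence, and the fusion rules."""

import numpy as np
import pytest

from falldet import nn
from falldet.architecture import (
    ClassEnsembleNetwork,
    EnsembleSpec,
    build_class_ensemble,
    build_head_model,
    build_stacked_ensemble,
    fuse_proposed,
    fuse_weighted_average,
    gru_param_count,
    lstm_param_count,
)
from falldet.labels import ClassLabel
from falldet.training import _bce_from_logits


def _spec(**kw):
    defaults = dict(input_shape=(256, 6))
    defaults.update(kw)
    return EnsembleSpec(**defaults)


class TestHeadModel:
    def test_three_blocks_halve_256_to_32x16(self):
        head = build_head_model(_spec())
        out = head.forward(np.zeros((2, 256, 6)))
        assert out.shape == (2, 32, 16)

    def test_four_blocks_give_16x16(self):
        head = build_head_model(_spec(
            head_blocks=4, head_widths=(16, 16, 16, 16)))
        out = head.forward(np.zeros((1, 256, 6)))
        assert out.shape == (1, 16, 16)

    def test_zero_blocks_identity(self):
        head = build_head_model(_spec(head_blocks=0, head_widths=()))
        x = np.random.default_rng(0).normal(size=(2, 256, 6))
        np.testing.assert_array_equal(head.forward(x), x)

    def test_indivisible_width_rejected_at_build(self):
        with pytest.raises(ValueError, match="divisible"):
            build_head_model(_spec(
                input_shape=(100, 6), head_blocks=3, head_widths=(16, 16, 16)))

    def test_separable_head_has_fewer_params_than_standard(self):
        sep = build_head_model(_spec(conv_type="separable"))
        std = build_head_model(_spec(conv_type="standard"))
        assert sep.n_params < std.n_params


class TestParameterCounts:
    def test_lstm_layer_matches_closed_form(self):
        rng = np.random.default_rng(0)
        layer = nn.LSTM(16, 16, rng)
        assert layer.n_params == lstm_param_count(16, 16) == 4 * (16 * 32 + 16)

    def test_gru_strictly_fewer_than_lstm_at_equal_width(self):
        gru = build_class_ensemble(_spec(recurrent_cell="gru"))
        lstm = build_class_ensemble(_spec(recurrent_cell="lstm"))
        assert gru.n_params < lstm.n_params
        rng = np.random.default_rng(0)
        assert nn.GRU(16, 16, rng).n_params == gru_param_count(16, 16)

    def test_submodel_count_grows_with_widths(self):
        small = build_class_ensemble(_spec())
        big = build_class_ensemble(_spec(recurrent_widths=(32, 64)))
        dense = 16 + 1  # width-16 output unit vs width-64 below
        expected_small = (
            lstm_param_count(16, 16) + lstm_param_count(16, 16) + dense
        )
        got_small = small.submodels[0].n_params
        assert got_small == expected_small
        expected_big = (
            lstm_param_count(32, 16) + lstm_param_count(64, 32) + (64 + 1)
        )
        assert big.submodels[0].n_params == expected_big
        assert big.n_params > small.n_params

    def test_bilstm_doubles_recurrent_params(self):
        rng = np.random.default_rng(0)
        assert nn.BiLSTM(16, 16, rng).n_params == 2 * lstm_param_count(16, 16)


class TestClassEnsemble:
    def test_one_submodel_per_class_with_disjoint_params(self):
        net = build_class_ensemble(_spec())
        assert len(net.submodels) == 3
        ids = [
            {id(p) for lay in nn.leaf_layers(sm.layers)
             for p in lay.params.values()}
            for sm in net.submodels
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert ids[i].isdisjoint(ids[j])

    def test_forward_yields_three_scores_in_unit_interval(self):
        net = build_class_ensemble(_spec())
        s = net.scores(np.random.default_rng(0).normal(size=(4, 256, 6)))
        assert s.shape == (4, 3)
        assert ((s > 0) & (s < 1)).all()

    def test_single_class_loss_leaves_other_submodels_untouched(self):
        """Gradients flow into the head and the active class's sub-model
        only: the other branches' parameters see zero gradient."""
        net = build_class_ensemble(_spec(
            input_shape=(32, 6), head_blocks=1, head_widths=(8,),
            recurrent_layers=1, recurrent_widths=(8,), dropout_rate=0.0))
        x = np.random.default_rng(0).normal(size=(2, 32, 6))
        net.zero_grad()
        logits = net.forward(x, training=True)
        dlogits = np.zeros_like(logits)
        dlogits[:, 1] = 1.0               # only PRE_FALL branch active
        net.backward(dlogits)
        for j, sm in enumerate(net.submodels):
            g = sum(
                float(np.abs(lay.grads[k]).sum())
                for lay in nn.leaf_layers(sm.layers)
                for k in lay.params
            )
            assert (g > 0) == (j == 1)
        head_g = sum(
            float(np.abs(lay.grads[k]).sum())
            for lay in nn.leaf_layers(net.head.layers)
            for k in lay.params
        )
        assert head_g > 0

    def test_weight_roundtrip_restores_outputs(self):
        net = build_class_ensemble(_spec(input_shape=(32, 6), head_blocks=1,
                                         head_widths=(8,)))
        x = np.random.default_rng(0).normal(size=(2, 32, 6))
        before = net.forward(x)
        saved = net.get_weights()
        for lay in nn.leaf_layers(net.layers):
            for k in lay.params:
                lay.params[k] = lay.params[k] + 1.0
        assert not np.allclose(net.forward(x), before)
        net.set_weights(saved)
        np.testing.assert_array_equal(net.forward(x), before)


class TestStackedEnsemble:
    def test_softmax_output_sums_to_one(self):
        net = build_stacked_ensemble(_spec(
            input_shape=(32, 6), recurrent_layers=1, recurrent_widths=(8,)))
        probs = net.forward(np.random.default_rng(0).normal(size=(5, 32, 6)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert net.predict(np.zeros((2, 32, 6))).shape == (2,)

    def test_single_submodel_degenerate_ensemble(self):
        net = build_stacked_ensemble(
            _spec(input_shape=(32, 6), recurrent_layers=1,
                  recurrent_widths=(8,)),
            n_submodels=1,
        )
        assert len(net.submodels) == 1
        assert net.final.params["W"].shape == (1, 3)


class TestFusion:
    def test_argmax_of_scores(self):
        assert fuse_proposed([0.1, 0.7, 0.2]) is ClassLabel.PRE_FALL
        assert fuse_proposed([0.0, 0.0, 1.0]) is ClassLabel.FALL

    def test_tie_break_applies_only_among_maxima(self):
        # tie {NON_FALL, PRE_FALL}: FALL priority is irrelevant, PRE_FALL wins
        assert fuse_proposed([0.4, 0.4, 0.1]) is ClassLabel.PRE_FALL
        assert fuse_proposed([0.4, 0.1, 0.4]) is ClassLabel.FALL

    def test_one_hot_identity(self):
        for c in ClassLabel:
            onehot = np.eye(3)[int(c)]
            assert fuse_proposed(onehot) is c

    def test_nan_score_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            fuse_proposed([0.1, np.nan, 0.2])

    def test_unit_weights_reduce_to_proposed(self):
        scores = np.array([0.3, 0.6, 0.1])
        assert fuse_weighted_average(scores, np.ones(3)) is fuse_proposed(scores)

    def test_weighted_average_hand_example(self):
        got = fuse_weighted_average([0.6, 0.5, 0.1], [0.5, 1.0, 1.0])
        assert got is ClassLabel.PRE_FALL  # 0.3 vs 0.5 vs 0.1

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fuse_weighted_average([0.5, 0.5, 0.5], [1.0, -0.1, 1.0])

    def test_weight_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fuse_weighted_average([0.5, 0.5, 0.5], [1.0, 1.0])
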