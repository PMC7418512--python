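"""Model families: layer contracts, heads, pair models, serialization."""

import numpy as np
import pytest

import tcrspec as ts
from tcrspec.nn.autograd import Tensor
from tcrspec.nn.model import load_model, save_model


def make_spec(kind="linear", width=8, head="categorical", n_antigens=4, **kw):
    defaults = dict(
        chain_mode="trb",
        seq_layer=ts.SequenceLayerSpec(kind=kind, width=width),
        embedding=ts.EmbeddingSpec(mode="learned"),
        head=head,
        n_antigens=n_antigens,
    )
    defaults.update(kw)
    return ts.ModelSpec(**defaults)


@pytest.fixture()
def batch(rng):
    return rng.random((6, 40, 20)), rng.random((6, 3))


class TestSequenceStack:
    def test_bidirectional_states_double_positions(self, batch):
        x, _ = batch
        model = ts.Model(make_spec("bigru", width=8), seed=0)
        acts = model._stack("seq", model._embed(x))
        assert acts.shape == (6, 80, 8)

    def test_recurrent_latent_is_two_directions_wide(self, batch):
        x, _ = batch
        model = ts.Model(make_spec("bigru", width=16), seed=0)
        latent = model._latent("seq", x)
        assert latent.shape == (6, 32)

    def test_conv_latent_flattens_positions_by_filters(self, batch):
        x, _ = batch
        model = ts.Model(make_spec("conv", width=8), seed=0)
        assert model._latent("seq", x).shape == (6, 40 * 8)

    def test_nettcr_latent_pools_per_kernel_filters(self, batch):
        x, _ = batch
        spec = make_spec("nettcr", width=16,
                         seq_layer=ts.SequenceLayerSpec(
                             kind="nettcr", width=16, kernel_sizes=(1, 3, 5, 7, 9)))
        model = ts.Model(spec, seed=0)
        assert model._latent("seq", x).shape == (6, 16 * 5)

    def test_zeroed_conv_layer_residual_is_identity(self, rng):
        # width == channels so the skip path is unprojected: y = relu(0) + x
        x = rng.random((3, 10, 5))
        spec = ts.ModelSpec(
            seq_layer=ts.SequenceLayerSpec(kind="conv", width=5),
            embedding=ts.EmbeddingSpec(mode="learned"),
            head="binary", n_antigens=1,
        )
        model = ts.Model(spec, seed=0)
        emb = model._embed(np.zeros((1, 10, 20)))  # materialize embed params
        model.store.get("seq.layer0.w", (5, 5, 5))
        model.store.get("seq.layer0.b", (5,), init="zeros")
        model.store.params["seq.layer0.w"].data[:] = 0.0
        inp = Tensor(x)
        from tcrspec.nn.layers import sequence_layer

        out = sequence_layer(model.store, "seq.layer0", inp, "conv", 5)
        np.testing.assert_array_equal(out.data, x)

    def test_noseq_prediction_depends_only_on_covariates(self, rng):
        spec = make_spec("noseq", covariate_set=("donor",))
        model = ts.Model(spec, seed=0)
        cov = rng.random((4, 2))
        p1 = model.predict(rng.random((4, 40, 20)), cov)
        p2 = model.predict(rng.random((4, 40, 20)), cov)
        np.testing.assert_array_equal(p1, p2)

    def test_deterministic_forward(self, batch):
        x, cov = batch
        a = ts.Model(make_spec("self_attention"), seed=3).predict(x, cov)
        b = ts.Model(make_spec("self_attention"), seed=3).predict(x, cov)
        np.testing.assert_array_equal(a, b)


class TestHeads:
    @pytest.mark.parametrize(
        "kind", ["bigru", "bilstm", "self_attention", "conv", "inception",
                 "nettcr", "linear", "noseq"]
    )
    def test_categorical_outputs_are_distributions(self, batch, kind):
        x, cov = batch
        model = ts.Model(make_spec(kind, n_antigens=8), seed=1)
        probs = model.predict(x, cov)
        assert probs.shape == (6, 9)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_count_outputs_strictly_positive(self, batch):
        x, cov = batch
        model = ts.Model(make_spec("linear", head="count", n_antigens=8), seed=1)
        assert np.all(model.predict(x, cov) > 0)

    def test_count_head_zero_weights_predict_one(self, batch):
        x, cov = batch
        model = ts.Model(make_spec("linear", head="count", n_antigens=3), seed=1)
        model.predict(x, cov)  # materialize
        model.store.params["head.out.w"].data[:] = 0.0
        model.store.params["head.out.b"].data[:] = 0.0
        np.testing.assert_array_equal(model.predict(x, cov), np.ones((6, 3)))

    def test_zero_covariate_vector_is_legal(self, batch):
        x, cov = batch
        model = ts.Model(make_spec("linear", covariate_set=("donor",)), seed=0)
        full = model.predict(x, cov)
        zeroed = model.predict(x, np.zeros_like(cov))
        assert full.shape == zeroed.shape
        assert not np.allclose(full, zeroed)  # covariates actually enter

    def test_covariate_width_frozen_after_first_forward(self, batch):
        x, cov = batch
        model = ts.Model(make_spec("linear"), seed=0)
        model.predict(x, cov)
        with pytest.raises(ValueError, match="covariate width"):
            model.predict(x, cov[:, :2])

    def test_binary_preactivation_is_affine_in_inputs(self, rng):
        # LINEAR stack + depth-0 dense head: second differences vanish
        spec = ts.ModelSpec(
            seq_layer=ts.SequenceLayerSpec(kind="linear"),
            embedding=ts.EmbeddingSpec(mode="blosum"),
            head="binary", n_antigens=1, dense_widths=(),
        )
        model = ts.Model(spec, seed=2)
        x = rng.random((1, 10, 20))
        d = rng.random((1, 10, 20))
        cov = np.zeros((1, 0))
        f = lambda a: model.forward(a, cov).data[0, 0]  # noqa: E731
        second_diff = f(x + 2 * d) - 2 * f(x + d) + f(x)
        assert abs(second_diff) < 1e-9

    def test_covariate_permutation_invariance(self, rng):
        spec = make_spec("linear", dense_widths=(7,))
        model = ts.Model(spec, seed=0)
        x = rng.random((5, 40, 20))
        cov = rng.random((5, 4))
        base = model.predict(x, cov)
        perm = rng.permutation(4)
        latent_dim = 40 * 5  # linear stack flattens the learned embedding
        w = model.store.params["head.dense0.w"].data
        w[latent_dim:] = w[latent_dim:][perm]
        np.testing.assert_allclose(model.predict(x, cov[:, perm]), base, atol=1e-12)


class TestPairModels:
    def _specs(self, pair_mode):
        return ts.ModelSpec(
            chain_mode="trb", pair_mode=pair_mode,
            seq_layer=ts.SequenceLayerSpec(kind="conv", width=8),
            embedding=ts.EmbeddingSpec(mode="learned"),
            head="binary", n_antigens=1,
        )

    def test_separate_latent_dims_add(self, rng):
        model = ts.Model(self._specs("separate"), seed=0)
        xt, xa = rng.random((4, 40, 20)), rng.random((4, 25, 20))
        lt = model._latent("seq_tcr", xt)
        la = model._latent("seq_ag", xa)
        assert lt.shape == (4, 40 * 8) and la.shape == (4, 25 * 8)
        out = model.predict((xt, xa), np.zeros((4, 0)))
        assert out.shape == (4,) and np.all((out > 0) & (out < 1))

    def test_concatenated_input_length_65(self, rng):
        model = ts.Model(self._specs("concatenated"), seed=0)
        xt, xa = rng.random((4, 40, 20)), rng.random((4, 25, 20))
        joint = np.concatenate([xt, xa], axis=1)
        assert joint.shape[1] == 65
        latent = model._latent("seq", joint)
        assert latent.shape == (4, 65 * 8)
        out = model.predict((xt, xa), np.zeros((4, 0)))
        assert np.all((out > 0) & (out < 1))

    def test_categorical_pair_config_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            ts.ModelSpec(pair_mode="separate", head="categorical", n_antigens=4)


class TestCountModelBuilders:
    def test_multitask_width_and_shared_trunk(self, rng):
        spec = make_spec("linear", head="count", n_antigens=8, dense_widths=(16,))
        x, cov = rng.random((4, 40, 20)), np.zeros((4, 0))
        multi = ts.build_multitask_count_model(spec, seed=0)
        assert multi.predict(x, cov).shape == (4, 8)
        singles = ts.build_singletask_count_models(spec, seed=0)
        assert len(singles) == 8
        for m in singles:
            assert m.predict(x, cov).shape == (4, 1)
        assert multi.n_parameters < sum(m.n_parameters for m in singles)

    def test_wrong_head_rejected(self):
        with pytest.raises(ValueError):
            ts.build_multitask_count_model(make_spec("linear", head="categorical"))


class TestSerialization:
    def test_save_load_bit_identical(self, batch, tmp_path):
        x, cov = batch
        model = ts.Model(make_spec("bigru", covariate_set=("donor",)), seed=5)
        before = model.predict(x, cov)
        path = save_model(model, tmp_path / "m.npz")
        reloaded = load_model(path)
        np.testing.assert_array_equal(reloaded.predict(x, cov), before)
        assert reloaded.spec == model.spec

    def test_spec_yaml_round_trip(self):
        spec = make_spec("inception", covariate_set=("donor", "nc"),
                         dense_widths=(32, 16))
        assert ts.ModelSpec.from_dict(spec.to_dict()) == spec
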