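"""Network assembly: shapes, determinism, parameter audit, checkpoints."""

import numpy as np
import pytest

from seizcos.checkpoint import load_model, save_model
from seizcos.nn.layers import ShapeError
from seizcos.nn.network import (
    HTSCCConfig,
    MCCConfig,
    ModelConfig,
    build_htscc,
    build_mcc,
    build_model,
    count_parameters,
)


def tiny_config(**kw):
    base = dict(
        n_channels=4, n_samples=128,
        mcc=MCCConfig(branch_kernel_lengths=(9, 5, 1), filters_per_branch=8,
                      pool_size=4, pool_stride=4),
        n_htscc_modules=2,
        htscc=HTSCCConfig(channels=8),
        fc_hidden=16, dtype="float64", seed=3,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestBuildMcc:
    def test_default_has_three_branches_of_32_channels(self):
        mcc = build_mcc(MCCConfig(), n_electrodes=18, n_samples=1024)
        assert len(mcc.branches) == 3
        x = np.random.default_rng(0).normal(size=(2, 1, 18, 1024)).astype("float32")
        out = mcc.forward(x)
        assert out.shape[1] == 32  # filters per branch survive the time concat
        assert out.shape[3] == sum(mcc.branch_widths)
        # each branch's pooled time axis is ~85 bins
        assert all(80 <= w <= 90 for w in mcc.branch_widths)

    def test_single_branch_concat_is_identity(self, rng):
        mcc = build_mcc(MCCConfig(branch_kernel_lengths=(9,), filters_per_branch=4,
                                  pool_size=4, pool_stride=4),
                        n_electrodes=3, n_samples=64, dtype="float64")
        x = rng.normal(size=(2, 1, 3, 64))
        out = mcc.forward(x)
        np.testing.assert_array_equal(out, mcc.branches[0].forward(x))

    def test_eval_forward_is_deterministic(self, rng):
        mcc = build_mcc(MCCConfig(filters_per_branch=4, pool_size=4,
                                  pool_stride=4), 3, 256, dtype="float64")
        x = rng.normal(size=(2, 1, 3, 256))
        np.testing.assert_array_equal(mcc.forward(x), mcc.forward(x))


class TestBuildHtscc:
    def test_add_merge_requires_equal_stream_shapes(self, rng):
        # both streams map to cfg.channels, so shapes only diverge if a
        # stream is altered; the runtime guard must still catch that
        blk = build_htscc(HTSCCConfig(channels=8, merge="add"), in_channels=4,
                          dtype="float64")
        from seizcos.nn.layers import CosineConv, Sequential

        blk.shallow = Sequential([CosineConv(4, 6, 3, padding="same")])
        with pytest.raises(ShapeError):
            blk.forward(rng.normal(size=(1, 4, 1, 32)))

    def test_add_merge_works_with_matching_channels(self, rng):
        blk = build_htscc(HTSCCConfig(channels=8, merge="add"), in_channels=8,
                          dtype="float64")
        out = blk.forward(rng.normal(size=(1, 8, 1, 32)))
        assert out.shape == (1, 8, 1, 32)

    def test_deep_stream_cosine_parameter_count(self):
        cfg = HTSCCConfig(channels=8, deep_layers=2)
        blk = build_htscc(cfg, in_channels=8)
        conv_params = sum(
            m.n_params() for m in blk.deep.layers if m.family == "cosine")
        # 2 scalars per (out, in) slot, summed over both layers
        assert conv_params == 2 * (8 * 8) * 2

    def test_eval_forward_deterministic(self, rng):
        blk = build_htscc(HTSCCConfig(channels=4), in_channels=4, dtype="float64")
        x = rng.normal(size=(2, 4, 1, 40))
        np.testing.assert_array_equal(blk.forward(x), blk.forward(x))


class TestBuildModel:
    def test_output_probabilities_sum_to_one(self, rng):
        net = build_model(tiny_config())
        p = net.forward(rng.normal(size=(3, 4, 128)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (3, 2)

    def test_zero_htscc_modules_supported(self, rng):
        net = build_model(tiny_config(n_htscc_modules=0))
        p = net.forward(rng.normal(size=(2, 4, 128)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("n_branches", [1, 2, 3, 4, 5])
    def test_branch_count_variants_build_and_run(self, n_branches, rng):
        """Architecture variants across the branch-count ablation axis."""
        kernels = tuple([9, 5, 1, 9, 5][:n_branches])
        cfg = ModelConfig(
            mcc=MCCConfig(branch_kernel_lengths=kernels, filters_per_branch=4,
                          pool_size=12, pool_stride=12),
            htscc=HTSCCConfig(channels=4), fc_hidden=8, dtype="float32")
        net = build_model(cfg)
        p = net.forward(rng.normal(size=(1, 18, 1024)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_wrong_input_shape_rejected(self, rng):
        net = build_model(tiny_config())
        with pytest.raises(ShapeError):
            net.forward(rng.normal(size=(1, 5, 128)))


class TestParameterAudit:
    def test_toy_cosine_conv_counts_two(self):
        from seizcos.nn.layers import CosineConv

        assert CosineConv(1, 1, 9).n_params() == 2

    def test_total_equals_sum_of_breakdown(self):
        net = build_model(tiny_config())
        total, breakdown = count_parameters(net)
        assert total == sum(c for _, _, c in breakdown)
        assert total == net.n_params()

    def test_family_swap_law(self):
        """params(standard) - params(cosine) = sum (k-2)*slots over swapped
        temporal layers, for randomized architectures."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            kernels = tuple(int(k) for k in rng.integers(1, 12, rng.integers(1, 4)))
            f = int(rng.integers(2, 9))
            hk = int(rng.integers(1, 6))
            hc = int(rng.integers(2, 9))
            nh = int(rng.integers(0, 3))
            cfg = tiny_config(
                mcc=MCCConfig(branch_kernel_lengths=kernels, filters_per_branch=f,
                              pool_size=4, pool_stride=4),
                htscc=HTSCCConfig(kernel_length=hk, channels=hc),
                n_htscc_modules=nh)
            cos_total, cos_bd = count_parameters(build_model(cfg))
            std_total, std_bd = count_parameters(
                build_model(cfg.with_family("standard")))

            expected = sum((k - 2) * f for k in kernels)  # MCC temporal convs
            ch_in = f
            for _ in range(nh):
                # shallow (ch_in->hc) + deep (ch_in->hc, hc->hc), all k=hk
                expected += (hk - 2) * (2 * ch_in * hc + hc * hc)
                ch_in = 2 * hc
            assert std_total - cos_total == expected

            # swap changes only cosine-family layers, slot-for-slot
            for (n1, f1, c1), (n2, f2, c2) in zip(cos_bd, std_bd):
                if f1 == "cosine":
                    assert f2 == "standard"
                else:
                    assert c1 == c2

    def test_branch_permutation_preserves_total(self):
        a = count_parameters(build_model(tiny_config(
            mcc=MCCConfig((9, 5, 1), 4, pool_size=4, pool_stride=4))))[0]
        b = count_parameters(build_model(tiny_config(
            mcc=MCCConfig((1, 9, 5), 4, pool_size=4, pool_stride=4))))[0]
        assert a == b

    def test_default_cosine_model_is_smaller_than_standard(self):
        cos = count_parameters(build_model(ModelConfig()))[0]
        std = count_parameters(build_model(ModelConfig(conv_family="standard")))[0]
        assert std > cos


class TestCheckpoint:
    def test_round_trip_preserves_forward(self, tmp_path, rng):
        net = build_model(tiny_config())
        x = rng.normal(size=(2, 4, 128))
        # perturb running stats so the buffers matter
        net.forward_logits(x, training=True, rng=rng)
        before = net.forward(x)
        save_model(net, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.forward(x), before)
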