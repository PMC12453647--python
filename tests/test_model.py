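"""Architecture blocks: dilated convolution against a nested-sum oracle,
attention contracts, residual identities, shapes, and parameter accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepsisnet.model import (
    ECLF,
    HDCB,
    RPCC,
    SCAN,
    BatchNormParams,
    ModelConfig,
    batch_norm,
    build_model,
    count_parameters,
    dilated_conv,
    tensorize_windows,
)
from sepsisnet.nn.autodiff import Tensor
from sepsisnet.preprocessing import NumericCohort, NumericPatient


def brute_force_dilated(x, kernel, d):
    """Direct nested-sum evaluation of Y[i,j,k] = sum X[i+m d, j+n d, k] W[m,n,k]."""
    H, W, C = x.shape
    kh, kw, _ = kernel.shape
    Hout, Wout = H - (kh - 1) * d, W - (kw - 1) * d
    out = np.zeros((Hout, Wout, C))
    for i in range(Hout):
        for j in range(Wout):
            for k in range(C):
                acc = 0.0
                for m in range(kh):
                    for n in range(kw):
                        acc += x[i + m * d, j + n * d, k] * kernel[m, n, k]
                out[i, j, k] = acc
    return out


class TestDilatedConv:
    def test_identity_kernel_returns_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 5, 2))
        kernel = np.zeros((3, 3, 2))
        kernel[1, 1, :] = 1.0
        np.testing.assert_allclose(dilated_conv(x, kernel, 1, "same"), x, atol=1e-12)

    @pytest.mark.parametrize("d", [1, 2])
    def test_matches_brute_force_6x6(self, d):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 6, 2))
        kernel = rng.normal(size=(3, 3, 2))
        np.testing.assert_allclose(
            dilated_conv(x, kernel, d), brute_force_dilated(x, kernel, d), rtol=1e-6
        )

    def test_oracle_equivalence_100_random_instances(self):
        """100 random instances up to 8x8x3, dilations 1-3, vs the nested sum."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            d = int(rng.integers(1, 4))
            k = int(rng.choice([1, 3]))
            H = int(rng.integers((k - 1) * d + 1, 9))
            W = int(rng.integers((k - 1) * d + 1, 9))
            C = int(rng.integers(1, 4))
            x = rng.normal(size=(H, W, C))
            kernel = rng.normal(size=(k, k, C))
            got = dilated_conv(x, kernel, d)
            want = brute_force_dilated(x, kernel, d)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_impulse_taps_spaced_by_dilation(self):
        x = np.zeros((7, 7, 1))
        x[3, 3, 0] = 1.0
        kernel = np.ones((3, 3, 1))
        out = dilated_conv(x, kernel, 2, "same")
        nz = np.argwhere(out[:, :, 0] != 0)
        # nonzero responses sit on the dilation-2 lattice around the impulse
        assert set(map(tuple, nz)) == {(i, j) for i in (1, 3, 5) for j in (1, 3, 5)}


class TestBatchNorm:
    def test_zero_mean_unit_sd_paper_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 3))
        x = (x - x.mean(0)) / x.std(0)
        out = batch_norm(x, BatchNormParams(eps=1e-5))
        np.testing.assert_allclose(out, x / (1 + 1e-5), atol=1e-9)

    def test_gamma_zero_gives_constant_beta(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 2))
        out = batch_norm(x, BatchNormParams(gamma=0.0, beta=2.5))
        np.testing.assert_allclose(out, 2.5)

    def test_forms_agree_when_sd_dominates_eps(self):
        rng = np.random.default_rng(4)
        x = rng.normal(scale=5.0, size=(500, 2))
        paper = batch_norm(x, BatchNormParams(eps=1e-5, form="paper"))
        variance = batch_norm(x, BatchNormParams(eps=1e-5, form="variance"))
        np.testing.assert_allclose(paper, variance, atol=1e-3)


def _numeric_patient(pid, n, F, labels=None):
    values = np.arange(n * F, dtype=float).reshape(n, F)
    return NumericPatient(
        patient_id=pid,
        times=np.arange(n, dtype=float),
        values=values,
        labels=np.zeros(n, int) if labels is None else np.asarray(labels),
    )


class TestTensorizeWindows:
    def test_early_timesteps_zero_padded(self):
        cohort = NumericCohort(["f0", "f1"], [_numeric_patient("A", 3, 2)])
        data = tensorize_windows(cohort, window_length=8)
        assert data.X.shape == (3, 8, 2, 1)
        np.testing.assert_array_equal(data.X[0, :7], 0.0)
        np.testing.assert_array_equal(data.X[0, 7, :, 0], [0.0, 1.0])

    def test_sample_count_equals_timestep_count(self, small_sim_cohort):
        from sepsisnet.preprocessing import fit, transform

        numeric = transform(small_sim_cohort, fit(small_sim_cohort))
        data = tensorize_windows(numeric, 8)
        assert len(data) == small_sim_cohort.n_timesteps

    def test_window_contains_rows_t_minus_T_plus_1_to_t(self):
        F, T = 3, 4
        cohort = NumericCohort([f"f{i}" for i in range(F)],
                               [_numeric_patient("A", 10, F)])
        data = tensorize_windows(cohort, T)
        V = cohort.patients[0].values
        for t in range(10):
            window = data.X[t, :, :, 0]
            expected = np.vstack(
                [np.zeros((max(T - 1 - t, 0), F)), V[max(t - T + 1, 0) : t + 1]]
            )
            np.testing.assert_array_equal(window, expected)

    def test_labels_come_from_final_hour(self):
        cohort = NumericCohort(
            ["f0"],
            [NumericPatient("A", np.arange(4.0), np.zeros((4, 1)),
                            np.array([0, 0, 1, 1]))],
        )
        data = tensorize_windows(cohort, 2)
        np.testing.assert_array_equal(data.y, [0, 0, 1, 1])

    def test_window_below_two_rejected(self):
        cohort = NumericCohort(["f0"], [_numeric_patient("A", 3, 1)])
        with pytest.raises(ValueError):
            tensorize_windows(cohort, 1)


class TestECLF:
    def test_default_shape_8x44(self):
        config = ModelConfig(n_features=44)
        block = ECLF(1, config, np.random.default_rng(0))
        out = block(Tensor(np.random.default_rng(1).normal(size=(2, 8, 44, 1))))
        assert out.shape == (2, 4, 22, 192)

    def test_zero_input_zero_biases_gives_zero(self):
        config = ModelConfig(n_features=10).compact()
        block = ECLF(1, config, np.random.default_rng(0))
        block.entry.bias.data[:] = 0
        for branch in block.branches:
            branch.bias.data[:] = 0
        out = block(Tensor(np.zeros((2, 8, 10, 1))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_branch_permutation_permutes_channel_blocks(self):
        """Swapping two branch weight sets swaps the corresponding channel
        blocks of the output (concatenation order is K1, K2, K3)."""
        config = ModelConfig(n_features=12, branch_kernels=(3, 3, 3)).compact()
        rng = np.random.default_rng(5)
        x = Tensor(rng.normal(size=(1, 8, 12, 1)).astype(np.float32))
        block = ECLF(1, config, np.random.default_rng(0))
        block.eval()
        base = block(x).data.copy()
        nb = config.branch_filters
        w0 = block.branches[0].weight.data.copy()
        b0 = block.branches[0].bias.data.copy()
        block.branches[0].weight.data = block.branches[1].weight.data.copy()
        block.branches[0].bias.data = block.branches[1].bias.data.copy()
        block.branches[1].weight.data = w0
        block.branches[1].bias.data = b0
        # also swap the BN statistics blocks so normalization follows channels
        for arr in (block.out_bn.gamma.data, block.out_bn.beta.data,
                    block.out_bn.running_mean, block.out_bn.running_std):
            tmp = arr[:nb].copy()
            arr[:nb] = arr[nb : 2 * nb]
            arr[nb : 2 * nb] = tmp
        swapped = block(x).data
        np.testing.assert_allclose(swapped[..., :nb], base[..., nb : 2 * nb], atol=1e-6)
        np.testing.assert_allclose(swapped[..., nb : 2 * nb], base[..., :nb], atol=1e-6)


class TestAttention:
    def _scan(self, channels=8, seed=0):
        config = ModelConfig(n_features=12, channel_bottleneck=8)
        return SCAN(channels, config, np.random.default_rng(seed))

    def test_spatial_map_strictly_in_unit_interval(self):
        scan = self._scan()
        x = Tensor(np.random.default_rng(1).normal(size=(2, 5, 6, 8)))
        scan(x)
        assert np.all(scan.spatial.last_map > 0)
        assert np.all(scan.spatial.last_map < 1)
        assert scan.spatial.last_map.shape == (2, 5, 6, 1)

    def test_spatial_ratio_constant_across_channels(self):
        scan = self._scan()
        x_data = np.random.default_rng(2).normal(size=(1, 4, 4, 8)) + 5.0
        out = scan.spatial(Tensor(x_data))
        ratio = out.data / x_data
        np.testing.assert_allclose(
            ratio, np.broadcast_to(ratio[..., :1], ratio.shape), atol=1e-6
        )

    def test_zeroed_weights_closed_form(self):
        """With all conv weights zero and bias b, A = sigmoid(b) everywhere."""
        scan = self._scan()
        b = 0.7
        scan.spatial.reduce.weight.data[:] = 0
        scan.spatial.reduce.bias.data[:] = 0
        scan.spatial.spatial.weight.data[:] = 0
        scan.spatial.spatial.bias.data[:] = b
        x_data = np.random.default_rng(3).normal(size=(1, 4, 4, 8))
        out = scan.spatial(Tensor(x_data))
        sig_b = 1 / (1 + np.exp(-b))
        np.testing.assert_allclose(scan.spatial.last_map, sig_b, atol=1e-6)
        np.testing.assert_allclose(out.data, sig_b * x_data, atol=1e-6)

    def test_channel_pooled_descriptor_is_mean(self):
        scan = self._scan()
        rng = np.random.default_rng(4)
        x_data = rng.normal(size=(1, 4, 4, 8))
        pooled = Tensor(x_data).mean(axis=(1, 2)).data
        # brute-force double-loop mean per channel
        brute = np.zeros((1, 8))
        for i in range(4):
            for j in range(4):
                brute[0] += x_data[0, i, j]
        brute /= 16
        np.testing.assert_allclose(pooled, brute, atol=1e-6)

    def test_constant_channel_pools_to_constant(self):
        x_data = np.full((1, 3, 5, 2), 0.0)
        x_data[..., 0] = 3.25
        x_data[..., 1] = -1.5
        pooled = Tensor(x_data).mean(axis=(1, 2)).data
        np.testing.assert_array_equal(pooled, [[3.25, -1.5]])

    def test_channel_weights_in_unit_interval(self):
        scan = self._scan()
        x = Tensor(np.random.default_rng(5).normal(size=(3, 4, 4, 8)))
        scan(x)
        assert np.all(scan.channel.last_weights > 0)
        assert np.all(scan.channel.last_weights < 1)

    def test_scan_equals_sequential_composition(self):
        scan = self._scan()
        x = Tensor(np.random.default_rng(6).normal(size=(2, 4, 4, 8)))
        composed = scan(x).data
        sequential = scan.channel(scan.spatial(x)).data
        np.testing.assert_allclose(composed, sequential, atol=1e-12)

    def test_scan_never_increases_magnitude(self):
        scan = self._scan()
        x_data = np.random.default_rng(7).normal(size=(2, 4, 4, 8))
        out = scan(Tensor(x_data)).data
        assert np.all(np.abs(out) <= np.abs(x_data) + 1e-12)


class TestHDCB:
    def test_concat_fusion_output_channels(self):
        for cin in (3, 8, 24):
            config = ModelConfig(n_features=12).compact()
            block = HDCB(cin, config, np.random.default_rng(0))
            out = block(Tensor(np.random.default_rng(1).normal(size=(1, 4, 6, cin))))
            assert out.shape == (1, 4, 6, config.fusion_filters)

    def test_spatial_dims_preserved(self):
        config = ModelConfig(n_features=12).compact()
        block = HDCB(5, config, np.random.default_rng(0))
        out = block(Tensor(np.random.default_rng(2).normal(size=(3, 7, 9, 5))))
        assert out.shape[:3] == (3, 7, 9)

    def test_sum_fusion_with_shared_weights_is_three_times_one_branch(self):
        config = ModelConfig(
            n_features=12, hdcb_fusion="sum", hdcb_dilations=(1, 1, 1)
        ).compact()
        block = HDCB(4, config, np.random.default_rng(0))
        for branch in block.branches[1:]:
            branch.weight.data = block.branches[0].weight.data.copy()
            branch.bias.data = block.branches[0].bias.data.copy()
        x = Tensor(np.random.default_rng(3).normal(size=(1, 5, 5, 4)).astype(np.float32))
        single = block.branches[0](x).data
        outs = [branch(x) for branch in block.branches]
        fused = (outs[0] + outs[1] + outs[2]).data
        np.testing.assert_allclose(fused, 3 * single, rtol=1e-5, atol=1e-5)


class TestRPCC:
    def _block(self, channels=6):
        config = ModelConfig(n_features=12, rpcc_filters=channels, rpcc_blocks=1)
        return RPCC(channels, config, np.random.default_rng(0))

    def test_zero_residual_function_is_identity(self):
        rpcc = self._block()
        rpcc.blocks[0].fn = lambda t: Tensor(np.zeros(t.shape))
        x = np.random.default_rng(1).normal(size=(2, 4, 4, 6))
        np.testing.assert_array_equal(rpcc(Tensor(x)).data, x)

    def test_stub_residual_adds_exactly(self):
        rpcc = self._block()
        r = np.random.default_rng(2).normal(size=(2, 4, 4, 6))
        rpcc.blocks[0].fn = lambda t: Tensor(r)
        x = np.random.default_rng(3).normal(size=(2, 4, 4, 6))
        np.testing.assert_allclose(rpcc(Tensor(x)).data, x + r, atol=1e-12)

    def test_two_block_recursion_composes(self):
        config = ModelConfig(n_features=12, rpcc_filters=6, rpcc_blocks=2)
        rpcc = RPCC(6, config, np.random.default_rng(0))

        def f1(t):
            return Tensor(0.5 * np.asarray(t.data))

        def f2(t):
            return Tensor(np.asarray(t.data) ** 0 * 2.0)  # constant 2

        rpcc.blocks[0].fn = f1
        rpcc.blocks[1].fn = f2
        x = np.random.default_rng(4).normal(size=(1, 3, 3, 6))
        # X1 = X + 0.5X = 1.5X; X2 = X1 + 2
        np.testing.assert_allclose(rpcc(Tensor(x)).data, 1.5 * x + 2.0, atol=1e-12)

    def test_projection_added_when_channels_differ(self):
        config = ModelConfig(n_features=12, rpcc_filters=8, rpcc_blocks=1)
        rpcc = RPCC(3, config, np.random.default_rng(0))
        out = rpcc(Tensor(np.random.default_rng(5).normal(size=(1, 4, 4, 3))))
        assert out.shape == (1, 4, 4, 8)


def _expected_parameter_count(c: ModelConfig) -> int:
    """Independent layer-by-layer sum for the default full-width model."""
    def conv(k, cin, cout):
        return k * k * cin * cout + cout

    def bn(ch):
        return 2 * ch

    total = 0
    total += conv(3, 1, c.entry_filters) + bn(c.entry_filters)
    for k in c.branch_kernels:
        total += conv(k, c.entry_filters, c.branch_filters)
    eclf_out = 3 * c.branch_filters
    total += bn(eclf_out)
    reduced = max(eclf_out // 8, 1)
    total += conv(1, eclf_out, reduced) + conv(c.spatial_kernel, reduced, 1)
    total += eclf_out * c.channel_bottleneck + c.channel_bottleneck
    total += c.channel_bottleneck * eclf_out + eclf_out
    for _ in c.hdcb_dilations:
        total += conv(3, eclf_out, c.hdcb_filters)
    total += conv(1, c.hdcb_filters * 3, c.fusion_filters) + bn(c.fusion_filters)
    if c.fusion_filters != c.rpcc_filters:
        total += conv(1, c.fusion_filters, c.rpcc_filters)
    for _ in range(c.rpcc_blocks):
        total += 2 * conv(3, c.rpcc_filters, c.rpcc_filters) + bn(c.rpcc_filters)
    units_in = c.rpcc_filters
    for units in c.dense_units:
        total += units_in * units + units
        units_in = units
    total += units_in * 1 + 1
    return total


class TestFullModel:
    def test_probabilities_strictly_in_unit_interval(self):
        config = ModelConfig(n_features=10).compact()
        model = build_model(config)
        x = np.random.default_rng(0).normal(size=(4, 8, 10, 1)).astype(np.float32)
        p = model.predict_proba(x)
        assert np.all(p > 0) and np.all(p < 1)

    def test_eval_forward_bit_identical(self):
        config = ModelConfig(n_features=10).compact()
        model = build_model(config)
        x = np.random.default_rng(1).normal(size=(4, 8, 10, 1)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_parameter_count_matches_layer_sum(self):
        config = ModelConfig(n_features=44)
        model = build_model(config)
        assert count_parameters(model) == _expected_parameter_count(config)

    def test_parameter_count_compact_matches_layer_sum(self):
        config = ModelConfig(n_features=14).compact()
        model = build_model(config)
        assert count_parameters(model) == _expected_parameter_count(config)

    def test_shape_mismatch_rejected(self):
        model = build_model(ModelConfig(n_features=10).compact())
        with pytest.raises(ValueError, match="incompatible"):
            model.predict_proba(np.zeros((2, 8, 11, 1), dtype=np.float32))

    @given(T=st.integers(4, 16), F=st.integers(8, 64))
    @settings(max_examples=12, deadline=None)
    def test_well_formed_across_window_and_feature_sizes(self, T, F):
        config = ModelConfig(n_features=F, window_length=T).compact()
        model = build_model(config)
        x = np.zeros((2, T, F, 1), dtype=np.float32)
        p = model.predict_proba(x)
        assert p.shape == (2,) and np.all((p > 0) & (p < 1))

    def test_seeded_builds_identical(self):
        a = build_model(ModelConfig(n_features=10, seed=3).compact())
        b = build_model(ModelConfig(n_features=10, seed=3).compact())
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
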