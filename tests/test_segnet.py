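"""Architecture contracts: shapes, gating bounds, scan causality, ablations."""

import numpy as np
import pytest

from fxcallus.nn import Tensor
from fxcallus.segnet import (
    EFDM,
    SS2D,
    NetworkConfig,
    TripletAttention,
    VMTEUNet,
    VSSTABlock,
    build_target_pyramid,
)


class TestTripletAttention:
    def test_shape_preserved(self, rng):
        ta = TripletAttention(3, rng)
        x = Tensor(rng.normal(size=(2, 5, 6, 7)))
        assert ta(x).shape == x.shape

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            TripletAttention(4, rng)

    def test_zero_input_gives_zero(self, rng):
        ta = TripletAttention(3, rng)
        out = ta(Tensor(np.zeros((1, 4, 5, 5))))
        assert np.array_equal(out.data, np.zeros((1, 4, 5, 5)))

    def test_per_branch_gate_bound(self, rng):
        """Each branch output is elementwise bounded by |x| (gate in (0,1))."""
        ta = TripletAttention(3, rng)
        for _ in range(100):
            x = Tensor(rng.normal(size=(1, 4, 6, 6)))
            for branch in ta.branch_outputs(x):
                assert np.all(np.abs(branch.data) <= np.abs(x.data) + 1e-12)


class TestSS2D:
    @pytest.mark.parametrize("hw", [(8, 8), (16, 12)])
    def test_shape_preserved(self, rng, hw):
        ss = SS2D(4, 2, rng)
        x = Tensor(rng.normal(size=(2, 4, *hw)))
        assert ss(x).shape == x.shape

    def test_closed_input_gate_gives_constant_bias_response(self, rng):
        """Zeroing the input projection closes the recurrence: the output is a
        bias-only response independent of the input."""
        ss = SS2D(4, 2, rng)
        ss.in_proj.weight.data[...] = 0.0
        ss.in_proj.bias.data[...] = 0.0
        y1 = ss(Tensor(rng.normal(size=(1, 4, 6, 6)))).data
        y2 = ss(Tensor(rng.normal(size=(1, 4, 6, 6)) * 10)).data
        assert np.array_equal(y1, y2)
        assert np.allclose(y1, y1[..., :1, :1])  # spatially constant

    def test_scan_causality_per_direction(self, rng):
        """A single-pixel impulse only influences positions at or after it in
        each direction's scan order (traced on a 4x4 grid)."""
        ss = SS2D(1, 2, rng)
        x = np.zeros((1, 1, 4, 4))
        x[0, 0, 1, 2] = 1.0
        dirs = ss.scan_directions(Tensor(x))
        base = ss.scan_directions(Tensor(np.zeros((1, 1, 4, 4))))
        p_row = 1 * 4 + 2  # row-major flat index
        p_col = 2 * 4 + 1  # column-major flat index
        for k, (d, b) in enumerate(zip(dirs, base)):
            diff = np.abs(d.data - b.data)[0, 0]
            flat = diff.ravel() if k in (0, 2) else diff.T.ravel()
            p = p_row if k in (0, 2) else p_col
            if k < 2:  # forward scans: nothing before the impulse
                assert np.all(flat[:p] == 0.0) and flat[p] != 0.0
            else:  # reversed scans: nothing after it
                assert np.all(flat[p + 1:] == 0.0) and flat[p] != 0.0


class TestVSSTABlock:
    def test_shape_and_residual(self, rng, tiny_net_config):
        block = VSSTABlock(4, tiny_net_config, rng)
        x = Tensor(rng.normal(size=(2, 4, 8, 8)))
        assert block(x).shape == x.shape

    def test_attention_flag_removes_attention(self, rng, tiny_net_config):
        from dataclasses import replace

        plain = VSSTABlock(4, replace(tiny_net_config, use_triplet_attention=False), rng)
        assert plain.attn is None

    def test_gradient_reaches_every_parameter(self, rng, tiny_net_config):
        block = VSSTABlock(4, tiny_net_config, rng)
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        (block(x) ** 2).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestEFDM:
    def test_emitted_maps_shapes(self, rng, tiny_net_config):
        efdm = EFDM(4, tiny_net_config, rng)
        x = Tensor(rng.normal(size=(2, 4, 8, 8)))
        edge, y_n, y_t, refined = efdm(x)
        assert edge.shape == (2, 8, 8) and y_n.shape == (2, 8, 8) and y_t.shape == (2, 8, 8)
        assert refined.shape == x.shape

    def test_disabled_branches_emit_none(self, rng, tiny_net_config):
        from dataclasses import replace

        cfg = replace(tiny_net_config, use_nsm=False, use_tpm=False)
        efdm = EFDM(4, cfg, rng)
        edge, y_n, y_t, refined = efdm(Tensor(rng.normal(size=(1, 4, 8, 8))))
        assert edge is not None and y_n is None and y_t is None

    def test_refine_flag_isolated(self, rng, tiny_net_config):
        from dataclasses import replace

        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        frozen = EFDM(4, replace(tiny_net_config, efdm_refine=False), rng)
        _, _, _, refined = frozen(x)
        assert np.array_equal(refined.data, x.data)


class TestNetwork:
    def test_forward_shapes_and_stage_count(self, rng):
        cfg = NetworkConfig(stage_dims=(4, 8, 16, 32), encoder_depths=(1, 1, 1, 1),
                            state_dim=2, ta_kernel=3, seed=0)
        net = VMTEUNet(cfg)
        out = net.forward(rng.normal(size=(1, 1, 64, 64)))
        assert out.seg_logits.shape == (1, 2, 64, 64)
        assert out.seg_prob.shape == (1, 64, 64)
        assert len(out.aux) == 3  # one EFDM triple per decoder hidden layer

    def test_indivisible_input_errors_with_required_multiple(self, tiny_net_config):
        net = VMTEUNet(tiny_net_config)
        with pytest.raises(ValueError, match="multiple of 4"):
            net.forward(np.zeros((1, 1, 63, 63)))

    def test_inference_determinism(self, rng, tiny_net_config):
        net = VMTEUNet(tiny_net_config)
        x = rng.normal(size=(1, 1, 8, 8))
        assert np.array_equal(net.forward(x).seg_logits.data, net.forward(x).seg_logits.data)

    def test_finite_outputs_across_random_configs(self, rng):
        """Forward maps stay finite over randomized small configurations."""
        for i in range(100):
            cfg = NetworkConfig(
                stage_dims=(int(rng.integers(2, 6)), int(rng.integers(4, 10))),
                encoder_depths=(1, int(rng.integers(1, 3))),
                patch_size=2,
                state_dim=int(rng.integers(1, 4)),
                ta_kernel=int(rng.choice([3, 5])),
                egm_atrous_rates=(1, int(rng.integers(2, 4))),
                use_egm=bool(rng.integers(0, 2)),
                use_nsm=bool(rng.integers(0, 2)),
                use_tpm=bool(rng.integers(0, 2)),
                use_triplet_attention=bool(rng.integers(0, 2)),
                seed=i,
            )
            out = VMTEUNet(cfg).forward(rng.normal(size=(1, 1, 8, 8)) * 10)
            assert np.all(np.isfinite(out.seg_logits.data))
            for triple in out.aux:
                for m in triple:
                    assert m is None or np.all(np.isfinite(m.data))

    def test_ablation_lattice(self, tiny_net_config):
        """Config flags materialize the branch lattice; the full model has
        strictly more parameters than every ablated variant."""
        variants = tiny_net_config.ablation_variants()
        assert set(variants) == {"vm_ta_unet", "egm", "egm_nsm", "vm_te_unet"}
        nets = {name: VMTEUNet(cfg) for name, cfg in variants.items()}
        x = np.zeros((1, 1, 8, 8))
        outs = {name: net.forward(x) for name, net in nets.items()}
        # branch presence pattern per variant
        assert all(t == (None, None, None) for t in outs["vm_ta_unet"].aux)
        assert all(t[0] is not None and t[1] is None and t[2] is None for t in outs["egm"].aux)
        assert all(t[0] is not None and t[1] is not None and t[2] is None for t in outs["egm_nsm"].aux)
        assert all(all(m is not None for m in t) for t in outs["vm_te_unet"].aux)
        full = nets["vm_te_unet"].num_parameters()
        for name in ("vm_ta_unet", "egm", "egm_nsm"):
            assert nets[name].num_parameters() < full

    def test_vm_unet_equivalent_baseline(self, tiny_net_config):
        cfg = tiny_net_config.vm_unet_equivalent()
        net = VMTEUNet(cfg)
        assert net.efdms == []
        assert all(b.attn is None for stage in net.enc_stages for b in stage)

    def test_full_gradient_flow_one_step(self, rng, tiny_net_config):
        """A single training step sends gradient into every parameter."""
        from fxcallus.losses import total_loss

        net = VMTEUNet(tiny_net_config)
        x = rng.normal(size=(2, 1, 8, 8))
        out = net.forward(x)
        roi = (rng.random((2, 8, 8)) > 0.5).astype(float)
        tgt = build_target_pyramid(roi, roi, rng.random((2, 8, 8)), rng.random((2, 8, 8)),
                                   tiny_net_config)
        loss, _ = total_loss(out, tgt)
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng, tiny_net_config):
        from fxcallus.segnet import load_checkpoint, save_checkpoint

        net = VMTEUNet(tiny_net_config)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        net2 = load_checkpoint(path)
        x = rng.normal(size=(1, 1, 8, 8))
        assert np.array_equal(net.forward(x).seg_logits.data, net2.forward(x).seg_logits.data)
        assert net2.cfg == tiny_net_config
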