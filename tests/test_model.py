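"""Architecture contracts: embeddings, encodings, gating, masking, pooling."""

import numpy as np
import pytest

from ricesits import autodiff as ad
from ricesits.autodiff import Tensor
from ricesits.model import (ARCHITECTURE_PRESETS, ChannelAttention,
                            ModelConfig, PhenologyGate, PositionalEncoding,
                            SITSFormer, SpatioSpectralEmbed,
                            TemporalMeanLogistic, config_for_preset,
                            fixed_sinusoidal_encoding)

DOYS = np.arange(152, 305, 5)
T = len(DOYS)


def small_config(**kw):
    base = dict(n_channels=5, d_model=16, n_heads=4, n_layers=2, d_ff=32,
                dropout=0.1, d_branch=8, branch_hidden=8, gate_hidden=8,
                head_hidden=8)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture
def batch(rng):
    x = rng.normal(size=(4, T, 5)).astype(np.float32)
    mask = np.ones((4, T), dtype=np.float32)
    mask[1, 20:] = 0
    return x, mask


class TestForwardContracts:
    def test_probabilities_normalised(self, batch):
        x, mask = batch
        m = SITSFormer(small_config(), seed=0)
        p = m.predict_proba(x, DOYS, mask)
        assert p.shape == (4, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, batch):
        x, mask = batch
        m = SITSFormer(small_config(), seed=0)
        a = m.predict_proba(x, DOYS, mask)
        b = m.predict_proba(x, DOYS, mask)
        assert np.array_equal(a, b)

    def test_masking_equivalent_to_removal(self, float64_autodiff, rng):
        x = rng.normal(size=(1, T, 5))
        keep = np.ones(T, bool)
        keep[[3, 10, 25]] = False
        m = SITSFormer(small_config(dropout=0.0), seed=0)
        m.eval()
        with ad.no_grad():
            masked = m.forward(x, DOYS, keep[None, :].astype(float)).data
            removed = m.forward(x[:, keep], DOYS[keep],
                                np.ones((1, keep.sum()))).data
        assert np.allclose(masked, removed, atol=1e-10)

    def test_padding_never_changes_outputs(self, float64_autodiff, rng):
        x = rng.normal(size=(1, T, 5))
        m = SITSFormer(small_config(dropout=0.0), seed=0)
        m.eval()
        with ad.no_grad():
            base = m.forward(x, DOYS, np.ones((1, T))).data
            xpad = np.concatenate([x, rng.normal(size=(1, 3, 5))], axis=1)
            dpad = np.r_[DOYS, [306, 311, 316]]
            mpad = np.concatenate([np.ones((1, T)), np.zeros((1, 3))], axis=1)
            padded = m.forward(xpad, dpad, mpad).data
        assert np.allclose(base, padded, atol=1e-10)

    def test_all_invalid_sample_rejected(self, batch):
        x, mask = batch
        mask[2] = 0
        m = SITSFormer(small_config(), seed=0)
        with pytest.raises(ValueError, match="no valid timestep"):
            m.forward(x, DOYS, mask)

    def test_channel_mismatch_rejected(self, rng):
        m = SITSFormer(small_config(), seed=0)
        with pytest.raises(ValueError, match="channels"):
            m.forward(rng.normal(size=(2, T, 7)), DOYS, np.ones((2, T)))

    def test_rice_probability_threshold(self, batch):
        x, mask = batch
        m = SITSFormer(small_config(), seed=0)
        p = m.predict_proba(x, DOYS, mask)
        assert np.array_equal(m.predict(x, DOYS, mask, threshold=0.5),
                              (p[:, 1] >= 0.5).astype(int))

    def test_parameter_count_reported(self):
        m = SITSFormer(ModelConfig(n_channels=9), seed=0)
        n = m.n_parameters()
        assert n == sum(p.data.size for p in m.parameters()) and n > 10_000


class TestPositionalEncoding:
    def test_function_of_doy_only(self):
        cfg = small_config()
        pe = PositionalEncoding(cfg, np.random.default_rng(0))
        a = pe(np.array([[160, 200, 280]])).data
        b = pe(np.array([[160, 200, 280, 280]])).data
        assert np.allclose(a, b[:, :3])
        assert np.allclose(a[0, 1], pe(np.array([[200]])).data[0, 0])

    def test_equal_doys_equal_encodings(self):
        pe = PositionalEncoding(small_config(), np.random.default_rng(0))
        enc = pe(np.array([[180, 180, 240]])).data
        assert np.allclose(enc[0, 0], enc[0, 1])
        assert not np.allclose(enc[0, 0], enc[0, 2])

    def test_stage_bins_default_edges(self):
        pe = PositionalEncoding(small_config(), np.random.default_rng(0))
        assert list(pe.stage_index(np.array([160, 220, 280]))) == [0, 1, 2]

    def test_doy_out_of_range_rejected(self):
        pe = PositionalEncoding(small_config(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            pe(np.array([[0, 100]]))

    def test_fixed_variant_parameter_free_sinusoid(self):
        cfg = small_config(positional="fixed")
        pe = PositionalEncoding(cfg, np.random.default_rng(0))
        assert len(list(pe.named_parameters())) == 0
        enc = pe(np.array([[200]])).data
        assert np.allclose(enc[0, 0],
                           fixed_sinusoidal_encoding(np.array([200]), 16)[0])


class TestChannelAttention:
    def test_weights_in_unit_interval(self, rng):
        ca = ChannelAttention(6, 2, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(3, 5, 6)).astype(np.float32))
        w = ca.weights(x, np.ones((3, 5))).data
        assert np.all((w > 0) & (w < 1))

    def test_zero_input_gives_half_weights(self):
        ca = ChannelAttention(6, 2, np.random.default_rng(0))
        for p in ca.parameters():
            p.data[:] = 0.0
        x = Tensor(np.zeros((2, 4, 6), dtype=np.float32))
        assert np.allclose(ca.weights(x, np.ones((2, 4))).data, 0.5)

    def test_identical_channels_identical_weights_at_symmetric_state(self):
        ca = ChannelAttention(4, 2, np.random.default_rng(0))
        # symmetric weight state: every channel treated identically
        ca.fc1.weight.data[:] = 0.3
        ca.fc1.bias.data[:] = 0.1
        ca.fc2.weight.data[:] = 0.2
        ca.fc2.bias.data[:] = 0.0
        x = Tensor(np.tile(np.linspace(0, 1, 5)[None, :, None],
                           (2, 1, 4)).astype(np.float32))
        w = ca.weights(x, np.ones((2, 5))).data
        assert np.allclose(w, w[:, :1])


class TestEmbeddings:
    def test_zero_input_bias_only_and_time_constant(self, float64_autodiff):
        m = SITSFormer(small_config(dropout=0.0), seed=0)
        x = Tensor(np.zeros((2, 6, 5)))
        out = m.embed(x, np.ones((2, 6))).data
        assert np.allclose(out, out[0, 0])  # identical across timesteps

    def test_interaction_branch_single_nonzero_channel(self):
        m = SITSFormer(small_config(), seed=0)
        x = np.zeros((1, 2, 5), dtype=np.float32)
        x[..., 2] = 3.0
        prods = m.embed.interactions(Tensor(x)).data
        nz = np.flatnonzero(np.abs(prods[0, 0]) > 0)
        pairs = list(zip(m.embed.idx_i, m.embed.idx_j))
        assert len(nz) == 1 and pairs[nz[0]] == (2, 2)
        assert prods[0, 0, nz[0]] == pytest.approx(9.0)

    def test_linear_embedding_preset(self):
        cfg = config_for_preset("original", n_channels=5, d_model=16,
                                n_heads=4, n_layers=1, d_ff=32,
                                head_hidden=8)
        m = SITSFormer(cfg, seed=0)
        assert type(m.embed).__name__ == "LinearEmbed"
        assert m.config.positional == "fixed" and not m.config.gate_enabled

    def test_architecture_presets_cover_ablation_axes(self):
        assert set(ARCHITECTURE_PRESETS) >= {
            "original", "+multiscale_embedding", "+adaptive_encoding",
            "+phenology_gate", "enhanced"}


class TestSpatioSpectralEmbed:
    CFG = dict(n_channels=5, d_model=16, n_heads=4, n_layers=1, d_ff=32,
               use_patch_branch=True, patch_size=3, conv_filters=4,
               head_hidden=8)

    def test_output_shape_and_time_distribution(self, rng):
        cfg = ModelConfig(**self.CFG)
        emb = SpatioSpectralEmbed(cfg, np.random.default_rng(0))
        patches = rng.uniform(size=(2, 3, 3, 4, 6)).astype(np.float32)
        out = emb(patches).data
        assert out.shape == (2, 6, 16)
        # permuting two timesteps permutes the embedding rows
        perm = patches[:, :, :, :, [1, 0, 2, 3, 4, 5]]
        out2 = emb(perm).data
        assert np.allclose(out[:, [1, 0, 2, 3, 4, 5]], out2, atol=1e-5)

    def test_zero_patch_bias_pathway(self):
        cfg = ModelConfig(**self.CFG)
        emb = SpatioSpectralEmbed(cfg, np.random.default_rng(0))
        out = emb(np.zeros((1, 3, 3, 4, 2), dtype=np.float32)).data
        assert np.allclose(out[0, 0], out[0, 1])

    def test_patch_shape_mismatch(self):
        cfg = ModelConfig(**self.CFG)
        emb = SpatioSpectralEmbed(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="patch shape"):
            emb(np.zeros((1, 5, 5, 4, 2), dtype=np.float32))

    def test_full_model_with_patch_branch(self, rng):
        cfg = ModelConfig(**self.CFG)
        m = SITSFormer(cfg, seed=0)
        feats = rng.normal(size=(2, 6, 5)).astype(np.float32)
        patches = rng.uniform(size=(2, 3, 3, 4, 6)).astype(np.float32)
        p = m.predict_proba(feats, np.arange(160, 190, 5),
                            np.ones((2, 6)), patches)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestPhenologyGate:
    def test_gates_in_unit_interval(self, rng):
        cfg = small_config()
        gate = PhenologyGate(cfg, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 4, 16)).astype(np.float32))
        pe = Tensor(rng.normal(size=(2, 4, 16)).astype(np.float32))
        g = gate.gates(x, pe).data
        assert np.all((g > 0) & (g < 1))

    def test_disabled_gate_is_identity(self, rng):
        cfg = small_config(gate_enabled=False)
        gate = PhenologyGate(cfg, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 4, 16)).astype(np.float32))
        assert gate(x, x) is x

    def test_zeroed_weights_halve_outputs(self, rng):
        cfg = small_config()
        gate = PhenologyGate(cfg, np.random.default_rng(0))
        for p in gate.parameters():
            p.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 4, 16)).astype(np.float32))
        pe = Tensor(rng.normal(size=(2, 4, 16)).astype(np.float32))
        out = gate(x, pe).data
        assert np.allclose(out, 0.5 * x.data, atol=1e-6)


class TestTemporalMeanLogistic:
    def test_probabilities_and_masking(self, rng):
        m = TemporalMeanLogistic(5, seed=0)
        x = rng.normal(size=(3, T, 5)).astype(np.float32)
        mask = np.ones((3, T), dtype=np.float32)
        p = m.predict_proba(x, DOYS, mask)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
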